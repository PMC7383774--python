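"""Readers and writers for cine sequences and label-map sequences.

Supported containers:

* PNG frame stack + JSON sidecar — one 8-bit grayscale PNG per frame plus
  ``<stem>.json`` holding pixel spacing, frame count and (for phantom
  output) the ground-truth trajectories and labels;
* NIfTI (.nii/.nii.gz) — frames stacked on the third axis; pixel spacing
  is carried in the header zooms in mm (the cm/px value times 10);
* multi-frame DICOM (read-only) for cine input.

Pixel spacing is optional on read: a sequence without calibration loads
successfully and downstream indices are reported in px units. Label
volumes are validated against the {0, 1, 2} coding; unknown values raise
with the offending labels named.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .datatypes import CineSequence, LabelMapSequence

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# PNG stack + JSON sidecar
# --------------------------------------------------------------------------

def write_cine_png(cine: CineSequence, directory, stem: str = "frame",
                   extra_meta: dict | None = None) -> Path:
    """Write a cine as ``<stem>_0000.png ...`` plus ``<stem>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = cine.frames
    if frames.dtype != np.uint8:
        frames = np.clip(frames, 0, 255).astype(np.uint8)
    for t, frame in enumerate(frames):
        iio.imwrite(directory / f"{stem}_{t:04d}.png", frame)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_frames": cine.n_frames,
        "pixel_spacing_cm": cine.pixel_spacing,
        "coordinate_convention": "0-based (row, col), row increases downward",
    }
    if cine.frame_times is not None:
        meta["frame_times_s"] = list(map(float, cine.frame_times))
    if extra_meta:
        meta.update(extra_meta)
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_cine_png(directory, stem: str = "frame") -> CineSequence:
    directory = Path(directory)
    sidecar = directory / f"{stem}.json"
    meta = json.loads(sidecar.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema version {meta.get('schema_version')} not supported "
            f"(expected {SCHEMA_VERSION}); refusing to combine"
        )
    frames = np.stack([
        iio.imread(directory / f"{stem}_{t:04d}.png")
        for t in range(meta["n_frames"])
    ])
    times = meta.get("frame_times_s")
    return CineSequence(
        frames,
        pixel_spacing=meta.get("pixel_spacing_cm"),
        frame_times=np.asarray(times) if times is not None else None,
    )


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------

def _nifti_affine(spacing_cm: float | None) -> np.ndarray:
    mm = (spacing_cm or 0.1) * 10.0
    return np.diag([mm, mm, 1.0, 1.0])


def write_cine_nifti(cine: CineSequence, path) -> Path:
    path = Path(path)
    data = np.moveaxis(cine.frames, 0, -1)  # (H, W, T)
    img = nib.Nifti1Image(data, _nifti_affine(cine.pixel_spacing))
    if cine.pixel_spacing is not None:
        mm = cine.pixel_spacing * 10.0
        img.header.set_zooms((mm, mm, 1.0))
    nib.save(img, path)
    return path


def read_cine_nifti(path, has_spacing: bool = True) -> CineSequence:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    frames = np.moveaxis(data, -1, 0)
    spacing = float(img.header.get_zooms()[0]) / 10.0 if has_spacing else None
    return CineSequence(frames, pixel_spacing=spacing)


def write_labels_nifti(labels: LabelMapSequence, path) -> Path:
    path = Path(path)
    data = np.moveaxis(labels.masks.astype(np.uint8), 0, -1)
    img = nib.Nifti1Image(data, _nifti_affine(labels.pixel_spacing))
    if labels.pixel_spacing is not None:
        mm = labels.pixel_spacing * 10.0
        img.header.set_zooms((mm, mm, 1.0))
    nib.save(img, path)
    return path


def read_labels_nifti(path, has_spacing: bool = True) -> LabelMapSequence:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    masks = np.moveaxis(data, -1, 0)
    if not np.issubdtype(masks.dtype, np.integer):
        rounded = np.round(masks)
        if not np.allclose(masks, rounded):
            raise ValueError("label volume contains non-integer values")
        masks = rounded.astype(np.int16)
    spacing = float(img.header.get_zooms()[0]) / 10.0 if has_spacing else None
    return LabelMapSequence(masks, pixel_spacing=spacing)  # validates {0,1,2}


# --------------------------------------------------------------------------
# multi-frame DICOM (read-only)
# --------------------------------------------------------------------------

def read_cine_dicom(path) -> CineSequence:
    """Read a multi-frame grayscale DICOM; spacing from PixelSpacing (mm)."""
    import pydicom

    ds = pydicom.dcmread(Path(path))
    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[None]
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps:
        spacing = float(ps[0]) / 10.0  # mm -> cm
    return CineSequence(arr, pixel_spacing=spacing)


# --------------------------------------------------------------------------
# dispatch + case output
# --------------------------------------------------------------------------

def read_cine(path, stem: str = "frame") -> CineSequence:
    """Read a cine from NIfTI, multi-frame DICOM, or a PNG-stack directory."""
    path = Path(path)
    if path.is_dir():
        return read_cine_png(path, stem=stem)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        return read_cine_nifti(path)
    if suffixes.endswith(".dcm"):
        return read_cine_dicom(path)
    raise ValueError(f"unsupported cine container: {path}")


def read_labels(path) -> LabelMapSequence:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        return read_labels_nifti(path)
    raise ValueError(f"unsupported label container: {path}")


def write_phantom_case(case, directory) -> Path:
    """Persist a phantom case: PNG cine + truth-label NIfTI + JSON truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = {
        "case_id": case.case_id,
        "dysfunction_label": bool(case.dysfunction_label),
        "truth_ltad_cm": {k: float(v) for k, v in case.truth_ltad.items()},
        "truth_ctad_cm": {k: float(v) for k, v in case.truth_ctad.items()},
        "truth_tracks_px": {
            k: np.asarray(t.positions).tolist() for k, t in case.truth_tracks.items()
        },
    }
    write_cine_png(case.cine, directory, stem="frame", extra_meta=truth)
    write_labels_nifti(case.truth_masks, directory / "truth_labels.nii.gz")
    return directory


def write_indices_json(indices_by_case: dict, path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "cases": {cid: idx.as_dict() for cid, idx in indices_by_case.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
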