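"""End-to-end automated quantification: segmentation -> tracking -> indices.

``quantify`` is single-pass and deterministic: the same cine and the same
model weights always yield bit-identical indices (no test-time
augmentation, no stochastic inference), which is what makes repeated
automated measurements agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ANNULUS_CLASSES,
    AnnulusTrajectory,
    CineSequence,
    DisplacementIndices,
    LabelMapSequence,
)
from .indices import compute_indices
from .nn.network import ResidualUNet
from .nn.train import predict
from .preprocess import standardize
from .track import track_sequence


@dataclass
class QuantifyResult:
    indices: DisplacementIndices
    tracks: dict[str, AnnulusTrajectory]  # in source-pixel coordinates
    predicted_labels: LabelMapSequence    # in network-grid coordinates


def segment_cine(net: ResidualUNet, cine: CineSequence):
    """Standardize every frame to the network grid and segment it.

    Returns the predicted label maps plus the (scale, pad) geometry needed
    to map network-grid coordinates back to the source frame grid.
    """
    target = net.config.input_size
    frames = []
    scale, pad = None, None
    for frame in cine.frames:
        std, scale, pad = standardize(frame, target=target)
        frames.append(std.astype(np.float32))
    preds = predict(net, np.stack(frames))
    labels = LabelMapSequence(preds.astype(np.int16), pixel_spacing=None)
    return labels, scale, pad


def quantify(
    net: ResidualUNet,
    cine: CineSequence,
    smooth_window: int = 3,
    keep_largest_component: bool = False,
    max_gap: int = 3,
) -> QuantifyResult:
    """Automated displacement indices for one cine sequence.

    Tracking runs on the network grid; trajectories are then mapped back
    to the source pixel grid (undoing the standardization resample and
    padding) so that the source pixel spacing calibrates the indices.
    Indices are in cm when the cine carries pixel spacing, px otherwise.
    """
    labels, scale, pad = segment_cine(net, cine)
    tracks: dict[str, AnnulusTrajectory] = {}
    for name, cid in ANNULUS_CLASSES.items():
        traj = track_sequence(labels, cid, smooth_window, keep_largest_component)
        src_positions = (traj.positions - np.asarray(pad, dtype=float)) / scale
        tracks[name] = AnnulusTrajectory(src_positions,
                                         pixel_spacing=cine.pixel_spacing)
    idx = compute_indices(tracks["lateral"], tracks["septal"], max_gap=max_gap)
    return QuantifyResult(indices=idx, tracks=tracks, predicted_labels=labels)


def quantify_safe(
    net: ResidualUNet,
    cine: CineSequence,
    **kwargs,
) -> DisplacementIndices:
    """``quantify`` that degrades to NaN indices when tracking fails.

    A case where the segmenter never detects one of the annuli is a
    quality failure of that case, not of the batch: it is reported as
    all-NaN indices flagged ``valid=False`` so cohort-level runs carry on.
    """
    try:
        return quantify(net, cine, **kwargs).indices
    except ValueError:
        nan = float("nan")
        return DisplacementIndices(
            ltad_lateral=nan, ctad_lateral=nan,
            ltad_septal=nan, ctad_septal=nan,
            units="cm" if cine.pixel_spacing is not None else "px",
            frames_used=0, missing_fraction=1.0, valid=False,
        )
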