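"""Annulus position tracking from per-frame label maps.

The annulus position in a frame is the centre of mass (unweighted pixel
mean) of all pixels carrying that annulus label; frames with no labelled
pixel are recorded as missing rather than interpolated. The resulting
per-coordinate time series is smoothed with a running median, which
removes single-frame segmentation dropouts without flattening the
systolic excursion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import ANNULUS_CLASSES, AnnulusTrajectory, LabelMapSequence


def centroid(mask: np.ndarray, class_id: int) -> np.ndarray | None:
    """Centre of mass of all pixels equal to ``class_id``, or None if empty.

    All labelled pixels contribute — spurious disconnected blobs are not
    filtered here (see ``largest_component`` for the optional variant).
    """
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("centroid expects an integer label map")
    sel = mask == class_id
    n = sel.sum()
    if n == 0:
        return None
    rows, cols = np.nonzero(sel)
    return np.array([rows.mean(), cols.mean()])


def largest_component(mask: np.ndarray, class_id: int) -> np.ndarray:
    """Binary mask of the largest connected component of ``class_id``."""
    sel = np.asarray(mask) == class_id
    labelled, n = ndimage.label(sel)
    if n <= 1:
        return sel
    sizes = ndimage.sum_labels(sel, labelled, index=np.arange(1, n + 1))
    return labelled == (1 + int(np.argmax(sizes)))


def track_sequence(
    labels: LabelMapSequence,
    class_id: int,
    smooth_window: int = 3,
    keep_largest_component: bool = False,
) -> AnnulusTrajectory:
    """Centroid trajectory of one annulus class over a label-map sequence."""
    positions = np.full((labels.n_frames, 2), np.nan)
    for t, mask in enumerate(labels.masks):
        m = mask
        if keep_largest_component:
            comp = largest_component(mask, class_id)
            m = np.where(comp, class_id, 0).astype(mask.dtype)
        pos = centroid(m, class_id)
        if pos is not None:
            positions[t] = pos
    traj = AnnulusTrajectory(positions, pixel_spacing=labels.pixel_spacing)
    return smooth(traj, smooth_window)


def smooth(trajectory: AnnulusTrajectory, window: int = 3) -> AnnulusTrajectory:
    """Per-coordinate running median with a shrinking window at the edges.

    The window shrinks symmetrically near the sequence ends (down to a
    single sample at the first and last frame) so edge values are not
    biased toward their neighbours. Missing frames are excluded from each
    window and stay missing in the output (no motion is invented). Raises
    if every frame is missing — tracking failed outright for the case.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    pos = trajectory.positions
    if np.isnan(pos).any(axis=1).all():
        raise ValueError("all frames missing: tracking failed for this case")
    if window == 1:
        return AnnulusTrajectory(pos.copy(), trajectory.pixel_spacing)
    half = window // 2
    n = len(pos)
    out = np.full_like(pos, np.nan)
    for t in range(n):
        if np.isnan(pos[t]).any():
            continue  # missing frames stay missing
        h = min(half, t, n - 1 - t)  # keep the window centred
        win = pos[t - h:t + h + 1]
        out[t] = np.nanmedian(win, axis=0)
    return AnnulusTrajectory(out, trajectory.pixel_spacing)


def track_all(
    labels: LabelMapSequence,
    smooth_window: int = 3,
    keep_largest_component: bool = False,
) -> dict[str, AnnulusTrajectory]:
    """Tracked trajectories for both annuli, keyed 'lateral'/'septal'."""
    return {
        name: track_sequence(labels, cid, smooth_window, keep_largest_component)
        for name, cid in ANNULUS_CLASSES.items()
    }
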