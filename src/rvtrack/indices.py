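"""Linear and circumferential tricuspid annular displacement (LTAD, CTAD).

LTAD is the maximum displacement between any two positions occupied by the
annulus over the clip — the largest pairwise Euclidean distance of the
tracked positions. CTAD is the total bidirectional distance traversed —
the sum of Euclidean step lengths between consecutive tracked frames. Both
are reported in cm when pixel spacing is calibrated, otherwise in px with
an explicit unit tag; CTAD >= LTAD always (path length dominates chord).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .datatypes import AnnulusTrajectory, DisplacementIndices


def _present(trajectory: AnnulusTrajectory) -> np.ndarray:
    pts = trajectory.present
    if len(pts) < 2:
        raise ValueError(
            f"displacement indices need >= 2 tracked frames, got {len(pts)}"
        )
    return pts


def _scale(trajectory: AnnulusTrajectory) -> tuple[float, str]:
    if trajectory.pixel_spacing is None:
        return 1.0, "px"
    return trajectory.pixel_spacing, "cm"


def ltad(trajectory: AnnulusTrajectory) -> float:
    """Maximum pairwise distance between tracked positions (cm or px)."""
    pts = _present(trajectory)
    scale, _ = _scale(trajectory)
    return float(pdist(pts).max()) * scale


def ctad(trajectory: AnnulusTrajectory) -> float:
    """Total path length over consecutive tracked positions (cm or px)."""
    pts = _present(trajectory)
    scale, _ = _scale(trajectory)
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum()) * scale


def compute_indices(
    lateral: AnnulusTrajectory,
    septal: AnnulusTrajectory,
    max_gap: int = 3,
) -> DisplacementIndices:
    """Per-case displacement indices for both annuli.

    A case is flagged invalid (``valid=False``) when either trajectory has
    a run of missing frames longer than ``max_gap``: summing CTAD across a
    long gap would silently bridge unseen motion. Units are cm only when
    both trajectories carry the same calibration.
    """
    s_lat, u_lat = _scale(lateral)
    s_sep, u_sep = _scale(septal)
    if u_lat != u_sep or not np.isclose(s_lat, s_sep):
        raise ValueError("lateral and septal trajectories disagree on calibration")
    gap = max(lateral.longest_gap(), septal.longest_gap())
    miss = max(lateral.missing_fraction, septal.missing_fraction)
    frames_used = int(min((~lateral.missing).sum(), (~septal.missing).sum()))
    return DisplacementIndices(
        ltad_lateral=ltad(lateral),
        ctad_lateral=ctad(lateral),
        ltad_septal=ltad(septal),
        ctad_septal=ctad(septal),
        units=u_lat,
        frames_used=frames_used,
        missing_fraction=miss,
        valid=gap <= max_gap,
    )
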