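"""Core in-memory containers shared across the pipeline.

Coordinate convention: 0-based ``(row, col)`` with row increasing downward,
matching NumPy array indexing. Physical calibration is carried as a scalar
``pixel_spacing`` in cm/px; when it is absent, downstream displacement
indices are reported in pixel units with an explicit unit tag rather than
silently mislabelled as centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Label coding used throughout: 0 background, 1 lateral annulus, 2 septal.
BACKGROUND, LATERAL, SEPTAL = 0, 1, 2
ANNULUS_CLASSES = {"lateral": LATERAL, "septal": SEPTAL}


@dataclass
class CineSequence:
    """Time-ordered grayscale frame stack.

    Parameters
    ----------
    frames
        ``(n_frames, H, W)`` array. Phantom output is uint8 in [0, 255];
        preprocessing rescales to [0, 1] floats.
    pixel_spacing
        Isotropic pixel size in cm/px, or ``None`` when the source carried
        no calibration.
    frame_times
        Optional acquisition time of each frame in seconds.
    """

    frames: np.ndarray
    pixel_spacing: float | None = None
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got {self.frames.shape}")
        if self.pixel_spacing is not None and self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class LabelMapSequence:
    """Per-frame integer masks (0 background, 1 lateral, 2 septal)."""

    masks: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError(f"masks must be (T, H, W), got {self.masks.shape}")
        if not np.issubdtype(self.masks.dtype, np.integer):
            raise TypeError("label maps must be integer-valued")
        bad = sorted({int(v) for v in np.unique(self.masks)}
                     - {BACKGROUND, LATERAL, SEPTAL})
        if bad:
            raise ValueError(f"unknown label values {bad}; expected subset of {{0, 1, 2}}")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class AnnulusTrajectory:
    """Per-frame 2D annulus positions for one annulus class.

    ``positions`` is an ``(n_frames, 2)`` float array of (row, col) in pixel
    coordinates; frames where the annulus was not detected hold NaN and are
    flagged in ``missing``.
    """

    positions: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError(f"positions must be (T, 2), got {self.positions.shape}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of frames with no detected position."""
        return np.isnan(self.positions).any(axis=1)

    @property
    def present(self) -> np.ndarray:
        """Positions of detected frames only, in frame order, shape (k, 2)."""
        return self.positions[~self.missing]

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())

    def longest_gap(self) -> int:
        """Length of the longest run of consecutive missing frames."""
        longest = run = 0
        for m in self.missing:
            run = run + 1 if m else 0
            longest = max(longest, run)
        return longest


@dataclass
class DisplacementIndices:
    """LTAD and CTAD per annulus for one case.

    ``units`` is ``"cm"`` when pixel spacing was available and ``"px"``
    otherwise; consumers must check it before pooling across cases.
    """

    ltad_lateral: float
    ctad_lateral: float
    ltad_septal: float
    ctad_septal: float
    units: str = "cm"
    frames_used: int = 0
    missing_fraction: float = 0.0
    valid: bool = True

    def as_dict(self) -> dict:
        return {
            "ltad_lateral": self.ltad_lateral,
            "ctad_lateral": self.ctad_lateral,
            "ltad_septal": self.ltad_septal,
            "ctad_septal": self.ctad_septal,
            "units": self.units,
            "frames_used": self.frames_used,
            "missing_fraction": self.missing_fraction,
            "valid": self.valid,
        }
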