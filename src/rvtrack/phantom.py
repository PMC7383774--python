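"""Synthetic apical-view echo phantom with known annular motion.

Real apical four-chamber clips with annotated tricuspid annuli are not
redistributable, so every downstream stage (segmentation, tracking, index
computation, statistics) is exercised on a phantom: a sector-shaped,
speckled grayscale cine containing two small bright landmarks — a "lateral"
and a "septal" annulus — that descend sinusoidally along a fixed direction
with a configurable peak excursion. A static bright band emulating the
interventricular septum runs beside the septal landmark so that the two
annuli are locally distinguishable, as they are in real apical views.

The peak excursion plays the role of the true annular displacement (the
quantity TAPSE estimates clinically); because the trajectory is known in
closed form, the linear and circumferential displacement indices have exact
ground truth per case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import (
    ANNULUS_CLASSES,
    CineSequence,
    LabelMapSequence,
    AnnulusTrajectory,
)

#: Clinical annular-excursion cutoff (cm) used to label phantom cases as
#: dysfunctional when no explicit cohort rule applies.
DYSFUNCTION_EXCURSION_CM = 1.6


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(*v))
    if n == 0:
        raise ValueError("motion_direction must be nonzero")
    return v / n


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom case.

    Amplitudes are peak annular excursions in cm (the ground-truth linear
    displacement); directions are (row, col) unit vectors. ``period_frames``
    defaults to ``n_frames`` so one clip covers exactly one cardiac cycle.
    """

    image_size: int = 256
    pixel_spacing: float = 0.05  # cm/px -> 12.8 cm field of view at 256 px
    n_frames: int = 30
    lateral_amplitude: float = 2.0
    septal_amplitude: float = 1.4
    lateral_direction: tuple[float, float] = (0.940, 0.342)   # ~20 deg off-axis
    septal_direction: tuple[float, float] = (0.940, -0.342)
    period_frames: int | None = None
    speckle_snr: float = 4.0
    sector_angle: float = 75.0  # full opening angle, degrees
    label_radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.lateral_amplitude < 0 or self.septal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.label_radius < 1:
            raise ValueError("label_radius must be >= 1")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def period(self) -> int:
        return self.n_frames if self.period_frames is None else self.period_frames


@dataclass
class PhantomCase:
    """One synthetic case: cine, truth masks, truth tracks and truth indices."""

    cine: CineSequence
    truth_masks: LabelMapSequence
    truth_tracks: dict[str, AnnulusTrajectory]
    truth_ltad: dict[str, float]  # cm per annulus
    truth_ctad: dict[str, float]
    dysfunction_label: bool
    config: PhantomConfig
    case_id: str = "case"


def _sector_mask(size: int, opening_deg: float) -> np.ndarray:
    """Wedge-shaped valid-image region, apex at the top-centre."""
    apex = (2.0, size / 2.0)
    rr, cc = np.mgrid[0:size, 0:size]
    dr = rr - apex[0]
    dc = cc - apex[1]
    half = math.radians(opening_deg / 2.0)
    with np.errstate(invalid="ignore"):
        ang = np.arctan2(np.abs(dc), dr)  # 0 = straight down
    radius = np.hypot(dr, dc)
    return (dr > 0) & (ang <= half) & (radius <= 0.95 * size)


def _truth_positions(cfg: PhantomConfig, base: np.ndarray, direction: np.ndarray,
                     amplitude_px: float) -> np.ndarray:
    """Sub-pixel landmark centres over the clip (kept in floating point)."""
    t = np.arange(cfg.n_frames)
    disp = amplitude_px * (1.0 - np.cos(2.0 * np.pi * t / cfg.period)) / 2.0
    return base[None, :] + disp[:, None] * direction[None, :]


def _disk_mask(shape: tuple[int, int], center: np.ndarray, radius: int) -> np.ndarray:
    # rasterize by rounding the centre to the nearest pixel (<=0.5 px error)
    r0, c0 = np.round(center).astype(int)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2


def path_max_pairwise(track: np.ndarray) -> float:
    """Brute-force maximum pairwise Euclidean distance (ground-truth LTAD in px)."""
    d = track[:, None, :] - track[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def path_length(track: np.ndarray) -> float:
    """Sum of consecutive step lengths (ground-truth CTAD in px)."""
    steps = np.diff(track, axis=0)
    return float(np.sqrt((steps ** 2).sum(-1)).sum())


def generate_case(config: PhantomConfig, case_id: str = "case") -> PhantomCase:
    """Render one phantom cine loop with matching ground truth.

    Raises
    ------
    ValueError
        If the configured amplitude (in px) moves a landmark, including its
        circular label, outside the image or the imaging sector.
    """
    cfg = config
    size = cfg.image_size
    rng = np.random.default_rng(cfg.seed)
    sector = _sector_mask(size, cfg.sector_angle)

    bases = {
        "lateral": np.array([0.50 * size, 0.68 * size]),
        "septal": np.array([0.50 * size, 0.47 * size]),
    }
    dirs = {
        "lateral": _unit(cfg.lateral_direction),
        "septal": _unit(cfg.septal_direction),
    }
    amps_px = {
        "lateral": cfg.lateral_amplitude / cfg.pixel_spacing,
        "septal": cfg.septal_amplitude / cfg.pixel_spacing,
    }

    tracks: dict[str, np.ndarray] = {}
    for name in ("lateral", "septal"):
        pos = _truth_positions(cfg, bases[name], dirs[name], amps_px[name])
        lo = pos.min(axis=0) - cfg.label_radius
        hi = pos.max(axis=0) + cfg.label_radius
        if lo.min() < 0 or hi.max() > size - 1:
            raise ValueError(
                f"{name} annulus motion ({cfg.lateral_amplitude if name == 'lateral' else cfg.septal_amplitude} cm "
                f"= {amps_px[name]:.1f} px) leaves the {size}x{size} image; "
                "reduce the amplitude or enlarge the image"
            )
        tracks[name] = pos

    # static anatomy: smooth background + septum-like bright band
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    background = 0.28 + 0.06 * np.sin(2 * np.pi * rr / size) * np.cos(2 * np.pi * cc / size)
    septum_col = bases["septal"][1] - 2.5 * cfg.label_radius
    band = 0.30 * np.exp(-((cc - septum_col) ** 2) / (2 * (0.7 * cfg.label_radius) ** 2))
    band *= np.clip((rr - 0.15 * size) / (0.25 * size), 0.0, 1.0)
    band *= np.clip((0.85 * size - rr) / (0.15 * size), 0.0, 1.0)

    # multiplicative Rayleigh speckle with unit mean; one field per frame
    ray_scale = math.sqrt(2.0 / math.pi)
    speckle_sd = math.sqrt((4.0 - math.pi) / math.pi)  # std of unit-mean Rayleigh
    blob_amp = cfg.speckle_snr * 0.28 * speckle_sd
    blob_sigma = 0.8 * cfg.label_radius

    frames = np.empty((cfg.n_frames, size, size), dtype=np.uint8)
    masks = np.zeros((cfg.n_frames, size, size), dtype=np.uint8)
    for t in range(cfg.n_frames):
        speckle = rng.rayleigh(scale=ray_scale, size=(size, size))
        img = (background + band) * speckle
        for name in ("lateral", "septal"):
            r0, c0 = tracks[name][t]
            img += blob_amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * blob_sigma ** 2))
            disk = _disk_mask((size, size), tracks[name][t], cfg.label_radius)
            masks[t][disk] = ANNULUS_CLASSES[name]
        img *= sector
        frames[t] = np.clip(img * 255.0, 0, 255).round().astype(np.uint8)
        if not sector[masks[t] > 0].all():
            raise ValueError(f"{case_id}: annulus label leaves the imaging sector at frame {t}")

    spacing = cfg.pixel_spacing
    truth_tracks = {
        name: AnnulusTrajectory(tracks[name], pixel_spacing=spacing)
        for name in ("lateral", "septal")
    }
    truth_ltad = {n: path_max_pairwise(tracks[n]) * spacing for n in tracks}
    truth_ctad = {n: path_length(tracks[n]) * spacing for n in tracks}

    return PhantomCase(
        cine=CineSequence(frames, pixel_spacing=spacing),
        truth_masks=LabelMapSequence(masks, pixel_spacing=spacing),
        truth_tracks=truth_tracks,
        truth_ltad=truth_ltad,
        truth_ctad=truth_ctad,
        dysfunction_label=cfg.lateral_amplitude < DYSFUNCTION_EXCURSION_CM,
        config=cfg,
        case_id=case_id,
    )


def generate_cohort(
    n_cases: int,
    dysfunction_fraction: float,
    base_config: PhantomConfig | None = None,
    normal_amplitude_range: tuple[float, float] = (1.6, 2.4),
    dysfunctional_amplitude_range: tuple[float, float] = (0.8, 1.4),
    septal_fraction: float = 0.7,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a labelled cohort of phantom cases.

    The first ``floor(n_cases * dysfunction_fraction)`` case indices are
    dysfunctional (deterministic tie-break by index); their lateral
    amplitudes are drawn uniformly from the low range, normals from the
    high range, and septal amplitude is ``septal_fraction`` of lateral.
    Overlapping ranges are allowed — classification on the truth indices is
    then imperfect by design.
    """
    if not 0.0 <= dysfunction_fraction <= 1.0:
        raise ValueError("dysfunction_fraction must lie in [0, 1]")
    base = base_config if base_config is not None else PhantomConfig()
    n_dys = int(math.floor(n_cases * dysfunction_fraction))
    children = np.random.SeedSequence(seed).spawn(n_cases)
    cases = []
    for idx in range(n_cases):
        dys = idx < n_dys
        rng = np.random.default_rng(children[idx])
        lo, hi = dysfunctional_amplitude_range if dys else normal_amplitude_range
        lat = float(rng.uniform(lo, hi))
        case_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(
            base,
            lateral_amplitude=lat,
            septal_amplitude=septal_fraction * lat,
            seed=case_seed,
        )
        case = generate_case(cfg, case_id=f"case{idx:03d}")
        case.dysfunction_label = dys
        cases.append(case)
    return cases
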