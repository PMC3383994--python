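"""Forward model of agarose-gel electrophoresis and lane densitometry.

Migration distance is affine in the log of fragment size,
``d = alpha + beta * ln(size)`` with ``beta < 0`` (large fragments travel
less far).  Each fragment deposits a Gaussian band centred at its
migration distance, with total area proportional to its length in
nucleotides -- intercalating-dye staining reports DNA *mass*, not
molecule count.  Fragments above the gel's resolvable size range
co-migrate in a compression zone near the well (limiting mobility), so
their mass stays on the lane instead of leaving the modelled grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


def _default_grid() -> np.ndarray:
    return np.linspace(2.0, 130.0, 512)


@dataclass
class GelModel:
    """Gel geometry, band spread and scanner response.

    alpha, beta
        Calibration truth: migration distance at size 1 nt and distance
        per ln(nt).  Defaults place 0.5-50 kb comfortably inside the
        default grid and resolve sizes up to ~300 kb.
    band_sigma
        Gaussian band spread, in distance units, size-independent.
    background, noise_sd
        Uniform lane background and additive truncated-Gaussian scanner
        noise per grid point, in intensity units.
    mass_scale
        Intensity-area units per nucleotide of DNA (linear scanner
        response).
    limiting_distance
        Migration floor emulating the compression zone near the well;
        ``None`` means ``grid[0] + 3 * band_sigma``.
    """

    alpha: float = 120.0
    beta: float = -9.0
    band_sigma: float = 1.5
    background: float = 2.0
    noise_sd: float = 0.1
    distance_grid: np.ndarray = field(default_factory=_default_grid)
    mass_scale: float = 1e-6
    limiting_distance: float | None = None

    def __post_init__(self) -> None:
        self.distance_grid = np.asarray(self.distance_grid, dtype=float)
        if self.beta >= 0:
            raise ValueError("beta must be negative (larger fragments migrate less)")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be >= 0")
        if len(self.distance_grid) < 2 or np.any(np.diff(self.distance_grid) <= 0):
            raise ValueError("distance_grid must be strictly increasing")

    @property
    def migration_floor(self) -> float:
        if self.limiting_distance is not None:
            return self.limiting_distance
        return float(self.distance_grid[0] + 3.0 * self.band_sigma)


@dataclass
class DensitometryTrace:
    """Sampled (distance, intensity) lane profile."""

    distances: np.ndarray
    intensities: np.ndarray
    lane_label: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances.shape != self.intensities.shape:
            raise ValueError("distances and intensities must have equal length")
        if len(self.intensities) and self.intensities.min() < 0:
            raise ValueError("intensities must be non-negative")

    def integrate(self) -> float:
        """Trapezoid integral of the profile (intensity * distance units)."""
        return float(np.trapezoid(self.intensities, self.distances))


@dataclass
class LadderAnnotation:
    """Supervised (distance, size) peak identifications for a ladder lane."""

    distances: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if len(self.distances) != len(self.sizes):
            raise ValueError("distances and sizes must have equal length")
        if len(self.sizes) < 2:
            raise ValueError("at least 2 annotated peaks are required")
        order = np.argsort(self.sizes)
        if np.any(np.diff(self.distances[order]) >= 0):
            raise ValueError("distances must decrease strictly with size")


def migrate(size, gel: GelModel):
    """Ideal migration distance ``alpha + beta * ln(size)`` for size >= 1 nt."""
    size = np.asarray(size, dtype=float)
    if np.any(size < 1):
        raise ValueError("fragment size must be >= 1 nt")
    out = gel.alpha + gel.beta * np.log(size)
    return float(out) if out.ndim == 0 else out


def _deposit_bands(
    grid: np.ndarray,
    centers: np.ndarray,
    masses: np.ndarray,
    sigma: float,
    chunk: int = 4096,
) -> np.ndarray:
    """Sum Gaussian bands (unit-area scaled by mass) onto the grid."""
    out = np.zeros_like(grid)
    norm = 1.0 / (sigma * _SQRT2PI)
    for i in range(0, len(centers), chunk):
        c = centers[i : i + chunk, None]
        m = masses[i : i + chunk, None]
        out += (m * norm * np.exp(-0.5 * ((grid[None, :] - c) / sigma) ** 2)).sum(
            axis=0
        )
    return out


def _offgrid_fraction(
    grid: np.ndarray, centers: np.ndarray, masses: np.ndarray, sigma: float
) -> float:
    from scipy.stats import norm

    inside = norm.cdf((grid[-1] - centers) / sigma) - norm.cdf(
        (grid[0] - centers) / sigma
    )
    total = masses.sum()
    return float(1.0 - (masses * inside).sum() / total) if total > 0 else 0.0


def render_trace(fragments, gel: GelModel, seed: int, lane_label: str = "") -> DensitometryTrace:
    """Render a fragment set as a noisy densitometry trace.

    Each fragment of length ``L`` contributes a Gaussian band at
    ``max(migrate(L), migration_floor)`` with area ``mass_scale * L``;
    the floor keeps mass from unresolvably large fragments on the lane,
    piled in the compression zone.  Background and clipped Gaussian noise
    are added on top.
    """
    grid = gel.distance_grid
    lengths, counts = np.unique(np.asarray(fragments.lengths), return_counts=True)
    if len(lengths):
        centers = np.maximum(migrate(lengths, gel), gel.migration_floor)
        masses = gel.mass_scale * lengths * counts
        signal = _deposit_bands(grid, centers, masses, gel.band_sigma)
        lost = _offgrid_fraction(grid, centers, masses, gel.band_sigma)
        if lost > 1e-3:
            warnings.warn(
                f"{lost:.1%} of fragment mass migrates outside the distance grid",
                stacklevel=2,
            )
    else:
        signal = np.zeros_like(grid)
    intens = signal + gel.background
    if gel.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, gel.noise_sd, size=len(grid))
    intens = np.clip(intens, 0.0, None)
    return DensitometryTrace(grid.copy(), intens, lane_label=lane_label)


def render_ladder(
    sizes, gel: GelModel, lane_label: str = "ladder"
) -> tuple[DensitometryTrace, LadderAnnotation]:
    """Render a size-standard lane with sharp equal-mass bands.

    Ladder bands are tight (``band_sigma / 4``), and the returned
    annotation records the true (distance, size) pairs, emulating
    supervised peak identification on the reference lane.
    """
    sizes = np.asarray(sizes, dtype=float)
    uniq = np.unique(sizes)
    if len(uniq) < len(sizes):
        warnings.warn("duplicate ladder sizes collapsed", stacklevel=2)
    if len(uniq) < 2:
        raise ValueError("at least 2 distinct ladder sizes are required")
    grid = gel.distance_grid
    centers = migrate(uniq, gel)
    masses = np.ones_like(uniq)  # equal mass per band, arbitrary units
    signal = _deposit_bands(grid, centers, masses, gel.band_sigma / 4.0)
    trace = DensitometryTrace(
        grid.copy(), np.clip(signal + gel.background, 0.0, None), lane_label
    )
    annotation = LadderAnnotation(distances=centers, sizes=uniq)
    return trace, annotation
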