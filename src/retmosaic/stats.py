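"""Distributional statistics of a mosaic field.

Covers the classical regularity toolkit for retinal mosaics:

* nearest-neighbor distance (NND) histograms,
* single-Gaussian fits to those histograms,
* the analytic nearest-neighbor density of a Poisson point process with the
  same spatial density (the "expected random distribution"),
* regularity indices (mean / s.d. of NNDs or Dirichlet-domain areas),
* the density recovery profile (DRP) from the 2-D point autocorrelogram,
* a deterministic histogram-vs-reference deviation record.

For an unconstrained Poisson process of intensity λ the nearest-neighbor
distance has density ``P(r) = 2πλ r exp(-λπr²)`` (a Rayleigh density with
scale 1/sqrt(2πλ)); its mean is ``1/(2√λ)`` and its regularity index is the
constant ``sqrt(π/(4-π)) ≈ 1.913``.  Regular mosaics have higher indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .geometry import MosaicField, circle_fraction_in_window

__all__ = [
    "NNDHistogram",
    "GaussianFitResult",
    "PoissonReference",
    "RegularityResult",
    "DRProfile",
    "ComparisonRecord",
    "POISSON_NND_RI",
    "nnd_histogram",
    "fit_gaussian",
    "poisson_nnd_pdf",
    "regularity_index",
    "density_recovery_profile",
    "compare_histogram_to_reference",
]

#: regularity index of an unconstrained Poisson point pattern, sqrt(pi/(4-pi))
POISSON_NND_RI = float(np.sqrt(np.pi / (4.0 - np.pi)))


@dataclass
class NNDHistogram:
    """Histogram of nearest-neighbor distances on half-open bins from 0.

    ``scale_mode`` is ``"counts"`` (Σ counts = n) for single fields or
    ``"per_micrometer"`` (Σ counts·Δ = n) for trial-averaged ensembles
    rescaled for direct comparison with n·P(r).
    """

    bin_width: float
    bin_left_edges: np.ndarray
    counts: np.ndarray
    n: int
    scale_mode: str = "counts"

    def __post_init__(self) -> None:
        self.bin_left_edges = np.asarray(self.bin_left_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.scale_mode not in ("counts", "per_micrometer"):
            raise ValueError("scale_mode must be 'counts' or 'per_micrometer'")

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_left_edges + self.bin_width / 2.0

    def as_per_micrometer(self) -> "NNDHistogram":
        if self.scale_mode == "per_micrometer":
            return self
        return NNDHistogram(
            bin_width=self.bin_width,
            bin_left_edges=self.bin_left_edges.copy(),
            counts=self.counts / self.bin_width,
            n=self.n,
            scale_mode="per_micrometer",
        )


@dataclass
class GaussianFitResult:
    """Parameters of y(x) = y0 + A·exp(−((x−x0)/w)²) with y0 fixed at 0.

    ``w`` is the Gaussian width parameter, related to the standard deviation
    by w = √2 · s.d.
    """

    amplitude_A: float
    x0: float
    w: float
    r_squared: float
    y0: float = 0.0

    @property
    def sd(self) -> float:
        return self.w / np.sqrt(2.0)


@dataclass
class PoissonReference:
    """Analytic NND density of a Poisson pattern with intensity λ = n/A."""

    lambda_density: float
    n: int
    r_grid: np.ndarray
    pdf: np.ndarray
    scaled: np.ndarray

    def cdf(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return 1.0 - np.exp(-self.lambda_density * np.pi * r**2)


@dataclass
class RegularityResult:
    statistic: str
    mean: float
    sd: float
    regularity_index: float
    n: int


@dataclass
class DRProfile:
    """Density recovery profile: annulus-binned autocorrelation density."""

    annulus_width: float
    radii: np.ndarray
    density_estimate: np.ndarray  # cells / mm² per annulus
    effective_radius: float
    mean_density: float  # cells / mm²


@dataclass
class ComparisonRecord:
    """Deterministic deviation of a histogram from a Poisson reference."""

    max_abs_deviation: float
    integrated_abs_deviation: float


def nnd_histogram(distances, bin_width: float = 1.0) -> NNDHistogram:
    """Bin distances into half-open bins [kΔ, (k+1)Δ) starting at 0."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("distances must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # one bin past the maximum so the last value sits in a half-open bin
    n_bins = int(np.floor(distances.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(distances, bins=edges)
    return NNDHistogram(
        bin_width=float(bin_width),
        bin_left_edges=edges[:-1],
        counts=counts,
        n=int(distances.size),
        scale_mode="counts",
    )


def _gauss(x, A, x0, w):
    return A * np.exp(-(((x - x0) / w) ** 2))


def fit_gaussian(histogram: NNDHistogram, max_restarts: int = 5) -> GaussianFitResult:
    """Unweighted least-squares Gaussian fit to bin-center/count pairs.

    The baseline y0 is fixed at 0.  Initialisation: x0 at the histogram mode,
    A at the peak count, w at √2 × the histogram's weighted s.d.; up to
    ``max_restarts`` perturbed restarts before raising.
    """
    x = histogram.bin_centers
    y = histogram.counts.astype(float)
    if np.count_nonzero(y) < 4:
        raise ValueError("need at least 4 non-empty bins to fit a Gaussian")
    total = y.sum()
    mean = float((x * y).sum() / total)
    var = float(((x - mean) ** 2 * y).sum() / total)
    sd0 = max(np.sqrt(var), histogram.bin_width / 2.0)
    p0 = np.array([float(y.max()), float(x[np.argmax(y)]), np.sqrt(2.0) * sd0])

    rng = np.random.default_rng(0)
    last_err: Optional[Exception] = None
    for attempt in range(max_restarts + 1):
        init = p0 if attempt == 0 else p0 * rng.uniform(0.7, 1.3, size=3)
        try:
            popt, _ = curve_fit(_gauss, x, y, p0=init, maxfev=20000)
            A, x0, w = float(popt[0]), float(popt[1]), abs(float(popt[2]))
            if A <= 0 or w <= 0:
                raise RuntimeError("non-positive amplitude or width")
            resid = y - _gauss(x, A, x0, w)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
            return GaussianFitResult(amplitude_A=A, x0=x0, w=w, r_squared=r2)
        except (RuntimeError, ValueError) as err:
            last_err = err
    raise RuntimeError(
        f"Gaussian fit did not converge after {max_restarts} restarts "
        f"(initial values A={p0[0]:.4g}, x0={p0[1]:.4g}, w={p0[2]:.4g}): {last_err}"
    )


def poisson_nnd_pdf(lambda_density: float, r_grid, n: int) -> PoissonReference:
    """Analytic NND density P(r) = 2πλ r exp(−λπr²) and its n-scaled form."""
    if lambda_density <= 0:
        raise ValueError("lambda_density must be positive")
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.size < 2 or np.any(np.diff(r) <= 0) or r[0] < 0:
        raise ValueError("r_grid must be 1-D, increasing and non-negative")
    pdf = 2.0 * np.pi * lambda_density * r * np.exp(-lambda_density * np.pi * r**2)
    return PoissonReference(
        lambda_density=float(lambda_density),
        n=int(n),
        r_grid=r,
        pdf=pdf,
        scaled=n * pdf,
    )


def regularity_index(values, statistic: str = "nnd") -> RegularityResult:
    """Mean / sample s.d. of the values (the mosaic regularity index)."""
    if statistic not in ("nnd", "dirichlet_area"):
        raise ValueError("statistic must be 'nnd' or 'dirichlet_area'")
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("at least two values required")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate distribution: all values identical (sd = 0)")
    return RegularityResult(
        statistic=statistic,
        mean=mean,
        sd=sd,
        regularity_index=mean / sd,
        n=int(values.size),
    )


def density_recovery_profile(
    field: MosaicField, annulus_width: float = 2.0, max_radius: float = 50.0
) -> DRProfile:
    """DRP from the 2-D point autocorrelogram with analytic edge correction.

    For every ordered cell pair (i, j) the separation is binned into annuli of
    width Δr around the reference cell i; each pair is weighted by the inverse
    of the fraction of the circle of radius dᵢⱼ centred on i that lies inside
    the window.  The effective radius summarises the exclusion zone near the
    origin via the cumulative density deficit relative to the mean density.
    """
    if field.n < 2:
        raise ValueError("at least two cells required")
    if annulus_width <= 0:
        raise ValueError("annulus_width must be positive")
    half_short = min(field.window.side_x, field.window.side_y) / 2.0
    if max_radius > half_short:
        raise ValueError(
            f"max_radius must not exceed half the shorter window side ({half_short:g} um)"
        )

    pts = field.points
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=max_radius, output_type="ndarray")
    n_bins = int(np.ceil(max_radius / annulus_width))
    edges = np.arange(n_bins + 1) * annulus_width
    weighted = np.zeros(n_bins)
    if pairs.size:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])  # ordered pairs
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        d = np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
        frac = circle_fraction_in_window(pts[i, 0], pts[i, 1], d, field.window)
        k = np.minimum((d / annulus_width).astype(int), n_bins - 1)
        np.add.at(weighted, k, 1.0 / frac)

    annulus_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)  # μm²
    dens_um2 = weighted / (field.n * annulus_area)
    lam = field.n / field.window.area  # μm⁻²

    # cumulative-deficit effective radius: sum the density shortfall from the
    # origin until the profile first reaches the mean density
    deficit = 0.0
    for k in range(n_bins):
        if dens_um2[k] >= lam:
            break
        deficit += (lam - dens_um2[k]) * annulus_area[k]
    effective_radius = float(np.sqrt(deficit / (np.pi * lam)))

    return DRProfile(
        annulus_width=float(annulus_width),
        radii=(edges[:-1] + edges[1:]) / 2.0,
        density_estimate=dens_um2 * 1e6,
        effective_radius=effective_radius,
        mean_density=lam * 1e6,
    )


def compare_histogram_to_reference(
    histogram: NNDHistogram, reference: PoissonReference
) -> ComparisonRecord:
    """Max-absolute and integrated absolute deviation, per-μm scale.

    The histogram is converted to per-μm densities and the n-scaled reference
    is evaluated at the bin centers; no p-value is claimed.
    """
    h = histogram.as_per_micrometer()
    centers = h.bin_centers
    r = reference.r_grid
    if r[0] > centers[0] or r[-1] < centers[-1]:
        raise ValueError(
            "incompatible bin structure: reference grid does not span the histogram support"
        )
    ref_vals = np.interp(centers, r, reference.scaled)
    diff = np.abs(h.counts - ref_vals)
    return ComparisonRecord(
        max_abs_deviation=float(diff.max()),
        integrated_abs_deviation=float(diff.sum() * h.bin_width),
    )
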