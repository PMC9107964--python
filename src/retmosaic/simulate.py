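"""Hard-core random mosaic simulator.

Generates random mosaics matched for density and constrained by soma size:
cell bodies are circles whose diameters are drawn from a Gaussian, placed one
at a time at uniform random positions inside the acquisition window and
rejected whenever they would overlap an already-placed cell (random
sequential addition).  Touching is allowed, overlap is not.  Setting
``point_mode`` drops the size constraint entirely and yields an unconstrained
binomial (Poisson-like) point pattern — the null against which the analytic
reference is exact.

The central scientific use is the matched-randomness experiment: simulate a
random mosaic with the *observed* cell count and soma-diameter distribution
of a real field and ask whether its nearest-neighbor statistics can be told
apart from the real ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    MosaicField,
    Window,
    dirichlet_domains,
    nearest_neighbor_distances,
)
from .stats import NNDHistogram, PoissonReference, poisson_nnd_pdf, regularity_index

__all__ = [
    "SimConfig",
    "SimEnsemble",
    "PackingError",
    "simulate_field",
    "run_ensemble",
    "sweep_scaling",
    "apparent_diameter",
    "trial_seed_sequence",
]


class PackingError(RuntimeError):
    """Raised when a cell cannot be placed within the attempt budget."""

    def __init__(self, cells_placed: int, n_requested: int, max_attempts: int):
        self.cells_placed = cells_placed
        self.n_requested = n_requested
        super().__init__(
            f"packing failure: placed {cells_placed} of {n_requested} cells "
            f"(no admissible position within {max_attempts} attempts)"
        )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a hard-core random mosaic ensemble.

    ``density_factor`` scales the number of cells placed and
    ``diameter_factor`` scales both the diameter mean and s.d. — the two
    knobs of the robustness sweeps.  ``point_mode`` treats cells as points
    (diameter 0).
    """

    window: Window = dc_field(default_factory=Window)
    n_cells: int = 292
    diameter_mean: float = 9.01
    diameter_sd: float = 0.39
    density_factor: float = 1.0
    diameter_factor: float = 1.0
    point_mode: bool = False
    trials: int = 100
    seed: int = 0
    max_attempts_per_cell: int = 10_000
    bin_width: float = 0.25

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.diameter_mean < 0 or self.diameter_sd < 0:
            raise ValueError("diameter mean and sd must be non-negative")
        for name in ("density_factor", "diameter_factor"):
            f = getattr(self, name)
            if not 0 < f <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")

    @property
    def n_placed(self) -> int:
        return int(round(self.n_cells * self.density_factor))


@dataclass
class SimEnsemble:
    """Multi-trial output of the simulator plus its paired Poisson reference."""

    config: SimConfig
    fields: List[MosaicField]
    averaged_histogram: NNDHistogram
    reference: PoissonReference
    summary: pd.DataFrame  # one row per trial


def trial_seed_sequence(master_seed: int, trial: int) -> np.random.SeedSequence:
    """Deterministic per-trial seed: SeedSequence((master_seed, trial))."""
    return np.random.SeedSequence((int(master_seed), int(trial)))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One N(mean, sd) draw truncated to > 0 by resampling."""
    if sd == 0.0:
        if mean <= 0:
            raise ValueError("degenerate diameter distribution at <= 0")
        return mean
    while True:
        d = rng.normal(mean, sd)
        if d > 0:
            return d


def simulate_field(config: SimConfig, trial_seed=None) -> MosaicField:
    """One random-sequential-addition hard-core mosaic.

    Centers are uniform in the window (discs may protrude past the edge);
    each placement cycle draws a fresh diameter, then redraws the position
    until the disc overlaps no placed cell (center distance ≥ mean of the two
    diameters, with a 1e-9 μm touching tolerance).
    """
    if trial_seed is None:
        trial_seed = config.seed
    rng = np.random.default_rng(trial_seed)
    n = config.n_placed
    w = config.window
    dm = config.diameter_mean * config.diameter_factor
    ds = config.diameter_sd * config.diameter_factor

    if config.point_mode or dm == 0.0:
        # no interaction: every placement is accepted, so drawing all
        # positions at once is distributionally identical and much faster
        xs = rng.uniform(w.x_min, w.x_max, size=n)
        ys = rng.uniform(w.y_min, w.y_max, size=n)
        diam = np.zeros(n)
    else:
        xs = np.empty(n)
        ys = np.empty(n)
        radii = np.empty(n)
        for i in range(n):
            d = _positive_normal(rng, dm, ds)
            r = d / 2.0
            placed = False
            for _ in range(config.max_attempts_per_cell):
                px = rng.uniform(w.x_min, w.x_max)
                py = rng.uniform(w.y_min, w.y_max)
                if i == 0:
                    placed = True
                    break
                contact = radii[:i] + r - 1e-9
                dsq = (xs[:i] - px) ** 2 + (ys[:i] - py) ** 2
                if np.all(dsq >= contact * contact):
                    placed = True
                    break
            if not placed:
                raise PackingError(i, n, config.max_attempts_per_cell)
            xs[i], ys[i], radii[i] = px, py, r
        diam = 2.0 * radii

    return MosaicField(
        x=xs,
        y=ys,
        window=w,
        field_id="sim",
        diameter=diam,
        edge_included=np.zeros(n, dtype=bool),
    )


def _reference_grid(lam: float, r_max: float, step: float) -> np.ndarray:
    # extend to where the Poisson NND survival drops below 1e-12
    r_tail = float(np.sqrt(-np.log(1e-12) / (lam * np.pi)))
    return np.arange(0.0, max(r_max, r_tail) + step, step)


def run_ensemble(config: SimConfig, include_tessellation: bool = True) -> SimEnsemble:
    """Simulate ``config.trials`` fields and average their NND histograms.

    Per-trial seeds are ``SeedSequence((config.seed, trial))`` so every trial
    is reproducible in isolation.  The averaged histogram is rescaled to
    per-μm densities (counts averaged across trials, divided by the bin
    width) for direct comparison with the n-scaled Poisson reference at
    λ = placed_n / window area.
    """
    fields: List[MosaicField] = []
    nnds: List[np.ndarray] = []
    rows = []
    for t in range(config.trials):
        try:
            f = simulate_field(config, trial_seed_sequence(config.seed, t))
        except PackingError as err:
            raise PackingError(err.cells_placed, err.n_requested,
                               config.max_attempts_per_cell) from err
        fields.append(f)
        nnd = nearest_neighbor_distances(f) if f.n >= 2 else np.array([])
        nnds.append(nnd)
        row = {"trial": t}
        if nnd.size >= 2:
            ri = regularity_index(nnd, "nnd")
            row.update(
                nnd_mean=ri.mean,
                nnd_sd=ri.sd,
                nnd_ri=ri.regularity_index,
                nnd_min=float(nnd.min()),
            )
        if include_tessellation and f.n >= 3:
            tess = dirichlet_domains(f)
            interior = tess.interior
            row["interior_neighbor_mean"] = (
                float(tess.neighbor_count[interior].mean()) if interior.any() else np.nan
            )
        rows.append(row)

    n_placed = config.n_placed
    all_nnd = np.concatenate(nnds) if nnds else np.array([])
    r_max = float(all_nnd.max()) if all_nnd.size else config.bin_width
    n_bins = int(np.floor(r_max / config.bin_width)) + 1
    edges = np.arange(n_bins + 1) * config.bin_width
    counts = np.zeros(n_bins)
    for nnd in nnds:
        c, _ = np.histogram(nnd, bins=edges)
        counts += c
    counts /= max(config.trials, 1)

    averaged = NNDHistogram(
        bin_width=config.bin_width,
        bin_left_edges=edges[:-1],
        counts=counts / config.bin_width,
        n=n_placed,
        scale_mode="per_micrometer",
    )
    lam = n_placed / config.window.area
    reference = poisson_nnd_pdf(
        lam, _reference_grid(lam, edges[-1], config.bin_width / 4.0), n_placed
    )
    return SimEnsemble(
        config=config,
        fields=fields,
        averaged_histogram=averaged,
        reference=reference,
        summary=pd.DataFrame(rows),
    )


def sweep_scaling(
    base_config: SimConfig,
    vary: str,
    factors: Sequence[float] = (1.0, 0.75, 0.5, 0.25),
    include_tessellation: bool = False,
) -> List[SimEnsemble]:
    """One ensemble per scaling factor of density or diameter.

    Density sweeps change the paired reference's λ in proportion; diameter
    sweeps keep λ fixed.  All ensembles share the base seed policy, so the
    factor-1.0 ensemble is identical to ``run_ensemble(base_config)``.
    """
    if vary not in ("density", "diameter"):
        raise ValueError("vary must be 'density' or 'diameter'")
    factors = list(factors)
    if len(set(factors)) != len(factors) or not all(0 < f <= 1 for f in factors):
        raise ValueError("factors must be distinct values in (0, 1]")
    key = "density_factor" if vary == "density" else "diameter_factor"
    return [
        run_ensemble(
            dataclasses.replace(base_config, **{key: f}),
            include_tessellation=include_tessellation,
        )
        for f in factors
    ]


def apparent_diameter(cross_section_area) -> np.ndarray | float:
    """Diameter of the circle with the same area: d = 2·√(area/π)."""
    area = np.asarray(cross_section_area, dtype=float)
    if np.any(area < 0):
        raise ValueError("cross-sectional area must be non-negative")
    d = 2.0 * np.sqrt(area / np.pi)
    return float(d) if d.ndim == 0 else d
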