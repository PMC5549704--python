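"""3-D lattice model of competitive microbial proliferation.

The model grows a microbial community layer by layer on an ``lx × ly × lz``
lattice with periodic boundaries in x and y.  The bottom layer (z = 0) is
seeded with ``n_initial_species`` species; every site of each subsequent
layer is filled either by copying one of the nine lower-layer neighbours
(the Moore-below neighbourhood) with probability ``p``, or by a brand-new
immigrant species with probability ``1 − p``.  Because already-abundant
species occupy more neighbour slots, the copy step implements a
"rich get richer" amplification of stochastic growth fluctuations, which
is what shapes the heavy-tailed abundance distributions this package
analyses.

Species may carry unequal growth weights: a neighbour site is then chosen
with probability proportional to the weight of the species occupying it,
which models communities where some strains proliferate faster (e.g. under
antibiotic pressure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "LatticeConfig",
    "Layer",
    "AbundanceProfile",
    "ReadSample",
    "EnsembleSummary",
    "SpeciesIdAllocator",
    "init_bottom_layer",
    "grow_layer",
    "run_simulation",
    "sample_reads",
    "simulate_ensemble",
]

InitMode = Literal["random_iid", "equal_tiling"]
Readout = Literal["whole", "top"]


@dataclass
class LatticeConfig:
    """Parameters of one lattice simulation.

    Parameters
    ----------
    lx, ly
        Cross-section of the lattice (sites per layer = ``lx * ly``).
    lz
        Number of layers, including the seeded bottom layer.
    p
        Copy probability.  A site copies a lower-layer neighbour with
        probability ``p`` and receives a new immigrant species with
        probability ``1 - p``.
    n_initial_species
        Number of species N(0) seeded on the bottom layer.
    init_mode
        ``"random_iid"`` assigns each bottom-layer site an independent
        uniform draw from the N(0) species (spatially uneven by chance);
        ``"equal_tiling"`` lays the species out in contiguous blocks of
        equal size (counts differ by at most one).
    growth_weights
        Optional map species-id -> positive weight used when copying:
        a neighbour site is selected with probability proportional to the
        weight of the species sitting on it.  Unlisted species get 1.0.
    immigrant_weight
        Growth weight assigned to every immigrant species.
    seed
        Root RNG seed; replicate streams are spawned from it.
    """

    lx: int = 40
    ly: int = 40
    lz: int = 2000
    p: float = 1.0
    n_initial_species: int = 200
    init_mode: InitMode = "random_iid"
    growth_weights: Mapping[int, float] | None = None
    immigrant_weight: float = 1.0
    seed: int | None = None

    @property
    def sites_per_layer(self) -> int:
        return self.lx * self.ly

    @property
    def total_sites(self) -> int:
        return self.lx * self.ly * self.lz

    def validate(self) -> None:
        if self.lx < 1 or self.ly < 1:
            raise ValueError("lattice cross-section must be at least 1x1")
        if self.lz < 2:
            raise ValueError("lz must be >= 2 (bottom layer plus growth)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"copy probability p={self.p} outside [0, 1]")
        if self.n_initial_species < 1:
            raise ValueError("n_initial_species must be positive")
        if self.init_mode not in ("random_iid", "equal_tiling"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if (
            self.init_mode == "equal_tiling"
            and self.n_initial_species > self.sites_per_layer
        ):
            raise ValueError(
                "equal_tiling requires n_initial_species <= lx*ly "
                f"({self.n_initial_species} > {self.sites_per_layer})"
            )
        if self.immigrant_weight <= 0:
            raise ValueError("immigrant_weight must be positive")
        if self.growth_weights is not None:
            for sp, w in self.growth_weights.items():
                if w <= 0:
                    raise ValueError(f"growth weight for species {sp} must be > 0")

    def has_uniform_weights(self) -> bool:
        """True when every species (incl. immigrants) shares one weight."""
        if not self.growth_weights:
            return self.immigrant_weight == 1.0
        vals = set(self.growth_weights.values())
        return len(vals) == 1 and vals == {1.0} and self.immigrant_weight == 1.0


@dataclass
class Layer:
    """One fully occupied lattice layer: an lx × ly grid of species ids."""

    grid: np.ndarray
    z_index: int


class SpeciesIdAllocator:
    """Hands out strictly increasing immigrant species ids.

    Initial species take ids ``0 .. N(0)-1``; immigrants continue from
    ``N(0)`` in order of arrival, so an id never collides with an earlier
    one and the number of immigrant species equals the number of
    immigration events.
    """

    def __init__(self, n_initial_species: int):
        self.n_initial_species = int(n_initial_species)
        self.next_id = int(n_initial_species)

    @property
    def n_immigrants(self) -> int:
        return self.next_id - self.n_initial_species

    def allocate(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        return ids


def init_bottom_layer(config: LatticeConfig, rng: np.random.Generator) -> Layer:
    """Seed the z = 0 layer according to ``config.init_mode``."""
    config.validate()
    n0 = config.n_initial_species
    sites = config.sites_per_layer
    if config.init_mode == "random_iid":
        grid = rng.integers(0, n0, size=(config.lx, config.ly), dtype=np.int64)
    else:  # equal_tiling
        base, extra = divmod(sites, n0)
        flat = np.repeat(np.arange(n0, dtype=np.int64), base)
        # the first `extra` species get one extra site so counts differ by <= 1
        flat = np.concatenate([flat, np.arange(extra, dtype=np.int64)])
        flat.sort()  # contiguous runs per species
        grid = flat.reshape(config.lx, config.ly)
    return Layer(grid=grid, z_index=0)


def _neighbor_stack(grid: np.ndarray) -> np.ndarray:
    """The 9 periodic-shifted copies of ``grid``: stack[k, x, y] is the
    species at lower-layer neighbour (x+dx, y+dy) for offset k."""
    shifts = [
        np.roll(np.roll(grid, -dx, axis=0), -dy, axis=1)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
    ]
    return np.stack(shifts)


def _grow_uniform(
    grid: np.ndarray, p: float, allocator: SpeciesIdAllocator, rng: np.random.Generator
) -> np.ndarray:
    """One growth step with equal weights: each upper site copies a
    uniformly chosen lower neighbour, or immigrates with prob 1-p."""
    lx, ly = grid.shape
    k = rng.integers(0, 9, size=(lx, ly))
    dx = k // 3 - 1
    dy = k % 3 - 1
    xi = (np.arange(lx)[:, None] + dx) % lx
    yi = (np.arange(ly)[None, :] + dy) % ly
    new = grid[xi, yi]
    if p < 1.0:
        imm = rng.random((lx, ly)) >= p
        n_imm = int(imm.sum())
        if n_imm:
            new[imm] = allocator.allocate(n_imm)
    return new


def _grow_weighted(
    grid: np.ndarray,
    p: float,
    wlut: "_WeightTable",
    allocator: SpeciesIdAllocator,
    rng: np.random.Generator,
) -> np.ndarray:
    """One growth step with species-dependent weights: neighbour j among
    the 9 is chosen with probability w(species at j) / sum_k w(species at k)."""
    nb = _neighbor_stack(grid)
    w = wlut.lookup(nb)
    cum = np.cumsum(w, axis=0)
    u = rng.random(grid.shape) * cum[-1]
    choice = (cum <= u[None, :, :]).sum(axis=0)
    choice = np.minimum(choice, 8)  # guard against u == cum[-1] round-off
    new = np.take_along_axis(nb, choice[None, :, :], axis=0)[0]
    if p < 1.0:
        imm = rng.random(grid.shape) >= p
        n_imm = int(imm.sum())
        if n_imm:
            new[imm] = allocator.allocate(n_imm)
    return new


class _WeightTable:
    """Growth-weight lookup by species id, growing as immigrants arrive."""

    def __init__(self, config: LatticeConfig, capacity: int):
        n0 = config.n_initial_species
        cap = max(capacity, n0 + 1)
        self._w = np.full(cap, config.immigrant_weight, dtype=np.float64)
        self._w[:n0] = 1.0
        if config.growth_weights:
            for sp, wt in config.growth_weights.items():
                if 0 <= sp < n0:
                    self._w[sp] = wt
        self._immigrant_weight = config.immigrant_weight

    def lookup(self, ids: np.ndarray) -> np.ndarray:
        top = int(ids.max()) + 1
        if top > len(self._w):
            extra = np.full(
                max(top - len(self._w), len(self._w)),
                self._immigrant_weight,
                dtype=np.float64,
            )
            self._w = np.concatenate([self._w, extra])
        return self._w[ids]


def grow_layer(
    lower: Layer,
    config: LatticeConfig,
    id_allocator: SpeciesIdAllocator,
    rng: np.random.Generator,
) -> Layer:
    """Grow the next layer on top of ``lower``.

    Each new site independently copies the species of one of its nine
    lower-layer neighbours (weight-proportionally) with probability ``p``,
    or receives a freshly allocated immigrant id with probability ``1-p``.
    Sites within a layer never interact, so the update is order-free.
    """
    if config.has_uniform_weights():
        new = _grow_uniform(lower.grid, config.p, id_allocator, rng)
    else:
        wlut = _WeightTable(config, id_allocator.next_id + config.sites_per_layer)
        new = _grow_weighted(lower.grid, config.p, wlut, id_allocator, rng)
    return Layer(grid=new, z_index=lower.z_index + 1)


@dataclass
class AbundanceProfile:
    """Species abundances read out from a finished simulation.

    ``species[i]`` has ``counts[i]`` occupied sites; only present species
    are listed, so all counts are >= 1 and ``counts.sum() == total_sites``
    (for the whole-lattice readout).
    """

    species: np.ndarray
    counts: np.ndarray
    total_sites: int
    n_immigrant_species: int = 0

    @classmethod
    def from_tally(
        cls, tally: np.ndarray, n_initial_species: int, total_sites: int | None = None
    ) -> "AbundanceProfile":
        species = np.nonzero(tally)[0].astype(np.int64)
        counts = tally[species].astype(np.int64)
        n_imm = int((species >= n_initial_species).sum())
        total = int(tally.sum()) if total_sites is None else total_sites
        return cls(species, counts, total, n_imm)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self.species.tolist(), self.counts.tolist()))

    def relative_abundances(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class ReadSample:
    """A sequencing-depth-limited view of a community: ``depth`` reads
    drawn multinomially from the abundance profile."""

    species: np.ndarray
    counts: np.ndarray
    depth: int

    @property
    def richness(self) -> int:
        return len(self.species)

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self.species.tolist(), self.counts.tolist()))

    def relative_abundances(self) -> np.ndarray:
        return self.counts / self.depth


def run_simulation(
    config: LatticeConfig,
    rng: np.random.Generator | None = None,
    readout: Readout = "whole",
) -> AbundanceProfile:
    """Run one full lattice simulation and tally species abundances.

    With ``readout="whole"`` (default) abundances are counted over all
    ``lx*ly*lz`` sites; ``readout="top"`` counts only the final layer.
    Only two layers are ever materialised; tallies are streamed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n0 = config.n_initial_species
    allocator = SpeciesIdAllocator(n0)
    uniform = config.has_uniform_weights()
    wlut = None if uniform else _WeightTable(config, n0 + config.sites_per_layer)

    grid = init_bottom_layer(config, rng).grid
    tally = np.bincount(grid.ravel(), minlength=n0).astype(np.int64)
    for _ in range(1, config.lz):
        if uniform:
            grid = _grow_uniform(grid, config.p, allocator, rng)
        else:
            grid = _grow_weighted(grid, config.p, wlut, allocator, rng)
        if readout == "whole":
            counts = np.bincount(grid.ravel(), minlength=len(tally))
            if len(counts) > len(tally):
                tally = np.pad(tally, (0, len(counts) - len(tally)))
            tally += counts
    if readout == "top":
        tally = np.bincount(grid.ravel(), minlength=allocator.next_id).astype(np.int64)
        total_sites = config.sites_per_layer
    else:
        total_sites = config.total_sites
    profile = AbundanceProfile.from_tally(tally, n0, total_sites)
    profile.n_immigrant_species = allocator.n_immigrants
    return profile


def sample_reads(
    profile: AbundanceProfile,
    depth: int = 2500,
    rng: np.random.Generator | None = None,
) -> ReadSample:
    """Draw ``depth`` reads multinomially, with per-species probabilities
    proportional to abundance.  Mirrors the rarefied 16S pipeline output
    the analysis side of the package expects (2,500 reads per sample)."""
    if profile.n_species == 0 or profile.counts.sum() <= 0:
        raise ValueError("cannot sample reads from an empty abundance profile")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pvals = profile.counts / profile.counts.sum()
    draws = rng.multinomial(depth, pvals)
    keep = draws > 0
    return ReadSample(
        species=profile.species[keep], counts=draws[keep].astype(np.int64), depth=depth
    )


@dataclass
class EnsembleSummary:
    """Per-replicate richness and fitted CRAD exponent for an ensemble.

    ``per_rep_beta`` holds NaN where a replicate's fit was excluded
    (too few window points, or goodness-of-fit rejection); such
    replicates are counted in ``n_excluded`` and omitted from
    ``mean_beta``.
    """

    n_reps: int
    per_rep_richness: list[int] = field(default_factory=list)
    per_rep_beta: list[float] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def mean_richness(self) -> float:
        return float(np.mean(self.per_rep_richness))

    @property
    def mean_beta(self) -> float:
        betas = np.asarray(self.per_rep_beta, dtype=float)
        kept = betas[~np.isnan(betas)]
        return float(kept.mean()) if len(kept) else float("nan")


def simulate_ensemble(
    config: LatticeConfig,
    n_reps: int,
    depth: int = 2500,
    fit_options: "FitOptions | None" = None,
    readout: Readout = "whole",
) -> EnsembleSummary:
    """Run ``n_reps`` independent replicates and summarise them.

    Each replicate runs the lattice, draws a ``depth``-read multinomial
    sample, records its richness, and fits the CRAD power-law exponent
    within the abundance window, applying the exclusion rules (fewer than
    2 window points, or bootstrap goodness-of-fit p < 0.1).  Replicate RNG
    streams are spawned deterministically from ``config.seed``.
    """
    from .crad_stats import FitOptions, fit_powerlaw_mle, gof_pvalue

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if fit_options is None:
        fit_options = FitOptions()
    summary = EnsembleSummary(n_reps=n_reps)
    streams = np.random.SeedSequence(config.seed).spawn(n_reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        profile = run_simulation(config, rng=rng, readout=readout)
        sample = sample_reads(profile, depth=depth, rng=rng)
        summary.per_rep_richness.append(sample.richness)
        if not fit_options.fit_beta:
            continue
        x = sample.relative_abundances()
        fit = fit_powerlaw_mle(x, window=fit_options.window, method=fit_options.method)
        if not fit.excluded and fit_options.gof and fit_options.n_boot > 0:
            gof_pvalue(fit, x, n_boot=fit_options.n_boot, rng=rng)
        if fit.excluded:
            summary.n_excluded += 1
            summary.per_rep_beta.append(float("nan"))
        else:
            summary.per_rep_beta.append(fit.beta)
    return summary
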