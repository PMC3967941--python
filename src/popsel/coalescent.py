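"""Hudson-style coalescent simulator with infinite-sites mutation.

Time is measured in units of 2N_ref generations; population sizes are
relative to N_ref and piecewise constant; populations merge (backwards in
time) at split times.  No migration and no intra-locus recombination: the
generated loci feed per-locus SFS statistics and their calibrated nulls,
where recombination does not change the single-site spectrum.  Haplotype
tests draw their positive controls from the forward simulator instead.

theta is the scaled mutation rate 4*N_ref*mu per locus; mutations are
Poisson(theta/2 * total branch length) placed uniformly on branches under
the infinite-sites model, so every simulated site is biallelic with a known
ancestral state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import ANC_REF, HaplotypeMatrix


@dataclass
class PopulationConfig:
    """Piecewise-constant history: epochs of (start_time, relative size)."""

    name: str
    epochs: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])

    def __post_init__(self) -> None:
        times = [t for t, _ in self.epochs]
        if times != sorted(times) or times[0] != 0.0:
            raise ValueError("epochs must start at 0 and be time-ordered")
        if any(s <= 0 for _, s in self.epochs):
            raise ValueError("population sizes must be positive")

    def size_at(self, t: float) -> float:
        size = self.epochs[0][1]
        for start, s in self.epochs:
            if t >= start:
                size = s
        return size


@dataclass
class DemographyConfig:
    """Populations plus (time, derived, ancestral) merge events."""

    populations: list[PopulationConfig] = field(
        default_factory=lambda: [PopulationConfig("pop1")])
    splits: list[tuple[float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = {p.name for p in self.populations}
        for t, d, a in self.splits:
            if d not in names or a not in names:
                raise ValueError(f"split references unknown population {d}/{a}")
        if sorted(t for t, _, _ in self.splits) != [t for t, _, _ in self.splits]:
            raise ValueError("splits must be time-ordered")

    def pop(self, name: str) -> PopulationConfig:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)


def two_population_split(tau: float, names=("pop1", "pop2")) -> DemographyConfig:
    """Two equal-size populations that merge ``tau`` time units ago."""
    return DemographyConfig(
        populations=[PopulationConfig(names[0]), PopulationConfig(names[1])],
        splits=[(tau, names[1], names[0])],
    )


def bottleneck_demography(
    t_bottleneck: float = 0.05, strength: float = 0.1, t_recover: float = 0.02,
    name: str = "pop1",
) -> DemographyConfig:
    """Out-of-Africa-like history: current size 1, a ``strength`` bottleneck
    between ``t_recover`` and ``t_bottleneck`` (backwards), ancestral size 1."""
    return DemographyConfig(populations=[PopulationConfig(
        name, epochs=[(0.0, 1.0), (t_recover, strength), (t_bottleneck, 1.0)])])


def _simulate_branches(
    rng: np.random.Generator,
    samples: dict[str, int],
    demog: DemographyConfig,
):
    """Run the structured coalescent; return (branches, tmrca).

    branches: list of (descendant sample indices, length).  Sample indices
    are assigned population by population in the order of ``samples``.
    """
    lineages: dict[str, list[tuple[list[int], float]]] = {}
    idx = 0
    for pop, n in samples.items():
        lineages[pop] = []
        for _ in range(n):
            lineages[pop].append(([idx], 0.0))
            idx += 1
    branches: list[tuple[list[int], float]] = []
    t = 0.0
    splits = list(demog.splits)
    epoch_times = sorted({start for p in demog.populations
                          for start, _ in p.epochs if start > 0})

    def n_active() -> int:
        return sum(len(v) for v in lineages.values())

    while n_active() > 1:
        boundaries = [bt for bt in epoch_times if bt > t]
        boundaries += [st for st, _, _ in splits if st > t]
        next_boundary = min(boundaries) if boundaries else math.inf
        rates = {}
        for pop, lns in lineages.items():
            k = len(lns)
            if k >= 2:
                rates[pop] = k * (k - 1) / 2 / demog.pop(pop).size_at(t)
        total = sum(rates.values())
        if total == 0.0:
            if math.isinf(next_boundary):
                raise RuntimeError("lineages isolated forever: missing split?")
            t = next_boundary
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= next_boundary:
                t = next_boundary
            else:
                t += wait
                pop = rng.choice(list(rates), p=np.array(list(rates.values())) / total)
                lns = lineages[pop]
                i, j = rng.choice(len(lns), size=2, replace=False)
                (d1, b1), (d2, b2) = lns[i], lns[j]
                for desc, birth in ((d1, b1), (d2, b2)):
                    branches.append((desc, t - birth))
                merged = (d1 + d2, t)
                lineages[pop] = [l for k2, l in enumerate(lns) if k2 not in (i, j)]
                lineages[pop].append(merged)
                continue
        # apply any boundary events at time t
        for st, d, a in [s for s in splits if s[0] == t]:
            lineages.setdefault(a, []).extend(lineages.get(d, []))
            lineages[d] = []
        splits = [s for s in splits if s[0] > t]
        epoch_times = [bt for bt in epoch_times if bt > t]
    return branches, t


def simulate_coalescent_locus(
    samples: "int | dict[str, int]",
    theta: float,
    demography: DemographyConfig | None = None,
    L: int = 10_000,
    rng: np.random.Generator | None = None,
    region_id: str = "locus",
    chrom: str = "1",
) -> HaplotypeMatrix:
    """Simulate one locus; returns a polarized HaplotypeMatrix.

    The true TMRCA (in 2N_ref generations) is attached as ``.true_tmrca``.
    Ancestral alleles are the reference alleles (state 0) at every site.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(samples, int):
        samples = {"pop1": samples}
    if demography is None:
        demography = DemographyConfig(
            populations=[PopulationConfig(p) for p in samples])
    n_tot = sum(samples.values())
    if n_tot < 2:
        raise ValueError("need at least 2 sampled chromosomes")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    branches, tmrca = _simulate_branches(rng, samples, demography)
    total_len = sum(b for _, b in branches)
    n_mut = rng.poisson(theta / 2.0 * total_len) if theta > 0 else 0

    calls = np.zeros((n_tot, n_mut), dtype=np.int8)
    if n_mut:
        lengths = np.array([b for _, b in branches])
        which = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
        for k, bi in enumerate(which):
            calls[branches[bi][0], k] = 1
    if n_mut > L:
        raise ValueError("more mutations than available sites; increase L")
    # unique strictly increasing integer positions on [1, L]
    u = np.sort(rng.random(n_mut))
    positions = np.unique(np.maximum(1, np.ceil(u * L).astype(np.int64)))
    while len(positions) < n_mut:  # resolve collisions keeping order
        extra = np.maximum(1, np.ceil(rng.random(n_mut - len(positions)) * L
                                      ).astype(np.int64))
        positions = np.unique(np.concatenate([positions, extra]))
    positions = positions[:n_mut]

    labels = np.concatenate([[p] * n for p, n in samples.items()]) \
        if n_tot else np.array([], object)
    hap = HaplotypeMatrix(
        region_id, chrom, positions, [("A", "G")] * n_mut, calls,
        labels.astype(object), np.full(n_mut, ANC_REF, np.int8),
        start=1, end=L,
    )
    hap.true_tmrca = tmrca  # type: ignore[attr-defined]
    return hap


def simulate_outgroup_divergence(
    theta: float, T: float, n: int, rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """(S, D) counts for one locus under the HKA sampling model.

    S ~ Poisson(theta * a_n) within-species polymorphisms and
    D ~ Poisson(theta * (T + 1)) fixed differences to the outgroup, where T
    is the species divergence in 2N-generation units and the +1 accounts for
    ancestral polymorphism.
    """
    if theta <= 0 or T < 0:
        raise ValueError("theta must be positive and T non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    a_n = sum(1.0 / i for i in range(1, n))
    return int(rng.poisson(theta * a_n)), int(rng.poisson(theta * (T + 1.0)))
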