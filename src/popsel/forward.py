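"""Forward Wright-Fisher simulation of selective sweeps.

Positive controls for the haplotype tests (DIND, iHS, lnRsb) need linked
variation around a selected allele, which the per-locus coalescent does not
provide.  This simulator evolves a window of biallelic sites in a diploid
Wright-Fisher population with recombination and infinite-sites mutation.

The population is initialized from a neutral coalescent sample of 2N
chromosomes (exact for the single-site spectrum) followed by a short
settling phase that lets recombination relax the initial linkage structure;
a beneficial mutation (fitnesses 1, 1+hs, 1+s) is then injected at the
window center and the population is run until a sampling condition (derived
frequency target, or fixation) is met.  Lost beneficial alleles are
re-injected with bounded retries.

Population sizes are small (N <= 1000) by design; selection coefficients
are interpreted at this scale, so 2Ns — not s alone — is the strength knob.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coalescent import simulate_coalescent_locus
from .haplotypes import ANC_REF, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class SweepConfig:
    n_diploid: int = 400          # N; haploid count is 2N
    s: float = 0.05               # selection coefficient of the homozygote
    h: float = 0.5                # dominance
    rec_rate: float = 1e-7        # per adjacent-bp, per gamete, per generation
    length_bp: int = 60_000       # window size
    mu_per_site: float = 5e-7     # per site per gamete per generation
    condition: str = "frequency"  # "frequency" | "fixation"
    target_freq: float = 0.8
    settle_generations: int | None = None  # default N // 2
    split_generations: int = 60   # two-deme drift time when s == 0
    max_retries: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")
        if self.n_diploid < 50:
            raise ValueError("N must be >= 50")
        if self.condition not in ("frequency", "fixation"):
            raise ValueError("condition must be 'frequency' or 'fixation'")


class _Population:
    """Mutable haplotype pool: (2N, S) uint8 plus sorted positions."""

    def __init__(self, calls: np.ndarray, positions: np.ndarray, L: int):
        self.calls = np.ascontiguousarray(calls, dtype=np.uint8)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.L = L
        self.used = set(int(p) for p in positions)
        self.sel_col: int | None = None

    def copy(self) -> "_Population":
        p = _Population(self.calls.copy(), self.positions.copy(), self.L)
        p.sel_col = self.sel_col
        return p

    def sel_count(self) -> int:
        return int(self.calls[:, self.sel_col].sum()) if self.sel_col is not None else 0

    def step(self, rng: np.random.Generator, s: float, h: float,
             rec_rate: float, mu: float) -> None:
        n2, n_site = self.calls.shape
        n = n2 // 2
        if self.sel_col is not None and s > 0:
            g = (self.calls[0::2, self.sel_col].astype(np.int64)
                 + self.calls[1::2, self.sel_col])
            w = 1.0 + np.where(g == 2, s, 0.0) + np.where(g == 1, h * s, 0.0)
            p = w / w.sum()
        else:
            p = None
        parents = rng.choice(n, size=n2, p=p)
        start = rng.integers(0, 2, size=n2)
        new = self.calls[2 * parents + start]
        # rare recombinant gametes handled individually
        n_x = rng.poisson(rec_rate * max(self.L - 1, 1), size=n2)
        for g_i in np.nonzero(n_x)[0]:
            bps = np.sort(rng.integers(1, self.L, size=n_x[g_i]))
            seg = np.searchsorted(bps, self.positions, side="right")
            use_first = (seg + start[g_i]) % 2 == 0
            h1 = self.calls[2 * parents[g_i]]
            h2 = self.calls[2 * parents[g_i] + 1]
            new[g_i] = np.where(use_first, h1, h2)
        self.calls = np.ascontiguousarray(new)
        # new mutations
        n_new = rng.poisson(mu * self.L * n2)
        if n_new:
            cols, pos = [], []
            for _ in range(n_new):
                for _try in range(100):
                    cand = int(rng.integers(1, self.L + 1))
                    if cand not in self.used:
                        break
                else:
                    continue
                self.used.add(cand)
                col = np.zeros(n2, dtype=np.uint8)
                col[rng.integers(0, n2)] = 1
                cols.append(col)
                pos.append(cand)
            if pos:
                self.calls = np.column_stack([self.calls] + cols)
                self.positions = np.concatenate([self.positions, pos])
                order = np.argsort(self.positions)
                sel_pos = (self.positions[self.sel_col]
                           if self.sel_col is not None else None)
                self.positions = self.positions[order]
                self.calls = np.ascontiguousarray(self.calls[:, order])
                if sel_pos is not None:
                    self.sel_col = int(np.searchsorted(self.positions, sel_pos))
        self._prune()

    def _prune(self) -> None:
        counts = self.calls.sum(axis=0)
        n2 = self.calls.shape[0]
        keep = (counts > 0) & (counts < n2)
        if self.sel_col is not None:
            keep[self.sel_col] = True
        if keep.all():
            return
        dropped = self.positions[~keep]
        self.used.difference_update(int(p) for p in dropped)
        sel_pos = self.positions[self.sel_col] if self.sel_col is not None else None
        self.positions = self.positions[keep]
        self.calls = np.ascontiguousarray(self.calls[:, keep])
        if sel_pos is not None:
            self.sel_col = int(np.searchsorted(self.positions, sel_pos))

    def inject(self, rng: np.random.Generator) -> None:
        """Add the beneficial mutation on one random chromosome at the center."""
        center = self.L // 2
        pos = center
        while pos in self.used:
            pos += 1
        self.used.add(pos)
        col = np.zeros(self.calls.shape[0], dtype=np.uint8)
        col[rng.integers(0, self.calls.shape[0])] = 1
        j = int(np.searchsorted(self.positions, pos))
        self.positions = np.insert(self.positions, j, pos)
        self.calls = np.ascontiguousarray(np.insert(self.calls, j, col, axis=1))
        self.sel_col = j

    def drop_selected(self) -> None:
        if self.sel_col is None:
            return
        self.used.discard(int(self.positions[self.sel_col]))
        self.positions = np.delete(self.positions, self.sel_col)
        self.calls = np.ascontiguousarray(np.delete(self.calls, self.sel_col, axis=1))
        self.sel_col = None


def _sample_matrix(pops: list[tuple[str, _Population, np.ndarray]],
                   region_id: str, sel_pos: int | None) -> HaplotypeMatrix:
    """Extract sampled rows into a HaplotypeMatrix on the union of sites."""
    all_pos = sorted({int(p) for _, pop, _ in pops for p in pop.positions})
    pos_index = {p: i for i, p in enumerate(all_pos)}
    rows, labels = [], []
    for name, pop, rows_idx in pops:
        block = np.zeros((len(rows_idx), len(all_pos)), dtype=np.int8)
        cols = [pos_index[int(p)] for p in pop.positions]
        block[:, cols] = pop.calls[rows_idx]
        rows.append(block)
        labels.extend([name] * len(rows_idx))
    calls = np.vstack(rows)
    seg = (calls.sum(axis=0) > 0) & (calls.sum(axis=0) < calls.shape[0])
    if sel_pos is not None:
        seg[pos_index[sel_pos]] = True
    positions = np.asarray(all_pos, np.int64)[seg]
    hap = HaplotypeMatrix(
        region_id, "1", positions, [("A", "G")] * int(seg.sum()),
        calls[:, seg], np.asarray(labels, object),
        np.full(int(seg.sum()), ANC_REF, np.int8),
        start=1, end=pops[0][1].L,
    )
    hap.selected_pos = sel_pos  # type: ignore[attr-defined]
    return hap


def simulate_sweep_forward(
    cfg: SweepConfig,
    n_sample: int,
    rng: np.random.Generator | None = None,
    neutral_copy: bool = False,
    region_id: str = "sweep",
) -> HaplotypeMatrix:
    """Simulate a sweep and return a phased sample with the selected site marked.

    With ``neutral_copy`` the population is duplicated at selection onset and
    the copy evolves neutrally for the same number of generations, yielding a
    two-population sample (pop1 swept, pop2 neutral) for FST/lnRsb controls.
    With ``cfg.s == 0`` no site is injected and the sample is neutral.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n2 = 2 * cfg.n_diploid
    theta = 4.0 * cfg.n_diploid * cfg.mu_per_site * cfg.length_bp
    init = simulate_coalescent_locus(n2, theta, L=cfg.length_bp, rng=rng)
    pop = _Population(init.calls.astype(np.uint8), init.positions, cfg.length_bp)

    settle = (cfg.settle_generations if cfg.settle_generations is not None
              else cfg.n_diploid // 2)
    for _ in range(settle):
        pop.step(rng, 0.0, 0.5, cfg.rec_rate, cfg.mu_per_site)

    if cfg.s == 0:
        if neutral_copy:
            pop2 = pop.copy()
            for _ in range(cfg.split_generations):
                pop.step(rng, 0.0, 0.5, cfg.rec_rate, cfg.mu_per_site)
                pop2.step(rng, 0.0, 0.5, cfg.rec_rate, cfg.mu_per_site)
            return _sample_matrix(
                [("pop1", pop, rng.choice(n2, size=n_sample, replace=False)),
                 ("pop2", pop2, rng.choice(n2, size=n_sample, replace=False))],
                region_id, None)
        rows = rng.choice(n2, size=n_sample, replace=False)
        return _sample_matrix([("pop1", pop, rows)], region_id, None)

    pop2 = pop.copy() if neutral_copy else None
    retries = 0
    pop.inject(rng)
    while True:
        pop.step(rng, cfg.s, cfg.h, cfg.rec_rate, cfg.mu_per_site)
        if pop2 is not None:
            pop2.step(rng, 0.0, 0.5, cfg.rec_rate, cfg.mu_per_site)
        cnt = pop.sel_count()
        if cnt == 0:
            retries += 1
            if retries > cfg.max_retries:
                raise RuntimeError("beneficial allele lost too many times")
            pop.drop_selected()
            pop.inject(rng)
            continue
        freq = cnt / n2
        if cfg.condition == "frequency" and freq >= cfg.target_freq:
            break
        if cfg.condition == "fixation" and cnt == n2:
            break
    if retries:
        log.debug("sweep required %d re-injections", retries)

    sel_pos = int(pop.positions[pop.sel_col])
    groups = [("pop1", pop, rng.choice(n2, size=n_sample, replace=False))]
    if pop2 is not None:
        groups.append(("pop2", pop2, rng.choice(n2, size=n_sample, replace=False)))
    return _sample_matrix(groups, region_id, sel_pos)
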