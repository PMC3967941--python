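"""Diversity and site-frequency-spectrum neutrality statistics.

All statistics are computed from :class:`SFSCounts`, a per-region summary of
a single population sample: the number of haplotypes n, segregating sites S,
the unfolded spectrum xi_i (i = derived-allele count), the singleton count
eta_s (minor count 1, no polarization needed), and the sum of pairwise
differences.  Monomorphic input yields a missing value (NaN) for the
normalized tests rather than 0, so empty windows never dilute empirical
null distributions.

Conventions:

* Watterson's theta_W = S / a_n with a_n = sum_{i<n} 1/i.
* pi = pairwise-difference sum / C(n, 2).
* Tajima's D with the 1989 e1/e2 constants.
* Fu & Li's D* and F* in the starred (no-outgroup) form with the corrected
  constants of Simonsen, Churchill & Aquadro (1995).
* Fay & Wu's H in the normalized form of Zeng et al. (2006), computed on
  ancestrally resolved sites only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .haplotypes import MISSING, HaplotypeMatrix


@dataclass
class SFSCounts:
    """Sufficient statistics for the SFS neutrality tests on one sample."""

    n: int
    S: int
    xi: np.ndarray          # unfolded SFS over resolved sites, length n-1
    eta_s: int              # singletons by minor allele count (unpolarized)
    dsum: float             # sum of pairwise differences over all C(n,2) pairs
    L: float = 1.0          # accessible length (bp) for per-site scaling
    S_resolved: int = 0     # segregating sites with resolved ancestry

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=np.int64)
        if self.n < 2:
            raise ValueError("need n >= 2 haplotypes")
        if len(self.xi) != self.n - 1:
            raise ValueError("xi must have length n-1")
        if self.L <= 0:
            raise ValueError("L must be positive")


def sfs_counts(hap: HaplotypeMatrix, pop: str | None = None, L: float | None = None) -> SFSCounts:
    """Summarize one population's haplotypes into :class:`SFSCounts`.

    Sites with any missing call in the focal population are excluded from
    every count (a shared n is required for the spectrum); frequency tables
    elsewhere use reduced per-site sample sizes instead.
    """
    sub = hap.pop(pop) if pop is not None else hap
    n = sub.n_hap
    if n < 2:
        raise ValueError("need >= 2 haplotypes in population")
    calls = sub.calls
    complete = ~(calls == MISSING).any(axis=0)
    calls = calls[:, complete]
    resolved = sub.resolved()[complete]

    alt = calls.sum(axis=0)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    minor = np.minimum(alt, n - alt)
    eta_s = int(((minor == 1) & seg).sum())
    dsum = float((alt[seg] * (n - alt[seg])).sum())

    der = sub.derived_calls()[:, complete]
    dcount = der.sum(axis=0)
    dseg = seg & resolved
    xi = np.bincount(dcount[dseg], minlength=n)[1:n] if dseg.any() else np.zeros(n - 1, np.int64)

    return SFSCounts(
        n=n, S=S, xi=xi, eta_s=eta_s, dsum=dsum,
        L=(L if L is not None else max(1.0, float((sub.end or 1) - (sub.start or 1) + 1))),
        S_resolved=int(dseg.sum()),
    )


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def watterson_theta(c: SFSCounts, per_site: bool = False) -> float:
    """Watterson's estimator S / a_n, optionally per accessible base."""
    theta = c.S / _harmonic(c.n)
    return theta / c.L if per_site else theta


def nucleotide_diversity_pi(c: SFSCounts, per_site: bool = False) -> float:
    """Mean pairwise difference, optionally per accessible base."""
    pi = c.dsum / math.comb(c.n, 2)
    return pi / c.L if per_site else pi


def tajimas_d(c: SFSCounts) -> float:
    """Tajima's D; NaN when the sample is monomorphic."""
    if c.S == 0 or c.n < 3:  # n=2 has pi = S identically: D degenerates
        return float("nan")
    n, S = c.n, c.S
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (nucleotide_diversity_pi(c) - watterson_theta(c)) / math.sqrt(var)


def fu_li_star(c: SFSCounts) -> tuple[float, float]:
    """Fu & Li's D* and F* (within-sample, singleton-based); NaN when S=0.

    Constants follow the corrected expressions of Simonsen et al. (1995),
    the form used by the standard C++/DnaSP implementations.
    """
    if c.S == 0:
        return float("nan"), float("nan")
    n, S, eta_s = c.n, c.S, c.eta_s
    if n < 3:
        return float("nan"), float("nan")
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n

    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2) / (n - 1) ** 2
          + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))

    v_d = ((n / (n - 1)) ** 2 * bn + an**2 * dn
           - 2 * (n * an * (an + 1)) / (n - 1) ** 2) / (an**2 + bn)
    u_d = (n / (n - 1)) * (an - n / (n - 1)) - v_d
    d_star = ((n / (n - 1)) * S - an * eta_s) / math.sqrt(u_d * S + v_d * S**2)

    v_f = (dn + 2 * (n**2 + n + 3) / (9 * n * (n - 1))
           - (2 / (n - 1)) * (4 * bn - 6 + 8.0 / n)) / (an**2 + bn)
    u_f = ((n / (n - 1) + (n + 1) / (3 * (n - 1)) - 4.0 / (n * (n - 1))
            + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))) / an) - v_f
    pi = nucleotide_diversity_pi(c)
    f_star = (pi - ((n - 1) / n) * eta_s) / math.sqrt(u_f * S + v_f * S**2)
    return d_star, f_star


def fay_wu_h_norm(c: SFSCounts) -> float:
    """Normalized Fay & Wu's H (Zeng et al. 2006); NaN without resolved sites.

    Contrasts pi with theta_L = (1/(n-1)) sum i*xi_i; both moments of theta
    in the variance are estimated from the resolved segregating sites.
    """
    S = c.S_resolved if c.S_resolved else int(c.xi.sum())
    if S == 0:
        return float("nan")
    n = c.n
    i = np.arange(1, n)
    # pi restricted to resolved sites, from the spectrum itself
    pi = float((2.0 * i * (n - i) * c.xi).sum() / (n * (n - 1)))
    theta_l = float((i * c.xi).sum()) / (n - 1)

    an = _harmonic(n)
    bn = _harmonic(n, 2)
    bn1 = bn + 1.0 / n**2
    theta_w = S / an
    theta_sq = S * (S - 1) / (an**2 + bn)
    var = ((n - 2) / (6 * (n - 1))) * theta_w + (
        (18 * n**2 * (3 * n + 2) * bn1 - (88 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9 * n * (n - 1) ** 2)
    ) * theta_sq
    if var <= 0:
        return float("nan")
    return (pi - theta_l) / math.sqrt(var)


_WINDOW_STATS = {
    "H": lambda c: fay_wu_h_norm(c),
    "D": lambda c: tajimas_d(c),
    "pi": lambda c: nucleotide_diversity_pi(c, per_site=True),
    "thetaW": lambda c: watterson_theta(c, per_site=True),
}


@dataclass
class WindowResult:
    start: int
    end: int
    stat: str
    value: float
    below_5th: bool = False


def sliding_window_stat(
    hap: HaplotypeMatrix,
    stat: str,
    span: int = 5000,
    step: int = 500,
    null=None,
    pop: str | None = None,
) -> list[WindowResult]:
    """Compute a statistic in sliding windows tiled from the region start.

    Windows are ``span`` bp moving by ``step`` bp; trailing partial windows
    are dropped.  With an :class:`~popsel.outliers.EmpiricalNull` supplied,
    each defined window is flagged when it falls below the null's 5th
    percentile (the sweep tail used for the window tracks).
    """
    if span < step:
        raise ValueError("span must be >= step")
    if stat not in _WINDOW_STATS:
        raise ValueError(f"stat must be one of {sorted(_WINDOW_STATS)}")
    sub = hap.pop(pop) if pop is not None else hap
    region_len = (sub.end or 0) - (sub.start or 0) + 1
    out: list[WindowResult] = []
    if region_len < span:
        return out
    n_win = (region_len - span) // step + 1
    fn = _WINDOW_STATS[stat]
    for w in range(n_win):
        w0 = (sub.start or 1) + w * step
        w1 = w0 + span - 1
        idx = np.where((sub.positions >= w0) & (sub.positions <= w1))[0]
        if len(idx) == 0:
            out.append(WindowResult(w0, w1, stat, float("nan")))
            continue
        c = sfs_counts(sub.take_sites(idx), L=span)
        if c.S == 0:
            out.append(WindowResult(w0, w1, stat, float("nan")))
            continue
        val = fn(c)
        flag = False
        if null is not None and not math.isnan(val):
            p5 = null.percentile(5.0)
            flag = bool(val < p5)
        out.append(WindowResult(w0, w1, stat, val, flag))
    return out
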