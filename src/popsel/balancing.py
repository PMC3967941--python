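"""Balancing-selection follow-up: coalescent p-values and TMRCA estimation.

Candidate regions (elevated theta_W or pi against the control panel) are
tested two ways: the MLHKA likelihood-ratio test (:mod:`popsel.hka`) and
one-sided p-values for SFS statistics from calibrated neutral coalescent
simulations conditioned on theta.  TMRCA is estimated from the average
pairwise difference between sampled chromosomes and the MRCA sequence,
converted to years by a mutation rate calibrated on human-chimpanzee fixed
differences (6 MY divergence, 25-year generations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import sfs
from .coalescent import DemographyConfig, simulate_coalescent_locus
from .haplotypes import HaplotypeMatrix

STAT_FUNCTIONS: dict[str, Callable[[sfs.SFSCounts], float]] = {
    "TajD": sfs.tajimas_d,
    "FuLiDstar": lambda c: sfs.fu_li_star(c)[0],
    "FuLiFstar": lambda c: sfs.fu_li_star(c)[1],
    "FayWuHnorm": sfs.fay_wu_h_norm,
    "pi": sfs.nucleotide_diversity_pi,
    "thetaW": sfs.watterson_theta,
}


def coalescent_pvalue(
    observed: float,
    stat: str,
    n: int,
    theta: float,
    demography: DemographyConfig | None = None,
    iterations: int = 10_000,
    tail: str = "upper",
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided Monte-Carlo p-value of a statistic under a neutral coalescent.

    p = (1 + #{simulated >= observed}) / (m + 1) for the upper tail (mirrored
    for the lower), where m counts simulations in which the statistic is
    defined; more than half undefined is an error.  Simulations condition on
    theta (fixed mutation rate), not on the observed S.
    """
    if stat not in STAT_FUNCTIONS:
        raise ValueError(f"stat must be one of {sorted(STAT_FUNCTIONS)}")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    rng = rng if rng is not None else np.random.default_rng()
    fn = STAT_FUNCTIONS[stat]
    hits = valid = 0
    for _ in range(iterations):
        hap = simulate_coalescent_locus(n, theta, demography, rng=rng)
        try:
            val = fn(sfs.sfs_counts(hap))
        except ValueError:
            continue
        if math.isnan(val):
            continue
        valid += 1
        if (val >= observed) if tail == "upper" else (val <= observed):
            hits += 1
    if valid < iterations / 2:
        raise RuntimeError(
            f"statistic {stat} undefined in {iterations - valid}/{iterations} simulations")
    return (1 + hits) / (valid + 1)


def calibrate_mutation_rate(
    fixed_differences: int,
    divergence_years: float = 6e6,
    generation_years: float = 25.0,
) -> tuple[float, float]:
    """Region-wide mutation rate from interspecies fixed differences.

    mu_year = fixed_differences / (2 * divergence_years): the differences
    accumulated on both branches since the species split.  Returns
    (per year, per generation).
    """
    if fixed_differences < 0:
        raise ValueError("fixed_differences must be >= 0")
    mu_year = fixed_differences / (2.0 * divergence_years)
    return mu_year, mu_year * generation_years


@dataclass
class TMRCAEstimate:
    mean_divergence: float   # mean pairwise differences to the MRCA
    mu_year: float
    tmrca_years: float
    sd_years: float
    method: str = "pairwise-to-MRCA; SD by site bootstrap"


def tmrca_pairwise(
    hap: HaplotypeMatrix,
    mu_year: float,
    mrca: np.ndarray | None = None,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> TMRCAEstimate:
    """TMRCA in years from mean divergence of all chromosomes to the MRCA.

    The default MRCA carries the ancestral allele at every segregating site
    (sites must be polarized).  SD is a bootstrap over segregating sites,
    standing in for the closed-form variance of the original method.
    """
    if mu_year <= 0:
        raise ValueError("mu_year must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    der = hap.derived_calls()
    resolved = hap.resolved()
    der = der[:, resolved]
    if mrca is None:
        mrca = np.zeros(der.shape[1], dtype=np.int8)
    else:
        mrca = np.asarray(mrca, np.int8)[resolved] if len(mrca) == hap.n_site \
            else np.asarray(mrca, np.int8)
    diffs = (der != mrca[None, :]).sum(axis=1)
    mean_div = float(diffs.mean())
    tmrca = mean_div / mu_year
    if der.shape[1] == 0 or n_bootstrap == 0:
        return TMRCAEstimate(mean_div, mu_year, tmrca, 0.0)
    m = der.shape[1]
    per_site = (der != mrca[None, :]).mean(axis=0)  # mean mismatch per site
    idx = rng.integers(0, m, size=(n_bootstrap, m))
    boot = per_site[idx].sum(axis=1) / mu_year
    return TMRCAEstimate(mean_div, mu_year, tmrca, float(boot.std(ddof=1)))
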