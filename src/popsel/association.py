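"""Case/control genetics on 2x3 genotype tables.

Three pieces: an exact conditional Hardy-Weinberg test; the
Wittke-Thompson disequilibrium-penetrance model that asks whether a genetic
model alone explains an HWE deviation in cases; and a label-swapping
permutation test of association.

The penetrance model is parametrized by q (susceptibility allele
frequency), alpha (risk in non-susceptible homozygotes), beta and gamma
(heterozygote and homozygote relative risks) and the trait prevalence Kp.
With genotypes in Hardy-Weinberg proportions in the general population, the
expected genotype probabilities are

    cases:    (q^2 alpha gamma, 2q(1-q) alpha beta, (1-q)^2 alpha) / Kp
    controls: (q^2 (1-alpha gamma), 2q(1-q)(1-alpha beta), (1-q)^2 (1-alpha)) / (1-Kp)

and alpha is eliminated through Kp = alpha[(1-q)^2 + 2q(1-q)beta + q^2 gamma].
Fitting minimizes the 6-cell goodness-of-fit chi-square by quasi-Newton
descent with Latin-hypercube multi-start; constrained models fix beta
(recessive beta=1; dominant beta=gamma; additive beta=(gamma+1)/2;
multiplicative beta=sqrt(gamma), all with gamma>1).  Model selection is by
AIC = chi2_min + 2 * n_free_parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc


@dataclass
class GenotypeCounts:
    """Genotype counts ordered rare-homozygote / heterozygote / common-homozygote."""

    label: str
    rare_hom: int
    het: int
    common_hom: int

    def __post_init__(self) -> None:
        if min(self.rare_hom, self.het, self.common_hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty cohort")

    @property
    def total(self) -> int:
        return self.rare_hom + self.het + self.common_hom

    def as_array(self) -> np.ndarray:
        return np.array([self.rare_hom, self.het, self.common_hom], float)


def genotype_frequencies(counts: GenotypeCounts) -> dict[str, float]:
    """Rare-allele frequency and genotype proportions (fractions)."""
    n = counts.total
    return {
        "rare_hom_proportion": counts.rare_hom / n,
        "het_proportion": counts.het / n,
        "common_hom_proportion": counts.common_hom / n,
        "rare_allele_frequency": (2 * counts.rare_hom + counts.het) / (2 * n),
    }


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional (Wigginton-style) two-sided HWE test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one.
    Monomorphic samples return p = 1.
    """
    n = counts.total
    n_rare = 2 * counts.rare_hom + counts.het
    m = min(n_rare, 2 * n - n_rare)  # minor allele count
    if m == 0:
        return 1.0
    het_obs = counts.het
    # heterozygote counts share the parity of the minor allele count
    h_vals = list(range(m % 2, m + 1, 2))
    # start from the largest feasible h and recurse downward
    probs = {}
    h = h_vals[-1]
    probs[h] = 1.0
    while h >= 2:
        hom_minor = (m - h) / 2
        hom_major = n - h - hom_minor
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_minor + 1) * (hom_major + 1))
        h -= 2
    total = sum(probs.values())
    p_obs = probs[het_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


_CONSTRAINED = ("recessive", "dominant", "additive", "multiplicative")
MODELS = ("general",) + _CONSTRAINED


def _beta_of(model: str, gamma: float) -> float:
    if model == "recessive":
        return 1.0
    if model == "dominant":
        return gamma
    if model == "additive":
        return (gamma + 1.0) / 2.0
    if model == "multiplicative":
        return math.sqrt(gamma)
    raise ValueError(model)


def model_probabilities(q: float, beta: float, gamma: float, kp: float):
    """(case probs, control probs, alpha) for the penetrance model; None if infeasible."""
    denom = (1 - q) ** 2 + 2 * q * (1 - q) * beta + q * q * gamma
    alpha = kp / denom
    if not (0 < alpha < 1 and 0 < alpha * beta < 1 and 0 < alpha * gamma < 1):
        return None
    case = np.array([q * q * alpha * gamma,
                     2 * q * (1 - q) * alpha * beta,
                     (1 - q) ** 2 * alpha]) / kp
    ctrl = np.array([q * q * (1 - alpha * gamma),
                     2 * q * (1 - q) * (1 - alpha * beta),
                     (1 - q) ** 2 * (1 - alpha)]) / (1 - kp)
    return case, ctrl, alpha


@dataclass
class PenetranceModelResults:
    model: str
    q: float
    alpha: float
    beta: float
    gamma: float
    kp: float
    chi2: float
    df: int
    pvalue: float
    aic: float
    n_free: int
    expected_cases: np.ndarray = field(repr=False, default=None)  # type: ignore
    expected_controls: np.ndarray = field(repr=False, default=None)  # type: ignore

    def summary(self) -> str:
        return (
            f"Penetrance-model fit ({self.model}), Kp = {self.kp:.3g}\n"
            f"  q     = {self.q:.4f}  (susceptibility allele frequency)\n"
            f"  alpha = {self.alpha:.4f}  (risk in non-susceptible homozygotes)\n"
            f"  beta  = {self.beta:.4f}  (heterozygote relative risk)\n"
            f"  gamma = {self.gamma:.4f}  (homozygote relative risk)\n"
            f"  chi2  = {self.chi2:.4f}  df = {self.df}  p = {self.pvalue:.4f}\n"
            f"  AIC   = {self.aic:.4f}"
        )


class PenetranceModel:
    """Wittke-Thompson goodness-of-fit model for a case/control 2x3 table."""

    def __init__(self, cases: GenotypeCounts, controls: GenotypeCounts, kp: float):
        if not 0 < kp < 1:
            raise ValueError("Kp must be in (0, 1)")
        self.cases = cases
        self.controls = controls
        self.kp = kp

    def _chi2(self, q: float, beta: float, gamma: float) -> float:
        probs = model_probabilities(q, beta, gamma, self.kp)
        if probs is None:
            return float("inf")
        case_p, ctrl_p, _ = probs
        e_case = case_p * self.cases.total
        e_ctrl = ctrl_p * self.controls.total
        if (e_case <= 0).any() or (e_ctrl <= 0).any():
            return float("inf")
        o_case = self.cases.as_array()
        o_ctrl = self.controls.as_array()
        return float((((o_case - e_case) ** 2) / e_case).sum()
                     + (((o_ctrl - e_ctrl) ** 2) / e_ctrl).sum())

    def _objective(self, x: np.ndarray, model: str) -> float:
        q = 1.0 / (1.0 + math.exp(-x[0]))
        if model == "general":
            beta, gamma = math.exp(x[1]), math.exp(x[2])
        else:
            gamma = 1.0 + math.exp(x[1])
            beta = _beta_of(model, gamma)
        val = self._chi2(q, beta, gamma)
        return val if math.isfinite(val) else 1e12

    def fit(self, model: str = "recessive", n_starts: int = 25,
            seed: int = 0) -> PenetranceModelResults:
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        dim = 3 if model == "general" else 2
        sampler = qmc.LatinHypercube(d=dim, seed=seed)
        starts = sampler.random(n_starts)
        # map unit cube to logit-q in (-5, 0), log-scale risks in (-2, 2.5)
        lo = np.array([-5.0] + [-2.0] * (dim - 1))
        hi = np.array([0.0] + [2.5] * (dim - 1))
        best = None
        for u in starts:
            x0 = lo + u * (hi - lo)
            res = optimize.minimize(self._objective, x0, args=(model,),
                                    method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError(f"penetrance fit failed for model {model}")
        x = best.x
        q = 1.0 / (1.0 + math.exp(-x[0]))
        if model == "general":
            beta, gamma = math.exp(x[1]), math.exp(x[2])
        else:
            gamma = 1.0 + math.exp(x[1])
            beta = _beta_of(model, gamma)
        case_p, ctrl_p, alpha = model_probabilities(q, beta, gamma, self.kp)
        n_free = dim
        df = 1 if model == "general" else 2
        chi2 = float(best.fun)
        return PenetranceModelResults(
            model=model, q=q, alpha=alpha, beta=beta, gamma=gamma, kp=self.kp,
            chi2=chi2, df=df, pvalue=float(stats.chi2.sf(chi2, df)),
            aic=chi2 + 2.0 * n_free, n_free=n_free,
            expected_cases=case_p * self.cases.total,
            expected_controls=ctrl_p * self.controls.total,
        )

    def fit_all(self, n_starts: int = 25, seed: int = 0) -> list[PenetranceModelResults]:
        return [self.fit(m, n_starts=n_starts, seed=seed) for m in MODELS]


def select_best_model_aic(fits: list[PenetranceModelResults]) -> PenetranceModelResults:
    """Minimum-AIC fit; ties broken toward fewer free parameters."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    return sorted(fits, key=lambda f: (round(f.aic, 12), f.n_free))[0]


def _chi2_tables(case_counts: np.ndarray, totals: np.ndarray,
                 n_case: int, n_total: int) -> np.ndarray:
    """Vectorized Pearson chi2 for 2xK tables with fixed margins.

    case_counts: (B, K) case rows; columns with zero total are skipped.
    """
    case_counts = np.atleast_2d(case_counts).astype(float)
    keep = totals > 0
    x = case_counts[:, keep]
    tot = totals[keep].astype(float)
    n_ctrl = n_total - n_case
    e_case = n_case * tot / n_total
    e_ctrl = n_ctrl * tot / n_total
    return (((x - e_case) ** 2 / e_case).sum(axis=1)
            + (((tot - x) - e_ctrl) ** 2 / e_ctrl).sum(axis=1))


def _collapse(counts: np.ndarray, model: str) -> np.ndarray:
    if model == "genotypic":
        return counts
    if model == "recessive":  # rare-homozygote vs the rest
        return np.array([counts[0], counts[1] + counts[2]])
    raise ValueError("model must be 'genotypic' or 'recessive'")


def permutation_association(
    cases: GenotypeCounts, controls: GenotypeCounts,
    model: str = "genotypic", b: int = 10_000,
    rng: np.random.Generator | None = None, seed: int | None = None,
) -> float:
    """Phenotype-label-swapping permutation p-value for a 2x3 (or collapsed 2x2) table.

    The statistic is the Pearson chi-square; permuted statistics are drawn by
    resampling the case row from the multivariate hypergeometric distribution
    implied by label swapping.  p = (1 + #{permuted >= observed}) / (B + 1).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    o_case = _collapse(cases.as_array(), model)
    o_ctrl = _collapse(controls.as_array(), model)
    totals = o_case + o_ctrl
    n_case, n_total = cases.total, cases.total + controls.total
    if (totals > 0).sum() < 2 or n_case == 0 or controls.total == 0:
        return 1.0
    obs = _chi2_tables(o_case, totals, n_case, n_total)[0]
    perm = rng.multivariate_hypergeometric(totals.astype(int), n_case, size=b)
    stat = _chi2_tables(perm, totals, n_case, n_total)
    hits = int((stat >= obs - 1e-12).sum())
    return (1 + hits) / (b + 1)


def exact_association_pvalue(cases: GenotypeCounts, controls: GenotypeCounts,
                             model: str = "genotypic") -> float:
    """Exhaustive-permutation analogue of :func:`permutation_association`.

    Enumerates every case-row configuration with its multivariate
    hypergeometric probability; feasible for small tables and used as the
    convergence oracle for the Monte-Carlo test.
    """
    o_case = _collapse(cases.as_array(), model).astype(int)
    o_ctrl = _collapse(controls.as_array(), model).astype(int)
    totals = o_case + o_ctrl
    n_case, n_total = cases.total, cases.total + controls.total
    if (totals > 0).sum() < 2:
        return 1.0
    obs = _chi2_tables(o_case, totals, n_case, n_total)[0]
    configs, probs = [], []

    def rec(i: int, remaining: int, cur: list[int]) -> None:
        if i == len(totals) - 1:
            if remaining <= totals[i]:
                configs.append(cur + [remaining])
            return
        for x in range(min(int(totals[i]), remaining) + 1):
            rec(i + 1, remaining - x, cur + [x])

    rec(0, n_case, [])
    ln_denom = math.lgamma(n_total + 1) - math.lgamma(n_case + 1) \
        - math.lgamma(n_total - n_case + 1)
    p = 0.0
    for cfg in configs:
        ln_num = sum(math.lgamma(t + 1) - math.lgamma(x + 1) - math.lgamma(t - x + 1)
                     for t, x in zip(totals, cfg))
        pr = math.exp(ln_num - ln_denom)
        if _chi2_tables(np.array(cfg, float), totals, n_case, n_total)[0] >= obs - 1e-12:
            p += pr
    return min(1.0, p)
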