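"""Empirical null distributions from a control-locus panel and selection calls.

The calibration object is :class:`EmpiricalNull`: percentile tables (1st,
5th, 95th, 99th), optionally binned by MAF (50 classes over [0, 0.5]) or DAF
(100 classes over [0, 1]), built from statistics computed on a panel of
control loci.  Outlier calls then combine evidence across signature
families:

* diversity — theta_W, pi (sweep tail: low)
* sfs — Tajima's D, Fu & Li's D*/F*, Fay & Wu's H (low)
* differentiation — FST (high)
* haplotype — DIND (high)

A gene is a directional-selection target when at least three distinct
families have a statistic past its 5% tail in the same population, or at
least two families are past their 1% tails.  Genes whose theta_W or pi
exceeds the panel's 95th percentile in any population are balancing-selection
candidates, to be confirmed by the MLHKA test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PERCENTILES = (1.0, 5.0, 95.0, 99.0)

#: statistic -> signature family (recorded so alternative groupings are testable)
STAT_FAMILY = {
    "thetaW": "diversity",
    "pi": "diversity",
    "TajD": "sfs",
    "FuLiDstar": "sfs",
    "FuLiFstar": "sfs",
    "FayWuHnorm": "sfs",
    "FST": "differentiation",
    "DIND": "haplotype",
}

#: family -> tail in which a sweep pushes the statistic
FAMILY_TAIL = {
    "diversity": "low",
    "sfs": "low",
    "differentiation": "high",
    "haplotype": "high",
}


@dataclass
class _NullClass:
    values: np.ndarray          # sorted panel values
    percentiles: dict[float, float]
    count: int
    reliable: bool              # >= min_count observations
    defined: bool = True        # False e.g. for capped-dominated DIND classes


@dataclass
class EmpiricalNull:
    statistic: str
    population: str | None
    bin_var: str | None          # None | "MAF" | "DAF"
    n_classes: int
    edges: np.ndarray
    classes: list[_NullClass]
    panel_id: str = ""

    def _class_index(self, bin_value: float | None) -> int:
        if self.bin_var is None:
            return 0
        if bin_value is None or np.isnan(bin_value):
            raise ValueError("binned null requires a bin value")
        return int(np.clip(np.digitize(bin_value, self.edges) - 1, 0,
                           self.n_classes - 1))

    def percentile(self, q: float, bin_value: float | None = None) -> float:
        cls = self.classes[self._class_index(bin_value)]
        if not cls.defined or cls.count == 0:
            return float("nan")
        if q in cls.percentiles:
            return cls.percentiles[q]
        return float(np.percentile(cls.values, q))

    def rank(self, value: float, bin_value: float | None = None) -> float:
        """Fraction of panel values <= value within the class; NaN if undefined."""
        cls = self.classes[self._class_index(bin_value)]
        if not cls.defined or cls.count == 0 or np.isnan(value):
            return float("nan")
        return float(np.searchsorted(cls.values, value, side="right") / cls.count)


def build_empirical_null(
    values: np.ndarray,
    statistic: str = "",
    population: str | None = None,
    bin_values: np.ndarray | None = None,
    bin_var: str | None = None,
    n_classes: int | None = None,
    capped: np.ndarray | None = None,
    min_count: int = 20,
    max_capped_fraction: float = 0.05,
    panel_id: str = "",
) -> EmpiricalNull:
    """Build percentile tables from panel values, optionally MAF/DAF binned.

    Percentiles use linear interpolation.  Classes with fewer than
    ``min_count`` observations are flagged unreliable; classes where capped
    values would carry the 95th percentile (fraction capped >
    ``max_capped_fraction``) are marked undefined and yield no calls.
    """
    values = np.asarray(values, float)
    keep = ~np.isnan(values)
    if bin_var is None:
        edges = np.array([0.0, 1.0])
        n_classes = 1
        bins = np.zeros(len(values), int)
    else:
        if n_classes is None:
            n_classes = {"MAF": 50, "DAF": 100}[bin_var]
        top = 0.5 if bin_var == "MAF" else 1.0
        edges = np.linspace(0.0, top, n_classes + 1)
        bv = np.asarray(bin_values, float)
        keep &= ~np.isnan(bv)
        bins = np.clip(np.digitize(np.where(keep, bv, 0.0), edges) - 1, 0,
                       n_classes - 1)
    cap = (np.zeros(len(values), bool) if capped is None
           else np.asarray(capped, bool))
    classes = []
    for b in range(n_classes):
        sel = keep & (bins == b)
        v = np.sort(values[sel])
        n_cap = int(cap[sel].sum())
        defined = len(v) > 0 and (n_cap / len(v) <= max_capped_fraction
                                  if len(v) else False)
        pct = ({q: float(np.percentile(v, q)) for q in PERCENTILES}
               if len(v) else {q: float("nan") for q in PERCENTILES})
        classes.append(_NullClass(v, pct, len(v), len(v) >= min_count, defined))
    return EmpiricalNull(statistic, population, bin_var, n_classes, edges,
                         classes, panel_id)


def percentile_rank(value: float, null: EmpiricalNull,
                    bin_value: float | None = None) -> float:
    return null.rank(value, bin_value)


@dataclass
class Evidence:
    statistic: str
    rank: float                          # percentile rank in the matched null
    family: str = ""
    tail: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            self.family = STAT_FAMILY[self.statistic]
        if not self.tail:
            self.tail = FAMILY_TAIL[self.family]

    def past_tail(self, alpha: float) -> bool:
        """Strictly past the alpha tail in the family's sweep direction."""
        if np.isnan(self.rank):
            return False
        return (self.rank < alpha) if self.tail == "low" else (self.rank > 1 - alpha)


@dataclass
class SelectionCall:
    gene: str
    population: str
    evidence: list[Evidence] = field(default_factory=list)
    verdict: str = "none"                # directional_target | balancing_candidate | none


def call_directional_targets(
    gene: str, population: str, evidence: list[Evidence],
    alpha_loose: float = 0.05, alpha_strict: float = 0.01, min_families: int = 3,
) -> SelectionCall:
    """Composite directional-selection verdict from multi-statistic evidence.

    directional_target iff >= ``min_families`` distinct signature families
    have a statistic past the 5% tail, or >= 2 families past the 1% tails.
    Tail boundaries are strict inequalities on the percentile rank.
    """
    fam5 = {e.family for e in evidence if e.past_tail(alpha_loose)}
    fam1 = {e.family for e in evidence if e.past_tail(alpha_strict)}
    verdict = "none"
    if len(fam5) >= min_families or len(fam1) >= 2:
        verdict = "directional_target"
    return SelectionCall(gene, population, list(evidence), verdict)


def flag_balancing_candidates(
    gene: str, ranks_by_pop: dict[str, dict[str, float]],
) -> SelectionCall:
    """Candidate iff whole-gene theta_W or pi rank > 0.95 in any population.

    ``ranks_by_pop`` maps population -> {"thetaW": rank, "pi": rank}.  The
    final balancing verdict is gated downstream on the MLHKA test.
    """
    evidence = []
    hit_pop = None
    for pop, ranks in ranks_by_pop.items():
        for stat in ("thetaW", "pi"):
            r = ranks.get(stat, float("nan"))
            evidence.append(Evidence(stat, r, family="diversity", tail="high"))
            if not np.isnan(r) and r > 0.95 and hit_pop is None:
                hit_pop = pop
    verdict = "balancing_candidate" if hit_pop else "none"
    return SelectionCall(gene, hit_pop or "", evidence, verdict)
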