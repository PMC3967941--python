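"""Extended haplotype homozygosity statistics: EHH, iHH, iHS, lnRsb, DIND.

All functions operate on a :class:`~popsel.haplotypes.HaplotypeMatrix`
restricted to one population (pass ``pop=`` to subset).  Sites with missing
calls in the working sample are dropped before any haplotype extension, and
focal sites are addressed by physical position (bp) so the dropping cannot
shift indices.

Conventions shared by all extensions: curves start at EHH=1 on the focal
SNP, are computed site by site outward, and are truncated at 100 kb per side
or when the curve falls below 0.05 (the convention of the standard EHH
tools); integrals (iHH, iES) are trapezoids over physical distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import MISSING, ANC_UNRESOLVED, HaplotypeMatrix

log = logging.getLogger(__name__)

MAX_EXTENT = 100_000  # bp per side
EHH_FLOOR = 0.05


@dataclass
class EHHResult:
    focal_pos: int
    allele: str                      # "ancestral" | "derived" | "pooled"
    side: str                        # "left" | "right"
    offsets: np.ndarray              # bp from the focal SNP, starting at 0
    ehh: np.ndarray                  # EHH values, ehh[0] == 1
    truncation: str                  # "floor" | "max_extent" | "end_of_data"

    @property
    def ihh(self) -> float:
        """Trapezoidal integral of the curve over physical distance."""
        return float(np.trapezoid(self.ehh, self.offsets))


@dataclass
class DINDResult:
    focal_pos: int
    daf: float
    ipi_a: float
    ipi_d: float
    dind: float
    capped: bool = False


def _working(hap: HaplotypeMatrix, pop: str | None):
    """Complete-call derived-coded matrix and positions for one population."""
    sub = hap.pop(pop) if pop is not None else hap
    complete = ~(sub.calls == MISSING).any(axis=0)
    der = sub.derived_calls()[:, complete]
    return sub, der, sub.positions[complete], sub.ancestral_state[complete]


def _homozygosity(groups: np.ndarray, denom: float) -> float:
    _, counts = np.unique(groups, return_counts=True)
    return float(sum(math.comb(int(k), 2) for k in counts) / denom)


def _extend(calls: np.ndarray, positions: np.ndarray, focal_idx: int,
            rows: np.ndarray, side: str, max_extent: int, floor: float,
            denom: float, start_value: float = 1.0):
    """Walk outward from the focal site refining haplotype groups."""
    step = -1 if side == "left" else 1
    j = focal_idx + step
    offsets = [0.0]
    values = [start_value]
    groups = np.zeros(len(rows), dtype=np.int64)
    truncation = "end_of_data"
    n_site = calls.shape[1]
    while 0 <= j < n_site:
        dist = abs(int(positions[j]) - int(positions[focal_idx]))
        if dist > max_extent:
            truncation = "max_extent"
            break
        col = calls[rows, j]
        groups = np.unique(groups * 2 + col, return_inverse=True)[1]
        val = _homozygosity(groups, denom) * start_value
        offsets.append(float(dist))
        values.append(val)
        if val < floor * start_value:
            truncation = "floor"
            break
        j += step
    return np.asarray(offsets), np.asarray(values), truncation


def ehh_curve(
    hap: HaplotypeMatrix, focal_pos: int, core: str, side: str,
    pop: str | None = None, max_extent: int = MAX_EXTENT, floor: float = EHH_FLOOR,
) -> EHHResult:
    """EHH for one core allele class on one side of the focal SNP.

    ``core`` is "ancestral" or "derived" (or "0"/"1" for raw alleles); the
    curve is Sum_h C(k_h,2) / C(k_core,2) over distinct extended haplotypes.
    """
    _, der, positions, _ = _working(hap, pop)
    idx = int(np.searchsorted(positions, focal_pos))
    if idx >= len(positions) or positions[idx] != focal_pos:
        raise KeyError(f"no complete-call site at position {focal_pos}")
    want = {"ancestral": 0, "derived": 1, "0": 0, "1": 1}[core]
    rows = np.where(der[:, idx] == want)[0]
    if len(rows) < 2:
        return EHHResult(focal_pos, core, side, np.array([0.0]),
                         np.array([np.nan]), "too_few_core")
    denom = math.comb(len(rows), 2)
    off, val, trunc = _extend(der, positions, idx, rows, side, max_extent,
                              floor, denom)
    return EHHResult(focal_pos, core, side, off, val, trunc)


def _ihh_both_sides(hap, focal_pos, core, pop, max_extent, floor) -> float:
    tot = 0.0
    for side in ("left", "right"):
        r = ehh_curve(hap, focal_pos, core, side, pop, max_extent, floor)
        if np.isnan(r.ehh).any():
            return float("nan")
        tot += r.ihh
    return tot


def ihs_unstandardized(
    hap: HaplotypeMatrix, focal_pos: int, pop: str | None = None,
    max_extent: int = MAX_EXTENT, floor: float = EHH_FLOOR,
) -> float:
    """ln(iHH_ancestral / iHH_derived); NaN when either class is degenerate."""
    sub = hap.pop(pop) if pop is not None else hap
    j = int(np.searchsorted(sub.positions, focal_pos))
    if j < len(sub.positions) and sub.positions[j] == focal_pos \
            and sub.ancestral_state[j] == ANC_UNRESOLVED:
        return float("nan")
    ihh_a = _ihh_both_sides(hap, focal_pos, "ancestral", pop, max_extent, floor)
    ihh_d = _ihh_both_sides(hap, focal_pos, "derived", pop, max_extent, floor)
    if not ihh_a or not ihh_d or math.isnan(ihh_a) or math.isnan(ihh_d):
        return float("nan")
    return math.log(ihh_a / ihh_d)


def standardize_ihs(
    raw: np.ndarray, daf: np.ndarray,
    cal_raw: np.ndarray | None = None, cal_daf: np.ndarray | None = None,
    n_bins: int = 50, min_bin: int = 50,
) -> np.ndarray:
    """Standardize unstandardized iHS within DAF bins of a calibration panel.

    iHS = (raw - mean_bin) / sd_bin with bin moments taken from the
    calibration set (the panel itself by default).  Queries falling in an
    empty calibration bin are missing; thin bins are logged.
    """
    raw = np.asarray(raw, float)
    daf = np.asarray(daf, float)
    if cal_raw is None:
        cal_raw, cal_daf = raw, daf
    cal_raw = np.asarray(cal_raw, float)
    cal_daf = np.asarray(cal_daf, float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cal_bin = np.clip(np.digitize(cal_daf, edges) - 1, 0, n_bins - 1)
    q_bin = np.clip(np.digitize(daf, edges) - 1, 0, n_bins - 1)
    out = np.full(len(raw), np.nan)
    for b in np.unique(q_bin):
        vals = cal_raw[(cal_bin == b) & ~np.isnan(cal_raw)]
        if len(vals) == 0:
            continue
        if len(vals) < min_bin:
            log.warning("iHS DAF bin %d has only %d calibration values", b, len(vals))
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        sel = q_bin == b
        if sd > 0:
            out[sel] = (raw[sel] - vals.mean()) / sd
        else:
            out[sel] = 0.0
    return out


def ehhs_ies(
    hap: HaplotypeMatrix, focal_pos: int, pop: str | None = None,
    max_extent: int = MAX_EXTENT, floor: float = EHH_FLOOR,
) -> float:
    """iES: integrated site-EHH pooled over alleles (Tang-style).

    EHHS(x) is the unbiased extended-haplotype homozygosity at distance x
    normalized by the homozygosity at the focal SNP itself, integrated over
    both sides with the shared truncation rules.
    """
    _, der, positions, _ = _working(hap, pop)
    idx = int(np.searchsorted(positions, focal_pos))
    if idx >= len(positions) or positions[idx] != focal_pos:
        raise KeyError(f"no complete-call site at position {focal_pos}")
    n = der.shape[0]
    denom = math.comb(n, 2)
    rows = np.arange(n)
    h0 = _homozygosity(der[:, idx].astype(np.int64), denom)
    if h0 == 0:
        return float("nan")
    tot = 0.0
    for side in ("left", "right"):
        # groups start already split by the focal alleles
        step = -1 if side == "left" else 1
        groups = der[:, idx].astype(np.int64)
        offsets = [0.0]
        values = [1.0]
        j = idx + step
        while 0 <= j < der.shape[1]:
            dist = abs(int(positions[j]) - int(positions[idx]))
            if dist > max_extent:
                break
            groups = np.unique(groups * 2 + der[rows, j], return_inverse=True)[1]
            val = _homozygosity(groups, denom) / h0
            offsets.append(float(dist))
            values.append(val)
            if val < floor:
                break
            j += step
        tot += float(np.trapezoid(values, offsets))
    return tot


def lnrsb_unnormalized(
    hap1: HaplotypeMatrix, hap2: HaplotypeMatrix, focal_pos: int,
    pop1: str | None = None, pop2: str | None = None,
    max_extent: int = MAX_EXTENT, floor: float = EHH_FLOOR,
) -> float:
    """lnRsb' = ln(iES_pop1 / iES_pop2) at a shared focal SNP."""
    ies1 = ehhs_ies(hap1, focal_pos, pop1, max_extent, floor)
    ies2 = ehhs_ies(hap2, focal_pos, pop2, max_extent, floor)
    if not ies1 or not ies2 or math.isnan(ies1) or math.isnan(ies2):
        return float("nan")
    return math.log(ies1 / ies2)


def normalize_lnrsb(values: np.ndarray, calibration: np.ndarray) -> np.ndarray:
    """(lnRsb' - median) / sd using a calibration SNP set."""
    cal = np.asarray(calibration, float)
    cal = cal[~np.isnan(cal)]
    med = np.median(cal)
    sd = cal.std(ddof=1)
    return (np.asarray(values, float) - med) / sd


def dind_statistic(
    hap: HaplotypeMatrix, focal_pos: int, pop: str | None = None,
    flank_variants: int = 40,
) -> DINDResult | None:
    """DIND = iπ_A / iπ_D over a constant number of flanking variants.

    iπ_A and iπ_D are mean pairwise differences over the ``flank_variants``
    sites nearest the focal SNP (half on each side) among ancestral and
    derived carriers.  SNPs without a full flank on each side get no DIND
    (None) — the constant flank count is what makes the DAF-binned null
    comparable.  iπ_D = 0 yields a capped result whose value is assigned
    panel-wide by :func:`apply_dind_cap`.
    """
    sub, der, positions, anc = _working(hap, pop)
    idx = int(np.searchsorted(positions, focal_pos))
    if idx >= len(positions) or positions[idx] != focal_pos:
        raise KeyError(f"no complete-call site at position {focal_pos}")
    if anc[idx] == ANC_UNRESOLVED:
        return None
    half = flank_variants // 2
    if idx < half or idx + half >= len(positions):
        return None  # not enough flanking variants on one side
    cols = np.r_[idx - half:idx, idx + 1:idx + half + 1]
    focal = der[:, idx]
    n = len(focal)
    daf = float(focal.sum() / n)
    out = {}
    for name, allele in (("A", 0), ("D", 1)):
        rows = np.where(focal == allele)[0]
        if len(rows) < 2:
            return DINDResult(focal_pos, daf, np.nan, np.nan, np.nan)
        k = len(rows)
        c = der[np.ix_(rows, cols)].sum(axis=0)
        out[name] = float((2.0 * c * (k - c)).sum() / (k * (k - 1)))
    if out["D"] == 0.0:
        return DINDResult(focal_pos, daf, out["A"], 0.0, np.nan, capped=True)
    return DINDResult(focal_pos, daf, out["A"], out["D"], out["A"] / out["D"])


def apply_dind_cap(df: pd.DataFrame, bonus: float = 20.0) -> pd.DataFrame:
    """Replace capped DIND values by the panel-wide finite maximum + bonus."""
    df = df.copy()
    finite = df.loc[~df["capped"], "dind"].dropna()
    cap = (float(finite.max()) if len(finite) else 0.0) + bonus
    df.loc[df["capped"], "dind"] = cap
    return df


def dind_table(
    hap: HaplotypeMatrix, pop: str | None = None, flank_variants: int = 40,
) -> pd.DataFrame:
    """DIND for every eligible SNP of a region (cap not yet applied)."""
    sub, der, positions, anc = _working(hap, pop)
    rows = []
    for pos in positions:
        r = dind_statistic(hap, int(pos), pop, flank_variants)
        if r is None or math.isnan(r.daf):
            continue
        rows.append({"pos": r.focal_pos, "DAF": r.daf, "ipi_A": r.ipi_a,
                     "ipi_D": r.ipi_d, "dind": r.dind, "capped": r.capped})
    return pd.DataFrame(rows, columns=["pos", "DAF", "ipi_A", "ipi_D",
                                       "dind", "capped"])
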