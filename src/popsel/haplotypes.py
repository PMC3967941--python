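"""Core haplotype data model: phased 0/1 calls, ancestral polarization, masks.

The central container is :class:`HaplotypeMatrix`: one row per haploid
chromosome, one column per biallelic site, values in {0 (ref), 1 (alt),
-1 (missing)}.  Sites are polarized against outgroup calls so that the
unfolded site frequency spectrum and derived-allele statistics (Fay & Wu's
H, DIND, iHS) are computable; polarization state is carried per site and
"unresolved" is a legal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: per-site ancestral state codes
ANC_REF = 0
ANC_ALT = 1
ANC_UNRESOLVED = -1

_ROLES = frozenset({"test_gene", "control_gene", "flank"})


@dataclass
class RegionSpec:
    """A genomic region, 1-based inclusive coordinates."""

    region_id: str
    chrom: str
    start: int
    end: int
    role: str = "test_gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.region_id}: start > end")
        if self.role not in _ROLES:
            raise ValueError(f"region role {self.role!r} not in {sorted(_ROLES)}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class AccessibilityMask:
    """Set of accessible intervals per chromosome.

    Intervals are stored 0-based half-open (the BED convention) and merged
    on construction, so overlap queries see a non-overlapping sorted set.
    """

    def __init__(self, intervals: dict[str, "np.ndarray | list"]):
        self._ivals: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            self._ivals[chrom] = _merge_intervals(a)

    def chroms(self) -> list[str]:
        return list(self._ivals)

    def accessible_bases(self, chrom: str, start: int, end: int) -> int:
        """Accessible bases within [start, end], 1-based inclusive."""
        ivals = self._ivals.get(chrom)
        if ivals is None or len(ivals) == 0:
            return 0
        lo, hi = start - 1, end  # half-open
        left = np.maximum(ivals[:, 0], lo)
        right = np.minimum(ivals[:, 1], hi)
        return int(np.maximum(right - left, 0).sum())

    def site_accessible(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean accessibility per 1-based position."""
        ivals = self._ivals.get(chrom)
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        if ivals is None or len(ivals) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(ivals[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < ivals[idx[ok], 1]
        return out


def _merge_intervals(a: np.ndarray) -> np.ndarray:
    if len(a) == 0:
        return a.reshape(0, 2)
    a = a[np.argsort(a[:, 0])]
    merged = [list(a[0])]
    for s, e in a[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def accessibility_fraction(
    region: RegionSpec, mask: AccessibilityMask, threshold: float = 0.80
) -> tuple[float, bool]:
    """Fraction of a region covered by the accessibility mask and a keep flag.

    Regions with less than ``threshold`` accessible sequence are dropped
    (keep=False); the boundary value itself is kept.
    """
    if region.length <= 0:
        raise ValueError("region length must be positive")
    frac = mask.accessible_bases(region.chrom, region.start, region.end) / region.length
    return frac, frac >= threshold


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes for one region, one or more populations.

    calls: (n_hap, n_site) int8 in {0, 1, -1}; 0/1 are ref/alt alleles.
    ancestral_state: per site, ANC_REF / ANC_ALT / ANC_UNRESOLVED.
    """

    region_id: str
    chrom: str
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    calls: np.ndarray
    pop_labels: np.ndarray
    ancestral_state: np.ndarray = field(default=None)  # type: ignore[assignment]
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.ancestral_state is None:
            self.ancestral_state = np.full(len(self.positions), ANC_REF, dtype=np.int8)
        self.ancestral_state = np.asarray(self.ancestral_state, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (haplotypes x sites)")
        n_hap, n_site = self.calls.shape
        if n_site != len(self.positions):
            raise ValueError("calls/positions dimension mismatch")
        if len(self.alleles) != n_site:
            raise ValueError("alleles/positions dimension mismatch")
        if len(self.ancestral_state) != n_site:
            raise ValueError("ancestral_state/positions dimension mismatch")
        if n_hap < 2:
            raise ValueError("need at least 2 haplotypes")
        if len(self.pop_labels) != n_hap:
            raise ValueError("pop_labels/calls dimension mismatch")
        if n_site and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.start is None:
            self.start = int(self.positions[0]) if n_site else 1
        if self.end is None:
            self.end = int(self.positions[-1]) if n_site else 1

    @property
    def n_hap(self) -> int:
        return self.calls.shape[0]

    @property
    def n_site(self) -> int:
        return self.calls.shape[1]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop(self, code: str) -> "HaplotypeMatrix":
        """Submatrix restricted to one population."""
        sel = self.pop_labels == code
        if not sel.any():
            raise KeyError(f"no haplotypes labeled {code!r}")
        return HaplotypeMatrix(
            self.region_id, self.chrom, self.positions, self.alleles,
            self.calls[sel], self.pop_labels[sel], self.ancestral_state,
            start=self.start, end=self.end,
        )

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            self.region_id, self.chrom, self.positions[idx],
            [self.alleles[i] for i in np.atleast_1d(idx)],
            self.calls[:, idx], self.pop_labels, self.ancestral_state[idx],
            start=self.start, end=self.end,
        )

    def derived_calls(self) -> np.ndarray:
        """Calls recoded as 0=ancestral, 1=derived; missing preserved.

        Unresolved sites keep the ref/alt coding (callers should mask them).
        """
        out = self.calls.copy()
        flip = self.ancestral_state == ANC_ALT
        cols = out[:, flip]
        swapped = np.where(cols == MISSING, MISSING, 1 - cols)
        out[:, flip] = swapped
        return out

    def resolved(self) -> np.ndarray:
        return self.ancestral_state != ANC_UNRESOLVED

    def site_table(self, accessible: np.ndarray | None = None) -> pd.DataFrame:
        """Per-site DAF/MAF per population (reduced n at sites with missing)."""
        der = self.derived_calls()
        rows = []
        for pop in self.populations():
            sub = der[self.pop_labels == pop]
            ok = sub != MISSING
            n_called = ok.sum(axis=0)
            cnt = np.where(ok, sub, 0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                daf = np.where(n_called > 0, cnt / np.maximum(n_called, 1), np.nan)
            resolved = self.resolved()
            daf = np.where(resolved, daf, np.nan)
            # MAF is computable even without polarization
            sub_raw = self.calls[self.pop_labels == pop]
            okr = sub_raw != MISSING
            nr = okr.sum(axis=0)
            alt = np.where(okr, sub_raw, 0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                paf = np.where(nr > 0, alt / np.maximum(nr, 1), np.nan)
            maf = np.minimum(paf, 1 - paf)
            rows.append(pd.DataFrame({
                "position": self.positions,
                "pop": pop,
                "DAF": daf,
                "MAF": maf,
                "ancestral_resolved": resolved,
                "accessible": (np.ones(self.n_site, bool)
                               if accessible is None else accessible),
            }))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["position", "pop", "DAF", "MAF", "ancestral_resolved", "accessible"])


def polarize_ancestral(
    site_alleles: tuple[str, str],
    outgroup_alleles: "list[str | None]",
) -> int:
    """Ancestral state of one biallelic site by outgroup parsimony.

    The first outgroup call is the closest outgroup (chimpanzee); it sets the
    ancestral allele when at least one other outgroup agrees or when no other
    outgroup is informative.  Disagreements without a majority, or outgroups
    matching neither human allele, leave the site unresolved.
    """
    ref, alt = site_alleles
    calls = [c for c in outgroup_alleles if c]
    if not calls:
        raise ValueError("at least one outgroup call required")

    def state(c: str) -> int | None:
        if c == ref:
            return ANC_REF
        if c == alt:
            return ANC_ALT
        return None

    states = [state(c) for c in calls]
    informative = [s for s in states if s is not None]
    if not informative:
        return ANC_UNRESOLVED
    closest = states[0]
    if closest is not None:
        others = [s for s in states[1:] if s is not None]
        if not others or closest in others:
            return closest
    # closest outgroup missing/uninformative or contradicted: simple majority
    n_ref = informative.count(ANC_REF)
    n_alt = informative.count(ANC_ALT)
    if n_ref > n_alt:
        return ANC_REF
    if n_alt > n_ref:
        return ANC_ALT
    return ANC_UNRESOLVED
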