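"""Per-SNP FST between population pairs (Hudson 1992 estimator).

FST = 1 - Hw/Hb with Hw the mean within-population heterozygosity corrected
for sample size (2p(1-p) n/(n-1)) and Hb = p1(1-p2) + p2(1-p1).  Slightly
negative estimates are reported as-is so empirical percentile nulls stay
unbiased; sites monomorphic in the pooled sample are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .haplotypes import MISSING, HaplotypeMatrix


def fst_per_snp(c1: int, n1: int, c2: int, n2: int) -> float:
    """Hudson FST from allele count/sample size in each population."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 sampled chromosomes per population")
    if (c1 + c2 == 0) or (c1 + c2 == n1 + n2):
        return float("nan")
    p1, p2 = c1 / n1, c2 / n2
    hw = 0.5 * (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb == 0:
        return float("nan")
    return 1.0 - hw / hb


def fst_table(hap: HaplotypeMatrix, pop1: str, pop2: str) -> pd.DataFrame:
    """Per-SNP FST for one labeled population pair of a region.

    Missing calls reduce the per-site sample size; sites where either
    population has fewer than 2 called chromosomes are skipped.
    """
    rows = []
    sub1 = hap.calls[hap.pop_labels == pop1]
    sub2 = hap.calls[hap.pop_labels == pop2]
    for j in range(hap.n_site):
        a1, a2 = sub1[:, j], sub2[:, j]
        ok1, ok2 = a1 != MISSING, a2 != MISSING
        n1, n2 = int(ok1.sum()), int(ok2.sum())
        if n1 < 2 or n2 < 2:
            continue
        c1, c2 = int(a1[ok1].sum()), int(a2[ok2].sum())
        p_pool = (c1 + c2) / (n1 + n2)
        rows.append({
            "chrom": hap.chrom, "pos": int(hap.positions[j]),
            "pair": f"{pop1}/{pop2}",
            "p1": c1 / n1, "p2": c2 / n2,
            "MAF_pooled": min(p_pool, 1 - p_pool),
            "FST": fst_per_snp(c1, n1, c2, n2),
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "pair", "p1", "p2",
                                       "MAF_pooled", "FST"])
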