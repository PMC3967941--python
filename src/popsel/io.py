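"""Readers and writers for the package's on-disk formats.

Phased variant data come in as VCF (phased GT, biallelic SNPs; the ``AA``
INFO tag, when present, polarizes sites) or as a plain haplotype table
(rows = haplotypes, header = positions).  Masks and region lists are BED
(0-based half-open, converted to the package's 1-based inclusive coordinates
on ingest); population assignments are a two-column sample→population TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import (
    ANC_ALT, ANC_REF, ANC_UNRESOLVED, MISSING,
    AccessibilityMask, HaplotypeMatrix, RegionSpec,
)

log = logging.getLogger(__name__)


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Sample → population map from a headerless two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    return dict(zip(df["sample"], df["pop"]))


def read_mask_bed(path: str | Path) -> AccessibilityMask:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    ivals: dict[str, list] = {}
    for chrom, g in df.groupby("chrom"):
        ivals[str(chrom)] = g[["start", "end"]].to_numpy()
    return AccessibilityMask(ivals)


def read_regions_bed(path: str | Path, role: str = "test_gene") -> list[RegionSpec]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    regions = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"region{i}"
        r = str(row[4]) if df.shape[1] > 4 and str(row[4]) in (
            "test_gene", "control_gene", "flank") else role
        regions.append(RegionSpec(name, str(row[0]), int(row[1]) + 1, int(row[2]), r))
    return regions


def read_haplotypes(
    vcf_path: str | Path,
    region: RegionSpec,
    pops: dict[str, str],
) -> HaplotypeMatrix:
    """Load phased haplotypes for one region from a VCF.

    Multiallelic, non-SNP, and unphased sites are skipped (counts logged);
    missing calls are preserved.  The ``AA`` INFO tag, when present and
    matching one of the alleles, sets the per-site ancestral state.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    keep = [i for i, s in enumerate(samples) if s in pops]
    if not keep:
        raise ValueError("no samples in the VCF match the population map")
    labels = []
    for i in keep:
        labels.extend([pops[samples[i]]] * 2)

    positions, alleles, anc, rows = [], [], [], []
    n_skip_multi = n_skip_unphased = 0
    try:  # region query needs a tabix index; plain-text VCFs are scanned
        records = vcf(f"{region.chrom}:{region.start}-{region.end}")
        records = list(records)
    except Exception:
        records = (v for v in vcf
                   if v.CHROM == region.chrom and region.start <= v.POS <= region.end)
    for v in records:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skip_multi += 1
            continue
        gts = v.genotypes  # [a1, a2, phased] per sample
        col = np.empty(2 * len(keep), dtype=np.int8)
        phased = True
        for j, i in enumerate(keep):
            a1, a2, ph = gts[i][0], gts[i][1], gts[i][2]
            if not ph and a1 != a2:  # homozygous calls are phase-unambiguous
                phased = False
                break
            col[2 * j] = MISSING if a1 < 0 else a1
            col[2 * j + 1] = MISSING if a2 < 0 else a2
        if not phased:
            n_skip_unphased += 1
            continue
        positions.append(v.POS)
        alleles.append((v.REF, v.ALT[0]))
        aa = v.INFO.get("AA")
        if aa is None:
            anc.append(ANC_REF)
        else:
            aa = str(aa).upper()
            anc.append(ANC_REF if aa == v.REF else ANC_ALT if aa == v.ALT[0]
                       else ANC_UNRESOLVED)
        rows.append(col)
    if n_skip_multi or n_skip_unphased:
        log.info("region %s: skipped %d multiallelic/non-SNP and %d unphased sites",
                 region.region_id, n_skip_multi, n_skip_unphased)
    calls = (np.asarray(rows, dtype=np.int8).T if rows
             else np.zeros((2 * len(keep), 0), dtype=np.int8))
    return HaplotypeMatrix(
        region.region_id, region.chrom, np.asarray(positions, np.int64),
        alleles, calls, np.asarray(labels, object),
        np.asarray(anc, np.int8), start=region.start, end=region.end,
    )


def write_vcf(hap: HaplotypeMatrix, path: str | Path, sample_prefix: str = "S") -> None:
    """Write a HaplotypeMatrix as a phased VCF (pairs of rows = one sample).

    Ancestral states are emitted in the ``AA`` INFO field ('.' when
    unresolved) so a read round-trip preserves polarization.
    """
    if hap.n_hap % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    n_samp = hap.n_hap // 2
    names = [f"{sample_prefix}{i}" for i in range(n_samp)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(hap.n_site):
            ref, alt = hap.alleles[j]
            aa = (ref if hap.ancestral_state[j] == ANC_REF
                  else alt if hap.ancestral_state[j] == ANC_ALT else ".")
            gts = []
            for s in range(n_samp):
                a1, a2 = hap.calls[2 * s, j], hap.calls[2 * s + 1, j]
                f1 = "." if a1 == MISSING else str(int(a1))
                f2 = "." if a2 == MISSING else str(int(a2))
                gts.append(f"{f1}|{f2}")
            fh.write(f"{hap.chrom}\t{hap.positions[j]}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"AA={aa}\tGT\t" + "\t".join(gts) + "\n")


def write_haplotype_table(hap: HaplotypeMatrix, path: str | Path) -> None:
    """Plain haplotype table: rows = haplotypes, header = positions."""
    df = pd.DataFrame(hap.calls, columns=[str(p) for p in hap.positions])
    df.insert(0, "pop", hap.pop_labels)
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_table(
    path: str | Path, region_id: str = "region", chrom: str = "1",
    ancestral_state: np.ndarray | None = None,
) -> HaplotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    pops = df.pop("pop").to_numpy(object) if "pop" in df.columns else np.asarray(
        ["pop1"] * len(df), object)
    positions = np.asarray([int(c) for c in df.columns], np.int64)
    calls = df.to_numpy(dtype=np.int8)
    alleles = [("A", "G")] * len(positions)
    return HaplotypeMatrix(region_id, chrom, positions, alleles, calls, pops,
                           ancestral_state)
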