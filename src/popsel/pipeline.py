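"""Orchestration of the two workflows: the directional scan and the follow-up.

The scan computes whole-gene diversity/SFS statistics for a control-locus
panel and for test genes, per-SNP FST (MAF-binned null, 50 classes) and DIND
(DAF-binned null, 100 classes) over the same loci, then issues composite
directional-selection calls and flags balancing candidates.  The follow-up
runs the MLHKA test, coalescent p-values and TMRCA on candidate regions, and
the penetrance-model association on genotype tables.

Every results directory contains the resolved configuration (YAML), the
seed, and the package version, so deterministic outputs reproduce exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import sfs
from .balancing import coalescent_pvalue, tmrca_pairwise
from .ehh import apply_dind_cap, dind_table, ihs_unstandardized, standardize_ihs
from .fst import fst_table
from .haplotypes import HaplotypeMatrix
from .hka import HKALocus, MLHKA
from .outliers import (
    EmpiricalNull, Evidence, SelectionCall, build_empirical_null,
    call_directional_targets, flag_balancing_candidates,
)

GENE_STATS = ("thetaW", "pi", "TajD", "FuLiDstar", "FuLiFstar", "FayWuHnorm")


@dataclass
class PipelineConfig:
    populations: list[str] = field(default_factory=lambda: ["pop1", "pop2"])
    pairs: list[tuple[str, str]] = field(default_factory=lambda: [("pop1", "pop2")])
    window_span: int = 5000
    window_step: int = 500
    maf_classes: int = 50
    daf_classes: int = 100
    alpha_loose: float = 0.05
    alpha_strict: float = 0.01
    min_families: int = 3
    flank_bp: int = 50_000
    dind_flank_variants: int = 40
    simulation_iterations: int = 10_000
    permutations: int = 10_000
    kp: float = 0.20
    seed: int = 0
    compute_ihs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairs" in raw:
            raw["pairs"] = [tuple(p) for p in raw["pairs"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["pairs"] = [list(p) for p in self.pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def gene_statistics(loci: list[HaplotypeMatrix], populations: list[str],
                    lengths: dict[str, float] | None = None) -> pd.DataFrame:
    """Whole-gene diversity and SFS statistics per locus and population.

    ``lengths`` optionally maps region_id to accessible length (bp) for the
    per-site scaling; the raw region span is used otherwise.
    """
    rows = []
    for hap in loci:
        span = float((hap.end or 1) - (hap.start or 1) + 1)
        L = (lengths or {}).get(hap.region_id, span)
        for pop in populations:
            if pop not in hap.populations():
                continue
            c = sfs.sfs_counts(hap, pop, L=L)
            dstar, fstar = sfs.fu_li_star(c)
            rows.append({
                "region_id": hap.region_id, "pop": pop, "n": c.n, "S": c.S,
                "thetaW": sfs.watterson_theta(c, per_site=True),
                "pi": sfs.nucleotide_diversity_pi(c, per_site=True),
                "TajD": sfs.tajimas_d(c),
                "FuLiDstar": dstar, "FuLiFstar": fstar,
                "FayWuHnorm": sfs.fay_wu_h_norm(c),
            })
    return pd.DataFrame(rows)


def snp_statistics(loci: list[HaplotypeMatrix], populations: list[str],
                   pairs: list[tuple[str, str]],
                   dind_flank_variants: int = 40) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP FST (per pair) and DIND (per population) tables.

    The DIND cap for iπ_D = 0 is applied per population across the whole
    dataset (panel maximum + 20), as the calibration requires.
    """
    fst_rows, dind_rows = [], []
    for hap in loci:
        pops_here = set(hap.populations())
        for p1, p2 in pairs:
            if p1 in pops_here and p2 in pops_here:
                t = fst_table(hap, p1, p2)
                t.insert(0, "region_id", hap.region_id)
                fst_rows.append(t)
        for pop in populations:
            if pop in pops_here:
                t = dind_table(hap, pop, dind_flank_variants)
                if len(t):
                    t.insert(0, "region_id", hap.region_id)
                    t.insert(1, "pop", pop)
                    dind_rows.append(t)
    fst_df = pd.concat(fst_rows, ignore_index=True) if fst_rows else pd.DataFrame(
        columns=["region_id", "chrom", "pos", "pair", "p1", "p2", "MAF_pooled", "FST"])
    dind_df = pd.concat(dind_rows, ignore_index=True) if dind_rows else pd.DataFrame(
        columns=["region_id", "pop", "pos", "DAF", "ipi_A", "ipi_D", "dind", "capped"])
    if len(dind_df):
        dind_df = pd.concat([apply_dind_cap(g) for _, g in dind_df.groupby("pop")],
                            ignore_index=True)
    return fst_df, dind_df


def _outlier_fraction(values, bins, null: EmpiricalNull,
                      threshold: float = 0.95) -> float:
    """Fraction of a gene's SNPs past the per-SNP 95th percentile."""
    ranks = [null.rank(v, b) for v, b in zip(values, bins) if not np.isnan(v)]
    ranks = [r for r in ranks if not np.isnan(r)]
    if not ranks:
        return float("nan")
    return float(np.mean([r > threshold for r in ranks]))


def build_scan_nulls(gene_df: pd.DataFrame, fst_df: pd.DataFrame,
                     dind_df: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Empirical nulls from the control panel.

    Gene-level statistics get unbinned nulls; per-SNP FST and DIND get
    MAF- and DAF-binned nulls (50/100 classes).  The SNP-based families are
    additionally calibrated at the gene level: each control gene's fraction
    of outlier SNPs (per-SNP rank > 0.95) forms a second-stage null, so a
    test gene's haplotype/differentiation evidence is an exchangeable
    percentile rank rather than a max over many SNPs.
    """
    nulls: dict = {}
    for pop, g in gene_df.groupby("pop"):
        for stat in GENE_STATS:
            nulls[(stat, pop)] = build_empirical_null(
                g[stat].to_numpy(), statistic=stat, population=pop,
                panel_id="control_panel")
    for pair, g in fst_df.groupby("pair"):
        null = build_empirical_null(
            g["FST"].to_numpy(), statistic="FST", population=pair,
            bin_values=g["MAF_pooled"].to_numpy(), bin_var="MAF",
            n_classes=cfg.maf_classes, panel_id="control_panel")
        nulls[("FST", pair)] = null
        fracs = [
            _outlier_fraction(gg["FST"].to_numpy(), gg["MAF_pooled"].to_numpy(), null)
            for _, gg in g.groupby("region_id")]
        nulls[("FST_gene", pair)] = build_empirical_null(
            np.asarray(fracs), statistic="FST_gene", population=pair,
            panel_id="control_panel")
    for pop, g in dind_df.groupby("pop"):
        null = build_empirical_null(
            g["dind"].to_numpy(), statistic="DIND", population=pop,
            bin_values=g["DAF"].to_numpy(), bin_var="DAF",
            n_classes=cfg.daf_classes, capped=g["capped"].to_numpy(),
            panel_id="control_panel")
        nulls[("DIND", pop)] = null
        fracs = [
            _outlier_fraction(gg["dind"].to_numpy(), gg["DAF"].to_numpy(), null)
            for _, gg in g.groupby("region_id")]
        nulls[("DIND_gene", pop)] = build_empirical_null(
            np.asarray(fracs), statistic="DIND_gene", population=pop,
            panel_id="control_panel")
    return nulls


def score_test_genes(gene_df: pd.DataFrame, fst_df: pd.DataFrame,
                     dind_df: pd.DataFrame, nulls: dict,
                     cfg: PipelineConfig) -> tuple[list[SelectionCall], pd.DataFrame]:
    """Composite directional calls and balancing candidates for test genes."""
    calls: list[SelectionCall] = []
    rank_rows = []
    genes = gene_df["region_id"].unique()
    for gene in genes:
        ranks_by_pop: dict[str, dict[str, float]] = {}
        for pop in cfg.populations:
            row = gene_df[(gene_df.region_id == gene) & (gene_df["pop"] == pop)]
            evidence: list[Evidence] = []
            if len(row):
                row = row.iloc[0]
                for stat in GENE_STATS:
                    null = nulls.get((stat, pop))
                    if null is None:
                        continue
                    r = null.rank(float(row[stat]))
                    evidence.append(Evidence(stat, r))
                    rank_rows.append({"region_id": gene, "pop": pop,
                                      "statistic": stat, "value": float(row[stat]),
                                      "rank": r})
                ranks_by_pop[pop] = {
                    "thetaW": nulls[("thetaW", pop)].rank(float(row["thetaW"])),
                    "pi": nulls[("pi", pop)].rank(float(row["pi"])),
                }
            # FST: gene-level rank of the outlier-SNP fraction, per pair
            for pair_key, g in fst_df[fst_df.region_id == gene].groupby("pair"):
                if pop not in pair_key.split("/"):
                    continue
                null = nulls.get(("FST", pair_key))
                gene_null = nulls.get(("FST_gene", pair_key))
                if null is None or gene_null is None or not len(g):
                    continue
                frac = _outlier_fraction(g["FST"].to_numpy(),
                                         g["MAF_pooled"].to_numpy(), null)
                if np.isnan(frac):
                    continue
                r = gene_null.rank(frac)
                evidence.append(Evidence("FST", r))
                rank_rows.append({"region_id": gene, "pop": pop,
                                  "statistic": f"FST[{pair_key}]",
                                  "value": frac, "rank": r})
            gd = dind_df[(dind_df.region_id == gene) & (dind_df["pop"] == pop)]
            null = nulls.get(("DIND", pop))
            gene_null = nulls.get(("DIND_gene", pop))
            if null is not None and gene_null is not None and len(gd):
                frac = _outlier_fraction(gd["dind"].to_numpy(),
                                         gd["DAF"].to_numpy(), null)
                if not np.isnan(frac):
                    r = gene_null.rank(frac)
                    evidence.append(Evidence("DIND", r))
                    rank_rows.append({"region_id": gene, "pop": pop,
                                      "statistic": "DIND",
                                      "value": frac, "rank": r})
            calls.append(call_directional_targets(
                gene, pop, evidence, cfg.alpha_loose, cfg.alpha_strict,
                cfg.min_families))
        calls.append(flag_balancing_candidates(gene, ranks_by_pop))
    return calls, pd.DataFrame(rank_rows)


def calls_frame(calls: list[SelectionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "gene": c.gene, "pop": c.population, "verdict": c.verdict,
            "evidence": ";".join(f"{e.statistic}:{e.rank:.3f}" for e in c.evidence
                                 if not np.isnan(e.rank)),
        })
    return pd.DataFrame(rows)


def run_scan(
    cfg: PipelineConfig,
    outdir: str | Path,
    panel: list[HaplotypeMatrix],
    test_loci: list[HaplotypeMatrix],
) -> Path:
    """Directional scan: panel nulls, test-gene scoring, call tables on disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not panel:
        raise RuntimeError("no control panel: generate or load one before scanning")
    pops = cfg.populations
    gene_panel = gene_statistics(panel, pops)
    gene_test = gene_statistics(test_loci, pops)
    fst_panel, dind_panel = snp_statistics(panel, pops, cfg.pairs,
                                           cfg.dind_flank_variants)
    fst_test, dind_test = snp_statistics(test_loci, pops, cfg.pairs,
                                         cfg.dind_flank_variants)
    nulls = build_scan_nulls(gene_panel, fst_panel, dind_panel, cfg)
    calls, ranks = score_test_genes(gene_test, fst_test, dind_test, nulls, cfg)

    gene_test.to_csv(out / "gene_stats.tsv", sep="\t", index=False)
    fst_test.to_csv(out / "fst_snps.tsv", sep="\t", index=False)
    dind_test.to_csv(out / "dind_snps.tsv", sep="\t", index=False)
    ranks.to_csv(out / "ranks.tsv", sep="\t", index=False)
    calls_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    if cfg.compute_ihs:
        ihs_df = _ihs_tables(panel, test_loci, pops)
        ihs_df.to_csv(out / "ihs_snps.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "config.yaml")
    (out / "run.json").write_text(json.dumps(
        {"popsel_version": _version, "seed": cfg.seed}, indent=2))
    return out


def _ihs_tables(panel, test_loci, pops) -> pd.DataFrame:
    """Standardized iHS for test-gene SNPs, calibrated on panel SNPs."""
    rows = []
    for kind, loci in (("calibration", panel), ("test", test_loci)):
        for hap in loci:
            for pop in pops:
                if pop not in hap.populations():
                    continue
                sub = hap.pop(pop)
                daf = sub.derived_calls().mean(axis=0)
                for j, pos in enumerate(sub.positions):
                    d = float(daf[j])
                    if d <= 0 or d >= 1:
                        continue
                    raw = ihs_unstandardized(hap, int(pos), pop)
                    rows.append({"kind": kind, "region_id": hap.region_id,
                                 "pop": pop, "pos": int(pos), "DAF": d,
                                 "ihs_raw": raw})
    df = pd.DataFrame(rows)
    out = []
    for pop, g in df.groupby("pop"):
        cal = g[g.kind == "calibration"]
        t = g[g.kind == "test"].copy()
        t["iHS"] = standardize_ihs(t["ihs_raw"].to_numpy(), t["DAF"].to_numpy(),
                                   cal["ihs_raw"].to_numpy(), cal["DAF"].to_numpy())
        out.append(t)
    return pd.concat(out, ignore_index=True) if out else df


def run_followup(
    cfg: PipelineConfig,
    outdir: str | Path,
    hka_loci: dict[str, list[HKALocus]] | None = None,
    candidate_haps: list[HaplotypeMatrix] | None = None,
    candidate_thetas: dict[str, float] | None = None,
    mu_year: float | None = None,
    genotype_tables: list[tuple] | None = None,
    rng: np.random.Generator | None = None,
) -> Path:
    """Balancing/association follow-up on candidate regions.

    hka_loci maps population -> loci list (reference + test); candidates are
    reported balancing only when the MLHKA rejects neutrality (p < 0.05).
    """
    from .association import PenetranceModel, hwe_exact_test, permutation_association, select_best_model_aic

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    results: dict = {"popsel_version": _version, "seed": cfg.seed}

    if hka_loci:
        hka_out = {}
        for pop, loci in hka_loci.items():
            r = MLHKA(loci).fit()
            hka_out[pop] = {"T": r.T, "k": r.k, "LRT": r.lrt, "df": r.df,
                            "p": r.pvalue,
                            "theta": {l.locus_id: t for l, t in zip(r.loci, r.theta)}}
        results["mlhka"] = hka_out
        results["balancing_confirmed"] = sorted({
            lid for pop, d in hka_out.items() for lid in d["k"]
            if d["p"] < 0.05})

    if candidate_haps:
        sim_rows, tmrca_rows = [], []
        for hap in candidate_haps:
            for pop in hap.populations():
                c = sfs.sfs_counts(hap, pop)
                theta = (candidate_thetas or {}).get(
                    hap.region_id, sfs.watterson_theta(c))
                for stat in ("TajD", "FuLiDstar", "FuLiFstar"):
                    from .balancing import STAT_FUNCTIONS
                    obs = STAT_FUNCTIONS[stat](c)
                    if np.isnan(obs):
                        continue
                    p = coalescent_pvalue(obs, stat, c.n, theta,
                                          iterations=cfg.simulation_iterations,
                                          tail="upper", rng=rng)
                    sim_rows.append({"region_id": hap.region_id, "pop": pop,
                                     "stat": stat, "observed": obs, "p": p})
            if mu_year:
                t = tmrca_pairwise(hap, mu_year, rng=rng)
                tmrca_rows.append({"region_id": hap.region_id,
                                   "tmrca_years": t.tmrca_years,
                                   "sd_years": t.sd_years, "method": t.method})
        pd.DataFrame(sim_rows).to_csv(out / "coalescent_pvalues.tsv",
                                      sep="\t", index=False)
        if tmrca_rows:
            pd.DataFrame(tmrca_rows).to_csv(out / "tmrca.tsv", sep="\t", index=False)

    if genotype_tables:
        assoc = []
        for cases, controls in genotype_tables:
            model = PenetranceModel(cases, controls, cfg.kp)
            fits = model.fit_all(seed=cfg.seed)
            best = select_best_model_aic(fits)
            assoc.append({
                "cases": cases.label, "controls": controls.label,
                "hwe_p_cases": hwe_exact_test(cases),
                "hwe_p_controls": hwe_exact_test(controls),
                "best_model": best.model,
                "fits": [{k: (float(v) if isinstance(v, (int, float)) else v)
                          for k, v in (("model", f.model), ("q", f.q),
                                       ("alpha", f.alpha), ("beta", f.beta),
                                       ("gamma", f.gamma), ("chi2", f.chi2),
                                       ("df", f.df), ("p", f.pvalue),
                                       ("AIC", f.aic))} for f in fits],
                "perm_p_genotypic": permutation_association(
                    cases, controls, "genotypic", cfg.permutations, rng=rng),
                "perm_p_recessive": permutation_association(
                    cases, controls, "recessive", cfg.permutations, rng=rng),
            })
        results["association"] = assoc

    cfg.to_yaml(out / "config.yaml")
    (out / "followup.json").write_text(json.dumps(results, indent=2, default=float))
    return out
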