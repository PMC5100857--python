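"""End-to-end orchestration: duplicate-pair discovery, Ka/Ks and the
purifying-selection LRT, per-stage region methylation and P_CG classes,
divergence and specificity indices, expression statistics and the
correlation/enrichment tables.

``run_pipeline`` is a pure function of (inputs, config): repeated runs
byte-match.  Every run writes a ``run_metadata.json`` carrying the
config hash, stage counts and per-table row counts, so any output table
can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import codonml, duplicates, io, methylation, stats

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "report_summary"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any compute when a run configuration is invalid."""


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    proteins: str = ""
    cds: str = ""
    hits: str = ""
    annotation: str = ""
    chrom_sizes: str = ""
    expression: str = ""
    outgroup: str = ""
    domains: str = ""
    promoters: str = ""
    methylomes: dict = field(default_factory=dict)  # stage -> path
    outdir: str = "results"
    # parameters
    focal_stage: str = "16-cell"
    embryo_stages: tuple = methylation.EMBRYO_STAGES
    promoter_len: int = 2000
    min_cov: int = 2
    call_threshold: float = 0.5
    min_ncg: int = 20
    min_coverage_fraction: float = 0.60
    merge_dyads: bool = True
    spike_chrom: str = "lambda_spike"
    ks_min: float = 0.01
    ks_max: float = 2.0
    omega_null: float = 0.5
    n_bins: int = 20
    mcl_inflation: float = 2.0
    run_lrt: bool = True
    substitution_rate: float = 4.13e-9
    fpkm_log_offset: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = ["proteins", "cds", "hits", "annotation", "chrom_sizes", "expression"]
        for key in required:
            path = getattr(self, key)
            if not path:
                raise ConfigError(f"config key {key!r} is required")
            if not os.path.exists(path):
                raise ConfigError(f"{key}: no such file {path!r}")
        for key in ("outgroup", "domains", "promoters"):
            path = getattr(self, key)
            if path and not os.path.exists(path):
                raise ConfigError(f"{key}: no such file {path!r}")
        if not self.methylomes:
            raise ConfigError("at least one methylome path is required")
        for stage, path in self.methylomes.items():
            if not os.path.exists(path):
                raise ConfigError(f"methylome {stage!r}: no such file {path!r}")
        if self.focal_stage not in self.methylomes:
            raise ConfigError(f"focal stage {self.focal_stage!r} has no methylome")
        if not 0 < self.call_threshold <= 1:
            raise ConfigError("call_threshold must be in (0, 1]")
        if self.min_cov < 1 or self.min_ncg < 1 or self.n_bins < 2:
            raise ConfigError("min_cov, min_ncg and n_bins must be positive")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _discover_pairs(cfg: RunConfig, counts: dict):
    proteins = io.read_fasta(cfg.proteins)
    lengths = io.sequence_lengths(proteins)
    hits = io.read_blast_tab(cfg.hits)
    counts["hits"] = len(hits)
    passing = duplicates.filter_homolog_pairs(hits, lengths)
    counts["passing_hits"] = len(passing)
    nodes = sorted({h.query_id for h in passing} | {h.subject_id for h in passing})
    edges = [(h.query_id, h.subject_id, h.identity) for h in passing]
    families = duplicates.mcl_cluster(nodes, edges, inflation=cfg.mcl_inflation)
    counts["families"] = len(families)
    fam_rows = [
        {"family_id": f"fam{i:04d}", "member": m}
        for i, fam in enumerate(families)
        for m in sorted(fam)
    ]
    return proteins, families, pd.DataFrame(fam_rows)


def _codon_alignments(cfg: RunConfig, proteins):
    cds = {r.id: r.seq for r in io.read_fasta(cfg.cds)}
    prot = {r.id: r.seq for r in proteins}
    cache: dict = {}

    def get(g1, g2):
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        if key not in cache:
            a, b = key
            if a not in cds or b not in cds or len(prot[a]) != len(prot[b]):
                # pre-aligned equal-length proteins are required; an external
                # protein aligner is out of scope here
                cache[key] = None
            else:
                try:
                    cache[key] = codonml.backtranslate(prot[a], prot[b], cds[a], cds[b])
                except ValueError:
                    cache[key] = None
        return cache[key]

    return get


def _kaks_stage(cfg: RunConfig, families, aln_of_pair, counts: dict) -> pd.DataFrame:
    ng_cache: dict = {}

    def ks_of_pair(g1, g2):
        key = (g1, g2)
        if key not in ng_cache:
            aln = aln_of_pair(g1, g2)
            ng_cache[key] = codonml.ng86_kaks(aln) if aln is not None else None
        res = ng_cache[key]
        return res.ks if res is not None else math.nan

    reps = duplicates.select_representative_pairs(families, ks_of_pair, cfg.ks_min, cfg.ks_max)
    counts["representative_pairs"] = len(reps)
    rows = []
    for g1, g2, ks in reps:
        aln = aln_of_pair(g1, g2)
        ng = codonml.ng86_kaks(aln)
        row = {
            "pair_id": f"{g1}__{g2}", "gene1": g1, "gene2": g2,
            "ka": ng.ka, "ks": ng.ks, "omega_ng86": ng.omega,
        }
        if cfg.run_lrt:
            model = codonml.CodonPairML(aln)
            fit_fixed = model.fit(fixed_omega=cfg.omega_null)
            fit_free = model.fit()
            stat, p = codonml.lrt_purifying(fit_fixed, fit_free)
            row.update(
                t_ml=fit_free.t, kappa_ml=fit_free.kappa, omega_ml=fit_free.omega,
                lnl_fixed=fit_fixed.llf, lnl_free=fit_free.llf,
                lrt_stat=stat, p_value=p,
            )
        rows.append(row)
    pairs = pd.DataFrame(rows)
    if cfg.run_lrt and len(pairs):
        pairs["q_value"] = stats.bh_fdr(pairs["p_value"].to_numpy())
        omega_ok = pairs["omega_ml"] < cfg.omega_null
        pairs["purifying_q05"] = (pairs["q_value"] < 0.05) & omega_ok
        pairs["purifying_p01"] = (pairs["p_value"] < 0.01) & omega_ok
    return pairs


def _methylation_stage(cfg: RunConfig, counts: dict):
    genes = io.read_annotation(cfg.annotation)
    chrom_sizes = io.read_chrom_sizes(cfg.chrom_sizes)
    regions = methylation.extract_regions(genes, chrom_sizes, cfg.promoter_len)
    counts["genes"] = len(genes)
    rows, nonconv = [], {}
    for stage in sorted(cfg.methylomes):
        report = io.read_cytosine_report(cfg.methylomes[stage], merge_dyads=cfg.merge_dyads)
        spike = report[report["chrom"] == cfg.spike_chrom]
        nonconv[stage] = (
            methylation.estimate_nonconversion(spike["m_count"], spike["u_count"])
            if len(spike)
            else math.nan
        )
        genome = report[report["chrom"] != cfg.spike_chrom]
        p_bg = methylation.estimate_background(
            genome["m_count"].to_numpy(), genome["u_count"].to_numpy(),
            cfg.min_cov, cfg.call_threshold,
        )
        by_chrom = {
            chrom: (
                grp["pos"].to_numpy(),
                grp["m_count"].to_numpy(dtype=float),
                grp["u_count"].to_numpy(dtype=float),
            )
            for chrom, grp in genome.groupby("chrom")
        }
        for region in regions:
            pos, m, u = by_chrom.get(region.chrom, (np.array([]), np.array([]), np.array([])))
            summ = methylation.region_summary(pos, m, u, region, cfg.min_cov, cfg.call_threshold)
            summ.dataset = stage
            methylation.classify_region(
                summ, p_bg, cfg.min_ncg, cfg.min_coverage_fraction
            )
            rows.append(dataclasses.asdict(summ))
    region_meth = pd.DataFrame(rows)
    counts["region_records"] = len(region_meth)
    gene_info = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "gene_length": [g.length for g in genes]}
    )
    return region_meth, gene_info, nonconv


def _divergence_stage(cfg: RunConfig, pairs: pd.DataFrame, region_meth: pd.DataFrame):
    """PMD/GMD per pair per dataset plus the SMI table.

    Orientation: gene1 is the lexicographically smaller id, fixed across
    datasets so divergence signs are comparable.
    """
    lvl = region_meth.set_index(["gene_id", "kind", "dataset"])["mean_level"]
    klass = region_meth.set_index(["gene_id", "kind", "dataset"])["klass"]

    def level(g, kind, ds):
        return float(lvl.get((g, kind, ds), math.nan))

    div_rows = []
    for _, p in pairs.iterrows():
        g1, g2 = sorted((p["gene1"], p["gene2"]))
        for ds in sorted(cfg.methylomes):
            div_rows.append(
                {
                    "pair_id": p["pair_id"], "dataset": ds,
                    "gene1": g1, "gene2": g2, "ks": p["ks"],
                    "prom1": level(g1, "promoter", ds), "prom2": level(g2, "promoter", ds),
                    "body1": level(g1, "body", ds), "body2": level(g2, "body", ds),
                    "pmd": methylation.methylation_divergence(
                        level(g1, "promoter", ds), level(g2, "promoter", ds)
                    ),
                    "gmd": methylation.methylation_divergence(
                        level(g1, "body", ds), level(g2, "body", ds)
                    ),
                }
            )
    divergence = pd.DataFrame(div_rows)

    stages = [s for s in cfg.embryo_stages if s in cfg.methylomes]
    smi_rows = []
    for gene in pd.unique(pairs[["gene1", "gene2"]].to_numpy().ravel()):
        levels = [level(gene, "promoter", s) for s in stages]
        value = methylation.smi(levels) if len(stages) >= 2 and not any(map(math.isnan, levels)) else math.nan
        smi_rows.append({"gene_id": gene, "smi": value, "n_stages": len(stages)})
    smi_table = pd.DataFrame(smi_rows)
    smi_of = smi_table.set_index("gene_id")["smi"]

    pair_rows = []
    for _, p in pairs.iterrows():
        g1, g2 = sorted((p["gene1"], p["gene2"]))
        consistent, member = methylation.consistent_promoter_divergence(
            [str(klass.get((g1, "promoter", ds), "insufficient")) for ds in sorted(cfg.methylomes)],
            [str(klass.get((g2, "promoter", ds), "insufficient")) for ds in sorted(cfg.methylomes)],
        )
        pair_rows.append(
            {
                "pair_id": p["pair_id"], "ks": p["ks"],
                "smi1": float(smi_of.get(g1, math.nan)), "smi2": float(smi_of.get(g2, math.nan)),
                "smi_divergence": methylation.smi_divergence(
                    float(smi_of.get(g1, math.nan)), float(smi_of.get(g2, math.nan))
                ),
                "consistent": consistent,
                "methylated_member": {1: g1, 2: g2}.get(member, ""),
            }
        )
    return divergence, smi_table, pd.DataFrame(pair_rows)


def _expression_stage(cfg: RunConfig, counts: dict):
    expr = io.read_expression(cfg.expression)
    counts["expression_genes"] = len(expr)
    rows = []
    for gene, vec in expr.iterrows():
        res = stats.shannon_specificity(vec.to_numpy())
        rows.append(
            {"gene_id": gene, "H": res.H, "specificity": res.specificity, "N": res.N}
        )
    return expr, pd.DataFrame(rows)


def _correlation_stage(cfg: RunConfig, pairs, divergence, pair_summary, region_meth, expr):
    """Binned Ks trends and methylation-expression (partial) correlations."""
    rows = []
    focal = divergence[divergence["dataset"] == cfg.focal_stage]
    pair_prom = (focal["prom1"] + focal["prom2"]) / 2
    pair_body = (focal["body1"] + focal["body2"]) / 2
    trends = {
        "promoter_level_vs_ks": pair_prom,
        "body_level_vs_ks": pair_body,
        "pmd_vs_ks": focal["pmd"],
        "gmd_vs_ks": focal["gmd"],
    }
    for name, values in trends.items():
        try:
            _, r_bin, p_bin = stats.ks_binned_trend(
                focal["ks"].to_numpy(), values.to_numpy(), cfg.n_bins
            )
        except ValueError:
            r_bin, p_bin = math.nan, math.nan
        try:
            r_gene, p_gene = stats.pearson(focal["ks"].to_numpy(), values.to_numpy())
        except ValueError:
            r_gene, p_gene = math.nan, math.nan
        rows.append(
            {"dataset": cfg.focal_stage, "metric": name, "level": "bin",
             "r": r_bin, "p": p_bin, "n": int(values.notna().sum())}
        )
        rows.append(
            {"dataset": cfg.focal_stage, "metric": name, "level": "gene",
             "r": r_gene, "p": p_gene, "n": int(values.notna().sum())}
        )
    try:
        r, p = stats.pearson(pair_summary["ks"].to_numpy(), pair_summary["smi_divergence"].to_numpy())
    except ValueError:
        r, p = math.nan, math.nan
    rows.append(
        {"dataset": "embryo-stages", "metric": "smi_divergence_vs_ks", "level": "gene",
         "r": r, "p": p, "n": int(pair_summary["smi_divergence"].notna().sum())}
    )

    # methylation vs expression, controlling the other region's methylation
    lvl = region_meth.pivot_table(
        index="gene_id", columns=["kind", "dataset"], values="mean_level", aggfunc="first"
    )
    dup_genes = pd.unique(pairs[["gene1", "gene2"]].to_numpy().ravel())
    for stage in sorted(cfg.methylomes):
        if stage not in expr.columns:
            continue
        idx = [g for g in dup_genes if g in lvl.index and g in expr.index]
        prom = np.array([lvl.loc[g].get(("promoter", stage), math.nan) for g in idx])
        body = np.array([lvl.loc[g].get(("body", stage), math.nan) for g in idx])
        logfpkm = stats.log_transform_fpkm(expr.loc[idx, stage].to_numpy(), cfg.fpkm_log_offset)
        for metric, x, z in (
            ("expression_vs_promoter_meth_partial", prom, body),
            ("expression_vs_body_meth_partial", body, prom),
        ):
            try:
                r, p = stats.partial_correlation(logfpkm, x, z)
                n = int(np.isfinite(logfpkm + x + z).sum())
            except ValueError:
                r, p, n = math.nan, math.nan, 0
            rows.append({"dataset": stage, "metric": metric, "level": "gene", "r": r, "p": p, "n": n})
    corr = pd.DataFrame(rows)
    corr["q"] = stats.bh_fdr(corr["p"].to_numpy())
    return corr


def _group_tests(cfg: RunConfig, pairs, pair_summary, region_meth, gene_info, expr, entropy):
    """Two-group comparisons keyed to promoter/body methylation classes."""
    focal = region_meth[region_meth["dataset"] == cfg.focal_stage]
    prom = focal[focal["kind"] == "promoter"].set_index("gene_id")
    body = focal[focal["kind"] == "body"].set_index("gene_id")
    dup_genes = [g for g in pd.unique(pairs[["gene1", "gene2"]].to_numpy().ravel())]
    rows = []

    def add_ttest(name, a, b, mean_scale=1.0):
        try:
            t, df, p = stats.two_sample_t(a, b)
            rows.append(
                {"test": name, "statistic": t, "p": p,
                 "n1": len(a), "n2": len(b),
                 "mean1": float(np.nanmean(a)) * mean_scale if len(a) else math.nan,
                 "mean2": float(np.nanmean(b)) * mean_scale if len(b) else math.nan}
            )
        except ValueError:
            rows.append({"test": name, "statistic": math.nan, "p": math.nan,
                         "n1": len(a), "n2": len(b), "mean1": math.nan, "mean2": math.nan})

    meth_genes = [g for g in dup_genes if g in prom.index and prom.loc[g, "klass"] == "methylated"]
    unmeth_genes = [g for g in dup_genes if g in prom.index and prom.loc[g, "klass"] == "unmethylated"]
    if cfg.focal_stage in expr.columns:
        a = stats.log_transform_fpkm(expr.reindex(meth_genes)[cfg.focal_stage].dropna().to_numpy())
        b = stats.log_transform_fpkm(expr.reindex(unmeth_genes)[cfg.focal_stage].dropna().to_numpy())
        add_ttest("expression_promoter_meth_vs_unmeth", a, b)
    ent = entropy.set_index("gene_id")["H"]
    add_ttest(
        "entropy_promoter_meth_vs_unmeth",
        ent.reindex(meth_genes).dropna().to_numpy(),
        ent.reindex(unmeth_genes).dropna().to_numpy(),
    )

    glen = gene_info.set_index("gene_id")["gene_length"]
    bm = [g for g in dup_genes if g in body.index and body.loc[g, "klass"] == "methylated"]
    bu = [g for g in dup_genes if g in body.index and body.loc[g, "klass"] == "unmethylated"]
    add_ttest(
        "gene_length_body_meth_vs_unmeth",
        glen.reindex(bm).dropna().to_numpy(),
        glen.reindex(bu).dropna().to_numpy(),
    )
    # Ks of body/promoter methylated vs unmethylated genes
    gene_ks = {}
    for _, p in pairs.iterrows():
        gene_ks[p["gene1"]] = p["ks"]
        gene_ks[p["gene2"]] = p["ks"]
    add_ttest(
        "ks_body_meth_vs_unmeth",
        np.array([gene_ks[g] for g in bm if g in gene_ks]),
        np.array([gene_ks[g] for g in bu if g in gene_ks]),
    )
    add_ttest(
        "ks_promoter_meth_vs_unmeth",
        np.array([gene_ks[g] for g in meth_genes if g in gene_ks]),
        np.array([gene_ks[g] for g in unmeth_genes if g in gene_ks]),
    )

    # recent (outgroup single-copy) vs remaining duplicates
    if cfg.outgroup:
        copies = io.read_two_column_map(cfg.outgroup)
        recent_flags = duplicates.flag_recent_duplicates(
            list(zip(pairs["gene1"], pairs["gene2"])), copies
        )
        pairs = pairs.assign(recent=recent_flags)
        prom_mean = prom["mean_level"]
        body_mean = body["mean_level"]
        for name, series in (("promoter_recent_vs_older", prom_mean), ("body_recent_vs_older", body_mean)):
            recent_genes = pd.unique(pairs.loc[pairs["recent"], ["gene1", "gene2"]].to_numpy().ravel())
            older_genes = pd.unique(pairs.loc[~pairs["recent"], ["gene1", "gene2"]].to_numpy().ravel())
            add_ttest(
                name,
                series.reindex(recent_genes).dropna().to_numpy(),
                series.reindex(older_genes).dropna().to_numpy(),
            )

    # functional divergence proportion test: consistent vs non-consistent pairs
    if cfg.domains:
        domains = io.read_domain_table(cfg.domains)
        consistent_ids = set(pair_summary.loc[pair_summary["consistent"], "pair_id"])
        k = {True: 0, False: 0}
        ntot = {True: 0, False: 0}
        for _, p in pairs.iterrows():
            status = duplicates.compare_domain_sets(
                domains.get(p["gene1"], ()), domains.get(p["gene2"], ())
            )
            if status == "unannotated":
                continue
            grp = p["pair_id"] in consistent_ids
            ntot[grp] += 1
            k[grp] += status == "different"
        if min(ntot.values()) > 0:
            chi2, p = stats.two_proportion_cc(k[True], ntot[True], k[False], ntot[False])
            rows.append(
                {"test": "functional_divergence_consistent_vs_not", "statistic": chi2, "p": p,
                 "n1": ntot[True], "n2": ntot[False],
                 "mean1": k[True] / ntot[True], "mean2": k[False] / ntot[False]}
            )

    # promoter composition: C fraction and CpG count, methylated vs unmethylated
    if cfg.promoters:
        proms = {r.id: r.seq for r in io.read_fasta(cfg.promoters)}
        comp_m = [methylation.promoter_composition(proms[g]) for g in meth_genes if g in proms]
        comp_u = [methylation.promoter_composition(proms[g]) for g in unmeth_genes if g in proms]
        if comp_m and comp_u:
            add_ttest(
                "promoter_c_fraction_meth_vs_unmeth",
                np.array([c for c, _ in comp_m]),
                np.array([c for c, _ in comp_u]),
            )
            add_ttest(
                "promoter_cpg_count_meth_vs_unmeth",
                np.array([n for _, n in comp_m], dtype=float),
                np.array([n for _, n in comp_u], dtype=float),
            )
    return pd.DataFrame(rows), pairs


def _wgd_dating(cfg: RunConfig, pairs) -> dict:
    """Date the whole-genome duplication from the Ks distribution's peak."""
    ks = pairs["ks"].dropna().to_numpy()
    out = {"ks_peak": math.nan, "wgd_age_years": math.nan}
    if len(ks) >= 10:
        edges = np.arange(0.0, cfg.ks_max + 0.1, 0.1)
        hist, _ = np.histogram(ks, bins=edges)
        peak_bin = int(hist.argmax())
        peak = float((edges[peak_bin] + edges[peak_bin + 1]) / 2)
        out["ks_peak"] = peak
        out["wgd_age_years"] = stats.age_from_ks(peak, cfg.substitution_rate)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write all output tables.

    Returns a dict of DataFrames (families, pairs, region_methylation,
    pair_divergence, smi, pair_summary, expression_stats, correlations,
    group_tests, summary) plus run metadata.
    """
    cfg = config
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    counts: dict = {}
    stage = "duplicate_discovery"
    try:
        proteins, families, fam_table = _discover_pairs(cfg, counts)
        stage = "kaks"
        aln_of_pair = _codon_alignments(cfg, proteins)
        pairs = _kaks_stage(cfg, families, aln_of_pair, counts)
        stage = "methylation"
        region_meth, gene_info, nonconv = _methylation_stage(cfg, counts)
        stage = "divergence"
        divergence, smi_table, pair_summary = _divergence_stage(cfg, pairs, region_meth)
        stage = "expression"
        expr, entropy = _expression_stage(cfg, counts)
        stage = "correlation"
        correlations = _correlation_stage(cfg, pairs, divergence, pair_summary, region_meth, expr)
        stage = "group_tests"
        group_tests, pairs = _group_tests(
            cfg, pairs, pair_summary, region_meth, gene_info, expr, entropy
        )
        dating = _wgd_dating(cfg, pairs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    counts["consistent_pairs"] = int(pair_summary["consistent"].sum())
    if "purifying_q05" in pairs:
        counts["purifying_pairs_q05"] = int(pairs["purifying_q05"].sum())
        counts["purifying_pairs_p01"] = int(pairs["purifying_p01"].sum())
    if "recent" in pairs:
        counts["recent_pairs"] = int(pairs["recent"].sum())

    results = {
        "families": fam_table,
        "pairs": pairs,
        "region_methylation": region_meth,
        "pair_divergence": divergence,
        "smi": smi_table,
        "pair_summary": pair_summary,
        "expression_stats": entropy,
        "correlations": correlations,
        "group_tests": group_tests,
    }
    summary = report_summary(results, counts, dating, nonconv)
    results["summary"] = summary

    meta = {
        "config_hash": cfg.config_hash(),
        "counts": counts,
        "nonconversion": {k: (None if math.isnan(v) else v) for k, v in nonconv.items()},
        "wgd": dating,
        "tables": {},
    }
    for name, df in results.items():
        path = os.path.join(cfg.outdir, f"{name}.tsv")
        io.write_table(df, path)
        meta["tables"][name] = {"rows": int(len(df)), "path": path}
        logger.info("stage output %s: %d rows", name, len(df))
    with open(os.path.join(cfg.outdir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    results["metadata"] = meta
    return results


def report_summary(results: dict, counts: dict, dating: dict, nonconv: dict) -> pd.DataFrame:
    """One tidy summary table: counts, dating, and every correlation row."""
    rows = [{"section": "count", "name": k, "value": float(v)} for k, v in sorted(counts.items())]
    rows += [{"section": "wgd", "name": k, "value": v} for k, v in dating.items()]
    rows += [
        {"section": "nonconversion", "name": k, "value": v} for k, v in sorted(nonconv.items())
    ]
    for _, r in results["correlations"].iterrows():
        rows.append(
            {"section": "correlation", "name": f"{r['metric']}[{r['dataset']}|{r['level']}]",
             "value": r["r"]}
        )
    for _, r in results["group_tests"].iterrows():
        rows.append({"section": "test_p", "name": r["test"], "value": r["p"]})
    return pd.DataFrame(rows)
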