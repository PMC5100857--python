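"""Self-contained synthetic inputs with the statistical structure the
analysis assumes: codon-pair divergence under the same substitution
model the estimator fits, stage-structured CpG read counts with planted
promoter/body methylation classes and Ks-coupled trends, FPKM vectors
negatively coupled to promoter methylation, and an unmethylated spike-in
chromosome for conversion-error estimation.

The generator's defaults define the study conditions the package's
tests run under; a truth manifest records every planted quantity so
each pipeline output can be scored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import codonml
from .io import GeneModel, SequenceRecord, write_fasta, write_table
from .methylation import DATASETS, EMBRYO_STAGES, PROMOTER_LEN

__all__ = [
    "ScenarioConfig",
    "GeneSet",
    "simulate_codon_pair",
    "simulate_gene_set",
    "simulate_methylome",
    "simulate_expression",
    "simulate_site_counts",
    "scenario_headline",
]

_UNIFORM_PI = np.full(len(codonml.SENSE_CODONS), 1.0 / len(codonml.SENSE_CODONS))


@dataclass
class ScenarioConfig:
    """Planted truth for the headline scenario.

    Trend coefficients are (intercept, slope) on Ks for mean region
    methylation; the pair asymmetry grows linearly with Ks so promoter
    methylation divergence rises with pair age while body divergence
    shrinks.  Expression is coupled negatively to promoter methylation
    on the log2 scale.
    """

    seed: int = 0
    n_pairs: int = 150
    n_trios: int = 10            # families of three to exercise lowest-Ks pairing
    n_codons: int = 200
    ks_min: float = 0.05
    ks_max: float = 1.95
    omega_purifying: float = 0.2
    omega_boundary: float = 0.5
    purifying_fraction: float = 0.8
    kappa: float = 2.0
    stages: tuple = DATASETS
    depth_mean: float = 20.0
    # methylation trends on Ks
    promoter_trend: tuple = (0.85, -0.30)
    body_trend: tuple = (0.25, 0.25)
    promoter_asym_slope: float = 0.25    # pair-level promoter asymmetry per Ks unit
    body_asym_intercept: float = 0.20    # body asymmetry shrinking with Ks
    site_concentration: float = 50.0     # Beta concentration of site-level noise
    nonconversion: float = 0.005
    spike_chrom: str = "lambda_spike"
    spike_sites: int = 5000
    # expression
    expression_baseline: float = 5.0
    expression_coupling: float = -2.0
    expression_noise_sd: float = 0.5
    onehot_fraction: float = 0.05
    # planted special pairs
    n_consistent_pairs: int = 50
    consistent_levels: tuple = (0.90, 0.05)
    recent_ks_max: float = 0.25          # outgroup-single-copy ("recent") pairs
    stage_specific_fraction: float = 0.15
    # genome layout
    chrom: str = "chrS"
    gene_spacing: int = 4500
    min_gene_length: int = 1200
    gene_length_log_mean: float = 8.0    # log of the baseline gene length
    gene_length_log_sd: float = 0.5
    gene_length_body_factor: float = 4.0  # body-methylated genes run longer
    body_cpg_spacing: int = 50
    # domain-annotation planted rates (different-domain fraction by consistency)
    p_unannotated: float = 0.074
    p_diff_consistent: float = 0.27
    p_diff_other: float = 0.15

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclass
class GeneSet:
    """Everything the headline scenario plants, pre-file-format."""

    genes: list                      # GeneModel, all genes
    chrom_sizes: dict
    cds: list                        # SequenceRecord
    proteins: list
    promoters: list
    pairs: pd.DataFrame              # per-pair truth
    gene_truth: pd.DataFrame         # per-gene truth
    hits_lines: list                 # BLAST-tabular lines
    outgroup: pd.DataFrame
    domains: pd.DataFrame


def simulate_codon_pair(n_codons, t, kappa, omega, freqs=None, rng=None, seed=None):
    """Evolve a duplicate pair: ancestor from ``freqs``, each lineage t/2.

    Uses the same scaled rate matrix as the ML estimator, so simulated
    divergence targets the estimator's t.  Returns two stop-free CDS
    strings of length 3*n_codons.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pi = _UNIFORM_PI if freqs is None else np.asarray(freqs, dtype=float)
    anc = rng.choice(len(pi), size=n_codons, p=pi)
    if t == 0:
        child1 = child2 = anc
    else:
        Q = codonml.build_rate_matrix(kappa, omega, pi)
        P = codonml.transition_matrix(Q, pi, t / 2.0)
        P = P / P.sum(axis=1, keepdims=True)
        child1 = np.empty(n_codons, dtype=np.intp)
        child2 = np.empty(n_codons, dtype=np.intp)
        for state in np.unique(anc):
            sel = anc == state
            k = int(sel.sum())
            child1[sel] = rng.choice(len(pi), size=k, p=P[state])
            child2[sel] = rng.choice(len(pi), size=k, p=P[state])
    codons = codonml.SENSE_CODONS
    return (
        "".join(codons[i] for i in child1),
        "".join(codons[i] for i in child2),
    )


def _random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _revcomp(seq):
    return str(Seq(seq).reverse_complement())


def simulate_gene_set(config: ScenarioConfig, rng=None) -> GeneSet:
    """Lay out duplicate pairs on a synthetic chromosome with planted truth.

    Per pair: a target Ks from a uniform grid, a true omega (mostly
    strongly purifying, a fraction at the tested boundary), promoter and
    body methylation targets from the Ks trends, and gene lengths drawn
    so body-methylated genes run longer.  CpG coordinates come from the
    generated promoter sequences (CG dinucleotides) and a uniform grid
    inside gene bodies.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    ks_grid = np.linspace(cfg.ks_min, cfg.ks_max, n)
    n_boundary = round(n * (1 - cfg.purifying_fraction))
    # deterministic interleaving of boundary-omega pairs
    boundary_idx = set(np.linspace(0, n - 1, n_boundary).astype(int)) if n_boundary else set()
    consistent_idx = set(np.linspace(0, n - 1, min(cfg.n_consistent_pairs, n)).astype(int) if cfg.n_consistent_pairs else [])

    genes, cds, prots, promoters = [], [], [], []
    gene_rows, pair_rows, hits = [], [], []
    cursor = 3000
    pi = _UNIFORM_PI

    def place_gene(gid, length, strand, prom_level, body_level, stage_bias):
        nonlocal cursor
        tx_start, tx_end = cursor, cursor + length
        cursor = tx_end + cfg.gene_spacing
        cds_end = min(tx_end, tx_start + 3 * cfg.n_codons)
        genes.append(GeneModel(gid, cfg.chrom, strand, tx_start, tx_end, [(tx_start, cds_end)]))
        # promoter window on the forward strand; CpG dyads are palindromic
        if strand == "+":
            w_start = tx_start - PROMOTER_LEN
        else:
            w_start = tx_end
        window = _random_dna(rng, PROMOTER_LEN)
        prom_cpgs = [w_start + i for i in range(PROMOTER_LEN - 1) if window[i : i + 2] == "CG"]
        promoters.append(SequenceRecord(gid, window if strand == "+" else _revcomp(window)))
        body_cpgs = list(range(tx_start + 25, tx_end - 1, cfg.body_cpg_spacing))
        gene_rows.append(
            {
                "gene_id": gid, "chrom": cfg.chrom, "strand": strand,
                "tx_start": tx_start, "tx_end": tx_end, "length": length,
                "prom_level": prom_level, "body_level": body_level,
                "stage_bias": stage_bias,
                "prom_cpgs": prom_cpgs, "body_cpgs": body_cpgs,
            }
        )

    stage_bias_genes = rng.random(2 * n) < cfg.stage_specific_fraction
    for i in range(n):
        ks = float(ks_grid[i])
        omega = cfg.omega_boundary if i in boundary_idx else cfg.omega_purifying
        consistent = i in consistent_idx
        t_true = codonml.time_for_target_ks(ks, cfg.kappa, omega, pi)
        g1, g2 = f"g{i:04d}a", f"g{i:04d}b"
        seq1, seq2 = simulate_codon_pair(cfg.n_codons, t_true, cfg.kappa, omega, pi, rng=rng)

        prom_base = float(np.clip(cfg.promoter_trend[0] + cfg.promoter_trend[1] * ks, 0.03, 0.97))
        body_base = float(np.clip(cfg.body_trend[0] + cfg.body_trend[1] * ks, 0.03, 0.97))
        d_prom = cfg.promoter_asym_slope * ks
        d_body = cfg.body_asym_intercept * max(0.0, 1.0 - ks / cfg.ks_max)
        if consistent:
            p1, p2 = cfg.consistent_levels
        else:
            p1 = float(np.clip(prom_base + d_prom / 2, 0.02, 0.98))
            p2 = float(np.clip(prom_base - d_prom / 2, 0.02, 0.98))
        b1 = float(np.clip(body_base + d_body / 2, 0.02, 0.98))
        b2 = float(np.clip(body_base - d_body / 2, 0.02, 0.98))

        for gid, seq, plev, blev, sbias in (
            (g1, seq1, p1, b1, stage_bias_genes[2 * i]),
            (g2, seq2, p2, b2, stage_bias_genes[2 * i + 1]),
        ):
            base_len = np.exp(cfg.gene_length_log_mean + cfg.gene_length_log_sd * rng.standard_normal())
            length = int(max(cfg.min_gene_length, base_len * (1 + cfg.gene_length_body_factor * blev)))
            sbias_stage = rng.choice(EMBRYO_STAGES) if (sbias and not consistent) else ""
            place_gene(gid, length, "+" if rng.random() < 0.5 else "-", plev, blev, sbias_stage)
            cds.append(SequenceRecord(gid, seq))
            prots.append(SequenceRecord(gid, str(Seq(seq).translate())))

        ident = float(np.clip(0.95 - 0.15 * ks + 0.02 * rng.standard_normal(), 0.35, 0.995))
        hits.append((g1, g2, ident * 100, cfg.n_codons))
        if rng.random() < 0.5:  # exercise reciprocal-hit collapsing
            hits.append((g2, g1, ident * 100 - 0.5, cfg.n_codons - 1))

        pair_rows.append(
            {
                "pair_id": f"pair{i:04d}", "gene1": g1, "gene2": g2,
                "ks_true": ks, "t_true": t_true, "omega_true": omega,
                "consistent": consistent, "recent": ks <= cfg.recent_ks_max,
                "prom_level1": p1, "prom_level2": p2,
                "body_level1": b1, "body_level2": b2,
            }
        )

        if i < cfg.n_trios:
            # a third, more distant family member: lowest-Ks pair must stay (a, b)
            g3 = f"g{i:04d}c"
            t3 = codonml.time_for_target_ks(min(ks * 2.5 + 0.5, 8.0), cfg.kappa, omega, pi)
            seq3 = simulate_codon_pair(cfg.n_codons, t3, cfg.kappa, omega, pi, rng=rng)[1]
            place_gene(g3, cfg.min_gene_length + int(rng.integers(0, 2000)), "+", prom_base, body_base, "")
            cds.append(SequenceRecord(g3, seq3))
            prots.append(SequenceRecord(g3, str(Seq(seq3).translate())))
            hits.append((g1, g3, max(35.0, ident * 100 - 12), cfg.n_codons))
            hits.append((g2, g3, max(35.0, ident * 100 - 13), cfg.n_codons))

    chrom_sizes = {cfg.chrom: cursor + 10_000}
    pairs = pd.DataFrame(pair_rows)
    gene_truth = pd.DataFrame(gene_rows)
    out_rows = []
    for _, row in pairs.iterrows():
        copies = 1 if row["recent"] else 2
        out_rows.append({"gene_id": row["gene1"], "outgroup_copies": copies})
        out_rows.append({"gene_id": row["gene2"], "outgroup_copies": copies})
    outgroup = pd.DataFrame(out_rows)
    dom_rows = []
    for _, row in pairs.iterrows():
        u = rng.random()
        if u < cfg.p_unannotated:
            d1 = d2 = ""
        else:
            p_diff = cfg.p_diff_consistent if row["consistent"] else cfg.p_diff_other
            shared = f"PF{rng.integers(1, 300):05d}"
            d1 = shared
            d2 = shared + f",PF{rng.integers(300, 600):05d}" if rng.random() < p_diff else shared
        dom_rows.append({"gene_id": row["gene1"], "domains": d1})
        dom_rows.append({"gene_id": row["gene2"], "domains": d2})
    domains = pd.DataFrame(dom_rows)
    hit_lines = [
        f"{q}\t{s}\t{pid:.2f}\t{alen}\t0\t0\t1\t{alen}\t1\t{alen}\t1e-50\t500.0"
        for q, s, pid, alen in hits
    ]
    return GeneSet(genes, chrom_sizes, cds, prots, promoters, pairs, gene_truth, hit_lines, outgroup, domains)


def _stage_level(base: float, stage: str, stage_bias: str) -> float:
    """Stage-specific modulation: biased genes peak in one embryo stage."""
    if not stage_bias:
        return base
    if stage == stage_bias:
        return float(np.clip(base * 1.4, 0.0, 0.98))
    return float(np.clip(base * 0.6, 0.0, 0.98))


def simulate_site_counts(level, n_sites, depth_mean, rng, concentration=50.0, nonconversion=0.0):
    """Per-CpG (m, u) read counts around a target regional level.

    Site propensities are Beta-distributed around ``level`` with the
    given concentration; depth is Poisson; observed methylation includes
    the non-conversion floor.  Zero-depth sites yield (0, 0) rows.
    """
    level = float(np.clip(level, 1e-4, 1 - 1e-4))
    a, b = level * concentration, (1 - level) * concentration
    p_site = rng.beta(a, b, size=n_sites)
    p_obs = p_site + (1 - p_site) * nonconversion
    depth = rng.poisson(depth_mean, size=n_sites)
    m = rng.binomial(depth, p_obs)
    return m, depth - m


def simulate_methylome(gene_set: GeneSet, config: ScenarioConfig, stage: str, rng) -> pd.DataFrame:
    """One stage's cytosine report (1-based, CpG dyads on the + strand).

    Every planted CpG site appears, covered or not, plus the fully
    unmethylated spike-in chromosome observed at the configured
    non-conversion rate.
    """
    cfg = config
    chroms, poss, ms, us = [], [], [], []
    for _, g in gene_set.gene_truth.iterrows():
        for sites, base in ((g["prom_cpgs"], g["prom_level"]), (g["body_cpgs"], g["body_level"])):
            if not sites:
                continue
            lvl = _stage_level(base, stage, g["stage_bias"])
            m, u = simulate_site_counts(
                lvl, len(sites), cfg.depth_mean, rng, cfg.site_concentration, cfg.nonconversion
            )
            chroms.extend([g["chrom"]] * len(sites))
            poss.extend(sites)
            ms.extend(m.tolist())
            us.extend(u.tolist())
    # spike-in chromosome: truly unmethylated, so apparent methylation = nonconversion
    spike_pos = np.arange(cfg.spike_sites) * 10 + 5
    depth = rng.poisson(cfg.depth_mean, size=cfg.spike_sites)
    sm = rng.binomial(depth, cfg.nonconversion)
    chroms.extend([cfg.spike_chrom] * cfg.spike_sites)
    poss.extend(spike_pos.tolist())
    ms.extend(sm.tolist())
    us.extend((depth - sm).tolist())
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss) + 1,  # 1-based at the file boundary
            "strand": "+",
            "m_count": ms,
            "u_count": us,
            "context": "CG",
        }
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_expression(gene_set: GeneSet, config: ScenarioConfig, rng) -> pd.DataFrame:
    """FPKM table (genes x stages) negatively coupled to promoter methylation.

    log2 FPKM = baseline + coupling * promoter_level + Gaussian noise;
    FPKM = 2^x - 1 floored at 0.  A configurable fraction of genes is
    one-hot expressed to exercise the specificity index.
    """
    cfg = config
    gt = gene_set.gene_truth
    n_genes = len(gt)
    onehot = rng.random(n_genes) < cfg.onehot_fraction
    rows = {}
    for gi, (_, g) in enumerate(gt.iterrows()):
        if onehot[gi]:
            vals = np.zeros(len(cfg.stages))
            vals[rng.integers(0, len(cfg.stages))] = float(2 ** cfg.expression_baseline)
        else:
            levels = np.array([_stage_level(g["prom_level"], s, g["stage_bias"]) for s in cfg.stages])
            x = (
                cfg.expression_baseline
                + cfg.expression_coupling * levels
                + cfg.expression_noise_sd * rng.standard_normal(len(cfg.stages))
            )
            vals = np.maximum(0.0, 2.0**x - 1.0)
        rows[g["gene_id"]] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(cfg.stages))
    df.index.name = "gene_id"
    return df


def _bed12_line(g: GeneModel) -> str:
    thick_s, thick_e = g.cds_intervals[0] if g.cds_intervals else (g.tx_start, g.tx_start)
    size = g.tx_end - g.tx_start
    return "\t".join(
        str(x)
        for x in (
            g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
            thick_s, thick_e, 0, 1, f"{size},", "0,",
        )
    )


def scenario_headline(config: ScenarioConfig | None = None, outdir: str = "scenario") -> dict:
    """Write the full synthetic input bundle and its truth manifest.

    Emits annotation (BED12), chromosome sizes, CDS/protein/promoter
    FASTA, an all-vs-all hit table, nine stage methylomes, an FPKM
    table, outgroup copy numbers, a domain table, per-pair and per-gene
    truth manifests and a config echo.  Deterministic given the config.

    Returns a dict of file paths keyed by role (methylomes under
    ``"methylomes"`` as a stage -> path dict).
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)
    gs = simulate_gene_set(cfg, rng)

    paths = {
        "annotation": os.path.join(outdir, "annotation.bed"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        "cds": os.path.join(outdir, "cds.fasta"),
        "proteins": os.path.join(outdir, "proteins.fasta"),
        "promoters": os.path.join(outdir, "promoters.fasta"),
        "hits": os.path.join(outdir, "hits.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "outgroup": os.path.join(outdir, "outgroup_copies.tsv"),
        "domains": os.path.join(outdir, "domains.tsv"),
        "truth_pairs": os.path.join(outdir, "truth_pairs.tsv"),
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
        "config": os.path.join(outdir, "config.yaml"),
        "methylomes": {},
    }
    with open(paths["annotation"], "w") as fh:
        for g in gs.genes:
            fh.write(_bed12_line(g) + "\n")
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in sorted(gs.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
        fh.write(f"{cfg.spike_chrom}\t{cfg.spike_sites * 10 + 100}\n")
    write_fasta(gs.cds, paths["cds"])
    write_fasta(gs.proteins, paths["proteins"])
    write_fasta(gs.promoters, paths["promoters"])
    with open(paths["hits"], "w") as fh:
        fh.write("\n".join(gs.hits_lines) + "\n")
    expr = simulate_expression(gs, cfg, rng)
    expr.reset_index().pipe(write_table, paths["expression"])
    write_table(gs.outgroup, paths["outgroup"])
    write_table(gs.domains, paths["domains"])
    write_table(gs.pairs, paths["truth_pairs"])
    gt = gs.gene_truth.copy()
    gt["n_prom_cpgs"] = gt["prom_cpgs"].map(len)
    gt["n_body_cpgs"] = gt["body_cpgs"].map(len)
    write_table(gt.drop(columns=["prom_cpgs", "body_cpgs"]), paths["truth_genes"])
    for stage in cfg.stages:
        p = os.path.join(outdir, f"meth_{stage}.tsv")
        simulate_methylome(gs, cfg, stage, rng).to_csv(p, sep="\t", header=False, index=False, lineterminator="\n")
        paths["methylomes"][stage] = p
    with open(paths["config"], "w") as fh:
        fh.write(cfg.to_yaml())
    return paths


def bundle_hash(paths: dict) -> str:
    """SHA-256 over every file in a scenario bundle (determinism checks)."""
    h = hashlib.sha256()
    flat = []
    for v in paths.values():
        flat.extend(sorted(v.values()) if isinstance(v, dict) else [v])
    for p in sorted(flat):
        with open(p, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()
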