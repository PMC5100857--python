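"""Reference recomputations: calibration, recovery and oracle-agreement
measurements run on synthetic data generated under the study conditions.

Each function regenerates its inputs from scratch with the given seed,
runs the package's own estimators, and returns the measured quantity.
They back both the validation test-suite and the reproduction script.
"""

from __future__ import annotations

import math
import tempfile
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd

from . import codonml as cm
from . import methylation as me
from . import stats
from .pipeline import RunConfig, run_pipeline
from .simulate import ScenarioConfig, scenario_headline, simulate_codon_pair, simulate_site_counts

__all__ = [
    "lrt_calibration",
    "omega_recovery",
    "classification_recovery",
    "pcg_oracle_max_error",
    "pcg_bimodality",
    "statistical_oracle_errors",
    "headline_scenario_metrics",
]


def _codons_of(cds):
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _spawn_seeds(seed, n):
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def lrt_calibration(
    seed: int,
    n_pairs: int = 200,
    n_codons: int = 300,
    t: float = 0.8,
    kappa: float = 2.0,
    omega: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the purifying-selection LRT at the null omega.

    Simulates pairs at the null (omega equal to the tested value) and
    returns the fraction rejected at ``alpha``.
    """
    rejections = 0
    for s in _spawn_seeds(seed, n_pairs):
        c1, c2 = simulate_codon_pair(n_codons, t, kappa, omega, seed=s)
        aln = cm.CodonAlignment(_codons_of(c1), _codons_of(c2))
        model = cm.CodonPairML(aln)
        _, p = cm.lrt_purifying(model.fit(fixed_omega=omega), model.fit())
        rejections += p < alpha
    return rejections / n_pairs


def omega_recovery(
    seed: int,
    omega: float,
    n_pairs: int = 50,
    n_codons: int = 300,
    t: float = 0.8,
    kappa: float = 2.0,
) -> float:
    """Mean free-fit omega-hat over simulated replicate pairs."""
    est = []
    for s in _spawn_seeds(seed, n_pairs):
        c1, c2 = simulate_codon_pair(n_codons, t, kappa, omega, seed=s)
        aln = cm.CodonAlignment(_codons_of(c1), _codons_of(c2))
        est.append(cm.CodonPairML(aln).fit().omega)
    return float(np.mean(est))


def classification_recovery(
    seed: int,
    n_per_class: int = 100,
    n_sites: int = 30,
    depth: float = 10.0,
    level_methylated: float = 0.9,
    level_unmethylated: float = 0.05,
    p_background: float = 0.5,
) -> float:
    """Fraction of planted methylated/unmethylated regions recovered.

    Plants regions at the two site levels, simulates binomial read
    counts, classifies with the P_CG rule and scores against the truth.
    """
    rng = np.random.default_rng(seed)
    region = me.Region("g", "promoter", "c", "+", 0, n_sites * 100)
    pos = np.arange(n_sites) * 100
    correct = 0
    for level, want in ((level_methylated, "methylated"), (level_unmethylated, "unmethylated")):
        for _ in range(n_per_class):
            m, u = simulate_site_counts(level, n_sites, depth, rng)
            summ = me.region_summary(pos, m, u, region)
            summ = me.classify_region(summ, p_background)
            correct += summ.klass == want
    return correct / (2 * n_per_class)


def pcg_oracle_max_error() -> float:
    """Max |P_CG - exact summation| over a grid of (n, m, p).

    The oracle sums binomial pmf terms in 50-digit decimal arithmetic,
    fully independent of the survival-function implementation.
    """
    getcontext().prec = 50
    worst = 0.0
    for n in (1, 2, 5, 10, 20, 50, 100, 250, 500, 1000):
        ms = range(0, n + 1) if n <= 50 else sorted({int(x) for x in np.linspace(0, n, 25)})
        for p in (0.05, 0.2, 0.5, 0.8, 0.95):
            pd_ = Decimal(repr(p))
            q = 1 - pd_
            for m in ms:
                if m == 0:
                    exact = 1.0
                else:
                    exact = float(
                        sum(
                            Decimal(math.comb(n, k)) * pd_**k * q ** (n - k)
                            for k in range(m, n + 1)
                        )
                    )
                worst = max(worst, abs(me.pcg_statistic(m, n, p) - exact))
    return worst


def pcg_bimodality(
    seed: int,
    n_per_class: int = 200,
    n_sites: int = 30,
    depth: float = 10.0,
) -> dict:
    """P_CG distribution of a planted methylated/unmethylated mixture.

    Returns the mass at the distribution's endpoints (P_CG < 0.05 or
    > 0.95) and in its interior; bimodality means the endpoints carry
    more mass.
    """
    rng = np.random.default_rng(seed)
    region = me.Region("g", "promoter", "c", "+", 0, n_sites * 100)
    pos = np.arange(n_sites) * 100
    pcgs = []
    for level in (0.9, 0.05):
        for _ in range(n_per_class):
            m, u = simulate_site_counts(level, n_sites, depth, rng)
            summ = me.region_summary(pos, m, u, region)
            summ = me.classify_region(summ, 0.5)
            if not math.isnan(summ.P_CG):
                pcgs.append(summ.P_CG)
    pcgs = np.asarray(pcgs)
    endpoint = float(((pcgs < 0.05) | (pcgs > 0.95)).mean())
    return {"endpoint_mass": endpoint, "interior_mass": 1.0 - endpoint, "n": len(pcgs)}


def statistical_oracle_errors(seed: int) -> dict:
    """Agreement of the statistical machinery with independent oracles.

    Fisher's exact test vs full hypergeometric enumeration, partial
    correlation vs residual regression, BH vs a hand step-up pass.
    """
    getcontext().prec = 50
    rng = np.random.default_rng(seed)

    def fisher_oracle(a, b, c, d):
        r1, r2, c1 = a + b, c + d, a + c
        denom = Decimal(math.comb(r1 + r2, c1))
        lo, hi = max(0, c1 - r2), min(r1, c1)
        probs = {
            k: Decimal(math.comb(r1, k) * math.comb(r2, c1 - k)) / denom
            for k in range(lo, hi + 1)
        }
        cutoff = probs[a] * (1 + Decimal("1e-14"))
        return float(sum(v for v in probs.values() if v <= cutoff))

    fisher_err = 0.0
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    fisher_err = max(
                        fisher_err,
                        abs(stats.fisher_exact(a, b, c, d)[1] - fisher_oracle(a, b, c, d)),
                    )
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        fisher_err = max(
            fisher_err, abs(stats.fisher_exact(a, b, c, d)[1] - fisher_oracle(a, b, c, d))
        )

    partial_err = 0.0
    for _ in range(100):
        n = int(rng.integers(10, 60))
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        y = -0.5 * z + rng.standard_normal(n)
        A = np.column_stack([np.ones(n), z])

        def resid(v):
            beta, *_ = np.linalg.lstsq(A, v, rcond=None)
            return v - A @ beta

        rx, ry = resid(x), resid(y)
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        partial_err = max(partial_err, abs(stats.partial_correlation(x, y, z)[0] - oracle))

    bh_err = 0.0
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 60)))
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            q[i] = prev
        bh_err = max(bh_err, float(np.max(np.abs(stats.bh_fdr(p) - q))))

    return {"fisher": fisher_err, "partial_correlation": partial_err, "bh_fdr": bh_err}


def headline_scenario_metrics(seed: int, config: ScenarioConfig | None = None) -> dict:
    """Generate the headline bundle, run the full pipeline, score it.

    Returns the four planted trend statistics (binned promoter and body
    methylation vs Ks, PMD vs Ks, expression vs promoter methylation
    partial correlation at the focal stage), the recovery of planted
    consistently-divergent pairs, and headline counts.
    """
    cfg = config or ScenarioConfig()
    cfg.seed = seed
    with tempfile.TemporaryDirectory() as tmp:
        paths = scenario_headline(cfg, f"{tmp}/bundle")
        rc = RunConfig(
            proteins=paths["proteins"], cds=paths["cds"], hits=paths["hits"],
            annotation=paths["annotation"], chrom_sizes=paths["chrom_sizes"],
            expression=paths["expression"], outgroup=paths["outgroup"],
            domains=paths["domains"], promoters=paths["promoters"],
            methylomes=paths["methylomes"], outdir=f"{tmp}/run",
        )
        results = run_pipeline(rc)
        truth = pd.read_csv(paths["truth_pairs"], sep="\t")

    corr = results["correlations"].set_index(["metric", "dataset", "level"])

    def corr_row(metric, level, dataset=rc.focal_stage):
        row = corr.loc[(metric, dataset, level)]
        return float(row["r"]), float(row["p"])

    prom_r, prom_p = corr_row("promoter_level_vs_ks", "bin")
    body_r, body_p = corr_row("body_level_vs_ks", "bin")
    pmd_r, pmd_p = corr_row("pmd_vs_ks", "bin")
    expr_r, expr_p = corr_row("expression_vs_promoter_meth_partial", "gene")

    # score the consistency scan on the planted pairs' classes directly, so
    # the measure reflects classification rather than Ks-window attrition
    klass = results["region_methylation"].set_index(["gene_id", "kind", "dataset"])["klass"]
    datasets = sorted(rc.methylomes)
    planted = truth.loc[truth["consistent"], ["gene1", "gene2"]]
    recovered = 0
    for g1, g2 in planted.itertuples(index=False):
        ok, _ = me.consistent_promoter_divergence(
            [str(klass.get((g1, "promoter", ds), "insufficient")) for ds in datasets],
            [str(klass.get((g2, "promoter", ds), "insufficient")) for ds in datasets],
        )
        recovered += ok
    pairs = results["pairs"]
    return {
        "promoter_trend_r": prom_r, "promoter_trend_p": prom_p,
        "body_trend_r": body_r, "body_trend_p": body_p,
        "pmd_trend_r": pmd_r, "pmd_trend_p": pmd_p,
        "expression_partial_r": expr_r, "expression_partial_p": expr_p,
        "n_pairs": int(len(pairs)),
        "purifying_fraction": float(pairs["purifying_q05"].mean()),
        "n_consistent_planted": int(len(planted)),
        "n_consistent_recovered": int(recovered),
        "n_recent": int(pairs["recent"].sum()) if "recent" in pairs else 0,
        "nonconversion_mean": float(
            np.nanmean([v for v in results["metadata"]["nonconversion"].values() if v is not None])
        ),
    }
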