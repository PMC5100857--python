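# dupmeth

How does DNA methylation relate to the evolutionary fate of duplicate
genes in zebrafish (*Danio rerio*)? After a gene duplication, one copy
is free to degenerate, and epigenetic silencing of a duplicate — heavy
CpG methylation of its promoter — is one mechanism that can tune its
expression while sequence divergence accumulates. `dupmeth` is a tested,
reusable implementation of that analysis for people working on duplicate
gene evolution and comparative epigenomics: it discovers paralog pairs,
dates them by synonymous divergence, tests them for purifying selection,
quantifies promoter and gene-body CpG methylation from bisulfite
cytosine reports, classifies regions as methylated or unmethylated,
and correlates methylation divergence with pair age and expression.
A synthetic-data generator emulates the statistical structure of the
underlying BS-seq/RNA-seq inputs so the whole pipeline is testable
without any downloads.

## What it computes

**Duplicate pairs.** All-vs-all protein hits are filtered by the
classical homology criteria: alignable region longer than 80% of the
longer protein, and identity `I ≥ 30%` when the alignable region is
longer than 150 aa, else `I ≥ 0.01 n + 4.8 L^(−0.32(1+exp(−L/1000)))`
with `n = 6`. Passing pairs are clustered into families with a Markov
Cluster implementation, and each family contributes the member pair
with the lowest Ks (kept when `0.01 < Ks ≤ 2`).

**Ka/Ks and selection.** Ks and Ka come from Nei–Gojobori (1986)
counting with Jukes–Cantor correction. A Goldman–Yang-style codon model
(61 sense codons; parameters `t`, `κ`, `ω`; F3x4 frequencies) is fitted
by maximum likelihood twice — `ω` fixed at 0.5 and `ω` free — and
`2ΔlnL` is compared to χ²(df = 1), with Benjamini–Hochberg FDR across
all pairs, to flag pairs under purifying selection (`ω < 0.5`).

**Methylation.** Per CpG site, methylation is `m/(m+u)`. Promoters are
the 2 kb upstream of the TSS; the gene body is the rest of the gene.
Region status uses the upper-tail binomial statistic

    P_CG = Σ_{i=m_cg}^{n_cg} C(n_cg, i) p_cg^i (1 − p_cg)^(n_cg − i)

with `p_cg` the genome-wide methylated-CpG proportion; regions with
`n_cg ≥ 20` and ≥ 60% of CpGs covered are called methylated at
`P_CG ≤ 0.05` and unmethylated at `P_CG ≥ 0.95`. Divergence between
paralogs is `PMD = (M_P1 − M_P2)/(M_P1 + M_P2)` (same for gene bodies,
GMD), stage specificity is `SMI = Σ(1 − m_i/m_max)/(n − 1)`, and
expression breadth uses Shannon entropy, `specificity = 1 − H/log2 N`.
Correlation machinery includes Pearson and first-order partial
correlation, equal-count Ks-binned trends, Welch t-tests, proportion
and Fisher exact tests, and BH FDR.

## Worked example

```python
from dupmeth import CodonPairML, ng86_kaks, lrt_purifying, backtranslate
from dupmeth.simulate import simulate_codon_pair
from dupmeth.methylation import pcg_statistic
from dupmeth.stats import age_from_ks

cds1, cds2 = simulate_codon_pair(300, t=0.8, kappa=2.0, omega=0.2, seed=11)
aln = backtranslate("X" * 300, "X" * 300, cds1, cds2)
ng = ng86_kaks(aln)
print(f"NG86: Ka={ng.ka:.4f}  Ks={ng.ks:.4f}  Ka/Ks={ng.omega:.4f}")
model = CodonPairML(aln)
fixed, free = model.fit(fixed_omega=0.5), model.fit()
print(free.summary())
stat, p = lrt_purifying(fixed, free)
print(f"LRT omega<0.5: stat={stat:.4f}  p={p:.3e}")
print(f"P_CG(m=28, n=30, p=0.5) = {pcg_statistic(28, 30, 0.5):.3e}")
print(f"age of Ks=1.6 at 4.13e-9/site/yr: {age_from_ks(1.6, 4.13e-9)/1e6:.0f} MYA")
```

prints

```
NG86: Ka=0.1239  Ks=0.8072  Ka/Ks=0.1535
Pairwise codon ML fit
==========================================
n codons                 300
log-likelihood    -1820.4111
converged               True
------------------------------------------
param       estimate     std err
t             0.8527      0.0759
kappa         2.3587      0.4205
omega         0.1881      0.0322
LRT omega<0.5: stat=33.7480  p=6.273e-09
P_CG(m=28, n=30, p=0.5) = 4.340e-07
age of Ks=1.6 at 4.13e-9/site/yr: 387 MYA
```

The pair was simulated at `t = 0.8`, `ω = 0.2`; both estimators recover
the planted divergence and constraint, the LRT firmly rejects `ω = 0.5`
(purifying selection), a promoter with 28 of 30 CpGs methylated against
a 50% genome background is emphatically methylated (`P_CG ≈ 4e−7`), and
a synonymous divergence of 1.6 at the standard silent-site rate dates a
duplication burst to roughly 387 million years ago — the timescale of
the teleost whole-genome duplication.

For an end-to-end run, generate a synthetic bundle and run the pipeline:

```
dupmeth simulate --seed 1 --outdir scenario
dupmeth print-config > run.yaml   # edit paths to the bundle
dupmeth run run.yaml
```

The run directory then holds TSV tables for families, pairs (with Ka,
Ks, ω̂, LRT and FDR columns), per-region methylation and classes,
PMD/GMD/SMI per pair, expression entropy, correlation and group-test
tables, and a `run_metadata.json` with the config hash and stage counts.

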