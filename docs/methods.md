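# Methods

This note documents the models, statistics and design choices behind
`dupmeth`, in the order the pipeline applies them, together with the
assumptions, tunable parameters and known limitations a user should
weigh before trusting a number.

## Conventions

All genomic coordinates are 0-based half-open internally; 1-based
coordinates exist only at file boundaries (Bismark-style cytosine
reports). Gene1 of a pair is always the lexicographically smaller id,
so the signs of PMD/GMD/SMI divergence are comparable across datasets.
Only the universal genetic code is supported (zebrafish nuclear genes).

## Duplicate-pair discovery

Undirected alignment hits come from a BLAST-tabular file; self-hits are
dropped and reciprocal hits collapsed to the record with the larger
aligned length (tie: larger identity), which makes the hit list
independent of input order and of whether both directions were
searched. A pair passes when

* the aligned region is *strictly* longer than 80% of the longer
  protein (full protein lengths come from the FASTA, since the
  12-column tabular format lacks them), and
* identity ≥ 0.30 for aligned regions strictly longer than 150 aa,
  otherwise identity ≥ `0.01·n + 4.8·L^(−0.32(1+exp(−L/1000)))` with
  `n = 6`.

The length-dependent curve is strictly decreasing on the domain where
it is consulted (L ≤ 150); past L ≈ 410 it turns upward again, which is
irrelevant because the fixed 30% cutoff governs there.

Families are built with an in-repo Markov Cluster implementation
(column-stochastic flow matrix; expansion = matrix power 2; inflation =
entry-wise power 2.0 then renormalisation; self-loop weight 1; entries
< 1e−9 pruned; convergence when the flow matrix changes by < 1e−6, cap
200 iterations). Edge weights are the identity fractions of passing
hits — any monotone similarity would do; identity is what the input
provides. Clusters are read off attractor rows, and overlapping
clusters are merged so families partition the gene universe. Per
family, the member pair with the lowest NG86 Ks is kept, then filtered
to `0.01 < Ks ≤ 2` (the window is applied after pairing). Ties break
lexicographically.

"Recent" duplicates are pairs whose two members both map to a
single-copy outgroup family (grass-carp-style copy-number table);
missing table entries leave a pair unflagged, with a log line.
Functional divergence compares paralogs' domain-identifier sets:
equal → same, both empty → unannotated, otherwise different.

## Ka/Ks and the purifying-selection test

Protein alignments are threaded back onto their CDSs; columns with a
gap, ambiguity or stop are dropped. The pipeline consumes pre-aligned
proteins — for equal-length paralogs (as in the synthetic bundle) the
identity alignment is used, and pairs with unequal protein lengths and
no supplied alignment are skipped with a log entry, since running an
external aligner is outside this package's scope.

**Counting estimator.** Nei–Gojobori (1986): per-codon synonymous site
fractions (each position contributes syn-changes/3), averaged over the
two sequences; observed differences partitioned over all shortest
mutational pathways with equal weights; both proportions corrected with
the Jukes–Cantor transform `d = −(3/4)·ln(1 − 4p/3)`. Mutations *to* a
stop codon count as nonsynonymous in site counting; pathways *through*
a stop are excluded (if every pathway is blocked, stop-passing pathways
are used with stop steps counted nonsynonymous). `p ≥ 3/4` yields a NaN
distance with a warning; `ω̂ = Ka/Ks` is NaN when Ks = 0. Note that the
equal-weight pathway rule attributes fractional nonsynonymous
differences to some multi-step codon pairs even when every underlying
substitution event was synonymous; that is a property of the counting
method, not a bug.

**Likelihood estimator.** A Goldman–Yang-style model on the 61 sense
codons: `q_ij = 0` for multi-nucleotide changes, else `π_j`, `κπ_j`,
`ωπ_j`, `ωκπ_j` for synonymous transversions/transitions and
nonsynonymous transversions/transitions; Q is scaled to one expected
substitution per codon per unit `t`, and `P(t) = exp(Qt)` is computed
by symmetric eigendecomposition (the chain is reversible). The pair
likelihood is `Σ_sites log(π_{c1} P_{c1→c2}(t))`, which is
order-invariant. Codon frequencies are F3x4 from the two sequences
pooled, floored at 1e−6 and renormalised. Fitting maximises over
`t ∈ [1e−5, 50]`, `κ ∈ [0.01, 100]`, `ω ∈ [1e−4, 20]` with L-BFGS-B in
log-parameter space from three fixed starts; alignments shorter than 10
codons are refused, and an alignment with zero differences returns the
`t → 0` likelihood with an `identifiable = False` flag (ω undefined).
Standard errors come from the finite-difference observed information at
the optimum.

The purifying-selection test fits twice (ω fixed at 0.5; ω free);
`stat = max(0, 2ΔlnL)` is referred to χ²(df = 1). Negative raw
statistics (numerical noise) are clipped and logged. BH FDR is applied
across all representative pairs in one batch, and because the
literature states both an FDR-of-5% rule and a `P < 0.01` rule, both
flags are emitted (`purifying_q05`, `purifying_p01`), each additionally
requiring `ω̂ < 0.5`.

This package deliberately implements its own NG86 and pairwise codon-ML
rather than wrapping yn00/codeml; estimates can therefore differ
slightly from PAML output (different optimiser, F3x4 pooling, and NG86
stop conventions), and output metadata records the package version that
produced each table.

## Methylation quantification and classification

Cytosine reports are filtered to CpG context. By default the two
cytosines of a CpG dyad are merged (counts summed onto the plus-strand
position): the literature is silent on strand handling, and merging
raises coverage symmetrically; `merge_dyads=False` preserves strands.

Promoters are the 2 kb upstream of the TSS, strand-aware and clipped at
chromosome bounds; the body is the full annotated gene span. Per site,
the level is `m/(m+u)` (NaN at zero coverage — never 0). A region
summary counts `n_cg` = CpG sites with coverage ≥ 2 (the "at least two
reads" reading of an ambiguous `>2`-vs-`≥2` wording; configurable),
`m_cg` = counted sites with level ≥ 0.5 (the site-level "methylated"
call is undefined in the source analysis; a symmetric 0.5 at coverage
≥ 2 is the simplest rule and is configurable), and the *unweighted*
mean of site levels (matching the per-site definition; a read-weighted
mean is one flag away). The coverage fraction's denominator is every
CpG site present in the report for the region, including 0/0 rows.

`P_CG` is the upper binomial tail `P(X ≥ m_cg)` for
`X ~ Bin(n_cg, p_cg)`, computed with scipy's survival function (it
matches 50-digit exact summation to < 1e−12 up to n = 1000). The
background `p_cg` is estimated per dataset — methylomes differ sharply
across gametes and embryo stages — as the fraction of covered CpG sites
called methylated, and clipped to `[1e−9, 1 − 1e−9]` before the tail.
Classes: insufficient if `n_cg < 20` or coverage fraction < 0.60; else
methylated (`P_CG ≤ 0.05`), unmethylated (`P_CG ≥ 0.95`), or
intermediate. `m_cg` counts *sites*, not reads.

The unmethylated spike-in chromosome's pooled `m/(m+u)` estimates the
summed non-conversion and T→C sequencing error rate, reported per
dataset in run metadata.

Pair indices: `PMD = (M_P1 − M_P2)/(M_P1 + M_P2)` on mean promoter
levels (GMD likewise on bodies), NaN when the denominator is 0;
`SMI = Σ(1 − m_i/m_max)/(n − 1)` over the six embryo stages (16-cell
through germ ring), NaN for an all-zero profile; SMI divergence uses
the same ratio form. A pair shows *consistent promoter divergence* only
when the same member is methylated and the other unmethylated in every
dataset — any insufficient, intermediate or flipped dataset disqualifies.

## Expression and statistics

Entropy uses `P_i = g_i/g_sum`, `H = −Σ P_i log2 P_i` (0·log 0 = 0),
`specificity = 1 − H/log2 N`; all-zero vectors are NaN and excluded.
Expression enters correlations as `log2(FPKM + 1)` (the offset and base
are configurable; the source figure axis gives neither). Pearson p
comes from the t transform; first-order partial correlation uses
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` with df = n − 3
(verified against residual regression to 1e−10). Ks trends use
equal-count quantile bins (default 20; equal-width by flag), per-bin
95% CI = mean ± 1.96·SE, and Pearson across bin means; both bin-level
and gene-level r are reported since the source does not say which
produced its printed values. Group comparisons use Welch's t-test
(pooled-variance was never specified; Welch is the safer default),
R-style proportion tests with Yates continuity correction, and
two-sided Fisher exact tests. All tests are two-sided. Ks converts to
age as `Ks/rate` with rate 4.13e−9 per silent site per year — the
convention that dates a Ks peak of 1.6 to ~387 MYA; `per_lineage=True`
gives the halved pairwise convention.

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity the pipeline measures, under one
seeded RNG (same seed → byte-identical bundle). Defaults define the
study conditions of the test-suite:

* 150 duplicate pairs (plus 10 three-member families to exercise
  lowest-Ks selection) with Ks on a uniform grid over (0.05, 1.95];
  80% of pairs at ω = 0.2, the rest at the ω = 0.5 boundary; κ = 2;
  200 codons per gene. Sequences evolve `t/2` per lineage under the
  same rate matrix the estimator fits, with `t` chosen so the expected
  NG86 Ks hits the planted value (synonymous-flux calculation, exact to
  first order; the JC correction absorbs multiple hits).
* Promoter methylation declining with Ks (0.85 − 0.30·Ks) and body
  methylation rising (0.25 + 0.25·Ks); within-pair promoter asymmetry
  growing with Ks (0.25·Ks, favouring gene1) so PMD rises with age,
  body asymmetry shrinking with Ks so GMD falls. 50 pairs are planted
  consistently divergent (promoter levels 0.90 vs 0.05 in all nine
  datasets). 15% of genes get a one-embryo-stage methylation peak to
  exercise SMI.
* Site-level noise is Beta around the regional target (concentration
  50); depth is Poisson (mean 20, roughly the coverage of the
  underlying BS-seq study); observed methylation includes a 0.005
  non-conversion floor; a 5000-site spike-in chromosome is appended.
  Promoter CpG coordinates are the CG dinucleotides of the emitted
  promoter sequences; body CpGs sit on a 50-bp grid.
* log2 FPKM = 5 − 2·(promoter level) + N(0, 0.5); 5% of genes are
  one-hot expressed. Gene lengths are lognormal scaled by
  (1 + 4·body level), so body-methylated genes run ~3× longer.
  Outgroup copy number is 1 for pairs with Ks ≤ 0.25 ("recent"), else
  2. Domain sets differ with probability 0.27 for consistent pairs and
  0.15 otherwise (the source study's observed rates).

These sizes keep a full end-to-end run under a minute and the entire
validation suite in a few minutes on one CPU.

What passing tests on this generator shows: the estimators are
calibrated and consistent under their own model, the classification and
divergence logic recovers planted truth through the real file formats,
and the pipeline's statistics detect planted couplings with the right
signs. What it does not show: robustness to real-data pathologies —
alignment error, paralog-collapsed read mapping, CpG-island structure,
copy-number artefacts, unplaced scaffolds, or model misspecification of
codon frequencies — none of which the generator emulates. Headline
correlation magnitudes here are properties of the planted effect sizes,
not predictions of the biological values.

## Numerical choices and degenerate inputs

* `P(t)` by symmetric eigendecomposition; probabilities floored at
  1e−300 before logs.
* Optimiser: L-BFGS-B, `ftol` 1e−12, three fixed starts; best optimum
  kept; `converged` comes from the optimiser status.
* `p_cg` clipped to `[1e−9, 1 − 1e−9]`; partial correlation raises when
  a control correlation is ±1 (denominator < 1e−24); zero-variance
  inputs raise rather than return 0.
* Empty Ks bins from ties are merged with a log line; constant metrics
  propagate NaN trends rather than errors.
* The WGD date uses the mode of a 0.1-wide Ks histogram — adequate for
  a synthetic grid; real Ks distributions deserve a mixture model.

## Known limitations

* Pairwise codon ML only: no site/branch models, no codon-bias models
  beyond F3x4, exactly two sequences.
* The pipeline does not align proteins; unequal-length pairs without a
  supplied alignment are dropped from Ka/Ks.
* `m_cg` site-counting (vs read-counting) and dyad merging are
  documented interpretations of an underspecified procedure; both are
  configurable.
* Genes on unplaced scaffolds are not excluded; motif discovery and GO
  clustering are out of scope (only the downstream Fisher test on
  occurrence counts is provided).
* Run metadata carries the config hash; the TSV tables themselves stay
  comment-free so they round-trip through ordinary parsers.
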