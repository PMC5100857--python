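"""Promoter/gene-body methylation quantification, the binomial P_CG
classification, and divergence / stage-specificity indices.

A promoter is the 2 kb upstream of the transcription start site
(strand-aware, clipped at chromosome bounds); the gene body is the
remainder of the gene region.  Per CpG site the methylation level is
m/(m+u).  A region's methylation status comes from the upper-tail
binomial statistic

    P_CG = P(X >= m_cg),  X ~ Binomial(n_cg, p_cg),

where p_cg is the genome-wide proportion of methylated CpG sites,
n_cg counts covered CpG sites in the region and m_cg those called
methylated.  Low P_CG means more densely methylated than expected at
random: regions are called methylated at P_CG <= 0.05 and unmethylated
at P_CG >= 0.95, provided n_cg >= 20 and at least 60% of the region's
CpG sites are covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "Region",
    "RegionMethylation",
    "site_level",
    "extract_regions",
    "region_summary",
    "pcg_statistic",
    "classify_region",
    "estimate_background",
    "estimate_nonconversion",
    "methylation_divergence",
    "smi",
    "smi_divergence",
    "consistent_promoter_divergence",
    "promoter_composition",
]

PROMOTER_LEN = 2000
DATASETS = (
    "egg", "sperm", "testis",
    "16-cell", "32-cell", "64-cell", "128-cell", "1k-cell", "germ-ring",
)
EMBRYO_STAGES = ("16-cell", "32-cell", "64-cell", "128-cell", "1k-cell", "germ-ring")


@dataclass
class Region:
    """One promoter or gene-body region (0-based half-open)."""

    gene_id: str
    kind: str  # "promoter" | "body"
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionMethylation:
    """Methylation summary of one gene region in one dataset."""

    gene_id: str
    kind: str
    dataset: str = ""
    mean_level: float = math.nan
    n_sites_total: int = 0  # CpG sites present in the region
    n_cg: int = 0           # of those, covered >= min_cov
    m_cg: int = 0           # of those, called methylated
    coverage_fraction: float = math.nan
    p_cg_background: float = math.nan
    P_CG: float = math.nan
    klass: str = "insufficient"


def site_level(m_count: int, u_count: int) -> float:
    """Per-site methylation level m/(m+u); NaN at zero coverage."""
    if m_count < 0 or u_count < 0:
        raise ValueError("read counts must be non-negative")
    cov = m_count + u_count
    return m_count / cov if cov else math.nan


def extract_regions(gene_models, chrom_sizes: dict, promoter_len: int = PROMOTER_LEN):
    """Strand-aware promoter and gene-body regions for each gene.

    Plus-strand genes: promoter [tx_start - L, tx_start); minus-strand:
    [tx_end, tx_end + L).  Body is the full gene span.  Promoters are
    clipped at chromosome bounds; a gene extending past its chromosome
    end raises an error.
    """
    regions = []
    for g in gene_models:
        size = chrom_sizes[g.chrom]
        if g.tx_end > size:
            raise ValueError(f"{g.gene_id} extends past the end of {g.chrom}")
        if g.strand == "+":
            p_start, p_end = max(0, g.tx_start - promoter_len), g.tx_start
        else:
            p_start, p_end = g.tx_end, min(size, g.tx_end + promoter_len)
        regions.append(Region(g.gene_id, "promoter", g.chrom, g.strand, p_start, p_end))
        regions.append(Region(g.gene_id, "body", g.chrom, g.strand, g.tx_start, g.tx_end))
    return regions


def region_summary(
    positions: np.ndarray,
    m_counts: np.ndarray,
    u_counts: np.ndarray,
    region: Region,
    min_cov: int = 2,
    call_threshold: float = 0.5,
) -> RegionMethylation:
    """Summarise one region from a chromosome's CpG-site arrays.

    ``positions`` must be sorted and include uncovered sites (0/0 rows
    of the cytosine report) so the coverage fraction has the right
    denominator.  ``mean_level`` is the unweighted mean of site levels
    over sites with coverage >= ``min_cov``; ``m_cg`` counts those
    sites whose level is >= ``call_threshold``.
    """
    lo = np.searchsorted(positions, region.start, side="left")
    hi = np.searchsorted(positions, region.end, side="left")
    m = np.asarray(m_counts[lo:hi], dtype=float)
    u = np.asarray(u_counts[lo:hi], dtype=float)
    total = hi - lo
    cov = m + u
    ok = cov >= min_cov
    n_cg = int(ok.sum())
    rm = RegionMethylation(region.gene_id, region.kind, n_sites_total=int(total), n_cg=n_cg)
    if total:
        rm.coverage_fraction = n_cg / total
    if n_cg:
        levels = m[ok] / cov[ok]
        rm.mean_level = float(levels.mean())
        rm.m_cg = int((levels >= call_threshold).sum())
    return rm


def pcg_statistic(m_cg: int, n_cg: int, p_cg: float) -> float:
    """Upper-tail binomial probability P(X >= m_cg), X ~ Bin(n_cg, p_cg)."""
    if not 0 <= m_cg <= n_cg:
        raise ValueError("need 0 <= m_cg <= n_cg")
    if not 0.0 < p_cg < 1.0:
        raise ValueError("p_cg must lie strictly inside (0, 1)")
    if m_cg == 0:
        return 1.0
    return float(binom.sf(m_cg - 1, n_cg, p_cg))


def classify_region(
    summary: RegionMethylation,
    p_cg_background: float,
    min_ncg: int = 20,
    min_coverage_fraction: float = 0.60,
    methylated_max: float = 0.05,
    unmethylated_min: float = 0.95,
) -> RegionMethylation:
    """Attach P_CG and the methylation class to a region summary.

    Regions failing the information filters (n_cg >= 20 and >= 60% of
    CpG sites covered) are "insufficient"; otherwise methylated when
    P_CG <= 0.05, unmethylated when P_CG >= 0.95, else intermediate.
    The background proportion is clipped away from 0/1 so the binomial
    tail is defined.
    """
    p = min(max(p_cg_background, 1e-9), 1 - 1e-9)
    summary.p_cg_background = p
    if summary.n_cg < min_ncg or not (summary.coverage_fraction >= min_coverage_fraction):
        summary.klass = "insufficient"
        summary.P_CG = math.nan
        return summary
    summary.P_CG = pcg_statistic(summary.m_cg, summary.n_cg, p)
    if summary.P_CG <= methylated_max:
        summary.klass = "methylated"
    elif summary.P_CG >= unmethylated_min:
        summary.klass = "unmethylated"
    else:
        summary.klass = "intermediate"
    return summary


def estimate_background(
    m_counts: np.ndarray,
    u_counts: np.ndarray,
    min_cov: int = 2,
    call_threshold: float = 0.5,
) -> float:
    """Genome-wide proportion of methylated CpG sites for one dataset.

    The fraction of CpG sites with coverage >= ``min_cov`` whose level
    is >= ``call_threshold``.
    """
    m = np.asarray(m_counts, dtype=float)
    u = np.asarray(u_counts, dtype=float)
    cov = m + u
    ok = cov >= min_cov
    if not ok.any():
        raise ValueError("no CpG sites pass the coverage filter")
    levels = m[ok] / cov[ok]
    return float((levels >= call_threshold).mean())


def estimate_nonconversion(m_counts, u_counts) -> float:
    """Apparent methylation of the unmethylated spike-in chromosome.

    total m / total (m+u) over the spike-in, measuring the summed rates
    of bisulfite non-conversion and T->C sequencing error.  NaN when the
    spike-in has no reads.
    """
    m = float(np.sum(m_counts))
    u = float(np.sum(u_counts))
    return m / (m + u) if (m + u) > 0 else math.nan


def methylation_divergence(m1: float, m2: float) -> float:
    """(M1 - M2) / (M1 + M2); NaN when the denominator is 0 or inputs missing.

    Applied identically for promoter (PMD) and gene-body (GMD)
    methylation divergence.
    """
    if math.isnan(m1) or math.isnan(m2):
        return math.nan
    if m1 < 0 or m2 < 0:
        raise ValueError("methylation levels must be non-negative")
    tot = m1 + m2
    return (m1 - m2) / tot if tot > 0 else math.nan


def smi(levels) -> float:
    """Stage-specificity index of methylation: sum(1 - m_i/m_max)/(n-1).

    0 for a constant profile, 1 for a one-hot profile; NaN when every
    stage is 0 (or any level is missing).
    """
    v = np.asarray(levels, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two stages")
    if np.isnan(v).any():
        return math.nan
    if (v < 0).any():
        raise ValueError("methylation levels must be non-negative")
    m_max = v.max()
    if m_max == 0:
        return math.nan
    return float((1.0 - v / m_max).sum() / (v.size - 1))


def smi_divergence(smi1: float, smi2: float) -> float:
    """(SMI1 - SMI2) / (SMI1 + SMI2), as for methylation divergence."""
    return methylation_divergence(smi1, smi2)


def consistent_promoter_divergence(classes1, classes2):
    """Test whether one paralog is promoter-methylated and the other
    unmethylated, with the same orientation, in every dataset.

    ``classes1``/``classes2`` list the promoter classes of the two
    members over the same datasets.  Any insufficient or intermediate
    class, or an orientation flip, makes the pair inconsistent.

    Returns (is_consistent, methylated_member) with methylated_member in
    {1, 2, None}.
    """
    if len(classes1) != len(classes2) or not classes1:
        raise ValueError("class lists must be non-empty and equal-length")
    orientations = set()
    for c1, c2 in zip(classes1, classes2):
        if c1 == "methylated" and c2 == "unmethylated":
            orientations.add(1)
        elif c1 == "unmethylated" and c2 == "methylated":
            orientations.add(2)
        else:
            return False, None
        if len(orientations) > 1:
            return False, None
    return True, orientations.pop()


def promoter_composition(promoter_sequence: str):
    """C-base fraction and CpG dinucleotide count of a promoter sequence.

    The CpG count uses an overlap-free scan (non-overlapping "CG"
    occurrences; with this dinucleotide the distinction is moot).
    """
    seq = promoter_sequence.upper()
    if not seq:
        raise ValueError("empty promoter sequence")
    c_fraction = seq.count("C") / len(seq)
    return c_fraction, seq.count("CG")
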