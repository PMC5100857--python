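"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are 0-based, half-open internally; 1-based
coordinates appear only at file boundaries (Bismark-style cytosine
reports).  Tabular outputs are TSV with a header line and a fixed,
deterministic column order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AlignmentHit",
    "GeneModel",
    "read_fasta",
    "sequence_lengths",
    "write_fasta",
    "read_blast_tab",
    "read_annotation",
    "read_cytosine_report",
    "read_expression",
    "read_chrom_sizes",
    "read_two_column_map",
    "read_domain_table",
    "write_table",
]


@dataclass
class SequenceRecord:
    """A named biological sequence (protein or nucleotide)."""

    id: str
    seq: str


@dataclass
class AlignmentHit:
    """An undirected protein-vs-protein alignment hit.

    ``identity`` is a fraction in [0, 1]; ``align_len`` counts aligned
    columns in amino acids.
    """

    query_id: str
    subject_id: str
    align_len: int
    identity: float


@dataclass
class GeneModel:
    """A gene's genomic extent: chrom, strand, transcript span and CDS."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}")
        prev_end = None
        for (s, e) in self.cds_intervals:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: CDS interval ({s},{e}) outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved.  Duplicate ids and empty sequences raise
    ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).strip()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def sequence_lengths(records) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in records}


def read_blast_tab(path) -> list[AlignmentHit]:
    """Read BLAST tabular output (outfmt-6-like, >= 4 leading columns).

    Percent identity is converted to a fraction; self-hits are dropped;
    reciprocal hits are collapsed to one undirected record keeping the
    larger ``align_len`` (ties broken by larger identity).  Protein
    lengths are not carried here; supply them separately from the FASTA.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated columns")
            q, s = parts[0], parts[1]
            try:
                pident = float(parts[2])
                alen = int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric identity/length: {exc}") from None
            if alen < 1:
                raise ValueError(f"{path}:{lineno}: alignment length must be >= 1")
            if q == s:  # self-hit
                continue
            key = (q, s) if q <= s else (s, q)
            hit = AlignmentHit(key[0], key[1], alen, pident / 100.0)
            prev = best.get(key)
            if prev is None:
                best[key] = hit
                order.append(key)
            elif (hit.align_len, hit.identity) > (prev.align_len, prev.identity):
                best[key] = hit
    # deterministic output independent of input line order
    return [best[k] for k in sorted(best)]


def read_annotation(path, fmt: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 (the pipeline's annotation dialect).

    BED is already 0-based half-open; thick-start/thick-end plus blocks
    give the CDS intervals.
    """
    if fmt != "bed12":
        raise ValueError(f"unsupported annotation format {fmt!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start for {name}")
            thick_s, thick_e = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")] if f[10].strip(",") else []
            starts = [int(x) for x in f[11].rstrip(",").split(",")] if f[11].strip(",") else []
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch for {name}")
            cds = []
            for bs, sz in zip(starts, sizes):
                ex_s, ex_e = start + bs, start + bs + sz
                s = max(ex_s, thick_s)
                e = min(ex_e, thick_e)
                if s < e:
                    cds.append((s, e))
            genes.append(GeneModel(name, chrom, strand, start, end, cds))
    return genes


_CPG_CONTEXTS = {"CG", "CpG"}


def read_cytosine_report(path, merge_dyads: bool = True) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a CpG-site table.

    Input columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context.  Only CpG-context rows are kept;
    positions become 0-based.  With ``merge_dyads`` the minus-strand
    cytosine of each CpG dyad is folded onto the plus-strand position
    (one base to its left) and counts are summed.

    Returns a DataFrame with columns chrom, pos, strand, m_count,
    u_count, sorted by (chrom, pos).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "m_count", "u_count", "context"],
        dtype={"chrom": str, "pos": int, "strand": str, "m_count": int, "u_count": int, "context": str},
    )
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        sym = df.loc[bad_strand, "strand"].iloc[0]
        raise ValueError(f"{path}: unknown strand symbol {sym!r}")
    if (df["m_count"] < 0).any() or (df["u_count"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    df = df[df["context"].isin(_CPG_CONTEXTS)].copy()
    df["pos"] = df["pos"] - 1  # to 0-based
    if merge_dyads:
        minus = df["strand"] == "-"
        df.loc[minus, "pos"] -= 1  # minus-strand C sits one base right of the dyad's plus C
        df = (
            df.groupby(["chrom", "pos"], as_index=False)[["m_count", "u_count"]]
            .sum()
            .assign(strand="+")
        )
        df = df[["chrom", "pos", "strand", "m_count", "u_count"]]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a per-gene FPKM table (TSV, first column gene_id).

    Ragged rows and negative FPKM values raise ``ValueError``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise ValueError(f"{path}:{lineno}: ragged row ({ncol} columns expected)")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing FPKM values")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def read_two_column_map(path, value_type=int) -> dict:
    """Read a headered two-column TSV into a dict (e.g. outgroup copy numbers)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return {str(k): value_type(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_domain_table(path) -> dict[str, frozenset]:
    """Read gene -> functional-domain-set table (TSV: gene_id, comma-joined domains).

    An empty domain field means annotated-with-no-domains is *not*
    distinguished from unannotated: both yield an empty set.
    """
    out: dict[str, frozenset] = {}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for gene, doms in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[gene] = frozenset(d for d in doms.split(",") if d)
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV with header, no index; deterministic order."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
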