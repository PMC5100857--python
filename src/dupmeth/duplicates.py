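"""Duplicate-gene discovery: homology filtering, Markov clustering into
gene families, and selection of one representative paralog pair per
family by lowest Ks.

Two proteins are called a duplicate pair when (1) the alignable region
is longer than 80% of the longer protein and (2) identity I >= 30% for
alignable regions longer than 150 aa, or I >= 0.01 n + 4.8 L^(-0.32 (1 +
exp(-L/1000))) with n = 6 otherwise (the length-dependent homology
threshold of Rost's curve as adapted for duplicate-gene surveys).
Families are built with the Markov Cluster algorithm on the identity-
weighted pair graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HomologyCriteria",
    "identity_threshold",
    "filter_homolog_pairs",
    "mcl_cluster",
    "select_representative_pairs",
    "flag_recent_duplicates",
    "compare_domain_sets",
]

logger = logging.getLogger(__name__)


@dataclass
class HomologyCriteria:
    """Thresholds for calling two proteins a duplicate pair."""

    coverage_min: float = 0.8
    long_align_cutoff: int = 150
    fixed_identity_min: float = 0.30
    n_param: int = 6

    def __post_init__(self):
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must be in (0, 1]")
        if not 0 < self.fixed_identity_min < 1:
            raise ValueError("fixed_identity_min must be in (0, 1)")


def identity_threshold(align_len_aa: float, n_param: int = 6) -> float:
    """Minimum identity fraction for an alignable region of L amino acids.

    I_min = 0.01 n + 4.8 L^(-0.32 (1 + exp(-L/1000))).
    """
    L = float(align_len_aa)
    if L <= 0:
        raise ValueError("alignable length must be positive")
    return 0.01 * n_param + 4.8 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))


def filter_homolog_pairs(hits, lengths, criteria: HomologyCriteria | None = None):
    """Apply the coverage and identity criteria to undirected alignment hits.

    ``lengths`` maps gene id -> protein length (aa).  Returns the list of
    passing hits.  A hit whose gene lacks a length raises ``KeyError``
    naming the gene.
    """
    criteria = criteria or HomologyCriteria()
    kept = []
    for hit in hits:
        for gid in (hit.query_id, hit.subject_id):
            if gid not in lengths:
                raise KeyError(f"no protein length known for gene {gid!r}")
        longer = max(lengths[hit.query_id], lengths[hit.subject_id])
        if not hit.align_len > criteria.coverage_min * longer:
            continue
        if hit.align_len > criteria.long_align_cutoff:
            min_ident = criteria.fixed_identity_min
        else:
            min_ident = identity_threshold(hit.align_len, criteria.n_param)
        if hit.identity >= min_ident:
            kept.append(hit)
    return kept


def mcl_cluster(
    nodes,
    edges,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    self_loop: float = 1.0,
    prune: float = 1e-9,
):
    """Markov Cluster algorithm on a weighted undirected graph.

    ``edges`` is an iterable of (u, v, weight).  Alternating expansion
    (matrix power) and inflation (entry-wise power, then column
    renormalisation) is iterated until the flow matrix stabilises;
    clusters are read off attractor rows.  Overlapping attractor
    clusters are merged so no two families share a member.

    Returns a list of frozensets partitioning ``nodes`` (sorted by their
    smallest member for determinism).
    """
    nodes = sorted(set(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    M = np.zeros((n, n))
    for u, v, w in edges:
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        i, j = idx[u], idx[v]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    M[np.diag_indices(n)] += self_loop

    def normalise(A):
        colsum = A.sum(axis=0)
        colsum[colsum == 0] = 1.0
        return A / colsum

    M = normalise(M)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        M = normalise(M)
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; using current matrix", max_iter)

    # attractors: nodes retaining flow on the diagonal
    eps = max(prune, 1e-12)
    clusters: list[set] = []
    for i in range(n):
        if M[i, i] > eps:
            members = {nodes[j] for j in np.nonzero(M[i] > eps)[0]}
            members.add(nodes[i])
            clusters.append(members)
    # merge overlapping clusters ("until no additional groups shared a member")
    merged: list[set] = []
    for c in clusters:
        hit = [m for m in merged if m & c]
        for m in hit:
            merged.remove(m)
            c = c | m
        merged.append(c)
    assigned = set().union(*merged) if merged else set()
    for node in nodes:
        if node not in assigned:
            merged.append({node})
    return sorted((frozenset(c) for c in merged), key=lambda c: min(c))


def select_representative_pairs(families, ks_of_pair, ks_min: float = 0.01, ks_max: float = 2.0):
    """Select one paralog pair per family: the pair with lowest Ks.

    ``ks_of_pair`` is a callable (gene1, gene2) -> Ks (NaN allowed).
    After per-family selection, pairs are kept only when
    ``ks_min < Ks <= ks_max``.  Ties break lexicographically by
    (gene1, gene2).  Single-member families are skipped.
    """
    out = []
    for fam in families:
        members = sorted(fam)
        if len(members) < 2:
            continue
        best = None
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                ks = ks_of_pair(a, b)
                if ks is None or (isinstance(ks, float) and math.isnan(ks)):
                    continue
                cand = (ks, a, b)
                if best is None or cand < best:
                    best = cand
        if best is None:
            continue
        ks, a, b = best
        if ks_min < ks <= ks_max:
            out.append((a, b, ks))
    return sorted(out, key=lambda p: (p[0], p[1], p[2]))


def flag_recent_duplicates(pairs, outgroup_copy_number: dict) -> list[bool]:
    """Flag pairs that are single-copy in the outgroup.

    ``pairs`` is an iterable of (gene1, gene2); the table maps each
    zebrafish gene to its outgroup family copy count.  A pair is
    "recent" when both members map to a single outgroup copy.  A
    missing entry leaves the pair unflagged with a log line.
    """
    flags = []
    for g1, g2 in pairs:
        c1 = outgroup_copy_number.get(g1)
        c2 = outgroup_copy_number.get(g2)
        if c1 is None or c2 is None:
            logger.info("pair (%s, %s) absent from outgroup copy-number table; not flagged", g1, g2)
            flags.append(False)
        else:
            flags.append(c1 == 1 and c2 == 1)
    return flags


def compare_domain_sets(domains1, domains2) -> str:
    """Compare two paralogs' functional-domain sets.

    Returns "unannotated" when both are empty, "same" on set equality,
    "different" otherwise.
    """
    d1, d2 = frozenset(domains1), frozenset(domains2)
    if not d1 and not d2:
        return "unannotated"
    return "same" if d1 == d2 else "different"
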