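"""Pairwise codon-level molecular evolution: Ka/Ks and the purifying-
selection likelihood-ratio test.

Two estimators are provided for a codon-aligned paralog pair:

* :func:`ng86_kaks` — Nei–Gojobori (1986) counting with equal-weight
  mutational pathways and Jukes–Cantor multiple-hit correction, giving
  (Ka, Ks, omega_hat).
* :class:`CodonPairML` — a Goldman–Yang-style codon substitution model
  (61 sense codons, parameters t, kappa, omega, F3x4 codon frequencies)
  fitted by maximum likelihood.  Fitting it twice — once with omega
  fixed at 0.5 and once free — yields the likelihood-ratio test of
  purifying selection (2*delta-lnL ~ chi-square, df = 1).

The model class follows the Model/Results convention: build the model
from data, call ``fit()``, read estimates and ``summary()`` off the
results object.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "SENSE_CODONS",
    "CodonAlignment",
    "backtranslate",
    "ng86_kaks",
    "NG86Result",
    "f3x4_frequencies",
    "build_rate_matrix",
    "transition_matrix",
    "CodonPairML",
    "CodonPairMLResults",
    "lrt_purifying",
    "time_for_target_ks",
]

logger = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]  # universal code; zebrafish nuclear genes
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
_NUCS = "ACGT"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


# Directed single-nucleotide neighbour structure over the 61 sense codons,
# precomputed once at import.
def _neighbours():
    I, J, syn, ts = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in _NUCS:
                if nt == ci[pos]:
                    continue
                cj = ci[:pos] + nt + ci[pos + 1 :]
                if cj in STOP_CODONS:
                    continue
                I.append(i)
                J.append(_CODON_INDEX[cj])
                syn.append(_AA[ci] == _AA[cj])
                ts.append(_is_transition(ci[pos], nt))
    return (
        np.asarray(I, dtype=np.intp),
        np.asarray(J, dtype=np.intp),
        np.asarray(syn, dtype=bool),
        np.asarray(ts, dtype=bool),
    )


_NB_I, _NB_J, _NB_SYN, _NB_TS = _neighbours()


@dataclass
class CodonAlignment:
    """Two equal-length lists of aligned sense codons (no gaps, no stops)."""

    codons1: list
    codons2: list

    def __post_init__(self):
        if len(self.codons1) != len(self.codons2):
            raise ValueError("aligned codon lists differ in length")
        if len(self.codons1) < 1:
            raise ValueError("alignment must retain at least one codon column")
        for seq in (self.codons1, self.codons2):
            for c in seq:
                if c not in _CODON_INDEX:
                    raise ValueError(f"not a sense codon: {c!r}")

    @property
    def n_codons(self) -> int:
        return len(self.codons1)

    def n_differences(self) -> int:
        return sum(a != b for a, b in zip(self.codons1, self.codons2))


def _split_codons(cds: str):
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]


def backtranslate(prot_aln1: str, prot_aln2: str, cds1: str, cds2: str) -> CodonAlignment:
    """Thread two CDSs onto their aligned proteins, giving a codon alignment.

    Protein gaps expand to codon gaps; any column containing a gap,
    ambiguity, or stop codon is dropped.  A trailing stop codon on
    either CDS is trimmed; an internal stop raises an error naming the
    codon position.
    """
    if len(prot_aln1) != len(prot_aln2):
        raise ValueError("aligned proteins differ in length")
    codons = []
    for label, (prot, cds) in (("1", (prot_aln1, cds1)), ("2", (prot_aln2, cds2))):
        cods = _split_codons(cds)
        if cods and cods[-1] in STOP_CODONS:
            cods = cods[:-1]
        ungapped = prot.replace("-", "")
        if len(cods) != len(ungapped):
            raise ValueError(
                f"sequence {label}: CDS has {len(cods)} codons but protein has "
                f"{len(ungapped)} residues"
            )
        for k, c in enumerate(cods):
            if c in STOP_CODONS:
                raise ValueError(f"sequence {label}: internal stop codon at codon {k + 1}")
        codons.append(cods)

    cols1, cols2 = [], []
    it1, it2 = iter(codons[0]), iter(codons[1])
    for a, b in zip(prot_aln1, prot_aln2):
        c1 = next(it1) if a != "-" else None
        c2 = next(it2) if b != "-" else None
        if c1 is None or c2 is None:
            continue
        if c1 in _CODON_INDEX and c2 in _CODON_INDEX:
            cols1.append(c1)
            cols2.append(c2)
    return CodonAlignment(cols1, cols2)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _codon_syn_sites(codon: str) -> float:
    """Fraction-weighted synonymous sites in one codon (NG86).

    Each position contributes syn_changes/3; mutations creating a stop
    codon count as nonsynonymous.
    """
    s = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue  # counted as nonsynonymous: contributes nothing to s
            if _AA[alt] == _AA[codon]:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str):
    """Average synonymous/nonsynonymous differences between two codons
    over all shortest mutational pathways, equally weighted.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, stop-passing pathways are used with stop steps counted
    as nonsynonymous.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        sd = nd = 0.0
        cur = c1
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1.0
            elif cur in STOP_CODONS:
                nd += 1.0
            elif _AA[cur] == _AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    for allow_stops in (False, True):
        results = [r for order in itertools.permutations(diff_pos) if (r := walk(order, allow_stops))]
        if results:
            sd = sum(r[0] for r in results) / len(results)
            nd = sum(r[1] for r in results) / len(results)
            return sd, nd
    raise AssertionError("unreachable")


def _jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        warnings.warn("difference proportion >= 3/4; distance undefined", RuntimeWarning)
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class NG86Result:
    ka: float
    ks: float
    omega: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def ng86_kaks(aln: CodonAlignment) -> NG86Result:
    """Nei–Gojobori (1986) Ka, Ks and omega for a codon alignment.

    Site fractions are averaged over the two sequences; differences are
    partitioned over all shortest mutational pathways with equal
    weights; proportions are Jukes–Cantor corrected.  omega is NaN when
    Ks is 0 or undefined.
    """
    s1 = sum(_codon_syn_sites(c) for c in aln.codons1)
    s2 = sum(_codon_syn_sites(c) for c in aln.codons2)
    S = 0.5 * (s1 + s2)
    N = 3.0 * aln.n_codons - S
    sd = nd = 0.0
    for c1, c2 in zip(aln.codons1, aln.codons2):
        d_s, d_n = _pathway_counts(c1, c2)
        sd += d_s
        nd += d_n
    ks = _jukes_cantor(sd / S) if S > 0 else math.nan
    ka = _jukes_cantor(nd / N) if N > 0 else math.nan
    omega = ka / ks if (ks and not math.isnan(ks) and ks > 0 and not math.isnan(ka)) else math.nan
    return NG86Result(ka, ks, omega, S, N, sd, nd)


# ---------------------------------------------------------------------------
# GY94-style pairwise maximum likelihood
# ---------------------------------------------------------------------------

def f3x4_frequencies(codon_lists, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from pooled sequences.

    Position-specific nucleotide frequencies are estimated from all
    supplied codon lists pooled; codon frequencies are their product
    over the 61 sense codons, floored at ``floor`` and renormalised.
    """
    counts = np.zeros((3, 4))
    for codons in codon_lists:
        for c in codons:
            for pos in range(3):
                counts[pos, _NUCS.index(c[pos])] += 1
    if counts.sum() == 0:
        raise ValueError("no codons supplied")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(len(SENSE_CODONS))
    for i, c in enumerate(SENSE_CODONS):
        pi[i] = freqs[0, _NUCS.index(c[0])] * freqs[1, _NUCS.index(c[1])] * freqs[2, _NUCS.index(c[2])]
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled 61x61 codon rate matrix Q.

    Off-diagonal q_ij is 0 for multi-nucleotide changes and otherwise
    pi_j times kappa for transitions and omega for nonsynonymous
    changes.  Q is scaled so the equilibrium expected rate is one
    substitution per codon per unit time.
    """
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("codon frequencies must sum to 1")
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    rates = pi[_NB_J] * np.where(_NB_TS, kappa, 1.0) * np.where(_NB_SYN, 1.0, omega)
    Q[_NB_I, _NB_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (Q is reversible)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    d = np.sqrt(pi)
    B = Q * d[:, None] / d[None, :]
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    P = (U * np.exp(w * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    np.clip(P, 1e-300, None, out=P)
    return P


class CodonPairML:
    """Pairwise codon substitution model for one aligned paralog pair.

    Parameters are t (expected substitutions per codon along the whole
    path between the two sequences), kappa (transition/transversion rate
    ratio) and omega (dN/dS).  Codon frequencies default to F3x4 from
    the pair.  ``fit()`` returns a :class:`CodonPairMLResults`.
    """

    #: bounded search region for (t, kappa, omega)
    BOUNDS = {"t": (1e-5, 50.0), "kappa": (0.01, 100.0), "omega": (1e-4, 20.0)}
    #: deterministic multi-start points (t, kappa, omega)
    STARTS = ((0.2, 2.0, 0.3), (1.0, 2.0, 1.0), (4.0, 4.0, 0.1))
    MIN_CODONS = 10

    def __init__(self, alignment: CodonAlignment, codon_freqs: np.ndarray | None = None):
        self.alignment = alignment
        if codon_freqs is None:
            codon_freqs = f3x4_frequencies([alignment.codons1, alignment.codons2])
        codon_freqs = np.asarray(codon_freqs, dtype=float)
        if abs(codon_freqs.sum() - 1.0) > 1e-6:
            raise ValueError("codon frequencies must sum to 1")
        self.codon_freqs = codon_freqs / codon_freqs.sum()
        patt = Counter(
            (_CODON_INDEX[a], _CODON_INDEX[b])
            for a, b in zip(alignment.codons1, alignment.codons2)
        )
        self._pi_idx = np.array([k[0] for k in patt], dtype=np.intp)
        self._pj_idx = np.array([k[1] for k in patt], dtype=np.intp)
        self._pcount = np.array(list(patt.values()), dtype=float)
        self._log_pi = np.log(self.codon_freqs)

    def loglike(self, t: float, kappa: float, omega: float) -> float:
        """Log-likelihood: sum over sites of log(pi_c1 * P_{c1->c2}(t))."""
        Q = build_rate_matrix(kappa, omega, self.codon_freqs)
        P = transition_matrix(Q, self.codon_freqs, t)
        ll = self._pcount @ (self._log_pi[self._pi_idx] + np.log(P[self._pi_idx, self._pj_idx]))
        return float(ll)

    def _loglike_t0(self) -> float:
        """t -> 0+ limit: -inf unless the sequences are identical."""
        if np.any(self._pi_idx != self._pj_idx):
            return -math.inf
        return float(self._pcount @ self._log_pi[self._pi_idx])

    def fit(self, fixed_omega: float | None = None) -> "CodonPairMLResults":
        """Maximise the likelihood over (t, kappa[, omega]).

        With ``fixed_omega`` set, omega is held at that value (the null
        of the purifying-selection LRT uses 0.5).  Bounded L-BFGS-B in
        log-parameter space from three deterministic starts; the best
        optimum is kept.
        """
        aln = self.alignment
        if aln.n_codons < self.MIN_CODONS:
            raise ValueError(f"need >= {self.MIN_CODONS} codons to fit, got {aln.n_codons}")
        if aln.n_differences() == 0:
            # omega (and kappa) unidentifiable; likelihood maximised at t -> 0
            llf = self._loglike_t0()
            return CodonPairMLResults(
                self, t=self.BOUNDS["t"][0], kappa=1.0,
                omega=float("nan") if fixed_omega is None else fixed_omega,
                llf=llf, converged=True, fixed_omega=fixed_omega, identifiable=False,
            )

        free_omega = fixed_omega is None
        names = ["t", "kappa"] + (["omega"] if free_omega else [])
        lb = np.log([self.BOUNDS[n][0] for n in names])
        ub = np.log([self.BOUNDS[n][1] for n in names])

        def negll(logx):
            x = np.exp(logx)
            t, kappa = x[0], x[1]
            omega = x[2] if free_omega else fixed_omega
            return -self.loglike(t, kappa, omega)

        best = None
        for start in self.STARTS:
            x0 = np.log(np.clip(start[: len(names)], np.exp(lb), np.exp(ub)))
            res = optimize.minimize(
                negll, x0, method="L-BFGS-B",
                bounds=list(zip(lb, ub)),
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        x = np.exp(best.x)
        t_hat, kappa_hat = float(x[0]), float(x[1])
        omega_hat = float(x[2]) if free_omega else float(fixed_omega)
        return CodonPairMLResults(
            self, t=t_hat, kappa=kappa_hat, omega=omega_hat, llf=-float(best.fun),
            converged=bool(best.success), fixed_omega=fixed_omega, identifiable=True,
        )


class CodonPairMLResults:
    """Estimates, uncertainties and diagnostics from a CodonPairML fit."""

    def __init__(self, model, t, kappa, omega, llf, converged, fixed_omega, identifiable):
        self.model = model
        self.t = t
        self.kappa = kappa
        self.omega = omega
        self.llf = llf
        self.converged = converged
        self.fixed_omega = fixed_omega
        self.identifiable = identifiable
        self._bse = None

    @property
    def params(self) -> dict:
        return {"t": self.t, "kappa": self.kappa, "omega": self.omega}

    @property
    def free_param_names(self):
        names = ["t", "kappa"]
        if self.fixed_omega is None:
            names.append("omega")
        return names

    @property
    def bse(self) -> dict:
        """Approximate standard errors from the numeric observed information."""
        if self._bse is None:
            self._bse = self._compute_bse()
        return self._bse

    def _compute_bse(self):
        names = self.free_param_names
        if not self.identifiable:
            return {n: math.nan for n in names}
        theta = np.array([self.params[n] for n in names])

        def ll(x):
            p = dict(zip(names, x))
            omega = p.get("omega", self.fixed_omega if self.fixed_omega is not None else self.omega)
            return self.model.loglike(p["t"], p["kappa"], omega)

        k = len(theta)
        h = np.maximum(1e-4 * np.abs(theta), 1e-6)
        H = np.zeros((k, k))
        f0 = ll(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (ll(theta + ei) - 2 * f0 + ll(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        ll(theta + ei + ej) - ll(theta + ei - ej)
                        - ll(theta - ei + ej) + ll(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, math.nan)
        return dict(zip(names, se))

    def summary(self) -> str:
        lines = ["Pairwise codon ML fit", "=" * 42]
        lines.append(f"{'n codons':<16}{self.model.alignment.n_codons:>12}")
        lines.append(f"{'log-likelihood':<16}{self.llf:>12.4f}")
        lines.append(f"{'converged':<16}{str(self.converged):>12}")
        if self.fixed_omega is not None:
            lines.append(f"{'omega fixed at':<16}{self.fixed_omega:>12.4f}")
        lines.append("-" * 42)
        lines.append(f"{'param':<8}{'estimate':>12}{'std err':>12}")
        bse = self.bse
        for name in self.free_param_names:
            lines.append(f"{name:<8}{self.params[name]:>12.4f}{bse[name]:>12.4f}")
        return "\n".join(lines)


def lrt_purifying(fit_fixed: CodonPairMLResults, fit_free: CodonPairMLResults):
    """Likelihood-ratio test of omega < its fixed null value.

    Returns (lrt_stat, p_value) with stat = max(0, 2*(lnL_free -
    lnL_fixed)) compared to chi-square with 1 df.  A negative raw
    statistic (numerical noise) is clipped and logged.
    """
    raw = 2.0 * (fit_free.llf - fit_fixed.llf)
    if raw < 0:
        logger.debug("negative LRT statistic %.3g clipped to 0", raw)
    stat = max(0.0, raw)
    return stat, float(chi2.sf(stat, df=1))


def _ng86_mean_syn_sites(pi: np.ndarray) -> float:
    return float(sum(p * _codon_syn_sites(c) for p, c in zip(pi, SENSE_CODONS)))


def time_for_target_ks(ks: float, kappa: float, omega: float, pi: np.ndarray) -> float:
    """Divergence time t (subs per codon) whose expected Ks is ``ks``.

    Uses the synonymous flux fraction of the scaled rate matrix and the
    NG86 synonymous sites per codon; exact to first order in t (the JC
    correction downstream absorbs multiple hits).
    """
    Q = build_rate_matrix(kappa, omega, pi)
    syn_flux = float((pi[_NB_I] * Q[_NB_I, _NB_J])[_NB_SYN].sum())
    s_sites = _ng86_mean_syn_sites(pi)
    return ks * s_sites / syn_flux
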