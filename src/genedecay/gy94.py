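"""GY94 codon substitution model and HKY nucleotide model.

State space: the 61 sense codons of the standard code, TCAG-ordered.  The
generator allows only single-nucleotide codon changes, with off-diagonal rate
pi_j * {1 | kappa | omega | omega*kappa} for {synonymous transversion |
synonymous transition | nonsynonymous transversion | nonsynonymous
transition}, scaled so the expected substitution rate at stationarity is 1
(branch lengths are then expected substitutions per codon).

Transition probability matrices are computed through the symmetric similarity
transform B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) that time-reversibility
affords, so a single eigendecomposition serves all branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from genedecay.code import GeneticCodeTable, STANDARD_CODE, is_transition
from genedecay.errors import GenedecayError, InsufficientDataError

NT_ORDER = "TCAG"
NT_INDEX = {b: i for i, b in enumerate(NT_ORDER)}


class CodonSpace:
    """Index maps and precomputed single-step structure over sense codons."""

    def __init__(self, code: GeneticCodeTable = STANDARD_CODE):
        self.code = code
        self.codons = list(code.sense_codons)
        self.n = len(self.codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        # single-nucleotide neighbor structure: (i, j, is_transition, is_syn)
        pairs = []
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [p for p in range(3) if ci[p] != cj[p]]
                if len(diffs) != 1:
                    continue
                p = diffs[0]
                pairs.append(
                    (i, j, is_transition(ci[p], cj[p]), code.is_synonymous(ci, cj))
                )
        self._pairs = pairs

    def encode(self, codon: str) -> int:
        """Index of a sense codon; -1 for anything else (gap, N, stop)."""
        return self.index.get(codon.upper(), -1)


_DEFAULT_SPACE: CodonSpace | None = None


def default_space() -> CodonSpace:
    global _DEFAULT_SPACE
    if _DEFAULT_SPACE is None:
        _DEFAULT_SPACE = CodonSpace()
    return _DEFAULT_SPACE


# ---------------------------------------------------------------------------
# Sanitization and codon frequencies


def sanitize_for_model(aln, space: CodonSpace | None = None, min_codons: int = 10):
    """Reduce an alignment to an in-frame sense-codon index matrix.

    Reference-frame codon columns containing a gap, an N, or a stop codon in
    any retained sequence are removed entirely (the usual pre-fit cleanup:
    premature stops must be stripped before omega estimation).  Returns
    ``(matrix, taxa, removal_log)`` where matrix is (n_taxa, n_sites) int
    codon indices and removal_log lists (ref_codon_index_1based, reason).
    """
    space = space or default_space()
    codon_cols = aln.reference_codon_columns()
    taxa = aln.species_ids
    kept_cols = []
    removal_log = []
    for k, cols in enumerate(codon_cols):
        reason = None
        for sp in taxa:
            codon = aln.codon_at(sp, cols)
            if "-" in codon:
                reason = "gap"
            elif "N" in codon:
                reason = "ambiguous"
            elif space.code.is_stop(codon):
                reason = "stop"
            if reason:
                break
        if reason:
            removal_log.append((k + 1, reason))
        else:
            kept_cols.append(cols)
    if len(kept_cols) < min_codons:
        raise InsufficientDataError(
            f"only {len(kept_cols)} codon columns survive sanitization "
            f"(need >= {min_codons})"
        )
    matrix = np.empty((len(taxa), len(kept_cols)), dtype=np.int64)
    for r, sp in enumerate(taxa):
        for c, cols in enumerate(kept_cols):
            matrix[r, c] = space.encode(aln.codon_at(sp, cols))
    return matrix, taxa, removal_log


def f3x4_frequencies(matrix: np.ndarray, space: CodonSpace | None = None) -> np.ndarray:
    """F3x4 codon frequencies from a sanitized codon-index matrix.

    Codon frequency is proportional to the product of position-specific
    nucleotide frequencies, renormalized over sense codons.  A pseudocount of
    0.5 per nucleotide per position keeps every frequency strictly positive.
    """
    space = space or default_space()
    counts = np.full((3, 4), 0.5)
    flat = matrix[matrix >= 0]
    for idx in flat:
        codon = space.codons[idx]
        for p in range(3):
            counts[p, NT_INDEX[codon[p]]] += 1
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, NT_INDEX[c[0]]]
            * pos_freqs[1, NT_INDEX[c[1]]]
            * pos_freqs[2, NT_INDEX[c[2]]]
            for c in space.codons
        ]
    )
    return freqs / freqs.sum()


def f1x4_frequencies(matrix: np.ndarray, space: CodonSpace | None = None) -> np.ndarray:
    """F1x4 codon frequencies (one shared nucleotide composition)."""
    space = space or default_space()
    counts = np.full(4, 0.5)
    for idx in matrix[matrix >= 0]:
        for b in space.codons[idx]:
            counts[NT_INDEX[b]] += 1
    nf = counts / counts.sum()
    freqs = np.array(
        [nf[NT_INDEX[c[0]]] * nf[NT_INDEX[c[1]]] * nf[NT_INDEX[c[2]]] for c in space.codons]
    )
    return freqs / freqs.sum()


def uniform_frequencies(space: CodonSpace | None = None) -> np.ndarray:
    space = space or default_space()
    return np.full(space.n, 1.0 / space.n)


# ---------------------------------------------------------------------------
# Rate matrices


def gy94_rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray, space: CodonSpace | None = None
) -> np.ndarray:
    """Scaled GY94 generator (rows sum to 0, mean rate 1 at stationarity)."""
    if kappa <= 0 or omega <= 0:
        raise GenedecayError("kappa and omega must be positive")
    space = space or default_space()
    n = space.n
    if len(freqs) != n:
        raise GenedecayError(f"need {n} codon frequencies")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise GenedecayError("codon frequencies must sum to 1")
    Q = np.zeros((n, n))
    for i, j, ts, syn in space._pairs:
        rate = freqs[j]
        if ts:
            rate *= kappa
        if not syn:
            rate *= omega
        Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    scale = -float(freqs @ np.diag(Q))
    return Q / scale


@dataclass
class SpectralQ:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    U: np.ndarray          # orthonormal eigenvectors of the symmetrized Q
    lam: np.ndarray        # eigenvalues
    sqrt_pi: np.ndarray
    inv_sqrt_pi: np.ndarray

    @classmethod
    def from_q(cls, Q: np.ndarray, freqs: np.ndarray) -> "SpectralQ":
        sqrt_pi = np.sqrt(freqs)
        B = (sqrt_pi[:, None] * Q) * (1.0 / sqrt_pi)[None, :]
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        lam, U = np.linalg.eigh(B)
        return cls(U=U, lam=lam, sqrt_pi=sqrt_pi, inv_sqrt_pi=1.0 / sqrt_pi)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); entries clipped at 0 (|negative| < 1e-12 only)."""
        if t < 0:
            raise GenedecayError("branch length must be >= 0")
        inner = (self.U * np.exp(self.lam * t)) @ self.U.T
        P = self.inv_sqrt_pi[:, None] * inner * self.sqrt_pi[None, :]
        neg = P.min()
        if neg < -1e-10:
            raise GenedecayError(f"transition matrix entry {neg} below tolerance")
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# HKY nucleotide model (for post-loss neutral simulation and ancestral
# reconstruction)


def hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """Scaled HKY generator over T,C,A,G (mean rate 1 at stationarity)."""
    if kappa <= 0:
        raise GenedecayError("kappa must be positive")
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != 4 or abs(freqs.sum() - 1.0) > 1e-9:
        raise GenedecayError("need 4 nucleotide frequencies summing to 1")
    Q = np.zeros((4, 4))
    for i, a in enumerate(NT_ORDER):
        for j, b in enumerate(NT_ORDER):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if is_transition(a, b) else 1.0)
    Q[np.diag_indices(4)] = 0.0
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    scale = -float(freqs @ np.diag(Q))
    return Q / scale
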