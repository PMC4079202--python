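"""Marginal ancestral sequence reconstruction under a nucleotide HKY model.

Reconstruction is nucleotide-level (the classical empirical-Bayes approach of
nucleotide ML programs): per site, the posterior over the 4 bases at an
internal node is proportional to the product of the downstream conditional
likelihood, the upstream partial, and the stationary prior.  The
maximum-posterior sequence can then be appended to a codon dataset as an
observed tip (after a reading-frame sanity check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from genedecay.core import CodonAlignment, SpeciesTree
from genedecay.errors import AlignmentError, GenedecayError
from genedecay.gy94 import NT_ORDER, NT_INDEX, SpectralQ, hky_rate_matrix


def nucleotide_matrix(records: list[tuple[str, str]]) -> tuple[np.ndarray, list[str]]:
    """Encode sequences as int states over T,C,A,G; gap/N -> -1 (missing)."""
    taxa = [sid for sid, _ in records]
    L = len(records[0][1])
    mat = np.full((len(records), L), -1, dtype=np.int64)
    for r, (_, seq) in enumerate(records):
        for c, b in enumerate(seq.upper()):
            mat[r, c] = NT_INDEX.get(b, -1)
    return mat, taxa


def empirical_base_freqs(mat: np.ndarray) -> np.ndarray:
    counts = np.array([(mat == i).sum() for i in range(4)], dtype=float) + 0.5
    return counts / counts.sum()


@dataclass
class AncestralSequence:
    node: str
    posteriors: np.ndarray          # (n_sites, 4), rows sum to 1
    map_sequence: str
    mean_posterior: float
    ties: list[int] = field(default_factory=list)  # 0-based tied sites


class _NucEngine:
    """Up/down partials for HKY on a fixed tree and nucleotide matrix."""

    def __init__(self, mat, taxa, tree: SpeciesTree, kappa: float, freqs: np.ndarray):
        self.tree = tree
        self.freqs = freqs
        Q = hky_rate_matrix(kappa, freqs)
        self.spec = SpectralQ.from_q(Q, freqs)
        self.nodes = list(tree.tree.postorder_node_iter())
        self.pos = {id(n): k for k, n in enumerate(self.nodes)}
        row = {t: r for r, t in enumerate(taxa)}
        self.n_sites = mat.shape[1]
        self.P = {}
        for n in self.nodes[:-1]:
            t = n.edge.length if n.edge.length is not None else 0.1
            self.P[self.pos[id(n)]] = self.spec.transition_matrix(float(t))
        # downpass (conditional likelihood of data below node, given state)
        self.down = [None] * len(self.nodes)
        for k, n in enumerate(self.nodes):
            if n.is_leaf():
                states = mat[row[n.taxon.label]] if n.taxon.label in row else None
                part = np.ones((4, self.n_sites))
                if states is not None:
                    obs = states >= 0
                    part[:, obs] = 0.0
                    part[states[obs], np.nonzero(obs)[0]] = 1.0
                self.down[k] = part
            else:
                part = np.ones((4, self.n_sites))
                for c in n.child_nodes():
                    ck = self.pos[id(c)]
                    part *= self.P[ck] @ self.down[ck]
                self.down[k] = part
        # uppass (partial for the rest of the tree; root's carries the prior)
        self.up = [None] * len(self.nodes)
        root_k = len(self.nodes) - 1
        self.up[root_k] = np.tile(self.freqs[:, None], (1, self.n_sites))
        for n in reversed(self.nodes):
            k = self.pos[id(n)]
            for c in n.child_nodes():
                ck = self.pos[id(c)]
                other = self.up[k].copy()
                for s in n.child_nodes():
                    if s is c:
                        continue
                    sk = self.pos[id(s)]
                    other *= self.P[sk] @ self.down[sk]
                self.up[ck] = self.P[ck].T @ other

    def log_likelihood(self) -> float:
        root = self.down[-1]
        site_l = self.freqs @ root
        return float(np.sum(np.log(site_l)))

    def posterior(self, node_label: str) -> np.ndarray:
        node = self.tree.node_by_label(node_label)
        k = self.pos[id(node)]
        post = self.down[k] * self.up[k]
        total = post.sum(axis=0, keepdims=True)
        if np.any(total <= 0):
            raise GenedecayError("zero posterior mass at some site")
        return (post / total).T  # (n_sites, 4)


def fit_hky_kappa(
    records: list[tuple[str, str]], tree: SpeciesTree,
    bounds: tuple[float, float] = (0.1, 50.0),
) -> tuple[float, float]:
    """ML estimate of HKY kappa with empirical base frequencies and the
    tree's branch lengths held fixed.  Returns (kappa, lnL)."""
    mat, taxa = nucleotide_matrix(records)
    freqs = empirical_base_freqs(mat)

    def neg(logk):
        try:
            return -_NucEngine(mat, taxa, tree, float(np.exp(logk)), freqs).log_likelihood()
        except GenedecayError:
            return 1e12

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    kappa = float(np.exp(res.x))
    return kappa, -float(res.fun)


def reconstruct_ancestor(
    records: list[tuple[str, str]],
    tree: SpeciesTree,
    node: str,
    kappa: float | None = None,
    freqs: np.ndarray | None = None,
) -> AncestralSequence:
    """Marginal posterior reconstruction at an internal node.

    ``records`` is a nucleotide alignment (same length rows); ``kappa`` is
    fitted by ML if not given.  Per site the maximum-posterior base is
    reported; ties are broken alphabetically and flagged.
    """
    target = tree.node_by_label(node)  # raises KeyError if absent
    if target.is_leaf():
        raise GenedecayError(f"node {node!r} is a tip, not an internal node")
    if kappa is None:
        kappa, _ = fit_hky_kappa(records, tree)
    mat, taxa = nucleotide_matrix(records)
    if freqs is None:
        freqs = empirical_base_freqs(mat)
    engine = _NucEngine(mat, taxa, tree, kappa, freqs)
    post = engine.posterior(node)
    seq_chars = []
    ties = []
    for i in range(post.shape[0]):
        row = post[i]
        top = float(row.max())
        near = [s for s in range(4) if top - row[s] < 1e-9]
        if len(near) > 1:
            ties.append(i)
        best = min(near, key=lambda s: NT_ORDER[s])  # alphabetical tie-break
        seq_chars.append(NT_ORDER[best])
    return AncestralSequence(
        node=node,
        posteriors=post,
        map_sequence="".join(seq_chars),
        mean_posterior=float(post.max(axis=1).mean()),
        ties=ties,
    )


def ancestor_as_tip(
    aln: CodonAlignment, ancestral: AncestralSequence, name: str | None = None
) -> CodonAlignment:
    """Append a reconstructed sequence to a codon alignment as an observed tip.

    The ancestral sequence must match the alignment's column count; the tip is
    named after the ancestral node unless overridden.
    """
    if len(ancestral.map_sequence) != aln.column_count:
        raise AlignmentError(
            f"ancestral sequence length {len(ancestral.map_sequence)} != "
            f"alignment columns {aln.column_count}"
        )
    tip_name = name or ancestral.node
    return CodonAlignment(
        records=aln.records + [(tip_name, ancestral.map_sequence)],
        reference_id=aln.reference_id,
    )
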