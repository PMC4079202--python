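"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and avoids the package's own model
machinery: translation goes through Biopython, matrix exponentials through
scipy.linalg.expm, and likelihoods through explicit enumeration of internal
states.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm

NTS = "ACGT"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def naive_site_counts(codon: str, R: float) -> tuple[float, float]:
    """Transition/transversion-weighted site counts by direct enumeration."""
    syn = 0.0
    aa = translate(codon)
    for pos in range(3):
        wt = ws = 0.0
        for alt in NTS:
            if alt == codon[pos]:
                continue
            w = R if is_transition(codon[pos], alt) else 1.0
            wt += w
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if translate(mut) == aa and translate(mut) != "*":
                ws += w
        syn += ws / wt
    return syn, 3.0 - syn


def naive_pathway_counts(ca: str, cb: str):
    """Average step classifications over all k! orderings, skipping paths
    through stops; None if all paths are blocked."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    tot_s = tot_n = 0.0
    n_ok = 0
    for order in itertools.permutations(pos):
        cur, s, n, ok = ca, 0, 0, True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if translate(cur) == translate(nxt):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            tot_s += s
            tot_n += n
            n_ok += 1
    if n_ok == 0:
        return None
    return tot_s / n_ok, tot_n / n_ok


# ---------------------------------------------------------------------------
# Naive GY94 / HKY machinery


def sense_codons() -> list[str]:
    return [
        "".join(c)
        for c in itertools.product("TCAG", repeat=3)
        if not is_stop("".join(c))
    ]


def naive_gy94_q(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    codons = sense_codons()
    n = len(codons)
    Q = np.zeros((n, n))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            rate = freqs[j]
            if is_transition(ci[p], cj[p]):
                rate *= kappa
            if translate(ci) != translate(cj):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / (-(freqs * np.diag(Q)).sum())


def naive_hky_q(kappa: float, freqs: np.ndarray, order: str = "TCAG") -> np.ndarray:
    Q = np.zeros((4, 4))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i != j:
                Q[i, j] = freqs[j] * (kappa if is_transition(a, b) else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / (-(freqs * np.diag(Q)).sum())


def exhaustive_loglik(tree, states_by_tip_per_site, Q, freqs) -> float:
    """Log-likelihood by summing over all internal-state assignments.

    ``tree`` is a dendropy tree with branch lengths; ``states_by_tip_per_site``
    is a list (over sites) of dicts tip-name -> state index (or -1 missing).
    Transition matrices via scipy expm.
    """
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    P = {id(n): expm(Q * n.edge.length) for n in nodes if n.parent_node is not None}
    n_states = Q.shape[0]
    total = 0.0
    for site in states_by_tip_per_site:
        site_l = 0.0
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            p = freqs[amap[id(nodes[-1])]]
            for n in nodes:
                if n.parent_node is None:
                    continue
                s_par = amap[id(n.parent_node)]
                if n.is_leaf():
                    s = site[n.taxon.label]
                    if s < 0:
                        continue  # missing tip: marginalized, P rows sum to 1
                else:
                    s = amap[id(n)]
                p *= P[id(n)][s_par, s]
            site_l += p
        total += np.log(site_l)
    return float(total)


def exhaustive_marginal_posterior(tree, states_by_tip, Q, freqs, node_label):
    """Posterior over states at one internal node for a single site, by
    enumerating all internal-state assignments."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    P = {id(n): expm(Q * n.edge.length) for n in nodes if n.parent_node is not None}
    n_states = Q.shape[0]
    target = next(n for n in internals if (n.label or "") == node_label)
    mass = np.zeros(n_states)
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        p = freqs[amap[id(nodes[-1])]]
        for n in nodes:
            if n.parent_node is None:
                continue
            s = states_by_tip[n.taxon.label] if n.is_leaf() else amap[id(n)]
            if n.is_leaf() and s < 0:
                continue
            p *= P[id(n)][amap[id(n.parent_node)], s]
        mass[amap[id(target)]] += p
    return mass / mass.sum()


def naive_mrca(tree, tip_names):
    """MRCA by path-to-root intersection (independent of dendropy.mrca)."""
    paths = []
    for name in tip_names:
        node = next(
            l for l in tree.leaf_node_iter() if l.taxon.label == name
        )
        path = []
        while node is not None:
            path.append(id(node))
            node = node.parent_node
        paths.append(path)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest common node = first common id along any tip's path
    for nid in paths[0]:
        if nid in common:
            for n in tree.preorder_node_iter():
                if id(n) == nid:
                    return n
    raise AssertionError("no common ancestor found")


def naive_disruption_scan(ref_row: str, sp_row: str):
    """Per-column diff scanner for one species against the reference.

    Returns a set of (kind, ref_start_1based, length) tuples, mirroring the
    event definitions but computed with a flat, per-column state machine.
    """
    events = set()
    # reference coordinate per column
    coord = []
    pos = 0
    for b in ref_row:
        if b != "-":
            pos += 1
        coord.append(pos)
    # deletions over reference-base columns
    runs = []
    cur = []
    for c, rb in enumerate(ref_row):
        if rb == "-":
            continue
        if sp_row[c] == "-":
            cur.append(c)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    for run in runs:
        kind = "frameshift_deletion" if len(run) % 3 else "inframe_deletion"
        events.add((kind, coord[run[0]], len(run)))
    # insertions over reference-gap columns
    cur = []
    for c, rb in enumerate(ref_row):
        if rb != "-":
            if cur:
                n = sum(1 for x in cur if sp_row[x] != "-")
                if n:
                    kind = "frameshift_insertion" if n % 3 else "inframe_insertion"
                    events.add((kind, coord[cur[0]], n))
                cur = []
            continue
        cur.append(c)
    if cur:
        n = sum(1 for x in cur if sp_row[x] != "-")
        if n:
            kind = "frameshift_insertion" if n % 3 else "inframe_insertion"
            events.add((kind, coord[cur[0]], n))
    # premature stops on reference codons
    ref_cols = [c for c, b in enumerate(ref_row) if b != "-"]
    codons = [ref_cols[i : i + 3] for i in range(0, len(ref_cols), 3)]
    if codons and is_stop("".join(ref_row[c] for c in codons[-1])):
        codons = codons[:-1]
    for cols in codons:
        codon = "".join(sp_row[c] for c in cols)
        if "-" in codon or "N" in codon:
            continue
        if is_stop(codon):
            events.add(("premature_stop", coord[cols[0]], 3))
    return {e for e in events if not e[0].startswith("inframe")}
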