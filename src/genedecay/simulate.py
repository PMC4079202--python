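"""Codon-alignment simulation along a phylogeny with gene-death events.

Functional lineages evolve by a continuous-time jump process under a
per-branch GY94 generator (the state space excludes stop codons, so
functional sequences never contain one).  At a *loss event* — a point on a
branch — the lineage and all its descendants switch to a neutral nucleotide
HKY process with the same kappa (stops permitted) plus a Poisson
insertion/deletion process with frame-shift-biased lengths.

The emitted alignment is exact: every sequence position carries a persistent
site identity, and the alignment is assembled from the master coordinate map
rather than re-aligned, so the truth log's disruption coordinates are exact
by construction.  Branch lengths are expected substitutions per codon for
functional lineages; the post-loss nucleotide process runs at 1/3 of that
per-site rate, the neutral-limit continuation of the codon clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from genedecay.core import (
    CodonAlignment,
    SpeciesManifest,
    SpeciesTree,
    label_whale_branches,
    write_alignment,
)
from genedecay.errors import GenedecayError
from genedecay.gy94 import (
    NT_ORDER,
    CodonSpace,
    default_space,
    gy94_rate_matrix,
    hky_rate_matrix,
    uniform_frequencies,
)

#: default indel length distribution: mostly frame-shifting (1,2,4,5), with a
#: small in-frame mass (3,6)
DEFAULT_INDEL_LENGTHS = {1: 0.35, 2: 0.25, 3: 0.10, 4: 0.15, 5: 0.10, 6: 0.05}


@dataclass
class SimulationConfig:
    """Everything needed to simulate one gene's alignment."""

    tree: SpeciesTree
    n_codons: int
    kappa: float = 2.0
    #: omega per branch class ("background" is the catch-all); a scalar means
    #: one omega everywhere
    omega_by_branch: dict[str, float] | float = 0.2
    codon_freqs: np.ndarray | None = None
    #: (branch id, fractional position along the branch in [0, 1])
    loss_events: list[tuple[str, float]] = field(default_factory=list)
    #: post-loss indel events per nucleotide site per unit (codon) branch length
    indel_rate: float = 0.02
    indel_length_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_LENGTHS)
    )
    seed: int = 0
    reference_id: str | None = None

    def omega_for(self, branch_class: str) -> float:
        if isinstance(self.omega_by_branch, (int, float)):
            return float(self.omega_by_branch)
        return self.omega_by_branch.get(
            branch_class, self.omega_by_branch.get("background", 0.2)
        )


@dataclass
class TruthDisruption:
    kind: str           # frameshift_deletion | frameshift_insertion |
                        # inframe_deletion | inframe_insertion | premature_stop
    ref_start: int      # 1-based reference nucleotide position
    length: int


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated alignment."""

    root_sequence: str
    seed: int
    loss_events: list[tuple[str, float]]
    substitution_counts: dict[str, int]           # branch id -> realized subs
    disruptions_by_species: dict[str, list[TruthDisruption]]
    internal_sequences: dict[str, str]            # node label -> ungapped seq
    indel_events: list[dict]                      # as applied, with branch ids

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)


class _JumpProcess:
    """Vectorized Gillespie sampler for one generator."""

    def __init__(self, Q: np.ndarray):
        self.rates = -np.diag(Q).copy()
        J = Q.copy()
        np.fill_diagonal(J, 0.0)
        J /= self.rates[:, None]
        self.jump_cum = np.cumsum(J, axis=1)

    def evolve(self, states: np.ndarray, t: float, rng) -> int:
        """Evolve states in place for duration t; returns substitution count."""
        n_subs = 0
        t_rem = np.full(states.size, t)
        active = np.arange(states.size)
        while active.size:
            r = self.rates[states[active]]
            wait = rng.exponential(1.0, size=active.size) / r
            left = t_rem[active] - wait
            jumped = left > 0
            idx = active[jumped]
            if idx.size == 0:
                break
            t_rem[idx] = left[jumped]
            u = rng.random(idx.size)
            states[idx] = (u[:, None] < self.jump_cum[states[idx]]).argmax(axis=1)
            n_subs += idx.size
            active = idx
        return n_subs


class _Lineage:
    """A sequence with persistent per-position site identities."""

    __slots__ = ("sites", "bases", "lost")

    def __init__(self, sites: list[int], bases: list[str], lost: bool):
        self.sites = sites
        self.bases = bases
        self.lost = lost

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.sites), list(self.bases), self.lost)


def simulate(
    config: SimulationConfig, space: CodonSpace | None = None
) -> tuple[CodonAlignment, SimulationTruth]:
    """Run one simulation; fully reproducible from ``config.seed``."""
    space = space or default_space()
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    freqs = (
        config.codon_freqs
        if config.codon_freqs is not None
        else uniform_frequencies(space)
    )
    nt_freqs = _nt_freqs_from_codon(freqs, space)

    known_branches = set(tree.branch_classes())
    loss_by_branch: dict[str, float] = {}
    for bid, frac in config.loss_events:
        if bid not in known_branches:
            raise KeyError(f"loss event on unknown branch {bid!r}")
        if not 0.0 <= frac <= 1.0:
            raise GenedecayError(f"loss fraction {frac} outside [0, 1]")
        loss_by_branch[bid] = min(frac, loss_by_branch.get(bid, 1.0))

    codon_procs: dict[float, _JumpProcess] = {}
    nt_proc = _JumpProcess(hky_rate_matrix(config.kappa, nt_freqs))

    # root sequence from codon frequencies
    L = config.n_codons
    root_codons = rng.choice(space.n, size=L, p=freqs)
    root_bases = [b for ci in root_codons for b in space.codons[ci]]
    root_sites = list(range(3 * L))
    global_order: list[int] = list(root_sites)
    next_site = 3 * L

    truth_subs: dict[str, int] = {}
    indel_log: list[dict] = []
    internal_seqs: dict[str, str] = {}
    tip_lineages: dict[str, _Lineage] = {}

    def indel_lengths():
        ls = sorted(config.indel_length_probs)
        ps = np.array([config.indel_length_probs[l] for l in ls], dtype=float)
        return ls, ps / ps.sum()

    ind_ls, ind_ps = indel_lengths()

    def codon_proc(omega: float) -> _JumpProcess:
        if omega not in codon_procs:
            codon_procs[omega] = _JumpProcess(
                gy94_rate_matrix(config.kappa, omega, freqs, space)
            )
        return codon_procs[omega]

    def evolve_functional(lin: _Lineage, omega: float, t: float) -> int:
        states = np.array(
            [space.index["".join(lin.bases[i : i + 3])] for i in range(0, len(lin.bases), 3)]
        )
        n = codon_proc(omega).evolve(states, t, rng)
        lin.bases = [b for ci in states for b in space.codons[ci]]
        return n

    def evolve_lost(lin: _Lineage, t: float, branch_id: str) -> int:
        nonlocal next_site
        # neutral nucleotide substitutions at 1/3 the codon clock
        nt_index = {b: i for i, b in enumerate(NT_ORDER)}
        states = np.array([nt_index[b] for b in lin.bases])
        n = nt_proc.evolve(states, t / 3.0, rng) if len(states) else 0
        lin.bases = [NT_ORDER[s] for s in states]
        # Poisson indel process
        n_indels = rng.poisson(config.indel_rate * len(lin.bases) * t)
        for _ in range(n_indels):
            length = int(rng.choice(ind_ls, p=ind_ps))
            if rng.random() < 0.5 and len(lin.bases) > length:  # deletion
                pos = int(rng.integers(0, len(lin.bases) - length + 1))
                removed = lin.sites[pos : pos + length]
                del lin.sites[pos : pos + length]
                del lin.bases[pos : pos + length]
                indel_log.append({
                    "branch": branch_id, "kind": "deletion", "length": length,
                    "sites": [int(s) for s in removed],
                })
            else:  # insertion
                pos = int(rng.integers(0, len(lin.bases) + 1))
                new_ids = list(range(next_site, next_site + length))
                next_site += length
                new_bases = [
                    NT_ORDER[i] for i in rng.choice(4, size=length, p=nt_freqs)
                ]
                if pos > 0:
                    anchor = global_order.index(lin.sites[pos - 1]) + 1
                else:
                    anchor = global_order.index(lin.sites[0]) if lin.sites else 0
                global_order[anchor:anchor] = new_ids
                lin.sites[pos:pos] = new_ids
                lin.bases[pos:pos] = new_bases
                indel_log.append({
                    "branch": branch_id, "kind": "insertion", "length": length,
                    "sites": new_ids,
                })
        return n

    def recurse(node, lin: _Lineage):
        label = SpeciesTree.branch_id(node)
        if node.is_leaf():
            tip_lineages[label] = lin
        else:
            internal_seqs[label] = "".join(lin.bases)
            for child in node.child_nodes():
                child_lin = lin.copy()
                bid = SpeciesTree.branch_id(child)
                t = child.edge.length if child.edge.length is not None else 0.0
                omega = config.omega_for(getattr(child.edge, "branch_class", "background"))
                subs = 0
                if child_lin.lost:
                    subs += evolve_lost(child_lin, t, bid)
                elif bid in loss_by_branch:
                    frac = loss_by_branch[bid]
                    if frac > 0:
                        subs += evolve_functional(child_lin, omega, t * frac)
                    child_lin.lost = True
                    subs += evolve_lost(child_lin, t * (1.0 - frac), bid)
                else:
                    subs += evolve_functional(child_lin, omega, t)
                truth_subs[bid] = subs
                recurse(child, child_lin)

    root = tree.tree.seed_node
    recurse(root, _Lineage(root_sites, root_bases, False))

    # assemble the alignment over columns that survive in at least one tip
    tip_maps = {
        sp: dict(zip(lin.sites, lin.bases)) for sp, lin in tip_lineages.items()
    }
    live = set()
    for m in tip_maps.values():
        live.update(m)
    columns = [sid for sid in global_order if sid in live]
    records = [
        (sp, "".join(tip_maps[sp].get(sid, "-") for sid in columns))
        for sp in tree.tip_names
    ]
    reference_id = config.reference_id or _pick_reference(tree, tip_lineages)
    aln = CodonAlignment(records=records, reference_id=reference_id)

    truth = SimulationTruth(
        root_sequence="".join(root_bases),
        seed=config.seed,
        loss_events=sorted(loss_by_branch.items()),
        substitution_counts=truth_subs,
        disruptions_by_species={
            sp: _truth_disruptions(tip_lineages[sp], root_sites, space)
            for sp in tip_lineages
            if sp != reference_id
        },
        internal_sequences=internal_seqs,
        indel_events=indel_log,
    )
    return aln, truth


def _nt_freqs_from_codon(freqs: np.ndarray, space: CodonSpace) -> np.ndarray:
    counts = np.zeros(4)
    for f, codon in zip(freqs, space.codons):
        for b in codon:
            counts[NT_ORDER.index(b)] += f
    return counts / counts.sum()


def _pick_reference(tree: SpeciesTree, tips: dict[str, _Lineage]) -> str:
    for name in tree.tip_names:
        if not tips[name].lost:
            return name
    raise GenedecayError("no functional lineage available as reference")


def _truth_disruptions(
    lin: _Lineage, root_sites: list[int], space: CodonSpace
) -> list[TruthDisruption]:
    """Final-state disruptions of one tip, from the master coordinate map.

    Independent of the alignment-column scanner: works directly on the
    simulator's site-identity bookkeeping.  Reference coordinates are root
    coordinates, valid because the reference lineage keeps every root site.
    """
    out: list[TruthDisruption] = []
    root_set = set(root_sites)
    have = set(lin.sites)
    # deletions: maximal runs of root sites missing from this lineage
    run_start = None
    prev_missing = False
    for k, sid in enumerate(root_sites + [None]):
        missing = sid is not None and sid not in have
        if missing and not prev_missing:
            run_start = k
        if not missing and prev_missing:
            length = k - run_start
            kind = "frameshift_deletion" if length % 3 else "inframe_deletion"
            out.append(TruthDisruption(kind=kind, ref_start=run_start + 1, length=length))
        prev_missing = missing
    # insertions: runs of non-root sites in this lineage's own order
    pos_of_root = {sid: k for k, sid in enumerate(root_sites)}
    k = 0
    last_root_pos = 0
    n = len(lin.sites)
    while k < n:
        sid = lin.sites[k]
        if sid in root_set:
            last_root_pos = pos_of_root[sid] + 1  # 1-based ref position
            k += 1
            continue
        j = k
        while j < n and lin.sites[j] not in root_set:
            j += 1
        length = j - k
        kind = "frameshift_insertion" if length % 3 else "inframe_insertion"
        out.append(TruthDisruption(kind=kind, ref_start=last_root_pos, length=length))
        k = j
    # premature stops in the reference (root) reading frame
    base_of = dict(zip(lin.sites, lin.bases))
    for c in range(0, len(root_sites), 3):
        triple = root_sites[c : c + 3]
        if all(s in base_of for s in triple):
            codon = "".join(base_of[s] for s in triple)
            if space.code.is_stop(codon):
                out.append(
                    TruthDisruption(kind="premature_stop", ref_start=c + 1, length=3)
                )
    out.sort(key=lambda d: (d.ref_start, d.kind))
    return out


# ---------------------------------------------------------------------------
# Canned fixtures

#: 12-taxon whale-like topology: one outgroup, six toothed whales, five
#: baleen whales, with an explicit stem branch
WHALE_NEWICK = (
    "(Cow:0.35,((Pcat:0.12,(Npho:0.09,((Lalb:0.03,Lacu:0.03):0.03,"
    "(Gmel:0.04,Ttru:0.04):0.02):0.03):0.03):0.06,"
    "(Bmys:0.09,(Bacu:0.07,(Bphy:0.05,(Bede:0.03,Bomu:0.03):0.02):0.02):0.02):0.07)"
    ":0.25);"
)

WHALE_CLADES = {
    "Cow": "outgroup",
    "Pcat": "toothed", "Npho": "toothed", "Lalb": "toothed",
    "Lacu": "toothed", "Gmel": "toothed", "Ttru": "toothed",
    "Bmys": "baleen", "Bacu": "baleen", "Bphy": "baleen",
    "Bede": "baleen", "Bomu": "baleen",
}

FIXTURE_SEED = 20140506


def whale_tree_and_manifest(
    genes: list[str] | None = None,
) -> tuple[SpeciesTree, SpeciesManifest]:
    """The canned 12-taxon whale-shaped tree with clade-labeled branches."""
    manifest = SpeciesManifest(
        clades=dict(WHALE_CLADES),
        genes={g: {sp: "+" for sp in WHALE_CLADES} for g in (genes or [])},
    )
    tree = SpeciesTree.from_newick(WHALE_NEWICK)
    label_whale_branches(tree, manifest)
    return tree, manifest


def stem_branch_id(tree: SpeciesTree) -> str:
    """Id of the branch classed ``stem``."""
    for bid, cls in tree.branch_classes().items():
        if cls == "stem":
            return bid
    raise GenedecayError("tree has no stem-classed branch")


def fixture_configs(seed: int = FIXTURE_SEED) -> dict[str, SimulationConfig]:
    """The four canned cases: stem-loss, purifying, neutral, 3-taxon micro."""
    tree_a, _ = whale_tree_and_manifest()
    tree_b, _ = whale_tree_and_manifest()
    tree_c, _ = whale_tree_and_manifest()
    micro = SpeciesTree.from_newick("(A:0.10,(B:0.15,C:0.20):0.05);")
    return {
        "stem_loss": SimulationConfig(
            tree=tree_a, n_codons=300, kappa=2.0, omega_by_branch=0.06,
            loss_events=[(stem_branch_id(tree_a), 0.3)],
            indel_rate=0.02, seed=seed, reference_id="Cow",
        ),
        "purifying": SimulationConfig(
            tree=tree_b, n_codons=300, kappa=2.0, omega_by_branch=0.06,
            seed=seed + 1, reference_id="Cow",
        ),
        "neutral": SimulationConfig(
            tree=tree_c, n_codons=300, kappa=2.0, omega_by_branch=1.0,
            seed=seed + 2, reference_id="Cow",
        ),
        "micro": SimulationConfig(
            tree=micro, n_codons=3, kappa=2.0, omega_by_branch=0.5,
            seed=seed + 3, reference_id="A",
        ),
    }


def make_fixture_suite(out_dir: str | Path, seed: int = FIXTURE_SEED) -> dict[str, dict]:
    """Write the canned fixture files (alignment, tree, manifest, truth).

    Returns {name: {"alignment": path, "tree": path, "manifest": path,
    "truth": path}}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict] = {}
    for name, config in fixture_configs(seed).items():
        aln, truth = simulate(config)
        base = out_dir / name
        p = {
            "alignment": base.with_suffix(".fasta"),
            "tree": base.with_suffix(".nwk"),
            "manifest": base.with_suffix(".manifest.tsv"),
            "truth": base.with_suffix(".truth.json"),
        }
        write_alignment(aln, p["alignment"])
        config.tree.write(p["tree"])
        if name == "micro":
            manifest = SpeciesManifest(
                clades={"A": "outgroup", "B": "toothed", "C": "baleen"},
                genes={"G1": {"A": "+", "B": "+", "C": "+"}},
            )
        else:
            _, manifest = whale_tree_and_manifest(genes=["G1"])
            for sp, disrs in truth.disruptions_by_species.items():
                if any(d.kind.startswith("frameshift") or d.kind == "premature_stop"
                       for d in disrs):
                    manifest.genes["G1"][sp] = "P"
        manifest.write(p["manifest"])
        p["truth"].write_text(truth.to_json() + "\n")
        paths[name] = {k: str(v) for k, v in p.items()}
    return paths
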