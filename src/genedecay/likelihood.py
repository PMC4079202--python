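"""Felsenstein-pruning likelihood and branch-class omega fitting under GY94.

Branch models assign one omega per *branch class group*; a class scheme maps
the tree's branch-class labels onto omega groups.  The ladder of schemes
mirrors the usual relaxed-selection test sequence for a focal clade with a
stem branch: one ratio everywhere; a second ratio on the stem; stem plus
crown sharing a ratio; stem and crown each free; and a toothed/baleen split
of the crown.  Nested fits are compared with chi-square likelihood-ratio
tests, one degree of freedom per freed omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from genedecay.core import SpeciesTree, BACKGROUND
from genedecay.errors import ConvergenceError, GenedecayError
from genedecay.gy94 import (
    CodonSpace,
    SpectralQ,
    default_space,
    f1x4_frequencies,
    f3x4_frequencies,
    gy94_rate_matrix,
    uniform_frequencies,
)

# ---------------------------------------------------------------------------
# Class schemes


@dataclass(frozen=True)
class ClassScheme:
    """Maps branch-class labels to omega groups (ordered; group 0 is the
    catch-all background)."""

    name: str
    groups: tuple[tuple[str, frozenset | None], ...]  # (group_name, labels or None)

    @property
    def n_omega(self) -> int:
        return len(self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)

    def group_index(self, branch_class: str) -> int:
        catch_all = 0
        for k, (_, labels) in enumerate(self.groups):
            if labels is None:
                catch_all = k
            elif branch_class in labels:
                return k
        return catch_all


_WHALE = frozenset({"stem", "toothed", "baleen"})

SCHEMES: dict[str, ClassScheme] = {
    "one_ratio": ClassScheme("one_ratio", ((BACKGROUND, None),)),
    "stem_two_ratio": ClassScheme(
        "stem_two_ratio", ((BACKGROUND, None), ("stem", frozenset({"stem"})))
    ),
    "crown_two_ratio": ClassScheme(
        "crown_two_ratio", ((BACKGROUND, None), ("whale", _WHALE))
    ),
    "stem_plus_crown_three_ratio": ClassScheme(
        "stem_plus_crown_three_ratio",
        (
            (BACKGROUND, None),
            ("crown", frozenset({"toothed", "baleen"})),
            ("stem", frozenset({"stem"})),
        ),
    ),
    "toothed_vs_baleen": ClassScheme(
        "toothed_vs_baleen",
        (
            (BACKGROUND, None),
            ("stem", frozenset({"stem"})),
            ("toothed", frozenset({"toothed"})),
            ("baleen", frozenset({"baleen"})),
        ),
    ),
}

#: Conventional null for each scheme in the LRT ladder.
NULL_OF = {
    "stem_two_ratio": "one_ratio",
    "crown_two_ratio": "one_ratio",
    "stem_plus_crown_three_ratio": "crown_two_ratio",
    "toothed_vs_baleen": "stem_plus_crown_three_ratio",
}


# ---------------------------------------------------------------------------
# Parameters and fits


@dataclass
class CodonModelParams:
    """GY94 branch-model parameters at (or on the way to) an optimum."""

    kappa: float
    omega_by_class: dict[str, float]          # omega-group name -> omega
    codon_freqs: np.ndarray
    branch_lengths: dict[str, float]          # branch id -> expected subs/codon

    def __post_init__(self):
        if self.kappa <= 0 or any(w <= 0 for w in self.omega_by_class.values()):
            raise GenedecayError("all rates must be positive")
        s = float(np.sum(self.codon_freqs))
        if abs(s - 1.0) > 1e-9:
            raise GenedecayError(f"codon frequencies sum to {s}, not 1")


@dataclass
class BranchModelFit:
    params: CodonModelParams
    lnL: float
    n_free_params: int
    scheme: str
    convergence: dict = field(default_factory=dict)


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


def lrt(null_fit: BranchModelFit, alt_fit: BranchModelFit) -> LRTResult:
    """Chi-square LRT of nested branch-model fits (stat clamped at 0)."""
    df = alt_fit.n_free_params - null_fit.n_free_params
    if df < 1:
        raise GenedecayError(
            f"alternative must have more free parameters than null (df={df})"
        )
    stat = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if stat < -1e-6:
        raise GenedecayError(
            f"alternative lnL below null by {-stat / 2:.3g}: fits are not nested "
            "or optimization failed"
        )
    stat = max(stat, 0.0)
    return LRTResult(stat=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def chi2_tail(stat: float, df: int) -> float:
    """Upper-tail chi-square probability used by the LRT."""
    return float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Pruning engine


def _compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (columns) and their multiplicities."""
    patterns, counts = np.unique(matrix, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class _TreeIndex:
    """Postorder arrays for one tree: children, branch lengths, classes."""

    def __init__(self, tree: SpeciesTree):
        nodes = list(tree.tree.postorder_node_iter())
        self.nodes = nodes
        self.node_pos = {id(n): k for k, n in enumerate(nodes)}
        self.children: list[list[int]] = []
        self.branch_ids: list[str | None] = []
        self.branch_lengths: list[float | None] = []
        self.branch_classes: list[str] = []
        self.leaf_taxon: list[str | None] = []
        for n in nodes:
            self.children.append([self.node_pos[id(c)] for c in n.child_nodes()])
            if n.parent_node is None:
                self.branch_ids.append(None)
                self.branch_lengths.append(None)
                self.branch_classes.append(BACKGROUND)
            else:
                self.branch_ids.append(SpeciesTree.branch_id(n))
                self.branch_lengths.append(n.edge.length)
                self.branch_classes.append(getattr(n.edge, "branch_class", BACKGROUND))
            self.leaf_taxon.append(n.taxon.label if n.is_leaf() else None)
        self.root = len(nodes) - 1
        self.n_branches = len(nodes) - 1


class PruningEngine:
    """Reusable likelihood evaluator for one (alignment, tree) pair.

    Site patterns, leaf states, and the tree traversal are prepared once;
    each call supplies kappa, per-group omegas, and branch lengths.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        taxa: list[str],
        tree: SpeciesTree,
        scheme: ClassScheme,
        freqs: np.ndarray | None = None,
        space: CodonSpace | None = None,
    ):
        self.space = space or default_space()
        self.scheme = scheme
        self.tidx = _TreeIndex(tree)
        self.patterns, self.weights = _compress_patterns(matrix)
        self.n_pat = self.patterns.shape[1]
        self.n_states = self.space.n
        taxon_row = {t: r for r, t in enumerate(taxa)}
        # leaf partial-index per node: codon state per pattern, -1 = missing
        self.leaf_states: dict[int, np.ndarray] = {}
        for k, taxon in enumerate(self.tidx.leaf_taxon):
            if taxon is None:
                continue
            if taxon in taxon_row:
                self.leaf_states[k] = self.patterns[taxon_row[taxon]]
            else:
                self.leaf_states[k] = np.full(self.n_pat, -1, dtype=np.int64)
        self.freqs = freqs if freqs is not None else f3x4_frequencies(matrix, self.space)
        self.omega_group = np.array(
            [scheme.group_index(c) for c in self.tidx.branch_classes]
        )
        self.site_log_weight_total = float(self.weights.sum())

    def default_branch_lengths(self) -> np.ndarray:
        out = np.array(
            [bl if bl is not None else 0.1 for bl in self.tidx.branch_lengths[:-1]]
            + [0.0]
        )
        return out

    def log_likelihood(
        self, kappa: float, omegas: np.ndarray, branch_lengths: np.ndarray
    ) -> float:
        """lnL by pruning; ``branch_lengths`` indexed like postorder nodes."""
        spectrals = [
            SpectralQ.from_q(gy94_rate_matrix(kappa, w, self.freqs, self.space), self.freqs)
            for w in omegas
        ]
        n, npat = self.n_states, self.n_pat
        partials: list[np.ndarray | None] = [None] * len(self.tidx.nodes)
        logscale = np.zeros(npat)
        for k, children in enumerate(self.tidx.children):
            if not children:  # leaf
                states = self.leaf_states[k]
                part = np.zeros((n, npat))
                missing = states < 0
                part[:, missing] = 1.0
                obs = ~missing
                part[states[obs], np.nonzero(obs)[0]] = 1.0
                partials[k] = part
                continue
            part = np.ones((n, npat))
            for c in children:
                P = spectrals[self.omega_group[c]].transition_matrix(
                    float(branch_lengths[c])
                )
                part *= P @ partials[c]
                partials[c] = None  # free memory
            scale = part.max(axis=0)
            if np.any(scale <= 0):
                raise GenedecayError("zero site likelihood (site partial vanished)")
            part /= scale
            logscale += np.log(scale)
            partials[k] = part
        site_l = self.freqs @ partials[self.tidx.root]
        if np.any(site_l <= 0) or not np.all(np.isfinite(site_l)):
            bad = int(np.argmin(site_l))
            raise GenedecayError(f"non-finite likelihood at site pattern {bad}")
        return float(self.weights @ (np.log(site_l) + logscale))


def log_likelihood(
    matrix: np.ndarray,
    taxa: list[str],
    tree: SpeciesTree,
    params: CodonModelParams,
    scheme: ClassScheme | str = "one_ratio",
    space: CodonSpace | None = None,
) -> float:
    """Pruning log-likelihood for explicit parameters (one-shot API)."""
    scheme = SCHEMES[scheme] if isinstance(scheme, str) else scheme
    engine = PruningEngine(matrix, taxa, tree, scheme, freqs=params.codon_freqs, space=space)
    omegas = np.array([params.omega_by_class[g] for g in scheme.group_names])
    bl = engine.default_branch_lengths()
    for k, bid in enumerate(engine.tidx.branch_ids):
        if bid is not None and bid in params.branch_lengths:
            bl[k] = params.branch_lengths[bid]
    return engine.log_likelihood(params.kappa, omegas, bl)


# ---------------------------------------------------------------------------
# Fitting

OMEGA_BOUNDS = (1e-4, 10.0)
KAPPA_BOUNDS = (0.1, 20.0)
LENGTH_BOUNDS = (1e-8, 20.0)


@dataclass
class FitOptions:
    fix_branch_lengths: bool = False
    freqs: str = "f3x4"                 # f3x4 | f1x4 | uniform
    tol: float = 1e-6                   # |delta lnL| convergence target
    restarts: int = 2
    seed: int = 0
    init_kappa: float = 2.0
    init_omega: float = 0.2


def _choose_freqs(matrix: np.ndarray, kind: str, space: CodonSpace) -> np.ndarray:
    if kind == "f3x4":
        return f3x4_frequencies(matrix, space)
    if kind == "f1x4":
        return f1x4_frequencies(matrix, space)
    if kind == "uniform":
        return uniform_frequencies(space)
    raise GenedecayError(f"unknown frequency model {kind!r}")


def fit_branch_model(
    matrix: np.ndarray,
    taxa: list[str],
    tree: SpeciesTree,
    class_scheme: str | ClassScheme = "one_ratio",
    opts: FitOptions | None = None,
    space: CodonSpace | None = None,
) -> BranchModelFit:
    """Maximize the GY94 branch-model likelihood.

    Jointly optimizes kappa, one omega per scheme group, and (unless
    ``opts.fix_branch_lengths``) all branch lengths, by bounded quasi-Newton
    on log-transformed parameters with seeded random restarts.  Deterministic
    given the seed.
    """
    opts = opts or FitOptions()
    scheme = SCHEMES[class_scheme] if isinstance(class_scheme, str) else class_scheme
    space = space or default_space()
    freqs = _choose_freqs(matrix, opts.freqs, space)
    engine = PruningEngine(matrix, taxa, tree, scheme, freqs=freqs, space=space)
    n_omega = scheme.n_omega
    fix_bl = opts.fix_branch_lengths
    bl0 = engine.default_branch_lengths()
    n_bl = engine.tidx.n_branches

    def unpack(x):
        kappa = math.exp(x[0])
        omegas = np.exp(x[1 : 1 + n_omega])
        if fix_bl:
            bl = bl0
        else:
            bl = np.empty(n_bl + 1)
            bl[:n_bl] = np.exp(x[1 + n_omega :])
            bl[n_bl] = 0.0
        return kappa, omegas, bl

    def negloglik(x):
        kappa, omegas, bl = unpack(x)
        try:
            return -engine.log_likelihood(kappa, omegas, bl)
        except GenedecayError:
            return 1e12

    bounds = [tuple(np.log(KAPPA_BOUNDS))] + [tuple(np.log(OMEGA_BOUNDS))] * n_omega
    x0 = [math.log(opts.init_kappa)] + [math.log(opts.init_omega)] * n_omega
    if not fix_bl:
        bounds += [tuple(np.log(LENGTH_BOUNDS))] * n_bl
        x0 += list(np.log(np.clip(bl0[:n_bl], *LENGTH_BOUNDS)))
    x0 = np.array(x0)

    rng = np.random.default_rng(opts.seed)
    best = None
    total_iters = 0
    starts = [x0] + [
        x0 + rng.normal(scale=0.5, size=x0.size) for _ in range(opts.restarts)
    ]
    for start in starts:
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            negloglik,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-10, "maxiter": 500},
        )
        total_iters += int(res.nit)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise ConvergenceError("branch-model fit failed to converge", best_fit=None)
    kappa, omegas, bl = unpack(best.x)
    params = CodonModelParams(
        kappa=kappa,
        omega_by_class={g: float(w) for g, w in zip(scheme.group_names, omegas)},
        codon_freqs=freqs,
        branch_lengths={
            bid: float(bl[k])
            for k, bid in enumerate(engine.tidx.branch_ids)
            if bid is not None
        },
    )
    n_free = 1 + n_omega + (0 if fix_bl else n_bl)
    grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else float("nan")
    return BranchModelFit(
        params=params,
        lnL=-float(best.fun),
        n_free_params=n_free,
        scheme=scheme.name,
        convergence={
            "iterations": total_iters,
            "restarts": opts.restarts,
            "gradient_norm": grad_norm,
            "success": bool(best.success),
        },
    )


def fit_ladder(
    matrix: np.ndarray,
    taxa: list[str],
    tree: SpeciesTree,
    schemes: list[str],
    opts: FitOptions | None = None,
) -> tuple[dict[str, BranchModelFit], dict[str, LRTResult]]:
    """Fit a list of schemes and run each one's conventional nested LRT."""
    fits = {
        name: fit_branch_model(matrix, taxa, tree, name, opts) for name in schemes
    }
    tests = {}
    for name in schemes:
        null_name = NULL_OF.get(name)
        if null_name in fits:
            tests[name] = lrt(fits[null_name], fits[name])
    return fits, tests
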