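"""Pairwise dN/dS by the modified Nei–Gojobori method.

The method counts synonymous and nonsynonymous *sites* per codon with each
possible point mutation weighted by the transition/transversion ratio R
(transitions weight R, transversions weight 1), and synonymous and
nonsynonymous *differences* between codons by averaging step classifications
over all mutational pathways.  Observed proportions are corrected for
multiple hits with the Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3), with the
analytic variance Var(d) = 9 p (1-p) / ((3-4p)^2 m).

Mutations into stop codons are excluded from synonymous/nonsynonymous
numerators but retained in site-count denominators; pathways through a stop
codon are skipped, and codon pairs whose every pathway is stop-blocked are
dropped and tallied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from genedecay.code import GeneticCodeTable, STANDARD_CODE, is_transition
from genedecay.core import CodonAlignment
from genedecay.errors import GenedecayError, SaturationError

_NTS = "ACGT"


@dataclass(frozen=True)
class DnDsConfig:
    """Options for modified Nei–Gojobori estimation.

    R is the transition/transversion *ratio* used in site counting; the
    default of 2.0 is a standard mammalian transition bias.
    """

    R: float = 2.0
    code: GeneticCodeTable = STANDARD_CODE

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("R must be > 0")


def count_sites(codon: str, config: DnDsConfig = DnDsConfig()) -> tuple[float, float]:
    """Weighted (synonymous, nonsynonymous) site counts for one sense codon.

    Per position, each of the 3 possible point mutations is weighted R
    (transition) or 1 (transversion); the position's synonymous site fraction
    is the weighted fraction of synonymous changes.  Mutations to stop codons
    count in the denominator but never in the synonymous numerator.  The two
    counts always sum to exactly 3.
    """
    codon = codon.upper()
    code = config.code
    if code.translate(codon) in ("*", "X"):
        raise GenedecayError(f"cannot count sites of non-sense codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        w_total = 0.0
        w_syn = 0.0
        for alt in _NTS:
            if alt == codon[pos]:
                continue
            w = config.R if is_transition(codon[pos], alt) else 1.0
            w_total += w
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if not code.is_stop(mutant) and code.is_synonymous(codon, mutant):
                w_syn += w
        syn += w_syn / w_total
    return syn, 3.0 - syn


def count_differences(
    codon_a: str, codon_b: str, code: GeneticCodeTable = STANDARD_CODE
) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    For k differing positions, step classifications are averaged over all k!
    mutational orderings, skipping orderings that pass through a stop codon.
    Returns ``None`` when every pathway is stop-blocked (the pair should be
    excluded and tallied by the caller).  Identical codons give (0, 0).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        path_syn = path_nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.is_synonymous(current, nxt):
                path_syn += 1
            else:
                path_nonsyn += 1
            current = nxt
        if not blocked:
            syn_total += path_syn
            nonsyn_total += path_nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, nonsyn_total / n_paths


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p} at or beyond JC saturation (3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jukes_cantor_variance(p: float, m: float) -> float:
    """Analytic variance of the JC distance given m sites."""
    if m <= 0:
        return float("nan")
    return 9.0 * p * (1.0 - p) / ((3.0 - 4.0 * p) ** 2 * m)


@dataclass
class PairwiseDnDs:
    """Modified Nei–Gojobori counts, corrected distances and variances."""

    N: float
    S: float
    Nd: float
    Sd: float
    dN: float
    dS: float
    varN: float
    varS: float
    n_codons: int
    n_excluded_stop_blocked: int = 0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else float("nan")

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else float("nan")

    @property
    def omega(self) -> float | None:
        """dN/dS, or None (undefined) when dS = 0."""
        if self.dS <= 0:
            return None
        return self.dN / self.dS


def _usable_codon_pairs(seq_a: str, seq_b: str, code: GeneticCodeTable):
    """Codon pairs surviving pairwise deletion of gap/N/stop codons."""
    if len(seq_a) != len(seq_b):
        raise GenedecayError("sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise GenedecayError("sequence length must be divisible by 3")
    pairs = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if any(b not in "ACGT" for b in ca + cb):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        pairs.append((ca, cb))
    return pairs


def pairwise_dnds(
    seq_a: str, seq_b: str, config: DnDsConfig = DnDsConfig()
) -> PairwiseDnDs:
    """Modified Nei–Gojobori dN/dS between two in-frame CDS strings.

    Codons containing gaps, N, or stops in either sequence are removed first
    (pairwise deletion).  Site counts N and S are averaged over the two
    sequences; distances are Jukes–Cantor corrected.
    """
    code = config.code
    pairs = _usable_codon_pairs(seq_a, seq_b, code)
    if not pairs:
        raise GenedecayError("no comparable codons after pairwise deletion")
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    excluded = 0
    kept = 0
    for ca, cb in pairs:
        diffs = count_differences(ca, cb, code)
        if diffs is None:
            excluded += 1
            continue
        sa, _ = count_sites(ca, config)
        sb, _ = count_sites(cb, config)
        S_a += sa
        S_b += sb
        Sd += diffs[0]
        Nd += diffs[1]
        kept += 1
    if kept == 0:
        raise GenedecayError("all codon pairs stop-blocked")
    S = (S_a + S_b) / 2.0
    N = 3.0 * kept - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return PairwiseDnDs(
        N=N, S=S, Nd=Nd, Sd=Sd,
        dN=jukes_cantor(pN), dS=jukes_cantor(pS),
        varN=jukes_cantor_variance(pN, N), varS=jukes_cantor_variance(pS, S),
        n_codons=kept, n_excluded_stop_blocked=excluded,
    )


def bootstrap_variances(
    seq_a: str, seq_b: str, config: DnDsConfig = DnDsConfig(),
    n_replicates: int = 500, seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap-over-codons variances of (dN, dS), as an alternative to the
    analytic forms."""
    code = config.code
    pairs = _usable_codon_pairs(seq_a, seq_b, code)
    rng = np.random.default_rng(seed)
    dns, dss = [], []
    n = len(pairs)
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        sa = "".join(pairs[i][0] for i in idx)
        sb = "".join(pairs[i][1] for i in idx)
        try:
            res = pairwise_dnds(sa, sb, config)
        except (GenedecayError, SaturationError):
            continue
        dns.append(res.dN)
        dss.append(res.dS)
    return float(np.var(dns, ddof=1)), float(np.var(dss, ddof=1))


@dataclass
class NeutralityTest:
    """Z-test of dN = dS."""

    Z: float
    p_two_sided: float
    p_purifying: float  # one-sided, H1: dN < dS


def z_test(res: PairwiseDnDs) -> NeutralityTest:
    """Codon-based Z-test of neutrality: Z = (dN - dS)/sqrt(varN + varS)."""
    var = res.varN + res.varS
    if var <= 0:
        if res.dN == res.dS:
            return NeutralityTest(Z=0.0, p_two_sided=1.0, p_purifying=0.5)
        raise GenedecayError("zero variance with dN != dS")
    z = (res.dN - res.dS) / math.sqrt(var)
    return NeutralityTest(
        Z=z,
        p_two_sided=float(2.0 * stats.norm.sf(abs(z))),
        p_purifying=float(stats.norm.cdf(z)),
    )


@dataclass
class GroupComparison:
    """One-sample two-tailed t-test of a group of dN/dS ratios vs a reference."""

    ratios: list[float]
    reference: float
    mean: float
    sd: float
    t: float
    df: int
    p_two_tailed: float
    degenerate: bool = False


def group_t_test(ratios: list[float], reference: float) -> GroupComparison:
    """One-sample t-test of mean(ratios) against ``reference``.

    SD uses the n-1 denominator.  Zero within-group variance is flagged and
    p reported as 1.0 (mean equals reference) or 0.0 otherwise.
    """
    vals = [r for r in ratios if r is not None and math.isfinite(r)]
    if len(vals) < 2:
        raise GenedecayError("need at least 2 finite ratios")
    arr = np.asarray(vals, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    df = len(vals) - 1
    if sd == 0.0:
        return GroupComparison(
            ratios=vals, reference=reference, mean=mean, sd=0.0,
            t=0.0 if mean == reference else math.copysign(math.inf, mean - reference),
            df=df, p_two_tailed=1.0 if mean == reference else 0.0, degenerate=True,
        )
    t = (mean - reference) / (sd / math.sqrt(len(vals)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(
        ratios=vals, reference=reference, mean=mean, sd=sd, t=t, df=df,
        p_two_tailed=p,
    )


def alignment_pairwise_table(
    aln: CodonAlignment,
    pairs: list[tuple[str, str]] | None = None,
    config: DnDsConfig = DnDsConfig(),
):
    """dN/dS and Z-test for species pairs drawn from a codon alignment.

    Sequences are extracted on reference codon columns; codons with gaps, N,
    or stops in either member are dropped pairwise.  ``pairs`` defaults to
    all unordered species pairs.
    """
    import pandas as pd

    species = [s for s in aln.species_ids]
    if pairs is None:
        pairs = list(itertools.combinations(species, 2))
    rows = []
    codon_cols = aln.reference_codon_columns()
    for a, b in pairs:
        sa = "".join(aln.codon_at(a, cols) for cols in codon_cols)
        sb = "".join(aln.codon_at(b, cols) for cols in codon_cols)
        try:
            res = pairwise_dnds(sa, sb, config)
            zt = z_test(res)
        except (GenedecayError, SaturationError) as exc:
            rows.append({"pair": f"{a}:{b}", "error": str(exc)})
            continue
        rows.append({
            "pair": f"{a}:{b}", "N": res.N, "S": res.S, "Nd": res.Nd, "Sd": res.Sd,
            "dN": res.dN, "dS": res.dS, "varN": res.varN, "varS": res.varS,
            "omega": res.omega if res.omega is not None else float("nan"),
            "Z": zt.Z, "p_two_sided": zt.p_two_sided, "p_purifying": zt.p_purifying,
            "n_codons": res.n_codons,
            "n_excluded_stop_blocked": res.n_excluded_stop_blocked,
        })
    return pd.DataFrame(rows)
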