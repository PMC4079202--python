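"""ORF-disruption detection, sharing classification, and loss dating.

A coding sequence is called a pseudogene when it carries frame-shifting
indels (length not a multiple of 3) or premature stop codons relative to an
intact reference.  Identical disruptions shared across species are grouped
and classed by the clades of their carriers:

* ``S``  — carriers span both toothed and baleen whales,
* ``S*`` — two or more carriers, all toothed whales,
* ``S#`` — two or more carriers, all baleen whales,
* ``U``  — a single carrier.

A shared disruption is dated by Dollo parsimony: it is assigned to the
branch subtending the most recent common ancestor of all its carriers (for a
toothed-plus-baleen pair this is the stem whale branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from genedecay.code import GeneticCodeTable, STANDARD_CODE
from genedecay.core import CodonAlignment, SpeciesManifest, SpeciesTree
from genedecay.errors import ManifestError


class DisruptionKind(str, Enum):
    FRAMESHIFT_DELETION = "frameshift_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    PREMATURE_STOP = "premature_stop"


class SharingClass(str, Enum):
    S = "S"        # spans toothed and baleen
    S_STAR = "S*"  # >=2 carriers, toothed only
    S_HASH = "S#"  # >=2 carriers, baleen only
    U = "U"        # single carrier


@dataclass
class Disruption:
    """One ORF-disrupting mutation in reference coordinates."""

    kind: DisruptionKind
    ref_start: int                  # 1-based reference nucleotide position
    length: int                     # nucleotides (indels) or 3 (stops)
    columns: tuple[int, ...]        # 0-based alignment columns involved
    carriers: frozenset[str]
    insertion_after: bool = False   # for insertions: ref_start is the base before

    def key(self):
        if self.kind is DisruptionKind.PREMATURE_STOP:
            return (self.kind, self.columns)
        return (self.kind, self.ref_start, self.length)


@dataclass
class Annotation:
    """A non-disrupting oddity worth surfacing (in-frame indels, shifted-frame
    stops)."""

    kind: str
    species: str
    ref_start: int
    length: int


@dataclass
class ScanResult:
    disruptions: list[Disruption]
    annotations: list[Annotation] = field(default_factory=list)


def detect_disruptions(
    aln: CodonAlignment,
    manifest: SpeciesManifest | None = None,
    code: GeneticCodeTable = STANDARD_CODE,
    gene: str | None = None,
) -> ScanResult:
    """Per-species scan for frame-shifting indels and premature stops.

    Indels are read off maximal gap runs against the reference: a deletion is
    a maximal run of reference positions the species lacks (broken only by
    positions where the species has a base); an insertion is a maximal run of
    species bases opposite reference gaps (broken only by reference bases).
    In-frame indels (length % 3 == 0) are recorded as annotations, not
    disruptions.  Premature stops are species codons, at reference-frame codon
    columns upstream of the reference's terminal stop, that translate to stop;
    codons containing N are skipped.  The reference itself is never scanned.
    """
    ref = aln.reference_sequence
    ref_cols = [i for i, b in enumerate(ref) if b != "-"]
    codon_cols = aln.reference_codon_columns()
    # exclude the reference's own terminal stop codon from the scan window
    last_codon = aln.codon_at(aln.reference_id, codon_cols[-1]) if codon_cols else ""
    scan_codons = codon_cols[:-1] if code.is_stop(last_codon) else codon_cols

    disruptions: list[Disruption] = []
    annotations: list[Annotation] = []
    for sp in aln.species_ids:
        if sp == aln.reference_id:
            continue
        if manifest is not None and gene is not None:
            avail = manifest.availability(gene, sp)
            if avail in ("absent_from_genome", "not_amplified"):
                raise ManifestError(
                    f"species {sp!r} flagged {avail} for gene {gene!r} but is "
                    "present in the alignment"
                )
        seq = aln.sequence(sp)

        # deletions: runs over reference positions where the species is gapped
        run: list[int] = []
        for col in ref_cols + [None]:
            if col is not None and seq[col] == "-":
                run.append(col)
                continue
            if run:
                start_pos, _ = aln.column_to_reference_coordinate(run[0])
                length = len(run)
                if length % 3 != 0:
                    disruptions.append(
                        Disruption(
                            kind=DisruptionKind.FRAMESHIFT_DELETION,
                            ref_start=start_pos, length=length,
                            columns=tuple(run), carriers=frozenset({sp}),
                        )
                    )
                else:
                    annotations.append(
                        Annotation("inframe_deletion", sp, start_pos, length)
                    )
                run = []

        # insertions: runs over reference-gap columns where the species has a
        # base; runs are broken only by reference bases
        ins_cols: list[int] = []
        for col in range(aln.column_count):
            if ref[col] == "-":
                if seq[col] != "-":
                    ins_cols.append(col)
                continue
            if ins_cols:
                _flush_insertion(aln, sp, ins_cols, disruptions, annotations)
                ins_cols = []
        if ins_cols:
            _flush_insertion(aln, sp, ins_cols, disruptions, annotations)

        # premature stops in the reference reading frame
        for k, cols in enumerate(scan_codons):
            codon = aln.codon_at(sp, cols)
            if "-" in codon or "N" in codon:
                continue
            if code.is_stop(codon):
                start_pos, _ = aln.column_to_reference_coordinate(cols[0])
                disruptions.append(
                    Disruption(
                        kind=DisruptionKind.PREMATURE_STOP,
                        ref_start=start_pos, length=3,
                        columns=cols, carriers=frozenset({sp}),
                    )
                )
    return ScanResult(disruptions=disruptions, annotations=annotations)


def _flush_insertion(aln, sp, ins_cols, disruptions, annotations):
    length = len(ins_cols)
    pos, _ = aln.column_to_reference_coordinate(ins_cols[0])
    if length % 3 != 0:
        disruptions.append(
            Disruption(
                kind=DisruptionKind.FRAMESHIFT_INSERTION,
                ref_start=pos, length=length,
                columns=tuple(ins_cols), carriers=frozenset({sp}),
                insertion_after=True,
            )
        )
    else:
        annotations.append(Annotation("inframe_insertion", sp, pos, length))


@dataclass
class GroupedDisruption:
    disruption: Disruption  # carriers merged
    sharing: SharingClass


def classify_carriers(
    carriers: frozenset[str], manifest: SpeciesManifest
) -> SharingClass:
    clades = {manifest.clade(sp) for sp in carriers}
    whale_clades = clades & {"toothed", "baleen"}
    if len(carriers) == 1:
        return SharingClass.U
    if whale_clades == {"toothed", "baleen"}:
        return SharingClass.S
    if whale_clades == {"toothed"} and len(carriers) >= 2:
        return SharingClass.S_STAR
    if whale_clades == {"baleen"} and len(carriers) >= 2:
        return SharingClass.S_HASH
    return SharingClass.U


def group_and_classify(
    disruptions: list[Disruption], manifest: SpeciesManifest
) -> tuple[list[GroupedDisruption], list[str]]:
    """Merge identical disruptions across species and class their sharing.

    Identity requires exact coordinate equality (same kind plus same
    ref_start/length for indels, same codon columns for stops).  Near-matches
    (same kind and length, start within one position) are surfaced as
    warnings, never auto-merged.  Returns (grouped, warnings).
    """
    by_key: dict[tuple, Disruption] = {}
    for d in disruptions:
        key = d.key()
        if key in by_key:
            prev = by_key[key]
            by_key[key] = Disruption(
                kind=prev.kind, ref_start=prev.ref_start, length=prev.length,
                columns=prev.columns, carriers=prev.carriers | d.carriers,
                insertion_after=prev.insertion_after,
            )
        else:
            by_key[key] = d
    grouped = [
        GroupedDisruption(disruption=d, sharing=classify_carriers(d.carriers, manifest))
        for d in sorted(by_key.values(), key=lambda d: (d.ref_start, d.kind.value))
    ]
    warnings = []
    items = [g.disruption for g in grouped]
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            if (
                a.kind == b.kind
                and a.length == b.length
                and 0 < abs(a.ref_start - b.ref_start) <= 1
            ):
                warnings.append(
                    f"near-match {a.kind.value} at ref {a.ref_start} vs "
                    f"{b.ref_start} (length {a.length}): possible alignment wobble"
                )
    return grouped, warnings


@dataclass
class GeneStatusCall:
    gene: str
    status: dict[str, str]          # species -> intact|pseudogene|absent|not_amplified
    grouped: list[GroupedDisruption]
    summary: str = ""


def call_gene_status(
    aln: CodonAlignment,
    manifest: SpeciesManifest,
    grouped: list[GroupedDisruption],
    gene: str,
) -> GeneStatusCall:
    """Per-species gene status from manifest flags and detected disruptions."""
    status: dict[str, str] = {}
    carriers_by_sp: dict[str, int] = {}
    for g in grouped:
        for sp in g.disruption.carriers:
            carriers_by_sp[sp] = carriers_by_sp.get(sp, 0) + 1
    for sp in manifest.species_ids:
        avail = manifest.availability(gene, sp)
        if avail == "absent_from_genome":
            status[sp] = "absent"
        elif avail == "not_amplified":
            status[sp] = "not_amplified"
        elif sp in aln.species_ids:
            status[sp] = "pseudogene" if carriers_by_sp.get(sp, 0) else "intact"
        else:
            status[sp] = "not_amplified"
    n_pseudo = sum(1 for v in status.values() if v == "pseudogene")
    n_shared = sum(1 for g in grouped if g.sharing is SharingClass.S)
    return GeneStatusCall(
        gene=gene, status=status, grouped=grouped,
        summary=f"{n_pseudo} pseudogenes, {n_shared} disruptions shared across clades",
    )


def infer_loss_branch(
    grouped: GroupedDisruption | Disruption, tree: SpeciesTree,
    manifest: SpeciesManifest | None = None,
) -> str:
    """Dollo assignment of a shared disruption to a tree branch.

    Returns the id of the branch subtending the MRCA of all carriers (the
    tip's own branch for a single carrier).  When carriers span the toothed
    and baleen clades this is the stem whale branch.
    """
    d = grouped.disruption if isinstance(grouped, GroupedDisruption) else grouped
    carriers = sorted(d.carriers)
    for sp in carriers:
        if sp not in tree.tip_names:
            raise KeyError(f"carrier {sp!r} not a tree tip")
    mrca = tree.mrca(carriers)
    return SpeciesTree.branch_id(mrca)


# ---------------------------------------------------------------------------
# Report tables

STATUS_CELL = {
    "intact": "+",
    "absent": "-",
    "not_amplified": ".",
}


def status_matrix_row(call: GeneStatusCall, species_order: list[str]) -> list[str]:
    """Fig-style status cells: +, -, ., or the gene's dominant sharing class
    for pseudogene carriers."""
    rank = [SharingClass.S, SharingClass.S_STAR, SharingClass.S_HASH, SharingClass.U]
    cells = []
    for sp in species_order:
        st = call.status.get(sp, "not_amplified")
        if st != "pseudogene":
            cells.append(STATUS_CELL[st])
            continue
        classes = {
            g.sharing for g in call.grouped if sp in g.disruption.carriers
        }
        cell = next((c.value for c in rank if c in classes), "U")
        cells.append(cell)
    return cells


def events_table(
    gene: str,
    grouped: list[GroupedDisruption],
    tree: SpeciesTree | None = None,
    manifest: SpeciesManifest | None = None,
):
    """Per-gene event table as a DataFrame (gene, kind, ref_start_1based,
    length, carriers, class, loss_branch)."""
    import pandas as pd

    rows = []
    for g in grouped:
        d = g.disruption
        rows.append({
            "gene": gene,
            "kind": d.kind.value,
            "ref_start_1based": d.ref_start,
            "length": d.length,
            "carriers": ",".join(sorted(d.carriers)),
            "class": g.sharing.value,
            "loss_branch": infer_loss_branch(g, tree) if tree is not None else "",
        })
    return pd.DataFrame(
        rows,
        columns=["gene", "kind", "ref_start_1based", "length", "carriers",
                 "class", "loss_branch"],
    )
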