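"""Core data model: codon alignments, species trees, species manifests.

Conventions shared by every downstream stage:

* internal coordinates are 0-based half-open; every user-facing report is
  1-based inclusive (the convention used when quoting mutation positions
  "following the reference sequence");
* IUPAC ambiguity codes other than ``N`` are read but collapsed to ``N`` and
  treated as missing downstream;
* branch classes ride on Newick node labels with a ``#label`` suffix
  (a widely understood foreground-marking dialect); unlabeled branches belong
  to class ``background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from genedecay.errors import AlignmentError, FrameError, ManifestError, TreeError

_VALID = set("ACGTN-")
_AMBIG = set("RYSWKMBDHV")

BACKGROUND = "background"


def _clean_base(b: str) -> str:
    b = b.upper()
    if b in _VALID:
        return b
    if b in _AMBIG:
        return "N"
    raise AlignmentError(f"illegal alignment character {b!r}")


@dataclass
class CodonAlignment:
    """An aligned set of coding sequences with a designated reference.

    The reference sequence, with gaps removed, defines the reading frame and
    the coordinate system in which disruptions are reported.
    """

    records: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentError("alignment needs at least 2 records")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate species ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.records = [
            (sid, "".join(_clean_base(b) for b in seq)) for sid, seq in self.records
        ]
        if self.reference_id not in ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")
        ref = self.sequence(self.reference_id)
        ungapped = ref.replace("-", "")
        if len(ungapped) % 3 != 0:
            raise FrameError(
                f"reference {self.reference_id!r} has gap-free length "
                f"{len(ungapped)}, not divisible by 3"
            )
        self._ref_coord_cache: list[tuple[int, bool]] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def column_count(self) -> int:
        return len(self.records[0][1])

    @property
    def species_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, species_id: str) -> str:
        for sid, seq in self.records:
            if sid == species_id:
                return seq
        raise KeyError(species_id)

    @property
    def reference_sequence(self) -> str:
        return self.sequence(self.reference_id)

    @property
    def n_reference_codons(self) -> int:
        return len(self.reference_sequence.replace("-", "")) // 3

    # -- coordinates -------------------------------------------------------

    def _coord_table(self) -> list[tuple[int, bool]]:
        """Per column: (1-based reference position, is_insertion)."""
        if self._ref_coord_cache is None:
            table = []
            pos = 0
            for b in self.reference_sequence:
                if b == "-":
                    table.append((pos, True))
                else:
                    pos += 1
                    table.append((pos, False))
            self._ref_coord_cache = table
        return self._ref_coord_cache

    def column_to_reference_coordinate(self, column: int) -> tuple[int, bool]:
        """Map alignment column (0-based) to a 1-based reference position.

        Columns where the reference is gapped map to the preceding reference
        position with the insertion flag set.  Monotone non-decreasing over
        columns.
        """
        if not 0 <= column < self.column_count:
            raise IndexError(f"column {column} out of range 0..{self.column_count - 1}")
        return self._coord_table()[column]

    def reference_codon_columns(self) -> list[tuple[int, int, int]]:
        """Column-index triples of consecutive reference bases, per ref codon."""
        cols = [i for i, b in enumerate(self.reference_sequence) if b != "-"]
        return [tuple(cols[i : i + 3]) for i in range(0, len(cols), 3)]

    def codon_at(self, species_id: str, columns: tuple[int, int, int]) -> str:
        seq = self.sequence(species_id)
        return "".join(seq[c] for c in columns)

    def subset(self, species_ids: list[str]) -> "CodonAlignment":
        keep = set(species_ids) | {self.reference_id}
        return CodonAlignment(
            records=[(s, q) for s, q in self.records if s in keep],
            reference_id=self.reference_id,
        )


def read_alignment(path: str | Path, reference_id: str) -> CodonAlignment:
    """Read an aligned FASTA into a validated :class:`CodonAlignment`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return CodonAlignment(records=records, reference_id=reference_id)


def write_alignment(aln: CodonAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Species tree


class SpeciesTree:
    """A rooted species tree with per-branch class labels.

    Wraps a :class:`dendropy.Tree`.  Every edge carries a ``branch_class``
    annotation (default ``background``); a branch is addressed by the label of
    the node below it (tips by name, internal nodes auto-labeled in preorder).
    """

    def __init__(self, tree: dendropy.Tree, lengths_missing: bool = False):
        self.tree = tree
        self.lengths_missing = lengths_missing
        self._label_nodes()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        # accept "#class" tags written after the branch length by moving them
        # onto the node label ("(A,B):0.05#1" -> "(A,B)#1:0.05")
        import re

        text = re.sub(r":([^,():;#\s]+)#([^,():;\s]+)", r"#\2:\1", text)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"cannot parse Newick: {exc}") from exc
        tree.is_rooted = True
        st = cls.__new__(cls)
        st.tree = tree
        # peel "#class" suffixes off labels onto edges
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            cls_label = BACKGROUND
            if label and "#" in label:
                label, _, cls_label = label.partition("#")
                cls_label = cls_label or BACKGROUND
                if node.taxon:
                    node.taxon.label = label
                else:
                    node.label = label or None
            node.edge.branch_class = cls_label
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip names in tree")
        st.lengths_missing = any(
            e.length is None for e in tree.preorder_edge_iter() if e.head_node.parent_node
        )
        st._label_nodes()
        return st

    @classmethod
    def read(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    def _label_nodes(self):
        counter = 1
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf() and not node.label:
                node.label = f"node{counter}"
            if not hasattr(node.edge, "branch_class"):
                node.edge.branch_class = BACKGROUND
            counter += 1

    # -- accessors ---------------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_by_label(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            if name == label:
                return node
        raise KeyError(f"no node labeled {label!r}")

    @staticmethod
    def branch_id(node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon else node.label

    def branch_class(self, label: str) -> str:
        return self.node_by_label(label).edge.branch_class

    def set_branch_class(self, label: str, branch_class: str) -> None:
        self.node_by_label(label).edge.branch_class = branch_class

    def branch_classes(self) -> dict[str, str]:
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                out[self.branch_id(node)] = node.edge.branch_class
        return out

    def mrca(self, tip_names: list[str]) -> dendropy.Node:
        taxa = []
        for name in tip_names:
            t = self.tree.taxon_namespace.get_taxon(name)
            if t is None:
                raise KeyError(f"tip {name!r} not in tree")
            taxa.append(t)
        if len(taxa) == 1:
            return self.tree.find_node_with_taxon_label(tip_names[0])
        return self.tree.mrca(taxa=taxa)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        clone = self.tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            cls_label = getattr(node.edge, "branch_class", BACKGROUND)
            if cls_label != BACKGROUND and node.parent_node is not None:
                if node.taxon:
                    node.taxon.label = f"{node.taxon.label}#{cls_label}"
                else:
                    node.label = f"{node.label or ''}#{cls_label}"
        return clone.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_tree(path: str | Path) -> SpeciesTree:
    """Read a Newick tree with optional ``#class`` branch tags."""
    return SpeciesTree.read(path)


def label_whale_branches(
    tree: SpeciesTree, manifest: "SpeciesManifest",
    stem_class: str = "stem", toothed_class: str = "toothed",
    baleen_class: str = "baleen",
) -> SpeciesTree:
    """Label branch classes from manifest clades.

    The branch above the most recent common ancestor of all whale tips gets
    ``stem``; branches inside the toothed and baleen subtrees get their clade
    name; everything else stays ``background``.
    """
    whales = [s for s in tree.tip_names if manifest.clade(s) in ("toothed", "baleen")]
    if not whales:
        raise ManifestError("no whale tips (clade toothed/baleen) found in tree")
    crown = tree.mrca(whales)
    if crown.parent_node is not None:
        crown.edge.branch_class = stem_class
    for node in crown.preorder_iter():
        if node is crown:
            continue
        clade_members = {
            manifest.clade(leaf.taxon.label) for leaf in node.leaf_iter()
        }
        if clade_members == {"toothed"}:
            node.edge.branch_class = toothed_class
        elif clade_members == {"baleen"}:
            node.edge.branch_class = baleen_class
    return tree


# ---------------------------------------------------------------------------
# Species manifest

#: availability-flag vocabulary, matching the status-matrix cell codes
FLAG_MEANINGS = {
    "+": "sequenced",          # intact ORF claimed / sequenced
    "P": "sequenced",          # sequenced pseudogene candidate
    "-": "absent_from_genome",
    ".": "not_amplified",
}


@dataclass
class SpeciesManifest:
    """Species -> clade map plus per-gene availability flags."""

    clades: dict[str, str]
    genes: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for sp, clade in self.clades.items():
            if clade not in ("toothed", "baleen", "outgroup"):
                raise ManifestError(f"unknown clade {clade!r} for species {sp!r}")
        for gene, flags in self.genes.items():
            for sp, flag in flags.items():
                if flag not in FLAG_MEANINGS:
                    raise ManifestError(
                        f"unknown flag {flag!r} for {gene}/{sp}; expected one of "
                        f"{sorted(FLAG_MEANINGS)}"
                    )
                if sp not in self.clades:
                    raise ManifestError(f"species {sp!r} in gene {gene} has no clade")

    def clade(self, species_id: str) -> str:
        try:
            return self.clades[species_id]
        except KeyError:
            raise ManifestError(f"species {species_id!r} missing from manifest")

    def availability(self, gene: str, species_id: str) -> str:
        flag = self.genes.get(gene, {}).get(species_id, "+")
        return FLAG_MEANINGS[flag]

    def flag(self, gene: str, species_id: str) -> str:
        return self.genes.get(gene, {}).get(species_id, "+")

    @property
    def species_ids(self) -> list[str]:
        return list(self.clades)

    def to_tsv(self) -> str:
        gene_names = sorted(self.genes)
        lines = ["\t".join(["species", "clade"] + gene_names)]
        for sp in self.clades:
            row = [sp, self.clades[sp]] + [self.flag(g, sp) for g in gene_names]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def read_manifest(path: str | Path) -> SpeciesManifest:
    """Read a manifest TSV: columns species, clade, then one column per gene."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:2] != ["species", "clade"]:
        raise ManifestError("manifest must start with columns 'species', 'clade'")
    gene_names = header[2:]
    clades: dict[str, str] = {}
    genes: dict[str, dict[str, str]] = {g: {} for g in gene_names}
    for ln in lines[1:]:
        parts = ln.split("\t")
        sp, clade = parts[0], parts[1]
        clades[sp] = clade
        for g, flag in zip(gene_names, parts[2:]):
            genes[g][sp] = flag
    return SpeciesManifest(clades=clades, genes=genes)
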