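"""Genetic-code tables and codon bookkeeping.

The standard (vertebrate nuclear) code is the default everywhere; all study
species in the intended applications are mammals.  Tables are pluggable via
:class:`GeneticCodeTable` for completeness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

NUCLEOTIDES = "TCAG"
#: Transition partner of each nucleotide (purine<->purine, pyrimidine<->pyrimidine).
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def is_transition(a: str, b: str) -> bool:
    return TRANSITION[a] == b


@dataclass(frozen=True)
class GeneticCodeTable:
    """A 64-entry codon -> amino-acid map with ``*`` marking stops."""

    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.codon_to_aa)}")
        stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")
        object.__setattr__(self, "stop_codons", stops)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The 61 (for the standard code) non-stop codons, TCAG-ordered."""
        return tuple(
            c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
            if c not in self.stop_codons
        )

    def translate(self, codon: str) -> str:
        """Amino-acid letter for a codon, ``*`` for stop, ``X`` if ambiguous."""
        codon = codon.upper()
        if any(b not in "ACGT" for b in codon):
            return "X"
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        """True if both codons are sense codons encoding the same residue."""
        aa, ab = self.translate(codon_a), self.translate(codon_b)
        if "*" in (aa, ab) or "X" in (aa, ab):
            raise ValueError(f"non-sense codon in comparison: {codon_a}, {codon_b}")
        return aa == ab


def _standard_table() -> GeneticCodeTable:
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    mapping = dict(bio.forward_table)
    for stop in bio.stop_codons:
        mapping[stop] = "*"
    return GeneticCodeTable(codon_to_aa=mapping)


#: The standard genetic code (TAA/TAG/TGA stops, 61 sense codons).
STANDARD_CODE = _standard_table()
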