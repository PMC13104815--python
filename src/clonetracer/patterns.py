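"""Degenerate-base patterns describing the lentiviral barcode design.

The lineage vector carries a semi-random barcode (by default 265 bp of ``N``)
immediately downstream of a fixed 33-bp anchor from the vector backbone.  The
first ``id_length`` bases of the barcode serve as the compact clone identifier
("barcode suffix").  Integrations that lost the barcode insert ("empty
vectors") read straight from the anchor into fixed downstream vector sequence
instead, which is what the extractor's empty-vector filter keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values

#: Fixed 3' vector-backbone sequence immediately upstream of the barcode.
DEFAULT_ANCHOR = "CAGATCTTAGCCACTTTTTAAAAGAAAAGGGGG"

#: Vector sequence that follows the anchor when no barcode insert is present
#: (5' end of the WPRE element, a standard lentiviral 3' cassette component).
DEFAULT_DOWNSTREAM_FIXED = "AATCAACCTCTGGATTACAAAATTTGTGAAAGATTGA"

#: Vector context placed 5' of the anchor in simulated reads (luciferase 3' end
#: style filler; any fixed sequence works, it is never parsed).
DEFAULT_UPSTREAM_CONTEXT = "TTTCGAGGTCGACGGTATCGATAAGCTTGATATCGAATTC"

# IUPAC degenerate codes -> allowed unambiguous bases (uppercase, DNA).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodePattern:
    """The barcode design: length, clone-ID length, degenerate pattern, anchor.

    Parameters
    ----------
    length : total barcode length in bases.
    id_length : number of leading barcode bases used as the clone ID.
    pattern : IUPAC degenerate string of ``length`` characters; ``None`` means
        fully random (``"N" * length``).
    anchor : fixed vector sequence preceding the barcode.
    downstream_fixed : vector sequence following the anchor in empty vectors.
    """

    length: int = 265
    id_length: int = 10
    pattern: str | None = None
    anchor: str = DEFAULT_ANCHOR
    downstream_fixed: str = DEFAULT_DOWNSTREAM_FIXED

    def __post_init__(self) -> None:
        if self.pattern is None:
            object.__setattr__(self, "pattern", "N" * self.length)
        if not (0 < self.id_length <= self.length):
            raise ValueError("require length >= id_length > 0")
        if len(self.pattern) != self.length:
            raise ValueError(
                f"pattern length {len(self.pattern)} != barcode length {self.length}"
            )
        bad = set(self.pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"pattern contains non-IUPAC codes: {sorted(bad)}")
        if not self.anchor or set(self.anchor) - set("ACGT"):
            raise ValueError("anchor must be a non-empty ACGT string")
        if set(self.downstream_fixed) - set("ACGT"):
            raise ValueError("downstream_fixed must be an ACGT string")

    @property
    def allowed_sets(self) -> list[frozenset[str]]:
        return [IUPAC_SETS[c] for c in self.pattern]

    def n_possible(self, prefix_length: int | None = None, cap: int = 1 << 62) -> int:
        """Number of distinct sequences the (prefix of the) pattern can emit,
        capped to avoid astronomically large integers."""
        n = 1
        upto = self.length if prefix_length is None else prefix_length
        for code in self.pattern[:upto]:
            n *= len(IUPAC_SETS[code])
            if n >= cap:
                return cap
        return n

    def count_mismatches(self, seq: str, offset: int = 0) -> int:
        """Positions of ``seq`` (aligned at pattern ``offset``) whose base is
        not allowed by the corresponding degenerate code."""
        window = self.pattern[offset : offset + len(seq)]
        return sum(b not in IUPAC_SETS[c] for b, c in zip(seq, window))

    def matches(self, seq: str, offset: int = 0) -> bool:
        return self.count_mismatches(seq, offset) == 0
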