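"""Core domain types for nuclear tRNA gene analysis.

The central object is :class:`TRNAGene`, one annotated tRNA-coding gene with
1-based inclusive genomic coordinates (the tRNAscan-SE convention).  Records
on the minus strand are normalised at parse time so that ``start <= end``
always holds and ``genomic_seq`` is always the coding (gene) strand.

Anticodons are stored as DNA (T, not U), uppercase.  The 64-anticodon space
and the standard genetic code live in :class:`GeneticCode`; decoding an
anticodon goes through its reverse-complement codon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

__all__ = [
    "ANTICODONS",
    "STOP_CODONS",
    "STOP_PAIRING",
    "GeneticCode",
    "TRNAGene",
    "SpeciesAssembly",
    "anticodon_to_amino_acid",
    "reverse_complement",
    "splice_introns",
]

DNA_BASES = "ACGT"

#: All 64 anticodons (DNA alphabet), lexicographic order.
ANTICODONS: Tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(DNA_BASES, repeat=3)
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Label returned for anticodons whose reverse-complement codon is a stop.
STOP_PAIRING = "stop-pairing"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_DNA = frozenset("ACGTNacgtn")

#: The 20 standard amino acids (three-letter), plus special isotype labels
#: used by tRNAscan-SE output: initiator Met, selenocysteine, undetermined.
STANDARD_AA: Tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
ISOTYPES = STANDARD_AA + ("iMet", "SeC", "Und")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over the ACGTN alphabet.

    Case is preserved; applying the function twice returns the input.
    """
    if not _VALID_DNA.issuperset(seq):
        bad = sorted(set(seq) - _VALID_DNA)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _build_codon_to_aa() -> Mapping[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    return {codon: seq3(aa) for codon, aa in table.forward_table.items()}


@dataclass(frozen=True)
class GeneticCode:
    """Standard genetic code over the full 64-anticodon space.

    ``codon_to_aa`` covers the 61 sense codons (three-letter amino-acid
    labels); the three stops are listed separately.  ``anticodon_to_codon``
    is the reverse-complement bijection over all 64 anticodons.  The
    anticodon TCA pairs the recoded stop TGA and is interpreted as
    selenocysteine (SeC) on request; the iMet/elongator-Met distinction is
    an annotation attribute of the gene record and is never derivable from
    the anticodon (both are CAT).
    """

    codon_to_aa: Mapping[str, str] = field(default_factory=_build_codon_to_aa)
    stop_codons: frozenset = STOP_CODONS

    @property
    def anticodon_to_codon(self) -> Mapping[str, str]:
        return {ac: reverse_complement(ac) for ac in ANTICODONS}

    def decode(self, anticodon: str, selenocysteine: bool = False) -> str:
        """Amino acid decoded by an anticodon's reverse-complement codon.

        Parameters
        ----------
        anticodon : str
            3-mer over ACGT (DNA alphabet, uppercase or lowercase).
        selenocysteine : bool
            When True, the anticodon TCA (codon TGA) is reported as "SeC";
            otherwise all stop-pairing anticodons return ``STOP_PAIRING``.
        """
        ac = anticodon.upper()
        if len(ac) != 3 or not set(ac).issubset(DNA_BASES):
            raise ValueError(f"invalid anticodon {anticodon!r}: need a 3-mer over ACGT")
        codon = reverse_complement(ac)
        if codon in self.stop_codons:
            if selenocysteine and codon == "TGA":
                return "SeC"
            return STOP_PAIRING
        return self.codon_to_aa[codon]


_STANDARD_CODE = GeneticCode()


def anticodon_to_amino_acid(anticodon: str, selenocysteine: bool = False) -> str:
    """Decode an anticodon under the standard genetic code.

    Convenience wrapper over :meth:`GeneticCode.decode`.
    """
    return _STANDARD_CODE.decode(anticodon, selenocysteine=selenocysteine)


@dataclass
class TRNAGene:
    """One annotated tRNA-coding gene.

    Coordinates are 1-based inclusive on ``seq_id``; ``genomic_seq`` is the
    coding-strand sequence including introns, so its length always equals
    ``end - start + 1``.  Intron spans are gene-relative, 1-based inclusive,
    sorted and non-overlapping.
    """

    gene_id: str
    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    genomic_seq: str
    intron_spans: Tuple[Tuple[int, int], ...] = ()
    score: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start ({self.end} < {self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.anticodon = self.anticodon.upper()
        if self.anticodon != "NNN" and self.anticodon not in ANTICODONS:
            raise ValueError(f"{self.gene_id}: invalid anticodon {self.anticodon!r}")
        self.genomic_seq = self.genomic_seq.upper()
        if self.genomic_seq and len(self.genomic_seq) != self.length:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.genomic_seq)} != "
                f"coordinate span {self.length}"
            )
        self.intron_spans = tuple(tuple(s) for s in self.intron_spans)
        prev_end = 0
        for s, e in self.intron_spans:
            if not (1 <= s <= e <= self.length):
                raise ValueError(
                    f"{self.gene_id}: intron span ({s}, {e}) outside gene of "
                    f"length {self.length}"
                )
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: intron spans overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        """Gene length in bp (introns included)."""
        return self.end - self.start + 1

    @property
    def has_intron(self) -> bool:
        return bool(self.intron_spans)

    @property
    def intron_lengths(self) -> Tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.intron_spans)

    @property
    def mature_seq(self) -> str:
        return splice_introns(self)


def splice_introns(gene: TRNAGene) -> str:
    """Return the mature (intron-less) sequence of a gene.

    The intron spans are removed in order; the result has length
    ``gene.length - sum(intron lengths)``.
    """
    seq = gene.genomic_seq
    if not gene.intron_spans:
        return seq
    parts = []
    cursor = 0
    for s, e in gene.intron_spans:
        parts.append(seq[cursor : s - 1])
        cursor = e
    parts.append(seq[cursor:])
    return "".join(parts)


@dataclass
class SpeciesAssembly:
    """Sizes of the sequences (chromosomes/scaffolds) of one assembly."""

    species: str
    seq_lengths: Mapping[str, int]

    @property
    def genome_size(self) -> int:
        return sum(self.seq_lengths.values())

    def contains(self, seq_id: str, start: int, end: int) -> bool:
        length = self.seq_lengths.get(seq_id)
        return length is not None and 1 <= start <= end <= length
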