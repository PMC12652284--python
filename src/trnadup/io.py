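"""Readers for tRNAscan-SE tabular output and FASTA; TSV/BED/JSON writers.

The tabular dialect is tRNAscan-SE v2 ``.out``: three header lines followed
by tab-separated columns (sequence name, tRNA#, begin, end, isotype,
anticodon, intron begin, intron end, score, and an optional note column
such as "pseudo" or "trunc_start").  Rows with begin > end are minus-strand
and are normalised on input; intron coordinates are converted to
gene-relative spans on the coding strand.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .model import SpeciesAssembly, TRNAGene, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "read_trnascan_table",
    "write_trnascan_table",
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "write_bed6",
    "write_json",
    "write_results",
    "load_annotation_dir",
]

_SORT_KEY = lambda g: (g.species, g.seq_id, g.start, g.end, g.gene_id)


@dataclass
class AnnotationSet:
    """An ordered collection of tRNA genes plus assembly metadata.

    Genes are kept sorted by (species, seq_id, start), with ties broken by
    end then gene_id; gene ids are unique.
    """

    genes: List[TRNAGene]
    assemblies: Dict[str, SpeciesAssembly] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=_SORT_KEY)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def by_id(self) -> Dict[str, TRNAGene]:
        return {g.gene_id: g for g in self.genes}

    def species(self) -> Tuple[str, ...]:
        return tuple(sorted({g.species for g in self.genes}))

    def merged(self, other: "AnnotationSet") -> "AnnotationSet":
        return AnnotationSet(
            genes=self.genes + other.genes,
            assemblies={**self.assemblies, **other.assemblies},
            provenance={**self.provenance, **other.provenance},
        )


def _is_header_line(line: str) -> bool:
    stripped = line.strip()
    if not stripped:
        return True
    if stripped.startswith(("Sequence", "Name")):
        return True
    return set(stripped) <= set("- \t")


def _parse_intron_cols(
    ib_field: str, ie_field: str
) -> List[Tuple[int, int]]:
    """Genomic intron bounds from the two intron columns; 0 means none.

    Comma-separated lists are accepted so fixtures may plant more than one
    intron per gene even though tRNAscan-SE reports at most one.
    """
    begins = [int(x) for x in str(ib_field).split(",")]
    ends = [int(x) for x in str(ie_field).split(",")]
    if len(begins) != len(ends):
        raise ValueError("intron begin/end lists differ in length")
    return [(b, e) for b, e in zip(begins, ends) if b != 0 or e != 0]


def read_trnascan_table(
    path: os.PathLike | str,
    species: str,
    genome: Optional[Mapping[str, str]] = None,
    gene_seqs: Optional[Mapping[str, str]] = None,
) -> AnnotationSet:
    """Parse a tRNAscan-SE v2 tabular file into an :class:`AnnotationSet`.

    Parameters
    ----------
    path : path
        tRNAscan-SE ``.out`` file (3 header lines then tab-separated rows).
    species : str
        Short species code attached to every gene (e.g. "Ath").
    genome : mapping, optional
        seq_id -> genomic sequence; when given, each gene's coding-strand
        sequence is extracted (reverse-complemented for minus strand).
    gene_seqs : mapping, optional
        gene_id -> coding-strand sequence, used when no genome is supplied
        (companion per-gene FASTA).
    """
    genes: List[TRNAGene] = []
    seq_lengths: Dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if _is_header_line(line):
            continue
        fields = line.rstrip("\n").split("\t")
        fields = [f.strip() for f in fields]
        if len(fields) < 9:
            raise ValueError(
                f"{path}:{lineno}: expected >= 9 tab-separated columns, "
                f"got {len(fields)}"
            )
        if len(fields) > 10:
            logger.warning(
                "%s:%d: ignoring %d unknown trailing column(s)",
                path, lineno, len(fields) - 10,
            )
        seq_name, trna_no, begin, end = fields[0], fields[1], int(fields[2]), int(fields[3])
        isotype, anticodon = fields[4], fields[5].upper()
        introns_genomic = _parse_intron_cols(fields[6], fields[7])
        score = float(fields[8]) if fields[8] else None
        note = fields[9] if len(fields) > 9 else ""

        if begin <= end:
            strand, start, stop = "+", begin, end
            rel = lambda g: g - start + 1
        else:
            strand, start, stop = "-", end, begin
            rel = lambda g: begin - g + 1
        spans = sorted(
            tuple(sorted((rel(ib), rel(ie)))) for ib, ie in introns_genomic
        )
        length = stop - start + 1
        for s, e in spans:
            if not (1 <= s <= e <= length):
                raise ValueError(
                    f"{path}:{lineno}: intron bounds outside gene "
                    f"(relative span {s}-{e}, gene length {length})"
                )

        gene_id = f"{species}.{seq_name}.trna{trna_no}"
        seq = ""
        if genome is not None:
            if seq_name not in genome:
                raise KeyError(f"{path}:{lineno}: sequence {seq_name!r} not in genome")
            chrom = genome[seq_name]
            seq_lengths[seq_name] = len(chrom)
            seq = chrom[start - 1 : stop].upper()
            if strand == "-":
                seq = reverse_complement(seq)
        elif gene_seqs is not None and gene_id in gene_seqs:
            seq = gene_seqs[gene_id].upper()

        genes.append(
            TRNAGene(
                gene_id=gene_id,
                species=species,
                seq_id=seq_name,
                start=start,
                end=stop,
                strand=strand,
                isotype=isotype,
                anticodon=anticodon,
                genomic_seq=seq,
                intron_spans=tuple(spans),
                score=score,
                note=note,
            )
        )
    assemblies = {}
    if genome is not None:
        assemblies[species] = SpeciesAssembly(
            species=species, seq_lengths={k: len(v) for k, v in genome.items()}
        )
    return AnnotationSet(
        genes=genes,
        assemblies=assemblies,
        provenance={species: str(path)},
    )


def write_trnascan_table(annot: AnnotationSet, path: os.PathLike | str) -> None:
    """Write genes back out in the tRNAscan-SE v2 tabular dialect."""
    lines = [
        "Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\t\tInf\t",
        "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote",
        "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\t----",
    ]
    for i, g in enumerate(annot.genes, start=1):
        if g.strand == "+":
            begin, end = g.start, g.end
            to_genomic = lambda r: g.start + r - 1
        else:
            begin, end = g.end, g.start
            to_genomic = lambda r: g.end - r + 1
        if g.intron_spans:
            ib = ",".join(str(to_genomic(s)) for s, _ in g.intron_spans)
            ie = ",".join(str(to_genomic(e)) for _, e in g.intron_spans)
        else:
            ib = ie = "0"
        score = f"{g.score:.1f}" if g.score is not None else ""
        # tRNA numbering restarts per sequence, as tRNAscan-SE does
        lines.append(
            "\t".join(
                [
                    g.seq_id,
                    g.gene_id.rsplit("trna", 1)[-1],
                    str(begin),
                    str(end),
                    g.isotype,
                    g.anticodon,
                    ib,
                    ie,
                    score,
                    g.note,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: os.PathLike | str) -> Dict[str, str]:
    """Read a multi-FASTA into an ordered id -> uppercase-sequence mapping.

    IDs are taken up to the first whitespace.  Duplicate IDs and empty
    records are errors.
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: os.PathLike | str, width: int = 60) -> None:
    """Write an id -> sequence mapping as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(df: pd.DataFrame, path: os.PathLike | str) -> None:
    """TSV writer with fixed float formatting (4 decimals) for stable diffs."""
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", lineterminator="\n")


def write_bed6(
    intervals: Iterable[Tuple[str, int, int, str, int, str]],
    path: os.PathLike | str,
) -> None:
    """Write BED6 lines from 1-based inclusive intervals.

    Each input tuple is (seq_id, start_1based, end_1based, name, score,
    strand); chromStart is start-1 (0-based half-open conversion).
    """
    with open(path, "w") as fh:
        for seq_id, start, end, name, score, strand in intervals:
            fh.write(f"{seq_id}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n")


def write_json(obj, path: os.PathLike | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_results(
    out_dir: os.PathLike | str,
    tables: Optional[Mapping[str, pd.DataFrame]] = None,
    bed_intervals: Optional[Mapping[str, Iterable[Tuple[str, int, int, str, int, str]]]] = None,
    summary: Optional[dict] = None,
) -> List[Path]:
    """Emit result TSV tables, BED6 files and a JSON run summary.

    Output is byte-stable given identical inputs.  Returns written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for name, df in sorted((tables or {}).items()):
        p = out / f"{name}.tsv"
        write_tsv(df, p)
        written.append(p)
    for name, intervals in sorted((bed_intervals or {}).items()):
        p = out / f"{name}.bed"
        write_bed6(intervals, p)
        written.append(p)
    if summary is not None:
        p = out / "summary.json"
        write_json(summary, p)
        written.append(p)
    return written


def load_annotation_dir(annot_dir: os.PathLike | str) -> AnnotationSet:
    """Load every ``<species>.trnascan.out`` (+ matching genome FASTA) in a directory.

    The layout is the one :func:`trnadup.simulate.write_fixture` produces:
    ``<species>.trnascan.out`` and ``<species>.genome.fasta`` per species.
    """
    annot_dir = Path(annot_dir)
    tables = sorted(annot_dir.glob("*.trnascan.out"))
    if not tables:
        raise FileNotFoundError(f"no *.trnascan.out files in {annot_dir}")
    merged: Optional[AnnotationSet] = None
    for table in tables:
        species = table.name.split(".")[0]
        fasta = annot_dir / f"{species}.genome.fasta"
        genome = read_fasta(fasta) if fasta.exists() else None
        one = read_trnascan_table(table, species=species, genome=genome)
        merged = one if merged is None else merged.merged(one)
    assert merged is not None
    return merged
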