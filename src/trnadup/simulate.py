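"""Seeded generator of multi-species tRNA annotation fixtures.

The generator emulates the statistical structure of nuclear tRNA gene
annotations: per-species anticodon abundance over the 64-anticodon space,
mature gene lengths in 62-98 bp with peaks near 72 and 82 bp, introns
inserted immediately 3' of the anticodon with lengths peaked at 12 bp
(range 3-261 bp) and concentrated in Met-CAT / Tyr-GTA genes, a
stem-high / anticodon-low GC architecture, and planted tandem arrays of
identical or diverged genes separated by configurable gaps.

All randomness flows through a single ``numpy.random.Generator`` seeded
from :class:`SyntheticSpec.seed`, so identical specs produce byte-identical
fixtures.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import AnnotationSet, write_fasta, write_json, write_trnascan_table
from .model import (
    ANTICODONS,
    SpeciesAssembly,
    TRNAGene,
    anticodon_to_amino_acid,
    reverse_complement,
)

__all__ = [
    "GeneratedTRNA",
    "ArraySpec",
    "SpeciesSpec",
    "SyntheticSpec",
    "Fixture",
    "generate_trna_sequence",
    "plant_array",
    "generate_fixture",
    "write_fixture",
    "default_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Base probabilities (A, C, G, T) for stem-like (GC-rich) and loop-like
#: (GC-poor) segments of the cloverleaf schematic.
_P_STEM = (0.10, 0.40, 0.40, 0.10)
_P_LOOP = (0.40, 0.10, 0.10, 0.40)


def _draw_bases(rng: np.random.Generator, n: int, probs) -> str:
    if n == 0:
        return ""
    idx = rng.choice(4, size=n, p=probs)
    return _BASES[idx].tobytes().decode()


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
    return _draw_bases(rng, n, p)


@dataclass(frozen=True)
class GeneratedTRNA:
    """A synthetic mature tRNA gene body.

    ``anticodon_start`` is the 0-based offset of the anticodon triplet;
    ``stem_mask[i]`` is True where position i belongs to a stem segment.
    """

    seq: str
    anticodon_start: int
    stem_mask: Tuple[bool, ...]

    @property
    def anticodon(self) -> str:
        return self.seq[self.anticodon_start : self.anticodon_start + 3]


def _cloverleaf_layout(length: int) -> List[Tuple[str, int, bool]]:
    """(segment name, length, is_stem) triples for a schematic cloverleaf.

    Fixed-size stems (acceptor 7+7, D 4+4, anticodon 5+5, T 5+5) and loops
    (anticodon loop 2+3+2, T loop 7); the D loop and variable loop absorb
    the remaining length, which confines total length to [62, 98].
    """
    if not 62 <= length <= 98:
        raise ValueError(f"tRNA gene length {length} outside [62, 98]")
    extra = length - 62
    d_loop = 4 + extra // 3
    var_loop = 2 + (extra - extra // 3)
    return [
        ("acceptor5", 7, True),
        ("d_stem5", 4, True),
        ("d_loop", d_loop, False),
        ("d_stem3", 4, True),
        ("ac_stem5", 5, True),
        ("ac_loop5", 2, False),
        ("anticodon", 3, False),
        ("ac_loop3", 2, False),
        ("ac_stem3", 5, True),
        ("var_loop", var_loop, False),
        ("t_stem5", 5, True),
        ("t_loop", 7, False),
        ("t_stem3", 5, True),
        ("acceptor3", 7, True),
    ]


def generate_trna_sequence(
    isotype: str, anticodon: str, length: int, rng: np.random.Generator
) -> GeneratedTRNA:
    """Draw one schematic tRNA gene body of the requested mature length.

    Stem segments are drawn GC-rich (expected GC 0.8) and loops GC-poor
    (expected GC 0.2); the literal anticodon is placed in the anticodon
    loop.  The output is deterministic given the rng state.
    """
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or not set(anticodon) <= set("ACGT"):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    parts: List[str] = []
    mask: List[bool] = []
    ac_start = 0
    pos = 0
    for name, seg_len, is_stem in _cloverleaf_layout(length):
        if name == "anticodon":
            ac_start = pos
            seg = anticodon
        else:
            seg = _draw_bases(rng, seg_len, _P_STEM if is_stem else _P_LOOP)
        parts.append(seg)
        mask.extend([is_stem] * seg_len)
        pos += seg_len
    return GeneratedTRNA(seq="".join(parts), anticodon_start=ac_start, stem_mask=tuple(mask))


def _sample_mature_length(rng: np.random.Generator) -> int:
    """Bimodal length draw with peaks at 72 and 82 bp, clipped to [62, 98]."""
    if rng.random() < 0.55:
        x = rng.normal(72.0, 2.0)
    else:
        x = rng.normal(82.0, 2.5)
    return int(np.clip(round(x), 62, 98))


def _sample_intron_length(rng: np.random.Generator) -> int:
    """Intron length peaked at 12 bp, range [3, 261], with a rare long tail."""
    if rng.random() < 0.03:
        x = 12 + int(rng.integers(10, 250))
    else:
        x = 12 + int(rng.geometric(0.30)) - int(rng.geometric(0.30))
    return int(np.clip(x, 3, 261))


def _insert_intron(
    body: GeneratedTRNA, intron_len: int, rng: np.random.Generator
) -> Tuple[str, Tuple[int, int]]:
    """Insert a GC-poor intron immediately 3' of the anticodon.

    Returns the genomic sequence and the gene-relative 1-based intron span.
    """
    k = body.anticodon_start + 3
    intron = _draw_bases(rng, intron_len, _P_LOOP)
    return body.seq[:k] + intron + body.seq[k:], (k + 1, k + intron_len)


@dataclass
class ArraySpec:
    """One planted tandem array.

    ``unit`` is the ordered (isotype, anticodon) block that is repeated
    ``copies`` times at increasing coordinates; consecutive genes are
    separated by ``intra_gap`` bp.  With ``divergence`` 0, all copies of a
    given unit slot are byte-identical; with divergence d > 0, every copy
    after the first receives exactly d random substitutions outside the
    anticodon triplet.
    """

    species: str
    seq_id: str
    anchor: int
    unit: Tuple[Tuple[str, str], ...]
    copies: int
    intra_gap: int
    divergence: int = 0

    def __post_init__(self) -> None:
        self.unit = tuple((iso, ac.upper()) for iso, ac in self.unit)
        if not 1 <= len(self.unit) <= 8:
            raise ValueError("unit length must be between 1 and 8")
        if self.copies < 1 or self.intra_gap < 0 or self.divergence < 0:
            raise ValueError("copies >= 1, intra_gap >= 0, divergence >= 0 required")

    @property
    def n_genes(self) -> int:
        return self.copies * len(self.unit)


@dataclass
class SpeciesSpec:
    """Per-species block of a synthetic fixture.

    ``anticodon_counts`` gives background (non-array) gene counts per sense
    anticodon; initiator-Met and SeC genes are requested separately since
    they share anticodons with Met (CAT) and a stop (TCA).  Background
    genes are placed with inter-gene gaps sampled uniformly from
    [min_gap, max_gap]; the 1000 bp default floor keeps background genes
    out of tandem-duplication range by construction.
    """

    species: str
    scaffolds: Dict[str, int]
    anticodon_counts: Dict[str, int] = field(default_factory=dict)
    imet_count: int = 0
    sec_count: int = 0
    background_gc: float = 0.36
    intron_prob: Dict[str, float] = field(
        default_factory=lambda: {"CAT": 0.45, "GTA": 0.60}
    )
    intron_prob_default: float = 0.01
    min_gap: int = 1000
    max_gap: int = 3000

    def __post_init__(self) -> None:
        for ac, n in self.anticodon_counts.items():
            if n < 0:
                raise ValueError(f"negative count for anticodon {ac}")
        if self.min_gap < 0 or self.max_gap < self.min_gap:
            raise ValueError("need 0 <= min_gap <= max_gap")


@dataclass
class SyntheticSpec:
    """Full parameterization of a generated multi-species fixture."""

    seed: int
    species_specs: List[SpeciesSpec]
    arrays: List[ArraySpec] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: os.PathLike | str) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        species = [SpeciesSpec(**s) for s in d.get("species_specs", [])]
        arrays = [
            ArraySpec(**{**a, "unit": tuple(tuple(u) for u in a["unit"])})
            for a in d.get("arrays", [])
        ]
        return cls(seed=int(d["seed"]), species_specs=species, arrays=arrays)

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "SyntheticSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class _ScaffoldDraft:
    species: str
    seq_id: str
    buf: bytearray
    occupied: List[Tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    cursor: int = 0  # rightmost placed end (background placement resumes here)
    n_genes: int = 0

    @property
    def length(self) -> int:
        return len(self.buf)

    def place(self, start: int, seq: str) -> Tuple[int, int]:
        end = start + len(seq) - 1
        if start < 1 or end > self.length:
            raise ValueError(
                f"{self.species}.{self.seq_id}: gene at {start}-{end} exceeds "
                f"scaffold length {self.length}"
            )
        for os_, oe in self.occupied:
            if start <= oe and end >= os_:
                raise ValueError(
                    f"{self.species}.{self.seq_id}: gene at {start}-{end} overlaps "
                    f"occupied interval {os_}-{oe}"
                )
        self.buf[start - 1 : end] = seq.encode()
        self.occupied.append((start, end))
        self.occupied.sort()
        return start, end

    def next_gene_id(self) -> str:
        self.n_genes += 1
        return f"{self.species}.{self.seq_id}.trna{self.n_genes}"


def _substitute(
    seq: str, n_subs: int, forbidden: range, rng: np.random.Generator
) -> str:
    """Apply exactly ``n_subs`` random substitutions outside ``forbidden``."""
    positions = [i for i in range(len(seq)) if i not in forbidden]
    if n_subs > len(positions):
        raise ValueError("more substitutions requested than available positions")
    chosen = rng.choice(len(positions), size=n_subs, replace=False)
    out = list(seq)
    for ci in sorted(int(c) for c in chosen):
        i = positions[ci]
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def plant_array(
    draft: _ScaffoldDraft, spec: ArraySpec, rng: np.random.Generator
) -> Tuple[List[TRNAGene], dict]:
    """Write one tandem array onto a scaffold draft.

    One template body is drawn per unit slot; every copy of that slot is
    the template itself (divergence 0) or the template with exactly
    ``divergence`` substitutions, never inside the anticodon triplet.
    Genes are plus-strand, at increasing coordinates with ``intra_gap`` bp
    between consecutive genes.  Returns the gene records and a truth-table
    entry for recovery tests.
    """
    templates = []
    for isotype, anticodon in spec.unit:
        length = _sample_mature_length(rng)
        templates.append(generate_trna_sequence(isotype, anticodon, length, rng))
    genes: List[TRNAGene] = []
    cursor = spec.anchor
    for copy_idx in range(spec.copies):
        for slot, (isotype, anticodon) in enumerate(spec.unit):
            body = templates[slot]
            seq = body.seq
            if spec.divergence > 0 and copy_idx > 0:
                forbidden = range(body.anticodon_start, body.anticodon_start + 3)
                seq = _substitute(seq, spec.divergence, forbidden, rng)
            start, end = draft.place(cursor, seq)
            genes.append(
                TRNAGene(
                    gene_id=draft.next_gene_id(),
                    species=spec.species,
                    seq_id=draft.seq_id,
                    start=start,
                    end=end,
                    strand="+",
                    isotype=isotype,
                    anticodon=anticodon,
                    genomic_seq=seq,
                    score=60.0,
                )
            )
            cursor = end + 1 + spec.intra_gap
    truth = {
        "species": spec.species,
        "seq_id": spec.seq_id,
        "start": genes[0].start,
        "end": genes[-1].end,
        "unit": [list(u) for u in spec.unit],
        "copies": spec.copies,
        "intra_gap": spec.intra_gap,
        "divergence": spec.divergence,
        "gene_ids": [g.gene_id for g in genes],
    }
    return genes, truth


@dataclass
class Fixture:
    """A generated fixture: annotation + genomes + machine-readable truth."""

    annotation: AnnotationSet
    genomes: Dict[str, Dict[str, str]]  # species -> seq_id -> sequence
    truth: dict


def _background_isotype(anticodon: str) -> str:
    aa = anticodon_to_amino_acid(anticodon, selenocysteine=True)
    return "Und" if aa == "stop-pairing" else aa


def generate_fixture(spec: SyntheticSpec) -> Fixture:
    """Generate the full multi-species fixture a :class:`SyntheticSpec` describes.

    Arrays are planted first at their anchors; background genes are then
    placed left to right with sampled gaps, skipping planted intervals with
    at least ``min_gap`` clearance.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    all_genes: List[TRNAGene] = []
    genomes: Dict[str, Dict[str, str]] = {}
    assemblies: Dict[str, SpeciesAssembly] = {}
    truth_arrays: List[dict] = []
    truth_genes: List[dict] = []

    for sp in spec.species_specs:
        drafts: Dict[str, _ScaffoldDraft] = {}
        for seq_id, length in sp.scaffolds.items():
            buf = bytearray(_random_dna(rng, length, sp.background_gc).encode())
            drafts[seq_id] = _ScaffoldDraft(species=sp.species, seq_id=seq_id, buf=buf)

        for arr in spec.arrays:
            if arr.species != sp.species:
                continue
            if arr.seq_id not in drafts:
                raise ValueError(f"array scaffold {arr.seq_id!r} not in {sp.species}")
            genes, truth = plant_array(drafts[arr.seq_id], arr, rng)
            all_genes.extend(genes)
            truth_arrays.append(truth)

        # deterministic background order: sense anticodons sorted, then iMet, SeC
        requests: List[Tuple[str, str]] = []
        for anticodon in sorted(sp.anticodon_counts):
            requests += [(_background_isotype(anticodon), anticodon)] * sp.anticodon_counts[anticodon]
        requests += [("iMet", "CAT")] * sp.imet_count
        requests += [("SeC", "TCA")] * sp.sec_count

        draft_list = list(drafts.values())
        d_idx = 0
        for isotype, anticodon in requests:
            body = generate_trna_sequence(
                isotype, anticodon, _sample_mature_length(rng), rng
            )
            p_intron = (
                sp.intron_prob.get(anticodon, sp.intron_prob_default)
                if isotype not in ("iMet", "SeC")
                else 0.0
            )
            spans: Tuple[Tuple[int, int], ...] = ()
            seq = body.seq
            if rng.random() < p_intron:
                seq, span = _insert_intron(body, _sample_intron_length(rng), rng)
                spans = (span,)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = False
            for _ in range(len(draft_list)):
                draft = draft_list[d_idx % len(draft_list)]
                gap = int(rng.integers(sp.min_gap, sp.max_gap + 1))
                pos = max(draft.cursor, 0) + gap + 1
                for os_, oe in draft.occupied:
                    if pos - sp.min_gap <= oe and pos + len(seq) - 1 + sp.min_gap >= os_:
                        pos = oe + gap + 1
                if pos + len(seq) - 1 <= draft.length:
                    written = seq if strand == "+" else reverse_complement(seq)
                    start, end = draft.place(pos, written)
                    draft.cursor = max(draft.cursor, end)
                    gene = TRNAGene(
                        gene_id=draft.next_gene_id(),
                        species=sp.species,
                        seq_id=draft.seq_id,
                        start=start,
                        end=end,
                        strand=strand,
                        isotype=isotype,
                        anticodon=anticodon,
                        genomic_seq=seq,
                        intron_spans=spans,
                        score=55.0,
                    )
                    all_genes.append(gene)
                    truth_genes.append(
                        {
                            "gene_id": gene.gene_id,
                            "species": sp.species,
                            "isotype": isotype,
                            "anticodon": anticodon,
                            "mature_length": len(body.seq),
                            "intron_lengths": list(gene.intron_lengths),
                        }
                    )
                    placed = True
                    break
                d_idx += 1
            if not placed:
                raise ValueError(
                    f"{sp.species}: scaffold capacity exhausted while placing "
                    f"background genes ({len(requests)} requested)"
                )
            d_idx += 1

        genomes[sp.species] = {sid: d.buf.decode() for sid, d in drafts.items()}
        assemblies[sp.species] = SpeciesAssembly(
            species=sp.species, seq_lengths=dict(sp.scaffolds)
        )

    annotation = AnnotationSet(
        genes=all_genes,
        assemblies=assemblies,
        provenance={"generator": f"trnadup.simulate(seed={spec.seed})"},
    )
    truth = {
        "seed": spec.seed,
        "arrays": truth_arrays,
        "background_genes": truth_genes,
        "anticodon_counts": {
            sp.species: dict(sorted(sp.anticodon_counts.items()))
            for sp in spec.species_specs
        },
    }
    return Fixture(annotation=annotation, genomes=genomes, truth=truth)


def write_fixture(fixture: Fixture, out_dir: os.PathLike | str) -> List[Path]:
    """Write genome FASTA + tRNAscan-style table per species, plus truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for species in sorted(fixture.genomes):
        fasta = out / f"{species}.genome.fasta"
        write_fasta(fixture.genomes[species], fasta)
        written.append(fasta)
        sub = AnnotationSet(
            genes=[g for g in fixture.annotation.genes if g.species == species],
            assemblies={species: fixture.annotation.assemblies[species]},
        )
        table = out / f"{species}.trnascan.out"
        write_trnascan_table(sub, table)
        written.append(table)
    truth_path = out / "truth.json"
    write_json(fixture.truth, truth_path)
    written.append(truth_path)
    return written


#: Stylised set of 15 anticodons left unused by the default fixture
#: (two stop-pairing anticodons plus thirteen sparsely used sense ones),
#: so 49 of the 64 anticodon types are populated.
ABSENT_ANTICODONS: Tuple[str, ...] = (
    "TTA", "CTA",  # stop-pairing (amber/ochre); TCA is kept for SeC
    "ACA", "ACC", "ACT", "GCG", "CCG", "GGA", "GGG", "GGT",
    "ATA", "ATC", "ATG", "CTC", "GTG",
)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Default three-species study fixture.

    Two seed-plant-like species ("Aaa", "Bbb") and one moss-like species
    ("Cpu") carry ~120 background genes each over 49 anticodon types, with
    abundant Asp-GTC and Gly-GCC, a few initiator-Met genes, and introns
    concentrated in Met-CAT / Tyr-GTA.  Planted arrays mirror the canonical
    tandem architectures: a 27-copy single-isotype Pro array, a
    Tyr-Tyr-Ser periodic array, three large identical arrays (26/18/14
    copies) on the moss scaffolds, and one diverged Pro array pairing
    different Pro anticodons.
    """
    present = [ac for ac in ANTICODONS if ac not in ABSENT_ANTICODONS and ac != "TCA"]
    boosted = {"GTC": 8, "GCC": 6, "CAT": 5, "GTA": 5, "TGG": 4, "GCT": 3}

    def counts(scale: int) -> Dict[str, int]:
        return {ac: scale * boosted.get(ac, 2) for ac in present}

    species = [
        SpeciesSpec(
            species="Aaa",
            scaffolds={"Aaa_sc1": 300_000, "Aaa_sc2": 250_000},
            anticodon_counts=counts(1),
            imet_count=3,
            background_gc=0.36,
        ),
        SpeciesSpec(
            species="Bbb",
            scaffolds={"Bbb_sc1": 300_000, "Bbb_sc2": 250_000},
            anticodon_counts=counts(1),
            imet_count=2,
            sec_count=1,
            background_gc=0.47,
        ),
        SpeciesSpec(
            species="Cpu",
            scaffolds={"Cpu_sc1": 300_000, "Cpu_sc2": 250_000},
            anticodon_counts=counts(1),
            imet_count=4,
            background_gc=0.40,
        ),
    ]
    arrays = [
        ArraySpec("Aaa", "Aaa_sc1", 200_000, (("Pro", "TGG"),), 27, 200),
        ArraySpec(
            "Aaa", "Aaa_sc2", 200_000,
            (("Tyr", "GTA"), ("Tyr", "GTA"), ("Ser", "GCT")), 9, 150,
        ),
        ArraySpec("Cpu", "Cpu_sc1", 200_000, (("Ile", "AAT"),), 26, 180),
        ArraySpec("Cpu", "Cpu_sc1", 240_000, (("Cys", "GCA"),), 18, 180),
        ArraySpec("Cpu", "Cpu_sc2", 200_000, (("Cys", "GCA"),), 14, 180),
        ArraySpec(
            "Bbb", "Bbb_sc1", 200_000,
            (("Pro", "TGG"), ("Pro", "AGG")), 5, 300, divergence=3,
        ),
    ]
    return SyntheticSpec(seed=seed, species_specs=species, arrays=arrays)
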