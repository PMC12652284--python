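"""Tandem-duplication detection for tRNA gene annotations.

The procedure: (1) find every pair of genes on the same (species,
scaffold) whose inter-gene distance is below 1 kb; (2) classify each pair
as 100%-identical (byte equality of coding-strand sequences) or divergent
(global-alignment identity); (3) chain pairs into maximal clusters by
connected components, separately for the identical-pair track and the
all-pair track; (4) decompose each cluster's ordered (isotype, anticodon)
label string into its smallest exact repeat unit; and (5) extract pairs
that decode the same amino acid through different ("degenerated")
anticodons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .align import DEFAULT_PARAMS, ScoringParams, global_align
from .io import AnnotationSet
from .model import TRNAGene, anticodon_to_amino_acid

logger = logging.getLogger(__name__)

__all__ = [
    "TandemPair",
    "TandemCluster",
    "proximal_pairs",
    "classify_pairs",
    "chain_clusters",
    "unit_decomposition",
    "periodic_prefix",
    "degenerate_anticodon_pairs",
]


@dataclass
class TandemPair:
    """A proximal gene pair; ``gene_a`` is the upstream gene (smaller start).

    ``gap_bp`` is start(b) - end(a) - 1, clamped to 0 for overlapping
    genes.  Identity fields are filled by :func:`classify_pairs`.
    """

    gene_a: str
    gene_b: str
    species: str
    seq_id: str
    gap_bp: int
    anticodon_a: str = "NNN"
    anticodon_b: str = "NNN"
    identical: Optional[bool] = None
    identity_pct: Optional[float] = None
    same_anticodon: Optional[bool] = None
    same_amino_acid: Optional[bool] = None


def _gap(upstream: TRNAGene, downstream: TRNAGene) -> int:
    return max(0, downstream.start - upstream.end - 1)


def proximal_pairs(annot: AnnotationSet, max_gap: int = 1000) -> List[TandemPair]:
    """All same-scaffold gene pairs with inter-gene distance < ``max_gap``.

    A sorted sweep per (species, seq_id): for each gene, downstream genes
    are scanned until their start exceeds the gap bound, so pairs need not
    be adjacent in rank.  Strand is ignored.
    """
    genes = annot.genes
    key = lambda g: (g.species, g.seq_id, g.start, g.end, g.gene_id)
    if any(key(genes[i]) > key(genes[i + 1]) for i in range(len(genes) - 1)):
        logger.warning("annotation not sorted; re-sorting for the pair sweep")
        genes = sorted(genes, key=key)
    pairs: List[TandemPair] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if (b.species, b.seq_id) != (a.species, a.seq_id):
                break
            if b.start - a.end - 1 >= max_gap:
                break
            pairs.append(
                TandemPair(
                    gene_a=a.gene_id,
                    gene_b=b.gene_id,
                    species=a.species,
                    seq_id=a.seq_id,
                    gap_bp=_gap(a, b),
                    anticodon_a=a.anticodon,
                    anticodon_b=b.anticodon,
                )
            )
    return pairs


def classify_pairs(
    pairs: Sequence[TandemPair],
    annot: AnnotationSet,
    params: ScoringParams = DEFAULT_PARAMS,
    align_divergent: bool = True,
) -> Tuple[List[TandemPair], dict]:
    """Annotate pairs with identity and anticodon/amino-acid agreement.

    A pair is *identical* when the full coding-strand genomic sequences
    are byte-equal (identity 100); otherwise identity comes from the
    global aligner (skipped when ``align_divergent`` is False and only the
    identical/divergent split is needed).  Returns the annotated pairs and
    a summary with the identical fraction as a percentage.
    """
    by_id = annot.by_id
    divergent_ids: List[float] = []
    for p in pairs:
        a, b = by_id[p.gene_a], by_id[p.gene_b]
        if not a.genomic_seq or not b.genomic_seq:
            raise ValueError(f"missing sequence for pair ({p.gene_a}, {p.gene_b})")
        p.identical = a.genomic_seq == b.genomic_seq
        if p.identical:
            p.identity_pct = 100.0
        elif align_divergent:
            p.identity_pct = global_align(a.genomic_seq, b.genomic_seq, params).identity_pct
            divergent_ids.append(p.identity_pct)
        p.same_anticodon = (
            a.anticodon == b.anticodon and a.anticodon != "NNN"
        )
        aa_a = _decode(a.anticodon)
        aa_b = _decode(b.anticodon)
        p.same_amino_acid = aa_a is not None and aa_a == aa_b
    n_total = len(pairs)
    n_identical = sum(1 for p in pairs if p.identical)
    summary = {
        "n_pairs": n_total,
        "n_identical": n_identical,
        "n_divergent": n_total - n_identical,
        "fraction_identical_pct": 100.0 * n_identical / n_total if n_total else None,
        "divergent_identity_min": min(divergent_ids) if divergent_ids else None,
        "divergent_identity_max": max(divergent_ids) if divergent_ids else None,
    }
    return list(pairs), summary


def _decode(anticodon: str) -> Optional[str]:
    if anticodon == "NNN":
        return None
    return anticodon_to_amino_acid(anticodon, selenocysteine=True)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


@dataclass
class TandemCluster:
    """A maximal chained cluster of proximal genes.

    ``labels`` is the ordered (isotype, anticodon) string of the member
    genes; ``unit``/``unit_len``/``repeats`` give its smallest exact
    repeat decomposition (repeats = 1 and unit = whole string when the
    smallest period does not divide the cluster size).
    """

    cluster_id: str
    species: str
    seq_id: str
    gene_ids: Tuple[str, ...]
    start: int
    end: int
    identity_class: str               # "all-identical" | "divergent"
    labels: Tuple[Tuple[str, str], ...]
    unit: Tuple[Tuple[str, str], ...]
    unit_len: int
    repeats: int
    periodic_prefix_unit_len: int     # informative: longest exactly periodic prefix
    periodic_prefix_repeats: int
    anticodon_summary: Counter = field(default_factory=Counter)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def span(self) -> Tuple[str, int, int]:
        return (self.seq_id, self.start, self.end)


def unit_decomposition(
    labels: Sequence[Tuple[str, str]]
) -> Tuple[Tuple[Tuple[str, str], ...], int, int]:
    """Smallest exact repeat unit of a label string.

    The smallest period p is n - border(n) from the KMP failure (border)
    array; when p divides n the string is unit^(n/p) exactly and
    (unit, p, n/p) is returned, otherwise the whole string with repeats 1.
    """
    labels = tuple(tuple(l) for l in labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty label string")
    border = [0] * (n + 1)
    k = 0
    for i in range(1, n):
        while k > 0 and labels[i] != labels[k]:
            k = border[k]
        if labels[i] == labels[k]:
            k += 1
        border[i + 1] = k
    p = n - border[n]
    if n % p == 0:
        return labels[:p], p, n // p
    return labels, n, 1


def periodic_prefix(labels: Sequence[Tuple[str, str]]) -> Tuple[int, int]:
    """(unit_len, repeats) of the longest exactly periodic prefix.

    Considers every candidate period p with at least two full repeats and
    returns the decomposition covering the most labels (smallest p wins
    ties); falls back to (n, 1) when no prefix repeats.
    """
    labels = tuple(tuple(l) for l in labels)
    n = len(labels)
    best = (n, 1)
    best_cover = 0
    for p in range(1, n // 2 + 1):
        r = 1
        while (r + 1) * p <= n and labels[r * p : (r + 1) * p] == labels[:p]:
            r += 1
        if r >= 2 and r * p > best_cover:
            best_cover = r * p
            best = (p, r)
    return best


def chain_clusters(
    pairs: Sequence[TandemPair],
    annot: AnnotationSet,
    mode: str = "all",
) -> List[TandemCluster]:
    """Connected components of the pair graph, as ordered clusters.

    ``mode`` selects the analysis track: "identical" uses only
    100%-identical pairs (pairs must have been classified), "all" uses
    every proximal pair.  Components with at least two genes become
    clusters; genes are ordered by start and the cluster's label string is
    decomposed into its smallest repeat unit.
    """
    if mode not in ("all", "identical"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "identical":
        if any(p.identical is None for p in pairs):
            raise ValueError("pairs must be classified before identical-mode chaining")
        used = [p for p in pairs if p.identical]
    else:
        used = list(pairs)
    uf = _UnionFind()
    for p in used:
        uf.union(p.gene_a, p.gene_b)
    components: Dict[str, List[str]] = {}
    for p in used:
        for gid in (p.gene_a, p.gene_b):
            components.setdefault(uf.find(gid), []).append(gid)
    by_id = annot.by_id
    clusters: List[TandemCluster] = []
    for root, ids in components.items():
        ids = sorted(set(ids), key=lambda gid: (by_id[gid].start, by_id[gid].end, gid))
        if len(ids) < 2:
            continue
        genes = [by_id[g] for g in ids]
        labels = tuple((g.isotype, g.anticodon) for g in genes)
        unit, unit_len, repeats = unit_decomposition(labels)
        pp_len, pp_rep = periodic_prefix(labels)
        seqs = {g.genomic_seq for g in genes}
        clusters.append(
            TandemCluster(
                cluster_id="",  # assigned after sorting
                species=genes[0].species,
                seq_id=genes[0].seq_id,
                gene_ids=tuple(ids),
                start=min(g.start for g in genes),
                end=max(g.end for g in genes),
                identity_class="all-identical" if len(seqs) == 1 else "divergent",
                labels=labels,
                unit=unit,
                unit_len=unit_len,
                repeats=repeats,
                periodic_prefix_unit_len=pp_len,
                periodic_prefix_repeats=pp_rep,
                anticodon_summary=Counter(g.anticodon for g in genes),
            )
        )
    clusters.sort(key=lambda c: (c.species, c.seq_id, c.start, c.end))
    for k, c in enumerate(clusters, start=1):
        c.cluster_id = f"{c.species}.{c.seq_id}.c{k}"
    return clusters


def clusters_to_frame(clusters: Sequence[TandemCluster]) -> pd.DataFrame:
    """Flat TSV-ready table of cluster attributes."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "species": c.species,
                "seq_id": c.seq_id,
                "start": c.start,
                "end": c.end,
                "n_genes": c.n_genes,
                "identity_class": c.identity_class,
                "unit": ";".join(f"{iso}-{ac}" for iso, ac in c.unit),
                "unit_len": c.unit_len,
                "repeats": c.repeats,
                "gene_ids": ",".join(c.gene_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "species", "seq_id", "start", "end", "n_genes",
            "identity_class", "unit", "unit_len", "repeats", "gene_ids",
        ],
    )


def pairs_to_frame(pairs: Sequence[TandemPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "species": p.species,
            "seq_id": p.seq_id,
            "gap_bp": p.gap_bp,
            "identical": p.identical,
            "identity_pct": p.identity_pct,
            "same_anticodon": p.same_anticodon,
            "same_amino_acid": p.same_amino_acid,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "species", "seq_id", "gap_bp", "identical",
            "identity_pct", "same_anticodon", "same_amino_acid",
        ],
    )


def degenerate_anticodon_pairs(
    pairs: Sequence[TandemPair],
) -> Tuple[List[TandemPair], pd.DataFrame, Counter]:
    """Pairs decoding the same amino acid through different anticodons.

    Keeps classified pairs with same_amino_acid and not same_anticodon,
    tabulates them per amino acid (count, species spread, identity range)
    and per species.  The amino acid is taken from either gene's
    anticodon (they agree by construction); pairs need classification
    first so the flags are present.
    """
    if any(p.same_amino_acid is None for p in pairs):
        raise ValueError("pairs must be classified before the degenerate-anticodon scan")
    kept = [p for p in pairs if p.same_amino_acid and not p.same_anticodon]
    per_species: Counter = Counter(p.species for p in kept)
    rows: Dict[str, dict] = {}
    for p in kept:
        aa = anticodon_to_amino_acid(p.anticodon_a, selenocysteine=True)
        row = rows.setdefault(
            aa,
            {"amino_acid": aa, "n_pairs": 0, "species": set(),
             "identity_min": None, "identity_max": None},
        )
        row["n_pairs"] += 1
        row["species"].add(p.species)
        if p.identity_pct is not None:
            lo, hi = row["identity_min"], row["identity_max"]
            row["identity_min"] = p.identity_pct if lo is None else min(lo, p.identity_pct)
            row["identity_max"] = p.identity_pct if hi is None else max(hi, p.identity_pct)
    table = pd.DataFrame(
        [
            {
                "amino_acid": aa,
                "n_pairs": row["n_pairs"],
                "n_species": len(row["species"]),
                "identity_min": row["identity_min"],
                "identity_max": row["identity_max"],
            }
            for aa, row in sorted(rows.items())
        ],
        columns=["amino_acid", "n_pairs", "n_species", "identity_min", "identity_max"],
    )
    return kept, table, per_species
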