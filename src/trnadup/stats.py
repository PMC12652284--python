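"""Descriptive conservation statistics for tRNA gene sets.

Covers sliding-window GC profiles along length-normalised gene positions,
their aggregation with a tricube local-linear (loess-style) smoother, the
species x anticodon abundance matrix over the full 64-anticodon space,
intron statistics (I/T ratios, length histogram), gene-length
distributions, and the correlation between gene count and genome size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ANTICODONS, TRNAGene, splice_introns

__all__ = [
    "GCProfile",
    "AggregateGCProfile",
    "AbundanceMatrix",
    "IntronStats",
    "CorrelationResult",
    "LengthDistribution",
    "gc_profile",
    "aggregate_gc",
    "abundance_matrix",
    "intron_stats",
    "genome_size_correlation",
    "length_distribution",
]

#: Isotype labels excluded from statistics by default (low-confidence calls).
_EXCLUDED_ISOTYPES = frozenset({"Und", "Pseudo", "Sup"})


def _analysis_genes(
    genes: Iterable[TRNAGene], include_und: bool = False
) -> List[TRNAGene]:
    if include_und:
        return list(genes)
    return [
        g for g in genes
        if g.isotype not in _EXCLUDED_ISOTYPES and "pseudo" not in g.note.lower()
    ]


@dataclass
class GCProfile:
    """Sliding-window GC series over one gene (or an aggregate).

    ``position`` holds window centres normalised by the total sequence
    length (so values lie in (0, 1)); ``gc`` is the GC fraction of each
    window.
    """

    position: np.ndarray
    gc: np.ndarray
    window: int = 5
    step: int = 1
    source: str = ""

    def __len__(self) -> int:
        return len(self.position)


def gc_profile(seq: str, window: int = 5, step: int = 1, source: str = "") -> GCProfile:
    """GC fraction in sliding windows of ``window`` bp every ``step`` bp.

    Window starts run i = 1, 1+step, ... (1-based) while the window fits;
    the normalised position of a window is its centre, i + (window-1)/2,
    divided by the sequence length.
    """
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    is_gc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    starts = np.arange(0, n - window + 1, step)  # 0-based
    gc = (csum[starts + window] - csum[starts]) / window
    centers = starts + 1 + (window - 1) / 2  # 1-based centres
    return GCProfile(
        position=centers / n, gc=gc, window=window, step=step, source=source
    )


def _tricube_local_linear(
    x: np.ndarray, y: np.ndarray, xq: np.ndarray, span: float = 0.75
) -> np.ndarray:
    """Local linear regression with tricube weights (loess, degree 1).

    At each query point the ``ceil(span * n)`` nearest data points are
    weighted by (1 - (d/h)^3)^3 with h the largest neighbour distance, and
    a weighted straight line is fitted in closed form.  Degenerate windows
    (h = 0 or collinear x) fall back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(xq))
    for qi, x0 in enumerate(np.asarray(xq, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            out[qi] = y[idx].mean()
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        sw = w.sum()
        if sw == 0:
            out[qi] = y[idx].mean()
            continue
        xw, yw = x[idx], y[idx]
        mx = (w * xw).sum() / sw
        my = (w * yw).sum() / sw
        sxx = (w * (xw - mx) ** 2).sum()
        if sxx <= 1e-300:
            out[qi] = my
            continue
        beta = (w * (xw - mx) * (yw - my)).sum() / sxx
        out[qi] = my + beta * (x0 - mx)
    return out


@dataclass
class AggregateGCProfile:
    """Binned aggregate GC profile with smoother and confidence band."""

    position: np.ndarray       # bin centres (normalised position)
    mean_gc: np.ndarray        # within-bin mean
    smooth_gc: np.ndarray      # tricube local-linear fit at bin centres
    band_lo: np.ndarray        # mean - 1.96 * SE
    band_hi: np.ndarray        # mean + 1.96 * SE
    n_points: np.ndarray       # points per bin
    n_bins: int = 100
    span: float = 0.75

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.position,
                "mean_gc": self.mean_gc,
                "smooth_gc": self.smooth_gc,
                "band_lo": self.band_lo,
                "band_hi": self.band_hi,
                "n_points": self.n_points,
            }
        )


def aggregate_gc(
    profiles: Sequence[GCProfile], n_bins: int = 100, span: float = 0.75
) -> AggregateGCProfile:
    """Aggregate per-gene GC profiles over normalised position.

    Points are pooled into ``n_bins`` equal-width bins on [0, 1] and
    averaged; a tricube local-linear smoother (span = fraction of bins per
    window) is evaluated at the non-empty bin centres, and a pointwise
    +/- 1.96 * SE band is derived from the within-bin variance.
    """
    if not profiles:
        raise ValueError("need at least one GC profile")
    pos = np.concatenate([p.position for p in profiles])
    gc = np.concatenate([p.gc for p in profiles])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_bins - 1)
    centers, means, se, counts = [], [], [], []
    for b in range(n_bins):
        mask = which == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        vals = gc[mask]
        centers.append((edges[b] + edges[b + 1]) / 2)
        means.append(vals.mean())
        counts.append(nb)
        se.append(vals.std(ddof=1) / np.sqrt(nb) if nb > 1 else 0.0)
    centers = np.array(centers)
    means = np.array(means)
    se = np.array(se)
    counts = np.array(counts)
    smooth = _tricube_local_linear(centers, means, centers, span=span)
    return AggregateGCProfile(
        position=centers,
        mean_gc=means,
        smooth_gc=smooth,
        band_lo=means - 1.96 * se,
        band_hi=means + 1.96 * se,
        n_points=counts,
        n_bins=n_bins,
        span=span,
    )


@dataclass
class AbundanceMatrix:
    """Species x anticodon gene-count matrix over the 64-anticodon space.

    ``counts`` merges initiator-Met genes into the CAT column (the 64-column
    view used for absent/present accounting); ``counts_imet`` keeps iMet as
    a 65th column for supplementary reporting.
    """

    counts: pd.DataFrame
    counts_imet: pd.DataFrame

    @property
    def absent(self) -> Tuple[str, ...]:
        total = self.counts.sum(axis=0)
        return tuple(sorted(c for c in self.counts.columns if total[c] == 0))

    @property
    def present(self) -> Tuple[str, ...]:
        total = self.counts.sum(axis=0)
        return tuple(sorted(c for c in self.counts.columns if total[c] > 0))

    @property
    def species_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def anticodon_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def abundance_matrix(
    genes: Iterable[TRNAGene], include_und: bool = False
) -> AbundanceMatrix:
    """Count genes by (species, anticodon) over all 64 anticodons.

    Genes with an undetermined anticodon ("NNN") are dropped; genes with
    isotype Und (or a pseudogene note) are excluded unless ``include_und``.
    """
    kept = [g for g in _analysis_genes(genes, include_und) if g.anticodon != "NNN"]
    species = sorted({g.species for g in kept})
    cols64 = list(ANTICODONS)
    counts = pd.DataFrame(0, index=species, columns=cols64, dtype=int)
    counts65 = pd.DataFrame(0, index=species, columns=cols64 + ["iMet"], dtype=int)
    for g in kept:
        counts.loc[g.species, g.anticodon] += 1
        col = "iMet" if g.isotype == "iMet" else g.anticodon
        counts65.loc[g.species, col] += 1
    return AbundanceMatrix(counts=counts, counts_imet=counts65)


@dataclass
class IntronStats:
    """Intron-containing gene counts, I/T ratios and intron-length stats."""

    per_species: pd.DataFrame       # species, n_intron_genes, n_genes, it_ratio_pct
    length_hist: Counter            # intron length -> count
    mean_length: Optional[float]
    mode_length: Optional[int]      # smallest length achieving max frequency
    per_isotype: pd.DataFrame       # isotype, n_intron_genes, fraction_pct

    @property
    def n_introns(self) -> int:
        return sum(self.length_hist.values())


def intron_stats(genes: Iterable[TRNAGene], include_und: bool = False) -> IntronStats:
    """Per-species I/T ratios plus the global intron-length histogram.

    I/T = 100 * (genes with at least one intron) / (total genes) per
    species; a species with zero genes gets a missing (NaN) ratio.
    """
    kept = _analysis_genes(genes, include_und)
    species = sorted({g.species for g in kept})
    rows = []
    for sp in species:
        sp_genes = [g for g in kept if g.species == sp]
        n_total = len(sp_genes)
        n_intron = sum(1 for g in sp_genes if g.has_intron)
        ratio = 100.0 * n_intron / n_total if n_total else float("nan")
        rows.append(
            {"species": sp, "n_intron_genes": n_intron, "n_genes": n_total,
             "it_ratio_pct": ratio}
        )
    per_species = pd.DataFrame(
        rows, columns=["species", "n_intron_genes", "n_genes", "it_ratio_pct"]
    )

    lengths = [l for g in kept for l in g.intron_lengths]
    hist = Counter(lengths)
    mean_length = float(np.mean(lengths)) if lengths else None
    mode_length = None
    if hist:
        top = max(hist.values())
        mode_length = min(l for l, c in hist.items() if c == top)

    intron_genes = [g for g in kept if g.has_intron]
    iso_counts = Counter(g.isotype for g in intron_genes)
    n_ig = len(intron_genes)
    per_isotype = pd.DataFrame(
        [
            {"isotype": iso, "n_intron_genes": c,
             "fraction_pct": 100.0 * c / n_ig}
            for iso, c in sorted(iso_counts.items())
        ],
        columns=["isotype", "n_intron_genes", "fraction_pct"],
    )
    return IntronStats(
        per_species=per_species,
        length_hist=hist,
        mean_length=mean_length,
        mode_length=mode_length,
        per_isotype=per_isotype,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation plus the matching simple linear regression."""

    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def genome_size_correlation(
    gene_counts: Mapping[str, int], genome_sizes: Mapping[str, int]
) -> Optional[CorrelationResult]:
    """Correlate per-species gene counts with genome sizes.

    Pearson r with a two-sided p-value (t distribution, n-2 df) and the
    ordinary-least-squares slope/intercept/R^2 on the same pairs.  Species
    present in only one mapping are dropped.  Returns None when either
    variable has zero variance (the correlation is undefined); requires at
    least 3 shared species.
    """
    shared = sorted(set(gene_counts) & set(genome_sizes))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 species with both values, got {len(shared)}")
    x = np.array([float(genome_sizes[s]) for s in shared])
    y = np.array([float(gene_counts[s]) for s in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(shared),
    )


@dataclass
class LengthDistribution:
    """Integer histogram of gene lengths with min/max and all tied modes."""

    hist: Counter
    min_length: int
    max_length: int
    modes: Tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"length": l, "count": c} for l, c in sorted(self.hist.items())],
            columns=["length", "count"],
        )


def length_distribution(
    genes: Iterable[TRNAGene], spliced: bool = True, include_und: bool = False
) -> LengthDistribution:
    """Histogram of gene lengths; every tied mode is reported.

    By default lengths are of the mature (intron-spliced) sequence, which
    is the scale on which tRNA gene lengths are conventionally quoted;
    ``spliced=False`` measures the genomic span instead.
    """
    kept = _analysis_genes(genes, include_und)
    if not kept:
        raise ValueError("no genes to summarise")
    lengths = [
        len(splice_introns(g)) if spliced else g.length for g in kept
    ]
    hist = Counter(lengths)
    top = max(hist.values())
    modes = tuple(sorted(l for l, c in hist.items() if c == top))
    return LengthDistribution(
        hist=hist, min_length=min(lengths), max_length=max(lengths), modes=modes
    )
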