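"""End-to-end pipeline: simulate -> ingest -> stats -> tandem -> cluster -> report.

A :class:`RunConfig` carries every tunable with its analysis default; the
pipeline writes TSV/BED/JSON result tables plus a JSON manifest with the
config hash, input checksums and per-stage row counts.  Re-running an
identical config reproduces every output byte-for-byte (timings excepted,
which live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import align, stats, tandem
from .io import (
    AnnotationSet,
    load_annotation_dir,
    write_bed6,
    write_json,
    write_tsv,
)
from .simulate import SyntheticSpec, default_spec, generate_fixture, write_fixture

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest on disk records the partial run."""


@dataclass
class RunConfig:
    """All pipeline inputs and tunables.

    Exactly one of ``spec_path`` / ``annot_dir`` provides the input: a
    synthetic-fixture spec (JSON) to simulate, or a directory of
    tRNAscan-style tables plus genome FASTAs to ingest.  When both are
    None the built-in default fixture spec is used with ``seed``.
    """

    out_dir: str = "trnadup_out"
    spec_path: Optional[str] = None
    annot_dir: Optional[str] = None
    seed: int = 0
    window: int = 5
    step: int = 1
    n_bins: int = 100
    span: float = 0.75
    max_gap: int = 1000
    min_id: float = 0.90
    min_cov: float = 0.80
    include_und: bool = False
    modes: Tuple[str, ...] = ("identical", "all")

    def to_json(self, path) -> None:
        write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(config: RunConfig, out: Path) -> Tuple[AnnotationSet, dict]:
    if config.annot_dir is not None:
        annot = load_annotation_dir(config.annot_dir)
        return annot, {"genes": len(annot), "source": "ingest"}
    if config.spec_path is not None:
        if not Path(config.spec_path).exists():
            raise FileNotFoundError(f"spec file not found: {config.spec_path}")
        spec = SyntheticSpec.from_json(config.spec_path)
    else:
        spec = default_spec(seed=config.seed)
    fixture = generate_fixture(spec)
    fix_dir = out / "fixture"
    write_fixture(fixture, fix_dir)
    return fixture.annotation, {"genes": len(fixture.annotation), "source": "simulate"}


def _stage_ingest(config: RunConfig, out: Path) -> Tuple[AnnotationSet, dict]:
    src = config.annot_dir if config.annot_dir is not None else out / "fixture"
    annot = load_annotation_dir(src)
    return annot, {"genes": len(annot)}


def _stage_stats(config: RunConfig, annot: AnnotationSet, out: Path) -> dict:
    genes = annot.genes
    ab = stats.abundance_matrix(genes, include_und=config.include_und)
    abundance = ab.counts.reset_index().rename(columns={"index": "species"})
    write_tsv(abundance, out / "abundance_matrix.tsv")

    ist = stats.intron_stats(genes, include_und=config.include_und)
    write_tsv(ist.per_species, out / "intron_stats.tsv")
    hist = pd.DataFrame(
        [{"intron_length": l, "count": c} for l, c in sorted(ist.length_hist.items())],
        columns=["intron_length", "count"],
    )
    write_tsv(hist, out / "intron_length_hist.tsv")

    ld = stats.length_distribution(genes, include_und=config.include_und)
    write_tsv(ld.to_frame(), out / "length_hist.tsv")

    profiles = [
        stats.gc_profile(g.genomic_seq, config.window, config.step, source=g.gene_id)
        for g in genes
        if g.genomic_seq and len(g.genomic_seq) >= config.window
    ]
    agg = stats.aggregate_gc(profiles, n_bins=config.n_bins, span=config.span)
    write_tsv(agg.to_frame(), out / "gc_profile.tsv")

    corr = None
    if annot.assemblies:
        counts = {sp: int(n) for sp, n in ab.species_totals.items()}
        sizes = {sp: a.genome_size for sp, a in annot.assemblies.items()}
        if len(set(counts) & set(sizes)) >= 3:
            corr = stats.genome_size_correlation(counts, sizes)
    summary = {
        "n_genes": len(genes),
        "n_species": len(annot.species()),
        "absent_anticodons": list(ab.absent),
        "n_absent_anticodons": len(ab.absent),
        "intron_mode_bp": ist.mode_length,
        "intron_mean_bp": ist.mean_length,
        "length_modes": list(ld.modes),
        "genome_size_correlation": asdict(corr) if corr else None,
    }
    write_json(summary, out / "stats_summary.json")
    return {
        "abundance_rows": len(abundance),
        "intron_rows": len(ist.per_species),
        "gc_rows": len(agg.position),
    }


def _stage_tandem(config: RunConfig, annot: AnnotationSet, out: Path) -> dict:
    pairs = tandem.proximal_pairs(annot, max_gap=config.max_gap)
    pairs, pair_summary = tandem.classify_pairs(pairs, annot)
    write_tsv(tandem.pairs_to_frame(pairs), out / "pairs.tsv")
    rows: Dict[str, int] = {"pairs": len(pairs)}
    cluster_summaries = {}
    for mode in config.modes:
        clusters = tandem.chain_clusters(pairs, annot, mode=mode)
        write_tsv(tandem.clusters_to_frame(clusters), out / f"clusters_{mode}.tsv")
        write_bed6(
            [
                (c.seq_id, c.start, c.end, c.cluster_id, c.n_genes, ".")
                for c in clusters
            ],
            out / f"clusters_{mode}.bed",
        )
        rows[f"clusters_{mode}"] = len(clusters)
        cluster_summaries[mode] = {
            "n_clusters": len(clusters),
            "n_genes": sum(c.n_genes for c in clusters),
            "max_cluster_size": max((c.n_genes for c in clusters), default=0),
        }
    kept, per_aa, per_species = tandem.degenerate_anticodon_pairs(pairs)
    write_tsv(per_aa, out / "degenerate_anticodon_pairs.tsv")
    rows["degenerate_pairs"] = len(kept)
    write_json(
        {
            "pair_summary": pair_summary,
            "clusters": cluster_summaries,
            "degenerate_pairs": {
                "n_pairs": len(kept),
                "per_species": dict(sorted(per_species.items())),
            },
        },
        out / "tandem_summary.json",
    )
    return rows


def _stage_cluster(config: RunConfig, annot: AnnotationSet, out: Path) -> dict:
    uniq = align.unique_sequences([g for g in annot.genes if g.genomic_seq])
    write_tsv(
        pd.DataFrame(
            [
                {
                    "name": u.name,
                    "isotype": u.isotype,
                    "anticodon": u.anticodon,
                    "n_members": len(u.member_ids),
                    "length": len(u.sequence),
                }
                for u in uniq
            ],
            columns=["name", "isotype", "anticodon", "n_members", "length"],
        ),
        out / "unique_sequences.tsv",
    )
    seqs = {u.name: u.sequence for u in uniq}
    clusters = align.greedy_cluster(seqs, min_id=config.min_id, min_cov=config.min_cov)
    write_tsv(
        pd.DataFrame(
            [
                {"representative": c.representative, "size": c.size,
                 "members": ",".join(c.members)}
                for c in clusters
            ],
            columns=["representative", "size", "members"],
        ),
        out / "greedy_clusters.tsv",
    )
    return {"unique_sequences": len(uniq), "greedy_clusters": len(clusters)}


def _stage_report(config: RunConfig, out: Path) -> dict:
    report = {}
    for name in ("stats_summary.json", "tandem_summary.json"):
        p = out / name
        if p.exists():
            report[name.replace(".json", "")] = json.loads(p.read_text())
    write_json(report, out / "report.json")
    return {"sections": len(report)}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the manifest; returns the manifest dict.

    Any stage error aborts with :class:`PipelineError` after writing a
    partial manifest marking the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
        "outputs": {},
    }
    annot: Optional[AnnotationSet] = None

    stage_fns = [
        ("simulate", lambda: _stage_simulate(config, out)),
        ("ingest", lambda: _stage_ingest(config, out)),
        ("stats", lambda: _stage_stats(config, annot, out)),
        ("tandem", lambda: _stage_tandem(config, annot, out)),
        ("cluster", lambda: _stage_cluster(config, annot, out)),
        ("report", lambda: _stage_report(config, out)),
    ]
    for name, fn in stage_fns:
        t0 = time.monotonic()
        logger.info("[%s] starting", name)
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"].append(
                {"name": name, "status": "failed", "error": str(exc),
                 "elapsed_s": round(time.monotonic() - t0, 3)}
            )
            write_json(manifest, out / "manifest.json")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        if name in ("simulate", "ingest"):
            annot, rows = result
        else:
            rows = result
        manifest["stages"].append(
            {"name": name, "status": "ok", "rows": rows,
             "elapsed_s": round(time.monotonic() - t0, 3)}
        )
        logger.info("[%s] done (%s)", name, rows)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    write_json(manifest, out / "manifest.json")
    return manifest
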