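"""End-to-end orchestration: map -> call loci -> quantify -> classify ->
sequence features -> cleavage scan -> enrichment -> report.

The in-memory entry point is :func:`analyze_libraries`; :func:`run_pipeline`
wraps it with file I/O (FASTA genome, GFF3 annotation, per-library read
FASTA/FASTQ, TSV/JSON outputs) and writes a manifest recording every
threshold actually used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cleavage import CleavageModelConfig, consistency_score
from .depclass import ClassifierConfig, classify_all, summarize_classes
from .enrich import kog_enrichment
from .ioutils import (
    ensure_dir,
    read_fasta,
    read_gff3,
    read_reads,
    write_bed,
    write_tsv,
)
from .locus import LocusCallerConfig, abundance_matrix, annotate_loci, call_loci
from .readmap import build_index, collapse_reads, map_reads
from .seqfeat import (
    five_prime_u_fraction,
    penultimate_u_statistic,
    positional_composition,
    purine_skew,
    size_distribution,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "analyze_libraries", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome_path: str
    annotation_path: str
    #: library_id -> reads file (FASTA/FASTQ)
    reads: dict = field(default_factory=dict)
    #: library_id -> genotype label (identity if omitted for a library)
    genotype_map: dict = field(default_factory=dict)
    out_dir: str = "rdrnascan_out"
    locus: LocusCallerConfig = field(default_factory=LocusCallerConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cleavage: CleavageModelConfig = field(default_factory=CleavageModelConfig)
    flank_width: int = 5
    size_window: tuple = (18, 25)
    max_mismatches: int = 0
    multimap_policy: str = "fractional"
    seed: int = 0


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"stage '{name}' failed: {e}") from e
        return wrapper
    return deco


def _reads_in_transcript_coords(reads: pd.DataFrame, fstart: int, fend: int, fstrand: str):
    """Convert genomic placements to transcript coordinates of one feature."""
    out = []
    for r in reads.itertuples(index=False):
        if r.start < fstart or r.end > fend:
            continue  # read pokes out of the annotated feature
        if fstrand == "+":
            s, e = r.start - fstart, r.end - fstart
            strand = "+" if r.strand == "+" else "-"
        else:
            s, e = fend - r.end, fend - r.start
            strand = "+" if r.strand == "-" else "-"
        out.append((s, e, strand, float(r.weight)))
    return out


def analyze_libraries(
    genome: dict,
    features: pd.DataFrame,
    libraries: dict,
    genotype_map: dict | None = None,
    locus_config: LocusCallerConfig = LocusCallerConfig(),
    classifier_config: ClassifierConfig = ClassifierConfig(),
    cleavage_config: CleavageModelConfig = CleavageModelConfig(),
    flank_width: int = 5,
    size_window: tuple = (18, 25),
    max_mismatches: int = 0,
    multimap_policy: str = "fractional",
) -> dict:
    """Run the full analysis on in-memory inputs.

    Parameters
    ----------
    libraries
        library_id -> collapsed read table (columns sequence, count,
        library_id) as produced by :func:`rdrnascan.readmap.collapse_reads`.
    genotype_map
        library_id -> genotype; the mapped genotypes must include ``WT``
        and the six mutant contrasts used by the classifier.

    Returns a dict of all stage outputs (mapped reads, loci, abundance
    matrix, per-locus calls, summary tables, composition profiles,
    cleavage reports, enrichment table, per-stage stats).
    """
    genotype_map = dict(genotype_map or {})
    for lib in libraries:
        genotype_map.setdefault(lib, lib)
    if "WT" not in set(genotype_map.values()):
        raise StageError("stage 'configure' failed: no library maps to genotype 'WT'")

    # -- map ---------------------------------------------------------------
    @_stage("map")
    def _map():
        index = build_index(genome)
        frames = []
        stats = []
        for lib_id in sorted(libraries):
            m, s = map_reads(
                libraries[lib_id],
                index,
                max_mismatches=max_mismatches,
                multimap_policy=multimap_policy,
                length_window=size_window,
            )
            frames.append(m)
            s["library_id"] = lib_id
            stats.append(s)
        mapped = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        return mapped, pd.DataFrame(stats)

    mapped, map_stats = _map()

    # -- call loci + annotate ---------------------------------------------
    @_stage("call-loci")
    def _call():
        loci, mapped_out = call_loci(mapped, locus_config)
        loci = annotate_loci(loci, features, valid_contigs=set(genome))
        return loci, mapped_out

    loci, mapped = _call()

    # -- quantify ----------------------------------------------------------
    @_stage("quantify")
    def _quant():
        return abundance_matrix(loci, mapped)

    matrix, loci2 = _quant()

    # -- classify ----------------------------------------------------------
    @_stage("classify")
    def _classify():
        rpm_g = matrix.rpm.rename(columns=genotype_map)
        # two libraries mapping to one genotype would collide silently
        if rpm_g.columns.duplicated().any():
            dup = rpm_g.columns[rpm_g.columns.duplicated()].tolist()
            raise ValueError(f"multiple libraries map to genotype(s) {dup}")
        calls = classify_all(rpm_g, config=classifier_config)
        summaries = summarize_classes(calls, loci2)
        return calls, summaries

    calls, summaries = _classify()

    # -- sequence features -------------------------------------------------
    @_stage("features")
    def _features():
        rd_ids = set(calls.loc[calls["class_label"].str.startswith("rdRNA"), "locus_id"])
        ex_ids = set(calls.loc[calls["class_label"].str.startswith("exsiRNA"), "locus_id"])
        out = {}
        for name, ids in (("rdRNA", rd_ids), ("exsiRNA", ex_ids)):
            sub = mapped[mapped["locus_id"].isin(ids)]
            if len(sub) == 0:
                out[name] = {"n_loci": 0}
                continue
            pu_frac, pu_enr = penultimate_u_statistic(sub)
            stats = {
                "n_loci": len(ids),
                "size_distribution": {int(k): v for k, v in size_distribution(sub).items()},
                "penultimate_u_fraction": pu_frac,
                "penultimate_u_enrichment": pu_enr,
                "five_prime_u_fraction": five_prime_u_fraction(sub),
                "purine_fraction": purine_skew(sub),
            }
            out[name] = stats
        profiles = {}
        rd = mapped[mapped["locus_id"].isin(rd_ids)]
        lo, hi = size_window
        for L in range(lo, hi + 1):
            prof = positional_composition(rd, genome, flank_width, L)
            if not prof.empty:
                profiles[L] = prof
        return out, profiles

    feature_stats, profiles = _features()

    # -- cleavage scan (per classified rdRNA locus) -------------------------
    @_stage("cleavage-scan")
    def _cleave():
        rows = []
        feat_idx = features.set_index("feature_id")
        rd = calls[calls["class_label"].str.startswith("rdRNA")]
        loc_idx = loci2.set_index("locus_id")
        for rec in rd.itertuples(index=False):
            loc = loc_idx.loc[rec.locus_id]
            fid = loc["feature_id"]
            if not fid or fid not in feat_idx.index:
                continue
            f = feat_idx.loc[fid]
            tseq = genome[f["contig"]][f["start"] : f["end"]]
            if f["strand"] == "-":
                tseq = tseq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
            reads = mapped[mapped["locus_id"] == rec.locus_id]
            treads = _reads_in_transcript_coords(
                reads, int(f["start"]), int(f["end"]), f["strand"]
            )
            rep = consistency_score(treads, tseq, cleavage_config)
            d = rep.to_dict()
            d["locus_id"] = rec.locus_id
            d["feature_id"] = fid
            rows.append(d)
        cols = [
            "locus_id", "feature_id", "n_cut_sites", "n_reads", "n_antisense",
            "frac_five_prime_at_cut", "frac_three_prime_at_cut",
            "frac_penultimate_u", "score",
        ]
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)

    cleavage_table = _cleave()

    # -- enrichment ---------------------------------------------------------
    @_stage("enrich")
    def _enrich():
        exons = features[features["category"] == "exon"]
        ann = exons.rename(columns={"feature_id": "gene_id"})[["gene_id", "kog_class"]]
        rd = calls[calls["class_label"].str.startswith("rdRNA")]
        regulated = sorted(
            set(loci2.set_index("locus_id").loc[rd["locus_id"], "feature_id"]) - {""}
        )
        regulated = [g for g in regulated if g in set(ann["gene_id"])]
        if not regulated:
            return pd.DataFrame()
        return kog_enrichment(regulated, ann)

    enrichment = _enrich()

    return {
        "mapped": mapped,
        "map_stats": map_stats,
        "loci": loci2,
        "matrix": matrix,
        "calls": calls,
        "summaries": summaries,
        "feature_stats": feature_stats,
        "profiles": profiles,
        "cleavage": cleavage_table,
        "enrichment": enrichment,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """File-based pipeline run; returns the report directory.

    Reads the genome (FASTA), annotation (GFF3) and one reads file per
    library, runs :func:`analyze_libraries`, and writes loci (BED6+),
    abundance matrix, per-locus calls, class summaries, composition
    profiles, cleavage reports, enrichment table and a manifest.  Rerunning
    with identical inputs produces byte-identical outputs.
    """
    out = ensure_dir(config.out_dir)

    @_stage("load-inputs")
    def _load():
        genome = read_fasta(config.genome_path)
        features = read_gff3(config.annotation_path)
        libraries = {}
        for lib_id, path in sorted(config.reads.items()):
            raw = read_reads(path)
            collapsed, _ = collapse_reads(raw, lib_id)
            libraries[lib_id] = collapsed
        return genome, features, libraries

    genome, features, libraries = _load()

    res = analyze_libraries(
        genome,
        features,
        libraries,
        genotype_map=config.genotype_map,
        locus_config=config.locus,
        classifier_config=config.classifier,
        cleavage_config=config.cleavage,
        flank_width=config.flank_width,
        size_window=tuple(config.size_window),
        max_mismatches=config.max_mismatches,
        multimap_policy=config.multimap_policy,
    )

    @_stage("report")
    def _report():
        loci = res["loci"].copy()
        loci["strand_bias"] = loci["strand_bias"].round(6)
        write_bed(
            loci.assign(n_reads=loci["n_reads"].round(3)),
            out / "loci.bed",
            name_col="locus_id",
            score_col="n_reads",
            strand_col="feature_strand",
            extra_cols=["category", "feature_id", "strand_bias"],
        )
        write_tsv(
            loci.drop(columns=["length_hist"]),
            out / "loci.tsv",
        )
        write_tsv(res["matrix"].rpm, out / "abundance_rpm.tsv", index=True)
        write_tsv(res["matrix"].raw, out / "abundance_raw.tsv", index=True)
        write_tsv(res["calls"], out / "calls.tsv")
        write_tsv(res["map_stats"], out / "mapping_stats.tsv")
        write_tsv(
            res["summaries"]["dependency_by_category"],
            out / "dependency_by_category.tsv",
            index=True,
        )
        write_tsv(res["summaries"]["r3b2_by_class"], out / "r3b2_by_class.tsv")
        write_tsv(res["summaries"]["heatmap"], out / "log2fc_heatmap.tsv", index=True)
        for L, prof in res["profiles"].items():
            write_tsv(prof.matrix, out / f"composition_{L}nt.tsv", index=True)
        write_tsv(res["cleavage"], out / "cleavage_reports.tsv")
        if len(res["enrichment"]):
            write_tsv(res["enrichment"], out / "enrichment.tsv")
        with open(out / "feature_stats.json", "w") as fh:
            json.dump(res["feature_stats"], fh, indent=2, sort_keys=True)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "genome": str(config.genome_path),
            "annotation": str(config.annotation_path),
            "libraries": {k: str(v) for k, v in sorted(config.reads.items())},
            "genotype_map": dict(sorted(config.genotype_map.items())),
            "parameters": {
                "locus": asdict(config.locus),
                "classifier": asdict(config.classifier),
                "cleavage": asdict(config.cleavage),
                "flank_width": config.flank_width,
                "size_window": list(config.size_window),
                "max_mismatches": config.max_mismatches,
                "multimap_policy": config.multimap_policy,
            },
            "tallies": {
                "n_loci": int(len(res["loci"])),
                "n_classified": int(
                    (res["calls"]["class_label"] != "unclassified").sum()
                )
                if len(res["calls"])
                else 0,
                "mapped_weight": {
                    r["library_id"]: r["mapped_weight"]
                    for r in res["map_stats"].to_dict("records")
                },
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return out

    return _report()
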