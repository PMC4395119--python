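"""sRNA locus calling, annotation, and RPM quantification.

Loci are the single-linkage clusters of mapped read intervals: reads on
either strand belong to one locus when consecutive reads (sorted by start)
lie within a configurable gap (200 bp by default) of the running cluster
end.  Pooling reads across all libraries before clustering guarantees that
every genotype contrast is evaluated on identical locus boundaries.

Each locus is assigned an annotation category with priority
exon > transposon > intergenic (among equal-priority overlaps the feature
with the largest overlap wins, ties to the smaller feature start), and
quantified as reads per million mapped reads (RPM) per library.  Strand
bias within a locus is (sense - antisense) / (sense + antisense) read
weight relative to the assigned feature's strand; +1 means all reads are
sense to the mRNA.  For intergenic loci the reference strand is '+' by
convention (flagged arbitrary in the output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocusCallerConfig",
    "AbundanceMatrix",
    "call_loci",
    "annotate_loci",
    "abundance_matrix",
]


@dataclass(frozen=True)
class LocusCallerConfig:
    #: maximum end-to-start distance (nt, inclusive) for two reads to share a locus
    gap: int = 200
    #: minimum total read weight for a cluster to be reported
    min_reads_per_locus: float = 2
    #: seed-index / mapping window bookkeeping lives upstream

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


@dataclass
class AbundanceMatrix:
    """Loci x libraries abundance, RPM-normalised to mapped library totals."""

    rpm: pd.DataFrame  # index locus_id, columns library_id
    raw: pd.DataFrame  # same shape, raw weights
    totals: pd.Series  # per-library total mapped weight


def call_loci(
    mapped: pd.DataFrame, config: LocusCallerConfig = LocusCallerConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster pooled mapped reads into loci.

    Parameters
    ----------
    mapped
        Placement table pooled across libraries (columns contig, start,
        end, strand, weight, ...).  Strands are pooled.

    Returns
    -------
    loci
        DataFrame with locus_id, contig, start, end (union span of member
        reads), n_reads (total weight); ids ordered by coordinate.
    mapped_out
        Copy of ``mapped`` with a ``locus_id`` column (NA for reads in
        clusters below ``min_reads_per_locus``).

    Clustering is order-independent: with reads sorted by (contig, start),
    read *i* opens a new cluster iff its start exceeds the running maximum
    end of all previous reads on the contig by more than ``gap``; this is
    exactly the transitive closure of the pairwise "within gap" relation.
    """
    out = mapped.copy()
    if len(mapped) == 0:
        loci = pd.DataFrame(columns=["locus_id", "contig", "start", "end", "n_reads"])
        out["locus_id"] = pd.Series(dtype=object)
        return loci, out

    order = np.lexsort((mapped["start"].to_numpy(), mapped["contig"].to_numpy()))
    df = pd.DataFrame(
        {
            "contig": mapped["contig"].to_numpy()[order],
            "start": mapped["start"].to_numpy()[order],
            "end": mapped["end"].to_numpy()[order],
            "weight": mapped["weight"].to_numpy()[order],
        }
    )
    # running maximum end of all earlier reads on the same contig; a read
    # opens a new cluster iff its start exceeds it by more than `gap`
    prev_cm = df.groupby("contig", sort=False)["end"].cummax().groupby(
        df["contig"], sort=False
    ).shift(1)
    breaks = prev_cm.isna() | (df["start"] - prev_cm > config.gap)
    cluster = breaks.cumsum().to_numpy() - 1
    df["cluster"] = cluster
    agg = df.groupby("cluster").agg(
        contig=("contig", "first"),
        start=("start", "min"),
        end=("end", "max"),
        n_reads=("weight", "sum"),
    )
    keep = agg[agg["n_reads"] >= config.min_reads_per_locus].copy()
    keep = keep.sort_values(["contig", "start"])
    keep["locus_id"] = [f"locus_{i+1:05d}" for i in range(len(keep))]
    cluster_to_id = keep["locus_id"].to_dict()

    locus_col = np.array([cluster_to_id.get(c) for c in cluster], dtype=object)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    out["locus_id"] = locus_col[inv]

    loci = keep.reset_index(drop=True)[["locus_id", "contig", "start", "end", "n_reads"]]
    return loci, out


def annotate_loci(
    loci: pd.DataFrame,
    features: pd.DataFrame,
    valid_contigs=None,
) -> pd.DataFrame:
    """Assign each locus a category and best-overlapping feature.

    ``features`` needs columns feature_id, contig, start, end, strand,
    category (exon/transposon); loci overlapping no feature are intergenic.
    Priority: exon beats transposon regardless of overlap length; within a
    category the largest overlap wins, ties to the smaller feature start.

    Raises ``ValueError`` naming the contig if a locus lies on a contig
    absent from ``valid_contigs`` (when provided).
    """
    if valid_contigs is not None:
        unknown = set(loci["contig"]) - set(valid_contigs)
        if unknown:
            raise ValueError(f"loci on unknown contig(s): {sorted(unknown)}")

    prio = {"exon": 0, "transposon": 1}
    cats, fids, fstrands = [], [], []
    by_contig = {c: g for c, g in features.groupby("contig")}
    for row in loci.itertuples(index=False):
        best = None  # (priority, -overlap, feature_start, feature_id, strand, category)
        g = by_contig.get(row.contig)
        if g is not None:
            fs = g["start"].to_numpy()
            fe = g["end"].to_numpy()
            ov = np.minimum(row.end, fe) - np.maximum(row.start, fs)
            hit = np.nonzero(ov > 0)[0]
            for j in hit:
                rec = g.iloc[j]
                key = (prio[rec["category"]], -int(ov[j]), int(rec["start"]))
                if best is None or key < best[0]:
                    best = (key, rec["feature_id"], rec["strand"], rec["category"])
        if best is None:
            cats.append("intergenic")
            fids.append("")
            fstrands.append("+")
        else:
            cats.append(best[3])
            fids.append(best[1])
            fstrands.append(best[2])
    out = loci.copy()
    out["category"] = cats
    out["feature_id"] = fids
    out["feature_strand"] = fstrands
    return out


def abundance_matrix(
    loci: pd.DataFrame,
    mapped: pd.DataFrame,
    library_totals: dict | None = None,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Quantify loci as RPM per library and compute per-locus strand bias.

    ``mapped`` must carry locus_id (from :func:`call_loci`) and library_id;
    placements outside any kept locus still contribute to the library
    total, which is the RPM denominator (total genome-mapped weight).
    ``library_totals`` overrides the denominators (e.g. when quantifying a
    locus subset).  A zero-total library is an error.

    Returns the :class:`AbundanceMatrix` and a copy of ``loci`` extended
    with strand_bias and a read-length histogram.
    """
    if library_totals is None:
        library_totals = mapped.groupby("library_id")["weight"].sum().to_dict()
    totals = pd.Series(library_totals, dtype=float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero mapped weight in library(ies): {list(zero.index)}")

    inloc = mapped[mapped["locus_id"].notna()]
    raw = (
        inloc.pivot_table(
            index="locus_id", columns="library_id", values="weight", aggfunc="sum", fill_value=0.0
        )
        .reindex(index=loci["locus_id"], columns=totals.index, fill_value=0.0)
    )
    rpm = raw * 1e6 / totals

    # strand bias and length histogram relative to the assigned feature
    fstrand = loci.set_index("locus_id")["feature_strand"] if "feature_strand" in loci else None
    bias = []
    hists = []
    grouped = {k: g for k, g in inloc.groupby("locus_id")}
    for row in loci.itertuples(index=False):
        g = grouped.get(row.locus_id)
        if g is None or len(g) == 0:
            bias.append(np.nan)
            hists.append({})
            continue
        ref = fstrand.loc[row.locus_id] if fstrand is not None else "+"
        w = g["weight"].to_numpy()
        sense = (g["strand"].to_numpy() == ref)
        ws = float(w[sense].sum())
        wa = float(w[~sense].sum())
        bias.append((ws - wa) / (ws + wa))
        lens = (g["end"] - g["start"]).to_numpy()
        h: dict = {}
        for L, wi in zip(lens, w):
            h[int(L)] = h.get(int(L), 0.0) + float(wi)
        hists.append(h)
    out = loci.copy()
    out["strand_bias"] = bias
    out["length_hist"] = hists
    return AbundanceMatrix(rpm=rpm, raw=raw, totals=totals), out
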