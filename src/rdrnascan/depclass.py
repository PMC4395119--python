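"""Genetic-dependency classification of sRNA loci.

Each locus is compared between every mutant library and wild type by log2
fold change of RPM.  A locus is *depleted* in a contrast when the fold
change is at or below minus the threshold (fourfold, i.e. log2 FC <= -2,
by default) and *unchanged* when |log2 FC| is inside the no-change band.
Loci whose wild-type abundance does not pass the 50-RPM floor are excluded
from classification.

Class assignment (most specific genotype pattern first):

* Dicer-dependent loci (depleted in dcl1, dcl2 or the double mutant):
  - class IV: depleted in dcl1, unchanged in dcl2;
  - class III: unchanged in each single dcl mutant but depleted in the
    double mutant, and depleted in both rdrp1 and rdrp2;
  - class II: depleted in dcl2 and in rdrp1;
  - class I: depleted in dcl2, unchanged in rdrp1.
* Dicer-independent loci (unchanged in all three dcl contrasts) depleted
  in rdrp1 and/or rdrp2 are rdRNA loci, subtyped by which rdrp contrasts
  are depleted.
* Everything else is unclassified.

Separately, a locus is r3b2-dependent when depleted in the r3b2 contrast,
and Ago-1-bound when the wild-type Ago-1 immunoprecipitate is enriched at
least fourfold over the ago-1 mutant IP (log2 FC >= +2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierConfig",
    "DependencyCall",
    "log2_fold_change",
    "classify_locus",
    "classify_all",
    "summarize_classes",
    "CLASS_ORDER",
]

#: mutant contrasts against WT required for classification
CONTRASTS = ("dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2", "r3b2")

CLASS_ORDER = (
    "rdRNA-rdrp1",
    "rdRNA-rdrp2",
    "rdRNA-both",
    "exsiRNA-I",
    "exsiRNA-II",
    "exsiRNA-III",
    "exsiRNA-IV",
    "unclassified",
)


@dataclass(frozen=True)
class ClassifierConfig:
    #: wild-type RPM floor; loci at or below are excluded (strict >)
    wt_min_rpm: float = 50.0
    #: depletion threshold in log2 units (2 = fourfold)
    fc_threshold: float = 2.0
    #: "no significant change" band: |log2 FC| < no_change_band
    no_change_band: float = 2.0
    #: pseudocount added to both RPM values before the ratio
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if self.wt_min_rpm < 0:
            raise ValueError("wt_min_rpm must be >= 0")


@dataclass
class DependencyCall:
    """Per-locus contrast fold changes, flags, and the assigned class."""

    locus_id: str
    log2fc: dict  # contrast -> extended real (may be -inf / nan)
    depleted: dict  # contrast -> bool
    unchanged: dict  # contrast -> bool
    class_label: str
    r3b2_dependent: bool
    ago1_bound: bool


def log2_fold_change(mut_rpm: float, wt_rpm: float, pseudocount: float = 0.0) -> float:
    """log2((mut + pc) / (wt + pc)).

    With zero pseudocount: mut = 0, wt > 0 gives -inf (complete depletion);
    both zero gives NaN (not applicable — the locus is absent from both
    libraries and is excluded from that contrast).
    """
    if mut_rpm < 0 or wt_rpm < 0:
        raise ValueError("RPM values must be >= 0")
    m = mut_rpm + pseudocount
    w = wt_rpm + pseudocount
    if w == 0 and m == 0:
        return math.nan
    if m == 0:
        return -math.inf
    if w == 0:
        return math.inf
    return math.log2(m / w)


def _flags(fc: float, config: ClassifierConfig) -> tuple[bool, bool]:
    """(depleted, unchanged) for one contrast's log2 fold change."""
    if math.isnan(fc):
        return False, False
    depleted = fc <= -config.fc_threshold
    unchanged = abs(fc) < config.no_change_band
    return depleted, unchanged


def classify_locus(
    rpm_row,
    config: ClassifierConfig = ClassifierConfig(),
    locus_id: str = "",
) -> DependencyCall:
    """Classify one locus from its per-genotype RPM values.

    ``rpm_row`` is a mapping (or Series) genotype -> RPM; it must contain
    ``WT`` and all of dcl1, dcl2, dcl1dcl2, rdrp1, rdrp2, r3b2.  The Ago-1
    IP pair (WT_ago1ip, ago1_ago1ip) is optional; without it,
    ``ago1_bound`` is False.
    """
    missing = [g for g in ("WT", *CONTRASTS) if g not in rpm_row]
    if missing:
        raise ValueError(f"missing required libraries: {missing}")
    wt = float(rpm_row["WT"])

    fc = {c: log2_fold_change(float(rpm_row[c]), wt, config.pseudocount) for c in CONTRASTS}
    dep = {}
    unch = {}
    for c in CONTRASTS:
        dep[c], unch[c] = _flags(fc[c], config)

    ago1_bound = False
    if "WT_ago1ip" in rpm_row and "ago1_ago1ip" in rpm_row:
        fc_ip = log2_fold_change(
            float(rpm_row["WT_ago1ip"]), float(rpm_row["ago1_ago1ip"]), config.pseudocount
        )
        fc["ago1ip"] = fc_ip
        ago1_bound = (not math.isnan(fc_ip)) and fc_ip >= config.fc_threshold

    label = _assign_class(dep, unch, wt, config)
    return DependencyCall(
        locus_id=locus_id,
        log2fc=fc,
        depleted=dep,
        unchanged=unch,
        class_label=label,
        r3b2_dependent=dep["r3b2"],
        ago1_bound=ago1_bound,
    )


def _assign_class(dep: dict, unch: dict, wt_rpm: float, config: ClassifierConfig) -> str:
    """Pure rule table mapping depletion/unchanged flags to a class label."""
    if not wt_rpm > config.wt_min_rpm:
        return "unclassified"
    dicer_dependent = dep["dcl1"] or dep["dcl2"] or dep["dcl1dcl2"]
    if dicer_dependent:
        if dep["dcl1"] and unch["dcl2"]:
            return "exsiRNA-IV"
        if (
            unch["dcl1"]
            and unch["dcl2"]
            and dep["dcl1dcl2"]
            and dep["rdrp1"]
            and dep["rdrp2"]
        ):
            return "exsiRNA-III"
        if dep["dcl2"] and dep["rdrp1"]:
            return "exsiRNA-II"
        if dep["dcl2"] and unch["rdrp1"]:
            return "exsiRNA-I"
        return "unclassified"
    if unch["dcl1"] and unch["dcl2"] and unch["dcl1dcl2"]:
        if dep["rdrp1"] and dep["rdrp2"]:
            return "rdRNA-both"
        if dep["rdrp1"]:
            return "rdRNA-rdrp1"
        if dep["rdrp2"]:
            return "rdRNA-rdrp2"
    return "unclassified"


def classify_all(
    rpm: pd.DataFrame,
    genotype_map: dict | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Classify every locus of an RPM matrix (index loci, columns libraries).

    ``genotype_map`` renames library columns to genotype labels first
    (identity if omitted).  Returns a per-locus table with one row per
    locus: the class label, flags, and the log2 fold change of every
    contrast.
    """
    mat = rpm.rename(columns=genotype_map) if genotype_map else rpm
    rows = []
    for locus_id, row in mat.iterrows():
        call = classify_locus(row, config, locus_id=str(locus_id))
        rec = {
            "locus_id": call.locus_id,
            "class_label": call.class_label,
            "r3b2_dependent": call.r3b2_dependent,
            "ago1_bound": call.ago1_bound,
            "wt_rpm": float(row["WT"]),
        }
        for c, v in call.log2fc.items():
            rec[f"log2fc_{c}"] = v
        for c in CONTRASTS:
            rec[f"depleted_{c}"] = call.depleted[c]
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_classes(
    calls: pd.DataFrame, loci: pd.DataFrame | None = None
) -> dict:
    """Build the class-summary tables and the per-locus heat-map matrix.

    Returns a dict with:

    * ``dependency_by_category`` — counts of classified loci by annotation
      category (transposon / intergenic / exon) x rdrp dependency
      (rdrp1-only / rdrp2-only / both), each cell "total (dicer-independent)"
      split into ``*_total`` and ``*_dicer_independent`` columns;
    * ``r3b2_by_class`` — per class: locus count, percent r3b2-dependent,
      and mean finite log2 FC in the r3b2 contrast;
    * ``heatmap`` — per-locus log2 FC matrix over all contrasts.
    """
    # (a) category x rdrp-dependency accounting
    cats = ("transposon", "intergenic", "exon")
    deps = ("rdrp1_only", "rdrp2_only", "both")
    table1 = pd.DataFrame(0, index=list(cats) + ["total"], columns=[
        f"{d}_{s}" for d in deps for s in ("total", "dicer_independent")
    ])
    if loci is not None and len(calls):
        merged = calls.merge(
            loci[["locus_id", "category"]], on="locus_id", how="left"
        )
    else:
        merged = calls.assign(category="exon") if len(calls) else calls
    for rec in merged.itertuples(index=False) if len(merged) else []:
        d1 = rec.depleted_rdrp1
        d2 = rec.depleted_rdrp2
        if not (d1 or d2):
            continue
        dkey = "both" if (d1 and d2) else ("rdrp1_only" if d1 else "rdrp2_only")
        dicer_indep = rec.class_label.startswith("rdRNA")
        cat = rec.category if rec.category in cats else "intergenic"
        for r in (cat, "total"):
            table1.loc[r, f"{dkey}_total"] += 1
            if dicer_indep:
                table1.loc[r, f"{dkey}_dicer_independent"] += 1

    # (b) per-class r3b2 dependence
    rows = []
    for label in CLASS_ORDER:
        sub = calls[calls["class_label"] == label] if len(calls) else calls
        n = len(sub)
        n_dep = int(sub["r3b2_dependent"].sum()) if n else 0
        finite = (
            sub["log2fc_r3b2"].replace([np.inf, -np.inf], np.nan).dropna()
            if n
            else pd.Series(dtype=float)
        )
        rows.append(
            {
                "class_label": label,
                "n_loci": n,
                "n_r3b2_dependent": n_dep,
                "pct_r3b2_dependent": round(100.0 * n_dep / n, 1) if n else 0.0,
                "mean_log2fc_r3b2": float(finite.mean()) if len(finite) else np.nan,
            }
        )
    table2 = pd.DataFrame(rows)

    # (c) heat-map matrix of per-locus fold changes
    fc_cols = [c for c in calls.columns if c.startswith("log2fc_")] if len(calls) else []
    heatmap = (
        calls.set_index("locus_id")[fc_cols]
        if len(calls)
        else pd.DataFrame(columns=[f"log2fc_{c}" for c in CONTRASTS])
    )
    return {
        "dependency_by_category": table1,
        "r3b2_by_class": table2,
        "heatmap": heatmap,
    }
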