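"""Functional-category (KOG) enrichment with Yates-corrected chi-squared.

A regulated gene set (genes owning at least one rdRNA locus, deduplicated
by gene) is compared per category against the genome background with
Pearson's chi-squared test on the 2x2 table

    a = regulated in category      b = regulated not in category
    c = background in category     d = background not in category

using Yates' continuity correction: each cell contributes
``max(|O - E| - 0.5, 0)^2 / E`` (the correction term is floored at zero
when |O - E| < 0.5).  The p-value comes from the chi-squared distribution
with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2

__all__ = ["EnrichmentResult", "yates_chi_square", "kog_enrichment"]


@dataclass
class EnrichmentResult:
    category: str
    a: int  # regulated in category
    b: int  # regulated not in category
    c: int  # background in category
    d: int  # background not in category
    regulated_pct: float
    background_pct: float
    statistic: float
    p_value: float
    direction: str  # "enriched" | "depleted" | "none"


def yates_chi_square(
    a: int, b: int, c: int, d: int, correction: bool = True
) -> tuple[float, float]:
    """Continuity-corrected chi-squared statistic and p-value for a 2x2 table.

    Expected counts come from the margins; with ``correction=False`` the
    uncorrected Pearson statistic is returned.  Raises ``ValueError`` on
    negative counts or a zero margin.
    """
    obs = [a, b, c, d]
    if any(x < 0 for x in obs):
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("both margins of the 2x2 table must be > 0")
    expected = [r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n]
    stat = 0.0
    for o, e in zip(obs, expected):
        diff = abs(o - e)
        if correction:
            diff = max(diff - 0.5, 0.0)
        stat += diff * diff / e
    p = float(chi2.sf(stat, df=1))
    return stat, p


def kog_enrichment(
    regulated_genes,
    annotation: pd.DataFrame,
    correction: bool = True,
    not_annotated_label: str = "not annotated",
) -> pd.DataFrame:
    """Per-category enrichment of a regulated gene set vs the genome.

    Parameters
    ----------
    regulated_genes
        Iterable of gene ids (deduplicated internally).
    annotation
        DataFrame with columns ``gene_id`` and ``kog_class``; an empty or
        missing class means not annotated.  A gene listed with several
        classes counts once in each class (the per-class percentages then
        need not sum to 100).

    Returns one row per category (including ``not annotated``) with the
    2x2 counts, the two percentages, the Yates statistic, p-value and
    direction.  Raises ``ValueError`` listing any regulated id absent from
    the annotation.
    """
    ann = annotation.copy()
    ann["kog_class"] = ann["kog_class"].fillna("").astype(str)
    ann.loc[ann["kog_class"].str.strip() == "", "kog_class"] = not_annotated_label

    regulated = set(regulated_genes)
    all_genes = set(ann["gene_id"])
    missing = sorted(regulated - all_genes)
    if missing:
        raise ValueError(f"regulated gene ids missing from annotation: {missing}")

    gene_classes: dict = {}
    for rec in ann.itertuples(index=False):
        gene_classes.setdefault(rec.gene_id, set()).add(rec.kog_class)

    n_reg = len(regulated)
    n_all = len(all_genes)
    categories = sorted({c for cs in gene_classes.values() for c in cs})

    rows = []
    for cat in categories:
        members = {g for g, cs in gene_classes.items() if cat in cs}
        a = len(regulated & members)
        b = n_reg - a
        c = len(members)  # background includes the regulated genes
        d = n_all - c
        reg_pct = 100.0 * a / n_reg if n_reg else 0.0
        bg_pct = 100.0 * c / n_all if n_all else 0.0
        stat, p = yates_chi_square(a, b, c, d, correction=correction)
        if reg_pct > bg_pct:
            direction = "enriched"
        elif reg_pct < bg_pct:
            direction = "depleted"
        else:
            direction = "none"
        rows.append(
            EnrichmentResult(
                category=cat,
                a=a,
                b=b,
                c=c,
                d=d,
                regulated_pct=reg_pct,
                background_pct=bg_pct,
                statistic=stat,
                p_value=p,
                direction=direction,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    # optional family-wise column; per-category p-values remain primary
    if len(df):
        df["p_bonferroni"] = (df["p_value"] * len(df)).clip(upper=1.0)
    return df
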