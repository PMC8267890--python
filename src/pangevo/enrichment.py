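"""Functional-category statistics for gain/loss and gene-set analyses.

Annotation hits are filtered with best-hit thresholds (identity >= 50%,
query coverage >= 50%, e-value <= 1e-5; max bitscore per gene).  Gains and
losses are cross-tabulated per category and tested with the Yates-corrected
chi-squared statistic

    chi2 = N * (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d))

with the two-tailed P value taken as the upper tail of chi2(1) (the
conventional reading for a 2x2 table).  Gene-set enrichment against a
background uses the one-sided hypergeometric tail with optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnnotationHit", "ContingencyResult", "filter_best_hits",
           "yates_chi2", "gain_loss_category_tests", "set_enrichment"]


@dataclass(frozen=True)
class AnnotationHit:
    gene_id: str
    category: str
    percent_identity: float      # [0, 100]
    query_coverage: float        # [0, 1]
    e_value: float
    bitscore: float

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError("query_coverage outside [0, 1]")
        if self.e_value < 0:
            raise ValueError("negative e-value")


@dataclass
class ContingencyResult:
    category: str
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p_two_tailed: float


def filter_best_hits(hits: list[AnnotationHit],
                     identity_min: float = 50.0,
                     coverage_min: float = 0.5,
                     e_max: float = 1e-5) -> dict[str, str]:
    """Best surviving hit per gene -> category map.

    Hits below the identity/coverage thresholds or above the e-value cutoff
    are dropped; among survivors the max-bitscore hit wins (ties to the
    smallest e-value, then the lexicographically first category).
    """
    best: dict[str, AnnotationHit] = {}
    for hit in hits:
        if (hit.percent_identity < identity_min
                or hit.query_coverage < coverage_min
                or hit.e_value > e_max):
            continue
        cur = best.get(hit.gene_id)
        if cur is None or (-hit.bitscore, hit.e_value, hit.category) < \
                (-cur.bitscore, cur.e_value, cur.category):
            best[hit.gene_id] = hit
    return {g: h.category for g, h in best.items()}


def yates_chi2(table, category: str = "") -> ContingencyResult:
    """Yates continuity-corrected chi-squared for a 2x2 table.

    The correction floors at zero: chi2 = 0 (P = 1) whenever |ad - bc| <= N/2.
    """
    (a, b), (c, d) = table
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    n = cells.sum()
    margins = (a + b, c + d, a + c, b + d)
    if n < 1 or any(m == 0 for m in margins):
        raise ValueError("degenerate table (zero marginal total)")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    chi2 = n * num * num / float(np.prod(np.array(margins, dtype=float)))
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(category=category,
                             table=((int(a), int(b)), (int(c), int(d))),
                             chi2=float(chi2), p_two_tailed=p)


def gain_loss_category_tests(gains: set[str], losses: set[str],
                             annot: dict[str, str]) -> pd.DataFrame:
    """Per-category Yates chi-squared contrasting gained vs lost genes.

    For category c the table is [[gains in c, gains not in c],
    [losses in c, losses not in c]], counted over annotated genes only; genes
    without a surviving annotation are excluded and their counts reported in
    ``DataFrame.attrs``.  Genes in both sets count in both rows (per-node
    events are independent observations).  Rows are sorted by P.
    """
    gain_cats = [annot[g] for g in sorted(gains) if g in annot]
    loss_cats = [annot[g] for g in sorted(losses) if g in annot]
    if not gain_cats or not loss_cats:
        raise ValueError("degenerate margin: no annotated gains or losses")
    rows = []
    for cat in sorted(set(gain_cats) | set(loss_cats)):
        a = sum(1 for x in gain_cats if x == cat)
        c = sum(1 for x in loss_cats if x == cat)
        res = yates_chi2(((a, len(gain_cats) - a), (c, len(loss_cats) - c)),
                         category=cat)
        rows.append({"category": cat, "gains_in": a,
                     "gains_out": len(gain_cats) - a, "losses_in": c,
                     "losses_out": len(loss_cats) - c,
                     "chi2": res.chi2, "p": res.p_two_tailed})
    df = pd.DataFrame(rows).sort_values(["p", "category"]).reset_index(drop=True)
    df.attrs["n_unannotated_gains"] = len(gains) - len(gain_cats)
    df.attrs["n_unannotated_losses"] = len(losses) - len(loss_cats)
    return df


def set_enrichment(study: set[str], background: set[str],
                   annot: dict[str, str], adjust: bool = False) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each category in a study set.

    P = P(X >= k) with X ~ Hypergeom(M = annotated background, K = category
    size in background, n = annotated study genes).  ``adjust`` adds a
    Benjamini-Hochberg column.
    """
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set is not a subset of the background")
    bg_annot = {g: annot[g] for g in background if g in annot}
    st_annot = {g: bg_annot[g] for g in study if g in bg_annot}
    m = len(bg_annot)
    n = len(st_annot)
    if n == 0:
        raise ValueError("no annotated study genes")
    rows = []
    for cat in sorted(set(bg_annot.values())):
        big_k = sum(1 for v in bg_annot.values() if v == cat)
        k = sum(1 for v in st_annot.values() if v == cat)
        p = float(stats.hypergeom.sf(k - 1, m, big_k, n))
        rows.append({"category": cat, "study_in": k, "study_n": n,
                     "background_in": big_k, "background_n": m, "p": p})
    df = pd.DataFrame(rows).sort_values(["p", "category"]).reset_index(drop=True)
    if adjust:
        df["p_bh"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df
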