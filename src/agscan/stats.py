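"""Cohort-level summaries of AG-gain call sets.

Covers the analyses used on curated pathogenic and population cohorts:
Fisher's exact test for YAG enrichment among new-acceptor variants,
distance-window shares (BP-distance >= 8, ACC-distance <= 17), score
histograms, and allele-frequency categories (singleton / rare / common).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

BP_DIST_MIN = 8
ACC_DIST_MAX = 17
COMMON_MAF = 0.01


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> float:
    """Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    ``two-sided`` uses the point-probability rule (sum of hypergeometric
    tables no more probable than the observed one); ``greater``/``less``
    are the one-sided tails on the first cell.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("Fisher test undefined for a zero margin")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)


def yag_enrichment_pvalue(yag_new_acc: int, nonyag_new_acc: int,
                          yag_other: int, nonyag_other: int) -> float:
    """One-sided Fisher p for YAG excess among variants creating new acceptors."""
    return fisher_exact_2x2(yag_new_acc, nonyag_new_acc, yag_other, nonyag_other,
                            alternative="greater")


def distance_summary(bp_dists, acc_dists) -> dict:
    """Shares, medians and histograms of BP/ACC distances of a call set."""
    bp = np.asarray(list(bp_dists), dtype=int)
    acc = np.asarray(list(acc_dists), dtype=int)
    if bp.size == 0 or acc.size == 0:
        raise ValueError("empty call set")
    return {
        "n": int(bp.size),
        "share_bp_dist_ge_8": float(np.mean(bp >= BP_DIST_MIN)),
        "share_acc_dist_le_17": float(np.mean(acc <= ACC_DIST_MAX)),
        "median_bp_dist": float(np.median(bp)),
        "median_acc_dist": float(np.median(acc)),
        "bp_dist_hist": {int(k): int(v) for k, v in
                         zip(*np.unique(bp, return_counts=True))},
        "acc_dist_hist": {int(k): int(v) for k, v in
                          zip(*np.unique(acc, return_counts=True))},
    }


def maf_categorize(ac: int, an: int) -> str:
    """singleton (AC = 1) > common (MAF >= 1%) > rare (MAF < 1%)."""
    if ac <= 0 or ac > an:
        raise ValueError(f"invalid allele counts AC={ac}, AN={an}")
    if ac == 1:
        return "singleton"
    return "common" if ac / an >= COMMON_MAF else "rare"


@dataclass
class CohortSummary:
    """Aggregated view of a scan table (one row per call)."""

    n_calls: int = 0
    by_zone: dict = field(default_factory=dict)
    by_mechanism: dict = field(default_factory=dict)
    score_hist: dict = field(default_factory=dict)
    distances: dict = field(default_factory=dict)
    maf_categories: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "by_zone": self.by_zone,
            "by_mechanism": self.by_mechanism,
            "score_hist": self.score_hist,
            "distances": self.distances,
            "maf_categories": self.maf_categories,
        }


def summarize_scan(table: pd.DataFrame, ac_col: str = "AC",
                   an_col: str = "AN") -> CohortSummary:
    """Summarise a scan TSV; AC/AN columns, when present, feed MAF categories."""
    s = CohortSummary(n_calls=len(table))
    if table.empty:
        return s
    s.by_zone = table["AGAIN_ZONE"].value_counts().to_dict()
    if "AGAIN_MECHANISM" in table:
        s.by_mechanism = table["AGAIN_MECHANISM"].value_counts().to_dict()
    s.score_hist = {int(k): int(v)
                    for k, v in table["AGAIN_SCORE"].value_counts().sort_index().items()}
    s.distances = distance_summary(table["AGAIN_BP_DIST"], table["AGAIN_ACC_DIST"])
    if ac_col in table and an_col in table:
        cats = [maf_categorize(int(ac), int(an))
                for ac, an in zip(table[ac_col], table[an_col])]
        s.maf_categories = pd.Series(cats).value_counts().to_dict()
    return s
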