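"""Allele-specific activity calls from read counts at heterozygous sites.

A heterozygous site shows allelic imbalance when it carries at least six
reads in total, the human-allele/macaque-allele read ratio exceeds 1.3, and
an exact binomial test against p = 0.5 gives P <= 1e-3 (two-sided by
default; the ratio filter supplies the direction). Replicates are merged by
summing counts before testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "HetSiteCounts",
    "ImbalanceCall",
    "call_imbalance",
    "merge_replicates",
    "imbalance_enrichment",
    "MUTATION_CLASSES",
]

MUTATION_CLASSES = (
    "essential",
    "nonessential",
    "preserved_background",
    "common_snp",
)


@dataclass(frozen=True)
class HetSiteCounts:
    site_id: str
    reads_human_allele: int
    reads_macaque_allele: int
    mutation_class: str = "preserved_background"

    def __post_init__(self) -> None:
        if self.reads_human_allele < 0 or self.reads_macaque_allele < 0:
            raise ValueError("read counts must be nonnegative")


@dataclass(frozen=True)
class ImbalanceCall:
    ratio: float  # may be inf when the macaque allele has no reads
    p_value: float
    imbalanced: bool
    filtered: bool  # True when total reads < min_total


def call_imbalance(
    counts: HetSiteCounts,
    min_total: int = 6,
    ratio_thr: float = 1.3,
    p_thr: float = 1e-3,
    alternative: str = "two-sided",
) -> ImbalanceCall:
    """Exact binomial imbalance call on one heterozygous site."""
    h, m = counts.reads_human_allele, counts.reads_macaque_allele
    total = h + m
    ratio = math.inf if m == 0 else h / m
    if total == 0:
        return ImbalanceCall(ratio=math.nan, p_value=1.0, imbalanced=False,
                             filtered=True)
    p = stats.binomtest(h, total, 0.5, alternative=alternative).pvalue
    if total < min_total:
        return ImbalanceCall(ratio=ratio, p_value=float(p), imbalanced=False,
                             filtered=True)
    imbalanced = ratio > ratio_thr and p <= p_thr
    return ImbalanceCall(ratio=ratio, p_value=float(p), imbalanced=bool(imbalanced),
                         filtered=False)


def merge_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Sum allele counts over replicates of each site before testing."""
    required = {"site_id", "reads_h", "reads_m"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    keys = ["site_id"] + (["class"] if "class" in table.columns else [])
    return (
        table.groupby(keys, as_index=False)[["reads_h", "reads_m"]]
        .sum()
        .sort_values("site_id", ignore_index=True)
    )


def imbalance_enrichment(
    calls: pd.DataFrame,
    background_class: str = "preserved_background",
) -> pd.DataFrame:
    """Per-class imbalance fraction and Fisher test against the background.

    ``calls`` needs columns ``class`` and ``imbalanced`` (bool). Empty
    classes are omitted with a warning. The background row carries p = NaN.
    """
    if not {"class", "imbalanced"}.issubset(calls.columns):
        raise ValueError("calls must have columns 'class' and 'imbalanced'")
    if background_class not in set(calls["class"]):
        raise ValueError(f"background class {background_class!r} absent")
    bg = calls[calls["class"] == background_class]
    bg_pos = int(bg["imbalanced"].sum())
    bg_neg = len(bg) - bg_pos
    rows = []
    for cls, sub in calls.groupby("class"):
        if len(sub) == 0:  # pragma: no cover - groupby yields no empty groups
            warnings.warn(f"class {cls!r} empty; omitted", stacklevel=2)
            continue
        pos = int(sub["imbalanced"].sum())
        neg = len(sub) - pos
        if cls == background_class:
            p = float("nan")
            odds = 1.0
        else:
            odds, p = stats.fisher_exact([[pos, neg], [bg_pos, bg_neg]])
        rows.append(
            {
                "class": cls,
                "n_sites": len(sub),
                "n_imbalanced": pos,
                "fraction": pos / len(sub),
                "odds_ratio_vs_background": float(odds),
                "fisher_p_vs_background": p,
            }
        )
    return pd.DataFrame(rows)
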