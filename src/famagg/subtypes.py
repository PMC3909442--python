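"""Nearest-centroid intrinsic-subtype classification and subtype summaries.

A sample is assigned the subtype whose centroid expression profile it
correlates with most strongly (rank-based correlation by default, as in the
standard 50-gene intrinsic-subtype classifier).  Also provides per-group
subtype distribution tables and a Fisher exact enrichment test between two
groups.

Expression matrices and centroid tables are plain pandas DataFrames with
gene ids as the index; samples (or subtypes) as columns.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INTRINSIC_SUBTYPES",
    "SubtypeCall",
    "match_genes",
    "classify_sample",
    "classify_cohort",
    "calls_to_frame",
    "subtype_distribution",
    "subtype_enrichment_test",
]

#: The five intrinsic molecular breast-cancer subtypes, in canonical order.
#: Order matters: it is the deterministic tie-break for classification.
INTRINSIC_SUBTYPES = ("Basal-like", "HER2-enriched", "LumA", "LumB", "Normal-like")


@dataclass(frozen=True)
class SubtypeCall:
    """Classification of one sample: assigned subtype plus all centroid scores."""

    sample_id: str
    assigned_subtype: str
    scores: Mapping[str, float]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


def match_genes(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Restrict matrix and centroids to their shared genes, identically ordered.

    Returns ``(matrix, centroids, overlap)`` where ``overlap`` is the fraction
    of centroid genes found in the matrix.  Raises if the overlap falls below
    ``min_overlap``, naming the missing genes.
    """
    _check_unique(matrix.index, "gene ids in expression matrix")
    _check_unique(centroids.index, "gene ids in centroid table")
    shared = centroids.index.intersection(matrix.index)
    overlap = len(shared) / len(centroids.index)
    if overlap < min_overlap:
        missing = centroids.index.difference(matrix.index).tolist()
        raise ValueError(
            f"only {len(shared)}/{len(centroids.index)} centroid genes present "
            f"(overlap {overlap:.2f} < {min_overlap}); missing: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    # keep the centroid file's gene order
    shared = centroids.index[centroids.index.isin(matrix.index)]
    return matrix.loc[shared], centroids.loc[shared], overlap


def _correlate(profile: np.ndarray, centroid_values: np.ndarray, method: str) -> np.ndarray:
    """Correlation of a profile against each centroid column."""
    if method == "spearman":
        if np.ptp(profile) == 0:
            raise ValueError(
                "profile has zero variance: rank correlation is undefined; "
                "check that the sample's expression values are not constant"
            )
        profile = stats.rankdata(profile)
        centroid_values = np.apply_along_axis(stats.rankdata, 0, centroid_values)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    p = profile - profile.mean()
    c = centroid_values - centroid_values.mean(axis=0)
    p_norm = np.sqrt((p**2).sum())
    c_norm = np.sqrt((c**2).sum(axis=0))
    if p_norm == 0:
        raise ValueError("profile has zero variance: correlation is undefined")
    if (c_norm == 0).any():
        raise ValueError("a centroid column has zero variance: correlation is undefined")
    return (p @ c) / (p_norm * c_norm)


def classify_sample(
    profile: pd.Series,
    centroids: pd.DataFrame,
    method: str = "spearman",
) -> SubtypeCall:
    """Assign one expression profile to its nearest centroid.

    ``profile`` and ``centroids`` must already be gene-aligned (see
    :func:`match_genes`).  Ties are broken by centroid column order.
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 genes to classify")
    if not profile.index.equals(centroids.index):
        raise ValueError("profile and centroids are not gene-aligned; call match_genes first")
    scores = _correlate(profile.to_numpy(float), centroids.to_numpy(float), method)
    best = int(np.argmax(scores))  # argmax -> first maximum: column-order tie-break
    return SubtypeCall(
        sample_id=str(profile.name),
        assigned_subtype=str(centroids.columns[best]),
        scores=dict(zip(centroids.columns.astype(str), map(float, scores))),
    )


def classify_cohort(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    method: str = "spearman",
    min_overlap: float = 0.5,
) -> list[SubtypeCall]:
    """Classify every sample (column) of an expression matrix."""
    matrix, centroids, _ = match_genes(matrix, centroids, min_overlap=min_overlap)
    _check_unique(matrix.columns, "sample ids")
    return [classify_sample(matrix[s], centroids, method=method) for s in matrix.columns]


def calls_to_frame(calls: Iterable[SubtypeCall]) -> pd.DataFrame:
    """Tabulate calls: one row per sample, assigned subtype plus score columns."""
    rows = []
    for c in calls:
        row = {"sample": c.sample_id, "assigned_subtype": c.assigned_subtype}
        row.update({f"score_{k}": v for k, v in c.scores.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def subtype_distribution(
    calls: Iterable[SubtypeCall],
    group_of: Mapping[str, str] | None = None,
    subtype_order: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-group subtype counts and integer percentages.

    Returns a DataFrame indexed by (group, subtype) with ``count``, ``total``
    and ``percent`` columns; percentages are rounded half away from zero to
    the nearest integer.  An empty group yields zero counts and percent 0.
    """
    calls = list(calls)
    if group_of is None:
        group_of = {c.sample_id: "all" for c in calls}
    for c in calls:
        if c.sample_id not in group_of:
            raise ValueError(f"sample {c.sample_id!r} missing from group map")
    if subtype_order is None:
        seen = {c.assigned_subtype for c in calls}
        subtype_order = [s for s in INTRINSIC_SUBTYPES if s in seen] + sorted(
            seen - set(INTRINSIC_SUBTYPES)
        )
    groups = sorted(set(group_of.values()))
    rows = []
    for g in groups:
        members = [c for c in calls if group_of[c.sample_id] == g]
        total = len(members)
        for st in subtype_order:
            n = sum(1 for c in members if c.assigned_subtype == st)
            pct = _round_half_away(100 * n / total) if total else 0
            rows.append({"group": g, "subtype": st, "count": n, "total": total,
                         "percent": pct, "empty_group": total == 0})
    return pd.DataFrame(rows).set_index(["group", "subtype"])


def subtype_enrichment_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> float:
    """Two-sided Fisher exact p for subtype enrichment between two groups.

    The 2x2 table is (subtype vs not) x (group A vs group B).
    """
    for name, c, t in (("A", count_a, total_a), ("B", count_b, total_b)):
        if c < 0 or t < 0:
            raise ValueError(f"negative count in group {name}")
        if c > t:
            raise ValueError(f"group {name}: count {c} exceeds total {t}")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
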