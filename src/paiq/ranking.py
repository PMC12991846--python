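"""Statistical ranking of quality metrics by their separability of quality levels.

Given per-image metric values grouped into quality-ordered subsets (a
"ladder"), each metric is scored by:

* **SC** (Significant Count): number of subset pairs whose metric values
  differ significantly under a two-sided Welch t-test at p < 0.05;
* **NMD** (Normalized Mean Difference): mean over the *significant* pairs of
  the absolute difference in subset means, normalized by the metric's value
  range — an effect size that treats lower-is-better metrics equivalently;
* **CS** (Composite Score): SC x NMD, the unified ranking criterion.

A Spearman correlation of per-image values against quality rank is provided
as a monotonicity check.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SubsetScores",
    "PairComparison",
    "RankingRow",
    "ALPHA",
    "pairwise_tests",
    "significant_count",
    "normalized_mean_difference",
    "composite_score",
    "rank_metrics",
    "spearman_vs_quality",
    "default_value_range",
    "rank_from_long_table",
]

ALPHA = 0.05

# nominal value ranges used to normalize mean differences: 1 for the
# similarity metrics (their practical range on nonnegative images) and a
# nominal 80 dB dynamic range for PSNR (a conventional ceiling for
# floating-point image comparisons).  GMSD-family and other unbounded
# metrics fall back to the observed pooled range.
_NOMINAL_RANGES = {
    "SSIM": 1.0, "MS-SSIM": 1.0, "IW-SSIM": 1.0, "S3IM": 1.0, "UQI": 1.0,
    "VIF": 1.0, "HaarPSI": 1.0, "FSIM": 1.0, "PSNR": 80.0,
}


@dataclass(frozen=True)
class SubsetScores:
    metric: str
    subset_label: str
    quality_rank: int
    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        finite = tuple(v for v in vals if np.isfinite(v))
        dropped = len(vals) - len(finite)
        if dropped:
            log.warning(
                "%s/%s: dropped %d non-finite values (e.g. PSNR identity pairs)",
                self.metric, self.subset_label, dropped,
            )
        object.__setattr__(self, "values", finite)


@dataclass(frozen=True)
class PairComparison:
    subset_a: str
    subset_b: str
    p_value: float
    mean_diff: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class RankingRow:
    metric: str
    SC: int
    NMD: float
    CS: float


def pairwise_tests(metric_scores: list[SubsetScores]) -> list[PairComparison]:
    """Two-sided Welch t-tests for every unordered subset pair of a ladder.

    Subsets with fewer than two finite values are skipped with a warning and
    do not enter the pair total.
    """
    usable = []
    for s in metric_scores:
        if len(s.values) < 2:
            warnings.warn(f"subset {s.subset_label!r} has <2 values; skipped")
            continue
        usable.append(s)
    if len(usable) < 2:
        return []
    comparisons = []
    for a, b in itertools.combinations(usable, 2):
        va, vb = np.asarray(a.values), np.asarray(b.values)
        if va.std() == 0.0 and vb.std() == 0.0:
            p = 1.0 if np.isclose(va.mean(), vb.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        comparisons.append(
            PairComparison(
                subset_a=a.subset_label,
                subset_b=b.subset_label,
                p_value=p,
                mean_diff=abs(float(va.mean()) - float(vb.mean())),
            )
        )
    return comparisons


def significant_count(comparisons: list[PairComparison]) -> int:
    """Number of subset pairs separated at p < 0.05."""
    return sum(1 for c in comparisons if c.significant)


def normalized_mean_difference(
    comparisons: list[PairComparison], value_range: float
) -> float:
    """Mean |subset-mean difference| / value_range over significant pairs only."""
    if value_range <= 0:
        raise ValueError("value_range must be positive")
    diffs = [c.mean_diff / value_range for c in comparisons if c.significant]
    return float(np.mean(diffs)) if diffs else 0.0


def composite_score(SC: int, NMD: float) -> float:
    """CS = SC x NMD."""
    if SC < 0 or NMD < 0:
        raise ValueError("SC and NMD must be non-negative")
    return SC * NMD


def rank_metrics(rows: list[RankingRow]) -> list[RankingRow]:
    """Sort descending by CS, breaking ties by SC descending then metric name."""
    return sorted(rows, key=lambda r: (-r.CS, -r.SC, r.metric))


def spearman_vs_quality(metric_scores: list[SubsetScores]) -> float:
    """Spearman correlation of per-image metric values against quality rank."""
    values, ranks = [], []
    for s in metric_scores:
        values.extend(s.values)
        ranks.extend([s.quality_rank] * len(s.values))
    if len(set(values)) < 2 or len(set(ranks)) < 2:
        warnings.warn("spearman_vs_quality: constant input; returning 0")
        return 0.0
    rho = stats.spearmanr(values, ranks).statistic
    return float(rho)


def default_value_range(metric: str, observed: np.ndarray) -> float:
    """Value range used for NMD: nominal where known, else observed."""
    if metric in _NOMINAL_RANGES:
        return _NOMINAL_RANGES[metric]
    observed = observed[np.isfinite(observed)]
    if metric in ("GMSD", "MS-GMSD"):
        mx = float(observed.max()) if observed.size else 0.0
        return mx if mx > 0 else 1.0
    rng = float(observed.max() - observed.min()) if observed.size else 0.0
    return rng if rng > 0 else 1.0


def rank_from_long_table(
    df: pd.DataFrame,
    value_ranges: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full ranking pipeline from a long-form metric table.

    Parameters
    ----------
    df
        Columns ``dataset, subset, quality_rank, metric, value`` (one row per
        image x metric), e.g. the CSV written by the batch metric runner.
    value_ranges
        Optional per-metric overrides of the normalization range.

    Returns
    -------
    (ranking, detail)
        ``ranking``: one row per metric with SC, NMD, CS, spearman, sorted.
        ``detail``: one row per (metric, dataset, subset pair) comparison.
    """
    needed = {"dataset", "subset", "quality_rank", "metric", "value"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"long-form table missing columns {sorted(missing)}")
    ranking_rows, detail_rows = [], []
    for metric, mdf in df.groupby("metric"):
        observed = mdf["value"].to_numpy(dtype=float)
        vrange = (value_ranges or {}).get(metric) or default_value_range(metric, observed)
        all_comparisons = []
        spearmans = []
        for dataset, ddf in mdf.groupby("dataset"):
            scores = [
                SubsetScores(
                    metric=metric,
                    subset_label=str(label),
                    quality_rank=int(grp["quality_rank"].iloc[0]),
                    values=tuple(grp["value"].astype(float)),
                )
                for label, grp in ddf.groupby("subset", sort=False)
            ]
            scores.sort(key=lambda s: s.quality_rank)
            comps = pairwise_tests(scores)
            all_comparisons.extend(comps)
            spearmans.append(spearman_vs_quality(scores))
            for c in comps:
                detail_rows.append(
                    {
                        "metric": metric, "dataset": dataset,
                        "subset_a": c.subset_a, "subset_b": c.subset_b,
                        "p_value": c.p_value, "mean_diff": c.mean_diff,
                        "significant": c.significant,
                    }
                )
        sc = significant_count(all_comparisons)
        nmd = normalized_mean_difference(all_comparisons, vrange)
        ranking_rows.append(
            {
                "metric": metric, "SC": sc, "NMD": nmd,
                "CS": composite_score(sc, nmd),
                "spearman": float(np.mean(spearmans)) if spearmans else 0.0,
                "n_pairs_tested": len(all_comparisons),
                "value_range": vrange,
            }
        )
    ranking = pd.DataFrame(ranking_rows).sort_values(
        ["CS", "SC", "metric"], ascending=[False, False, True]
    ).reset_index(drop=True)
    detail = pd.DataFrame(detail_rows)
    return ranking, detail
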