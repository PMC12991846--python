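"""Batch scoring of quality ladders: manifest in, long-form metric table out."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import LadderManifest, load_image, normalize_minmax, validate_pair
from .fr_metrics import FRConfigs, METRIC_ORDER, compute_metrics

__all__ = ["score_manifest", "LONG_COLUMNS"]

LONG_COLUMNS = [
    "dataset", "subset", "quality_rank", "image_id",
    "metric", "value", "higher_is_better",
]


def score_manifest(
    manifest: LadderManifest,
    metrics: list[str] | None = None,
    configs: FRConfigs | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Compute full-reference metrics for every record of a ladder manifest.

    Parameters
    ----------
    manifest
        Quality ladder whose records point at test/reference image files.
    metrics
        Subset of :data:`~paiq.fr_metrics.METRIC_ORDER` (default: all eleven).
    configs
        Per-metric configuration bundle.
    normalize
        Min-max normalize each image before scoring (the standard
        preprocessing for reconstructed photoacoustic images).

    Returns
    -------
    Long-form DataFrame with one row per image x metric.
    """
    wanted = list(metrics) if metrics is not None else list(METRIC_ORDER)
    unknown = set(wanted) - set(METRIC_ORDER)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {METRIC_ORDER}")
    rows = []
    cache: dict[str, object] = {}
    for subset in manifest.subsets:
        for test_path, ref_path in subset.records:
            ref = cache.get(ref_path)
            if ref is None:
                ref = load_image(ref_path)
                if normalize:
                    ref = normalize_minmax(ref)
                cache[ref_path] = ref
            test = load_image(test_path)
            if normalize:
                test = normalize_minmax(test)
            pair = validate_pair(ref, test)
            results = {r.metric: r for r in compute_metrics(pair, wanted, configs)}
            for name in wanted:
                r = results[name]
                rows.append(
                    {
                        "dataset": manifest.dataset,
                        "subset": subset.label,
                        "quality_rank": subset.quality_rank,
                        "image_id": Path(test_path).stem,
                        "metric": r.metric,
                        "value": r.value,
                        "higher_is_better": r.higher_is_better,
                    }
                )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)
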