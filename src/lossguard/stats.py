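"""Statistical comparisons and report serialization.

Thin, convention-fixing wrappers over scipy: paired Wilcoxon signed-rank
for per-genome category comparisons, Wilcoxon rank-sum for profile-length
group comparisons, Kendall rank correlation against assembly quality
(log N50), ordinary least squares for cross-set percentage fits, and
half-up 2-decimal display rounding for reported percentages (internal
math keeps full precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "percent",
    "paired_signed_rank_test",
    "rank_correlation_vs_quality",
    "length_group_comparison",
    "linear_fit",
    "render_report",
]


def percent(found: float, total: float) -> float:
    """``100 * found / total`` rounded half-up to two decimals for display."""
    if total <= 0:
        raise ValueError("total must be > 0")
    value = Decimal(100) * Decimal(found) / Decimal(total)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n: int


def paired_signed_rank_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on genome-paired values.

    Zero differences are dropped; the exact null distribution is used
    for n <= 25 untied differences, otherwise the normal approximation
    with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n < 2:
        raise ValueError("fewer than 2 nonzero pairs")
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), n=n)


def rank_correlation_vs_quality(
    found_pct: Sequence[float], n50: Sequence[float], log_transform: bool = True
) -> TestResult:
    """Kendall tau-b between per-genome found-absence percentage and
    (log-transformed) assembly N50, with a two-sided p-value."""
    x = np.asarray(found_pct, dtype=float)
    y = np.asarray(n50, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if log_transform:
        if (y <= 0).any():
            raise ValueError("N50 values must be positive for log transform")
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = sps.kendalltau(x, y)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), n=len(x))


def length_group_comparison(
    model_lengths: Mapping[str, int],
    found_counts: Mapping[str, int],
    k: int = 100,
) -> dict:
    """Compare profile lengths of the k domains with the most found
    absences against the rest (two-sided Wilcoxon rank-sum).

    Returns group medians, group sizes and the p-value.  Exact null for
    small untied groups, normal approximation otherwise.
    """
    domains = sorted(model_lengths)
    if k >= len(domains):
        raise ValueError("k must be smaller than the number of domains")
    ranked = sorted(domains, key=lambda d: (-found_counts.get(d, 0), d))
    top = ranked[:k]
    rest = ranked[k:]
    top_lengths = np.array([model_lengths[d] for d in top], dtype=float)
    rest_lengths = np.array([model_lengths[d] for d in rest], dtype=float)
    pooled = np.concatenate([top_lengths, rest_lengths])
    exact_ok = len(top_lengths) <= 20 and len(rest_lengths) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(
        top_lengths, rest_lengths, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    return {
        "median_length_top": float(np.median(top_lengths)),
        "median_length_rest": float(np.median(rest_lengths)),
        "n_top": len(top_lengths),
        "n_rest": len(rest_lengths),
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
    }


def linear_fit(x: Sequence[float], y: Sequence[float]) -> dict:
    """Ordinary least squares y ~ x: slope, intercept, R^2 and the 95%
    confidence half-width of the slope."""
    res = sps.linregress(np.asarray(x, float), np.asarray(y, float))
    n = len(x)
    tcrit = sps.t.ppf(0.975, n - 2) if n > 2 else float("nan")
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "slope_ci95_halfwidth": float(tcrit * res.stderr) if n > 2 else float("nan"),
        "n": n,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, TestResult):
        return {"statistic": obj.statistic, "pvalue": obj.pvalue, "n": obj.n}
    return obj


def render_report(results: dict, json_path=None, tsv_dir=None) -> str:
    """Serialize a results dictionary deterministically to JSON (and any
    DataFrame members additionally as TSV files when ``tsv_dir`` is set).

    Returns the JSON string.
    """
    if tsv_dir is not None:
        from pathlib import Path

        tsv_dir = Path(tsv_dir)
        tsv_dir.mkdir(parents=True, exist_ok=True)
        for key, value in results.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(tsv_dir / f"{key}.tsv", sep="\t")
    text = json.dumps(_jsonable(results), indent=2, sort_keys=True)
    if json_path is not None:
        with open(json_path, "w") as fh:
            fh.write(text + "\n")
    return text


def plot_loss_histograms(uncorrected: Mapping[int, int], corrected: Mapping[int, int], path) -> None:
    """Overlaid uncorrected/corrected loss-count histograms with an inset
    difference panel (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted(set(uncorrected) | set(corrected))
    u = [uncorrected.get(k, 0) for k in keys]
    c = [corrected.get(k, 0) for k in keys]
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.bar(keys, u, color="white", edgecolor="black", label="uncorrected")
    ax.bar(keys, c, color="orange", alpha=0.6, label="corrected")
    ax.set_xlabel("losses per domain")
    ax.set_ylabel("number of domains")
    ax.legend()
    inset = fig.add_axes([0.55, 0.55, 0.33, 0.3])
    inset.bar(keys, np.array(c) - np.array(u), color="steelblue")
    inset.set_title("corrected - uncorrected", fontsize=8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
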