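"""Group-comparison statistics and the report bundle.

Batches of per-sample metrics are summarized as mean +/- SD per group and
compared by classical one-way ANOVA followed by Tukey's HSD post hoc test
(studentized range; Tukey-Kramer harmonic-mean adjustment for unbalanced
groups, via :func:`scipy.stats.tukey_hsd`). Significance is flagged at
two-tailed p < 0.05 on the unrounded p-value. No correction is applied across
metrics — only the within-family Tukey adjustment — which mirrors per-panel
testing and is a documented limitation.

A metric table is a long-format DataFrame with columns
``sample_id, group, timepoint, metric, value``; each row is one experimental
unit (pooling of technical replicates is left to the caller).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__ as _pkg_version  # noqa: F401  (kept in reports)

ALPHA = 0.05

REQUIRED_COLUMNS = ("sample_id", "group", "timepoint", "metric", "value")


class StatsError(Exception):
    """Invalid metric table or degenerate comparison."""


@dataclass
class AnovaResult:
    """One-way ANOVA outcome for one metric."""

    metric: str
    f_statistic: float
    p_value: float | None
    df_between: int
    df_within: int
    defined: bool = True


@dataclass
class TukeyPair:
    """One pairwise Tukey HSD contrast."""

    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float
    significant: bool


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format contract and key uniqueness."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise StatsError(f"metric table missing column {col!r}")
    keys = table[["sample_id", "timepoint", "metric"]]
    if keys.duplicated().any():
        raise StatsError("(sample_id, timepoint, metric) rows must be unique")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise StatsError("metric values must be finite")
    return table


def _groups(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise StatsError(f"no rows for metric {metric!r}")
    return {
        str(g): np.sort(v["value"].to_numpy(dtype=float))
        for g, v in sub.groupby("group", sort=True)
    }


def summarize(table: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Per-group mean +/- SD (sample SD, n-1 denominator) and n.

    A single-value group reports SD 0.0; its ``n`` column makes the
    zero-width interval explicit.
    """
    validate_metric_table(table)
    metrics = [metric] if metric is not None else sorted(table["metric"].unique())
    rows = []
    for m in metrics:
        for g, vals in _groups(table, m).items():
            rows.append(
                {
                    "metric": m,
                    "group": g,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def one_way_anova(table: pd.DataFrame, metric: str) -> AnovaResult:
    """Classical one-way ANOVA: between/within mean-square ratio.

    Degenerate cases: zero within-group variance with separated means gives
    an infinite F and p reported as 0.0 (below the machine floor); zero
    variance everywhere leaves p undefined (``defined=False``).
    """
    validate_metric_table(table)
    groups = _groups(table, metric)
    if len(groups) < 2:
        raise StatsError("ANOVA needs >= 2 groups")
    for g, vals in groups.items():
        if vals.size < 2:
            raise StatsError(f"group {g!r} needs n >= 2")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(metric, float("nan"), None, df_b, df_w, defined=False)
    if ss_within == 0:
        return AnovaResult(metric, float("inf"), 0.0, df_b, df_w)
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(scipy.stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(metric, float(f_stat), p, df_b, df_w)


def tukey_hsd(table: pd.DataFrame, metric: str) -> list[TukeyPair]:
    """Tukey HSD over all unordered group pairs, alphabetical group order.

    Adjusted p-values come from the studentized-range distribution; unequal
    group sizes use the Tukey-Kramer harmonic-mean standard error.
    """
    validate_metric_table(table)
    groups = _groups(table, metric)
    if len(groups) < 2:
        raise StatsError("Tukey HSD needs >= 2 groups")
    for g, vals in groups.items():
        if vals.size < 2:
            raise StatsError(f"group {g!r} needs n >= 2")
    labels = list(groups.keys())
    arrays = [groups[g] for g in labels]
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    pairs: list[TukeyPair] = []
    if ss_within == 0:
        # degenerate: identical values within every group
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                diff = float(arrays[i].mean() - arrays[j].mean())
                p = 1.0 if diff == 0 else 0.0
                pairs.append(TukeyPair(labels[i], labels[j], diff, p, p < ALPHA))
        return pairs
    res = scipy.stats.tukey_hsd(*arrays)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            pairs.append(
                TukeyPair(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_difference=float(arrays[i].mean() - arrays[j].mean()),
                    p_adjusted=p,
                    significant=p < ALPHA,
                )
            )
    return pairs


def compare_all_metrics(table: pd.DataFrame) -> list[dict]:
    """ANOVA + Tukey for every metric in a table (where group sizes allow)."""
    validate_metric_table(table)
    out = []
    for metric in sorted(table["metric"].unique()):
        anova = one_way_anova(table, metric)
        pairs = tukey_hsd(table, metric)
        out.append(
            {
                "metric": metric,
                "anova": asdict(anova),
                "tukey": [asdict(p) for p in pairs],
            }
        )
    return out


def build_report(
    metric_table: pd.DataFrame,
    comparisons: list[dict] | None = None,
    config: dict | None = None,
    seeds: list[int] | None = None,
) -> dict:
    """Assemble the report bundle: per-sample metrics, summaries, comparisons.

    The returned dict serializes to deterministic bytes via
    :func:`report_to_json` (sorted keys, no timestamps), so identical inputs
    give byte-identical reports.
    """
    validate_metric_table(metric_table)
    summary = summarize(metric_table)
    report = {
        "schema_version": "1",
        "software_version": _pkg_version,
        "samples": metric_table.sort_values(list(REQUIRED_COLUMNS))
        .to_dict(orient="records"),
        "group_summaries": summary.to_dict(orient="records"),
        "comparisons": comparisons or [],
        "config": config or {},
        "seeds": seeds or [],
    }
    return report


def report_to_json(report: dict) -> str:
    """Serialize a report with sorted keys for byte-stable output."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


def write_report(report: dict, json_path, csv_path=None) -> None:
    """Write the JSON bundle and, optionally, the long-format sample CSV."""
    with open(json_path, "w") as fh:
        fh.write(report_to_json(report))
    if csv_path is not None:
        pd.DataFrame(report["samples"]).to_csv(csv_path, index=False)
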