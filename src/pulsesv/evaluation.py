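"""Validation metrics, Bland–Altman agreement, and rank aggregation.

Each candidate formula is scored against the measured stroke volume on four
metrics — Pearson r, standardized mean difference (Hedges g with pooled SD),
sum of squared residuals (observed − predicted), and mean bias — then given
a competition rank per metric (|r| descending; |g|, SSR, |bias| ascending;
ties share the minimum rank). The total score is the sum of the four ranks;
the best formula minimises it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import pair_series, stratum_mask
from .registry import FormulaRegistry, VolumeFactorTable, predict_vector
from .types import ALL_STRATA, Stratum, ValidationError

__all__ = [
    "MetricSet",
    "BlandAltman",
    "RankingTable",
    "pearson_r",
    "hedges_g",
    "sum_squared_residuals",
    "mean_bias",
    "bland_altman",
    "compute_metrics",
    "predictions_frame",
    "evaluate_stratum",
    "rank_formulae",
    "min_ssr_formula",
    "stratified_report",
    "plot_bland_altman",
]


def _aligned(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and aligned")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either series is constant."""
    x, y = _aligned(x, y)
    if len(x) < 3:
        return float("nan")
    # exact-constancy check (np.std of identical values can round to ~1e-14)
    if (x == x[0]).all() or (y == y[0]).all():
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def hedges_g(x, y, estimator: str = "hedges") -> float:
    """Standardized mean difference |mean(x) − mean(y)| / s_pooled.

    s_pooled = sqrt((sd_x² + sd_y²)/2) with sample SDs; the ``hedges``
    estimator applies the small-sample correction J = 1 − 3/(4·(2n−2)−1),
    ``cohen`` omits it. Reported as a positive value. Infinite when the
    pooled SD vanishes but the means differ.
    """
    x, y = _aligned(x, y)
    n = len(x)
    if n < 2 or len(y) < 2:
        return float("nan")
    diff = abs(float(np.mean(x)) - float(np.mean(y)))
    s_pooled = math.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    if s_pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    d = diff / s_pooled
    if estimator == "cohen":
        return d
    if estimator == "hedges":
        j = 1.0 - 3.0 / (4.0 * (2 * n - 2) - 1.0)
        return d * j
    raise ValidationError(f"unknown effect-size estimator {estimator!r}")


def sum_squared_residuals(x, y) -> float:
    """SSR = Σ(xᵢ − yᵢ)² (mL²)."""
    x, y = _aligned(x, y)
    return float(np.sum((x - y) ** 2))


def mean_bias(x, y) -> float:
    """Signed mean of (observed − predicted); ranking consumes |bias|."""
    x, y = _aligned(x, y)
    if len(x) == 0:
        return float("nan")
    return float(np.mean(x - y))


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement for a method comparison."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    level: float = 0.95
    n: int = 0

    def loa_relative_to_mean(self, reference_mean: float) -> tuple[float, float]:
        """Limits of agreement as a fraction (%) of a reference mean SV.

        An interpretation of agreement-band width relative to a typical
        stroke volume; provided for descriptive use only.
        """
        return (
            100.0 * self.loa_low / reference_mean,
            100.0 * self.loa_high / reference_mean,
        )


def bland_altman(x, y) -> BlandAltman:
    """Bias ± 1.96·SD limits of agreement on the paired differences x − y."""
    x, y = _aligned(x, y)
    if len(x) < 3:
        raise ValidationError("Bland–Altman needs at least 3 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(d),
    )


@dataclass(frozen=True)
class MetricSet:
    """The four validation metrics for one formula in one stratum."""

    formula_id: str
    stratum: str
    n: int
    r: float
    g: float
    ssr: float
    bias: float
    mean_measured: float
    sd_measured: float
    mean_predicted: float
    sd_predicted: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    x,
    y,
    formula_id: str = "",
    stratum: str = "both|both",
    effect_size: str = "hedges",
) -> MetricSet:
    """All four metrics plus per-series summaries for aligned pairs."""
    x, y = _aligned(x, y)
    n = len(x)
    if n == 0:
        nan = float("nan")
        return MetricSet(formula_id, stratum, 0, nan, nan, nan, nan, nan, nan, nan, nan)
    return MetricSet(
        formula_id=formula_id,
        stratum=stratum,
        n=n,
        r=pearson_r(x, y),
        g=hedges_g(x, y, estimator=effect_size),
        ssr=sum_squared_residuals(x, y),
        bias=mean_bias(x, y),
        mean_measured=float(np.mean(x)),
        sd_measured=float(np.std(x, ddof=1)) if n > 1 else float("nan"),
        mean_predicted=float(np.mean(y)),
        sd_predicted=float(np.std(y, ddof=1)) if n > 1 else float("nan"),
    )


# ---------------------------------------------------------------------------
# ranking


@dataclass(frozen=True)
class RankingTable:
    """Per-metric competition ranks and total scores for one stratum."""

    stratum: str
    rows: tuple[Mapping, ...]  # ordered by ascending total_score

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    @property
    def best(self) -> Mapping:
        return self.rows[0]

    def row(self, formula_id: str) -> Mapping:
        for r in self.rows:
            if r["formula_id"] == formula_id:
                return r
        raise KeyError(formula_id)


def _competition_rank(values: np.ndarray) -> np.ndarray:
    """Ascending competition ranks; NaN (undefined metric) ranks last."""
    v = values.copy()
    undefined = ~np.isfinite(v)
    v[undefined] = np.inf
    # ties share the minimum rank
    return stats.rankdata(v, method="min").astype(int)


def rank_formulae(metric_sets: Sequence[MetricSet]) -> RankingTable:
    """Aggregate the four per-metric ranks into a total score per formula.

    |r| is ranked descending (higher correlation is better); |g|, SSR and
    |bias| ascending. Undefined metrics rank last for that metric and the
    row is flagged.
    """
    if len(metric_sets) < 2:
        raise ValidationError("ranking needs at least two formulae")
    strata = {m.stratum for m in metric_sets}
    if len(strata) != 1:
        raise ValidationError("metric sets span multiple strata")
    r_abs = np.array([abs(m.r) for m in metric_sets], dtype=float)
    g_abs = np.array([abs(m.g) for m in metric_sets], dtype=float)
    ssr = np.array([m.ssr for m in metric_sets], dtype=float)
    bias_abs = np.array([abs(m.bias) for m in metric_sets], dtype=float)
    rank_r = _competition_rank(-r_abs)  # descending
    rank_g = _competition_rank(g_abs)
    rank_ssr = _competition_rank(ssr)
    rank_bias = _competition_rank(bias_abs)
    total = rank_r + rank_g + rank_ssr + rank_bias
    rows = []
    for i, m in enumerate(metric_sets):
        flagged = not all(
            np.isfinite(v) for v in (r_abs[i], g_abs[i], ssr[i], bias_abs[i])
        )
        rows.append(
            {
                "formula_id": m.formula_id,
                "n": m.n,
                "r": m.r,
                "g": m.g,
                "ssr": m.ssr,
                "bias": m.bias,
                "rank_r": int(rank_r[i]),
                "rank_g": int(rank_g[i]),
                "rank_ssr": int(rank_ssr[i]),
                "rank_bias": int(rank_bias[i]),
                "total_score": int(total[i]),
                "undefined_metric": flagged,
                "mean_measured": m.mean_measured,
                "sd_measured": m.sd_measured,
                "mean_predicted": m.mean_predicted,
                "sd_predicted": m.sd_predicted,
            }
        )
    rows.sort(key=lambda row: (row["total_score"], row["formula_id"]))
    totals = np.array([row["total_score"] for row in rows], dtype=float)
    positions = _competition_rank(totals)
    for row, pos in zip(rows, positions):
        row["final_position"] = int(pos)
    return RankingTable(stratum=metric_sets[0].stratum, rows=tuple(rows))


# ---------------------------------------------------------------------------
# stratified pipeline


def predictions_frame(
    frame: pd.DataFrame,
    registry: FormulaRegistry,
    remington_table: VolumeFactorTable | None = None,
) -> pd.DataFrame:
    """One prediction column per formula, row-aligned with ``frame``.

    Formulae that cannot be evaluated at all (the Remington entry without a
    volume-factor table) are omitted; inapplicable rows hold NaN.
    """
    cols: dict[str, np.ndarray] = {}
    for spec in registry:
        if spec.form == "remington_table" and remington_table is None:
            continue
        sv, _ = predict_vector(spec, frame, remington_table=remington_table)
        cols[spec.formula_id] = sv
    return pd.DataFrame(cols, index=frame.index)


def evaluate_stratum(
    frame: pd.DataFrame,
    predictions: pd.DataFrame,
    stratum: Stratum,
    effect_size: str = "hedges",
) -> list[MetricSet]:
    """Metric sets for every predicted formula within one analysis cell."""
    out = []
    for formula_id in predictions.columns:
        x, y = pair_series(frame, predictions, formula_id, stratum)
        out.append(
            compute_metrics(x, y, formula_id, stratum.label, effect_size=effect_size)
        )
    return out


def min_ssr_formula(
    metric_sets: Sequence[MetricSet], same_record_set: bool = True
) -> MetricSet:
    """The formula with the smallest SSR in one stratum.

    SSR is a sum, so it is only comparable between formulae evaluated on the
    identical record set; with ``same_record_set`` (default) the comparison
    is restricted to formulae whose n equals the stratum maximum, excluding
    formulae reduced by applicability constraints.
    """
    cands = [m for m in metric_sets if np.isfinite(m.ssr)]
    if same_record_set:
        full_n = max(m.n for m in cands)
        cands = [m for m in cands if m.n == full_n]
    if not cands:
        raise ValidationError("no formulae with a defined SSR")
    return min(cands, key=lambda m: m.ssr)


def stratified_report(
    frame: pd.DataFrame,
    registry: FormulaRegistry,
    strata: Sequence[Stratum] = ALL_STRATA,
    effect_size: str = "hedges",
    remington_table: VolumeFactorTable | None = None,
) -> dict[str, RankingTable]:
    """One ranking table per non-empty analysis cell, keyed by stratum label.

    Empty strata are omitted. The best formula per stratum is the first row
    of each table (ascending total score).
    """
    predictions = predictions_frame(frame, registry, remington_table)
    report: dict[str, RankingTable] = {}
    for stratum in strata:
        if not stratum_mask(frame, stratum).any():
            continue
        metric_sets = evaluate_stratum(frame, predictions, stratum, effect_size)
        metric_sets = [m for m in metric_sets if m.n >= 2]
        if len(metric_sets) < 2:
            continue
        report[stratum.label] = rank_formulae(metric_sets)
    return report


def best_formula_summary(report: dict[str, RankingTable]) -> pd.DataFrame:
    """Best formula per stratum with its metrics and measured/predicted mean±SD."""
    rows = []
    for label, table in report.items():
        best = table.best
        rows.append({"stratum": label, **best})
    return pd.DataFrame(rows)


def plot_bland_altman(x, y, path: str, title: str = "") -> BlandAltman:
    """Write a Bland–Altman plot (differences vs means, bias/±SD/LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _aligned(x, y)
    ba = bland_altman(x, y)
    means = (x + y) / 2.0
    diffs = x - y
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(means, diffs, s=8, alpha=0.5, color="0.3")
    ax.axhline(ba.bias, color="k", lw=1.5, label=f"bias = {ba.bias:.2f} mL")
    for sign in (-1, 1):
        ax.axhline(
            ba.bias + sign * ba.sd_diff, color="tab:orange", lw=0.8, ls=":",
            label="±1 SD" if sign == 1 else None,
        )
        ax.axhline(
            ba.bias + sign * 1.96 * ba.sd_diff, color="tab:blue", lw=1.5, ls="--",
            label="95% LoA" if sign == 1 else None,
        )
    ax.set_xlabel("Mean of measured and predicted SV (mL)")
    ax.set_ylabel("Measured − predicted SV (mL)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return ba
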