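"""Operating characteristics of the ICΔ detector on control pairs.

Runs labelled positive and negative control drug-condition pairs through an
analytical setting and summarises detector performance: sensitivity and
specificity at the ICΔ025 > 0 threshold, bias (the location of the
negative-control ICΔ distribution, ideally 0), and the rank-based AUC (the
probability that a random positive control out-scores a random negative one,
ties counting one half). Incalculable pairs never enter a denominator; their
count is a first-class output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counts import CountStore
from .ic import AnalysisSetting, ICDeltaResult, icdelta_simultaneous
from .simulate import GroundTruth


def auc_mann_whitney(positive_scores, negative_scores) -> float:
    """Rank-based AUC: P(positive score > negative score) + ½·P(tie).

    Equivalent to the Mann-Whitney U statistic normalised by the number of
    positive-negative pairs. NaN if either class is empty.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass
class EvaluationResult:
    """Per-pair ICΔ results and summary operating characteristics for one setting."""

    setting: AnalysisSetting
    per_pair: pd.DataFrame  # drug_id, condition_id, label, icdelta..., signal, incalculable
    sensitivity: float
    specificity: float
    false_positive_rate: float
    bias: float
    auc: float
    n_incalculable: int

    @property
    def calculable_negatives(self) -> pd.DataFrame:
        df = self.per_pair
        return df[(df.label == "negative") & (~df.incalculable)]

    @property
    def calculable_positives(self) -> pd.DataFrame:
        df = self.per_pair
        return df[(df.label == "positive") & (~df.incalculable)]


def evaluate(
    store: CountStore,
    truth: GroundTruth,
    setting: AnalysisSetting,
    pick: str = "point",
) -> EvaluationResult:
    """Score every control pair under the setting and summarise performance.

    Sensitivity is the signal fraction among calculable positives;
    specificity the non-signal fraction among calculable negatives; bias the
    mean negative-control ICΔ; AUC ranks the ICΔ point estimates. Metrics
    with an empty denominator are NaN (undefined), never zero.
    """
    rows = []
    for label, pairs in (("positive", truth.positive_pairs), ("negative", truth.negative_pairs)):
        for drug, condition in sorted(pairs):
            r: ICDeltaResult = icdelta_simultaneous(store, drug, condition, setting, pick=pick)
            rows.append(
                {
                    "drug_id": drug,
                    "condition_id": condition,
                    "label": label,
                    "observed_v": r.observed_v,
                    "expected_star": r.expected_star,
                    "icdelta": r.icdelta,
                    "icdelta025": r.icdelta025,
                    "icdelta975": r.icdelta975,
                    "chosen_control": str(r.chosen_control) if r.chosen_control else "",
                    "signal": r.signal,
                    "incalculable": r.incalculable,
                    "reason": r.reason or "",
                }
            )
    per_pair = pd.DataFrame(rows)

    calc = per_pair[~per_pair.incalculable]
    pos = calc[calc.label == "positive"]
    neg = calc[calc.label == "negative"]
    sensitivity = float(pos.signal.mean()) if len(pos) else float("nan")
    specificity = float((~neg.signal).mean()) if len(neg) else float("nan")
    bias = float(neg.icdelta.mean()) if len(neg) else float("nan")
    auc = auc_mann_whitney(pos.icdelta.to_numpy(), neg.icdelta.to_numpy())
    return EvaluationResult(
        setting=setting,
        per_pair=per_pair,
        sensitivity=sensitivity,
        specificity=specificity,
        false_positive_rate=1.0 - specificity if len(neg) else float("nan"),
        bias=bias,
        auc=auc,
        n_incalculable=int(per_pair.incalculable.sum()),
    )


def bias_distribution(result: EvaluationResult) -> tuple[np.ndarray, dict[str, float]]:
    """Negative-control ICΔ values with location/spread summaries.

    Reports mean, median and mean absolute value (the field does not agree
    on one location summary for bias), plus the central 95% span.
    """
    values = result.calculable_negatives.icdelta.to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError("no calculable negative controls")
    summary = {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "mean_abs": float(np.abs(values).mean()),
        "p2.5": float(np.percentile(values, 2.5)),
        "p97.5": float(np.percentile(values, 97.5)),
        "n": int(len(values)),
    }
    return values, summary


def plot_bias_distribution(results: list[EvaluationResult], path: str) -> str:
    """Histogram of negative-control ICΔ per setting (bias plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(results), 1, figsize=(6, 2.2 * len(results)), squeeze=False)
    for ax, result in zip(axes[:, 0], results):
        values = result.calculable_negatives.icdelta.to_numpy(dtype=float)
        if len(values):
            ax.hist(values, bins=30, color="#4878a8")
        ax.axvline(0.0, color="black", lw=1)
        ax.set_title(f"{result.setting.name}: negative-control ICΔ", fontsize=9)
        ax.set_xlabel("ICΔ")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


@dataclass
class SettingComparison:
    """Side-by-side operating characteristics for several settings."""

    table: pd.DataFrame
    results: dict[str, EvaluationResult]
    best_auc_setting: str
    min_bias_setting: str


def compare_settings(
    store: CountStore,
    truth: GroundTruth,
    settings: list[AnalysisSetting],
    pick: str = "point",
) -> SettingComparison:
    """Evaluate each setting and identify max-AUC and min-|bias| settings."""
    if not settings:
        raise ValueError("at least one setting required")
    results = {s.name: evaluate(store, truth, s, pick=pick) for s in settings}
    table = pd.DataFrame(
        [
            {
                "setting": name,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "false_positive_rate": r.false_positive_rate,
                "bias": r.bias,
                "auc": r.auc,
                "n_incalculable": r.n_incalculable,
            }
            for name, r in results.items()
        ]
    )
    by_auc = table.dropna(subset=["auc"])
    by_bias = table.dropna(subset=["bias"])
    best_auc = by_auc.loc[by_auc.auc.idxmax(), "setting"] if len(by_auc) else ""
    min_bias = (
        by_bias.loc[by_bias.bias.abs().idxmin(), "setting"] if len(by_bias) else ""
    )
    return SettingComparison(
        table=table, results=results, best_auc_setting=best_auc, min_bias_setting=min_bias
    )
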