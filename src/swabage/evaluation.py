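"""Accuracy and comparison statistics for age predictions.

Conventions follow forensic epigenetic-clock practice:

* **MAD** is the *mean* absolute deviation of predicted from chronological
  age in years (not the robust median-absolute-deviation statistic; the
  function is named ``mad_prediction`` to avoid that collision).
* **R²** is the squared Pearson correlation of predicted vs chronological
  age. It is invariant to affine rescaling of the predictions, so a model
  can show high R² together with a large systematic offset — R² alone
  never certifies calibration; always read it next to the MAD and the mean
  signed error.
* Model comparisons use the paired two-sided Student's t-test on
  per-sample absolute errors; group comparisons use the unpaired two-sided
  t-test (classical equal-variance by default, Welch behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "evaluate",
    "mad_prediction",
    "compare_models",
    "stratify",
    "compare_groups",
]


@dataclass
class EvaluationReport:
    """Cohort-level accuracy summary of one model's predictions."""

    model_name: str
    n: int
    mad: float
    mean_signed_error: float
    r2: float  # NaN when undefined
    r2_reason: str | None = None
    strata: dict[str, tuple[int, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"evaluation: {self.model_name} (n={self.n})",
            f"  MAD                {self.mad:.4f} years",
            f"  mean signed error  {self.mean_signed_error:+.4f} years",
        ]
        if np.isnan(self.r2):
            lines.append(f"  R²                 undefined ({self.r2_reason})")
        else:
            lines.append(f"  R² (Pearson)       {self.r2:.4f}")
        for name, (n, mad) in self.strata.items():
            mad_s = "n/a" if np.isnan(mad) else f"{mad:.4f}"
            lines.append(f"  stratum {name:<12} n={n:<4} MAD={mad_s}")
        return "\n".join(lines)


def mad_prediction(predicted: Sequence[float], chronological: Sequence[float]) -> float:
    """Mean absolute deviation between predicted and chronological age."""
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if len(p) != len(c) or len(p) == 0:
        raise ValueError("need equal, nonzero numbers of predictions and ages")
    return float(np.mean(np.abs(p - c)))


def evaluate(
    pairs: Sequence[tuple[float, float]], model_name: str = "model"
) -> EvaluationReport:
    """Summarise (predicted, chronological) pairs into an EvaluationReport."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise ValueError("pairs must be a nonempty sequence of (predicted, chronological)")
    pred, chron = arr[:, 0], arr[:, 1]
    r2, reason = float("nan"), None
    if len(arr) < 2:
        reason = "fewer than 2 pairs"
    elif np.std(pred) == 0 or np.std(chron) == 0:
        reason = "zero variance in predictions or ages"
    else:
        r2 = float(np.corrcoef(pred, chron)[0, 1] ** 2)
    return EvaluationReport(
        model_name=model_name,
        n=len(arr),
        mad=mad_prediction(pred, chron),
        mean_signed_error=float(np.mean(pred - chron)),
        r2=r2,
        r2_reason=reason,
    )


def compare_models(
    abs_errors_a: Sequence[float], abs_errors_b: Sequence[float]
) -> tuple[float, float]:
    """Paired two-sided t-test on per-sample absolute errors.

    Returns (t statistic, two-sided p). The pairing is by sample: both
    error vectors must come from the same samples in the same order.
    """
    a = np.asarray(abs_errors_a, dtype=float)
    b = np.asarray(abs_errors_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired comparison needs equal-length error vectors")
    if len(a) < 3:
        raise ValueError("need ≥ 3 pairs")
    d = a - b
    if np.var(d) == 0:
        if np.all(d == 0):  # identical vectors: no difference at all
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences: t-test degenerate")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Unpaired two-sided t-test between two groups.

    Classical equal-variance test by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n ≥ 2")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):  # identical constant groups
            return 0.0, 1.0
        raise ValueError("zero pooled variance: t-test degenerate")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def stratify(
    triples: Sequence[tuple[float, float]],
    cutpoint_years: float,
) -> dict[str, tuple[int, float]]:
    """Per-stratum n and MAD, split at chronological age ``cutpoint_years``.

    ``triples`` are (predicted, chronological) pairs; strata are
    ``"<cut"`` (chronological < cutpoint) and ``">=cut"``. An empty
    stratum reports n=0 with MAD NaN.
    """
    arr = np.asarray(triples, dtype=float)
    out: dict[str, tuple[int, float]] = {}
    for name, mask in (
        (f"<{cutpoint_years:g}", arr[:, 1] < cutpoint_years) if len(arr) else (f"<{cutpoint_years:g}", np.array([], bool)),
        (f">={cutpoint_years:g}", arr[:, 1] >= cutpoint_years) if len(arr) else (f">={cutpoint_years:g}", np.array([], bool)),
    ):
        sub = arr[mask] if len(arr) else arr.reshape(0, 2)
        if len(sub) == 0:
            out[name] = (0, float("nan"))
        else:
            out[name] = (len(sub), mad_prediction(sub[:, 0], sub[:, 1]))
    return out
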