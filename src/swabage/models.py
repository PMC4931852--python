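"""Model classes that re-derive every clock from annotated cohort data.

Each estimator follows the familiar model/results split: construct a model
from a :class:`~swabage.io.BetaMatrix`, call :meth:`fit`, get back a results
object carrying the fitted clock, its diagnostics (training MAD in years,
Pearson R²) and a ``summary()`` table.

=====================  =====================================================
model class            what it fits
=====================  =====================================================
AgeClockModel          OLS of chronological age on β at chosen CpGs
OneCpGClockModel       simple regression of β on age, inverted for
                       prediction (β = b0 + b1·age  ⇒  age = (β − b0)/b1)
CellSignatureModel     per-CpG calibration of counted %epithelial on β,
                       averaged ½/½ into a cell signature
EpithelialMixtureModel two-stage mixture-weighted estimation of the
                       epithelial clock with the blood clock and cell
                       signature held fixed (plug-in)
=====================  =====================================================

The mixture estimation is the distinctive step: for each sample the
epithelial weight w_i = ϐ_i/100 comes from the (clamped) cell signature, the
fixed blood clock explains the leukocyte share, and the epithelial
coefficients c solve the least-squares problem

    age_i − (1 − w_i)·blood(x_i)  ≈  w_i·[1, α_i, β_i, γ_i]·c

with no free intercept (the epithelial intercept is c₀ inside the scaled
design). Samples with w_i ≈ 0 carry almost no information but are retained;
if every w_i is zero the epithelial component is unidentifiable and the fit
fails. No regularization anywhere — these are plain linear models.

Ordinary least squares is delegated to statsmodels; the module's own
content is the design construction and the plug-in two-stage procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clocks import AgeModel, CellSignature, MixtureAgeModel, OneCpGModel
from .io import BetaMatrix, counted_fractions

__all__ = [
    "FitError",
    "ClockFitResults",
    "AgeClockModel",
    "OneCpGClockModel",
    "CellSignatureModel",
    "EpithelialMixtureModel",
    "fit_age_model",
    "fit_one_cpg_model",
    "calibrate_cell_signature",
    "fit_epithelial_age_model",
]


class FitError(ValueError):
    """A model could not be fitted (too few samples, degenerate design...)."""


@dataclass
class ClockFitResults:
    """Fit diagnostics plus the fitted clock (the FitReport).

    ``residual_mad`` is the mean absolute deviation of predicted from
    chronological age on the training samples, in years; ``r2`` the squared
    Pearson correlation of the same pairs (NaN when either side has zero
    variance). ``excluded_samples`` lists (sample_id, reason) for samples
    dropped before fitting.
    """

    model: AgeModel | OneCpGModel | CellSignature | MixtureAgeModel
    n_samples: int
    residual_mad: float
    r2: float
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    extras: dict[str, float] = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isnan(self.r2) and not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")

    @property
    def params(self) -> pd.Series:
        m = self.model
        if isinstance(m, AgeModel):
            return pd.Series({"intercept": m.intercept, **m.coefficients})
        if isinstance(m, OneCpGModel):
            return pd.Series({"beta0": m.beta0, "slope": m.slope})
        if isinstance(m, CellSignature):
            return pd.Series(
                {
                    f"{m.probe_delta}_slope": m.cal_delta[0],
                    f"{m.probe_delta}_intercept": m.cal_delta[1],
                    f"{m.probe_epsilon}_slope": m.cal_epsilon[0],
                    f"{m.probe_epsilon}_intercept": m.cal_epsilon[1],
                }
            )
        if isinstance(m, MixtureAgeModel):
            return pd.Series(
                {"epithelial_intercept": m.epithelial.intercept, **m.epithelial.coefficients}
            )
        raise TypeError(type(m))

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit: {self.model.name}",
            "=" * 58,
            f"{'n samples (fitted)':<28}{self.n_samples}",
            f"{'n samples (excluded)':<28}{len(self.excluded_samples)}",
            f"{'training MAD [years]':<28}{self.residual_mad:.4f}",
            f"{'training R² (Pearson)':<28}{self.r2:.4f}",
            "-" * 58,
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<28}{v: .6f}")
        for k, v in self.extras.items():
            lines.append(f"{k:<28}{v: .6f}")
        for n in self.notes:
            lines.append(f"note: {n}")
        for sid, why in self.excluded_samples:
            lines.append(f"excluded: {sid} ({why})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model.name,
            "n_samples": self.n_samples,
            "residual_mad": self.residual_mad,
            "r2": None if np.isnan(self.r2) else self.r2,
            "params": {k: float(v) for k, v in self.params.items()},
            "extras": self.extras,
            "excluded_samples": self.excluded_samples,
            "notes": list(self.notes),
        }


def _pearson_r2(pred: np.ndarray, actual: np.ndarray) -> float:
    if len(pred) < 2 or np.std(pred) == 0 or np.std(actual) == 0:
        return float("nan")
    return float(np.corrcoef(pred, actual)[0, 1] ** 2)


def _training_rows(
    data: BetaMatrix, probes: list[str], need_age: bool = True
) -> tuple[pd.DataFrame, pd.Series, list[tuple[str, str]]]:
    """Rows with age and all requested probes present; others listed out."""
    excluded: list[tuple[str, str]] = []
    keep = []
    for sid in data.values.index:
        if need_age and np.isnan(data.ages.loc[sid]):
            excluded.append((str(sid), "missing age"))
            continue
        missing = [p for p in probes if np.isnan(data.values.loc[sid, p])]
        if missing:
            excluded.append((str(sid), f"missing β at {','.join(missing)}"))
            continue
        keep.append(sid)
    return data.values.loc[keep, probes], data.ages.loc[keep], excluded


def _check_design(X: np.ndarray, colnames: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        const = [n for n, col in zip(colnames, X.T) if np.ptp(col) == 0 and n != "intercept"]
        if const:
            raise FitError(f"rank-deficient design: constant column(s) {const}")
        raise FitError("rank-deficient design (collinear columns)")


class AgeClockModel:
    """OLS of chronological age on β-values at ``probes``, with intercept."""

    def __init__(self, data: BetaMatrix, probes: list[str], name: str = "retrained-age-model"):
        if len(probes) != len(set(probes)):
            raise ValueError("duplicate probes")
        self.data = data
        self.probes = list(probes)
        self.name = name

    def fit(self) -> ClockFitResults:
        X_df, ages, excluded = _training_rows(self.data, self.probes)
        n, k = len(X_df), len(self.probes)
        if n < k + 2:
            raise FitError(f"need ≥ {k + 2} samples with age and all probes, have {n}")
        X = sm.add_constant(X_df.to_numpy(), has_constant="add")
        _check_design(X, ["intercept", *self.probes])
        res = sm.OLS(ages.to_numpy(), X).fit()
        model = AgeModel(
            name=self.name,
            intercept=float(res.params[0]),
            coefficients={p: float(c) for p, c in zip(self.probes, res.params[1:])},
        )
        pred = X @ res.params
        return ClockFitResults(
            model=model,
            n_samples=n,
            residual_mad=float(np.mean(np.abs(pred - ages.to_numpy()))),
            r2=_pearson_r2(pred, ages.to_numpy()),
            excluded_samples=excluded,
        )


class OneCpGClockModel:
    """Simple regression of β on age at one CpG, inverted for prediction."""

    def __init__(self, data: BetaMatrix, probe: str, name: str = "retrained-1-CpG-model"):
        self.data = data
        self.probe = probe
        self.name = name

    def fit(self) -> ClockFitResults:
        X_df, ages, excluded = _training_rows(self.data, [self.probe])
        n = len(X_df)
        if n < 3:
            raise FitError(f"need ≥ 3 samples with age and {self.probe}, have {n}")
        a = ages.to_numpy()
        if np.var(a) == 0:
            raise FitError("zero variance in ages")
        b = X_df[self.probe].to_numpy()
        if np.ptp(b) == 0:
            raise FitError(f"{self.probe}: constant β, fitted slope is 0, model not invertible")
        # β = beta0 + slope·age, fitted in the forward direction
        res = sm.OLS(b, sm.add_constant(a)).fit()
        beta0, slope = float(res.params[0]), float(res.params[1])
        if slope == 0:
            raise FitError(f"{self.probe}: fitted slope is 0, model not invertible")
        model = OneCpGModel(name=self.name, probe_id=self.probe, beta0=beta0, slope=slope)
        pred = (b - beta0) / slope
        return ClockFitResults(
            model=model,
            n_samples=n,
            residual_mad=float(np.mean(np.abs(pred - a))),
            r2=_pearson_r2(pred, a),
            excluded_samples=excluded,
        )


class CellSignatureModel:
    """Calibrate the two-CpG cell signature on cytology-counted samples.

    Requires counted epithelial percentages attached (via
    :func:`swabage.io.join` with cytology records). Fits, independently, the
    simple regression counted% = slope·β + intercept for each of the two
    CpGs, and averages the two calibrated predictions ½/½.
    """

    def __init__(
        self,
        data: BetaMatrix,
        probe_delta: str,
        probe_epsilon: str,
        name: str = "retrained-cell-signature",
    ):
        self.data = data
        self.probe_delta = probe_delta
        self.probe_epsilon = probe_epsilon
        self.name = name

    def fit(self) -> ClockFitResults:
        counted = counted_fractions(self.data)
        probes = [self.probe_delta, self.probe_epsilon]
        excluded: list[tuple[str, str]] = []
        keep = []
        for sid in self.data.values.index:
            if np.isnan(counted.loc[sid]):
                excluded.append((str(sid), "no counted fraction"))
                continue
            missing = [p for p in probes if np.isnan(self.data.values.loc[sid, p])]
            if missing:
                excluded.append((str(sid), f"missing β at {','.join(missing)}"))
                continue
            keep.append(sid)
        n = len(keep)
        if n < 3:
            raise FitError(f"need ≥ 3 calibration samples, have {n}")
        y = counted.loc[keep].to_numpy()
        if np.var(y) == 0:
            raise FitError("zero variance in counted fractions")
        cals: dict[str, tuple[float, float]] = {}
        per_cpg_r2: dict[str, float] = {}
        for probe in probes:
            b = self.data.values.loc[keep, probe].to_numpy()
            if np.ptp(b) == 0:
                raise FitError(f"{probe}: constant β, cannot calibrate")
            res = sm.OLS(y, sm.add_constant(b)).fit()
            cals[probe] = (float(res.params[1]), float(res.params[0]))  # (slope, intercept)
            per_cpg_r2[probe] = _pearson_r2(res.fittedvalues, y)
        sig = CellSignature(
            name=self.name,
            probe_delta=self.probe_delta,
            probe_epsilon=self.probe_epsilon,
            cal_delta=cals[self.probe_delta],
            cal_epsilon=cals[self.probe_epsilon],
        )
        combined = np.array(
            [
                sig.predict(p).raw
                for p in self.data.profiles()
                if p.sample_id in {str(s) for s in keep}
            ]
        )
        return ClockFitResults(
            model=sig,
            n_samples=n,
            residual_mad=float(np.mean(np.abs(combined - y))),
            r2=_pearson_r2(combined, y),
            excluded_samples=excluded,
            extras={
                f"r2_{self.probe_delta}": per_cpg_r2[self.probe_delta],
                f"r2_{self.probe_epsilon}": per_cpg_r2[self.probe_epsilon],
            },
            notes=("residual_mad is in percent epithelial cells, not years",),
        )


class EpithelialMixtureModel:
    """Estimate the epithelial clock from mixed swabs, blood clock fixed.

    Two-stage plug-in: epithelial weights w_i = ϐ_i/100 come from the given
    (clamped) cell signature; the blood clock's contribution
    (1 − w_i)·blood(x_i) is subtracted from age; the residual is regressed
    on the scaled design w_i·[1, probes...] with no free intercept.
    """

    def __init__(
        self,
        data: BetaMatrix,
        blood: AgeModel,
        signature: CellSignature,
        probes: list[str],
        name: str = "retrained-5-CpG-model",
    ):
        if set(blood.coefficients) != set(probes):
            raise ValueError("blood model probes must match the requested probe list")
        self.data = data
        self.blood = blood
        self.signature = signature
        self.probes = list(probes)
        self.name = name

    def fit(self) -> ClockFitResults:
        sig_probes = [self.signature.probe_delta, self.signature.probe_epsilon]
        X_df, ages, excluded = _training_rows(self.data, self.probes + sig_probes)
        n, k = len(X_df), len(self.probes)
        if n < k + 2:
            raise FitError(f"need ≥ {k + 2} complete samples, have {n}")
        keep = {str(s) for s in X_df.index}
        profiles = [p for p in self.data.profiles() if p.sample_id in keep]
        w = np.array([self.signature.predict(p).value for p in profiles]) / 100.0
        if np.all(w == 0):
            raise FitError("all epithelial fractions are 0: epithelial clock unidentifiable")
        blood_pred = np.array(
            [self.blood.predict(p, warn_negative=False).value for p in profiles]
        )
        a = ages.to_numpy()
        resid = a - (1.0 - w) * blood_pred
        X = w[:, None] * np.column_stack(
            [np.ones(n), X_df[self.probes].to_numpy()]
        )
        _check_design(X, ["intercept", *self.probes])
        res = sm.OLS(resid, X).fit()  # no added constant: intercept lives inside the scaling
        epithelial = AgeModel(
            name=f"{self.name}-epithelial",
            intercept=float(res.params[0]),
            coefficients={p: float(c) for p, c in zip(self.probes, res.params[1:])},
        )
        model = MixtureAgeModel(
            name=self.name, blood=self.blood, epithelial=epithelial, signature=self.signature
        )
        mix_pred = (1.0 - w) * blood_pred + w * (X_df[self.probes].to_numpy() @ res.params[1:] + res.params[0])
        return ClockFitResults(
            model=model,
            n_samples=n,
            residual_mad=float(np.mean(np.abs(mix_pred - a))),
            r2=_pearson_r2(mix_pred, a),
            excluded_samples=excluded,
            notes=("blood clock and cell signature held fixed (plug-in two-stage fit)",),
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_age_model(data: BetaMatrix, probes: list[str], name: str = "retrained-age-model"):
    """OLS age clock on ``probes``; returns a :class:`ClockFitResults`."""
    return AgeClockModel(data, probes, name=name).fit()


def fit_one_cpg_model(data: BetaMatrix, probe: str, name: str = "retrained-1-CpG-model"):
    """Inverted single-CpG clock; returns a :class:`ClockFitResults`."""
    return OneCpGClockModel(data, probe, name=name).fit()


def calibrate_cell_signature(
    data: BetaMatrix,
    probe_delta: str,
    probe_epsilon: str,
    name: str = "retrained-cell-signature",
):
    """Two-CpG cell-composition signature; returns a :class:`ClockFitResults`."""
    return CellSignatureModel(data, probe_delta, probe_epsilon, name=name).fit()


def fit_epithelial_age_model(
    data: BetaMatrix,
    blood: AgeModel,
    signature: CellSignature,
    probes: list[str],
    name: str = "retrained-5-CpG-model",
):
    """Mixture-weighted epithelial clock; returns a :class:`ClockFitResults`."""
    return EpithelialMixtureModel(data, blood, signature, probes, name=name).fit()
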