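"""Frozen, exactly-reproducible buccal-swab age predictors.

Five published linear models over pyrosequencing β-values:

* ``3-CpG-blood-model``   age = 38.0 − 26.4·α − 23.7·β + 164.7·γ
* ``3-CpG-swab-model``    age = 32.69 − 8.42·α − 47.38·β + 183.25·γ
* ``1-CpG-swab-model``    age = (γ − 0.0648) / 0.0046
* ``Buccal-Cell-Signature``
      ϐ [%] = (99.8·δ + 1.92)/2 + (−98.12·ε + 88.54)/2
* ``5-CpG-swab-model``    age = (1 − ϐ/100)·blood + (ϐ/100)·epithelial,
      with epithelial = 2.6 − 11.0·α − 15.6·β + 181.7·γ

where α..ε are β-values at the registry CpGs (see :mod:`swabage.registry`).
Coefficients are stored at their printed precision and never re-derived.
Where two printings of the same constant disagree, the more precise one is
adopted and the discrepancy recorded in the model's ``notes``.

Estimated epithelial fractions ϐ are clamped into [0, 100] (a physical
percentage); predicted ages are never clamped — a negative age signals a
calibration problem and is reported as-is with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, BetaProfile
from .registry import DEFAULT_REGISTRY

__all__ = [
    "AgeModel",
    "OneCpGModel",
    "CellSignature",
    "MixtureAgeModel",
    "Prediction",
    "FractionPrediction",
    "MixturePrediction",
    "predict_age_linear",
    "predict_age_one_cpg",
    "predict_buccal_fraction",
    "predict_age_mixture",
    "published_models",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Prediction:
    """A single age prediction; ``value`` is None when inputs were missing."""

    value: float | None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class FractionPrediction:
    """Estimated percent epithelial cells, clamped into [0, 100].

    ``raw`` keeps the pre-clamp value for diagnostics.
    """

    value: float | None
    raw: float | None = None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class MixturePrediction:
    """Mixture-model age plus the epithelial fraction ϐ that weighted it."""

    value: float | None
    fraction: float | None = None
    fraction_raw: float | None = None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None


# ---------------------------------------------------------------------------
# model classes


@dataclass(frozen=True)
class AgeModel:
    """Affine map from β-values to age: intercept + Σ coef·β (years)."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("coefficient map must be non-empty")
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.name}: non-finite coefficient")

    def predict(self, profile: BetaProfile, warn_negative: bool = True) -> Prediction:
        total = self.intercept
        for probe, coef in self.coefficients.items():
            b = profile.get(probe)
            if b is None:
                return Prediction(None, f"missing β at {probe}")
            total += coef * b
        if total < 0 and warn_negative:
            warnings.warn(
                f"{self.name}: negative predicted age {total:.2f} y for "
                f"sample {profile.sample_id!r}",
                stacklevel=2,
            )
        return Prediction(float(total))


@dataclass(frozen=True)
class OneCpGModel:
    """Single-CpG clock: β = beta0 + slope·age fitted, inverted to predict.

    Prediction is (β − beta0) / slope.
    """

    name: str
    probe_id: str
    beta0: float
    slope: float
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero (model not invertible)")

    def predict(self, profile: BetaProfile) -> Prediction:
        b = profile.get(self.probe_id)
        if b is None:
            return Prediction(None, f"missing β at {self.probe_id}")
        return Prediction(float((b - self.beta0) / self.slope))


@dataclass(frozen=True)
class CellSignature:
    """Two per-CpG linear calibrations averaged into percent epithelial cells.

    Each calibration maps a β-value to a percentage, percent = slope·β +
    intercept; the two estimates are combined with ``weights`` (default ½/½)
    and the combination clamped into [0, 100].
    """

    name: str
    probe_delta: str
    probe_epsilon: str
    cal_delta: tuple[float, float]  # (slope, intercept), δ → percent
    cal_epsilon: tuple[float, float]
    weights: tuple[float, float] = (0.5, 0.5)
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {self.weights}")
        if not np.all(np.isfinite([*self.cal_delta, *self.cal_epsilon])):
            raise ValueError("non-finite calibration")

    def predict(self, profile: BetaProfile) -> FractionPrediction:
        d = profile.get(self.probe_delta)
        e = profile.get(self.probe_epsilon)
        if d is None:
            return FractionPrediction(None, reason=f"missing β at {self.probe_delta}")
        if e is None:
            return FractionPrediction(None, reason=f"missing β at {self.probe_epsilon}")
        raw = self.weights[0] * (self.cal_delta[0] * d + self.cal_delta[1]) + self.weights[
            1
        ] * (self.cal_epsilon[0] * e + self.cal_epsilon[1])
        return FractionPrediction(float(np.clip(raw, 0.0, 100.0)), raw=float(raw))


@dataclass(frozen=True)
class MixtureAgeModel:
    """Cell-composition-weighted clock: two tissue clocks mixed by ϐ.

    predicted age = (1 − ϐ/100)·blood(α,β,γ) + (ϐ/100)·epithelial(α,β,γ),
    with ϐ from the cell signature unless a fixed fraction is supplied.
    """

    name: str
    blood: AgeModel
    epithelial: AgeModel
    signature: CellSignature
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.blood.coefficients) != set(self.epithelial.coefficients):
            raise ValueError("blood and epithelial sub-models must share a probe set")

    def predict(
        self, profile: BetaProfile, fixed_fraction: float | None = None
    ) -> MixturePrediction:
        if fixed_fraction is not None:
            if not 0 <= fixed_fraction <= 100:
                raise ValueError(f"fixed_fraction {fixed_fraction} outside [0, 100]")
            frac, frac_raw = float(fixed_fraction), float(fixed_fraction)
        else:
            fp = self.signature.predict(profile)
            if fp.is_missing:
                return MixturePrediction(None, reason=fp.reason)
            frac, frac_raw = fp.value, fp.raw
        pb = self.blood.predict(profile, warn_negative=False)
        if pb.is_missing:
            return MixturePrediction(None, reason=pb.reason)
        pe = self.epithelial.predict(profile, warn_negative=False)
        if pe.is_missing:
            return MixturePrediction(None, reason=pe.reason)
        w = frac / 100.0
        value = float((1 - w) * pb.value + w * pe.value)
        if value < 0:
            warnings.warn(
                f"{self.name}: negative predicted age {value:.2f} y for "
                f"sample {profile.sample_id!r}",
                stacklevel=2,
            )
        return MixturePrediction(value, fraction=frac, fraction_raw=frac_raw)


# ---------------------------------------------------------------------------
# functional API (spec surface)


def predict_age_linear(model: AgeModel, profile: BetaProfile) -> Prediction:
    return model.predict(profile)


def predict_age_one_cpg(model: OneCpGModel, profile: BetaProfile) -> Prediction:
    return model.predict(profile)


def predict_buccal_fraction(sig: CellSignature, profile: BetaProfile) -> FractionPrediction:
    return sig.predict(profile)


def predict_age_mixture(
    model: MixtureAgeModel, profile: BetaProfile, fixed_fraction: float | None = None
) -> MixturePrediction:
    return model.predict(profile, fixed_fraction=fixed_fraction)


def predict_matrix(model, matrix: BetaMatrix, fixed_fraction: float | None = None) -> pd.DataFrame:
    """Apply any model to every sample; one row per sample with status.

    Columns: sample_id, predicted, fraction_pct (mixture/signature only),
    status ('ok' or the missing-β reason).
    """
    rows = []
    for profile in matrix.profiles():
        rec: dict[str, object] = {"sample_id": profile.sample_id}
        if isinstance(model, MixtureAgeModel):
            p = model.predict(profile, fixed_fraction=fixed_fraction)
            rec["predicted"] = p.value
            rec["fraction_pct"] = p.fraction
        elif isinstance(model, CellSignature):
            p = model.predict(profile)
            rec["predicted"] = p.value
            rec["fraction_pct"] = p.value
        else:
            p = model.predict(profile)
            rec["predicted"] = p.value
        rec["status"] = "ok" if not p.is_missing else p.reason
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frozen registry

_REG = DEFAULT_REGISTRY
_ALPHA, _BETA, _GAMMA = _REG.age_probes()
_DELTA, _EPSILON = _REG.signature_probes()

BLOOD_3CPG = AgeModel(
    name="3-CpG-blood-model",
    intercept=38.0,
    coefficients={_ALPHA: -26.4, _BETA: -23.7, _GAMMA: 164.7},
    notes=("trained on 82 blood samples",),
)

SWAB_3CPG = AgeModel(
    name="3-CpG-swab-model",
    intercept=32.69,
    coefficients={_ALPHA: -8.42, _BETA: -47.38, _GAMMA: 183.25},
    notes=(
        "trained on 55 buccal swab samples",
        "intercept printed as 32.70 in one place and 32.69 in another; "
        "the more precise 32.69 is adopted",
    ),
)

SWAB_1CPG = OneCpGModel(
    name="1-CpG-swab-model",
    probe_id=_GAMMA,
    beta0=0.0648,
    slope=0.0046,
    notes=("PDE4C regression of β on age, inverted for prediction",),
)

BUCCAL_CELL_SIGNATURE = CellSignature(
    name="Buccal-Cell-Signature",
    probe_delta=_DELTA,
    probe_epsilon=_EPSILON,
    cal_delta=(99.8, 1.92),
    cal_epsilon=(-98.12, 88.54),
    notes=(
        "constants also printed rounded (1.9 / −98.1 / 88.5); the more "
        "precise printing (1.92 / −98.12 / 88.54) is adopted",
    ),
)

EPITHELIAL_3CPG = AgeModel(
    name="buccal-epithelial-sub-model",
    intercept=2.6,
    coefficients={_ALPHA: -11.0, _BETA: -15.6, _GAMMA: 181.7},
    notes=("estimated by mixture-weighted regression with the blood model fixed",),
)

SWAB_5CPG = MixtureAgeModel(
    name="5-CpG-swab-model",
    blood=BLOOD_3CPG,
    epithelial=EPITHELIAL_3CPG,
    signature=BUCCAL_CELL_SIGNATURE,
)


def published_models() -> dict[str, AgeModel | OneCpGModel | CellSignature | MixtureAgeModel]:
    """The five frozen published models, keyed by their published names."""
    return {
        m.name: m
        for m in (BLOOD_3CPG, SWAB_3CPG, SWAB_1CPG, BUCCAL_CELL_SIGNATURE, SWAB_5CPG)
    }


#: short CLI aliases
MODEL_ALIASES = {
    "blood3": "3-CpG-blood-model",
    "swab3": "3-CpG-swab-model",
    "swab1": "1-CpG-swab-model",
    "signature": "Buccal-Cell-Signature",
    "mix5": "5-CpG-swab-model",
}


# ---------------------------------------------------------------------------
# flat key-value serialization (round-trip exact via float repr)


def _emit(model) -> list[str]:
    if isinstance(model, AgeModel):
        lines = ["kind = age_model", f"name = {model.name}", f"intercept = {model.intercept!r}"]
        lines += [f"coef {p} = {c!r}" for p, c in model.coefficients.items()]
        return lines
    if isinstance(model, OneCpGModel):
        return [
            "kind = one_cpg_model",
            f"name = {model.name}",
            f"probe_id = {model.probe_id}",
            f"beta0 = {model.beta0!r}",
            f"slope = {model.slope!r}",
        ]
    if isinstance(model, CellSignature):
        return [
            "kind = cell_signature",
            f"name = {model.name}",
            f"probe_delta = {model.probe_delta}",
            f"probe_epsilon = {model.probe_epsilon}",
            f"cal_delta_slope = {model.cal_delta[0]!r}",
            f"cal_delta_intercept = {model.cal_delta[1]!r}",
            f"cal_epsilon_slope = {model.cal_epsilon[0]!r}",
            f"cal_epsilon_intercept = {model.cal_epsilon[1]!r}",
            f"weight_delta = {model.weights[0]!r}",
            f"weight_epsilon = {model.weights[1]!r}",
        ]
    if isinstance(model, MixtureAgeModel):
        lines = ["kind = mixture_age_model", f"name = {model.name}"]
        for prefix, sub in (
            ("blood.", model.blood),
            ("epithelial.", model.epithelial),
            ("signature.", model.signature),
        ):
            lines += [prefix + ln for ln in _emit(sub)]
        return lines
    raise TypeError(f"cannot serialize {type(model).__name__}")


def save_model(model, path) -> None:
    """Serialize any model to flat ``key = value`` text (round-trip exact)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(_emit(model)) + "\n")


def _parse_kv(lines: list[str]) -> dict[str, str]:
    out = {}
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        key, _, val = ln.partition(" = ")
        out[key] = val
    return out


def _build(kv: dict[str, str]):
    kind = kv["kind"]
    if kind == "age_model":
        coefs = {
            k.removeprefix("coef "): float(v) for k, v in kv.items() if k.startswith("coef ")
        }
        return AgeModel(name=kv["name"], intercept=float(kv["intercept"]), coefficients=coefs)
    if kind == "one_cpg_model":
        return OneCpGModel(
            name=kv["name"],
            probe_id=kv["probe_id"],
            beta0=float(kv["beta0"]),
            slope=float(kv["slope"]),
        )
    if kind == "cell_signature":
        return CellSignature(
            name=kv["name"],
            probe_delta=kv["probe_delta"],
            probe_epsilon=kv["probe_epsilon"],
            cal_delta=(float(kv["cal_delta_slope"]), float(kv["cal_delta_intercept"])),
            cal_epsilon=(float(kv["cal_epsilon_slope"]), float(kv["cal_epsilon_intercept"])),
            weights=(float(kv["weight_delta"]), float(kv["weight_epsilon"])),
        )
    if kind == "mixture_age_model":
        subs = {}
        for prefix in ("blood.", "epithelial.", "signature."):
            sub_kv = {k.removeprefix(prefix): v for k, v in kv.items() if k.startswith(prefix)}
            subs[prefix.rstrip(".")] = _build(sub_kv)
        return MixtureAgeModel(
            name=kv["name"],
            blood=subs["blood"],
            epithelial=subs["epithelial"],
            signature=subs["signature"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


def load_model(path):
    """Load a model previously written by :func:`save_model`."""
    with open(path, "r", encoding="utf-8") as fh:
        return _build(_parse_kv(fh.readlines()))
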