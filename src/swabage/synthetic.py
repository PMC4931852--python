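"""Synthetic two-cell-type methylation cohorts for end-to-end testing.

A buccal swab is modelled as a compositional mixture of two cell types —
leukocytes and buccal epithelial cells — each with its own β-value profile:

* marker CpGs: age-independent baselines that differ strongly between the
  two cell types (one hypo-, one hypermethylated in leukocytes);
* age CpGs: β linear in chronological age, with cell-type-specific
  intercepts and slopes;
* decoy CpGs: age-independent, tissue-shared random baselines (screening
  negatives).

For a sample of age *a* and epithelial fraction *f* (percent), every
emitted β is the convex combination

    β = (1 − f/100)·β_leuko(a) + (f/100)·β_epi(a) + ε,   ε ~ N(0, noise_sd²)

clipped into [0, 1] (clip events are counted in ``matrix.meta``).

The default cell-type profiles are constructed by
:func:`reference_cell_types` to be *exactly consistent* with the published
five-CpG mixture clock: marker baselines put the two-CpG cell signature on
an affine map of the true fraction, and the per-tissue age curves solve the
linear constraints under which

    age = (1 − ϐ/100)·blood(β) + (ϐ/100)·epithelial(β)

holds identically (ϐ being the signature output on the noise-free mixture).
A noiseless cohort drawn from these specs therefore satisfies the published
model to machine precision, which is what makes exact parameter-recovery
tests possible.

Default cohort conditions mirror the study design: 55 samples, ages uniform
on [1, 85] years, epithelial fractions uniform on [24, 91] %, β-noise
sd 0.02; the 11-sample calibration set spans counted epithelial fractions
37–88 % (leukocytes 12–63 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clocks import SWAB_5CPG, MixtureAgeModel
from .io import BetaMatrix, CytologyRecord
from .registry import DEFAULT_REGISTRY

__all__ = [
    "CellTypeSpec",
    "CohortSpec",
    "reference_cell_types",
    "generate_cohort",
    "generate_calibration_set",
    "screening_panel",
]

#: permitted excursion of the noise-free curves outside [0, 1]
CLIP_TOLERANCE = 0.01

TRUE_FRACTION_LABEL = "true_fraction_pct"


@dataclass(frozen=True)
class CellTypeSpec:
    """β-value profile of one pure cell type.

    ``marker_baselines`` maps probe → age-independent β;
    ``age_cpg_params`` maps probe → (intercept β, slope β/year).
    """

    name: str
    marker_baselines: dict[str, float] = field(default_factory=dict)
    age_cpg_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def beta_at(self, probe: str, age: float | np.ndarray) -> float | np.ndarray:
        if probe in self.marker_baselines:
            return np.broadcast_to(self.marker_baselines[probe], np.shape(age)).copy() \
                if np.ndim(age) else self.marker_baselines[probe]
        b0, b1 = self.age_cpg_params[probe]
        return b0 + b1 * age

    @property
    def probes(self) -> list[str]:
        return list(self.marker_baselines) + list(self.age_cpg_params)

    def validate(self, age_range: tuple[float, float]) -> None:
        lo, hi = age_range
        for probe in self.probes:
            for a in (lo, hi):
                v = float(np.asarray(self.beta_at(probe, a)))
                if not -CLIP_TOLERANCE <= v <= 1 + CLIP_TOLERANCE:
                    raise ValueError(
                        f"cell type {self.name!r}: probe {probe} implies β={v:.4f} "
                        f"at age {a}, outside [0,1] beyond the clipping tolerance"
                    )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort."""

    seed: int
    n_samples: int = 55
    age_range: tuple[float, float] = (1.0, 85.0)
    fraction_range: tuple[float, float] = (24.0, 91.0)
    noise_sd: float = 0.02
    n_decoy_probes: int = 0
    decoy_seed: int | None = None  # defaults to seed; fix it to share decoys across panels
    noise_model: str = "gaussian"  # or "beta": bounded noise, no clipping needed

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_range[0] <= self.fraction_range[1] <= 100):
            raise ValueError(f"fraction_range {self.fraction_range} outside [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")
        if self.noise_model not in ("gaussian", "beta"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


# ---------------------------------------------------------------------------
# construction of model-consistent cell types


def _signature_affine_in_fraction(
    model: MixtureAgeModel, leuko_markers: dict[str, float], epi_markers: dict[str, float]
) -> tuple[float, float]:
    """Signature output on a noise-free mixture as ϐ = c0·100 + c1·(100 f).

    With markers mixed linearly, the signature is affine in the fraction
    f ∈ [0, 1]; returns (c0, c1) with ϐ/100 = c0 + c1·f.
    """
    sig = model.signature
    d0, e0 = leuko_markers[sig.probe_delta], leuko_markers[sig.probe_epsilon]
    d1, e1 = epi_markers[sig.probe_delta], epi_markers[sig.probe_epsilon]
    at0 = sig.weights[0] * (sig.cal_delta[0] * d0 + sig.cal_delta[1]) + sig.weights[1] * (
        sig.cal_epsilon[0] * e0 + sig.cal_epsilon[1]
    )
    at1 = sig.weights[0] * (sig.cal_delta[0] * d1 + sig.cal_delta[1]) + sig.weights[1] * (
        sig.cal_epsilon[0] * e1 + sig.cal_epsilon[1]
    )
    return at0 / 100.0, (at1 - at0) / 100.0


def reference_cell_types(
    model: MixtureAgeModel = SWAB_5CPG,
    leuko_markers: dict[str, float] | None = None,
    epi_markers: dict[str, float] | None = None,
    leuko_alpha: tuple[float, float] = (0.90, -0.0050),
    leuko_beta: tuple[float, float] = (0.95, -0.0040),
    epi_alpha: tuple[float, float] = (0.85, -0.0035),
) -> tuple[CellTypeSpec, CellTypeSpec]:
    """Leukocyte/epithelial specs exactly consistent with ``model``.

    Marker baselines default to strongly opposing values (δ: 0.02 leuko /
    0.95 epi; ε: 0.92 leuko / 0.05 epi). The α and β age curves for
    leukocytes and the α curve for epithelium are free realism choices; the
    remaining curves are solved from the linear constraints that make

        age ≡ (1 − w)·blood(β_mix) + w·epithelial(β_mix),
        w = signature(β_mix)/100

    hold identically in (age, fraction) on noise-free mixtures.
    """
    reg = DEFAULT_REGISTRY
    pa, pb, pg = reg.age_probes()
    pd_, pe_ = reg.signature_probes()
    if leuko_markers is None:
        leuko_markers = {pd_: 0.02, pe_: 0.92}
    if epi_markers is None:
        epi_markers = {pd_: 0.95, pe_: 0.05}

    b0 = model.blood.intercept
    b = np.array([model.blood.coefficients[p] for p in (pa, pb, pg)])
    e0 = model.epithelial.intercept
    e = np.array([model.epithelial.coefficients[p] for p in (pa, pb, pg)])
    c0, c1 = _signature_affine_in_fraction(model, leuko_markers, epi_markers)

    # Leukocyte curves L(a): (b + c0·(e−b))·L(a) + b0 + c0·(e0−b0) = a.
    # α and β chosen; solve the γ curve.
    coef = b + c0 * (e - b)
    La = np.array([leuko_alpha[0], leuko_beta[0], 0.0])
    Ls = np.array([leuko_alpha[1], leuko_beta[1], 0.0])
    La[2] = (-(b0 + c0 * (e0 - b0)) - coef[:2] @ La[:2]) / coef[2]
    Ls[2] = (1.0 - coef[:2] @ Ls[:2]) / coef[2]

    # Epithelial curves E(a) via Δ = E − L, solving
    #   (e − b)·Δ = 0                       (kills the f² term)
    #   b·Δ + c1·((e0−b0) + (e−b)·L) = 0    (kills the f term)
    # for the β and γ probes, α being the free choice.
    d = e - b
    Ea = np.array([epi_alpha[0], 0.0, 0.0])
    Es = np.array([epi_alpha[1], 0.0, 0.0])
    A = np.array([[d[1], d[2]], [b[1], b[2]]])
    rhs_const = np.array(
        [
            -d[0] * (Ea[0] - La[0]),
            -b[0] * (Ea[0] - La[0]) - c1 * ((e0 - b0) + d @ La),
        ]
    )
    rhs_slope = np.array(
        [
            -d[0] * (Es[0] - Ls[0]),
            -b[0] * (Es[0] - Ls[0]) - c1 * (d @ Ls),
        ]
    )
    Ea[1:] = La[1:] + np.linalg.solve(A, rhs_const)
    Es[1:] = Ls[1:] + np.linalg.solve(A, rhs_slope)

    leuko = CellTypeSpec(
        name="leukocyte",
        marker_baselines=dict(leuko_markers),
        age_cpg_params={p: (float(La[i]), float(Ls[i])) for i, p in enumerate((pa, pb, pg))},
    )
    epi = CellTypeSpec(
        name="buccal_epithelial",
        marker_baselines=dict(epi_markers),
        age_cpg_params={p: (float(Ea[i]), float(Es[i])) for i, p in enumerate((pa, pb, pg))},
    )
    return leuko, epi


# ---------------------------------------------------------------------------
# cohort generation


def _decoy_probes(n: int, seed: int) -> dict[str, tuple[float, float]]:
    """Decoy CpGs: tissue-shared baseline plus donor-level biological sd.

    Ordinary CpGs vary between donors far more than purpose-selected
    cell-type markers do; each decoy gets a per-donor scatter sd drawn
    uniformly from [0.02, 0.20] β-units, shared across tissues.
    """
    rng = np.random.default_rng([int(seed), 1013])
    means = rng.uniform(0.1, 0.9, size=n)
    sds = rng.uniform(0.02, 0.20, size=n)
    return {f"cgd{i:05d}": (float(m), float(s)) for i, (m, s) in enumerate(zip(means, sds))}


def _beta_noise(mu: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw Beta-distributed β with mean ``mu`` and sd ≈ ``sd``.

    Method-of-moments: ν = μ(1−μ)/σ² − 1, shape a = μν, b = (1−μ)ν. Near the
    boundaries the requested sd exceeds what a Beta with that mean supports;
    the sd is shrunk there so the shapes stay positive (bounded noise never
    needs clipping).
    """
    mu = np.clip(mu, 1e-6, 1 - 1e-6)
    max_var = mu * (1 - mu)
    var = np.minimum(np.full_like(mu, sd**2), 0.5 * max_var)
    nu = max_var / var - 1.0
    return rng.beta(mu * nu, (1 - mu) * nu)


def generate_cohort(
    leuko: CellTypeSpec, epi: CellTypeSpec, spec: CohortSpec
) -> BetaMatrix:
    """Draw one cohort; true ages go into ``.ages``, true fractions into the
    ``true_fraction_pct`` label. Deterministic for a given spec."""
    if set(leuko.probes) != set(epi.probes):
        raise ValueError("cell types must define the same probe set")
    leuko.validate(spec.age_range)
    epi.validate(spec.age_range)

    rng_age = np.random.default_rng([int(spec.seed), 1])
    rng_frac = np.random.default_rng([int(spec.seed), 2])
    rng_noise = np.random.default_rng([int(spec.seed), 3])
    rng_decoy = np.random.default_rng([int(spec.seed), 5])

    n = spec.n_samples
    ages = rng_age.uniform(*spec.age_range, size=n)
    fracs = rng_frac.uniform(*spec.fraction_range, size=n) / 100.0

    probes = list(leuko.probes)
    decoys = _decoy_probes(
        spec.n_decoy_probes,
        spec.seed if spec.decoy_seed is None else spec.decoy_seed,
    )
    cols = {}
    for p in probes:
        bl = np.asarray(leuko.beta_at(p, ages), dtype=float)
        be = np.asarray(epi.beta_at(p, ages), dtype=float)
        cols[p] = (1 - fracs) * bl + fracs * be
    for p, (m, sd) in decoys.items():
        cols[p] = m + rng_decoy.normal(0.0, sd, size=n)

    values = pd.DataFrame(cols, index=[f"S{i + 1:03d}" for i in range(n)])
    clipped = 0
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            values += rng_noise.normal(0.0, spec.noise_sd, size=values.shape)
            clipped = int(((values < 0) | (values > 1)).to_numpy().sum())
            values = values.clip(0.0, 1.0)
        else:
            values = pd.DataFrame(
                _beta_noise(values.to_numpy(), spec.noise_sd, rng_noise),
                index=values.index, columns=values.columns,
            )
    else:
        clipped = int(((values < 0) | (values > 1)).to_numpy().sum())
        values = values.clip(0.0, 1.0)

    matrix = BetaMatrix(
        values,
        ages=pd.Series(ages, index=values.index),
        labels=pd.DataFrame(
            {TRUE_FRACTION_LABEL: [repr(float(f * 100)) for f in fracs]}, index=values.index
        ),
    )
    matrix.meta["n_clipped"] = clipped
    matrix.meta["spec"] = spec
    return matrix


def true_fractions(matrix: BetaMatrix) -> pd.Series:
    """True epithelial percentages stored by :func:`generate_cohort`."""
    return matrix.labels[TRUE_FRACTION_LABEL].astype(float)


def generate_calibration_set(
    leuko: CellTypeSpec,
    epi: CellTypeSpec,
    n: int = 11,
    noise_sd: float = 0.0,
    seed: int = 0,
    fraction_range: tuple[float, float] = (37.0, 88.0),
    counting_sd: float = 0.0,
) -> tuple[BetaMatrix, list[CytologyRecord]]:
    """Paired β-profiles and cytology counts for signature calibration.

    Defaults emulate the 11-smear counting experiment: epithelial fractions
    spanning 37–88 % (leukocytes 12–63 %). ``counting_sd`` adds Gaussian
    noise (in percent, clipped to [0, 100]) to the counted values.
    """
    if n < 3:
        raise ValueError("calibration set needs n ≥ 3")
    spec = CohortSpec(
        seed=seed,
        n_samples=n,
        age_range=(20.0, 60.0),
        fraction_range=fraction_range,
        noise_sd=noise_sd,
    )
    matrix = generate_cohort(leuko, epi, spec)
    rng = np.random.default_rng([int(seed), 4])
    records = []
    for sid, f in true_fractions(matrix).items():
        counted = f + (rng.normal(0.0, counting_sd) if counting_sd > 0 else 0.0)
        records.append(
            CytologyRecord(
                sample_id=str(sid),
                pct_epithelial=float(np.clip(counted, 0.0, 100.0)),
                n_cells_counted=328,
            )
        )
    return matrix, records


def screening_panel(
    leuko: CellTypeSpec,
    epi: CellTypeSpec,
    seed: int,
    n_tissue_a: int = 10,
    n_tissue_b: int = 27,
    n_age_ref: int = 3000,
    age_ref_range: tuple[float, float] = (19.0, 101.0),
    n_decoys: int = 48,
    noise_sd: float = 0.02,
) -> tuple[BetaMatrix, BetaMatrix, BetaMatrix]:
    """Matrices for the marker screen, sharing decoy baselines.

    Returns (tissue_a, tissue_b, age_reference): tissue A is pure
    epithelium (10 samples, the size of a typical swab array series),
    tissue B pure leukocytes (27 samples, a whole-blood series), and the
    age reference a large pure-blood cohort spanning adult ages. Decoys
    share baselines across all panels via a common ``decoy_seed``.

    The age reference defaults to 3000 samples so that the screen's
    |r| < 0.05 age veto sits ≈ 2.7 null standard errors (se ≈ 1/√n) above
    chance: with a smaller reference the veto would reject genuinely
    age-independent CpGs — including true markers — at a substantial rate.
    """
    common = dict(noise_sd=noise_sd, n_decoy_probes=n_decoys, decoy_seed=seed)
    tissue_a = generate_cohort(
        leuko,
        epi,
        CohortSpec(
            seed=seed * 3 + 1, n_samples=n_tissue_a, fraction_range=(100.0, 100.0), **common
        ),
    )
    tissue_b = generate_cohort(
        leuko,
        epi,
        CohortSpec(
            seed=seed * 3 + 2, n_samples=n_tissue_b, fraction_range=(0.0, 0.0), **common
        ),
    )
    age_ref = generate_cohort(
        leuko,
        epi,
        CohortSpec(
            seed=seed * 3 + 3,
            n_samples=n_age_ref,
            fraction_range=(0.0, 0.0),
            age_range=age_ref_range,
            **common,
        ),
    )
    return tissue_a, tissue_b, age_ref
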