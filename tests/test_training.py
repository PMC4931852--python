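import numpy as np
import pandas as pd
import pytest

from conftest import ols_oracle
from swabage.clocks import SWAB_3CPG, SWAB_5CPG, CellSignature
from swabage.io import BetaMatrix, join
from swabage.models import (
    FitError,
    calibrate_cell_signature,
    fit_age_model,
    fit_epithelial_age_model,
    fit_one_cpg_model,
)
from swabage.registry import DEFAULT_REGISTRY
from swabage.synthetic import CohortSpec, generate_calibration_set, generate_cohort

AGE_PROBES = list(DEFAULT_REGISTRY.age_probes())
DELTA, EPSILON = DEFAULT_REGISTRY.signature_probes()


def matrix_from_arrays(betas: np.ndarray, probes, ages=None) -> BetaMatrix:
    idx = [f"S{i}" for i in range(len(betas))]
    values = pd.DataFrame(betas, index=idx, columns=probes)
    return BetaMatrix(
        values, ages=pd.Series(ages, index=idx) if ages is not None else None
    )


class TestAgeClock:
    def test_recovers_printed_model_from_noiseless_data(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(12, 3))
        ages = SWAB_3CPG.intercept + X @ np.array(
            [SWAB_3CPG.coefficients[p] for p in AGE_PROBES]
        )
        ages = np.clip(ages, 0, None)  # keep ages admissible
        keep = ages > 0
        res = fit_age_model(matrix_from_arrays(X[keep], AGE_PROBES, ages[keep]), AGE_PROBES)
        assert res.model.intercept == pytest.approx(SWAB_3CPG.intercept, abs=1e-6)
        for p in AGE_PROBES:
            assert res.model.coefficients[p] == pytest.approx(
                SWAB_3CPG.coefficients[p], abs=1e-6
            )
        assert res.residual_mad == pytest.approx(0.0, abs=1e-8)

    def test_constant_age_gives_flat_model(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(10, 3))
        res = fit_age_model(matrix_from_arrays(X, AGE_PROBES, np.full(10, 33.0)), AGE_PROBES)
        assert res.model.intercept == pytest.approx(33.0, abs=1e-8)
        for c in res.model.coefficients.values():
            assert c == pytest.approx(0.0, abs=1e-7)
        assert np.isnan(res.r2)  # zero age variance: correlation undefined

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(20, 3))
        ages = rng.uniform(1, 85, size=20)
        res = fit_age_model(matrix_from_arrays(X, AGE_PROBES, ages), AGE_PROBES)
        expect = ols_oracle(np.column_stack([np.ones(20), X]), ages)
        got = np.array([res.model.intercept] + [res.model.coefficients[p] for p in AGE_PROBES])
        np.testing.assert_allclose(got, expect, rtol=1e-8)

    def test_constant_column_named_in_error(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(10, 3))
        X[:, 1] = 0.4
        with pytest.raises(FitError, match=AGE_PROBES[1]):
            fit_age_model(matrix_from_arrays(X, AGE_PROBES, rng.uniform(1, 85, 10)), AGE_PROBES)

    def test_too_few_samples(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(4, 3))
        with pytest.raises(FitError, match="samples"):
            fit_age_model(matrix_from_arrays(X, AGE_PROBES, [1, 2, 3, 4]), AGE_PROBES)

    def test_samples_missing_probes_excluded_and_listed(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.1, 0.9, size=(10, 3))
        m = matrix_from_arrays(X, AGE_PROBES, rng.uniform(1, 85, 10))
        m.values.iloc[0, 0] = np.nan
        res = fit_age_model(m, AGE_PROBES)
        assert res.n_samples == 9
        assert res.excluded_samples == [("S0", f"missing β at {AGE_PROBES[0]}")]


class TestOneCpGClock:
    def test_recovers_printed_constants_at_zero_noise(self):
        ages = np.linspace(1, 85, 20)
        betas = 0.0648 + 0.0046 * ages
        m = matrix_from_arrays(betas[:, None], [AGE_PROBES[2]], ages)
        res = fit_one_cpg_model(m, AGE_PROBES[2])
        assert res.model.beta0 == pytest.approx(0.0648, abs=1e-10)
        assert res.model.slope == pytest.approx(0.0046, abs=1e-10)

    def test_age_independent_beta_not_invertible(self):
        ages = np.linspace(1, 85, 10)
        m = matrix_from_arrays(np.full((10, 1), 0.3), [AGE_PROBES[2]], ages)
        with pytest.raises(FitError, match="invertible"):
            fit_one_cpg_model(m, AGE_PROBES[2])

    def test_slope_matches_closed_form_oracle(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(1, 85, size=55)
        betas = np.clip(0.0648 + 0.0046 * ages + rng.normal(0, 0.02, 55), 0, 1)
        res = fit_one_cpg_model(matrix_from_arrays(betas[:, None], ["g"], ages), "g")
        # closed-form simple regression of beta on age
        slope = np.sum((ages - ages.mean()) * (betas - betas.mean())) / np.sum(
            (ages - ages.mean()) ** 2
        )
        beta0 = betas.mean() - slope * ages.mean()
        assert res.model.slope == pytest.approx(slope, rel=1e-10)
        assert res.model.beta0 == pytest.approx(beta0, rel=1e-10)


class TestSignatureCalibration:
    def test_noiseless_calibration_is_exact(self, cell_types):
        leuko, epi = cell_types
        matrix, records = generate_calibration_set(leuko, epi, n=11, noise_sd=0.0, seed=2)
        res = calibrate_cell_signature(join(matrix, cytology=records), DELTA, EPSILON)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.residual_mad == pytest.approx(0.0, abs=1e-7)

    def test_combined_r2_at_least_worst_single_cpg(self, cell_types):
        leuko, epi = cell_types
        matrix, records = generate_calibration_set(leuko, epi, n=11, noise_sd=0.02, seed=3)
        res = calibrate_cell_signature(join(matrix, cytology=records), DELTA, EPSILON)
        assert res.r2 >= min(res.extras.values()) - 1e-9

    def test_per_cpg_regressions_match_oracle(self, cell_types):
        leuko, epi = cell_types
        matrix, records = generate_calibration_set(leuko, epi, n=11, noise_sd=0.02, seed=4)
        joined = join(matrix, cytology=records)
        res = calibrate_cell_signature(joined, DELTA, EPSILON)
        y = np.array([r.pct_epithelial for r in records])
        for probe, (slope, intercept) in (
            (DELTA, res.model.cal_delta), (EPSILON, res.model.cal_epsilon)
        ):
            X = np.column_stack([np.ones(11), joined.values[probe].to_numpy()])
            expect = ols_oracle(X, y)
            assert intercept == pytest.approx(expect[0], rel=1e-8)
            assert slope == pytest.approx(expect[1], rel=1e-8)

    def test_two_samples_insufficient(self, cell_types):
        leuko, epi = cell_types
        with pytest.raises(ValueError):
            generate_calibration_set(leuko, epi, n=2, seed=5)
        matrix, records = generate_calibration_set(leuko, epi, n=3, seed=5)
        with pytest.raises(FitError):
            calibrate_cell_signature(join(matrix, cytology=records[:2]), DELTA, EPSILON)


class TestEpithelialMixtureFit:
    def test_zero_noise_recovers_printed_epithelial_coefficients(self, cell_types):
        leuko, epi = cell_types
        cohort = generate_cohort(leuko, epi, CohortSpec(seed=11, noise_sd=0.0))
        res = fit_epithelial_age_model(
            cohort, SWAB_5CPG.blood, SWAB_5CPG.signature, AGE_PROBES
        )
        fitted = res.model.epithelial
        assert fitted.intercept == pytest.approx(2.6, abs=1e-6)
        assert fitted.coefficients[AGE_PROBES[0]] == pytest.approx(-11.0, abs=1e-6)
        assert fitted.coefficients[AGE_PROBES[1]] == pytest.approx(-15.6, abs=1e-6)
        assert fitted.coefficients[AGE_PROBES[2]] == pytest.approx(181.7, abs=1e-6)

    def test_zero_noise_matches_weighted_normal_equations_oracle(self, cell_types):
        leuko, epi = cell_types
        cohort = generate_cohort(
            leuko, epi, CohortSpec(seed=12, n_samples=30, noise_sd=0.01)
        )
        res = fit_epithelial_age_model(
            cohort, SWAB_5CPG.blood, SWAB_5CPG.signature, AGE_PROBES
        )
        w = np.array(
            [SWAB_5CPG.signature.predict(p).value for p in cohort.profiles()]
        ) / 100.0
        blood = np.array([SWAB_5CPG.blood.predict(p, warn_negative=False).value
                          for p in cohort.profiles()])
        ages = cohort.ages.to_numpy()
        X = w[:, None] * np.column_stack(
            [np.ones(30), cohort.values[AGE_PROBES].to_numpy()]
        )
        expect = ols_oracle(X, ages - (1 - w) * blood)
        got = res.params.to_numpy()
        np.testing.assert_allclose(got, expect, rtol=1e-8)

    # the printed signature cannot emit exactly 0 or 100 for β in [0,1]
    # (raw span is -3.83..95.13), so the degenerate-weight cases use a
    # full-range calibration instead
    _FULL_RANGE_SIG = CellSignature(
        name="full-range", probe_delta=DELTA, probe_epsilon=EPSILON,
        cal_delta=(100.0, 0.0), cal_epsilon=(-100.0, 100.0),
    )

    def test_all_epithelial_reduces_to_plain_age_fit(self, cell_types):
        leuko, epi = cell_types
        cohort = generate_cohort(
            leuko, epi,
            CohortSpec(seed=13, n_samples=25, noise_sd=0.01, fraction_range=(100.0, 100.0)),
        )
        # signature fraction exactly 100 for every sample
        cohort.values[DELTA] = 1.0
        cohort.values[EPSILON] = 0.0
        res = fit_epithelial_age_model(
            cohort, SWAB_5CPG.blood, self._FULL_RANGE_SIG, AGE_PROBES
        )
        plain = fit_age_model(cohort, AGE_PROBES)
        np.testing.assert_allclose(
            res.params.to_numpy(), plain.params.to_numpy(), rtol=1e-8
        )

    def test_all_leukocyte_unidentifiable(self, cell_types):
        leuko, epi = cell_types
        cohort = generate_cohort(
            leuko, epi,
            CohortSpec(seed=14, n_samples=25, noise_sd=0.0, fraction_range=(0.0, 0.0)),
        )
        cohort.values[DELTA] = 0.0
        cohort.values[EPSILON] = 1.0  # signature output exactly 0
        with pytest.raises(FitError, match="unidentifiable"):
            fit_epithelial_age_model(
                cohort, SWAB_5CPG.blood, self._FULL_RANGE_SIG, AGE_PROBES
            )

    def test_mixture_training_mad_beats_unadjusted_blood_model(self, cell_types):
        leuko, epi = cell_types
        for seed in range(5):
            cohort = generate_cohort(leuko, epi, CohortSpec(seed=seed, noise_sd=0.02))
            res = fit_epithelial_age_model(
                cohort, SWAB_5CPG.blood, SWAB_5CPG.signature, AGE_PROBES
            )
            blood_pred = np.array(
                [SWAB_5CPG.blood.predict(p, warn_negative=False).value
                 for p in cohort.profiles()]
            )
            blood_mad = float(np.mean(np.abs(blood_pred - cohort.ages.to_numpy())))
            assert res.residual_mad <= blood_mad


class TestOracleEquivalenceProperty:
    """Every least-squares fit agrees with (X'X)^-1 X'y on random designs."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_designs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        X = rng.uniform(0.05, 0.95, size=(n, 3))
        ages = rng.uniform(1, 85, size=n)
        res = fit_age_model(matrix_from_arrays(X, AGE_PROBES, ages), AGE_PROBES)
        expect = ols_oracle(np.column_stack([np.ones(n), X]), ages)
        got = np.array([res.model.intercept] + [res.model.coefficients[p] for p in AGE_PROBES])
        np.testing.assert_allclose(got, expect, rtol=1e-8)
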