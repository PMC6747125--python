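"""Constrained exhaustive model search: enumeration, fitting, constraint,
within-error counting, and end-to-end search behaviour."""

import itertools

import numpy as np
import pytest

from wntcrd import (
    LIPID_PROTEIN,
    PROTEIN_PROTEIN,
    AffinityMeasurement,
    AffinityPrediction,
    DescriptorRecord,
    LinearAffinityModel,
    ModelSearchConfig,
    ModelTerm,
    SyntheticSpec,
    check_lipid_favourable,
    count_within_experimental_error,
    delta_g_from_kd,
    enumerate_subsets,
    fit_least_squares,
    generate_descriptor_matrix,
    generate_measurements,
    search,
)


class TestEnumerateSubsets:
    def test_counts_match_combinatorics(self):
        classes = {f"p{i}": PROTEIN_PROTEIN for i in range(4)} | {"l0": LIPID_PROTEIN}
        assert len(enumerate_subsets(classes, k=4, n_lipid=1)) == 4  # C(4,3) * 1

        classes = {f"p{i}": PROTEIN_PROTEIN for i in range(3)} | {
            f"l{i}": LIPID_PROTEIN for i in range(2)
        }
        assert len(enumerate_subsets(classes, k=2, n_lipid=1)) == 6  # 3 * 2

    def test_composition_enforced(self):
        classes = {f"p{i}": PROTEIN_PROTEIN for i in range(5)} | {
            f"l{i}": LIPID_PROTEIN for i in range(2)
        }
        for subset in enumerate_subsets(classes, k=3, n_lipid=1):
            assert sum(1 for n in subset if n.startswith("l")) == 1
            assert len(set(subset)) == 3

    def test_deterministic_lexicographic_order(self):
        classes = {"b": PROTEIN_PROTEIN, "a": PROTEIN_PROTEIN, "z": LIPID_PROTEIN}
        subsets = enumerate_subsets(classes, k=2, n_lipid=1)
        assert subsets == sorted(subsets)
        assert subsets == enumerate_subsets(classes, k=2, n_lipid=1)

    def test_infeasible_composition_raises(self):
        classes = {"p0": PROTEIN_PROTEIN, "l0": LIPID_PROTEIN}
        with pytest.raises(ValueError, match="cannot form subsets"):
            enumerate_subsets(classes, k=3, n_lipid=2)


class TestFitLeastSquares:
    def test_exact_line(self):
        x = np.arange(5.0).reshape(-1, 1)
        y = 2.0 * x[:, 0] - 1.0
        coefs, intercept = fit_least_squares(x, y)
        assert coefs[0] == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(-1.0, abs=1e-12)

    def test_constant_target(self):
        x = np.arange(6.0).reshape(-1, 1)
        coefs, intercept = fit_least_squares(x, np.full(6, 3.5))
        assert coefs[0] == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(3.5)

    def test_planted_coefficients_recovered_noiselessly(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, size=(10, 3))
        beta = np.array([1.5, -0.7, 0.2])
        y = x @ beta + 0.9
        coefs, intercept = fit_least_squares(x, y)
        assert np.allclose(coefs, beta, atol=1e-8)
        assert intercept == pytest.approx(0.9, abs=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        coefs, intercept = fit_least_squares(x, y)
        resid = y - (x @ coefs + intercept)
        assert np.all(np.abs(x.T @ resid) < 1e-8)
        assert abs(resid.sum()) < 1e-8

    def test_agrees_with_statsmodels(self):
        """Independent cross-check of the OLS fit against statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        coefs, intercept = fit_least_squares(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit().params
        assert intercept == pytest.approx(ref[0], abs=1e-10)
        assert np.allclose(coefs, ref[1:], atol=1e-10)


def _lipid_model(coef):
    return LinearAffinityModel(
        "m", (ModelTerm("lp", coef, LIPID_PROTEIN), ModelTerm("pp", 1.0, PROTEIN_PROTEIN)), 0.0
    )


class TestCheckLipidFavourable:
    def records(self, lp_values):
        return [DescriptorRecord(f"c{i}", {"lp": v, "pp": 0.0}) for i, v in enumerate(lp_values)]

    def test_negative_coefficient_on_positive_descriptor(self):
        assert check_lipid_favourable(_lipid_model(-0.3), self.records([5.0, 20.0, 1.0]))

    def test_positive_coefficient_on_positive_descriptor(self):
        assert not check_lipid_favourable(_lipid_model(0.3), self.records([5.0, 20.0]))

    def test_zero_coefficient_is_favourable(self):
        assert check_lipid_favourable(_lipid_model(0.0), self.records([5.0, 20.0]))

    def test_mean_mode_relaxes_per_sample(self):
        # one unfavourable sample, favourable on average
        recs = self.records([-10.0, 1.0])
        model = _lipid_model(1.0)
        assert not check_lipid_favourable(model, recs, mode="per-sample")
        assert check_lipid_favourable(model, recs, mode="mean")


class TestCountWithinExperimentalError:
    def _pred(self, cid, dg):
        return AffinityPrediction(complex_id=cid, dg_kcal_mol=dg)

    def test_zero_width_ranges_require_exact_match(self):
        meas = [AffinityMeasurement(f"c{i}", kd_nm=10.0 * (i + 1), kd_err_nm=0.0)
                for i in range(3)]
        exact = [self._pred(m.complex_id, m.dg_exp) for m in meas]
        assert count_within_experimental_error(exact, meas) == 3
        off = [self._pred(m.complex_id, m.dg_exp + 0.01) for m in meas]
        assert count_within_experimental_error(off, meas) == 0

    def test_interval_membership(self):
        meas = [AffinityMeasurement("c", kd_nm=10.0, kd_err_nm=5.0)]
        inside = [self._pred("c", delta_g_from_kd(12.0))]
        assert count_within_experimental_error(inside, meas) == 1
        outside = [self._pred("c", delta_g_from_kd(16.0))]
        assert count_within_experimental_error(outside, meas) == 0

    def test_missing_error_range_counts_as_not_within(self):
        meas = [AffinityMeasurement("c", kd_nm=10.0, kd_err_nm=None)]
        preds = [self._pred("c", delta_g_from_kd(10.0))]
        assert count_within_experimental_error(preds, meas) == 0

    def test_error_band_wider_than_kd_still_bounded_above(self):
        meas = [AffinityMeasurement("c", kd_nm=10.0, kd_err_nm=50.0)]
        assert count_within_experimental_error([self._pred("c", -20.0)], meas) == 1

    def test_unmatched_complex_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            count_within_experimental_error(
                [self._pred("ghost", -10.0)],
                [AffinityMeasurement("c", kd_nm=10.0, kd_err_nm=1.0)],
            )


def brute_force_search(matrix, measurements, k, n_lipid):
    """Independent naive enumeration: per-sample constraint, numpy polyfit-free
    normal-equation OLS, no ranking — returns {subset: (rmse_train, rmse_test)}."""
    by_id = {m.complex_id: m for m in measurements}
    train = [c for c in matrix.complex_ids if by_id[c].set_label == "training"]
    test = [c for c in matrix.complex_ids if by_id[c].set_label == "test"]
    protein = sorted(n for n, c in matrix.classes.items() if c == PROTEIN_PROTEIN)
    lipid = sorted(n for n, c in matrix.classes.items() if c == LIPID_PROTEIN)
    out = {}
    for pp in itertools.combinations(protein, k - n_lipid):
        for lp in itertools.combinations(lipid, n_lipid):
            subset = tuple(sorted(pp + lp))
            xtr = matrix.data.loc[train, list(subset)].to_numpy()
            ytr = np.array([by_id[c].dg_exp for c in train])
            a = np.column_stack([xtr, np.ones(len(train))])
            beta = np.linalg.solve(a.T @ a, a.T @ ytr)
            lipid_cols = [i for i, n in enumerate(subset) if n in lp]
            contrib = xtr[:, lipid_cols] @ beta[lipid_cols]
            if np.any(contrib > 0):
                continue
            xte = matrix.data.loc[test, list(subset)].to_numpy()
            yte = np.array([by_id[c].dg_exp for c in test])
            rtr = float(np.sqrt(np.mean((a @ beta - ytr) ** 2)))
            pte = np.column_stack([xte, np.ones(len(test))]) @ beta
            rte = float(np.sqrt(np.mean((pte - yte) ** 2)))
            out[subset] = (rtr, rte)
    return out


@pytest.fixture
def noiseless_study():
    spec = SyntheticSpec(m_protein=10, m_lipid=2, noise_sd=0.0, seed=123)
    matrix = generate_descriptor_matrix(spec)
    measurements, dg_true = generate_measurements(matrix, spec)
    return spec, matrix, measurements, dg_true


class TestSearch:
    def test_planted_model_recovered_noiselessly(self, noiseless_study):
        spec, matrix, measurements, _ = noiseless_study
        result = search(matrix, measurements, ModelSearchConfig(k=4, n_lipid=1))
        best = result.best
        planted = spec.planted_model
        assert best.model.descriptor_names == tuple(sorted(planted.descriptor_names))
        fitted = {t.descriptor: t.coefficient for t in best.model.terms}
        for term in planted.terms:
            assert fitted[term.descriptor] == pytest.approx(term.coefficient, abs=1e-6)
        assert best.model.intercept == pytest.approx(planted.intercept, abs=1e-6)
        assert best.rmse_train == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_oracle(self):
        """Feasible subsets and their RMSEs equal an independent enumeration."""
        spec = SyntheticSpec(n_train=12, n_test=6, m_protein=8, m_lipid=2,
                             noise_sd=0.25, seed=77)
        matrix = generate_descriptor_matrix(spec)
        measurements, _ = generate_measurements(matrix, spec)
        config = ModelSearchConfig(k=2, n_lipid=1)
        result = search(matrix, measurements, config)
        oracle = brute_force_search(matrix, measurements, k=2, n_lipid=1)
        ours = {c.model.descriptor_names: (c.rmse_train, c.rmse_test)
                for c in result.candidates}
        assert set(ours) == set(oracle)
        for subset, (rtr, rte) in oracle.items():
            assert ours[subset][0] == pytest.approx(rtr, abs=1e-10)
            assert ours[subset][1] == pytest.approx(rte, abs=1e-10)

    def test_every_candidate_satisfies_constraint(self, noiseless_study):
        _, matrix, measurements, _ = noiseless_study
        result = search(matrix, measurements, ModelSearchConfig(k=3, n_lipid=1))
        train_records = [r for r in matrix.records()
                         if any(m.complex_id == r.complex_id and m.set_label == "training"
                                for m in measurements)]
        assert result.candidates
        for cand in result.candidates:
            assert check_lipid_favourable(cand.model, train_records, "per-sample")

    def test_unfavourable_planted_lipid_subset_excluded(self):
        planted = LinearAffinityModel(
            "anti",
            (
                ModelTerm("pp_001", 0.06715, PROTEIN_PROTEIN),
                ModelTerm("pp_002", 0.001913, PROTEIN_PROTEIN),
                ModelTerm("pp_003", -0.01128, PROTEIN_PROTEIN),
                ModelTerm("lp_001", +0.3072, LIPID_PROTEIN),  # unfavourable sign
            ),
            intercept=-6.2941,
        )
        spec = SyntheticSpec(m_protein=10, m_lipid=2, noise_sd=0.0, seed=9,
                             planted_model=planted)
        matrix = generate_descriptor_matrix(spec)
        measurements, _ = generate_measurements(matrix, spec)
        result = search(matrix, measurements, ModelSearchConfig(k=4, n_lipid=1))
        planted_subset = tuple(sorted(planted.descriptor_names))
        assert planted_subset not in {c.model.descriptor_names for c in result.candidates}
        assert result.n_rejected_constraint >= 1

    def test_ranking_by_rmse_train_puts_minimum_first(self, noiseless_study):
        _, matrix, measurements, _ = noiseless_study
        result = search(matrix, measurements,
                        ModelSearchConfig(k=2, n_lipid=1, ranking="rmse_train"))
        rmses = [c.rmse_train for c in result.candidates]
        assert rmses == sorted(rmses)

    def test_collinear_subsets_skipped_and_counted(self, noiseless_study):
        _, matrix, measurements, _ = noiseless_study
        data = matrix.data.copy()
        data["pp_dup"] = data["pp_001"] * 2.0  # exact duplicate direction
        classes = dict(matrix.classes) | {"pp_dup": PROTEIN_PROTEIN}
        from wntcrd import DescriptorMatrix

        widened = DescriptorMatrix(data=data, classes=classes)
        result = search(widened, measurements, ModelSearchConfig(k=2, n_lipid=0))
        assert result.n_skipped_collinear >= 1
        assert ("pp_001", "pp_dup") not in {c.model.descriptor_names
                                            for c in result.candidates}

    def test_no_feasible_candidates_gives_empty_list_with_diagnostics(self):
        planted = LinearAffinityModel(
            "anti", (ModelTerm("pp_001", 0.1, PROTEIN_PROTEIN),
                     ModelTerm("lp_001", 0.3, LIPID_PROTEIN)), -8.0)
        spec = SyntheticSpec(n_train=8, n_test=4, m_protein=2, m_lipid=1,
                             noise_sd=0.0, seed=21, planted_model=planted)
        matrix = generate_descriptor_matrix(spec)
        measurements, _ = generate_measurements(matrix, spec)
        # with one lipid column correlating positively with dG, every k=1
        # lipid-only model gets a positive coefficient and is rejected
        result = search(matrix, measurements, ModelSearchConfig(k=1, n_lipid=1))
        assert result.candidates == []
        assert result.n_enumerated == 1
        assert result.n_rejected_constraint == 1

    def test_least_squares_beats_perturbed_coefficients(self, noiseless_study):
        """No coefficient perturbation improves training RMSE on the same subset."""
        spec = SyntheticSpec(m_protein=6, m_lipid=1, noise_sd=0.4, seed=31)
        matrix = generate_descriptor_matrix(spec)
        measurements, _ = generate_measurements(matrix, spec)
        result = search(matrix, measurements, ModelSearchConfig(k=2, n_lipid=1))
        best = result.best
        by_id = {m.complex_id: m for m in measurements}
        train = [c for c in matrix.complex_ids if by_id[c].set_label == "training"]
        x = matrix.data.loc[train, list(best.model.descriptor_names)].to_numpy()
        y = np.array([by_id[c].dg_exp for c in train])
        base = np.array([t.coefficient for t in best.model.terms])
        rng = np.random.default_rng(0)
        for _ in range(20):
            perturbed = base + rng.normal(0, 0.05, base.shape)
            rmse_p = np.sqrt(np.mean((x @ perturbed + best.model.intercept - y) ** 2))
            assert rmse_p >= best.rmse_train - 1e-12


class TestMeasurementValidation:
    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            AffinityMeasurement("c", kd_nm=0.0)

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            AffinityMeasurement("c", kd_nm=1.0, kd_err_nm=-1.0)

    def test_unknown_set_label_rejected(self):
        with pytest.raises(ValueError, match="set label"):
            AffinityMeasurement("c", kd_nm=1.0, set_label="validation")
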