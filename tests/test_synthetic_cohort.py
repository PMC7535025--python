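"""Generator: quantile-anchored marginals, copula calibration, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anemiascope.synthetic_cohort import (
    CalibrationError,
    CopulaSpec,
    QuantileAnchoredMarginal,
    build_anchors,
    calibrate_copula,
    default_cohort_spec,
    generate_cohort,
    read_cohort_csv,
    repair_correlation_matrix,
    sample_marginal,
    write_cohort_csv,
)

HB_ANCHORS = ((0.066, 110.0), (0.191, 120.0), (0.25, 123.0), (0.5, 131.5),
              (0.75, 139.0))


@pytest.fixture()
def hb_marginal():
    return QuantileAnchoredMarginal(name="hb", anchors=HB_ANCHORS)


class TestQuantileAnchoredMarginal:
    @pytest.mark.parametrize(
        "u, expected",
        [(0.5, 131.5), (0.25, 123.0), (0.75, 139.0), (0.191, 120.0),
         (0.066, 110.0)],
    )
    def test_anchor_values_reproduced(self, hb_marginal, u, expected):
        assert sample_marginal(hb_marginal, [u])[0] == pytest.approx(expected)

    def test_anemia_threshold_anchor_inverts_to_printed_prevalence(
        self, hb_marginal
    ):
        # the anchor at 120 g/L is placed so P(Hb < 120) = 0.191; invert the
        # interpolator to confirm
        assert hb_marginal.cdf(120.0) == pytest.approx(0.191, abs=1e-12)
        assert hb_marginal.cdf(110.0) == pytest.approx(0.066, abs=1e-12)

    def test_non_monotone_anchors_rejected_with_offending_pair(self):
        with pytest.raises(CalibrationError, match=r"\(0.5, 131.5\)"):
            QuantileAnchoredMarginal(
                name="bad", anchors=((0.25, 123.0), (0.5, 131.5), (0.75, 131.0))
            )

    def test_log_scale_requires_positive_values(self):
        with pytest.raises(CalibrationError, match="<= 0"):
            QuantileAnchoredMarginal(
                name="bad", anchors=((0.25, -1.0), (0.5, 2.0)), log_scale=True
            )

    def test_u_outside_unit_interval_rejected(self, hb_marginal):
        with pytest.raises(ValueError):
            hb_marginal.ppf([0.0, 0.5])

    def test_log_scale_interpolates_geometrically(self):
        m = QuantileAnchoredMarginal(
            name="ferritin", anchors=((0.25, 12.0), (0.75, 56.0)),
            log_scale=True,
        )
        # midpoint in probability is the geometric mean of the anchors
        assert m.ppf([0.5])[0] == pytest.approx(np.sqrt(12.0 * 56.0))

    def test_upper_tail_capped(self):
        m = QuantileAnchoredMarginal(
            name="x", anchors=((0.4, 10.0), (0.5, 100.0)), log_scale=True
        )
        assert m.ppf([0.999])[0] == pytest.approx(500.0)  # 5x outer anchor

    def test_bounds_clip(self):
        m = QuantileAnchoredMarginal(
            name="selenium", anchors=((0.25, 2.6), (0.5, 3.0), (0.75, 3.4)),
            bounds=(2.0, 5.0),
        )
        v = m.ppf(np.linspace(0.001, 0.999, 500))
        assert v.min() >= 2.0 and v.max() <= 5.0

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=2, max_size=30))
    def test_ppf_is_monotone(self, u):
        m = QuantileAnchoredMarginal(name="hb", anchors=HB_ANCHORS)
        u = np.sort(np.asarray(u))
        v = m.ppf(u)
        assert np.all(np.diff(v) >= -1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.067, 0.749))
    def test_cdf_inverts_ppf_inside_anchor_range(self, u):
        m = QuantileAnchoredMarginal(name="hb", anchors=HB_ANCHORS)
        assert m.cdf(m.ppf([u])[0]) == pytest.approx(u, abs=1e-9)


class TestBuildAnchors:
    def test_threshold_takes_precedence_over_conflicting_iqr(self):
        # zinc: printed IQR upper quartile 11 contradicts 78% below 10.7
        with pytest.warns(UserWarning, match="conflicts"):
            anchors = build_anchors(
                "zinc", median=9.5, iqr=(8.0, 11.0),
                thresholds=[(10.7, 0.78)],
            )
        assert anchors == ((0.25, 8.0), (0.5, 9.5), (0.78, 10.7))

    def test_consistent_anchors_all_kept(self):
        anchors = build_anchors(
            "hb", median=131.5, iqr=(123.0, 139.0),
            thresholds=[(110.0, 0.066), (120.0, 0.191)],
        )
        assert anchors == HB_ANCHORS


class TestCopula:
    def test_identity_target_gives_identity_latent(self):
        spec = default_cohort_spec(seed=0)
        identity = CopulaSpec(
            variables=spec.copula.variables,
            target_corr=np.eye(len(spec.copula.variables)),
        )
        out = calibrate_copula(identity, spec.marginals, n_cal=1000, seed=0)
        np.testing.assert_allclose(
            out.repaired_latent_corr, np.eye(len(spec.copula.variables))
        )
        assert out.max_repair_perturbation == 0.0

    def test_target_correlation_recovered_on_generated_data(self):
        # printed CRP-AGP association r = 0.34 on the log scale
        spec = default_cohort_spec(n=100_000, seed=5)
        spec.copula = calibrate_copula(
            spec.copula, spec.marginals, n_cal=100_000, seed=5
        )
        df = generate_cohort(spec)
        r = np.corrcoef(np.log(df["crp"]), np.log(df["agp"]))[0, 1]
        assert r == pytest.approx(0.34, abs=0.01)

    def test_non_positive_definite_target_repaired(self):
        bad = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0  # oracle: eigendecomposition
        repaired, perturbation = repair_correlation_matrix(bad)
        assert np.linalg.eigvalsh(repaired).min() > 1e-8
        assert perturbation > 0
        np.testing.assert_allclose(np.diag(repaired), 1.0)

    def test_unattainable_target_names_the_pair(self):
        spec = default_cohort_spec(seed=0)
        k = len(spec.copula.variables)
        t = np.eye(k)
        t[0, 1] = t[1, 0] = 0.99999
        bad = CopulaSpec(variables=spec.copula.variables, target_corr=t)
        with pytest.raises(CalibrationError, match="hb, ferritin"):
            calibrate_copula(bad, spec.marginals, n_cal=2000, seed=0)

    def test_asymmetric_target_rejected(self):
        t = np.eye(2)
        t[0, 1] = 0.3
        with pytest.raises(CalibrationError, match="symmetric"):
            CopulaSpec(variables=("a", "b"), target_corr=t)


class TestGenerateCohort:
    def test_single_record(self, calibrated_spec):
        spec = dataclasses.replace(calibrated_spec, n=1)
        df = generate_cohort(spec)
        assert len(df) == 1
        assert (df[list(calibrated_spec.marginals)] > 0).all().all()

    def test_seed_determinism_byte_identical_csv(self, calibrated_spec, tmp_path):
        spec = dataclasses.replace(calibrated_spec, n=200)
        for tag in ("a", "b"):
            write_cohort_csv(generate_cohort(spec), tmp_path / f"{tag}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_csv_round_trip_lossless(self, cohort, tmp_path):
        write_cohort_csv(cohort, tmp_path / "c.csv")
        back = read_cohort_csv(tmp_path / "c.csv")
        pd.testing.assert_frame_equal(back, cohort)

    def test_missing_column_rejected_by_name(self, cohort, tmp_path):
        cohort.drop(columns=["agp"]).to_csv(tmp_path / "c.csv", index=False)
        with pytest.raises(ValueError, match="agp"):
            read_cohort_csv(tmp_path / "c.csv")

    def test_marginals_preserved_through_copula(self, cohort, calibrated_spec):
        # each empirical quantile at an anchor probability matches the anchor
        for name, m in calibrated_spec.marginals.items():
            for p, q in m.anchors:
                emp = np.quantile(cohort[name], p)
                assert emp == pytest.approx(q, rel=0.05), name

    def test_record_invariants(self, cohort):
        assert cohort["hb"].between(40, 200).all()
        assert cohort["selenium"].between(2.0, 5.0).all()
        for col in ("ferritin", "tfr", "crp", "agp", "plasma_iron",
                    "hepcidin", "zinc"):
            assert (cohort[col] > 0).all()
        assert cohort["gravidity"].between(1, 8).all()
        assert (cohort["gravidity"] >= cohort["n_children"].clip(upper=8)).all()

    def test_hfias_frequency_requires_occurrence(self, cohort):
        for i in range(1, 10):
            occ = cohort[f"hfias{i}_occ"]
            freq = cohort[f"hfias{i}_freq"]
            assert ((freq > 0) == (occ == 1)).all()

    def test_categorical_frequencies_match_spec(self, cohort, calibrated_spec):
        probs = calibrated_spec.categorical_probs["education"]
        emp = (cohort["education"] == "illiterate").mean()
        assert emp == pytest.approx(probs["illiterate"], abs=0.03)

    def test_effects_hook_lowers_hb_for_risk_groups(self, calibrated_spec):
        from anemiascope.synthetic_cohort import EffectsHook

        base = dataclasses.replace(calibrated_spec, n=3000)
        with_fx = dataclasses.replace(
            calibrated_spec, n=3000, effects=EffectsHook()
        )
        df0, df1 = generate_cohort(base), generate_cohort(with_fx)
        # same seed: only hemoglobin differs, by the exact penalty
        both = (df1["muac"] < 22) & (df1["education"] == "illiterate")
        neither = (df1["muac"] >= 22) & (df1["education"] == "literate")
        shift = df0["hb"] - df1["hb"]
        np.testing.assert_allclose(shift[both], 6.0 + 4.0)
        np.testing.assert_allclose(shift[neither], 0.0)

    def test_invalid_n_rejected(self, calibrated_spec):
        with pytest.raises(ValueError, match="n must be"):
            dataclasses.replace(calibrated_spec, n=0)

    def test_uncalibrated_copula_rejected(self):
        spec = default_cohort_spec(n=10, seed=0)
        with pytest.raises(CalibrationError, match="calibrate"):
            generate_cohort(spec)
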