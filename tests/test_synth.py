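import dataclasses

import numpy as np
import pytest

from hcsa.errors import NoPulsatilityError, ParameterError
from hcsa.synth import (
    EMBRYO_JITTER_SD,
    PhantomParams,
    simulate_cohort,
    simulate_heart_series,
)


def small_params(**kwargs):
    defaults = dict(
        image_shape=(96, 96),
        n_frames=10,
        blood_semi_axes_ed=(24.0, 18.0),
        blood_semi_axes_es=(16.0, 12.0),
        wall_thickness_px=6.0,
        noise_sd=0.02,
    )
    defaults.update(kwargs)
    return PhantomParams(**defaults)


class TestPhantom:
    def test_circular_pool_ef_from_squared_radii(self):
        p = small_params(
            blood_semi_axes_ed=(30.0, 30.0),
            blood_semi_axes_es=(30.0 * 0.5**0.5, 30.0 * 0.5**0.5),
        )
        _, _, truth = simulate_heart_series(p)
        assert truth.EF_true == pytest.approx(50.0, abs=1e-9)

    def test_ground_truth_identities_exact(self):
        _, _, t = simulate_heart_series(small_params())
        assert t.SA_true == t.EDBA_true - t.ESBA_true
        assert t.EF_true == 100.0 * t.SA_true / t.EDBA_true
        assert t.MMI_true == t.tESA_true - t.ESBA_true
        assert t.delta_pct_tA_true == pytest.approx(
            100.0 * (t.tEDA_true - t.tESA_true) / t.tEDA_true
        )
        assert t.EDBA_true == pytest.approx(t.blood_area_trace.max())
        assert t.ESBA_true == pytest.approx(t.blood_area_trace.min())

    def test_same_seed_is_bit_identical(self):
        s1, _, _ = simulate_heart_series(small_params(seed=11))
        s2, _, _ = simulate_heart_series(small_params(seed=11))
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_different_seed_differs(self):
        s1, _, _ = simulate_heart_series(small_params(seed=11))
        s2, _, _ = simulate_heart_series(small_params(seed=12))
        assert not np.array_equal(s1.frames, s2.frames)

    def test_rois_cover_every_analytic_extreme(self):
        _, rois, truth = simulate_heart_series(small_params())
        for fi in np.concatenate([truth.ed_frames, truth.es_frames]):
            assert int(fi) in rois

    def test_non_beating_phantom_triggers_no_pulsatility(self):
        from hcsa.pipeline import quantify

        p = small_params(
            blood_semi_axes_es=(24.0, 18.0), noise_sd=0.0
        )  # es == ed
        series, rois, truth = simulate_heart_series(p)
        assert truth.EF_true == 0.0 and truth.SA_true == 0.0
        with pytest.raises(NoPulsatilityError):
            quantify(series, rois)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(blood_semi_axes_es=(30.0, 18.0)),  # es > ed
            dict(heart_rate_hz=2.0),  # 2.5 frames/cycle at 0.2 s
            dict(n_frames=3),  # under one cycle
            dict(noise_sd=-0.1),
            dict(hb_absorption=0.1, myocardium_absorption=0.5),
            dict(blood_semi_axes_ed=(60.0, 45.0)),  # outer ellipse exceeds 96px frame
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            simulate_heart_series(small_params(**kwargs))


class TestCohort:
    def test_counts_labels_and_seed_uniqueness(self):
        res = simulate_cohort(small_params(), {"treated": {}}, n_per_group=3)
        df = res.truth_table
        assert len(df) == 6
        assert set(df["group"]) == {"control", "treated"}
        assert df["embryo_id"].is_unique
        assert df["seed"].is_unique

    def test_null_effect_gives_identical_distribution_in_law(self):
        res = simulate_cohort(small_params(), {"treated": {}}, n_per_group=40)
        df = res.truth_table
        ef_c = df.loc[df["group"] == "control", "EF"]
        ef_t = df.loc[df["group"] == "treated", "EF"]
        # same generator, different seeds: close means, no systematic offset
        sem = np.hypot(ef_c.sem(), ef_t.sem())
        assert abs(ef_c.mean() - ef_t.mean()) < 4 * sem

    def test_impaired_emptying_lowers_mean_ef(self):
        res = simulate_cohort(
            small_params(),
            {"treated": {"blood_semi_axes_es": 1.15}},
            n_per_group=30,
        )
        df = res.truth_table
        assert (
            df.loc[df["group"] == "treated", "EF"].mean()
            < df.loc[df["group"] == "control", "EF"].mean()
        )

    def test_truth_table_identities_hold_per_embryo(self):
        df = simulate_cohort(small_params(), {}, n_per_group=5).truth_table
        np.testing.assert_allclose(df["SA"], df["EDBA"] - df["ESBA"], rtol=1e-12)
        np.testing.assert_allclose(df["EF"], 100 * df["SA"] / df["EDBA"], rtol=1e-12)
        np.testing.assert_allclose(df["MMI"], df["tESA"] - df["ESBA"], rtol=1e-12)

    def test_jitter_magnitude_matches_declared_sd(self):
        df = simulate_cohort(small_params(), {}, n_per_group=400).truth_table
        # EDBA = pi*a*b with two independent lognormal(0, 0.05) factors
        log_area = np.log(df["EDBA"])
        assert np.std(log_area) == pytest.approx(
            np.sqrt(2) * EMBRYO_JITTER_SD, rel=0.2
        )

    def test_rendered_cohort_carries_series(self):
        res = simulate_cohort(
            small_params(), {}, n_per_group=2, render_images=True
        )
        assert res.embryos is not None and len(res.embryos) == 2
        series, rois, truth = next(iter(res.embryos.values()))
        assert series.n_frames == 10

    def test_invalid_effect_names_embryo(self):
        with pytest.raises(ParameterError, match="treated_000"):
            simulate_cohort(
                small_params(),
                {"treated": {"blood_semi_axes_es": 2.0}},  # es would exceed ed
                n_per_group=1,
            )

    def test_reproducible_given_base_seed(self):
        d1 = simulate_cohort(small_params(), {}, 5, base_seed=3).truth_table
        d2 = simulate_cohort(small_params(), {}, 5, base_seed=3).truth_table
        assert d1.equals(d2)
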