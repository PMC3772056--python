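"""Morlet decomposition, design construction and mass-univariate regression."""

import numpy as np
import pandas as pd
import pytest

from valueframe import (
    DesignMatrix,
    GroundTruth,
    ProspectParams,
    TFConfig,
    TrialPowerRegression,
    build_design,
    generate_stimulus_set,
    hemispheric_difference,
    morlet_power,
    regress_power,
    simulate_choices,
    simulate_epochs,
)
from valueframe.tfr import TFPower, morlet_wavelet

FS = 200.0


def _sine_epochs(freq, n_trials=4, amp=1.0, n_samp=600):
    t = np.arange(n_samp) / FS
    return amp * np.tile(np.sin(2 * np.pi * freq * t), (n_trials, 1))


class TestMorletPower:
    def test_peak_at_carrier_and_quadratic_amplitude_scaling(self):
        cfg = TFConfig(freqs=np.arange(5.0, 41.0, 1.0))
        p1 = morlet_power(_sine_epochs(20.0, amp=1.0), cfg, fs=FS)
        p2 = morlet_power(_sine_epochs(20.0, amp=2.0), cfg, fs=FS)
        prof = p1.power.mean(axis=(0, 2))
        assert cfg.freqs[int(np.argmax(prof))] == 20.0
        mid = p1.valid.all(axis=0)
        ratio = p2.power[:, :, mid] / np.maximum(p1.power[:, :, mid], 1e-30)
        assert np.median(ratio) == pytest.approx(4.0, rel=1e-6)

    def test_zero_input_gives_zero_power(self):
        p = morlet_power(np.zeros((3, 400)), TFConfig(freqs=[10.0, 20.0]), fs=FS)
        assert np.all(p.power == 0)

    def test_white_noise_spectrum_is_smooth(self, rng):
        data = rng.standard_normal((60, 600))
        cfg = TFConfig(freqs=np.arange(5.0, 41.0, 1.0))
        p = morlet_power(data, cfg, fs=FS)
        prof = p.power.mean(axis=(0, 2))
        neighbours = 0.5 * (prof[:-2] + prof[2:])
        assert np.all(prof[1:-1] < 3 * neighbours)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_power(np.zeros((2, 400)), TFConfig(freqs=[90.0, 100.0]), fs=FS)

    def test_edge_flagging_scales_with_wavelet_support(self):
        cfg = TFConfig(freqs=[5.0, 30.0], stride_ms=5.0)
        p = morlet_power(np.zeros((2, 600)), cfg, fs=FS)
        # slower wavelets have wider invalid edges
        assert p.valid[0].sum() < p.valid[1].sum()

    def test_matches_mne_reference(self):
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 600))
        freqs = np.array([10.0, 20.0, 30.0])
        cfg = TFConfig(freqs=freqs, stride_ms=1000.0 / FS)  # no decimation
        ours = morlet_power(data, cfg, fs=FS)
        ref = mne.time_frequency.tfr_array_morlet(
            data[:, None, :], FS, freqs, n_cycles=5.0, output="power", zero_mean=False,
        )[:, 0]
        mid = ours.valid.all(axis=0)
        # same wavelet family up to a fixed per-frequency gain: correlation ~= 1
        for fi in range(freqs.size):
            r = np.corrcoef(ours.power[:, fi, mid].ravel(), ref[:, fi, mid].ravel())[0, 1]
            assert r > 0.999


@pytest.fixture(scope="module")
def trials():
    t = generate_stimulus_set(n_per_type=120, seed=40)
    return simulate_choices(t, ProspectParams(0.8, 0.7, 3.0), seed=41)


class TestBuildDesign:
    def test_goods_space_shape_on_harder_trials(self, trials):
        comp = trials[trials.trial_type == "comparison"]
        design = build_design(comp, "goods_space", trial_selection="harder")
        assert design.names == ["const", "v_chosen", "v_unchosen", "choice"]
        assert design.n_trials == (~comp["nobrainer"]).sum()

    def test_value_columns_standardized(self, trials):
        design = build_design(trials, "action_space")
        for name in ("v_contra", "v_ipsi"):
            col = design.column(name)
            assert col.mean() == pytest.approx(0.0, abs=1e-10)
            assert col.std() == pytest.approx(1.0, abs=1e-10)
        assert set(np.unique(design.column("choice"))) == {-1.0, 1.0}

    def test_duplicated_regressor_rejected(self, trials):
        X = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(X=X, names=["const", "a", "b"], standardized=[])

    def test_unknown_spec_rejected(self, trials):
        with pytest.raises(ValueError):
            build_design(trials, "nonsense")


def _power_from_signal(signal_bins, rng, n_trials=324):
    """TFPower whose bins equal given per-trial signals plus noise."""
    nf, nt = 3, 5
    power = rng.standard_normal((n_trials, nf, nt)) + 10.0
    power[:, 1, 2] = signal_bins
    return TFPower(
        power=np.maximum(power, 0.01),
        freqs=np.array([10.0, 20.0, 30.0]),
        times_ms=np.arange(5) * 25.0,
        valid=np.ones((3, 5), bool),
    )


class TestRegression:
    def test_known_coefficient_recovered(self, rng):
        n = 324
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std()
        c = rng.choice([1.0, -1.0], n)
        power = _power_from_signal(10.0 + 2.0 * z + rng.standard_normal(n), rng)
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), z, c]),
            names=["const", "value", "choice"], standardized=["value"],
        )
        res = TrialPowerRegression(power, design).fit()
        beta = res.beta[1, 1, 2]
        se = beta / res.effect_map("value").values[1, 2]
        assert abs(beta - 2.0) < 2 * se

    def test_constant_power_gives_zero_effects(self):
        n = 50
        rng = np.random.default_rng(3)
        power = TFPower(
            power=np.full((n, 2, 3), 5.0),
            freqs=np.array([10.0, 20.0]), times_ms=np.arange(3) * 25.0,
            valid=np.ones((2, 3), bool),
        )
        z = rng.standard_normal(n)
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), z - z.mean()]),
            names=["const", "value"], standardized=["value"],
        )
        res = TrialPowerRegression(power, design).fit()
        np.testing.assert_allclose(res.beta[1], 0.0, atol=1e-10)

    def test_null_effects_are_student_t(self, rng):
        # power independent of the design -> effect values ~ t(n-k)
        n, k = 60, 3
        nrep = 400
        vals = []
        for _ in range(nrep):
            y = rng.standard_normal(n)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            r = y - X @ beta
            s2 = r @ r / (n - k)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            vals.append(beta[1] / se)
        from scipy import stats
        ks = stats.kstest(vals, stats.t(n - k).cdf)
        assert ks.pvalue > 0.01

    def test_too_few_trials_rejected(self, rng):
        power = _power_from_signal(np.zeros(4), rng, n_trials=4)
        design = DesignMatrix(
            X=np.column_stack([np.ones(4), rng.standard_normal(4), rng.standard_normal(4)]),
            names=["const", "a", "b"], standardized=[],
        )
        with pytest.raises(ValueError):
            TrialPowerRegression(power, design)

    def test_permutation_invariance(self, rng):
        n = 100
        z = rng.standard_normal(n)
        c = rng.choice([1.0, -1.0], n)
        power = _power_from_signal(10 + z + rng.standard_normal(n), rng, n_trials=n)
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), z, c]),
            names=["const", "value", "choice"], standardized=[],
        )
        perm = rng.permutation(n)
        power2 = TFPower(power.power[perm], power.freqs, power.times_ms, power.valid)
        design2 = DesignMatrix(X=design.X[perm], names=design.names, standardized=[])
        a = TrialPowerRegression(power, design).fit().effect_map("value").values
        b = TrialPowerRegression(power2, design2).fit().effect_map("value").values
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestContrast:
    def _fit(self, rng):
        n = 120
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        power = _power_from_signal(10 + x1 - x2 + rng.standard_normal(n), rng, n_trials=n)
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), x1, x2]),
            names=["const", "x1", "x2"], standardized=[],
        )
        return TrialPowerRegression(power, design).fit()

    def test_identity_weight_equals_component(self, rng):
        res = self._fit(rng)
        np.testing.assert_allclose(
            res.contrast({"x1": 1.0}).values,
            res.effect_map("x1").values, atol=1e-12,
        )

    def test_self_difference_is_zero(self, rng):
        res = self._fit(rng)
        c = res.contrast({"x1": 1.0, "x1": 1.0})  # single column, weight 1
        z = res.contrast({"x1": 1.0, "x2": 0.0})
        np.testing.assert_allclose(c.values, z.values, atol=1e-12)

    def test_value_difference_contrast_recovers_injection(self):
        # end-to-end: injected desynchronising value-difference effect
        rng = np.random.default_rng(8)
        n = 324
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std()
        c = rng.choice([1.0, -1.0], n)
        truth = GroundTruth(g_value=-0.4, g_choice=0.0, tau_value_ms=500.0)
        ep = simulate_epochs(z, c, truth, fs=FS, window_ms=(-500, 1500), seed=9)
        cfg = TFConfig(freqs=np.arange(13.0, 31.0, 1.0))
        power = morlet_power(ep, cfg).crop(0, 1000)
        # split z into two correlated option values so the (1,-1) contrast is z
        v1 = (z + rng.standard_normal(n)) / 2
        v2 = v1 - z / 1.0
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), v1, v2, c]),
            names=["const", "v_contra", "v_ipsi", "choice"], standardized=[],
        )
        res = TrialPowerRegression(power, design).fit()
        cmap = res.contrast({"v_contra": 1.0, "v_ipsi": -1.0})
        fi = np.argmin(np.abs(cfg.freqs - truth.carrier_hz))
        ti = np.argmin(np.abs(power.times_ms - 500.0))
        assert cmap.values[fi, ti] < -3.0


class TestHemisphericDifference:
    def _map(self, vals):
        from valueframe.tfr import EffectMap
        return EffectMap(values=vals, freqs=np.array([20.0]),
                         times_ms=np.array([0.0, 25.0]), df=17)

    def test_identical_maps_cancel(self):
        m = self._map(np.array([[1.0, 2.0]]))
        assert np.all(hemispheric_difference(m, m).values == 0)

    def test_mirrored_effects_double(self):
        a = self._map(np.array([[1.0, 2.0]]))
        b = self._map(np.array([[-1.0, -2.0]]))
        np.testing.assert_allclose(hemispheric_difference(a, b).values,
                                   2 * a.values)

    def test_mismatched_grids_rejected(self):
        from valueframe.tfr import EffectMap
        a = self._map(np.array([[1.0, 2.0]]))
        b = EffectMap(values=np.array([[1.0, 2.0]]), freqs=np.array([10.0]),
                      times_ms=np.array([0.0, 50.0]), df=17)
        with pytest.raises(ValueError):
            hemispheric_difference(a, b)


def test_regress_power_surface(rng):
    n = 40
    power = _power_from_signal(np.zeros(n) + 10, rng, n_trials=n)
    design = DesignMatrix(
        X=np.column_stack([np.ones(n), rng.standard_normal(n)]),
        names=["const", "value"], standardized=[],
    )
    maps = regress_power(power, design)
    assert set(maps) == {"const", "value"}
    assert maps["value"].df == n - 2
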