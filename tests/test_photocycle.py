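"""Sequential-kinetics forward model and global fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from anionpump import photocycle as pc
from anionpump.errors import SingularTransformError, ValidationError


def rk_oracle(tau, times):
    """Independent numerical integration of the chain ODEs (stiff-safe)."""
    k = 1.0 / np.asarray(tau, dtype=float)
    n = k.size

    def rhs(t, c):
        dc = -k * c
        dc[1:] += k[:-1] * c[:-1]
        return dc

    c0 = np.zeros(n)
    c0[0] = 1.0
    sol = solve_ivp(rhs, (0.0, times[-1]), c0, t_eval=times, method="LSODA",
                    rtol=1e-10, atol=1e-14)
    return sol.y


class TestBateman:
    def test_single_species_is_pure_exponential(self):
        scheme = pc.SequentialScheme(["A"], [1.0])
        t = np.array([0.0, 0.5, 1.0, 2.0])
        c = pc.bateman_concentrations(scheme, t)
        np.testing.assert_allclose(c[0], np.exp(-t), rtol=1e-12)
        assert c[0, 0] == 1.0

    def test_two_species_closed_form(self):
        # k1/(k2-k1) (e^{-k1 t} - e^{-k2 t}) at tau=[1,2], t=1
        scheme = pc.SequentialScheme(["A", "B"], [1.0, 2.0])
        c = pc.bateman_concentrations(scheme, [1.0])
        assert c[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)
        # -2 (e^-1 - e^-0.5) = 0.4773024...
        assert c[1, 0] == pytest.approx(0.4773024, rel=1e-6)
        np.testing.assert_allclose(c[:, 0], rk_oracle([1.0, 2.0], np.array([1.0]))[:, 0],
                                   atol=1e-6)

    def test_all_species_decay_to_zero(self):
        scheme = pc.SequentialScheme(list("ABC"), [1e-3, 5e-3, 2e-2])
        c = pc.bateman_concentrations(scheme, [100 * 2e-2])
        assert np.all(c < 1e-40)

    def test_conservation_with_ground_state(self):
        """Total amount is conserved: sum of species + recovered ground = 1."""
        scheme = pc.SequentialScheme(list("ABC"), [0.3, 1.0, 4.0])
        t = np.linspace(0.0, 40.0, 300)
        c = pc.bateman_concentrations(scheme, t)
        ground = 1.0 - c.sum(axis=0)
        assert np.all(c >= 0) and np.all(c <= 1)
        assert np.all(np.diff(ground) >= -1e-12), "ground fraction must not decrease"
        # ground fraction from the chain integral must close the balance
        total = c.sum(axis=0) + ground
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_numerical_integration(self, seed):
        rng = np.random.default_rng(seed)
        tau = np.sort(10.0 ** rng.uniform(-2, 1, size=3))
        times = np.geomspace(1e-3, 20.0, 50)
        scheme = pc.SequentialScheme(list("ABC"), tau)
        c = pc.bateman_concentrations(scheme, times)
        np.testing.assert_allclose(c, rk_oracle(tau, times), atol=1e-6)

    def test_near_degenerate_limit(self):
        """As tau2 -> tau1 the pair approaches the repeated-root limit t*k*e^{-kt}."""
        k = 2.0
        t = np.linspace(0.1, 3.0, 40)
        scheme = pc.SequentialScheme(["A", "B"], [1 / k, (1 + 1e-6) / k])
        c = pc.bateman_concentrations(scheme, t)
        np.testing.assert_allclose(c[1], t * k * np.exp(-k * t), atol=1e-4)

    def test_exactly_degenerate_uses_matrix_path(self):
        t = np.linspace(0.1, 3.0, 20)
        scheme = pc.SequentialScheme(["A", "B"], [0.5, 0.5])
        c = pc.bateman_concentrations(scheme, t)
        np.testing.assert_allclose(c[1], t * 2.0 * np.exp(-2.0 * t), atol=1e-10)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValidationError):
            pc.SequentialScheme(["A"], [0.0])
        with pytest.raises(ValidationError):
            pc.SequentialScheme(["A", "B"], [1.0, -2.0])


class TestDadsSads:
    def test_single_species_identity(self):
        scheme = pc.SequentialScheme(["A"], [1.5])
        sads = np.random.default_rng(0).normal(size=(7, 1))
        np.testing.assert_allclose(pc.dads_from_sads(scheme, sads), sads)

    def test_two_species_closed_form_map(self):
        # tau=[1,2]: dads1 = sads1 - 2 sads2, dads2 = 2 sads2
        scheme = pc.SequentialScheme(["A", "B"], [1.0, 2.0])
        rng = np.random.default_rng(1)
        sads = rng.normal(size=(9, 2))
        dads = pc.dads_from_sads(scheme, sads)
        np.testing.assert_allclose(dads[:, 0], sads[:, 0] - 2 * sads[:, 1], rtol=1e-12)
        np.testing.assert_allclose(dads[:, 1], 2 * sads[:, 1], rtol=1e-12)

    def test_dads_regression_oracle(self):
        """DADS equal the coefficients of the forward model in the e^{-t/tau} basis."""
        scheme = pc.SequentialScheme(list("ABC"), [0.05, 0.4, 2.0])
        rng = np.random.default_rng(3)
        wl = np.linspace(400, 700, 12)
        sads = rng.normal(size=(12, 3))
        t = np.geomspace(1e-3, 20, 120)
        data = pc.forward_model(scheme, sads, wl, t)
        E = np.exp(-np.outer(scheme.rates, t))
        coef, *_ = np.linalg.lstsq(E.T, data.deltaA.T, rcond=None)
        np.testing.assert_allclose(pc.dads_from_sads(scheme, sads), coef.T, atol=1e-8)

    def test_round_trip_is_identity(self):
        scheme = pc.SequentialScheme(list("ABC"), [0.1, 0.7, 3.0])
        rng = np.random.default_rng(2)
        sads = rng.normal(size=(15, 3))
        back = pc.sads_from_dads(scheme, pc.dads_from_sads(scheme, sads))
        np.testing.assert_allclose(back, sads, atol=1e-10)

    def test_coincident_taus_raise(self):
        scheme = pc.SequentialScheme.__new__(pc.SequentialScheme)
        with pytest.raises(SingularTransformError):
            pc.bateman_coefficients(np.array([1.0, 1.0]))
        del scheme

    def test_reconstruction_agreement(self):
        """SADS@concentrations and DADS@exponentials give the same matrix."""
        scheme = pc.SequentialScheme(list("ABC"), [0.05, 0.4, 2.0])
        rng = np.random.default_rng(4)
        wl = np.linspace(420, 710, 30)
        sads = rng.normal(size=(30, 3))
        t = np.geomspace(1e-4, 20, 60)
        via_sads = sads @ pc.bateman_concentrations(scheme, t)
        E = np.exp(-np.outer(scheme.rates, t))
        via_dads = pc.dads_from_sads(scheme, sads) @ E
        np.testing.assert_allclose(via_sads, via_dads, atol=1e-10)


class TestForwardModel:
    def test_zero_sads_gives_zero_matrix(self):
        scheme = pc.SequentialScheme(["A", "B"], [0.1, 1.0])
        wl = np.linspace(400, 700, 10)
        data = pc.forward_model(scheme, np.zeros((10, 2)), wl, np.geomspace(0.01, 5, 20))
        assert np.all(data.deltaA == 0)

    def test_single_species_rows_proportional_to_exponential(self):
        scheme = pc.SequentialScheme(["A"], [1.0])
        wl = np.linspace(400, 700, 5)
        sads = np.arange(1.0, 6.0).reshape(-1, 1)
        t = np.geomspace(0.01, 5, 30)
        data = pc.forward_model(scheme, sads, wl, t)
        np.testing.assert_allclose(data.deltaA, np.outer(sads[:, 0], np.exp(-t)), rtol=1e-12)

    def test_ground_state_recovery_at_long_times(self, wt_photocycle_data):
        """Long after the slowest decay the signal returns to baseline."""
        late = wt_photocycle_data.times_s > 1.0  # slowest planted tau is 12 ms
        noise_scale = 0.01 * np.max(np.abs(wt_photocycle_data.deltaA))
        assert np.max(np.abs(wt_photocycle_data.deltaA[:, late])) < 6 * noise_scale

    def test_shape_mismatch_raises(self):
        scheme = pc.SequentialScheme(["A", "B"], [0.1, 1.0])
        with pytest.raises(ValidationError):
            pc.forward_model(scheme, np.zeros((10, 3)), np.linspace(400, 700, 10), [0.1, 1.0])


class TestGlobalFit:
    def test_noiseless_three_exponential_recovery(self):
        scheme = pc.SequentialScheme(list("KLO"), [5e-5, 2.2e-3, 1.2e-2])
        rng = np.random.default_rng(5)
        wl = np.arange(420.0, 711.0, 10.0)
        sads = rng.normal(size=(wl.size, 3))
        data = pc.forward_model(scheme, sads, wl, np.geomspace(1e-5, 4.0, 60))
        res = pc.fit_global(data, 3)
        np.testing.assert_allclose(res.scheme.tau_s, scheme.tau_s, rtol=1e-6)
        assert res.rss < 1e-20
        assert res.converged

    def test_multistart_initialization_invariance(self):
        """Different explicit starts land on the same noiseless optimum."""
        scheme = pc.SequentialScheme(["A", "B"], [1e-3, 2e-2])
        wl = np.linspace(420, 710, 8)
        sads = np.random.default_rng(6).normal(size=(8, 2))
        data = pc.forward_model(scheme, sads, wl, np.geomspace(1e-4, 1.0, 40))
        taus = [
            pc.fit_global(data, 2, init_tau_s=init).scheme.tau_s
            for init in ([5e-4, 5e-2], [2e-3, 1e-2], [1e-4, 1e-1])
        ]
        for tau in taus[1:]:
            np.testing.assert_allclose(tau, taus[0], rtol=1e-6)

    def test_single_exponential_matches_loglinear_regression(self):
        """n_exp=1 on clean 1-exp data equals the closed-form log-linear slope."""
        tau_true = 0.37
        t = np.linspace(0.05, 2.0, 40)
        y = 0.8 * np.exp(-t / tau_true)
        data = pc.TransientDataset(np.array([500.0]), t, y[None, :])
        res = pc.fit_global(data, 1)
        slope = np.polyfit(t, np.log(y), 1)[0]
        np.testing.assert_allclose(res.scheme.tau_s[0], -1.0 / slope, rtol=1e-8)
        np.testing.assert_allclose(res.scheme.tau_s[0], tau_true, rtol=1e-8)

    def test_taus_sorted_ascending(self, wt_photocycle_data):
        res = pc.fit_global(wt_photocycle_data, 3)
        assert np.all(np.diff(res.scheme.tau_s) > 0)

    def test_selected_wavelength_mode(self, wt_photocycle_data):
        """Fitting only the 470/570/600 nm traces still recovers the taus."""
        res = pc.fit_global(wt_photocycle_data, 3, wavelengths_nm=[470, 570, 600])
        assert res.wavelengths_nm.size == 3
        np.testing.assert_allclose(res.scheme.tau_s, [5e-5, 2.2e-3, 1.2e-2], rtol=0.15)

    def test_too_few_time_points_rejected(self):
        data = pc.TransientDataset(np.array([500.0]), np.array([0.1, 0.2, 0.3]),
                                   np.ones((1, 3)))
        with pytest.raises(ValidationError):
            pc.fit_global(data, 2)

    def test_overfit_never_raises(self):
        """Fitting 2 exponentials to 1-exponential data returns a result, no exception."""
        t = np.geomspace(0.01, 5.0, 40)
        data = pc.TransientDataset(np.array([500.0]), t, np.exp(-t)[None, :])
        res = pc.fit_global(data, 2, n_starts=4)
        assert res.rss < 1e-20  # the true single exponential is inside the model class
        assert np.any(np.isclose(res.scheme.tau_s, 1.0, rtol=1e-4))


class TestAssignment:
    @staticmethod
    def _result_with_sads(wl, sads, tau):
        scheme = pc.SequentialScheme([str(i) for i in range(sads.shape[1])], tau)
        return pc.GlobalFitResult(
            scheme=scheme, dads=pc.dads_from_sads(scheme, sads), sads=sads,
            rss=0.0, per_tau_stderr=np.zeros(len(tau)), converged=True,
            wavelengths_nm=wl,
        )

    def test_l_and_o_band_labels(self):
        wl = np.arange(420.0, 711.0, 10.0)
        l_band = np.exp(-0.5 * ((wl - 460) / 25) ** 2) - 0.8 * np.exp(-0.5 * ((wl - 560) / 35) ** 2)
        o_band = np.exp(-0.5 * ((wl - 620) / 25) ** 2) - 0.5 * np.exp(-0.5 * ((wl - 560) / 35) ** 2)
        res = self._result_with_sads(wl, np.column_stack([l_band, o_band]), [1e-3, 1e-2])
        assert pc.assign_intermediates(res).labels == ("L", "O")

    def test_all_zero_sads_is_bleach_only(self):
        wl = np.arange(420.0, 711.0, 10.0)
        res = self._result_with_sads(wl, np.zeros((wl.size, 1)), [1e-3])
        assert pc.assign_intermediates(res).labels == ("bleach-only",)

    def test_wt_scenario_labels_k_l_o(self, wt_photocycle_data):
        res = pc.fit_global(wt_photocycle_data, 3)
        assert pc.assign_intermediates(res).labels == ("K", "L", "O")

    def test_labels_never_duplicated(self):
        wl = np.arange(420.0, 711.0, 10.0)
        band = np.exp(-0.5 * ((wl - 460) / 25) ** 2)
        res = self._result_with_sads(wl, np.column_stack([band, band]), [1e-3, 1e-2])
        labels = pc.assign_intermediates(res).labels
        assert len(set(labels)) == len(labels)


class TestOAccumulation:
    def test_wt_accumulates(self, wt_photocycle_data):
        res = pc.fit_global(wt_photocycle_data, 3)
        o = pc.detect_o_accumulation(res)
        assert o.accumulating and o.score > 0.3

    def test_o_free_mutant_does_not(self):
        from anionpump import scenarios, synthetic

        data = synthetic.gen_transient(scenarios.load_scenario("H167A-photocycle", seed=11))
        res = pc.fit_global(data, 3)
        o = pc.detect_o_accumulation(res)
        assert not o.accumulating and o.score < 0.1

    def test_zero_threshold_boundary(self, wt_photocycle_data):
        res = pc.fit_global(wt_photocycle_data, 3)
        assert pc.detect_o_accumulation(res, threshold=0.0).accumulating

    def test_no_bleach_returns_false_with_warning(self):
        wl = np.arange(420.0, 711.0, 10.0)
        sads = np.exp(-0.5 * ((wl - 620) / 25) ** 2)[:, None]  # positive only
        scheme = pc.SequentialScheme(["1"], [1e-2])
        res = pc.GlobalFitResult(scheme=scheme, dads=sads, sads=sads, rss=0.0,
                                 per_tau_stderr=np.zeros(1), converged=True,
                                 wavelengths_nm=wl)
        o = pc.detect_o_accumulation(res)
        assert not o.accumulating and o.warning is not None


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_bateman_values_bounded_and_conserved(seed):
    """Chain concentrations stay in [0,1] and never exceed unit total."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 5))
    tau = 10.0 ** rng.uniform(-3, 1, size=n)
    t = np.geomspace(1e-4, 50.0, 40)
    c = pc.bateman_concentrations(pc.SequentialScheme([str(i) for i in range(n)], tau), t)
    assert np.all(c >= 0.0) and np.all(c <= 1.0)
    assert np.all(c.sum(axis=0) <= 1.0 + 1e-12)
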