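import warnings

import numpy as np
import pytest

import redifine as rd
from redifine.fitting import CONDENSATE_PARAM_NAMES, DecayDataset


def _truth_dict(params):
    return {n: getattr(params, n) for n in CONDENSATE_PARAM_NAMES}


def _warm_spec(params, seed=0, **kwargs):
    """Replicate-study spec: start at the generating values, few starts."""
    defaults = dict(
        n_starts=2,
        random_seed=seed,
        initial_guesses=_truth_dict(params),
        param_tol=1e-6,
        perturbation_scale=0.3,
    )
    defaults.update(kwargs)
    return rd.FitSpec(**defaults)


class TestChiObjective:
    def test_self_consistent_data_has_zero_objective(
        self, condensate_params, noiseless_dataset
    ):
        assert rd.chi_objective(noiseless_dataset, condensate_params) < 1e-10

    def test_single_residual_contributes_its_square(
        self, condensate_params, noiseless_dataset
    ):
        intensities = noiseless_dataset.intensities.copy()
        r = 0.05
        intensities[10] += r
        perturbed = DecayDataset(
            noiseless_dataset.diffusion_times,
            noiseless_dataset.fractions,
            intensities,
            noiseless_dataset.scheme,
        )
        chi = rd.chi_objective(perturbed, condensate_params)
        assert chi**2 == pytest.approx(r**2, rel=1e-6)

    def test_invariant_to_point_order(self, condensate_params, noiseless_dataset):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(noiseless_dataset))
        shuffled = DecayDataset(
            noiseless_dataset.diffusion_times[perm],
            noiseless_dataset.fractions[perm],
            noiseless_dataset.intensities[perm],
            noiseless_dataset.scheme,
        )
        assert rd.chi_objective(shuffled, condensate_params) == pytest.approx(
            rd.chi_objective(noiseless_dataset, condensate_params), rel=1e-12
        )


class TestDatasetContract:
    def test_single_curve_warns_but_constructs(self, protein_scheme):
        with pytest.warns(UserWarning, match="single diffusion time"):
            DecayDataset(
                np.full(3, 0.05),
                np.array([0.1, 0.5, 0.9]),
                np.array([0.9, 0.5, 0.2]),
                protein_scheme,
            )

    def test_duplicate_points_rejected(self, protein_scheme):
        with pytest.raises(ValueError, match="duplicate"):
            DecayDataset(
                np.array([0.05, 0.05, 0.1]),
                np.array([0.5, 0.5, 0.5]),
                np.array([0.5, 0.5, 0.5]),
                protein_scheme,
            )

    def test_out_of_range_intensities_rejected(self, protein_scheme):
        with pytest.raises(ValueError, match="intensities"):
            DecayDataset(
                np.array([0.05, 0.1]),
                np.array([0.5, 0.5]),
                np.array([1.7, 0.5]),
                protein_scheme,
            )


class TestGlobalCondensateFit:
    def test_noiseless_recovery_from_heuristic_starts(
        self, condensate_params, noiseless_dataset
    ):
        result = rd.fit_redifine(noiseless_dataset, rd.FitSpec(n_starts=20, random_seed=1))
        assert result.chi < 1e-8
        for name in CONDENSATE_PARAM_NAMES:
            assert getattr(result.params, name) == pytest.approx(
                getattr(condensate_params, name), rel=0.01
            )
        assert result.derived is not None
        assert result.derived.k_cd == pytest.approx(
            3 * condensate_params.p / condensate_params.R_drop, rel=0.01
        )

    def test_fit_is_deterministic_given_seed(self, condensate_params, protein_scheme):
        ds = rd.generate_dataset(
            condensate_params, protein_scheme, rd.NoiseSpec(sigma=0.01, seed=5)
        )
        spec = _warm_spec(condensate_params, seed=9)
        r1 = rd.fit_redifine(ds, spec)
        r2 = rd.fit_redifine(ds, spec)
        for name in CONDENSATE_PARAM_NAMES:
            assert getattr(r1.params, name) == getattr(r2.params, name)
        assert r1.chi == r2.chi
        assert r1.uncertainties == r2.uncertainties

    def test_monoexponential_limit_flags_droplet_parameters(self, protein_scheme):
        params = rd.CondensateParams(
            D_dil=8e-11, D_cond=8.9e-13, nu_cond=0.0, R_drop=1.21e-6, p=0.405e-6
        )
        ds = rd.generate_dataset(params, protein_scheme)
        result = rd.fit_redifine(ds, rd.FitSpec(n_starts=6, random_seed=2))
        assert result.params.D_dil == pytest.approx(8e-11, rel=1e-3)
        for name in ("D_cond", "R_drop", "p"):
            assert name in result.unidentifiable

    def test_too_few_curves_is_an_error(self, condensate_params, protein_scheme):
        ds = rd.generate_dataset(condensate_params, protein_scheme)
        mask = ds.diffusion_times == 0.05
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            single = DecayDataset(
                ds.diffusion_times[mask],
                ds.fractions[mask],
                ds.intensities[mask],
                protein_scheme,
            )
        with pytest.raises(rd.FitError, match="at least 2"):
            rd.fit_redifine(single, rd.FitSpec(n_starts=1))

    def test_few_curves_warns_about_acquisition_guidance(
        self, condensate_params, protein_scheme
    ):
        ds = rd.generate_dataset(condensate_params, protein_scheme)
        mask = np.isin(ds.diffusion_times, (0.05, 1.0))
        subset = DecayDataset(
            ds.diffusion_times[mask],
            ds.fractions[mask],
            ds.intensities[mask],
            protein_scheme.with_diffusion_times((0.05, 1.0)),
        )
        with pytest.warns(UserWarning, match="six"):
            rd.fit_redifine(subset, _warm_spec(condensate_params, n_starts=1))


class TestUncertainties:
    def test_noiseless_fit_has_vanishing_standard_errors(
        self, condensate_params, noiseless_dataset
    ):
        result = rd.fit_redifine(noiseless_dataset, rd.FitSpec(n_starts=20, random_seed=1))
        for name in CONDENSATE_PARAM_NAMES:
            assert result.uncertainties[name] < 1e-4 * abs(getattr(result.params, name))

    def test_low_condensed_population_leaves_condensed_diffusion_undetermined(
        self, protein_scheme
    ):
        params = rd.CondensateParams(
            D_dil=8e-11, D_cond=8.9e-13, nu_cond=0.10, R_drop=1.21e-6, p=0.405e-6
        )
        ds = rd.generate_dataset(
            params, protein_scheme, rd.NoiseSpec(sigma=0.01, seed=7, renormalize=False)
        )
        result = rd.fit_redifine(ds, _warm_spec(params, seed=3))
        rel = {
            n: result.uncertainties[n] / abs(getattr(result.params, n))
            for n in ("D_cond", "D_dil")
        }
        assert rel["D_cond"] > 5 * rel["D_dil"]

    def test_repeated_measurements_shrink_errors_by_sqrt_two(
        self, condensate_params, protein_scheme
    ):
        ds = rd.generate_dataset(
            condensate_params,
            protein_scheme,
            rd.NoiseSpec(sigma=0.01, seed=13, renormalize=False),
        )
        result = rd.fit_redifine(ds, _warm_spec(condensate_params, seed=4))
        # an (almost) duplicated dataset: every point measured twice
        eps = 1e-9
        doubled = DecayDataset(
            np.concatenate([ds.diffusion_times, ds.diffusion_times]),
            np.concatenate([ds.fractions, ds.fractions + eps]),
            np.concatenate([ds.intensities, ds.intensities]),
            protein_scheme,
        )
        doubled_se = rd.parameter_uncertainties(
            rd.FitResult(
                model="condensate",
                params=result.params,
                uncertainties={},
                covariance=np.zeros((5, 5)),
                free_names=result.free_names,
                chi=np.sqrt(2) * result.chi,
                n_starts_converged=1,
                best_start_index=0,
            ),
            doubled,
        )
        for name in CONDENSATE_PARAM_NAMES:
            assert doubled_se[name] / result.uncertainties[name] == pytest.approx(
                1 / np.sqrt(2), rel=0.05
            )

    def test_two_curves_at_least_double_radius_uncertainty(
        self, condensate_params, protein_scheme
    ):
        ds6 = rd.generate_dataset(
            condensate_params,
            protein_scheme,
            rd.NoiseSpec(sigma=0.01, seed=11, renormalize=False),
        )
        res6 = rd.fit_redifine(ds6, _warm_spec(condensate_params, seed=5))
        mask = np.isin(ds6.diffusion_times, (0.05, 1.0))
        ds2 = DecayDataset(
            ds6.diffusion_times[mask],
            ds6.fractions[mask],
            ds6.intensities[mask],
            protein_scheme.with_diffusion_times((0.05, 1.0)),
        )
        with pytest.warns(UserWarning, match="six"):
            res2 = rd.fit_redifine(ds2, _warm_spec(condensate_params, seed=5))
        assert res2.uncertainties["R_drop"] >= 2 * res6.uncertainties["R_drop"]


class TestBindingFit:
    def test_no_exchange_data_yields_negligible_off_rate(self, binding_scheme):
        bp = rd.BindingParams(D_free=1e-10, D_complex=4e-11, nu_complex=0.6, k_off=0.0)
        ds = rd.generate_dataset(bp, binding_scheme)
        guesses = {
            "D_free": 1e-10,
            "D_complex": 4e-11,
            "nu_complex": 0.6,
            "k_off": 0.05,
        }
        result = rd.fit_binding(
            ds, spec=rd.FitSpec(n_starts=4, random_seed=1, initial_guesses=guesses)
        )
        assert result.params.k_off < 0.01

    def test_inconsistent_totals_keep_fit_but_mark_affinity(
        self, binding_params, noiseless_binding_dataset
    ):
        totals = rd.MixtureTotals(150e-6, 10e-6)  # not enough partner
        result = rd.fit_binding(
            noiseless_binding_dataset,
            totals,
            rd.FitSpec(n_starts=4, random_seed=1),
        )
        assert result.params.nu_complex == pytest.approx(0.945, rel=0.01)
        assert "error" in result.binding_derived


class TestSingleCurveDiagnostics:
    def test_monoexponential_curve_recovered_exactly(self, protein_scheme):
        D = 8e-11
        q = protein_scheme.q_values()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = DecayDataset(
                np.full(len(q), 0.05),
                np.asarray(protein_scheme.gradient_fractions),
                np.exp(-q * q * 0.05 * D),
                protein_scheme.with_diffusion_times((0.05,)),
            )
            D_fit, resid = rd.fit_monoexponential(ds)
        assert D_fit == pytest.approx(D, rel=1e-12)
        assert resid < 1e-12

    def test_biphasic_curve_deviates_from_monoexponential(
        self, condensate_params, noiseless_dataset
    ):
        _, resid = rd.fit_monoexponential(noiseless_dataset, 0.2)
        assert resid > 1e-2

    def test_kurtosis_zero_for_gaussian_diffusion(self, protein_scheme):
        D = 8e-11
        q = protein_scheme.q_values()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = DecayDataset(
                np.full(len(q), 0.05),
                np.asarray(protein_scheme.gradient_fractions),
                np.exp(-q * q * 0.05 * D),
                protein_scheme.with_diffusion_times((0.05,)),
            )
            D_app, K = rd.estimate_kurtosis(ds)
        assert D_app == pytest.approx(D, rel=1e-9)
        assert abs(K) < 1e-6

    def test_static_mixture_has_positive_kurtosis(self, protein_scheme):
        params = rd.CondensateParams(
            D_dil=8e-11, D_cond=8.9e-13, nu_cond=0.4, R_drop=1.21e-6, p=0.0
        )
        ds = rd.generate_dataset(params, protein_scheme)
        _, K = rd.estimate_kurtosis(ds, 0.05)
        assert K > 0

    def test_kurtosis_matches_polynomial_fit_oracle(
        self, condensate_params, noiseless_dataset
    ):
        Delta = 0.1
        D_app, K = rd.estimate_kurtosis(noiseless_dataset, Delta)
        b, inten = noiseless_dataset.curve(Delta)
        # independent quadratic regression through the origin on ln(I)
        coef = np.linalg.solve(
            np.array(
                [[np.sum(b**2), np.sum(b**3)], [np.sum(b**3), np.sum(b**4)]]
            ),
            np.array([np.dot(b, np.log(inten)), np.dot(b**2, np.log(inten))]),
        )
        assert D_app == pytest.approx(-coef[0], rel=1e-8)
        assert K == pytest.approx(6 * coef[1] / coef[0] ** 2, rel=1e-8)

    def test_degenerate_designs_rejected(self, protein_scheme):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tiny = DecayDataset(
                np.full(3, 0.05),
                np.array([0.1, 0.5, 0.9]),
                np.array([0.9, 0.5, 0.2]),
                protein_scheme.with_diffusion_times((0.05,)),
            )
            with pytest.raises(ValueError, match=">= 4"):
                rd.estimate_kurtosis(tiny)
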