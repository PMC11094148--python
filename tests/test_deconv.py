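import numpy as np
import pandas as pd
import pytest

import methdeconv as md
from methdeconv.containers import (
    ConditioningError,
    ConfigurationError,
    CoverageError,
)


class TestRPC:
    def test_exact_recovery_on_noiseless_mixtures(self, exact_mixtures):
        signature, ms = exact_mixtures
        res = md.deconvolve_rpc(ms.mixtures, signature)
        err = np.abs(
            res.proportions.to_numpy() - ms.truth.values.to_numpy()
        ).max()
        assert err <= 1e-6

    def test_pure_sample_is_one_hot(self, exact_mixtures):
        signature, _ = exact_mixtures
        pure = md.BetaMatrix(
            signature.values[["NK"]].rename(columns={"NK": "pure"})
        )
        res = md.deconvolve_rpc(pure, signature)
        assert res.proportions.loc["NK", "pure"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_statsmodels_rlm_on_noisy_data(self, exact_mixtures):
        """Huber IRLS must agree with the canonical robust-regression
        implementation when residuals are non-degenerate."""
        statsmodels = pytest.importorskip("statsmodels.api")
        signature, ms = exact_mixtures
        rng = np.random.default_rng(0)
        noisy = md.BetaMatrix(
            (ms.mixtures.values.iloc[:, :5]
             + rng.normal(0, 0.03, (ms.mixtures.shape[0], 5))).clip(0, 1)
        )
        res = md.deconvolve_rpc(noisy, signature)
        X = signature.values.to_numpy()
        for j, sid in enumerate(noisy.sample_ids):
            rlm = statsmodels.RLM(
                noisy.values.iloc[:, j].to_numpy(), X,
                M=statsmodels.robust.norms.HuberT(t=1.345),
            ).fit()
            expected = np.clip(rlm.params, 0, None)
            expected /= expected.sum()
            np.testing.assert_allclose(
                res.proportions[sid].to_numpy(), expected, atol=2e-3
            )

    def test_coverage_error(self, exact_mixtures):
        signature, ms = exact_mixtures
        truncated = md.BetaMatrix(ms.mixtures.values.iloc[:700])
        with pytest.raises(CoverageError):
            md.deconvolve_rpc(truncated, signature)

    def test_rank_deficient_signature_rejected(self, exact_mixtures):
        signature, ms = exact_mixtures
        dup = signature.values.copy()
        dup["TC"] = dup["Epi"]
        with pytest.raises(ConditioningError):
            md.deconvolve_rpc(ms.mixtures, md.SignatureMatrix(dup))

    def test_degenerate_fit_returns_uniform_with_flag(self, exact_mixtures):
        signature, _ = exact_mixtures
        zero = md.BetaMatrix(
            pd.DataFrame(0.0, index=signature.probe_ids, columns=["empty"])
        )
        res = md.deconvolve_rpc(zero, signature)
        k = len(signature.cell_types)
        np.testing.assert_allclose(
            res.proportions["empty"].to_numpy(), np.full(k, 1 / k)
        )
        assert bool(res.diagnostics.loc["empty", "degenerate"])

    def test_constant_shift_sensitivity_is_bounded(self, exact_mixtures):
        """No-intercept model: a level shift perturbs estimates by a
        bounded, documented amount rather than leaving them unchanged."""
        signature, ms = exact_mixtures
        base = md.BetaMatrix(ms.mixtures.values.iloc[:, :3])
        shifted = md.BetaMatrix((base.values + 0.05).clip(0, 1))
        a = md.deconvolve_rpc(base, signature).proportions.to_numpy()
        b = md.deconvolve_rpc(shifted, signature).proportions.to_numpy()
        change = np.abs(a - b).max()
        assert 0 < change <= 0.5


class TestSVR:
    def test_recovery_within_one_percent(self, exact_mixtures):
        signature, ms = exact_mixtures
        res = md.deconvolve_svr(ms.mixtures, signature)
        err = np.abs(
            res.proportions.to_numpy() - ms.truth.values.to_numpy()
        ).max()
        assert err <= 1e-2

    def test_single_nu_grid_is_recorded(self, exact_mixtures):
        signature, ms = exact_mixtures
        few = md.BetaMatrix(ms.mixtures.values.iloc[:, :2])
        res = md.deconvolve_svr(few, signature, nu_grid=(0.4,))
        assert (res.diagnostics["nu"] == 0.4).all()

    def test_empty_nu_grid_rejected(self, exact_mixtures):
        signature, ms = exact_mixtures
        with pytest.raises(ConfigurationError):
            md.deconvolve_svr(ms.mixtures, signature, nu_grid=())


class TestWeightedSVR:
    def test_reduces_to_plain_svr(self, exact_mixtures):
        signature, ms = exact_mixtures
        few = md.BetaMatrix(ms.mixtures.values.iloc[:, :4])
        plain = md.deconvolve_svr(few, signature)
        reduced = md.deconvolve_weighted_svr(
            few, signature, condition_number_max=np.inf, refit_rounds=0
        )
        np.testing.assert_allclose(
            reduced.proportions.to_numpy(), plain.proportions.to_numpy(),
            atol=1e-12,
        )

    def test_pruning_never_worsens_conditioning(self, exact_mixtures):
        signature, _ = exact_mixtures
        full_cond = np.linalg.cond(signature.values.to_numpy())
        pruned, info = md.prune_for_conditioning(
            signature, condition_number_max=full_cond * 0.8, floor_probes=200
        )
        assert info["condition_number_after"] <= full_cond
        assert pruned.values.shape[0] >= 200

    def test_rare_component_recovered(self, exact_mixtures):
        signature, _ = exact_mixtures
        types = list(signature.cell_types)
        s = np.full(len(types), (1 - 0.01) / (len(types) - 1))
        s[types.index("Eosino")] = 0.01
        comp = md.CompositionMatrix(
            pd.DataFrame(s[:, None], index=types, columns=["rare"])
        )
        profiles = md.ProfileMatrix(signature.values.copy())
        ms = md.mix(profiles, comp)
        res = md.deconvolve_weighted_svr(ms.mixtures, signature)
        assert res.proportions.loc["Eosino", "rare"] == pytest.approx(
            0.01, abs=0.005
        )


@pytest.fixture(scope="module")
def panel(noiseless_reference):
    main_sig, immune_sig, *_ = md.build_hierarchical_panel(
        noiseless_reference
    )
    return main_sig, immune_sig


class TestHierarchical:
    def test_missing_ic_column_rejected(self, panel, exact_mixtures):
        main_sig, immune_sig = panel
        _, ms = exact_mixtures
        no_ic = md.SignatureMatrix(
            main_sig.values.drop(columns="IC"), step="main"
        )
        with pytest.raises(ConfigurationError, match="IC"):
            md.deconvolve_hierarchical(ms.mixtures, no_ic, immune_sig)

    def test_subtypes_scale_with_ic_total(self, panel, noiseless_reference):
        main_sig, immune_sig = panel
        ref = noiseless_reference
        types = list(md.DEFAULT_CELL_TYPES)
        profiles = md.build_profile_matrix(ref, {t: 2 for t in types}, seed=4)
        comps = md.sample_compositions(
            12, types, immune_types=md.IMMUNE_SUBTYPES, immune_cap=0.3,
            seed=6,
        )
        ms = md.mix(profiles, comps)
        res = md.deconvolve_hierarchical(ms.mixtures, main_sig, immune_sig)
        subtype_sum = res.proportions.loc[list(md.IMMUNE_SUBTYPES)].sum(axis=0)
        main_total = res.proportions.sum(axis=0)
        np.testing.assert_allclose(main_total, 1.0, atol=1e-9)
        # subtype block equals the step-1 IC estimate by construction
        step1 = md.deconvolve_rpc(ms.mixtures, main_sig)
        np.testing.assert_allclose(
            subtype_sum, step1.proportions.loc["IC"], atol=1e-9
        )

    def test_zero_ic_zeroes_all_subtypes(self, panel, noiseless_reference):
        main_sig, immune_sig = panel
        ref = noiseless_reference
        types = list(md.DEFAULT_CELL_TYPES)
        s = np.zeros((len(types), 1))
        s[types.index("Epi")] = 0.6
        s[types.index("Fib")] = 0.4
        comp = md.CompositionMatrix(
            pd.DataFrame(s, index=types, columns=["stroma"])
        )
        profiles = md.build_profile_matrix(ref, {t: 2 for t in types}, seed=4)
        ms = md.mix(profiles, comp)
        res = md.deconvolve_hierarchical(ms.mixtures, main_sig, immune_sig)
        ic_est = float(
            md.deconvolve_rpc(ms.mixtures, main_sig).proportions.loc[
                "IC", "stroma"
            ]
        )
        np.testing.assert_allclose(
            res.proportions.loc[list(md.IMMUNE_SUBTYPES), "stroma"],
            ic_est * md.deconvolve_rpc(ms.mixtures, immune_sig)
            .proportions["stroma"].to_numpy(),
            atol=1e-12,
        )

    def test_ten_type_noiseless_accuracy(self, panel, noiseless_reference):
        main_sig, immune_sig = panel
        ref = noiseless_reference
        types = list(md.DEFAULT_CELL_TYPES)
        profiles = md.build_profile_matrix(ref, {t: 2 for t in types}, seed=8)
        comps = md.sample_compositions(
            20, types, immune_types=md.IMMUNE_SUBTYPES, immune_cap=0.2,
            seed=9,
        )
        ms = md.mix(profiles, comps)
        # the intercept soaks up the non-immune baseline at immune probes,
        # which otherwise biases relative subtype estimates toward uniform
        res = md.deconvolve_hierarchical(
            ms.mixtures, main_sig, immune_sig, immune_fit_intercept=True
        )
        pred = res.proportions.loc[types, list(ms.truth.sample_ids)]
        err = (pred - ms.truth.values).abs()
        assert err.loc[["TC", "Epi", "Fib"]].to_numpy().max() <= 0.01
        assert err.loc[list(md.IMMUNE_SUBTYPES)].to_numpy().max() <= 0.03


class TestInvariants:
    @pytest.mark.parametrize("method", ["rpc", "svr", "weighted_svr"])
    def test_simplex_validity_on_arbitrary_mixtures(
        self, method, exact_mixtures
    ):
        signature, _ = exact_mixtures
        rng = np.random.default_rng(13)
        arbitrary = md.BetaMatrix(
            pd.DataFrame(
                rng.random((len(signature.probe_ids), 4)),
                index=signature.probe_ids,
                columns=[f"r{i}" for i in range(4)],
            )
        )
        res = md.deconvolve(arbitrary, signature, method=method)
        arr = res.proportions.to_numpy()
        assert (arr >= 0).all()
        np.testing.assert_allclose(arr.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("method", ["rpc", "svr"])
    def test_permutation_equivariance(self, method, exact_mixtures):
        signature, ms = exact_mixtures
        few = md.BetaMatrix(ms.mixtures.values.iloc[:, :3])
        base = md.deconvolve(few, signature, method=method)
        perm = list(signature.cell_types)[::-1]
        permuted_sig = md.SignatureMatrix(
            signature.values[perm], aggregator=signature.aggregator
        )
        res = md.deconvolve(few, permuted_sig, method=method)
        np.testing.assert_allclose(
            res.proportions.loc[list(signature.cell_types)].to_numpy(),
            base.proportions.to_numpy(),
            atol=1e-9,
        )

    def test_error_grows_with_mixture_noise(self, exact_mixtures):
        signature, _ = exact_mixtures
        types = list(signature.cell_types)
        comps = md.sample_compositions(15, types, seed=21)
        profiles = md.ProfileMatrix(signature.values.copy())
        med_errs = []
        for sd in (0.0, 0.01, 0.05):
            ms = md.mix(profiles, comps, noise_sd=sd, seed=5)
            res = md.deconvolve_rpc(ms.mixtures, signature)
            err = np.abs(
                res.proportions.to_numpy() - ms.truth.values.to_numpy()
            )
            med_errs.append(np.median(err))
        assert med_errs[0] <= med_errs[1] <= med_errs[2]
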