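import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methdeconv as md


def _reference_from_array(arr, n_group, n_rest):
    n_probes = arr.shape[0]
    cols = [f"g{i}" for i in range(n_group)] + [f"r{i}" for i in range(n_rest)]
    values = pd.DataFrame(arr, index=[f"cg{i:05d}" for i in range(n_probes)],
                          columns=cols)
    labels = pd.Series(
        ["grp"] * n_group + ["rest"] * n_rest, index=cols
    )
    return md.LabeledReference(md.BetaMatrix(values), labels)


class TestModeratedDifferentialTest:
    def test_constant_data_yields_null_everywhere(self):
        arr = np.full((50, 8), 0.5)
        ref = _reference_from_array(arr, 4, 4)
        out = md.moderated_differential_test(
            ref, ref.samples_of("grp"), ref.samples_of("rest"), "null"
        )
        assert (out["delta"] == 0).all()
        assert not (out["q_value"] < 0.01).any()

    def test_planted_probe_matches_welch_oracle(self):
        rng = np.random.default_rng(17)
        arr = np.clip(rng.normal(0.5, 0.02, size=(200, 12)), 0, 1)
        arr[0, :6] = np.clip(rng.normal(0.9, 0.02, 6), 0, 1)
        arr[0, 6:] = np.clip(rng.normal(0.1, 0.02, 6), 0, 1)
        ref = _reference_from_array(arr, 6, 6)
        out = md.moderated_differential_test(
            ref, ref.samples_of("grp"), ref.samples_of("rest"), "planted"
        ).set_index("probe_id")
        hit = out.loc["cg00000"]
        assert hit["delta"] == pytest.approx(0.8, abs=0.05)
        assert hit["q_value"] < 0.01
        # independent Welch oracle on the same data
        t_w, p_w = stats.ttest_ind(arr[0, :6], arr[0, 6:], equal_var=False)
        assert np.sign(hit["t_stat"]) == np.sign(t_w)
        assert p_w < 1e-6
        # delta is exactly the difference of group means
        assert hit["delta"] == pytest.approx(
            arr[0, :6].mean() - arr[0, 6:].mean(), abs=1e-12
        )

    def test_global_null_controls_discoveries(self):
        rng = np.random.default_rng(4)
        arr = np.clip(rng.normal(0.5, 0.05, size=(10_000, 12)), 0, 1)
        perm = rng.permutation(12)
        ref = _reference_from_array(arr[:, perm], 6, 6)
        out = md.moderated_differential_test(
            ref, ref.samples_of("grp"), ref.samples_of("rest"), "perm-null"
        )
        assert (out["q_value"] < 0.01).mean() <= 0.02

    def test_too_few_samples_rejected(self, tiny_labeled_reference):
        ref = tiny_labeled_reference
        with pytest.raises(ValueError, match=">= 2"):
            md.moderated_differential_test(
                ref, ["s1"], ["t1", "t2"], "bad"
            )

    def test_agrees_with_limma_oracle(self, tmp_path):
        """Moderated t and p must match Bioconductor limma's eBayes."""
        rng = np.random.default_rng(8)
        arr = np.clip(rng.normal(0.5, 0.08, size=(150, 10)), 0.01, 0.99)
        arr[:10, :5] += 0.25  # some real effects so shrinkage is non-trivial
        arr = np.clip(arr, 0.01, 0.99)
        ref = _reference_from_array(arr, 5, 5)
        ours = md.moderated_differential_test(
            ref, ref.samples_of("grp"), ref.samples_of("rest"), "cmp"
        )
        mat = tmp_path / "mat.csv"
        pd.DataFrame(arr).to_csv(mat, index=False)
        out_csv = tmp_path / "limma.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{mat}"))
            design <- cbind(Intercept=1, grp=c(rep(1,5), rep(0,5)))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
                      "{out_csv}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        limma = pd.read_csv(out_csv)
        np.testing.assert_allclose(ours["t_stat"], limma["t"],
                                   rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(ours["p_value"], limma["p"],
                                   rtol=1e-5, atol=1e-12)


class TestOneVsAllSelection:
    def test_recovers_planted_markers_exactly(self, four_type_reference):
        """Markers selected on normalized betas at the panel thresholds
        must be exactly the planted sets: sensitivity 1, no false picks."""
        ref = four_type_reference
        norm = md.LabeledReference(
            md.min_max_normalize(ref.betas), ref.labels, ref.source_set
        )
        sel = md.select_features_one_vs_all(norm, fdr_max=0.01)
        for t in ("TC", "Epi", "Fib", "IC"):
            got = set(sel.per_comparison[f"{t}_vs_rest"]["probe_id"])
            planted = set(ref.planted_markers[t])
            assert got == planted

    def test_selected_probes_satisfy_thresholds_on_retest(
        self, four_type_reference
    ):
        ref = four_type_reference
        norm = md.LabeledReference(
            md.min_max_normalize(ref.betas), ref.labels, ref.source_set
        )
        sel = md.select_features_one_vs_all(norm, fdr_max=0.01)
        thresholds = sel.parameters["delta_min_by_type"]
        for t in ("TC", "Epi", "Fib", "IC"):
            stats_df = md.moderated_differential_test(
                norm, norm.samples_of(t),
                [s for s in norm.labels.index if norm.labels[s] != t],
                f"{t}_vs_rest",
            ).set_index("probe_id")
            chosen = stats_df.loc[
                sel.per_comparison[f"{t}_vs_rest"]["probe_id"]
            ]
            assert (chosen["delta"].abs() >= thresholds[t]).all()
            assert (chosen["q_value"] < 0.01).all()

    def test_unattainable_threshold_warns_and_selects_nothing(
        self, four_type_reference
    ):
        with pytest.warns(UserWarning, match="no probes selected"):
            sel = md.select_features_one_vs_all(
                four_type_reference,
                delta_min_by_type={t: 1.0 for t in ("TC", "Epi", "Fib", "IC")},
            )
        assert sel.union == []
        assert len(sel.warnings) == 4

    def test_selection_is_deterministic(self, four_type_reference):
        ref = md.LabeledReference(
            md.min_max_normalize(four_type_reference.betas),
            four_type_reference.labels,
        )
        a = md.select_features_one_vs_all(ref)
        b = md.select_features_one_vs_all(ref)
        assert a.union == b.union
        for k in a.per_comparison:
            pd.testing.assert_frame_equal(
                a.per_comparison[k], b.per_comparison[k]
            )


class TestPairwiseSelection:
    def test_union_bounded_by_cap_arithmetic(self, four_type_reference):
        sel = md.select_features_pairwise(
            four_type_reference, max_per_pair=1, delta_median_min=0.2
        )
        assert len(sel.union) <= 2 * 6  # 2 directions x C(4,2) pairs

    def test_stronger_separation_ranked_first(self):
        rng = np.random.default_rng(0)
        arr = np.clip(rng.normal(0.5, 0.01, size=(40, 8)), 0, 1)
        arr[0, :4], arr[0, 4:] = 0.9, 0.1  # median diff 0.8
        arr[1, :4], arr[1, 4:] = 0.65, 0.4  # median diff 0.25
        values = pd.DataFrame(arr, index=[f"cg{i:03d}" for i in range(40)],
                              columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=values.columns)
        ref = md.LabeledReference(md.BetaMatrix(values), labels)
        sel = md.select_features_pairwise(ref, max_per_pair=1,
                                          delta_median_min=0.2)
        hyper = sel.per_comparison["a_vs_b"]
        assert "cg000" in set(hyper["probe_id"])
        assert "cg001" not in set(hyper["probe_id"])

    def test_large_cap_recovers_all_planted_markers(self, four_type_reference):
        ref = four_type_reference
        sel = md.select_features_pairwise(ref, max_per_pair=1000,
                                          delta_median_min=0.2)
        planted = {p for t in ("TC", "Epi", "Fib", "IC")
                   for p in ref.planted_markers[t]}
        assert planted <= set(sel.union)


class TestBuildSignature:
    def test_single_sample_aggregation_is_identity(self, tiny_labeled_reference):
        ref = tiny_labeled_reference.subset_samples(["s1", "t1"])
        sig = md.build_signature(ref, ["cg1", "cg2"], aggregator="mean")
        np.testing.assert_array_equal(sig.values["alpha"], [0.2, 0.9])
        np.testing.assert_array_equal(sig.values["beta"], [0.8, 0.1])

    def test_median_aggregation_is_order_statistic(self):
        values = pd.DataFrame(
            {"s1": [0.1], "s2": [0.2], "s3": [0.9]}, index=["cg1"]
        )
        labels = pd.Series("one", index=values.columns)
        ref = md.LabeledReference(md.BetaMatrix(values), labels)
        sig = md.build_signature(ref, ["cg1"], aggregator="median")
        assert sig.values.loc["cg1", "one"] == 0.2

    def test_missing_probe_is_reported(self, tiny_labeled_reference):
        with pytest.raises(KeyError, match="cg999"):
            md.build_signature(tiny_labeled_reference, ["cg1", "cg999"])

    def test_values_bounded(self, four_type_reference):
        sel = md.select_features_one_vs_all(
            md.LabeledReference(
                md.min_max_normalize(four_type_reference.betas),
                four_type_reference.labels,
            )
        )
        sig = md.build_signature(four_type_reference, sel)
        arr = sig.values.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1

    def test_noiseless_signature_reproduces_target_profile(
        self, noiseless_reference
    ):
        ref = noiseless_reference
        probes = ref.planted_markers["Epi"]
        sig = md.build_signature(ref, probes, aggregator="median")
        expected = ref.target_profile.loc[probes, list(sig.cell_types)]
        np.testing.assert_allclose(
            sig.values.to_numpy(), expected.to_numpy(), atol=1e-12
        )
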