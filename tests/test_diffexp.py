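"""NB dispersion estimation, the GLM likelihood-ratio test and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from trex.diffexp import NBDiffExp, adjust_fdr
from trex.simulate import SyntheticSpec, generate

from oracles import bh_by_hand, poisson_lrt_pvalues

SEED = 20150903


class TestCommonDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        spec = SyntheticSpec(
            n_genes=2000, conditions=("WT", "Mut"), n_reps=3,
            dispersion=0.0, de_fraction=0.0, seed=SEED,
        )
        table, factors, *_ = generate(spec)
        de = NBDiffExp().fit(table.values, factors.condition.to_numpy())
        assert de.common_dispersion_ < 0.01

    def test_nb_dispersion_recovered(self, null_fit):
        # truth is phi = 0.1
        assert 0.08 <= null_fit["de"].common_dispersion_ <= 0.12

    def test_library_size_scaling_invariance(self):
        spec = SyntheticSpec(
            n_genes=400, conditions=("WT", "Mut"), n_reps=3,
            dispersion=0.1, de_fraction=0.0, seed=SEED + 2,
        )
        table, factors, *_ = generate(spec)
        cond = factors.condition.to_numpy()
        de1 = NBDiffExp().fit(table.values, cond)
        de2 = NBDiffExp().fit(
            table.values, cond, effective_lib=table.values.sum(axis=0) * 2.0
        )
        # doubling all offsets shifts the intercepts, not the dispersion
        assert de2.common_dispersion_ == pytest.approx(
            de1.common_dispersion_, rel=0.02
        )

    def test_no_replicates_is_hard_error_with_remedy(self):
        df = pd.DataFrame(
            np.random.default_rng(0).poisson(100, (50, 2)).astype(float),
            index=[f"g{i}" for i in range(50)],
            columns=["a", "b"],
        )
        with pytest.raises(ValueError, match="dispersion"):
            NBDiffExp().fit(df, ["x", "y"])
        # a fixed dispersion unlocks unreplicated designs
        de = NBDiffExp(dispersion=0.1).fit(df, ["x", "y"])
        assert de.common_dispersion_ == 0.1


class TestTagwiseDispersion:
    def test_huge_prior_df_shrinks_to_common(self):
        spec = SyntheticSpec(
            n_genes=200, conditions=("WT", "Mut"), n_reps=3,
            dispersion=0.1, de_fraction=0.0, seed=SEED + 3,
        )
        table, factors, *_ = generate(spec)
        de = NBDiffExp(prior_df=1e9).fit(table.values, factors.condition.to_numpy())
        assert np.max(np.abs(de.tagwise_dispersion_ - de.common_dispersion_)) < 1e-4

    def test_outlier_gene_gets_larger_dispersion(self):
        rng = np.random.default_rng(SEED + 4)
        spec = SyntheticSpec(
            n_genes=500, conditions=("WT", "Mut"), n_reps=3,
            dispersion=0.05, de_fraction=0.0, seed=SEED + 4,
        )
        table, factors, *_ = generate(spec)
        counts = table.values.copy()
        # replace one gene with a highly overdispersed one (phi = 1)
        mu, r = 500.0, 1.0
        counts.iloc[0] = rng.negative_binomial(r, r / (r + mu), counts.shape[1])
        de = NBDiffExp().fit(counts, factors.condition.to_numpy())
        assert (
            de.tagwise_dispersion_.iloc[0]
            > de.tagwise_dispersion_.iloc[1:].median()
        )

    def test_constant_gene_hits_lower_bound_without_shrinkage(self):
        # equal library sizes so identical counts mean zero residual
        # variance; a negligible prior exposes the per-gene optimum
        spec = SyntheticSpec(
            n_genes=100, conditions=("WT", "Mut"), n_reps=3,
            dispersion=0.1, de_fraction=0.0, lib_size_cv=0.0, seed=SEED + 5,
        )
        table, factors, *_ = generate(spec)
        counts = table.values.copy()
        counts.iloc[0] = 300.0  # identical counts, zero variability
        lib = pd.Series(spec.lib_size_mean, index=counts.columns)
        de = NBDiffExp(prior_df=1e-3).fit(
            counts, factors.condition.to_numpy(), effective_lib=lib
        )
        # the Cox-Reid adjustment leaves a tiny interior optimum rather
        # than the numeric bound; "effectively zero" is the real property
        assert de.tagwise_dispersion_.iloc[0] < de.common_dispersion_ / 100

    def test_moderate_prior_shrinks_constant_gene_toward_common(self):
        spec = SyntheticSpec(
            n_genes=100, conditions=("WT", "Mut"), n_reps=3,
            dispersion=0.1, de_fraction=0.0, lib_size_cv=0.0, seed=SEED + 5,
        )
        table, factors, *_ = generate(spec)
        counts = table.values.copy()
        counts.iloc[0] = 300.0
        lib = pd.Series(spec.lib_size_mean, index=counts.columns)
        de = NBDiffExp(prior_df=10.0).fit(
            counts, factors.condition.to_numpy(), effective_lib=lib
        )
        lo = de.tagwise_dispersion_.iloc[0]
        assert 1e-4 < lo < de.common_dispersion_  # pulled up but still lowest
        assert lo <= de.tagwise_dispersion_.min() + 1e-12


class TestContrastTest:
    def test_type_one_error_near_nominal(self, null_fit):
        p = null_fit["result"].table["p_value"].to_numpy()
        assert 0.035 <= np.mean(p <= 0.05) <= 0.065

    def test_null_pvalues_approximately_uniform(self, null_fit):
        p = null_fit["result"].table["p_value"].to_numpy()
        assert kstest(p, "uniform").statistic < 0.03

    def test_spiked_logfc_recovered(self, spiked_fit):
        truth = spiked_fit["truth"].log2fc["Mut"]
        est = spiked_fit["result"].table["logFC"]
        up = truth.index[truth == 2.0]
        down = truth.index[truth == -2.0]
        assert 1.7 <= est[up].mean() <= 2.3
        assert -2.3 <= est[down].mean() <= -1.7

    def test_swapping_target_control_negates_logfc_keeps_p(self, spiked_fit):
        de = spiked_fit["de"]
        fwd = de.test_contrast("Mut", "WT").table
        rev = de.test_contrast("WT", "Mut").table
        assert np.allclose(fwd["logFC"], -rev["logFC"], atol=1e-12)
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_power_monotone_in_effect_size(self):
        powers = []
        for i, lfc in enumerate([1.0, 2.0, 4.0]):
            spec = SyntheticSpec(
                n_genes=600, conditions=("WT", "Mut"), n_reps=3,
                dispersion=0.1, de_fraction=0.2, de_log2fc=(lfc,),
                seed=SEED + 6,  # same seed: identical gene selection
            )
            table, factors, _, _, truth = generate(spec)
            de = NBDiffExp().fit(table.values, factors.condition.to_numpy())
            res = de.test_contrast("Mut", "WT").table
            deg = truth.de_genes("Mut")
            powers.append(float((res.loc[deg, "p_value"] <= 0.05).mean()))
        assert powers[0] < powers[1] < powers[2]

    def test_small_dispersion_matches_poisson_lrt(self):
        rng = np.random.default_rng(SEED + 7)
        counts = pd.DataFrame(
            rng.poisson(200, (20, 6)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        lib = counts.sum(axis=0).astype(float)
        de = NBDiffExp(dispersion=1e-7).fit(
            counts, ["a"] * 3 + ["b"] * 3, effective_lib=lib
        )
        ours = de.test_contrast("b", "a").table["p_value"].to_numpy()
        theirs = poisson_lrt_pvalues(
            counts.iloc[:, 3:].to_numpy(),
            counts.iloc[:, :3].to_numpy(),
            lib.iloc[3:].to_numpy(),
            lib.iloc[:3].to_numpy(),
        )
        assert np.max(np.abs(ours - theirs)) < 1e-3

    def test_missing_level_is_hard_error(self, null_fit):
        with pytest.raises(ValueError, match="absent"):
            null_fit["de"].test_contrast("Mut", "Ghost")

    def test_all_zero_gene_gets_p_one_and_finite_logfc(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(100, (30, 6)).astype(float),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(6)],
        )
        counts.iloc[0] = 0.0
        counts.iloc[1, :3] = 0.0  # absent in control only
        de = NBDiffExp(dispersion=0.1).fit(counts, ["c"] * 3 + ["t"] * 3)
        t = de.test_contrast("t", "c").table
        assert t["p_value"].iloc[0] == pytest.approx(1.0)
        assert np.isfinite(t["logFC"]).all()
        assert t["logFC"].iloc[1] > 0  # present in target, absent in control
        assert bool(t["zero_flag"].iloc[0]) and bool(t["zero_flag"].iloc[1])


class TestFDR:
    def test_hand_checked_step_up(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(adjust_fdr(p), [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize(
        "p,expected",
        [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ([0.07], [0.07])],
    )
    def test_degenerate_cases(self, p, expected):
        assert np.allclose(adjust_fdr(p), expected)

    def test_matches_definition_on_random_vectors(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(adjust_fdr(p), bh_by_hand(list(p)), atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(size=100))
        assert np.all(np.diff(adjust_fdr(p)) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
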