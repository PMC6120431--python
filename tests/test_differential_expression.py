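import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidalplast.data_model import CountMatrix, DesignError, SampleDesign
from tidalplast.differential_expression import (
    bh_adjust,
    call_significant,
    divergence_contrast,
    nb_wald_test,
    plasticity_contrast,
    standard_contrasts,
)
from tidalplast.normalization import filter_low_expression, size_factors
from tidalplast.synthetic_data import SimConfig, simulate_counts, simulate_null_shared_baseline

from conftest import full_design_frame
from oracles import bh_bruteforce


class TestBHAdjust:
    def test_hand_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_single_pvalue_passthrough(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    def test_matches_bruteforce_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=n)
        mask = rng.random(n) < 0.2
        p[mask] = rng.choice(p, size=int(mask.sum()))  # introduce ties
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-14)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallSignificant:
    def test_strict_threshold_boundary(self):
        import pandas as pd
        from tidalplast.data_model import DEResult

        table = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2_effect": [1.0, 1.0, 1.0],
                "se": [0.1] * 3,
                "pvalue": [0.01, 0.01, 0.01],
                "qvalue": [0.049, 0.05, 0.051],
            }
        )
        assert call_significant(DEResult("x", table)) == {"a"}

    def test_empty_result_gives_empty_set(self):
        import pandas as pd
        from tidalplast.data_model import DEResult

        table = pd.DataFrame(
            columns=["gene_id", "log2_effect", "se", "pvalue", "qvalue"]
        )
        assert call_significant(DEResult("x", table)) == set()


class TestNBWaldTest:
    def test_identical_groups_give_zero_effect_and_p_near_one(self):
        design = SampleDesign(full_design_frame(sites=("BYQ",)))
        rng = np.random.default_rng(0)
        arr = rng.integers(50, 200, size=(40, 18))
        # make the two 0 h tide groups exactly identical per gene
        i0 = design.mask(tide="I", time_h=0)
        s0 = design.mask(tide="S", time_h=0)
        arr[:, np.flatnonzero(i0)] = 100
        arr[:, np.flatnonzero(s0)] = 100
        cm = CountMatrix([f"g{i}" for i in range(40)], design.sample_ids, arr)
        de = nb_wald_test(cm, design, divergence_contrast("BYQ"), size_factors=np.ones(18))
        np.testing.assert_allclose(de.table.log2_effect, 0.0, atol=1e-8)
        assert (de.table.pvalue >= 0.99).all()

    def test_fourfold_change_recovered(self):
        """Two groups of 3, true 4-fold change: log2 effect within +-0.5 of 2 in >=90% of genes."""
        rng = np.random.default_rng(123)
        n_genes = 200
        alpha = 0.05
        mu = 100.0
        a = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(n_genes, 3))
        b = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * 4 * mu), size=(n_genes, 3))
        design = SampleDesign(full_design_frame(sites=("BYQ",)))
        arr = np.zeros((n_genes, 18), dtype=int)
        arr[:, design.mask(tide="S", time_h=0)] = a
        arr[:, design.mask(tide="I", time_h=0)] = b
        arr[:, ~design.mask(time_h=0)] = rng.integers(50, 150, size=(n_genes, 12))
        cm = CountMatrix([f"g{i}" for i in range(n_genes)], design.sample_ids, arr)
        de = nb_wald_test(cm, design, divergence_contrast("BYQ"), size_factors=np.ones(18))
        err = de.table.log2_effect.to_numpy() - 2.0
        # oracle: the naive log-ratio estimator (same information content) has
        # error sd sqrt(2/3 * (1/mu + alpha)) / ln 2 ~= 0.29, so ~89% of genes
        # land within +-0.5; check unbiasedness, the information-bound sd, and
        # a recovery fraction consistent with that bound
        assert abs(err.mean()) <= 0.07
        assert 0.24 <= err.std() <= 0.37
        assert (np.abs(err) <= 0.5).mean() >= 0.83

    def test_type_i_error_calibrated_on_null_simulation(self):
        counts, design, _ = simulate_null_shared_baseline(SimConfig(seed=31, n_genes=2000))
        filt = filter_low_expression(counts)
        sf = size_factors(filt)
        de = nb_wald_test(filt, design, divergence_contrast("LT"), size_factors=sf)
        rate = float((de.table.pvalue < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_two_sided_symmetry_under_group_relabeling(self):
        counts, design, _ = simulate_counts(SimConfig(seed=17, n_genes=100))
        filt = filter_low_expression(counts)
        sf = size_factors(filt)
        fwd = divergence_contrast("BYQ")
        rev = divergence_contrast("BYQ")
        rev.baseline, rev.alt = fwd.alt, fwd.baseline
        de_f = nb_wald_test(filt, design, fwd, size_factors=sf)
        de_r = nb_wald_test(filt, design, rev, size_factors=sf)
        np.testing.assert_allclose(de_f.table.pvalue, de_r.table.pvalue, atol=1e-9)
        np.testing.assert_allclose(de_f.table.log2_effect, -de_r.table.log2_effect, atol=1e-9)

    def test_effect_invariant_to_doubling_counts_and_size_factors(self):
        counts, design, _ = simulate_counts(SimConfig(seed=19, n_genes=80))
        filt = filter_low_expression(counts)
        sf = size_factors(filt)
        de1 = nb_wald_test(filt, design, plasticity_contrast("BYQ", 6), size_factors=sf)
        doubled = CountMatrix(filt.gene_ids, filt.sample_ids, filt.counts * 2)
        de2 = nb_wald_test(doubled, design, plasticity_contrast("BYQ", 6), size_factors=2 * sf)
        # NB MLEs are only approximately scale-equivariant (doubling counts
        # halves the relative Poisson noise, changing the score weights)
        np.testing.assert_allclose(
            de1.table.log2_effect, de2.table.log2_effect, atol=0.1
        )
        assert np.corrcoef(de1.table.log2_effect, de2.table.log2_effect)[0, 1] > 0.999

    def test_all_zero_gene_flagged_with_p_one(self):
        design = SampleDesign(full_design_frame(sites=("BYQ",)))
        rng = np.random.default_rng(3)
        arr = rng.integers(10, 60, size=(5, 18))
        arr[2, design.mask(time_h=0)] = 0
        cm = CountMatrix([f"g{i}" for i in range(5)], design.sample_ids, arr)
        de = nb_wald_test(cm, design, divergence_contrast("BYQ"), size_factors=np.ones(18))
        row = de.table.iloc[2]
        assert row.flag == "all_zero" and row.pvalue == 1.0 and row.log2_effect == 0.0

    def test_contrast_with_too_few_samples_rejected(self):
        design = SampleDesign(full_design_frame(sites=("BYQ",)))
        with pytest.raises(DesignError, match="2 samples"):
            plasticity_contrast("LT", 6).group_masks(design)

    def test_standard_contrast_battery(self, full_design):
        names = [c.name for c in standard_contrasts(full_design)]
        assert names == [
            "divergence:BYQ",
            "divergence:LT",
            "plasticity:BYQ:6h",
            "plasticity:BYQ:24h",
            "plasticity:LT:6h",
            "plasticity:LT:24h",
        ]


class TestAgainstDESeq2:
    def test_effect_estimates_track_independent_nb_glm_implementation(self):
        """Cross-check the in-package NB fit against pydeseq2 on a small dataset."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, design, _ = simulate_counts(SimConfig(seed=77, n_genes=150, sites=("BYQ",)))
        filt = filter_low_expression(counts)
        sf = size_factors(filt)
        ours = nb_wald_test(filt, design, divergence_contrast("BYQ"), size_factors=sf)

        meta = design.table.set_index("sample_id")
        meta = meta[meta.time_h == 0]
        cdf = filt.to_frame().T.loc[meta.index]
        dds = DeseqDataSet(counts=cdf, metadata=meta, design="~tide", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["tide", "I", "S"], quiet=True)
        ds.summary()
        theirs = ds.results_df.loc[ours.table.gene_id]

        r = np.corrcoef(ours.table.log2_effect, theirs.log2FoldChange)[0, 1]
        assert r > 0.95
        # significant calls should largely agree in direction
        both_sig = (ours.table.qvalue.to_numpy() < 0.05) & (theirs.padj.to_numpy() < 0.05)
        if both_sig.any():
            same_sign = np.sign(ours.table.log2_effect.to_numpy()[both_sig]) == np.sign(
                theirs.log2FoldChange.to_numpy()[both_sig]
            )
            assert same_sign.all()
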