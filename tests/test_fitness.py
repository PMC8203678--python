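"""Fitness model: collapse, normalization, dispersion, NB fit, shrinkage, FD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chemofit as cf
from chemofit.fitness import (
    DISPERSION_FLOOR,
    estimate_prior_scale,
    fit_screen,
    flag_screens,
)

from conftest import tag_matrix


def single_screen_design(n_replicates=3):
    return cf.make_design([("X", "1mM", "DMSO")], n_replicates=n_replicates)


def gene_matrix(counts: pd.DataFrame, design: cf.ScreenDesign) -> cf.GeneCountMatrix:
    return cf.GeneCountMatrix(counts=counts, design=design)


class TestCollapseTags:
    def test_uptag_plus_downtag(self, small_catalog):
        des = single_screen_design(1)
        counts = pd.DataFrame(0, index=small_catalog.tags, columns=des.samples)
        row = small_catalog.frame.iloc[0]
        counts.loc[row.uptag, des.samples[0]] = 10
        counts.loc[row.downtag, des.samples[0]] = 15
        gc = cf.collapse_tags(tag_matrix(counts), small_catalog, des)
        assert gc.counts.loc[row.gene, des.samples[0]] == 25

    def test_missing_downtag_counts_as_zero(self, small_catalog):
        des = single_screen_design(1)
        counts = pd.DataFrame(
            7, index=list(small_catalog.frame["uptag"]), columns=des.samples
        )
        gc = cf.collapse_tags(tag_matrix(counts), small_catalog, des)
        assert (gc.counts.to_numpy() == 7).all()

    def test_stray_tag_rejected(self, small_catalog):
        des = single_screen_design(1)
        counts = pd.DataFrame(1, index=["A" * 20], columns=des.samples)
        with pytest.raises(ValueError, match="not in catalog"):
            cf.collapse_tags(tag_matrix(counts), small_catalog, des)


class TestSizeFactors:
    def test_threefold_sample_hand_computed(self):
        """Median-of-ratios on a 5-gene toy: second sample 3x the first."""
        first = np.array([10.0, 20, 40, 100, 400])
        counts = pd.DataFrame({"a": first, "b": 3 * first}).astype(int)
        sf = cf.size_factors(counts)
        # by hand: ratios to the geometric mean are c/sqrt(3) and sqrt(3)c
        assert sf["b"] / sf["a"] == pytest.approx(3.0, abs=1e-12)
        assert sf["a"] == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [5, 8, 12], "b": [5, 8, 12]})
        sf = cf.size_factors(counts)
        assert sf["a"] == sf["b"] == pytest.approx(1.0)

    def test_gene_with_zero_excluded_from_median(self):
        counts = pd.DataFrame({"a": [10, 0, 10], "b": [20, 1000, 20]})
        sf = cf.size_factors(counts)  # only rows 0 and 2 inform the median
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_all_zero_row_everywhere_fails(self):
        counts = pd.DataFrame({"a": [0, 1], "b": [1, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            cf.size_factors(counts)


class TestEstimateDispersions:
    def _simulate(self, dispersion, n_genes, seed, mu=800.0):
        des = single_screen_design(3)
        cat_frame = pd.DataFrame(
            {
                "strain_id": [f"s{i}" for i in range(n_genes)],
                "gene": [f"g{i}" for i in range(n_genes)],
                "uptag": ["A"] * n_genes,  # unused here
                "downtag": ["C"] * n_genes,
            }
        )
        rng = np.random.default_rng(seed)
        cols = {}
        for s in des.samples:
            if dispersion < 1e-8:
                cols[s] = rng.poisson(mu, size=n_genes)
            else:
                n = 1.0 / dispersion
                cols[s] = rng.negative_binomial(n, n / (n + mu), size=n_genes)
        counts = pd.DataFrame(cols, index=cat_frame["gene"])
        return gene_matrix(counts, des), des

    def test_poisson_counts_give_tiny_estimates(self):
        gc, des = self._simulate(0.0, 600, seed=1)
        sf = cf.size_factors(gc)
        disp = cf.estimate_dispersions(gc, sf, des)
        assert (disp <= 0.01).mean() >= 0.9

    def test_nb_dispersion_recovered(self):
        gc, des = self._simulate(0.05, 1000, seed=2)
        sf = cf.size_factors(gc)
        disp = cf.estimate_dispersions(gc, sf, des)
        assert 0.025 <= disp.median() <= 0.1

    def test_constant_counts_hit_floor(self):
        des = single_screen_design(2)
        counts = pd.DataFrame(50, index=["g0", "g1"], columns=des.samples)
        gc = gene_matrix(counts, des)
        disp = cf.estimate_dispersions(gc, cf.size_factors(gc), des)
        assert (disp == DISPERSION_FLOOR).all()


class TestFitScreen:
    def test_null_gene_flat(self):
        des = single_screen_design(3)
        counts = pd.DataFrame(100, index=["g0"], columns=des.samples)
        gc = gene_matrix(counts, des)
        sf = pd.Series(1.0, index=des.samples)
        disp = pd.Series(1e-6, index=["g0"])
        fit = fit_screen(gc, sf, disp, des, des.screen_ids[0])
        assert fit["raw_lfc"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert fit["p"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_fourfold(self):
        """Control mean 200 vs treatment 50 with vanishing dispersion: -2."""
        des = single_screen_design(3)
        values = {
            s: (50 if "T" in s.split("_")[-1] else 200) for s in des.samples
        }
        counts = pd.DataFrame(values, index=["g0"])
        gc = gene_matrix(counts, des)
        sf = pd.Series(1.0, index=des.samples)
        disp = pd.Series(1e-8, index=["g0"])
        fit = fit_screen(gc, sf, disp, des, des.screen_ids[0])
        assert fit["raw_lfc"].iloc[0] == pytest.approx(-2.0, abs=1e-6)

    def test_recovery_of_planted_lfc(self, small_catalog):
        """Mean raw LFC over 100 noise seeds lands within 0.2 of -1.5."""
        des = single_screen_design(3)
        gene = small_catalog.genes[0]
        truth = cf.make_truth(small_catalog, des, {des.screen_ids[0]: {gene: -1.5}})
        estimates = []
        for seed in range(100):
            params = cf.NBParams(baseline_log_mean=np.log(700), seed=seed)
            counts, _ = cf.simulate_counts(small_catalog, des, truth, params)
            gc = cf.collapse_tags(tag_matrix(counts), small_catalog, des)
            sf = cf.size_factors(gc)
            disp = cf.estimate_dispersions(gc, sf, des)
            fit = fit_screen(gc, sf, disp, des, des.screen_ids[0])
            estimates.append(fit.loc[gene, "raw_lfc"])
        assert abs(np.mean(estimates) + 1.5) <= 0.2

    def test_unknown_screen_rejected(self, small_catalog):
        des = single_screen_design(1)
        counts = pd.DataFrame(1, index=["g0"], columns=des.samples)
        gc = gene_matrix(counts, des)
        with pytest.raises(KeyError):
            fit_screen(gc, pd.Series(1.0, index=des.samples), pd.Series(0.1, index=["g0"]), des, "nope")


class TestShrinkLfc:
    def test_zero_stays_zero(self):
        for prior in ("cauchy", "normal"):
            out = cf.shrink_lfc([0.0], [1.3], tau2=0.25, prior=prior)
            assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_se_returns_raw(self):
        for prior in ("cauchy", "normal"):
            out = cf.shrink_lfc([-2.4], [0.0], tau2=0.25, prior=prior)
            assert out[0] == pytest.approx(-2.4)

    def test_normal_prior_posterior_mean_halves_at_matched_variance(self):
        """raw=-2 with se^2 = tau^2 gives raw*tau^2/(tau^2+se^2) = -1."""
        out = cf.shrink_lfc([-2.0], [0.5], tau2=0.25, prior="normal")
        assert out[0] == pytest.approx(-1.0, abs=1e-12)

    def test_prior_scale_floor(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 0.1, size=500)
        se = np.full(500, 0.1)
        assert estimate_prior_scale(raw, se) == pytest.approx(0.25)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(-8, 8),
        st.floats(0, 4),
        st.sampled_from(["cauchy", "normal"]),
    )
    def test_contraction_and_sign_preservation(self, raw, se, prior):
        out = float(cf.shrink_lfc([raw], [se], tau2=0.25, prior=prior)[0])
        assert abs(out) <= abs(raw) + 1e-9
        assert out * raw >= -1e-12  # sign preserved or zero


class TestFdTable:
    def _table_for_counts(self, treat, ctrl, n_null=400, seed=0):
        des = single_screen_design(3)
        rng = np.random.default_rng(seed)
        null = rng.poisson(1000, size=(n_null, 6))
        block = np.vstack([np.array([[treat] * 3 + [ctrl] * 3]), null])
        counts = pd.DataFrame(
            block,
            index=[f"g{i}" for i in range(n_null + 1)],
            columns=list(des.treatment_samples(des.screen_ids[0]))
            + list(des.control_samples(des.screen_ids[0])),
        )
        gc = gene_matrix(counts, des)
        return cf.fd_table(gc, des)

    def test_sign_convention_depletion_is_positive(self):
        table = self._table_for_counts(treat=2_000_000, ctrl=8_000_000)
        row = table.frame.iloc[0]
        assert row["raw_lfc"] == pytest.approx(-2.0, abs=0.01)
        assert row["fd"] == pytest.approx(2.0, abs=0.02)
        assert row["call"] == "sensitive"

    def test_enrichment_is_negative_fd(self):
        table = self._table_for_counts(treat=8_000_000, ctrl=2_000_000)
        row = table.frame.iloc[0]
        assert row["fd"] == pytest.approx(-2.0, abs=0.02)
        assert row["call"] == "resistant"

    def test_threshold_is_inclusive(self):
        frame = pd.DataFrame(
            {
                "gene": ["g"],
                "screen_id": ["s"],
                "fd": [1.0],
                "raw_lfc": [-1.0],
                "se": [0.0],
                "p": [0.01],
                "fdr": [0.01],
                "call": ["sensitive"],
            }
        )
        table = cf.FitnessTable(frame=frame, fd_threshold=1.0)
        assert table.sensitive_genes("s") == ["g"]

    def test_fdr_never_below_p(self):
        table = self._table_for_counts(treat=500, ctrl=2000)
        assert (table.frame["fdr"] >= table.frame["p"] - 1e-12).all()


def test_scaling_one_sample_preserves_fd():
    """Scaling a sample's counts moves its size factor (relative to the other
    samples) by that constant and leaves FD scores unchanged, checked on a
    zero-free noise-free toy matrix where the tolerance 1e-6 is meaningful."""
    des = single_screen_design(3)
    rng = np.random.default_rng(5)
    v = rng.integers(1_000_000, 2_000_000, size=300)
    v_treat = v.copy()
    v_treat[:10] //= 4  # planted two-fold-squared depletion
    treat = des.treatment_samples(des.screen_ids[0])
    ctrl = des.control_samples(des.screen_ids[0])
    counts = pd.DataFrame(
        {treat[0]: v_treat, treat[1]: 2 * v_treat, treat[2]: 3 * v_treat,
         ctrl[0]: v, ctrl[1]: 2 * v, ctrl[2]: 2 * v},
        index=[f"g{i}" for i in range(300)],
    )
    gc = gene_matrix(counts, des)
    base = cf.fd_table(gc, des)
    scaled_counts = counts.copy()
    sample = treat[0]
    scaled_counts[sample] = scaled_counts[sample] * 7
    gc2 = gene_matrix(scaled_counts, des)
    scaled = cf.fd_table(gc2, des)
    sf1, sf2 = cf.size_factors(gc), cf.size_factors(gc2)
    assert (sf2[sample] / sf1[sample]) / (sf2[ctrl[0]] / sf1[ctrl[0]]) == pytest.approx(7.0, rel=1e-9)
    np.testing.assert_allclose(base.frame["fd"], scaled.frame["fd"], atol=1e-6)
    assert base.frame.loc[0, "fd"] == pytest.approx(2.0, abs=1e-3)


def test_low_replicate_correlation_is_flagged():
    des = single_screen_design(3)
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(
        rng.poisson(100, size=(200, 6)),
        index=[f"g{i}" for i in range(200)],
        columns=des.samples,
    )
    treat = des.treatment_samples(des.screen_ids[0])
    counts[treat[0]] = rng.permutation(counts[treat[0]].to_numpy())
    counts += 1
    gc = gene_matrix(counts, des)
    flagged = flag_screens(gc, cf.size_factors(gc), des)
    assert des.screen_ids[0] in flagged
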