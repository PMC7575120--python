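"""Generator contracts: determinism, planted structure, downsampling moments."""

import numpy as np
import pytest

from coexnet import (correlation_matrix, dispersion_stats, filter_detected,
                     fit_power_law, generate_expression,
                     generate_replicate_draws, run_mcl, build_threshold_graph)
from coexnet.matrix import ExpressionMatrix
from coexnet.pipeline import recovery_ari
from coexnet.synthetic import (ModuleSpec, SampleGroup, SyntheticSpec,
                               SyntheticSpecError, default_modules)

import pandas as pd


def counts_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            unit="counts")


class TestSpecValidation:
    def test_too_many_special_genes_rejected(self):
        spec = SyntheticSpec(n_genes=100)  # default modules need 280 genes
        with pytest.raises(SyntheticSpecError, match="exceed"):
            spec.validate()

    def test_unknown_active_group_rejected(self):
        spec = SyntheticSpec(modules=(
            ModuleSpec("m", 10, active_groups=("nowhere.nothing",)),))
        with pytest.raises(SyntheticSpecError, match="unknown group"):
            spec.validate()

    def test_signal_module_needs_active_groups(self):
        spec = SyntheticSpec(modules=(ModuleSpec("m", 10),))
        with pytest.raises(SyntheticSpecError, match="no active groups"):
            spec.validate()

    def test_bad_depth_rejected(self):
        with pytest.raises(SyntheticSpecError, match="library_depth"):
            SyntheticSpec(library_depth=0).validate()


class TestGenerateExpression:
    def test_identical_spec_and_seed_bit_identical(self):
        spec = SyntheticSpec(n_genes=400, library_depth=200_000)
        a = generate_expression(spec, seed=11)
        b = generate_expression(spec, seed=11)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
        assert (a[3].membership == b[3].membership).all()

    def test_membership_covers_every_gene_once(self, default_atlas):
        truth = default_atlas[3]
        assert len(truth.membership) == 2000
        assert truth.membership.index.is_unique
        assert truth.mean_matrix.to_numpy().min() >= 0

    def test_noiseless_module_profiles_perfectly_correlated(self):
        spec = SyntheticSpec(n_genes=300, noise_sigma=1e-12,
                             housekeeping_sigma=1e-13,
                             library_depth=100_000)
        tpm, _, _, truth = generate_expression(spec, seed=5)
        members = truth.membership[truth.membership == "module:microglia"].index
        corr = correlation_matrix(tpm.subset_genes(members), axis="genes")
        assert np.allclose(corr.values, 1.0, atol=1e-6)

    def test_tpm_columns_sum_to_1e6(self, default_atlas):
        tpm = default_atlas[0]
        assert np.allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_columns_pass_power_law_check(self, default_atlas):
        tpm = default_atlas[0]
        for j in range(tpm.n_samples):
            fit = fit_power_law(tpm.values[:, j])
            assert fit.compliant
            assert abs(fit.slope - (-1.0)) <= 0.3

    def test_housekeeping_cov_below_module_median(self, default_atlas):
        tpm, _, _, truth = default_atlas
        disp = dispersion_stats(tpm)
        hk = disp.loc[truth.membership == "housekeeping", "cov"]
        module = disp.loc[truth.membership.str.startswith("module:"), "cov"]
        assert hk.max() < module.median()

    def test_ieg_module_active_in_half_the_samples(self, default_atlas):
        truth = default_atlas[3]
        assert len(truth.module_active_groups["ieg"]) == 16  # 32 samples / 2

    def test_contaminant_confined_to_its_project(self, default_atlas):
        _, _, annotation, truth = default_atlas
        active = set(truth.module_active_groups["contaminant"])
        project_groups = {
            row["tissue"] + "." + row["cell_type_label"]
            for _, row in annotation.table.iterrows()
            if row["bioproject"] == "PRJX03"}
        assert active == project_groups

    def test_adding_a_module_preserves_earlier_memberships(self):
        base = SyntheticSpec(n_genes=600, library_depth=100_000)
        extra = SyntheticSpec(
            n_genes=600, library_depth=100_000,
            modules=tuple(default_modules()) + (
                ModuleSpec("late_addition", 10,
                           active_groups=("brain.microglia",)),))
        t_base = generate_expression(base, seed=3)[3]
        t_extra = generate_expression(extra, seed=3)[3]
        for name in ("microglia", "alveolar", "ieg"):
            label = "IEG" if name == "ieg" else f"module:{name}"
            assert set(t_base.membership[t_base.membership == label].index) \
                == set(t_extra.membership[t_extra.membership == label].index)


class TestReplicateDraws:
    def test_depth_equal_to_total_returns_library_unchanged(self):
        counts = counts_matrix([[30.0], [70.0]])
        (draw,) = generate_replicate_draws(counts, depth=100, k=1, seed=0)
        assert np.array_equal(draw.values, counts.values)

    def test_single_gene_library_gets_full_depth(self):
        counts = counts_matrix([[1000.0], [0.0]])
        (draw,) = generate_replicate_draws(counts, depth=400, k=1, seed=0)
        assert draw.values[0, 0] == 400
        assert draw.values[1, 0] == 0

    def test_depth_conserved_exactly(self, small_atlas):
        counts = small_atlas[1]
        draws = generate_replicate_draws(counts, depth=50_000, k=3, seed=9)
        for d in draws:
            assert (d.values.sum(axis=0) == 50_000).all()

    def test_insufficient_depth_names_library(self):
        counts = counts_matrix([[10.0, 1000.0]], samples=["shallow", "deep"])
        with pytest.raises(SyntheticSpecError, match="'shallow'"):
            generate_replicate_draws(counts, depth=100, k=1, seed=0)

    def test_hypergeometric_mean_within_3_se(self):
        """Sampled counts match closed-form hypergeometric moments.

        A gene holding K=5e5 of an N=1e6-read library downsampled to n=1e5
        has mean nK/N = 5e4 and variance n(K/N)(1-K/N)(N-n)/(N-1).
        """
        N, K, n, n_seeds = 1_000_000, 500_000, 100_000, 200
        counts = counts_matrix([[K], [N - K]])
        observed = [
            generate_replicate_draws(counts, depth=n, k=1, seed=s)[0].values[0, 0]
            for s in range(n_seeds)]
        expected = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        se = np.sqrt(var / n_seeds)
        assert abs(np.mean(observed) - expected) <= 3 * se


class TestRecovery:
    def _ari(self, spec, seed):
        tpm, _, _, truth = generate_expression(spec, seed=seed)
        filtered = filter_detected(tpm)
        corr = correlation_matrix(filtered, axis="genes")
        clusters = run_mcl(build_threshold_graph(corr, 0.75))
        return recovery_ari(clusters, truth)

    def test_recovery_non_increasing_in_noise(self):
        """More measurement noise never improves planted-module recovery."""
        means = []
        for sigma in (0.2, 0.4, 0.8):
            spec = SyntheticSpec(noise_sigma=sigma)
            means.append(np.mean([self._ari(spec, s) for s in (1, 2, 3)]))
        assert means[0] >= means[1] >= means[2]
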