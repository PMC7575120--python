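"""Cluster profiles, group-ratio marker screen, hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coexnet import (ExpressionMatrix, SampleAnnotation, cluster_profiles,
                     gene_set_enrichment, group_ratio_screen, read_gmt,
                     write_gmt)
from coexnet.mcl import ClusterSet, MclParams
from coexnet.profiles import ProfileError


def _mat(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def cluster_set(*groups):
    ordered = sorted((frozenset(g) for g in groups),
                     key=lambda c: (-len(c), min(c)))
    return ClusterSet(clusters=ordered, unassigned=frozenset(),
                      params=MclParams())


class TestClusterProfiles:
    def test_singleton_cluster_is_own_profile(self, rng):
        m = _mat(rng.gamma(1, 10, size=(4, 5)))
        (prof,) = cluster_profiles(cluster_set({"g2"}), m)
        assert np.allclose(prof.profile, m.data.loc["g2"])

    def test_identical_rows_give_that_row(self):
        m = _mat(np.tile([[1.0, 5.0, 9.0]], (3, 1)))
        (prof,) = cluster_profiles(cluster_set({"g0", "g1", "g2"}), m)
        assert np.allclose(prof.profile, [1.0, 5.0, 9.0])

    def test_matches_summation_oracle(self, rng):
        m = _mat(rng.gamma(1, 10, size=(12, 6)))
        members = {"g1", "g4", "g7", "g9"}
        (prof,) = cluster_profiles(cluster_set(members), m)
        oracle = sum(m.data.loc[g].to_numpy() for g in members) / 4
        assert np.allclose(prof.profile, oracle, atol=1e-12)

    def test_union_is_size_weighted_mean(self, rng):
        m = _mat(rng.gamma(1, 10, size=(10, 4)))
        a, b = {"g0", "g1", "g2"}, {"g5", "g6"}
        pa, pb = cluster_profiles(cluster_set(a, b), m)
        (pu,) = cluster_profiles(cluster_set(a | b), m)
        weighted = (3 * pa.profile + 2 * pb.profile) / 5
        assert np.allclose(pu.profile, weighted, atol=1e-12)

    def test_missing_member_errors(self, rng):
        m = _mat(rng.gamma(1, 10, size=(3, 3)))
        with pytest.raises(ProfileError, match="'ghost'"):
            cluster_profiles(cluster_set({"g0", "ghost"}), m)


def annotation_for(samples, classes):
    return SampleAnnotation(pd.DataFrame({
        "sample_id": samples,
        "tissue": ["t"] * len(samples),
        "cell_type_class": classes,
        "cell_type_label": classes,
        "bioproject": ["P1"] * len(samples),
    }))


class TestGroupRatioScreen:
    def _fixture(self, rng):
        m = _mat(rng.gamma(2, 30, size=(6, 6)))
        ann = annotation_for(m.sample_ids,
                             ["mononuclear"] * 3 + ["DC"] * 3)
        return m, ann

    def test_equal_group_means_give_unit_ratio(self):
        m = _mat(np.tile([[4.0]], (1, 6)))
        ann = annotation_for(m.sample_ids, ["mononuclear"] * 3 + ["DC"] * 3)
        out = group_ratio_screen(m, ann)
        assert out["ratio"].iloc[0] == 1.0

    def test_reciprocal_identity_exact(self, rng):
        m, ann = self._fixture(rng)
        ab = group_ratio_screen(m, ann, "mononuclear", "DC")
        ba = group_ratio_screen(m, ann, "DC", "mononuclear")
        prod = ab["ratio"].sort_index() * ba["ratio"].sort_index()
        assert np.allclose(prod, 1.0, rtol=1e-15, atol=0)

    def test_matches_two_pass_mean_oracle(self, rng):
        m, ann = self._fixture(rng)
        out = group_ratio_screen(m, ann, epsilon=1.0).sort_index()
        mean_a = m.values[:, :3].mean(axis=1)
        mean_b = m.values[:, 3:].mean(axis=1)
        oracle = (mean_a + 1.0) / (mean_b + 1.0)
        assert np.allclose(out["ratio"], oracle, atol=1e-12)

    def test_reference_gene_mode(self, rng):
        m, ann = self._fixture(rng)
        out = group_ratio_screen(m, ann, reference_gene="g0")
        ref_ratio = out.loc["g0", "ratio"]
        assert out.loc["g0", "ge_reference"]
        assert (out.loc[out["ge_reference"], "ratio"] >= ref_ratio).all()

    def test_macrophage_marker_enriched_in_macrophages(self, default_atlas):
        """A module gene active only in mononuclear groups has ratio > 1."""
        tpm, _, annotation, truth = default_atlas
        marker = truth.membership[
            truth.membership == "module:monocyte"].index[0]
        out = group_ratio_screen(tpm, annotation, "mononuclear", "DC")
        assert out.loc[marker, "ratio"] > 1.0

    def test_empty_group_errors(self, rng):
        m, _ = self._fixture(rng)
        ann = annotation_for(m.sample_ids, ["mononuclear"] * 6)
        with pytest.raises(ProfileError, match="empty group"):
            group_ratio_screen(m, ann)


def enrichment_p_by_enumeration(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of all n-subsets."""
    universe = range(N)
    hits = set(range(K))
    total = eligible = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(hits.intersection(combo)) >= k:
            eligible += 1
    return eligible / total


class TestEnrichment:
    def _cs(self, *groups):
        return cluster_set(*groups)

    def test_set_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        cs = self._cs(set(universe[:5]))
        out = gene_set_enrichment(cs, {"all": set(universe)}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)
        assert out["overlap"].iloc[0] == 5

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        cs = self._cs(set(universe[:3]))
        out = gene_set_enrichment(cs, {"disjoint": set(universe[5:])},
                                  universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_example(self):
        # universe 10, set 4, cluster 5, overlap 4 -> C(4,4)C(6,1)/C(10,5)
        universe = [f"g{i}" for i in range(10)]
        cs = self._cs(set(universe[:4]) | {universe[9]})
        out = gene_set_enrichment(cs, {"s": set(universe[:4])}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(6 / 252)

    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(11)]
        gene_set = set(universe[:5])
        for cluster_genes in (set(universe[2:7]), set(universe[:3]),
                              set(universe[4:10])):
            cs = self._cs(cluster_genes)
            out = gene_set_enrichment(cs, {"s": gene_set}, universe)
            k = len(cluster_genes & gene_set)
            oracle = enrichment_p_by_enumeration(11, 5, len(cluster_genes), k)
            assert out["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_q_values_bh_and_bounds(self, rng):
        universe = [f"g{i}" for i in range(30)]
        cs = self._cs(set(universe[:6]), set(universe[6:12]))
        sets = {"a": set(universe[:8]), "b": set(universe[10:20])}
        out = gene_set_enrichment(cs, sets, universe)
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        assert (out["overlap"] <=
                np.minimum(out["cluster_size"], out["set_size"])).all()

    def test_super_uniform_under_random_assignment(self):
        """Empirical type-I error at alpha=0.05 stays at or below ~0.05."""
        rng = np.random.default_rng(77)
        universe = [f"g{i}" for i in range(60)]
        gene_set = set(universe[:15])
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            members = set(rng.choice(universe, size=12, replace=False))
            cs = self._cs(members)
            p = gene_set_enrichment(cs, {"s": gene_set},
                                    universe)["p_value"].iloc[0]
            rejections += p <= 0.05
        assert rejections / n_perm <= 0.06

    def test_empty_universe_errors(self):
        with pytest.raises(ProfileError, match="universe"):
            gene_set_enrichment(self._cs({"a"}), {"s": {"a"}}, [])


class TestGmtIo:
    def test_round_trip(self, tmp_path):
        sets = {"one": {"a", "b"}, "two": {"c", "d", "e"}}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path, description="desc")
        assert read_gmt(path) == sets

    def test_short_line_errors_with_location(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ProfileError, match=":1"):
            read_gmt(path)
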