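"""Weighted counts, reference comparison, RNA-protein co-sedimentation,
and the shuffled-assignment permutation null."""

import numpy as np
import pandas as pd
import pytest

import gradprof as gp
from gradprof.exceptions import ValidationError
from gradprof.gradient_stats import observed_vs_null_test


def _matrix(values, fractions=None, ids=None, kind="rna"):
    values = np.asarray(values, dtype=float)
    fractions = fractions if fractions is not None else np.arange(3, 3 + values.shape[1])
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    return gp.FractionProfileMatrix(entity_ids=ids, fraction_indices=np.asarray(fractions),
                                    values=values, entity_kind=kind)


def _norm(values, **kw):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    m = _matrix(values, **kw)
    return gp.NormalizedProfileMatrix(entity_ids=m.entity_ids,
                                      fraction_indices=m.fraction_indices,
                                      values=m.values, entity_kind=m.entity_kind)


class TestWeightedCounts:
    def test_single_occupied_fraction(self):
        vals = np.zeros((1, 22))
        vals[0, 2] = 10.0   # fraction 5
        m = _matrix(vals, fractions=np.arange(3, 25))
        wc = gp.weighted_counts(m, gp.WeightedCountConfig(3, 24))
        assert wc.iloc[0] == pytest.approx(50.0)

    def test_all_zero_entity(self):
        m = _matrix(np.zeros((1, 22)), fractions=np.arange(3, 25))
        wc = gp.weighted_counts(m, gp.WeightedCountConfig(3, 24))
        assert wc.iloc[0] == 0.0

    def test_uniform_profile_equals_brute_force_sum(self):
        m = _matrix(np.ones((1, 22)), fractions=np.arange(3, 25))
        wc = gp.weighted_counts(m, gp.WeightedCountConfig(3, 24))
        brute = sum(i * 1.0 for i in range(3, 25))
        assert brute == 297
        assert wc.iloc[0] == pytest.approx(brute)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5, size=(4, 22))
        b = rng.uniform(0, 5, size=(4, 22))
        cfg = gp.WeightedCountConfig(3, 24)
        f = np.arange(3, 25)
        wa = gp.weighted_counts(_matrix(a, f), cfg)
        wb = gp.weighted_counts(_matrix(b, f), cfg)
        wab = gp.weighted_counts(_matrix(a + b, f), cfg)
        assert np.allclose(wab, wa + wb, atol=1e-9)

    def test_single_fraction_reduction(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 5, size=(5, 22))
        m = _matrix(vals, np.arange(3, 25))
        wc = gp.weighted_counts(m, gp.WeightedCountConfig(7, 7))
        assert np.allclose(wc, 7 * vals[:, 4])

    def test_missing_range_error_lists_fractions(self):
        m = _matrix(np.ones((1, 5)), fractions=np.arange(3, 8))
        with pytest.raises(ValidationError, match="8"):
            gp.weighted_counts(m, gp.WeightedCountConfig(3, 9))


class TestCompareToReference:
    def test_identical_vectors_r_one_zero_residuals(self):
        v = pd.Series([1.0, 5, 9, 20, 3, 7, 100, 2, 8, 4, 6, 11],
                      index=[f"g{i}" for i in range(12)])
        out = gp.compare_weighted_to_reference(v, v, log_transform=True)
        assert out["r"] == pytest.approx(1.0)
        assert np.allclose(out["residuals"], 0.0, atol=1e-9)

    def test_too_few_shared_genes(self):
        v = pd.Series([1.0, 2], index=["a", "b"])
        with pytest.raises(ValidationError):
            gp.compare_weighted_to_reference(v, v)

    def test_ribosome_driven_gradient_correlates(self):
        """When sedimentation tracks a single underlying scale (ribosome
        load), weighted counts correlate tightly with that scale."""
        rng = np.random.default_rng(7)
        n = 300
        load = 10 ** rng.uniform(0, 2.5, n)       # per-gene ribosome load
        fractions = np.arange(3, 25)
        # denser sedimentation with higher load: peak position scales with load
        centers = 4 + 18 * (np.log10(load) / 2.5)
        vals = np.exp(-0.5 * ((fractions[None, :] - centers[:, None]) / 2.5) ** 2)
        vals = vals / vals.sum(axis=1, keepdims=True) * load[:, None]
        vals *= np.exp(rng.normal(0, 0.2, size=vals.shape))
        m = _matrix(vals, fractions, ids=[f"g{i}" for i in range(n)])
        wc = gp.weighted_counts(m, gp.WeightedCountConfig(3, 24))
        ref = pd.Series(load, index=wc.index)
        out = gp.compare_weighted_to_reference(wc, ref)
        assert out["r"] >= 0.95

    def test_light_shifted_subset_has_negative_residuals(self):
        """A gene subset sedimenting lighter than its expression predicts
        sits below the diagonal (negative orthogonal residuals)."""
        rng = np.random.default_rng(8)
        n = 200
        load = 10 ** rng.uniform(0.5, 2.5, n)
        wc = load * rng.lognormal(0, 0.1, n)
        light = np.zeros(n, dtype=bool)
        light[:40] = True
        wc[light] *= 0.25   # membrane-bound subset floats light
        w = pd.Series(wc, index=[f"g{i}" for i in range(n)])
        ref = pd.Series(load, index=w.index)
        out = gp.compare_weighted_to_reference(w, ref)
        resid = out["residuals"]
        light_ids = [f"g{i}" for i in range(40)]
        other_ids = [f"g{i}" for i in range(40, n)]
        assert np.median(resid[light_ids]) < 0
        from gradprof.stats import wilcoxon_rank_sum
        _, p = wilcoxon_rank_sum(resid[light_ids], resid[other_ids], "less")
        assert p < 0.01


class TestRnaProteinCorrelations:
    def test_identical_profiles_r_one(self):
        rna = _norm([[1, 2, 3, 4], [4, 1, 1, 4]], ids=["a", "b"])
        prot = _norm([[1, 2, 3, 4], [4, 1, 1, 4]], ids=["a", "b"], kind="protein")
        pairs = gp.rna_protein_correlations(rna, prot)
        assert all(c.r == pytest.approx(1.0) for c in pairs)

    def test_reversed_monotone_profile_r_minus_one(self):
        rna = _norm([[1, 2, 3, 4]], ids=["a"])
        prot = _norm([[4, 3, 2, 1]], ids=["a"], kind="protein")
        (pair,) = gp.rna_protein_correlations(rna, prot)
        assert pair.r == pytest.approx(-1.0)

    def test_uses_fraction_intersection(self):
        rna = _norm(np.random.default_rng(0).uniform(1, 5, (3, 8)),
                    fractions=np.arange(3, 11))
        prot = _norm(np.random.default_rng(1).uniform(1, 5, (3, 5)),
                     fractions=np.arange(3, 8), kind="protein")
        pairs = gp.rna_protein_correlations(rna, prot)
        assert all(c.n_fractions_used == 5 for c in pairs)

    def test_simulated_coupling_gives_negative_median(self, rna_norm, prot_norm):
        pairs = gp.rna_protein_correlations(rna_norm, prot_norm)
        rs = np.array([c.r for c in pairs])
        assert np.median(rs) < 0


class TestPercentileAnnotationRate:
    def _pairs(self, rs):
        return [gp.GenePairCorrelation(gene_id=f"g{i:03d}", r=r, n_fractions_used=10)
                for i, r in enumerate(rs)]

    def test_all_annotated(self):
        pairs = self._pairs(np.linspace(-1, 1, 20))
        ann = {c.gene_id: True for c in pairs}
        out = gp.percentile_annotation_rate(pairs, ann)
        assert out["top_rate"] == 1.0 and out["bottom_rate"] == 1.0

    def test_top_half_annotated(self):
        rs = np.linspace(-0.9, 0.9, 20)
        pairs = self._pairs(rs)
        ranked = sorted(pairs, key=lambda c: -c.r)
        ann = {c.gene_id: i < 10 for i, c in enumerate(ranked)}
        out = gp.percentile_annotation_rate(pairs, ann, pct=20)
        assert out["top_rate"] == 1.0 and out["bottom_rate"] == 0.0

    def test_coupled_secreted_genes_enriched_on_top(self, dataset, rna_norm, prot_norm):
        pairs = gp.rna_protein_correlations(rna_norm, prot_norm)
        signal = {g: a["has_signal"] for g, a in dataset.annotations.items()}
        out = gp.percentile_annotation_rate(pairs, signal, pct=20)
        assert out["top_rate"] >= 2 * max(out["bottom_rate"], 0.01)


class TestClusterMedianPairwise:
    def test_identical_profiles(self):
        m = _norm([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert gp.cluster_median_pairwise(m, ["g0", "g1", "g2"]) == pytest.approx(1.0)

    def test_reversal_triplet_median_minus_one(self):
        # pairwise correlations {1, -1, -1} -> median -1
        m = _norm([[1, 2, 3, 4], [4, 3, 2, 1], [1, 2, 3, 4]])
        assert gp.cluster_median_pairwise(m, ["g0", "g1", "g2"]) == pytest.approx(-1.0)

    def test_tight_synthetic_cluster(self):
        ds = gp.simulate(gp.SimulationConfig(seed=5, noise_sigma=0.05))
        norm = gp.normalize_profiles(ds.rna, 1.0)
        members = [g for g, c in ds.truth.gene_compartment.items()
                   if c == "proteasome"][:50]
        assert gp.cluster_median_pairwise(norm, members) >= 0.95

    def test_fewer_than_two_members(self, rna_norm):
        with pytest.raises(ValidationError):
            gp.cluster_median_pairwise(rna_norm, [rna_norm.entity_ids[0]])


class TestShuffledAssignmentNull:
    def _random_setup(self, seed, n_prot=50, n_frac=17):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.5, 2.0, size=(n_prot, n_frac))
        prot = _norm(vals, fractions=np.arange(3, 3 + n_frac),
                     ids=[f"g{i}" for i in range(n_prot)], kind="protein")
        assignments = {f"g{i}": (i % 10) + 1 for i in range(n_prot)}
        return gp.ClusterAssignment(assignments=assignments), prot

    def test_independent_profiles_center_near_zero(self):
        clusters, prot = self._random_setup(0)
        out = gp.shuffled_assignment_null(clusters, prot, n_perm=100, seed=11)
        assert abs(float(np.mean(out["null"]))) < 0.05

    def test_identity_permutation_reproduces_observed(self):
        clusters, prot = self._random_setup(1)
        out = gp.shuffled_assignment_null(
            clusters, prot, n_perm=1, seed=0, _permutation_hook=lambda ids: list(ids))
        observed = sorted(out["observed"].values())
        assert np.allclose(sorted(out["null"]), observed, atol=1e-12)

    def test_exchangeability_across_seeds(self):
        clusters, prot = self._random_setup(2)
        a = gp.shuffled_assignment_null(clusters, prot, n_perm=60, seed=1)["null"]
        b = gp.shuffled_assignment_null(clusters, prot, n_perm=60, seed=2)["null"]
        se = np.sqrt(np.var(a) / a.size + np.var(b) / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_coupled_clusters_beat_null(self, clusters_filtered, prot_norm):
        out = gp.shuffled_assignment_null(clusters_filtered, prot_norm,
                                          n_perm=100, seed=1)
        t = observed_vs_null_test(out)
        assert t["p"] < 0.01
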