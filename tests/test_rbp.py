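"""RBP-target correlation, hexamer counting/enrichment/conservation, and
CLIP density stratification."""

import numpy as np
import pytest

import gradprof as gp
from gradprof.exceptions import EmptyResultError, UndefinedCorrelationError, ValidationError
from gradprof.rbp import N_HEXAMERS, hexamer_index, index_to_hexamer
from oracles import count_kmer_occurrences


def _norm(values, fractions=None, ids=None, kind="rna"):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    fractions = fractions if fractions is not None else np.arange(3, 3 + values.shape[1])
    return gp.NormalizedProfileMatrix(
        entity_ids=ids or [f"g{i}" for i in range(values.shape[0])],
        fraction_indices=np.asarray(fractions), values=values, entity_kind=kind)


class TestCorrelateRbpToRnas:
    def test_identical_profile_in_set(self):
        rna = _norm([[1, 2, 5, 2], [5, 2, 1, 1]], ids=["t", "o"])
        res = gp.correlate_rbp_to_rnas("r1", (np.arange(3, 7), [1, 2, 5, 2]), rna)
        assert res.correlations["t"] == pytest.approx(1.0)
        assert "t" in res.correlated_set

    def test_threshold_one_empty_set(self):
        rng = np.random.default_rng(0)
        rna = _norm(rng.uniform(1, 5, (5, 6)))
        res = gp.correlate_rbp_to_rnas("r1", (np.arange(3, 9), rng.uniform(1, 5, 6)),
                                       rna, threshold=1.0)
        assert res.correlated_set == set()

    def test_constant_rbp_profile_raises(self):
        rna = _norm([[1, 2, 3, 4]])
        with pytest.raises(UndefinedCorrelationError):
            gp.correlate_rbp_to_rnas("r1", (np.arange(3, 7), [2, 2, 2, 2]), rna)

    def test_threshold_monotonicity(self, dataset, rna_norm):
        rbps = dataset.rbp_peptides
        prof = (rbps.fraction_indices, rbps.row("rbp_er"))
        sizes = []
        for thr in (0.5, 0.7, 0.85, 0.95):
            res = gp.correlate_rbp_to_rnas("rbp_er", prof, rna_norm, threshold=thr)
            sizes.append(len(res.correlated_set))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_rbp_sensitivity_specificity(self, dataset, rna_norm):
        rbps = dataset.rbp_peptides
        res = gp.correlate_rbp_to_rnas(
            "rbp_er", (rbps.fraction_indices, rbps.row("rbp_er")), rna_norm)
        metrics = gp.truth_metrics(dataset.truth,
                                   {"rbp_correlated": {"rbp_er": res.correlated_set}})
        assert metrics["rbp_recall"]["rbp_er"] >= 0.8
        assert metrics["rbp_fpr"]["rbp_er"] <= 0.05


class TestCorrelateRbpsToClusters:
    def _profiles(self):
        shapes = np.array([[5, 3, 1, 0.5], [0.5, 1, 3, 5.0]])
        shapes = shapes / shapes.sum(axis=1, keepdims=True)
        return [gp.ClusterProfile(cluster_id=i + 1, mean_profile=s, member_count=10)
                for i, s in enumerate(shapes)]

    def test_exact_cluster_mean_is_best_match(self):
        profiles = self._profiles()
        rbp_m = gp.FractionProfileMatrix(
            entity_ids=["r1"], fraction_indices=np.arange(3, 7),
            values=profiles[0].mean_profile[None, :] * 100, entity_kind="protein")
        df = gp.correlate_rbps_to_clusters(rbp_m, profiles, np.arange(3, 7))
        best = df[df.best]
        assert list(best.cluster) == [1]
        assert best.r.iloc[0] == pytest.approx(1.0)

    def test_no_match_above_threshold(self):
        profiles = self._profiles()
        rbp_m = gp.FractionProfileMatrix(
            entity_ids=["r1"], fraction_indices=np.arange(3, 7),
            values=np.array([[1.0, 5.0, 1.0, 5.0]]), entity_kind="protein")
        df = gp.correlate_rbps_to_clusters(rbp_m, profiles, np.arange(3, 7),
                                           threshold=0.99)
        assert df.empty

    def test_simulated_rbps_map_to_their_compartments(
            self, dataset, rna_norm, clusters_filtered):
        profiles = gp.cluster_mean_profiles(clusters_filtered, rna_norm)
        df = gp.correlate_rbps_to_clusters(dataset.rbp_peptides, profiles,
                                           rna_norm.fraction_indices)
        comp_of = dataset.truth.gene_compartment
        majority = {}
        for cp in profiles:
            members = clusters_filtered.members(cp.cluster_id)
            comps = [comp_of[g] for g in members if comp_of[g] != "noise"]
            majority[cp.cluster_id] = max(set(comps), key=comps.count)
        hits = 0
        for rbp_id, target in dataset.truth.rbp_compartment.items():
            best = df[(df.rbp == rbp_id) & df.best]
            if len(best) == 1 and majority[int(best.cluster.iloc[0])] == target:
                hits += 1
        assert hits >= 4   # of the 5 planted RBPs


class TestHexamerCounting:
    def test_overlapping_occurrences_counted(self):
        counts = gp.hexamer_counts(["AAAAAAA"])
        assert counts[hexamer_index("AAAAAA")] == 2
        assert counts.sum() == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_total_equals_length_minus_five(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 400)))
        counts = gp.hexamer_counts([seq])
        assert counts.sum() == len(seq) - 5

    def test_windows_with_n_skipped(self):
        counts = gp.hexamer_counts(["AAANAAAAA"])
        # positions 0-3 contain the N; only windows 4..8 x ... wait: windows
        # starting at 4,5,6 are N-free runs of A; scan oracle agrees
        seq = "AAANAAAAA"
        expected = sum(count_kmer_occurrences(seq, index_to_hexamer(i))
                       for i in range(N_HEXAMERS) if "N" not in index_to_hexamer(i))
        assert counts.sum() == expected == 0  # longest N-free run is 5 < 6

    def test_matches_position_scan_oracle(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        counts = gp.hexamer_counts([seq])
        for hexamer in ("ACGTAC", "TGCATG", "AAAAAA", "GGGCCC"):
            assert counts[hexamer_index(hexamer)] == count_kmer_occurrences(seq, hexamer)


class TestHexamerEnrichment:
    def test_identical_composition_flat_ratios(self):
        seqs = ["ACGTACGTACGTACGTACGT" * 5] * 3
        stats = gp.hexamer_enrichment(seqs, seqs)
        ratios = np.array([s.log2_ratio for s in stats])
        assert np.allclose(ratios, 0.0, atol=1e-9)

    def test_empty_foreground_raises(self):
        with pytest.raises(EmptyResultError):
            gp.hexamer_enrichment([], ["ACGTACGTAC"])

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(2)
        fg = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
        bg = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
        fwd = {s.hexamer: s.log2_ratio for s in gp.hexamer_enrichment(fg, bg)}
        rev = {s.hexamer: s.log2_ratio for s in gp.hexamer_enrichment(bg, fg)}
        for h in list(fwd)[:500]:
            assert fwd[h] == pytest.approx(-rev[h], abs=1e-9)

    def test_planted_motif_ranks_top_ten(self, dataset, rna_norm):
        rbps = dataset.rbp_peptides
        res = gp.correlate_rbp_to_rnas(
            "rbp_er", (rbps.fraction_indices, rbps.row("rbp_er")), rna_norm)
        fg = [dataset.utrs[g] for g in sorted(res.correlated_set)]
        bg = [dataset.utrs[g] for g in sorted(set(dataset.utrs) - res.correlated_set)]
        stats = gp.hexamer_enrichment(fg, bg)
        ranking = [s.hexamer for s in stats]
        metrics = gp.truth_metrics(dataset.truth, {"hexamer_ranking": ranking})
        assert metrics["motif_rank"]["rbp_er"] <= 10


class TestHexamerConservation:
    def test_all_true_masks(self):
        seqs = ["ACGTACGTAC"]
        rates = gp.hexamer_conservation_rate(seqs, [np.ones(10, bool)])
        assert all(v == 1.0 for v in rates.values())

    def test_all_false_masks(self):
        seqs = ["ACGTACGTAC"]
        rates = gp.hexamer_conservation_rate(seqs, [np.zeros(10, bool)])
        assert all(v == 0.0 for v in rates.values())

    def test_random_mask_rate_near_p_to_the_sixth(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 200000))
        mask = rng.random(len(seq)) < 0.5
        rates = gp.hexamer_conservation_rate([seq], [mask])
        # common hexamers occur ~49 times each; pool across all of them
        counts = gp.hexamer_counts([seq])
        pooled = np.average([rates[index_to_hexamer(i)] for i in range(N_HEXAMERS)
                             if counts[i] > 0],
                            weights=counts[counts > 0])
        # E[rate] != 0.5^6 exactly only through overlap correlation; wide band
        assert pooled == pytest.approx(0.5 ** 6, abs=0.002)

    def test_length_mismatch_names_record(self):
        with pytest.raises(ValidationError, match="record 0"):
            gp.hexamer_conservation_rate(["ACGTAC"], [np.ones(5, bool)])


class TestClipDensity:
    def test_identical_densities_p_one(self):
        genes = [f"g{i}" for i in range(12)]
        clip = {g: 4 for g in genes}
        expr = {g: 2.0 for g in genes}
        corrs = {g: (-0.5 if i < 6 else 0.5) for i, g in enumerate(genes)}
        out = gp.clip_density_by_bin(clip, expr, corrs, bin_edges=(-1, 0, 1))
        assert all(t["p_raw"] == pytest.approx(1.0) for t in out["tests"])

    def test_complete_separation_exact_p(self):
        """Six high-bin genes all denser than six low-bin genes: exact
        two-sided rank-sum p = 2/C(12,6)."""
        genes = [f"g{i}" for i in range(12)]
        clip = {g: (i + 1 if i < 6 else 100 + i) for i, g in enumerate(genes)}
        expr = {g: 1.0 for g in genes}
        corrs = {g: (-0.5 if i < 6 else 0.5) for i, g in enumerate(genes)}
        out = gp.clip_density_by_bin(clip, expr, corrs, bin_edges=(-1, 0, 1))
        (test,) = out["tests"]
        assert test["p_raw"] == pytest.approx(2 / 924, abs=1e-12)

    def test_simulated_density_increases_across_bins(self, dataset, rna_norm):
        rbps = dataset.rbp_peptides
        res = gp.correlate_rbp_to_rnas(
            "rbp_er", (rbps.fraction_indices, rbps.row("rbp_er")), rna_norm)
        expr = {g: float(dataset.rna.row(g).mean()) for g in dataset.rna.entity_ids}
        out = gp.clip_density_by_bin(dataset.clip_counts, expr,
                                     dict(res.correlations))
        bins = sorted(out["medians"])
        medians = [out["medians"][b] for b in bins]
        assert all(a < b for a, b in zip(medians, medians[1:]))
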