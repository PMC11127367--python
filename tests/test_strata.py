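"""Stratified statistics, calibration of the test procedures, insertion test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import scnoise as sc
from scnoise.strata import fisher_pseudobulk_test


def oracle_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration: sum the
    probabilities of all tables (fixed margins) no more likely than the
    observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestStratifiedStats:
    def _pool(self, n_cells=400, seed=3):
        cfg = sc.SimulationConfig(
            n_clones=1, integrations_per_clone=(6, 0), cells_per_clone=n_cells,
            mu_loc=(float(np.log(40.0)), 0.3), dropout_rate=0.1,
            barcode_error_rate=0.0, seed=seed,
        )
        truth = sc.build_truth(cfg)
        counts = sc.simulate_counts(truth, cfg)
        return sc.normalize_counts(counts.loc[(counts > 0).sum(axis=1) >= 2])

    def test_min_cells_rule_excludes_sparse_locations(self):
        norm = self._pool()
        labels = pd.Series(
            np.where(np.arange(len(norm)) % 2 == 0, "G1", "S"), index=norm.index
        )
        # add a location expressed in only 14 G1 cells
        sparse = pd.Series(0.0, index=norm.index)
        sparse.iloc[:14] = 1.0
        norm = norm.assign(SPARSE=sparse)
        stats, fits = sc.stratified_location_stats(norm, labels, min_cells=15)
        assert "SPARSE" not in set(stats["loc_barcode"])
        assert fits["n_locations_dropped"] >= 1

    def test_boundary_location_retained(self):
        norm = self._pool()
        labels = pd.Series("A", index=norm.index)
        labels.iloc[: len(labels) // 2] = "B"
        extra = pd.Series(0.0, index=norm.index)
        # exactly 30 expressing cells in each stratum
        extra[labels.index[labels == "A"][:30]] = 1.0
        extra[labels.index[labels == "B"][:30]] = 1.0
        norm = norm.assign(EDGE=extra)
        stats, _ = sc.stratified_location_stats(norm, labels, min_cells=30)
        assert "EDGE" in set(stats["loc_barcode"])

    def test_uniform_labels_reduce_to_unstratified(self):
        norm = self._pool()
        labels = pd.Series("all", index=norm.index)
        stats, _ = sc.stratified_location_stats(norm, labels, min_cells=5)
        plain = sc.location_statistics(norm)
        plain, _ = sc.mean_independent_noise(plain)
        merged = stats.merge(plain, on="loc_barcode", suffixes=("_s", "_p"))
        assert np.allclose(merged["mean_s"], merged["mean_p"])
        assert np.allclose(merged["min_s"], merged["min_p"])

    def test_permuted_labels_give_equal_stratum_means(self):
        norm = self._pool(n_cells=2000)
        rng = np.random.default_rng(0)
        labels = pd.Series(
            rng.permutation(np.repeat(["x", "y"], len(norm) // 2)), index=norm.index
        )
        stats, _ = sc.stratified_location_stats(norm, labels, min_cells=15)
        wide = stats.pivot(index="loc_barcode", columns="stratum", values="mean")
        # same underlying distribution: stratum means agree within ~5 SE
        rel = (wide["x"] - wide["y"]).abs() / wide.mean(axis=1)
        assert rel.median() < 0.1


class TestSubstateProportions:
    def test_identical_compositions_not_significant(self):
        labels = pd.DataFrame(
            {
                "substate": np.repeat(["stem-like", "differentiated"], 90),
                "phase": list(np.repeat(["G1", "S", "G2M"], 30)) * 2,
            }
        )
        res = sc.substate_proportion_test(labels)
        assert (res["pvalue"] > 0.5).all()

    def test_fully_separated_phases_extreme_p(self):
        labels = pd.DataFrame(
            {
                "substate": np.repeat(["A", "B"], 100),
                "phase": ["S"] * 100 + ["G1"] * 100,
            }
        )
        res = sc.substate_proportion_test(labels).set_index("phase")
        assert res.loc["S", "pvalue"] < 1e-15

    def test_fractions_sum_to_one_per_substate(self):
        rng = np.random.default_rng(1)
        labels = pd.DataFrame(
            {
                "substate": rng.choice(["A", "B"], 300),
                "phase": rng.choice(["G1", "S", "G2M"], 300),
            }
        )
        res = sc.substate_proportion_test(labels)
        assert res["frac_A"].sum() == pytest.approx(1.0)
        assert res["frac_B"].sum() == pytest.approx(1.0)

    def test_empty_substate_rejected(self):
        labels = pd.DataFrame({"substate": ["A"] * 5, "phase": ["G1"] * 5})
        with pytest.raises(ValueError):
            sc.substate_proportion_test(labels)


class TestPermutationTest:
    def test_disjoint_ranges_minimal_p(self):
        vals = np.concatenate([np.zeros(10), np.ones(10) + 5])
        groups = np.repeat(["lo", "hi"], 10)
        _, p = sc.label_permutation_test(vals, groups, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b"], 15)
        r1 = sc.label_permutation_test(vals, groups, n_perm=199, seed=5)
        r2 = sc.label_permutation_test(vals, groups, n_perm=199, seed=5)
        assert r1 == r2

    def test_constant_values_warn_p_one(self):
        with pytest.warns(UserWarning):
            _, p = sc.label_permutation_test(
                np.ones(20), np.repeat(["a", "b"], 10), n_perm=100
            )
        assert p == 1.0

    def test_null_type_one_error_controlled(self):
        rejections = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(10_000 + seed)
            vals = rng.normal(size=30)
            _, p = sc.label_permutation_test(
                vals, np.repeat(["a", "b"], 15), n_perm=199, seed=seed
            )
            rejections += p <= 0.05
        assert rejections / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestClassifier:
    def test_oracle_feature_classifies_perfectly(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=100), index=[f"L{i}" for i in range(100)])
        feats = pd.DataFrame(
            {"oracle": scores, "junk": rng.normal(size=100)}, index=scores.index
        )
        res = sc.classify_extreme_locations(feats, scores)
        assert res["loocv_accuracy"] >= 0.95
        assert res["perfect_separation"]  # flagged, not an error

    def test_duplicated_feature_same_predictions(self):
        rng = np.random.default_rng(6)
        idx = [f"L{i}" for i in range(100)]
        scores = pd.Series(rng.normal(size=100), index=idx)
        base = pd.DataFrame(rng.normal(size=(100, 3)), index=idx, columns=list("abc"))
        base["a2"] = base["a"]
        r1 = sc.classify_extreme_locations(base[["a", "b", "c"]], scores)
        r2 = sc.classify_extreme_locations(base, scores)
        assert r1["loocv_accuracy"] == pytest.approx(r2["loocv_accuracy"], abs=0.06)

    def test_too_few_locations_rejected(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=20), index=[f"L{i}" for i in range(20)])
        feats = pd.DataFrame({"f": rng.normal(size=20)}, index=scores.index)
        with pytest.raises(ValueError):
            sc.classify_extreme_locations(feats, scores, quantile=0.2)


class TestInsertionEffect:
    def _spiked(self, fold, seed=3):
        cfg = sc.SimulationConfig(n_clones=4, cells_per_clone=500, seed=seed)
        truth = sc.build_truth(cfg)
        genes, _ = sc.emit_gene_counts(
            truth, cfg, insertion_spec=("clone001", "gene0010", fold), n_genes=100
        )
        return genes, truth.cell_clones

    def test_fisher_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            _, p = fisher_pseudobulk_test(a, b, c, d)
            assert p == pytest.approx(oracle_fisher_two_sided(a, c, b, d), rel=1e-6)

    def test_identical_pseudobulks_null(self):
        fc, p = fisher_pseudobulk_test(50, 950, 50, 950)
        assert fc == 0.0 and p == 1.0

    def test_four_fold_spike_flagged(self):
        genes, clones = self._spiked(4.0)
        res = sc.insertion_effect_test(genes, clones, "clone001", "gene0010", seed=0)
        assert res["significant"]
        assert res["pvalue"] < 0.05 and abs(res["log2fc"]) > 0.5

    def test_shuffled_labels_on_null_data_flag_nothing(self):
        genes, clones = self._spiked(1.0)
        ins = [("clone001", g) for g in genes.index]
        scr = sc.insertion_effect_screen(
            genes, clones, ins, shuffle_gene_labels=True, n_resample=5, seed=1
        )
        assert int(scr["significant"].sum()) == 0

    def test_unknown_gene_rejected(self):
        genes, clones = self._spiked(1.0)
        with pytest.raises(KeyError):
            sc.insertion_effect_test(genes, clones, "clone001", "nope")
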