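"""F-ratio screen vs ANOVA oracle, Ward clustering, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import evquant as ev
from evquant.multivariate import retained_proteins


def design_for(labels):
    """A minimal design whose runs carry the given group labels as bpa-free
    grouping column (exposed via an explicit label list)."""
    rows = []
    for i, _ in enumerate(labels):
        rows.append((f"r{i}", "minus", 0.0, 0.0, 6.0, 1, i + 1))
    return ev.ConditionDesign(
        pd.DataFrame(
            rows,
            columns=["run_id", "bpa", "dose_gy", "irradiation_min", "harvest_h", "biorep", "techrep"],
        )
    )


class TestFScreen:
    def test_flat_protein_no_signal(self):
        labels = ["a", "a", "b", "b"]
        matrix = ev.CountMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["P"], columns=[f"r{i}" for i in range(4)]),
            "run",
        )
        res = ev.f_screen(matrix, design_for(labels), labels)[0]
        assert res.f_ratio == 0.0 and res.p_value == 1.0 and not res.retained

    def test_two_group_hand_example(self):
        labels = ["a"] * 3 + ["b"] * 3
        matrix = ev.CountMatrix(
            pd.DataFrame(
                [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                index=["P"],
                columns=[f"r{i}" for i in range(6)],
            ),
            "run",
        )
        res = ev.f_screen(matrix, design_for(labels), labels)[0]
        assert res.f_ratio == pytest.approx(13.5)
        f, p = st.f_oneway([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_perfect_separation_retained(self):
        labels = ["a", "a", "b", "b"]
        matrix = ev.CountMatrix(
            pd.DataFrame([[1.0, 1.0, 2.0, 2.0]], index=["P"], columns=[f"r{i}" for i in range(4)]),
            "run",
        )
        res = ev.f_screen(matrix, design_for(labels), labels)[0]
        assert np.isinf(res.f_ratio) and res.p_value == 0.0 and res.retained

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_groups = int(rng.integers(2, 7))
            sizes = rng.integers(2, 5, size=n_groups)
            labels = sum([[f"g{g}"] * int(s) for g, s in enumerate(sizes)], [])
            n = len(labels)
            X = rng.gamma(2.0, 3.0, size=(8, n))
            matrix = ev.CountMatrix(
                pd.DataFrame(X, index=[f"P{i}" for i in range(8)], columns=[f"r{i}" for i in range(n)]),
                "run",
            )
            res = ev.f_screen(matrix, design_for(labels), labels)
            arr = np.array(labels)
            for i, r in enumerate(res):
                groups = [X[i, arr == g] for g in dict.fromkeys(labels)]
                f, p = st.f_oneway(*groups)
                assert r.f_ratio == pytest.approx(f, rel=1e-9, abs=1e-9)
                assert r.p_value == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_retention_monotone_in_thresholds(self, small_psm, default_design):
        kept, _ = ev.filter_species(small_psm)
        norm = ev.normalize_runs(ev.aggregate_counts(kept, default_design))
        strict = set(retained_proteins(ev.f_screen(norm, default_design, f_min=3.0, p_max=0.01)))
        loose = set(retained_proteins(ev.f_screen(norm, default_design, f_min=2.0, p_max=0.05)))
        assert strict <= loose

    def test_planted_deps_retained_above_null_rate(self):
        cfg = ev.SimulationConfig(seed=13)
        counts, truth = ev.simulate_counts(cfg)
        design = cfg.resolved_design()
        norm = ev.normalize_runs(
            ev.CountMatrix(counts.data[counts.species == "human"], "run")
        )
        res = ev.f_screen(norm, design)
        retained = {r.protein for r in res if r.retained}
        deps = set(truth.dep_proteins)
        dep_rate = len(retained & deps) / len(deps)
        null = {r.protein for r in res} - deps
        null_rate = len(retained & null) / len(null)
        assert dep_rate > null_rate


class TestCluster:
    def test_identical_columns_merge_first_at_zero(self):
        data = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]}, index=["P1", "P2"]
        )
        dend = ev.cluster(ev.CountMatrix(data, "run"), standardize=False)
        assert dend.linkage[0, 2] == pytest.approx(0.0)
        left, right = dend.top_split()
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"a", "b"}),
            frozenset({"c"}),
        }

    def test_two_separated_groups_split_at_top(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(0, 0.1, size=(30, 2))
        g2 = rng.normal(10, 0.1, size=(30, 2))
        data = pd.DataFrame(
            np.hstack([g1, g2]) + 20.0, columns=["a1", "a2", "b1", "b2"]
        )
        dend = ev.cluster(ev.CountMatrix(data, "run"), standardize=False)
        left, right = dend.top_split()
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
        }

    def test_matches_exhaustive_ward_oracle(self):
        """scipy Ward equals an independent agglomerator that recomputes the
        minimum-variance merge objective from scratch at every step."""
        rng = np.random.default_rng(5)

        def ward_cost(ca, cb):
            ca, cb = np.asarray(ca), np.asarray(cb)
            na, nb = len(ca), len(cb)
            d2 = np.sum((ca.mean(0) - cb.mean(0)) ** 2)
            return na * nb / (na + nb) * d2

        for _ in range(10):
            X = rng.normal(0, 1, size=(5, 4))  # 5 features x 4 columns
            cols = [f"c{i}" for i in range(4)]
            data = pd.DataFrame(X + 10, columns=cols)
            dend = ev.cluster(ev.CountMatrix(data, "run"), standardize=False)
            # brute-force greedy agglomeration on Ward objective
            clusters = {i: [X[:, i] + 10] for i in range(4)}
            heights = []
            while len(clusters) > 1:
                best = min(
                    itertools.combinations(clusters, 2),
                    key=lambda ab: ward_cost(clusters[ab[0]], clusters[ab[1]]),
                )
                cost = ward_cost(clusters[best[0]], clusters[best[1]])
                heights.append(np.sqrt(2 * cost))
                clusters[best[0]] = clusters[best[0]] + clusters.pop(best[1])
            assert np.allclose(sorted(dend.heights()), sorted(heights), atol=1e-8)

    def test_heights_nondecreasing_and_permutation_invariant(self, small_psm, default_design):
        kept, _ = ev.filter_species(small_psm)
        norm = ev.normalize_runs(ev.aggregate_counts(kept, default_design))
        dend = ev.cluster(norm)
        assert (np.diff(dend.heights()) >= -1e-9).all()
        shuffled = ev.CountMatrix(
            norm.data[list(reversed(norm.columns))], "run"
        )
        dend2 = ev.cluster(shuffled)
        assert np.allclose(dend.linkage, dend2.linkage)
        assert dend.labels == dend2.labels

    def test_nan_rejected(self):
        data = pd.DataFrame({"a": [1.0], "b": [1.0]})
        matrix = ev.CountMatrix(data, "run")
        matrix.data.loc[0, "a"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ev.cluster(matrix)

    def test_newick_export_parses_and_preserves_leaves(self, small_psm, default_design):
        dendropy = pytest.importorskip("dendropy")
        kept, _ = ev.filter_species(small_psm)
        norm = ev.normalize_runs(ev.aggregate_counts(kept, default_design))
        dend = ev.cluster(norm)
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        leaves = {l.taxon.label.replace(" ", "_") for l in tree.leaf_node_iter()}
        assert len(leaves) == 72


class TestPca:
    def test_two_conditions_single_component(self):
        data = pd.DataFrame({"c1": [1.0, 5.0, 2.0], "c2": [2.0, 1.0, 9.0]})
        res = ev.pca(ev.CountMatrix(data, "condition"))
        assert res.n_components == 1
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_duplicated_condition_scores_coincide(self):
        rng = np.random.default_rng(0)
        base = rng.gamma(2, 3, size=10)
        data = pd.DataFrame(
            {"c1": base, "c2": base, "c3": rng.gamma(2, 3, size=10)}
        )
        res = ev.pca(ev.CountMatrix(data, "condition"))
        assert np.allclose(res.scores.loc["c1"], res.scores.loc["c2"], atol=1e-9)

    def test_reconstruction_from_all_components(self, small_apsm):
        res = ev.pca(small_apsm)
        X = small_apsm.data.to_numpy().T
        centred = X - X.mean(axis=0)
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(approx, centred, atol=1e-8)

    def test_variance_fractions_sorted_and_bounded(self, small_apsm):
        res = ev.pca(small_apsm)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-9

    def test_bpa_groups_separate_on_pc1(self):
        cfg = ev.SimulationConfig(seed=21)
        counts, _ = ev.simulate_counts(cfg)
        design = cfg.resolved_design()
        norm = ev.normalize_runs(
            ev.CountMatrix(counts.data[counts.species == "human"], "run")
        )
        retained = retained_proteins(ev.f_screen(norm, design))
        apsm = ev.average_condition(norm, design).restrict(retained)
        res = ev.pca(apsm)
        pc1 = res.scores["PC1"]
        plus = pc1[[c for c in pc1.index if c.startswith("BPA+")]]
        minus = pc1[[c for c in pc1.index if c.startswith("BPA-")]]
        assert plus.min() > minus.max() or minus.min() > plus.max()


class TestCombineSelections:
    def test_union_sizes(self):
        assert len(ev.combine_selections({"a", "b", "c"}, {"d", "e"})) == 5
        assert len(ev.combine_selections({"a", "b"}, {"a"})) == 2

    def test_inclusion_exclusion_example(self):
        screen = {f"s{i}" for i in range(70)} | {f"shared{i}" for i in range(16)}
        deps = {f"d{i}" for i in range(11)} | {f"shared{i}" for i in range(16)}
        assert len(screen) == 86 and len(deps) == 27
        combined = ev.combine_selections(screen, deps)
        assert len(combined) == 97
        assert combined["shared0"] == {"screen", "dep"}
        assert combined["s0"] == {"screen"}
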