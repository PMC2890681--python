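"""Jaccard distances, neighbour-joining, principal coordinates, assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ssrkit import (
    DistanceResult,
    assign_knn,
    jaccard_distance,
    neighbor_joining,
    pco,
    to_allelic_phenotype,
)

from conftest import make_panel


def jaccard_oracle(set_a, set_b):
    """Naive set-based Jaccard distance."""
    if not (set_a | set_b):
        return np.nan
    return 1.0 - len(set_a & set_b) / len(set_a | set_b)


class TestJaccard:
    def test_identical_disjoint_partial(self):
        panel = make_panel(
            {
                "P1": {"L": {"a", "b"}},
                "P2": {"L": {"a", "b"}},
                "P3": {"L": {"c"}},
                "P4": {"L": {"b", "c"}},
            },
            {"L": ["a", "b", "c"]},
        )
        d = jaccard_distance(to_allelic_phenotype(panel)).to_frame()
        assert d.loc["P1", "P2"] == pytest.approx(0.0)
        assert d.loc["P1", "P3"] == pytest.approx(1.0)
        assert d.loc["P1", "P4"] == pytest.approx(2.0 / 3.0)  # {a,b} vs {b,c}

    def test_missing_locus_columns_skipped(self):
        panel = make_panel(
            {
                "P1": {"L": {"a"}, "M": None},
                "P2": {"L": {"a"}, "M": {"x"}},
            },
            {"L": ["a"], "M": ["x", "y"]},
        )
        d = jaccard_distance(to_allelic_phenotype(panel)).to_frame()
        # M is dropped for the pair; only L compares -> identical
        assert d.loc["P1", "P2"] == pytest.approx(0.0)

    def test_no_coscored_pair_is_nan_with_warning(self):
        panel = make_panel(
            {
                "P1": {"L": {"a"}, "M": None},
                "P2": {"L": None, "M": {"x"}},
            },
            {"L": ["a"], "M": ["x"]},
        )
        with pytest.warns(UserWarning, match="no co-scored"):
            d = jaccard_distance(to_allelic_phenotype(panel)).to_frame()
        assert np.isnan(d.loc["P1", "P2"])

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_set_oracle(self, data):
        n_plants = data.draw(st.integers(3, 8))
        alleles = ["a", "b", "c", "d", "e"]
        calls = {}
        for i in range(n_plants):
            s = data.draw(st.sets(st.sampled_from(alleles), min_size=1, max_size=5))
            calls[f"P{i}"] = {"L": s}
        panel = make_panel(calls, {"L": alleles})
        d = jaccard_distance(to_allelic_phenotype(panel)).to_frame()
        for i in range(n_plants):
            for j in range(n_plants):
                expect = 0.0 if i == j else jaccard_oracle(calls[f"P{i}"]["L"], calls[f"P{j}"]["L"])
                assert d.iloc[i, j] == pytest.approx(expect)

    def test_variety_level_union_consensus(self):
        panel = make_panel(
            {
                "P1": {"L": {"a"}},
                "P2": {"L": {"b"}},
                "P3": {"L": {"a", "b"}},
            },
            {"L": ["a", "b", "c"]},
            varieties={"P1": "V1", "P2": "V1", "P3": "V2"},
        )
        d = jaccard_distance(to_allelic_phenotype(panel), level="variety").to_frame()
        # both consensus profiles are {a, b}
        assert d.loc["V1", "V2"] == pytest.approx(0.0)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceResult(["A", "B", "C"], np.array(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]
        ))
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):0.5,(C:1.5,D:1):0); path lengths are additive
        labels = ["A", "B", "C", "D"]
        dm = np.array(
            [
                [0.0, 3.0, 3.0, 2.5],
                [3.0, 0.0, 4.0, 3.5],
                [3.0, 4.0, 0.0, 2.5],
                [2.5, 3.5, 2.5, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceResult(labels, dm))
        td = tree.tip_tip_distances()
        rebuilt = pd.DataFrame(td.data, index=td.ids, columns=td.ids)
        assert np.allclose(rebuilt.loc[labels, labels].to_numpy(), dm, atol=1e-9)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            # random additive matrix from a random tree: build via random
            # bifurcating merge with positive branch lengths
            from skbio import TreeNode

            tips = [TreeNode(name=f"T{i}", length=float(rng.uniform(0.1, 1))) for i in range(n)]
            while len(tips) > 1:
                a = tips.pop(int(rng.integers(len(tips))))
                b = tips.pop(int(rng.integers(len(tips))))
                parent = TreeNode(length=float(rng.uniform(0.1, 1)), children=[a, b])
                tips.append(parent)
            true = tips[0]
            td = true.tip_tip_distances()
            labels = list(td.ids)
            rebuilt_tree = neighbor_joining(DistanceResult(labels, td.data))
            td2 = rebuilt_tree.tip_tip_distances()
            got = pd.DataFrame(td2.data, index=td2.ids, columns=td2.ids)
            assert np.allclose(got.loc[labels, labels].to_numpy(), td.data, atol=1e-9)

    def test_undefined_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(DistanceResult(["A", "B", "C"], d))


class TestPCO:
    def test_equilateral_triangle_two_equal_eigenvalues(self):
        d = DistanceResult(["A", "B", "C"], 1.0 - np.eye(3))
        _, ev = pco(d)
        assert ev[0] == pytest.approx(ev[1], rel=1e-9)
        assert ev[2] == pytest.approx(0.0, abs=1e-9)

    def test_collinear_points_single_positive_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        coords, ev = pco(DistanceResult(list("ABCD"), d))
        assert coords.shape[1] == 1
        got = np.abs(coords.iloc[:, 0].to_numpy()[:, None] - coords.iloc[:, 0].to_numpy()[None, :])
        assert np.allclose(got, d, atol=1e-9)

    def test_gower_distance_recovery_and_trace_identity(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, ev = pco(DistanceResult([f"P{i}" for i in range(6)], d))
        got = np.linalg.norm(
            coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=-1
        )
        assert np.allclose(got, d, atol=1e-9)
        n = 6
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (d**2) @ J
        assert ev.sum() == pytest.approx(np.trace(B), abs=1e-9)

    def test_truncation_warning(self):
        x = np.array([0.0, 1.0, 2.0])
        d = np.abs(x[:, None] - x[None, :])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, _ = pco(DistanceResult(list("ABC"), d), k=3)
        assert coords.shape[1] == 1


class TestAssignment:
    def test_duplicate_plant_wins_at_k1(self):
        panel = make_panel(
            {
                "P1": {"L": {"a", "b"}},
                "P2": {"L": {"a", "b"}},
                "P3": {"L": {"c"}},
            },
            {"L": ["a", "b", "c"]},
            varieties={"P1": "V1", "P2": "V2", "P3": "V3"},
        )
        res = assign_knn(to_allelic_phenotype(panel), k=1)
        assert res.assignments.loc["P1", "assigned"] == "V2"
        assert res.assignments.loc["P2", "assigned"] == "V1"

    def test_sa_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        calls, varieties = {}, {}
        for v in ("V1", "V2", "V3"):
            for i in range(5):
                pid = f"{v}-{i}"
                calls[pid] = {"L": set(rng.choice(["a", "b", "c", "d"], size=2))}
                varieties[pid] = v
        panel = make_panel(calls, {"L": ["a", "b", "c", "d"]}, varieties=varieties)
        res = assign_knn(to_allelic_phenotype(panel), k=3)
        assert np.allclose(res.similarity_by_assignment.sum(axis=1), 1.0)

    def test_k_bounds_enforced(self):
        panel = make_panel(
            {"P1": {"L": {"a"}}, "P2": {"L": {"a"}}}, {"L": ["a"]}
        )
        with pytest.raises(ValueError):
            assign_knn(to_allelic_phenotype(panel), k=2)

    def test_well_separated_varieties_assigned_back(self):
        from ssrkit import SimulationConfig, VarietySpec, simulate_panel

        cfg = SimulationConfig(
            seed=20,
            n_loci=6,
            alleles_per_locus=(6,) * 6,
            varieties=[VarietySpec(f"V{i}", "B1", 2, 30) for i in range(6)],
            breeder_divergence=0.0,
            line_divergence=0.4,
            paired_pools=False,
            dropout_rate=0.0,
        )
        panel, _ = simulate_panel(cfg)
        res = assign_knn(to_allelic_phenotype(panel), k=10)
        assert res.correct_by_variety.mean() >= 24.0

    def test_accuracy_monotone_in_divergence(self):
        from ssrkit import SimulationConfig, VarietySpec, simulate_panel

        accuracies = []
        for div in (0.05, 0.2, 0.5):
            cfg = SimulationConfig(
                seed=21,
                n_loci=5,
                alleles_per_locus=(5,) * 5,
                varieties=[VarietySpec(f"V{i}", "B1", 2, 12) for i in range(5)],
                breeder_divergence=0.0,
                line_divergence=div,
                paired_pools=False,
                dropout_rate=0.0,
            )
            panel, _ = simulate_panel(cfg)
            res = assign_knn(to_allelic_phenotype(panel), k=5)
            accuracies.append(res.assignments["correct"].mean())
        assert accuracies[0] <= accuracies[1] <= accuracies[2]
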