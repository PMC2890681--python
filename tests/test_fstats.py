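"""Gene-diversity F-statistics: hand-checked cases, identities, jackknife, permutations."""

import numpy as np
import pandas as pd
import pytest

from ssrkit import (
    FStatisticsModel,
    PermutationScheme,
    compare_scoring_modes,
    f_coefficients,
    fst_dominant,
    gene_diversities_codominant,
    multilocus_jackknife,
    to_allelic_phenotype,
    to_codominant,
    weir_cockerham_theta,
)

from conftest import make_panel


def two_group_panel(calls_a, calls_b, loci_alleles, ploidy=2):
    calls, varieties = {}, {}
    for i, c in enumerate(calls_a):
        calls[f"A{i}"] = c
        varieties[f"A{i}"] = "GA"
    for i, c in enumerate(calls_b):
        calls[f"B{i}"] = c
        varieties[f"B{i}"] = "GB"
    return make_panel(calls, loci_alleles, ploidy=ploidy, varieties=varieties)


class TestCodominantDiversities:
    def test_fixation_case(self):
        panel = two_group_panel(
            [{"L": {"a"}}] * 2, [{"L": {"b"}}] * 2, {"L": ["a", "b"]}
        )
        comp = gene_diversities_codominant(to_codominant(panel))
        assert comp.loc["L"].tolist() == pytest.approx([0.0, 0.0, 0.5])
        fis, fst, fit = f_coefficients(*comp.loc["L"])
        assert fst == pytest.approx(1.0)

    def test_all_heterozygous_maximal_excess(self):
        panel = two_group_panel(
            [{"L": {"a", "b"}}] * 3, [{"L": {"a", "b"}}] * 3, {"L": ["a", "b"]}
        )
        comp = gene_diversities_codominant(to_codominant(panel))
        ho, hs, ht = comp.loc["L"]
        assert (ho, hs, ht) == pytest.approx((1.0, 0.5, 0.5))
        fis, _, _ = f_coefficients(ho, hs, ht)
        assert fis == pytest.approx(-1.0)

    def test_hand_computed_mixed_groups(self):
        # group A {(a,a),(a,b)} p=(0.75,0.25); group B {(b,b),(a,b)} p=(0.25,0.75)
        panel = two_group_panel(
            [{"L": {"a"}}, {"L": {"a", "b"}}],
            [{"L": {"b"}}, {"L": {"a", "b"}}],
            {"L": ["a", "b"]},
        )
        comp = gene_diversities_codominant(to_codominant(panel))
        ho, hs, ht = comp.loc["L"]
        assert ho == pytest.approx(0.5)
        assert hs == pytest.approx(0.375)
        assert ht == pytest.approx(0.5)
        _, fst, _ = f_coefficients(ho, hs, ht)
        assert fst == pytest.approx(0.25)

    def test_monomorphic_locus_reported_undefined_not_zero(self):
        panel = two_group_panel(
            [{"L": {"a"}}] * 2, [{"L": {"a"}}] * 2, {"L": ["a"]}
        )
        comp = gene_diversities_codominant(to_codominant(panel))
        fis, fst, fit = f_coefficients(*comp.loc["L"])
        assert comp.loc["L", "Hs"] == 0.0 and comp.loc["L", "Ht"] == 0.0
        assert np.isnan(fst) and np.isnan(fis) and np.isnan(fit)


class TestFCoefficients:
    @pytest.mark.parametrize(
        "fis,fst,fit",
        [(-0.113, 0.135, 0.038), (0.0, 0.0, 0.0), (0.82, 0.459, 0.903)],
    )
    def test_identity_reconstruction(self, fis, fst, fit):
        assert 1 - (1 - fis) * (1 - fst) == pytest.approx(fit, abs=2e-3)

    def test_fis_from_ho_hs(self):
        fis, _, _ = f_coefficients(0.069, 0.383, 1.0)
        assert fis == pytest.approx(0.820, abs=3e-3)

    def test_identity_holds_on_random_components(self):
        rng = np.random.default_rng(3)
        ho = rng.uniform(0, 1, 50)
        hs = rng.uniform(0.01, 1, 50)
        ht = hs + rng.uniform(0.0, 0.5, 50)
        fis, fst, fit = f_coefficients(ho, hs, ht)
        assert np.allclose((1 - fit), (1 - fis) * (1 - fst), atol=1e-9)


class TestDominantFst:
    def test_disjoint_and_identical_profiles(self):
        panel = two_group_panel(
            [{"L": {"a"}}] * 3, [{"L": {"b"}}] * 3, {"L": ["a", "b"]}
        )
        assert fst_dominant(to_allelic_phenotype(panel)).loc["L", "Fst"] == pytest.approx(1.0)
        panel2 = two_group_panel(
            [{"L": {"a"}}, {"L": {"b"}}], [{"L": {"a"}}, {"L": {"b"}}], {"L": ["a", "b"]}
        )
        assert fst_dominant(to_allelic_phenotype(panel2)).loc["L", "Fst"] == pytest.approx(0.0)

    def test_hand_computed_carrier_case(self):
        # carriers (4,0) vs (2,2): Hs=(0+0.5)/2=0.25, Ht=1-(0.75^2+0.25^2)=0.375
        panel = two_group_panel(
            [{"L": {"a"}}] * 4,
            [{"L": {"a"}}, {"L": {"a"}}, {"L": {"b"}}, {"L": {"b"}}],
            {"L": ["a", "b"]},
        )
        row = fst_dominant(to_allelic_phenotype(panel)).loc["L"]
        assert row["Hs"] == pytest.approx(0.25)
        assert row["Ht"] == pytest.approx(0.375)
        assert row["Fst"] == pytest.approx(1.0 / 3.0)

    def test_mixed_ploidy_in_one_run(self):
        panel = two_group_panel(
            [{"L": {"a", "b", "c"}}] * 2,
            [{"L": {"a"}}] * 2,
            {"L": ["a", "b", "c"]},
            ploidy={"A0": 3, "A1": 3, "B0": 2, "B1": 2},
        )
        fst = fst_dominant(to_allelic_phenotype(panel)).loc["L", "Fst"]
        assert 0.0 < fst <= 1.0


class TestJackknife:
    def test_identical_loci_zero_se(self):
        comp = pd.DataFrame({"Ho": [0.2] * 3, "Hs": [0.4] * 3, "Ht": [0.5] * 3})
        mean, se = multilocus_jackknife(comp, "fst")
        assert mean == pytest.approx(1 - 0.4 / 0.5)
        assert se == pytest.approx(0.0)

    def test_matches_explicit_enumeration(self):
        comp = pd.DataFrame({"Ho": [0.1, 0.3], "Hs": [0.5, 0.4], "Ht": [0.6, 0.9]})
        thetas = []
        for drop in (0, 1):
            keep = comp.drop(index=drop)
            thetas.append(1 - keep["Hs"].sum() / keep["Ht"].sum())
        mean, se = multilocus_jackknife(comp, "fst")
        assert mean == pytest.approx(np.mean(thetas))
        assert se == pytest.approx(
            np.sqrt(0.5 * np.sum((np.array(thetas) - np.mean(thetas)) ** 2))
        )

    def test_single_locus_rejected(self):
        comp = pd.DataFrame({"Ho": [0.1], "Hs": [0.5], "Ht": [0.6]})
        with pytest.raises(ValueError):
            multilocus_jackknife(comp, "fst")


class TestModelFit:
    def _panel(self):
        rng = np.random.default_rng(11)
        calls, varieties = {}, {}
        for g, pool in (("GA", ["a", "b"]), ("GB", ["b", "c"])):
            for i in range(8):
                pid = f"{g}{i}"
                calls[pid] = {
                    "L": set(rng.choice(pool, size=2)),
                    "M": set(rng.choice(["x", "y"], size=2)),
                }
                varieties[pid] = g
        return make_panel(
            calls, {"L": ["a", "b", "c"], "M": ["x", "y"]}, varieties=varieties
        )

    def test_multilocus_identity_and_summary(self):
        res = FStatisticsModel(self._panel(), mode="codominant").fit()
        fis, fst, fit = (res.multilocus[c] for c in ("fis", "fst", "fit"))
        assert (1 - fit) == pytest.approx((1 - fis) * (1 - fst), abs=1e-9)
        per = res.per_locus.dropna()
        assert np.allclose(
            1 - per["Fit"], (1 - per["Fis"]) * (1 - per["Fst"]), atol=1e-9
        )
        text = res.summary()
        assert "Fst" in text and "jackknife" in text

    def test_permutation_determinism_and_fully_differentiated_p(self):
        panel = two_group_panel(
            [{"L": {"a"}, "M": {"x"}}] * 10,
            [{"L": {"b"}, "M": {"y"}}] * 10,
            {"L": ["a", "b"], "M": ["x", "y"]},
        )
        model = FStatisticsModel(panel, mode="dominant")
        r1 = model.fit(n_permutations=999, seed=5)
        r2 = model.fit(n_permutations=999, seed=5)
        pd.testing.assert_frame_equal(r1.permutation_p, r2.permutation_p)
        # disjoint groups: no permutation can reach the observed Fst = 1
        assert r1.permutation_p.loc["multilocus", "p_fst"] == pytest.approx(1 / 1000)

    def test_degenerate_single_group_rejected(self):
        panel = make_panel(
            {"P1": {"L": {"a"}}, "P2": {"L": {"b"}}}, {"L": ["a", "b"]}
        )
        with pytest.raises(ValueError, match=">= 2 groups"):
            FStatisticsModel(panel, mode="dominant")

    def test_permutation_scheme_validation(self):
        with pytest.raises(ValueError):
            PermutationScheme(n_permutations=0)


class TestWeirCockerham:
    def test_fixed_groups_theta_one(self):
        panel = two_group_panel(
            [{"L": {"a"}}] * 4, [{"L": {"b"}}] * 4, {"L": ["a", "b"]}
        )
        theta = weir_cockerham_theta(to_codominant(panel))
        assert theta.loc["L", "theta"] == pytest.approx(1.0)

    def test_theta_near_zero_for_identical_groups(self):
        panel = two_group_panel(
            [{"L": {"a"}}, {"L": {"b"}}, {"L": {"a", "b"}}] * 2,
            [{"L": {"a"}}, {"L": {"b"}}, {"L": {"a", "b"}}] * 2,
            {"L": ["a", "b"]},
        )
        theta = weir_cockerham_theta(to_codominant(panel))
        assert abs(theta.loc["L", "theta"]) < 0.15


class TestScoringComparison:
    def test_identical_scorings_when_all_heterozygotes_distinct(self):
        # every plant heterozygous with two distinct alleles, so carrier
        # counting equals copy counting; pair overlap varies across loci so
        # the per-locus Fst values are not all equal
        loci = {f"L{i}": ["a", "b", "c", "d"] for i in range(3)}
        pairs = {
            "L0": {"GA": ("a", "b"), "GB": ("c", "d")},
            "L1": {"GA": ("a", "b"), "GB": ("b", "c")},
            "L2": {"GA": ("a", "b"), "GB": ("a", "c")},
        }
        calls, varieties = {}, {}
        for g in ("GA", "GB"):
            for i in range(4):
                pid = f"{g}{i}"
                calls[pid] = {loc: set(pairs[loc][g]) for loc in loci}
                varieties[pid] = g
        panel = make_panel(calls, loci, varieties=varieties)
        cmp_ = compare_scoring_modes(panel)
        assert cmp_.r_squared == pytest.approx(1.0)
        assert cmp_.multilocus_dominant == pytest.approx(cmp_.multilocus_codominant)

    def test_too_few_loci_rejected(self):
        panel = two_group_panel(
            [{"L": {"a", "b"}}] * 3, [{"L": {"b", "c"}}] * 3, {"L": ["a", "b", "c"]}
        )
        with pytest.raises(ValueError, match="correlation"):
            compare_scoring_modes(panel)
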