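"""Overlap statistics, over-representation, fold-change concordance,
panel scoring and stratified medians."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bloodlens as bl
from conftest import target_base_proportions


def brute_force_tail(k: int, universe_n: int, n_a: int, n_b: int) -> float:
    """Enumerate every size-n_b draw from the universe and count draws
    overlapping a fixed size-n_a set by >= k."""
    universe = range(universe_n)
    a = set(range(n_a))
    hits = sum(1 for draw in combinations(universe, n_b) if len(a & set(draw)) >= k)
    return hits / comb(universe_n, n_b)


class TestHypergeometricTail:
    def test_tiny_enumeration_example(self):
        # N=6, |A|=|B|=2, overlap 2: exactly 1 of the 15 draws
        assert bl.hypergeom_upper_tail(2, 6, 2, 2) == pytest.approx(1 / 15, abs=1e-12)

    @pytest.mark.parametrize("universe_n", [5, 8, 12])
    def test_matches_enumeration_small_universes(self, universe_n):
        for n_a in range(universe_n + 1):
            for n_b in range(universe_n + 1):
                for k in range(min(n_a, n_b) + 1):
                    assert bl.hypergeom_upper_tail(k, universe_n, n_a, n_b) == pytest.approx(
                        brute_force_tail(k, universe_n, n_a, n_b), abs=1e-12
                    )

    @given(
        n=st.integers(20, 200), na=st.integers(1, 20), nb=st.integers(1, 20),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_nonincreasing_in_overlap(self, n, na, nb):
        tails = [bl.hypergeom_upper_tail(k, n, na, nb) for k in range(min(na, nb) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
        assert tails[0] == 1.0


class TestOverlapTest:
    def test_zero_overlap_p_one(self):
        rep = bl.overlap_test(["a", "b"], ["c", "d"], universe_n=100)
        assert rep.p == 1.0 and rep.n_overlap == 0

    def test_published_scale_overlap_order_of_magnitude(self):
        """199 vs 181 genes overlapping by 23 in a 28,000-gene universe is
        astronomically unlikely (tail ~ 1e-22..1e-19)."""
        a = [f"a{i}" for i in range(176)] + [f"o{i}" for i in range(23)]
        b = [f"b{i}" for i in range(158)] + [f"o{i}" for i in range(23)]
        rep = bl.overlap_test(a, b, universe_n=28000)
        assert rep.n_overlap == 23
        assert 1e-22 < rep.p < 1e-19
        assert rep.expected_overlap == pytest.approx(199 * 181 / 28000)

    def test_discordant_direction_reported(self):
        """An overlap gene down in one signature and up in the other (like
        FN1: -2.18 vs +3.39) is listed as discordant."""
        fa = {"FN1": np.log2(1 / 2.18), "TLR2": -0.6, "tiny": 0.01}
        fb = {"FN1": np.log2(3.39), "TLR2": -0.7, "tiny": -0.01}
        rep = bl.overlap_test(list(fa), list(fb), 1000, fa, fb)
        assert rep.discordant_genes == ["FN1"]  # dead zone shields 'tiny'

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bl.overlap_test(["a"], ["b"], 10, universe={"a"})

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError, match="universe_n"):
            bl.overlap_test(["a", "b"], ["c"], universe_n=2)


class TestOra:
    def test_exact_match_closed_form(self):
        genes = [f"g{i}" for i in range(10)]
        table = bl.ora(genes, {"the_set": genes}, universe_n=1000)
        row = table.iloc[0]
        assert row["k_overlap"] == 10
        assert row["p"] == pytest.approx(1 / comb(1000, 10), rel=1e-9)

    def test_disjoint_set_p_one(self):
        table = bl.ora(["a", "b"], {"s": ["c", "d"]}, universe_n=100)
        assert table.iloc[0]["p"] == 1.0 and table.iloc[0]["k_overlap"] == 0

    def test_universe_as_set_always_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        table = bl.ora(universe[:7], {"everything": universe}, universe_n=50)
        assert table.iloc[0]["p"] == 1.0

    def test_planted_markers_rank_their_panel_first(self, small_atlas):
        atlas, truth = small_atlas
        sets = {f"{ct}_panel": genes for ct, genes in truth.items()}
        target = atlas.specific_types[3]
        table = bl.ora(truth[target], sets, universe_n=len(atlas.gene_ids))
        assert table.iloc[0]["set"] == f"{target}_panel"
        assert table.iloc[0]["q_bh"] <= table.iloc[0]["p"] * len(sets)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bl.ora([], {"s": ["a"]}, 10)


class TestFcConcordance:
    def _deg(self, folds):
        t = pd.DataFrame({"gene": list(folds), "log2FC": list(folds.values())})
        return bl.DEGTable(t, case="x", control="y")

    def test_identical_tables_correlate_perfectly(self):
        folds = {f"g{i}": v for i, v in enumerate([0.5, -1.2, 2.0, 0.1, -0.4])}
        rep = bl.fc_concordance(self._deg(folds), self._deg(folds), list(folds))
        assert rep.spearman == pytest.approx(1.0)
        assert rep.pearson == pytest.approx(1.0)

    def test_negated_tables_anticorrelate(self):
        folds = {f"g{i}": v for i, v in enumerate([0.5, -1.2, 2.0, 0.1])}
        neg = {g: -v for g, v in folds.items()}
        rep = bl.fc_concordance(self._deg(folds), self._deg(neg), list(folds))
        assert rep.spearman == pytest.approx(-1.0)
        assert rep.pearson == pytest.approx(-1.0)

    def test_short_pooled_list_rejected(self):
        folds = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError, match="at least 3"):
            bl.fc_concordance(self._deg(folds), self._deg(folds), ["a", "b"])

    def test_shared_perturbations_give_partial_concordance(self, blood_atlas):
        """Two cohorts whose perturbations share a graded fold profile over
        most genes (plus a few cohort-private ones) agree partially:
        0 < correlation < 1, and the value is seed-reproducible."""
        atlas, _ = blood_atlas
        shared_genes = bl.exclusive_markers(atlas, "nk")[:14]
        shared = {g: f for g, f in zip(shared_genes, np.linspace(1.4, 3.5, 14))}
        own_a = {g: 2.0 for g in bl.exclusive_markers(atlas, "mait_t")[:2]}
        own_b = {g: 2.0 for g in bl.exclusive_markers(atlas, "treg")[:2]}

        def cohort(folds, seed):
            spec = bl.ScenarioSpec(kind="expression_shift", target_cell_type=None,
                                   n_per_group=15, dispersion=0.1, seed=seed)
            counts, meta, _ = bl.simulate_cohort(atlas, spec, perturb_genes=folds)
            return bl.nb_wald_test(counts, meta.groups_for(counts.sample_ids),
                                   case="inoca", control="control")

        rhos = []
        for _ in range(2):
            deg_a = cohort({**shared, **own_a}, seed=5)
            deg_b = cohort({**shared, **own_b}, seed=6)
            pooled = list(shared) + list(own_a) + list(own_b)
            rep = bl.fc_concordance(deg_a, deg_b, pooled)
            assert 0.0 < rep.spearman < 1.0
            assert 0.0 < rep.pearson < 1.0
            rhos.append(rep.spearman)
        assert rhos[0] == rhos[1]


class TestPanelScore:
    def test_identical_groups_p_one_no_flags(self):
        nrc = pd.DataFrame(
            np.tile(np.array([[4.0, 7.0, 9.0]]), (1, 4)),
            index=["MPO"], columns=[f"s{i}" for i in range(12)],
        )
        groups = np.repeat(["control", "inoca", "cad_stress_neg", "cad_stress_pos"], 3)
        panel = bl.PanelDefinition("bacterial", "bacterial", ["MPO"])
        table = bl.panel_score(nrc, panel, groups, reference_group="inoca")
        assert all(table[c].iloc[0] == 1.0 for c in table.columns if c.startswith("p_"))
        assert not any(table[c].iloc[0] for c in table.columns if c.startswith("sig_"))

    def test_single_gene_exact_p(self):
        nrc = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["CTSG"],
                           columns=[f"s{i}" for i in range(6)])
        groups = np.array(["inoca"] * 3 + ["control"] * 3)
        panel = bl.PanelDefinition("bacterial", "bacterial", ["CTSG"])
        table = bl.panel_score(nrc, panel, groups, reference_group="inoca")
        assert table["p_control_vs_inoca"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_schema_mirrors_published_layout(self, small_atlas):
        """Rows carry gene, description, panel type, then one mean (sd)
        column pair per study group."""
        atlas, _ = small_atlas
        rng = np.random.default_rng(3)
        nrc = pd.DataFrame(rng.poisson(20, (3, 16)).astype(float),
                           index=["ACTB", "MPO", "RSAD2"],
                           columns=[f"s{i}" for i in range(16)])
        groups = np.repeat(["control", "inoca", "cad_stress_neg", "cad_stress_pos"], 4)
        panels = [
            bl.PanelDefinition("control", "control", ["ACTB"], {"ACTB": "Actin-B"}),
            bl.PanelDefinition("bacterial", "bacterial", ["MPO"]),
            bl.PanelDefinition("viral", "viral", ["RSAD2"]),
        ]
        table = bl.panel_score(nrc, panels, groups, reference_group="inoca")
        for col in ("gene", "description", "panel_type",
                    "mean_control", "sd_control", "mean_inoca", "sd_inoca",
                    "mean_cad_stress_neg", "mean_cad_stress_pos"):
            assert col in table.columns
        assert list(table["gene"]) == ["ACTB", "MPO", "RSAD2"]
        # means equal independently computed group means
        assert table["mean_control"].iloc[1] == pytest.approx(
            nrc.loc["MPO"].to_numpy()[groups == "control"].mean()
        )

    def test_all_genes_missing_rejected(self):
        nrc = pd.DataFrame(np.ones((1, 4)), index=["X"], columns=list("abcd"))
        panel = bl.PanelDefinition("p", "p", ["NOT_THERE"])
        with pytest.raises(ValueError, match="no panel gene"):
            bl.panel_score(nrc, panel, np.array(["a", "a", "b", "b"]), "a")


class TestStratifiedMedians:
    def test_reference_is_100_and_scale_doubles(self):
        base = np.array([[10.0, 12.0, 11.0, 20.0, 24.0, 22.0]])
        nrc = pd.DataFrame(base, index=["DAAM2"], columns=[f"s{i}" for i in range(6)])
        strata = np.array(["male_neg"] * 3 + ["female_neg"] * 3)
        out = bl.stratified_medians(nrc, strata, "male_neg")
        assert out["pct_male_neg"].iloc[0] == 100.0
        assert out["pct_female_neg"].iloc[0] == pytest.approx(200.0)

    def test_zero_reference_median_is_na(self):
        nrc = pd.DataFrame([[0.0, 0.0, 5.0, 6.0]], index=["IFI27"],
                           columns=list("abcd"))
        out = bl.stratified_medians(nrc, np.array(["r", "r", "x", "x"]), "r")
        assert np.isnan(out["pct_x"].iloc[0])

    def test_sex_specific_regulation_recovered(self, blood_atlas):
        """A 0.5x female-specific effect shows up as female strata near 50%
        of the male reference."""
        atlas, _ = blood_atlas
        gene = bl.exclusive_markers(atlas, "neutrophil")[0]
        spec = bl.ScenarioSpec(kind="null", n_per_group=40, dispersion=0.05, seed=77)
        counts, meta, _ = bl.simulate_cohort(atlas, spec, sex_effect={gene: 0.5})
        sf = bl.estimate_size_factors(counts)
        nrc = pd.DataFrame(bl.normalize_counts(counts, sf),
                           index=counts.gene_ids, columns=counts.sample_ids)
        strata = np.array([
            f"{sex}_{grp}" for sex, grp in zip(meta.frame["sex"], meta.frame["group"])
        ])
        out = bl.stratified_medians(nrc.loc[[gene]], strata, "male_control")
        assert out["pct_female_control"].iloc[0] == pytest.approx(50.0, abs=8.0)
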