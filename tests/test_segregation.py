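from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from buteo.pedigree import Pedigree
from buteo.segregation import (
    COMBINATIONS,
    SCENARIOS,
    CrossTable,
    MorphScheme,
    compare_crosses,
    expected_segregation,
    family_bootstrap_test,
    goodness_of_fit,
    map_morph,
    reconstruct_counts,
    study_cross_table,
    tabulate_crosses,
    STUDY_OBSERVED,
)
from buteo.simulate import MendelianSimConfig, PedigreeSimConfig, simulate_mendelian, simulate_pedigree

from .oracles import exact_multinomial_p, fisher_exact_p

#: one-locus two-allele expected (D, I, L) percentages per parental combination
EXPECTED_BLOCK = {
    "DxD": (100.0, 0.0, 0.0),
    "DxI": (50.0, 50.0, 0.0),
    "DxL": (0.0, 100.0, 0.0),
    "IxI": (25.0, 50.0, 25.0),
    "IxL": (0.0, 50.0, 50.0),
    "LxL": (0.0, 0.0, 100.0),
}


class TestMorphScheme:
    @pytest.mark.parametrize("scenario", sorted(SCENARIOS))
    def test_extremes_fixed_in_every_scenario(self, scenario):
        scheme = SCENARIOS[scenario]
        assert map_morph(1, scheme) == "D"
        assert map_morph(7, scheme) == "L"

    def test_default_scenario_widest_intermediate(self):
        assert map_morph(4, SCENARIOS["1"]) == "I"
        assert [map_morph(s, SCENARIOS["1"]) for s in range(1, 8)] == list("DDIIILL")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_morph(0, SCENARIOS["1"])

    def test_non_monotone_mapping_rejected(self):
        mapping = {1: "D", 2: "I", 3: "D", 4: "I", 5: "I", 6: "L", 7: "L"}
        with pytest.raises(ValueError, match="monotone"):
            MorphScheme("bad", mapping)

    def test_extremes_must_map_to_extremes(self):
        mapping = {s: "I" for s in range(1, 8)}
        with pytest.raises(ValueError, match="extremes"):
            MorphScheme("bad", mapping)


class TestExpectedSegregation:
    @pytest.mark.parametrize("combo,expected", EXPECTED_BLOCK.items())
    def test_gamete_enumeration_block(self, combo, expected):
        assert expected_segregation(combo[0], combo[2]) == expected

    @given(
        p1=st.sampled_from(["D", "I", "L"]),
        p2=st.sampled_from(["D", "I", "L"]),
    )
    @settings(deadline=None)
    def test_symmetric_and_sums_to_100(self, p1, p2):
        triple = expected_segregation(p1, p2)
        assert triple == expected_segregation(p2, p1)
        assert sum(triple) == 100.0


class TestTabulate:
    def test_single_family_counts(self):
        rows = [("S", None, None, "M", 4), ("D", None, None, "F", 3)]
        rows += [("O1", "S", "D", "U", 4), ("O2", "S", "D", "U", 5),
                 ("O3", "S", "D", "U", 1), ("O4", "S", "D", "U", 7)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "morph7"]))
        ct = tabulate_crosses(ped, SCENARIOS["1"])
        assert ct.observed("IxI").tolist() == [1, 2, 1]
        assert ct.n_offspring("IxI") == 4
        assert ct.counts.drop("IxI").to_numpy().sum() == 0

    def test_unscored_parent_skipped_and_counted(self):
        rows = [("S", None, None, "M", None), ("D", None, None, "F", 3),
                ("O1", "S", "D", "U", 4)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "morph7"]))
        ct = tabulate_crosses(ped, SCENARIOS["1"])
        assert ct.counts.to_numpy().sum() == 0
        assert ct.n_skipped == 1

    def test_empty_phenotypes_all_zero(self):
        ped = Pedigree(pd.DataFrame({"id": ["A"], "sire": [None], "dam": [None]}))
        ct = tabulate_crosses(ped, SCENARIOS["1"])
        assert ct.counts.to_numpy().sum() == 0

    def test_mendelian_simulation_matches_expectation(self):
        # large simulated dataset: observed percentages within sampling error
        ped = simulate_pedigree(PedigreeSimConfig(n_pairs=600, seed=42))
        ped = simulate_mendelian(ped, MendelianSimConfig(seed=43))
        ct = tabulate_crosses(ped, SCENARIOS["1"])
        pct = ct.percentages()
        for combo in COMBINATIONS:
            n = ct.n_offspring(combo)
            if n < 50:
                continue
            for m, exp in zip("DIL", EXPECTED_BLOCK[combo]):
                se = 100 * np.sqrt(max(exp / 100 * (1 - exp / 100), 0.25 / n) / n)
                assert abs(pct.loc[combo, f"n_{m}"] - exp) < 4 * se + 1e-9


class TestGoodnessOfFit:
    def expected(self):
        return EXPECTED_BLOCK

    def test_modal_outcome_gives_p_one(self):
        ct = CrossTable.from_counts({"IxI": (25, 50, 25)})
        res = goodness_of_fit(ct, EXPECTED_BLOCK, "IxI")
        assert res.p_value == pytest.approx(1.0)

    def test_observation_in_impossible_class_gives_p_zero(self):
        # D x L expects 100% intermediates; any D or L offspring refutes it
        ct = CrossTable.from_counts({"DxL": (0, 16, 84)})
        res = goodness_of_fit(ct, EXPECTED_BLOCK, "DxL")
        assert res.p_value == 0.0

    @pytest.mark.parametrize("observed", [(2, 5, 3), (0, 0, 10), (10, 0, 0), (4, 4, 2)])
    def test_exact_p_equals_enumeration_oracle(self, observed):
        ct = CrossTable.from_counts({"IxI": observed})
        res = goodness_of_fit(ct, EXPECTED_BLOCK, "IxI")
        oracle = exact_multinomial_p(
            observed, (Fraction(1, 4), Fraction(1, 2), Fraction(1, 4))
        )
        assert res.p_value == pytest.approx(float(oracle), abs=1e-12)

    def test_monte_carlo_close_to_exact_and_needs_seed(self):
        ct = CrossTable.from_counts({"IxI": (10, 20, 20)})
        exact = goodness_of_fit(ct, EXPECTED_BLOCK, "IxI")
        mc = goodness_of_fit(ct, EXPECTED_BLOCK, "IxI", method="monte-carlo",
                             n_resamples=20000, seed=7)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.01)
        assert mc.seed == 7
        with pytest.raises(ValueError, match="seed"):
            goodness_of_fit(ct, EXPECTED_BLOCK, "IxI", method="monte-carlo")

    def test_empty_combination_rejected(self):
        ct = CrossTable.empty()
        with pytest.raises(ValueError, match="no offspring"):
            goodness_of_fit(ct, EXPECTED_BLOCK, "IxI")


class TestCompareCrosses:
    def test_published_counts_reconstruct(self):
        ct = study_cross_table()
        for combo, (n, *pcts) in STUDY_OBSERVED.items():
            assert ct.n_offspring(combo) == n
        assert ct.observed("IxI").tolist() == [39, 191, 28]
        assert ct.observed("DxL").tolist() == [6, 14, 12]

    def test_reconstruction_rejects_inconsistent_percentages(self):
        with pytest.raises(ValueError, match="printed percentage"):
            reconstruct_counts((50.0, 30.0, 20.0), 7)

    def test_headline_contrast_significant(self):
        ct = study_cross_table()
        for method in ("pearson", "exact"):
            res = compare_crosses(ct, "IxI", "DxL", "I", method=method)
            assert res.p_value < 0.001

    def test_identical_proportions_not_significant(self):
        ct = CrossTable.from_counts({"IxI": (5, 10, 5), "DxL": (5, 10, 5)})
        exact = compare_crosses(ct, "IxI", "DxL", "I", method="exact")
        chi2 = compare_crosses(ct, "IxI", "DxL", "I", method="pearson")
        assert exact.p_value == pytest.approx(1.0)
        assert chi2.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("a,b", [((3, 2, 0), (2, 3, 0)), ((1, 4, 0), (4, 1, 0))])
    def test_exact_matches_hypergeometric_oracle(self, a, b):
        ct = CrossTable.from_counts({"IxI": a, "DxL": b})
        res = compare_crosses(ct, "IxI", "DxL", "D", method="exact")
        table = np.array([[a[0], sum(a) - a[0]], [b[0], sum(b) - b[0]]])
        assert res.p_value == pytest.approx(float(fisher_exact_p(table)), abs=1e-12)

    def test_degenerate_margin_warns_p_one(self):
        ct = CrossTable.from_counts({"IxI": (0, 10, 0), "DxL": (0, 5, 0)})
        res = compare_crosses(ct, "IxI", "DxL", "D")
        assert res.p_value == 1.0


def _family_pedigree(seed, combo_sizes, p_focal_by_family):
    """Pedigree of I x I and D x L families with given per-family focal
    (intermediate) probabilities."""
    rng = np.random.default_rng(seed)
    rows = []
    oid = 0
    for combo, fams in combo_sizes.items():
        m1, m2 = (3, 3) if combo == "IxI" else (1, 7)
        for f in range(fams):
            s, d = f"S_{combo}{f}", f"D_{combo}{f}"
            rows.append((s, None, None, "M", m1))
            rows.append((d, None, None, "F", m2))
            p = p_focal_by_family(rng)
            for _ in range(6):
                oid += 1
                morph = 4 if rng.random() < p else 1
                rows.append((f"O{oid}", s, d, "U", morph))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "morph7"]))


class TestFamilyBootstrap:
    def test_complete_separation(self):
        ped = _family_pedigree(
            1, {"IxI": 5, "DxL": 5},
            lambda rng: 1.0,
        )
        # flip DxL families to all non-focal
        t = ped.table.copy()
        dxl = t["sire"].fillna("").str.contains("DxL")
        t.loc[dxl & t["sire"].notna(), "morph7"] = 1
        ped = Pedigree(t)
        res = family_bootstrap_test(ped, SCENARIOS["1"], "IxI", "DxL", "I",
                                    n_boot=999, seed=3)
        assert res.p_value <= 1 / (999 + 1)

    def test_agrees_with_chi_square_without_clustering(self):
        # no between-family heterogeneity: bootstrap p ~ chi-square p
        ped = _family_pedigree(11, {"IxI": 40, "DxL": 40}, lambda rng: 0.6)
        boot = family_bootstrap_test(ped, SCENARIOS["1"], "IxI", "DxL", "I",
                                     n_boot=4000, seed=5)
        ct = tabulate_crosses(ped, SCENARIOS["1"])
        chi2 = compare_crosses(ct, "IxI", "DxL", "I")
        assert abs(boot.p_value - chi2.p_value) < 0.12

    def test_anticonservative_counts_under_clustering(self):
        # strong family clustering: the naive count test overstates evidence,
        # so the bootstrap p should exceed the chi-square p on average
        diffs = []
        for seed in range(8):
            ped = _family_pedigree(
                seed, {"IxI": 12, "DxL": 12},
                lambda rng: 0.95 if rng.random() < 0.5 else 0.05,
            )
            boot = family_bootstrap_test(ped, SCENARIOS["1"], "IxI", "DxL", "I",
                                         n_boot=2000, seed=seed)
            ct = tabulate_crosses(ped, SCENARIOS["1"])
            chi2 = compare_crosses(ct, "IxI", "DxL", "I")
            diffs.append(boot.p_value - chi2.p_value)
        assert np.mean(diffs) > 0

    def test_too_few_families_rejected(self):
        ped = _family_pedigree(2, {"IxI": 1, "DxL": 3}, lambda rng: 0.5)
        with pytest.raises(ValueError, match="fewer than 2 families"):
            family_bootstrap_test(ped, SCENARIOS["1"], "IxI", "DxL", "I",
                                  n_boot=100, seed=1)

    def test_seed_required(self, nuclear_pedigree):
        with pytest.raises(ValueError, match="seed"):
            family_bootstrap_test(nuclear_pedigree, SCENARIOS["1"], "IxI", "DxL", "I")
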