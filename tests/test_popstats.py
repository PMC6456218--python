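"""Population layer: prevalence, proportion tests, BH, Apriori, LDA, viz."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hervk_typer.calling import GenotypeMatrix
from hervk_typer.popstats import (
    StatsError,
    apriori_cooccurrence,
    bh_adjust,
    burden_categories,
    burden_histogram,
    compare_populations,
    compare_proportions,
    comparison_families,
    export_viz_json,
    lda_project,
    prevalence,
)

from _oracles import brute_force_itemsets, step_up_bh


def metadata_for(samples, populations, supers=None):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "population": populations,
            "super_population": supers or populations,
        }
    )


class TestPrevalence:
    def test_direct_fractions(self):
        states = pd.DataFrame(
            {"L": ["provirus_reference"] * 3 + ["solo_LTR"] * 2 + ["absent"] * 5},
            index=[f"s{i}" for i in range(10)],
        )
        geno = GenotypeMatrix(states=states)
        meta = metadata_for(states.index, ["P1"] * 10)
        prev = prevalence(geno, meta)
        assert prev.fraction("L", "P1", "provirus") == pytest.approx(0.30)
        assert prev.fraction("L", "P1", "solo_LTR") == pytest.approx(0.20)
        assert prev.fraction("L", "P1", "absent") == pytest.approx(0.50)

    def test_all_provirus_is_full_prevalence(self):
        states = pd.DataFrame({"L": ["provirus_allele"] * 10},
                              index=[f"s{i}" for i in range(10)])
        geno = GenotypeMatrix(states=states)
        prev = prevalence(geno, metadata_for(states.index, ["P1"] * 10))
        assert prev.fraction("L", "P1") == 1.0

    def test_fractions_sum_to_one_and_counts_to_population_size(self):
        rng = np.random.default_rng(40)
        states = pd.DataFrame(
            rng.choice(
                ["provirus_reference", "provirus_allele", "solo_LTR", "absent"],
                size=(30, 4),
            ),
            index=[f"s{i}" for i in range(30)],
            columns=[f"L{j}" for j in range(4)],
        )
        geno = GenotypeMatrix(states=states)
        meta = metadata_for(states.index, ["P1"] * 15 + ["P2"] * 15)
        table = prevalence(geno, meta).table
        sums = table.provirus_frac + table.solo_LTR_frac + table.absent_frac
        assert np.allclose(sums, 1.0)
        counts = table.provirus + table.solo_LTR + table.absent
        assert (counts == table.n).all()

    def test_samples_without_metadata_are_warned_and_excluded(self):
        states = pd.DataFrame({"L": ["absent"] * 3}, index=["s0", "s1", "ghost"])
        geno = GenotypeMatrix(states=states)
        meta = metadata_for(["s0", "s1"], ["P1", "P1"])
        with pytest.warns(UserWarning, match="ghost"):
            prev = prevalence(geno, meta)
        assert prev.table.n.max() == 2


class TestCompareProportions:
    def test_identical_proportions_give_p_one(self):
        assert compare_proportions(50, 100, 50, 100) == 1.0

    def test_extreme_difference_is_overwhelming(self):
        assert compare_proportions(90, 100, 10, 100) < 1e-10

    def test_degenerate_zero_proportions_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert compare_proportions(0, 10, 0, 10) == 1.0

    def test_symmetry_in_the_two_groups(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            na, nb = rng.integers(5, 200, size=2)
            xa, xb = rng.integers(0, na + 1), rng.integers(0, nb + 1)
            if xa + xb in (0, na + nb):
                continue
            assert compare_proportions(xa, na, xb, nb) == pytest.approx(
                compare_proportions(xb, nb, xa, na)
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            compare_proportions(1, 0, 1, 10)
        with pytest.raises(StatsError):
            compare_proportions(11, 10, 1, 10)

    def test_matches_r_prop_test(self):
        """Cross-check against the R implementation this test mirrors."""
        cases = [(30, 100, 45, 120), (5, 40, 15, 40), (70, 80, 55, 90)]
        script = "\n".join(
            f"cat(sprintf('%.15g', prop.test(c({xa},{xb}), c({na},{nb}))$p.value), '\\n')"
            for xa, na, xb, nb in cases
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_values = [float(v) for v in proc.stdout.split()]
        for (xa, na, xb, nb), expected in zip(cases, r_values):
            assert compare_proportions(xa, na, xb, nb) == pytest.approx(
                expected, rel=1e-9
            )


class TestBhAdjust:
    def test_single_p_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(42)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_definition(self, p_values):
        assert np.allclose(bh_adjust(p_values), step_up_bh(p_values), atol=1e-12)


class TestComparisonFamilies:
    def test_five_superpopulations_give_ten_families(self):
        fams = comparison_families(["AFR", "AMR", "EAS", "EUR", "SAS"])
        assert len(fams) == 10
        assert len(set(fams)) == 10

    def test_compare_populations_adjusts_within_family(self):
        rng = np.random.default_rng(43)
        states = pd.DataFrame(
            rng.choice(["provirus_reference", "absent"], size=(60, 5), p=[0.5, 0.5]),
            index=[f"s{i}" for i in range(60)],
            columns=[f"L{j}" for j in range(5)],
        )
        geno = GenotypeMatrix(states=states)
        meta = metadata_for(states.index, ["P1"] * 20 + ["P2"] * 20 + ["P3"] * 20)
        comp = compare_populations(prevalence(geno, meta))
        assert set(comp.table.family.str.split(":").str[1]) == {
            "P1-P2", "P1-P3", "P2-P3"
        }
        for _, fam in comp.table.groupby("family"):
            assert np.allclose(
                fam.p_adj.to_numpy(), step_up_bh(fam.p_raw.tolist()), atol=1e-12
            )
            assert (fam.p_adj >= fam.p_raw - 1e-12).all()


class TestApriori:
    def presence(self, rows, columns):
        return pd.DataFrame(rows, columns=columns,
                            index=[f"s{i}" for i in range(len(rows))])

    def test_three_loci_zero_support_gives_seven_itemsets(self):
        pres = self.presence([[1, 0, 1], [0, 1, 1]], ["a", "b", "c"])
        result = apriori_cooccurrence(pres.astype(bool), min_support=0.0)
        assert len(result.itemsets) == 7  # 2^3 - 1

    def test_all_ones_matrix_has_full_support_everywhere(self):
        pres = self.presence(np.ones((5, 4), dtype=bool), list("abcd"))
        result = apriori_cooccurrence(pres, min_support=0.5)
        assert len(result.itemsets) == 15
        assert all(v == 1.0 for v in result.itemsets.values())

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(44)
        pres = self.presence(
            rng.random((50, 8)) < 0.55, [f"L{i}" for i in range(8)]
        )
        result = apriori_cooccurrence(pres, min_support=0.2)
        oracle = brute_force_itemsets(pres, 0.2)
        assert result.itemsets == oracle

    def test_support_is_anti_monotone(self):
        rng = np.random.default_rng(45)
        pres = self.presence(rng.random((40, 6)) < 0.6, list("abcdef"))
        result = apriori_cooccurrence(pres, min_support=0.05)
        for s_big, sup_big in result.itemsets.items():
            for s_small, sup_small in result.itemsets.items():
                if s_small < s_big:
                    assert sup_small >= sup_big

    def test_max_size_caps_the_search(self):
        pres = self.presence(np.ones((4, 5), dtype=bool), list("abcde"))
        result = apriori_cooccurrence(pres, min_support=0.0, max_size=2)
        assert max(len(s) for s in result.itemsets) == 2

    def test_per_population_supports(self):
        pres = self.presence([[1, 1], [1, 0], [1, 1], [0, 0]], ["a", "b"])
        meta = metadata_for(pres.index, ["P1", "P1", "P2", "P2"])
        result = apriori_cooccurrence(pres.astype(bool), 0.0, metadata=meta)
        assert result.per_population[frozenset(["a", "b"])] == {
            "P1": 0.5, "P2": 0.5,
        }

    def test_empty_matrix_rejected(self):
        with pytest.raises(StatsError):
            apriori_cooccurrence(pd.DataFrame(), 0.1)

    def test_bad_support_rejected(self):
        pres = self.presence([[1]], ["a"])
        with pytest.raises(StatsError):
            apriori_cooccurrence(pres.astype(bool), 1.5)


class TestLdaProject:
    def test_separated_classes_align_first_axis(self):
        rng = np.random.default_rng(46)
        n = 500
        a = rng.normal(0.0, 1.0, size=(n, 5))
        b = rng.normal(0.0, 1.0, size=(n, 5))
        b[:, 2] += 10.0  # 10 sigma apart in coordinate 2
        X = pd.DataFrame(np.vstack([a, b]))
        y = np.array(["A"] * n + ["B"] * n)
        proj, scalings, sep = lda_project(X, y, n_components=2)
        axis = scalings[:, 0] / np.linalg.norm(scalings[:, 0])
        assert abs(axis[2]) > 0.99
        lo = proj[y == "A"].iloc[:, 0]
        hi = proj[y == "B"].iloc[:, 0]
        assert max(lo.max(), hi.max()) - min(lo.min(), hi.min()) > 0
        assert (lo.max() < hi.min()) or (hi.max() < lo.min())  # separable
        assert sep[("A", "B")] > 50

    def test_identical_distributions_score_below_permutation_null(self):
        rng = np.random.default_rng(47)
        X = pd.DataFrame(rng.normal(size=(100, 4)))
        y = np.array(["A"] * 50 + ["B"] * 50)
        _, _, sep = lda_project(X, y)
        observed = sep[("A", "B")]
        null = []
        for _ in range(60):
            perm = rng.permutation(y)
            _, _, s = lda_project(X, perm)
            null.append(s[("A", "B")])
        assert observed < np.quantile(null, 0.95)

    def test_informative_feature_gets_largest_loading(self):
        rng = np.random.default_rng(48)
        n = 60
        X = rng.normal(size=(2 * n, 6))
        y = np.array(["A"] * n + ["B"] * n)
        X[n:, 4] += 4.0
        _, scalings, _ = lda_project(pd.DataFrame(X), y, n_components=1)
        loadings = np.abs(scalings[:, 0])
        assert np.argmax(loadings) == 4

    def test_degenerate_classes_rejected(self):
        X = pd.DataFrame(np.random.default_rng(49).normal(size=(4, 2)))
        with pytest.raises(StatsError):
            lda_project(X, np.array(["A"] * 4))
        with pytest.raises(StatsError):
            lda_project(X, np.array(["A", "A", "A", "B"]))


class TestBurdenHistogram:
    def test_twenty_loci_give_twenty_one_categories(self):
        assert burden_categories(20) == list(range(21))
        assert len(burden_categories(20)) == 21

    def test_histogram_counts_individuals(self):
        burdens = pd.Series([2, 2, 3, 0], index=["s0", "s1", "s2", "s3"])
        meta = metadata_for(burdens.index, ["P1", "P1", "P2", "P2"])
        hist = burden_histogram(burdens, meta, n_loci=4)
        assert hist.loc[2, "P1"] == 2
        assert hist.loc[3, "P2"] == 1
        assert hist.to_numpy().sum() == 4
        assert list(hist.index) == list(range(5))


class TestVizExport:
    def make_inputs(self):
        states = pd.DataFrame(
            {
                "c19a": ["provirus_reference"] * 4 + ["absent"] * 4,
                "c19b": ["provirus_allele"] * 6 + ["absent"] * 2,
                "c19c": ["provirus_reference"] * 8,
            },
            index=[f"s{i}" for i in range(8)],
        )
        geno = GenotypeMatrix(states=states)
        meta = metadata_for(states.index, ["P1"] * 4 + ["P2"] * 4)
        info = pd.DataFrame(
            {
                "locus_id": ["c19a", "c19b", "c19c"],
                "chrom": ["chr19"] * 3,
                "start": [100, 500, 900],
                "end": [200, 600, 1000],
            }
        )
        return geno, meta, info

    def test_cooccurrence_is_and_over_selected_columns(self, tmp_path):
        geno, meta, info = self.make_inputs()
        payload = export_viz_json(
            geno, ["c19a", "c19b", "c19c"], info, meta,
            path=tmp_path / "viz.json",
        )
        by_pop = {p["id"]: p for p in payload["populations"]}
        assert by_pop["P1"]["cooccurrence_prevalence"] == 1.0
        assert by_pop["P2"]["cooccurrence_prevalence"] == 0.0
        reloaded = json.loads((tmp_path / "viz.json").read_text())
        assert reloaded["loci"][0]["label"] == "chr19:101-200"
        assert len(reloaded["matrix"]) == 8

    def test_single_locus_equals_its_prevalence(self):
        geno, meta, info = self.make_inputs()
        payload = export_viz_json(geno, ["c19b"], info, meta)
        by_pop = {p["id"]: p for p in payload["populations"]}
        prev = prevalence(geno, meta)
        for pop in ("P1", "P2"):
            assert by_pop[pop]["cooccurrence_prevalence"] == pytest.approx(
                prev.fraction("c19b", pop)
            )

    def test_empty_selection_rejected(self):
        geno, meta, info = self.make_inputs()
        with pytest.raises(StatsError):
            export_viz_json(geno, [], info, meta)

    def test_unknown_locus_rejected(self):
        geno, meta, info = self.make_inputs()
        with pytest.raises(StatsError):
            export_viz_json(geno, ["nope"], info, meta)
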