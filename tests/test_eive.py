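import itertools

import numpy as np
import pytest

from paraniche.cover import AggregatedPlot, aggregate_dataset
from paraniche.data import TraitRecord
from paraniche.eive import (aggregate_eive, fill_aggregate_eive,
                            modified_permutation_test, observed_difference,
                            permutation_tests_all, plot_mean_eive)

from conftest import make_trait


class TestAggregateEive:
    def test_mean_over_members(self):
        members = [make_trait("a", eive_n=3.0), make_trait("b", eive_n=5.0)]
        assert aggregate_eive(members)["N"] == 4.0

    def test_missing_member_skipped(self):
        members = [make_trait("a", eive_n=3.0), make_trait("b")]
        assert aggregate_eive(members)["N"] == 3.0

    def test_no_data_propagates_missing(self):
        assert aggregate_eive([make_trait("a")])["N"] is None

    def test_fill_aggregate_from_members(self):
        traits = [
            make_trait("a", eive_n=2.0),
            make_trait("b", eive_n=6.0),
            TraitRecord("agg", "autotroph", is_aggregate=True, member_taxa=["a", "b"]),
        ]
        filled = {t.taxon_id: t for t in fill_aggregate_eive(traits)}
        assert filled["agg"].eive_n == 4.0


def _plot(pid, taxa):
    p = AggregatedPlot(plot_id=pid)
    for t in taxa:
        p.species_cover[t] = 10.0
    return p


class TestPlotMeanEive:
    TRAITS = {
        "a1": make_trait("a1", eive_n=2.0),
        "a2": make_trait("a2", eive_n=4.0),
        "h1": make_trait("h1", "euphytoid", eive_n=5.0),
    }

    def test_unweighted_mean(self):
        assert plot_mean_eive(_plot("p", ["a1", "a2"]), self.TRAITS, "N") == 3.0

    def test_focal_type_excluded(self):
        plot = _plot("p", ["a1", "a2", "h1"])
        assert plot_mean_eive(plot, self.TRAITS, "N", exclude_type="euphytoid") == 3.0

    def test_only_focal_type_gives_missing(self):
        plot = _plot("p", ["h1"])
        assert plot_mean_eive(plot, self.TRAITS, "N", exclude_type="euphytoid") is None

    def test_explicit_taxon_exclusion(self):
        plot = _plot("p", ["a1", "a2"])
        assert plot_mean_eive(plot, self.TRAITS, "N", exclude_taxa=["a1"]) == 4.0


class TestObservedDifference:
    def test_worked_examples(self):
        assert observed_difference([4.0, 6.0], [3.0, 3.0]) == 2.0
        assert observed_difference([3.0], [3.0]) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            observed_difference([], [3.0])

    def test_injected_shift_recovered(self, synth_2000_agg):
        dataset, truth, agg = synth_2000_agg
        traits = dataset.trait_map()
        for ftype, delta in truth.eive_shift.items():
            occ, unocc = [], []
            for plot in agg.values():
                m = plot_mean_eive(plot, traits, "N", exclude_type=ftype)
                if m is None:
                    continue
                (occ if plot.type_presence.get(ftype) else unocc).append(m)
            diff = observed_difference(occ, unocc)
            assert diff == pytest.approx(delta, abs=0.2)


def _toy_three_species():
    """3 species with distinct N values; the focal parasite sits in two plots."""
    traits = {
        "a1": make_trait("a1", eive_n=2.0),
        "a2": make_trait("a2", eive_n=8.0),
        "h1": make_trait("h1", "euphytoid", eive_n=5.0),
    }
    plots = {
        "p1": _plot("p1", ["a1", "h1"]),
        "p2": _plot("p2", ["a2", "h1"]),
        "p3": _plot("p3", ["a1", "a2"]),
        "p4": _plot("p4", ["a1"]),
    }
    for p in plots.values():
        for t in p.species_cover:
            p.type_presence["euphytoid"] = p.type_presence.get("euphytoid", 0) or (
                1 if traits[t].functional_type == "euphytoid" else 0)
    return plots, traits


def _enumeration_oracle(plots, traits):
    """Brute-force permutation distribution over all value assignments."""
    species = sorted(t for t in traits)
    values = [traits[s].eive_n for s in species]
    occupied = {p for p, plot in plots.items() if plot.type_presence.get("euphytoid")}
    diffs = []
    for perm in itertools.permutations(values):
        val = dict(zip(species, perm))
        means = {}
        for pid, plot in plots.items():
            vs = [val[t] for t in plot.species_cover
                  if traits[t].functional_type != "euphytoid"]
            if vs:
                means[pid] = np.mean(vs)
        occ = [m for p, m in means.items() if p in occupied]
        unocc = [m for p, m in means.items() if p not in occupied]
        diffs.append(np.mean(occ) - np.mean(unocc))
    return np.array(diffs)


class TestModifiedPermutationTest:
    def test_exact_enumeration_matches_bruteforce_oracle(self):
        plots, traits = _toy_three_species()
        result = modified_permutation_test(plots, traits, "euphytoid", "N", exact=True)
        diffs = _enumeration_oracle(plots, traits)
        assert result.n_perm == 6
        assert sorted(result.null_diffs) == pytest.approx(sorted(diffs))
        if result.ses > 0:
            expect_p = np.sum(diffs >= result.diff_real) / len(diffs)
        else:
            expect_p = np.sum(diffs <= result.diff_real) / len(diffs)
        assert result.p == expect_p

    def test_seed_reproducible(self, synth_2000_agg):
        dataset, _, agg = synth_2000_agg
        traits = dataset.trait_map()
        a = modified_permutation_test(agg, traits, "euphytoid", "N", n_perm=99, seed=4)
        b = modified_permutation_test(agg, traits, "euphytoid", "N", n_perm=99, seed=4)
        assert a.null_diffs == b.null_diffs and a.p == b.p and a.ses == b.ses

    def test_injected_shift_detected(self, synth_2000_agg):
        dataset, truth, agg = synth_2000_agg
        traits = dataset.trait_map()
        result = modified_permutation_test(agg, traits, "euphytoid", "N",
                                           n_perm=199, seed=0)
        assert result.ses < -2.0  # configured negative nitrogen shift
        assert result.p < 0.05
        assert np.sign(result.diff_real) == np.sign(truth.eive_shift["euphytoid"])

    def test_degenerate_null_sd_zero(self):
        traits = {
            "a1": make_trait("a1", eive_n=4.0),
            "a2": make_trait("a2", eive_n=4.0),
            "h1": make_trait("h1", "euphytoid", eive_n=4.0),
        }
        plots, _ = _toy_three_species()
        result = modified_permutation_test(plots, traits, "euphytoid", "N", exact=True)
        assert result.ses is None and result.p == 1.0

    def test_joint_mode_reproducible_and_consistent(self, synth_2000_agg):
        dataset, _, agg = synth_2000_agg
        traits = dataset.trait_map()
        res = permutation_tests_all(agg, traits, "euphytoid", indicators=("N", "M"),
                                    n_perm=49, seed=1, joint=True)
        res2 = permutation_tests_all(agg, traits, "euphytoid", indicators=("N", "M"),
                                     n_perm=49, seed=1, joint=True)
        assert set(res) == {"N", "M"}
        for ind in res:
            assert res[ind].null_diffs == res2[ind].null_diffs
            assert res[ind].p == res2[ind].p

    def test_two_sided_p_doubles_directional(self):
        plots, traits = _toy_three_species()
        result = modified_permutation_test(plots, traits, "euphytoid", "N", exact=True)
        assert result.p_two_sided == min(1.0, 2.0 * result.p)
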