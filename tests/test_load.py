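"""Genetic-load proxy, clade comparisons and rare-variant fractions."""

import numpy as np
import pytest

from purgescan.load import (
    clade_load_table,
    load_reports,
    pis_load_relation,
    rare_fraction,
    sample_load,
)
from purgescan.popstats import SFS
from purgescan.variant_io import MISSING, CladeMap


def matrix(dn, ff):
    """Stack dnSNP rows then fourfold rows into one derived-dosage matrix."""
    dn, ff = np.asarray(dn, dtype=np.int8), np.asarray(ff, dtype=np.int8)
    derived = np.vstack([dn, ff])
    return derived, np.arange(len(dn)), len(dn) + np.arange(len(ff))


class TestSampleLoad:
    def test_worked_example(self):
        # het at one dnSNP + hom-derived at another (dosage 3) over 30
        # derived fourfold alleles -> 0.1
        dn = [[1], [2]]
        ff = [[2]] * 15
        derived, dn_rows, ff_rows = matrix(dn, ff)
        rep = sample_load(derived, dn_rows, ff_rows, 0, "s")
        assert rep.derived_dnsnp_alleles == 3
        assert rep.derived_fourfold_alleles == 30
        assert rep.load_proxy == pytest.approx(0.1)

    def test_zero_dnsnp_dosage_gives_zero_load(self):
        derived, dn_rows, ff_rows = matrix([[0], [0]], [[1], [2]])
        assert sample_load(derived, dn_rows, ff_rows, 0, "s").load_proxy == 0.0

    def test_zero_denominator_flagged_undefined(self):
        derived, dn_rows, ff_rows = matrix([[1]], [[0]])
        rep = sample_load(derived, dn_rows, ff_rows, 0, "s")
        assert not rep.defined and np.isnan(rep.load_proxy)

    def test_missing_calls_excluded(self):
        derived, dn_rows, ff_rows = matrix([[MISSING], [2]], [[2], [MISSING]])
        rep = sample_load(derived, dn_rows, ff_rows, 0, "s")
        assert rep.derived_dnsnp_alleles == 2
        assert rep.derived_fourfold_alleles == 2
        assert rep.n_called_dnsnp_sites == 1

    def test_overlapping_site_sets_rejected(self):
        derived = np.zeros((3, 1), dtype=np.int8)
        with pytest.raises(ValueError, match="disjoint"):
            sample_load(derived, np.array([0, 1]), np.array([1, 2]), 0, "s")

    def test_carrier_counting_variant(self):
        derived, dn_rows, ff_rows = matrix([[2], [2]], [[2], [1]])
        rep = sample_load(derived, dn_rows, ff_rows, 0, "s", counting="carrier")
        assert rep.derived_dnsnp_alleles == 2  # two carrier sites
        assert rep.derived_fourfold_alleles == 2

    def test_invariant_to_monomorphic_and_duplicated_sites(self):
        rng = np.random.default_rng(0)
        dn = rng.integers(0, 3, size=(10, 4))
        ff = rng.integers(0, 3, size=(20, 4))
        derived, dn_rows, ff_rows = matrix(dn, ff)
        base = sample_load(derived, dn_rows, ff_rows, 2, "s").load_proxy
        # add monomorphic (all-zero) sites: ratio unchanged
        derived2, dn2, ff2 = matrix(
            np.vstack([dn, np.zeros((5, 4), int)]), np.vstack([ff, np.zeros((5, 4), int)])
        )
        assert sample_load(derived2, dn2, ff2, 2, "s").load_proxy == pytest.approx(base)
        # duplicate every site: ratio unchanged (scale invariance)
        derived3, dn3, ff3 = matrix(np.vstack([dn, dn]), np.vstack([ff, ff]))
        assert sample_load(derived3, dn3, ff3, 2, "s").load_proxy == pytest.approx(base)


class TestCladeTable:
    def reports(self, values_by_clade):
        derived_rows = []
        samples, clades = [], {}
        for clade, vals in values_by_clade.items():
            for i, v in enumerate(vals):
                name = f"{clade}_{i}"
                samples.append(name)
                clades[name] = clade
                derived_rows.append(v)
        # one dnSNP site with dosage v*10, ten fourfold sites with dosage 1
        n = len(samples)
        dn = np.array([[v * 10 for v in derived_rows]], dtype=np.int8)
        ff = np.ones((5, n), dtype=np.int8) * 2
        derived = np.vstack([dn, ff])
        cm = CladeMap(clades)
        reps = load_reports(derived, np.array([0]), 1 + np.arange(5), samples, cm)
        return reps, cm

    def test_identical_clades_null(self):
        reps, cm = self.reports({"A": [0.1, 0.2, 0.3], "B": [0.1, 0.2, 0.3]})
        summary, pairs = clade_load_table(reps, cm)
        meds = dict(zip(summary["clade"], summary["median_load"]))
        assert meds["A"] == meds["B"]
        assert pairs.loc[0, "p_value"] > 0.9

    def test_lower_median_clade_identified(self):
        reps, cm = self.reports({"A": [0.1, 0.1, 0.1], "B": [0.2, 0.2, 0.2]})
        summary, _ = clade_load_table(reps, cm)
        meds = dict(zip(summary["clade"], summary["median_load"]))
        assert meds["A"] < meds["B"]

    def test_bh_adjustment_matches_step_up_by_hand(self):
        reps, cm = self.reports(
            {"A": [0.0, 0.0, 0.1], "B": [0.1, 0.2, 0.2], "C": [0.3, 0.4, 0.4]}
        )
        _, pairs = clade_load_table(reps, cm)
        p = pairs["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        assert np.allclose(pairs["p_adj_bh"].to_numpy(), adj)

    def test_singleton_clade_kept_in_medians_not_tests(self):
        reps, cm = self.reports({"A": [0.1, 0.2], "B": [0.3, 0.4], "C": [0.5]})
        summary, pairs = clade_load_table(reps, cm)
        assert set(summary["clade"]) == {"A", "B", "C"}
        tested = set(pairs["clade_a"]) | set(pairs["clade_b"])
        assert "C" not in tested


class TestPisLoadRelation:
    def test_collinear_pearson_one(self):
        rel = pis_load_relation({"a": 1, "b": 2, "c": 3}, {"a": 2, "b": 4, "c": 6})
        assert rel["pearson_r"] == pytest.approx(1.0)

    def test_antiordered_spearman_minus_one(self):
        rel = pis_load_relation({"a": 1, "b": 2, "c": 3}, {"a": 9, "b": 5, "c": 1})
        assert rel["spearman_rho"] == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        rel = pis_load_relation({"a": 1, "b": 1, "c": 1}, {"a": 1, "b": 2, "c": 3})
        assert np.isnan(rel["pearson_r"])

    def test_needs_three_clades(self):
        with pytest.raises(ValueError):
            pis_load_relation({"a": 1, "b": 2}, {"a": 1, "b": 2})


class TestRareFraction:
    def test_worked_example(self):
        sfs = SFS(n=4, counts=np.array([8.0, 1.0, 1.0]))
        assert rare_fraction(sfs, 0.3) == pytest.approx(0.8)

    def test_threshold_one_includes_everything(self):
        sfs = SFS(n=4, counts=np.array([8.0, 1.0, 1.0]))
        assert rare_fraction(sfs, 1.0) == 1.0

    def test_empty_sfs_undefined(self):
        sfs = SFS(n=4, counts=np.zeros(3))
        assert np.isnan(rare_fraction(sfs, 0.1))
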