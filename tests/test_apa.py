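import math
import random

import numpy as np
import pandas as pd
import pytest

from endcall import major_isoform, switch_catalog, utr_length_stats
from endcall import test_switch as switch_one_gene
from endcall import test_switches_genomewide as switch_genomewide
from endcall.apa_switching import (DISTAL_SHIFT, PROXIMAL_SHIFT,
                                   fisher_two_sided)
from oracles import fisher_exact_oracle


def counts_df(rows, samples):
    idx = pd.MultiIndex.from_tuples(rows.keys(),
                                    names=["gene_id", "cluster_id"])
    return pd.DataFrame(list(rows.values()), index=idx, columns=samples)


class TestMajorIsoform:
    ORDER = {"i1": 1, "i2": 2}

    def test_plain_maximum(self):
        assert major_isoform(pd.Series({"i1": 70, "i2": 30}), self.ORDER) == "i1"

    def test_tie_goes_distal(self):
        assert major_isoform(pd.Series({"i1": 50, "i2": 50}), self.ORDER) == "i2"

    def test_single_isoform(self):
        assert major_isoform(pd.Series({"i1": 9}), self.ORDER) == "i1"

    def test_zero_total_none(self):
        assert major_isoform(pd.Series({"i1": 0, "i2": 0}), self.ORDER) is None


class TestFisherExact:
    def test_worked_table(self):
        """[[8,2],[2,8]] has exactly 4252/184756 two-sided mass."""
        p = fisher_two_sided(((8, 2), (2, 8)))
        assert math.isclose(p, 4252 / 184756, rel_tol=1e-12)
        assert math.isclose(fisher_exact_oracle(((8, 2), (2, 8))),
                            4252 / 184756, rel_tol=1e-15)

    def test_complete_switch_vanishing_p(self):
        assert fisher_two_sided(((100, 0), (0, 100))) < 1e-20

    def test_no_association_p_one(self):
        assert fisher_two_sided(((50, 50), (50, 50))) == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self):
        rng = random.Random(11)
        for _ in range(200):
            n = rng.randint(1, 60)
            a = rng.randint(0, n)
            b = rng.randint(0, n - a)
            c = rng.randint(0, n - a - b)
            d = n - a - b - c
            table = ((a, b), (c, d))
            assert math.isclose(fisher_two_sided(table),
                                fisher_exact_oracle(table),
                                rel_tol=1e-9, abs_tol=1e-12)

    def test_symmetric_in_condition_labels(self):
        rng = random.Random(5)
        for _ in range(50):
            t = [[rng.randint(0, 30) for _ in range(2)] for _ in range(2)]
            p1 = fisher_two_sided((tuple(t[0]), tuple(t[1])))
            p2 = fisher_two_sided((tuple(t[1]), tuple(t[0])))
            assert math.isclose(p1, p2, rel_tol=1e-9, abs_tol=1e-12)


class TestTestSwitch:
    def test_isoform_vs_rest_tables(self):
        counts = pd.DataFrame({"A": [60, 30, 10], "B": [10, 30, 60]},
                              index=["i1", "i2", "i3"])
        res = switch_one_gene("g", counts, "A", "B")
        assert [r.table for r in res] == [
            ((60, 40), (10, 90)), ((30, 70), (30, 70)), ((10, 90), (60, 40))]
        assert res[0].usage_a == 0.6 and res[0].usage_b == 0.1

    def test_zero_condition_total_skips_gene(self):
        counts = pd.DataFrame({"A": [60, 40], "B": [0, 0]}, index=["i1", "i2"])
        assert switch_one_gene("g", counts, "A", "B") == []

    def test_low_coverage_gate(self):
        counts = pd.DataFrame({"A": [5, 4], "B": [4, 5]}, index=["i1", "i2"])
        assert switch_one_gene("g", counts, "A", "B", min_reads=20) == []

    def test_single_isoform_not_tested(self):
        counts = pd.DataFrame({"A": [60], "B": [40]}, index=["i1"])
        assert switch_one_gene("g", counts, "A", "B") == []


class TestGenomewide:
    def make_counts(self):
        return counts_df({
            ("g1", "i1"): [90, 95, 10, 12],     # switches
            ("g1", "i2"): [10, 8, 90, 88],
            ("g2", "i1"): [50, 52, 49, 50],     # stable
            ("g2", "i2"): [50, 48, 51, 50],
        }, ["A1", "A2", "B1", "B2"])

    CONDS = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}

    def test_bh_is_monotone_and_bounds_p(self):
        res = switch_genomewide(self.make_counts(), self.CONDS, "A", "B")
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)
        assert all(r.q_value >= r.p_value - 1e-12 for r in res)

    def test_switched_gene_detected_stable_not(self):
        res = switch_genomewide(self.make_counts(), self.CONDS, "A", "B")
        sig = {r.gene_id for r in res if r.significant}
        assert sig == {"g1"}

    def test_catalog_directions(self):
        counts = self.make_counts()
        res = switch_genomewide(counts, self.CONDS, "A", "B")
        order = {"i1": 1, "i2": 2}
        catalog, summary = switch_catalog(res, counts, self.CONDS, "A", "B",
                                          order)
        (entry,) = catalog
        assert entry.gene_id == "g1"
        assert entry.direction == DISTAL_SHIFT      # major moves i1 -> i2
        assert summary[DISTAL_SHIFT] == 1 and summary[PROXIMAL_SHIFT] == 0

    def test_significant_without_major_change_counted_separately(self):
        counts = counts_df({
            ("g1", "i1"): [90, 90, 60, 60],   # still major in both
            ("g1", "i2"): [10, 10, 40, 40],
        }, ["A1", "A2", "B1", "B2"])
        res = switch_genomewide(counts, self.CONDS, "A", "B")
        assert any(r.significant for r in res)
        catalog, summary = switch_catalog(res, counts, self.CONDS, "A", "B",
                                          {"i1": 1, "i2": 2})
        assert catalog == [] and summary["usage_change_only"] == 1


class TestUtrLengthStats:
    def test_median(self):
        s = utr_length_stats(pd.Series([10, 72, 300]))
        assert s["median"] == 72 and s["n"] == 3

    def test_top_expression_exclusion(self):
        lengths = pd.Series({"a": 10, "b": 100, "c": 200})
        expr = pd.Series({"a": 1000, "b": 10, "c": 5})
        s = utr_length_stats(lengths, expression=expr,
                             exclude_top_fraction=1 / 3)
        assert s["median"] == 150 and s["n"] == 2

    def test_gene_family_exclusion(self):
        lengths = pd.Series({"rpl-1": 30, "b": 100, "c": 200})
        s = utr_length_stats(lengths, exclude_genes={"rpl-1"})
        assert s["median"] == 150

    def test_single_isoform(self):
        assert utr_length_stats(pd.Series([42]))["median"] == 42

    def test_empty_after_exclusion(self):
        s = utr_length_stats(pd.Series({"a": 10}), exclude_genes={"a"})
        assert s["n"] == 0 and math.isnan(s["median"])
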