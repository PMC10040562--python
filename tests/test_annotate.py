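"""Feature assignment, category tables, superfamily/family summaries and
cross-genotype overlap decomposition."""

import numpy as np
import pytest

from methyldmr.annotate import (GENE_BODY, GENE_ELEMENT_AND_TE, OTHER,
                                PROMOTER, TE, DmrAssignment, assign_dmr,
                                assign_dmrs, family_representation,
                                format_fraction, overlap_summary, percent,
                                superfamily_summary, tabulate_categories)
from methyldmr.dmr import Dmr
from methyldmr.io import (FeatureSet, Gene, GenomicInterval,
                          TransposableElement)


def dmr(start, end, direction="hypo", context="CHH", chrom="chr1"):
    return Dmr(location=GenomicInterval(chrom, start, end), context=context,
               direction=direction, wt_level=0.5, mut_level=0.2,
               n_sites=25, p_value=1e-5, counts=(50, 50, 20, 80))


def feature_set(genes=(), tes=(), length=100_000):
    return FeatureSet(genes=list(genes), tes=list(tes),
                      genome={"chr1": length})


class TestAssignDmr:
    def test_exact_half_overlap_is_gene_body(self):
        # minus strand puts the promoter at [500, 700), well clear
        fs = feature_set(genes=[Gene(
            "g1", GenomicInterval("chr1", 150, 500, "-"), "-")])
        a = assign_dmr(dmr(100, 200), fs)
        assert a.category == GENE_BODY
        assert a.gene_ids == ("g1",)

    def test_te_match_and_combination_with_gene(self):
        te = TransposableElement("t1", "F", "SINE",
                                 GenomicInterval("chr1", 149, 500))
        a = assign_dmr(dmr(100, 200), feature_set(tes=[te]))
        assert a.category == TE and a.te_ids == ("t1",)
        gene = Gene("g1", GenomicInterval("chr1", 100, 600, "+"), "+")
        b = assign_dmr(dmr(100, 200), feature_set(genes=[gene], tes=[te]))
        assert b.category == GENE_ELEMENT_AND_TE
        assert b.gene_element == GENE_BODY

    def test_sub_threshold_overlaps_are_other(self):
        fs = feature_set(
            genes=[Gene("g1", GenomicInterval("chr1", 151, 500, "-"), "-")],
            tes=[TransposableElement("t1", "F", "SINE",
                                     GenomicInterval("chr1", 5000, 5049))])
        # both overlaps are 49/100 < 50%
        assert assign_dmr(dmr(100, 200), fs).category == OTHER
        assert assign_dmr(dmr(4951, 5051), fs).category == OTHER

    def test_promoter_takes_precedence_over_body(self):
        # minus-strand gene: promoter [500, 700); a DMR covering the
        # junction can reach 50% on both promoter and body
        g = Gene("g1", GenomicInterval("chr1", 100, 500, "-"), "-")
        a = assign_dmr(dmr(400, 600), feature_set(genes=[g]))
        assert a.gene_element == PROMOTER
        assert a.category == PROMOTER

    def test_te_inside_gene_intron_matches_both(self):
        gene = Gene("g1", GenomicInterval("chr1", 1000, 9000, "+"), "+")
        te = TransposableElement("t1", "F", "LTR/Gypsy",
                                 GenomicInterval("chr1", 4000, 5000))
        a = assign_dmr(dmr(4200, 4400),
                       feature_set(genes=[gene], tes=[te]))
        assert a.category == GENE_ELEMENT_AND_TE
        assert a.gene_ids == ("g1",) and a.te_ids == ("t1",)

    def test_assignment_order_independent(self):
        fs = feature_set(
            tes=[TransposableElement(f"t{i}", "F", "SINE",
                                     GenomicInterval("chr1", 100 * i,
                                                     100 * i + 80))
                 for i in range(1, 20)])
        dmrs = [dmr(100 * i, 100 * i + 80) for i in range(1, 20)]
        fwd = [a.category for a in assign_dmrs(dmrs, fs)]
        rev = [a.category for a in assign_dmrs(dmrs[::-1], fs)][::-1]
        assert fwd == rev


class TestTabulateCategories:
    def _assignments(self, n_te, n_total, direction="hyper"):
        out = []
        for i in range(n_total):
            d = dmr(1000 * i, 1000 * i + 100, direction=direction)
            cat = TE if i < n_te else OTHER
            out.append(DmrAssignment(dmr=d, category=cat,
                                     te_ids=("x",) if cat == TE else ()))
        return out

    def test_te_percentage(self):
        table = tabulate_categories(self._assignments(155, 231),
                                    direction_split=False)
        row = table.iloc[0]
        assert row["total"] == 231
        assert row["te"] == 155
        assert row["te_pct"] == 67.1

    def test_empty_input_all_zero(self):
        table = tabulate_categories([])
        assert (table["total"] == 0).all()

    def test_disjoint_category_percentages_sum_to_100(self, rng):
        cats = [PROMOTER, GENE_BODY, TE, GENE_ELEMENT_AND_TE, OTHER]
        assignments = []
        for i in range(rng.integers(50, 400)):
            cat = cats[rng.integers(0, len(cats))]
            a = DmrAssignment(
                dmr=dmr(100 * i, 100 * i + 50,
                        direction="hypo" if rng.random() < 0.5 else "hyper"),
                category=cat,
                gene_element=(PROMOTER if cat == PROMOTER
                              else GENE_BODY if cat in (GENE_BODY,
                                                        GENE_ELEMENT_AND_TE)
                              else None),
                te_ids=("x",) if cat in (TE, GENE_ELEMENT_AND_TE) else ())
            assignments.append(a)
        table = tabulate_categories(assignments).set_index("type")
        for row_name in ("hypermethylated", "hypomethylated", "total"):
            row = table.loc[row_name]
            if row["total"] == 0:
                continue
            # mutually exclusive decomposition: promoter-only, body-only,
            # te-only, both, other
            disjoint = (row["gene_elements_pct"] + row["te_pct"]
                        + row["other_pct"] - row["gene_element_and_te_pct"])
            assert disjoint == pytest.approx(100.0, abs=0.3)


class TestSuperfamilySummary:
    def _fixture(self):
        tes = []
        sfs = ["LTR/Gypsy"] * 4 + ["DNA/MuDR"] * 3 + ["SINE"] * 3
        for i, sf in enumerate(sfs):
            tes.append(TransposableElement(
                f"t{i}", f"fam{sf[:2]}", sf,
                GenomicInterval("chr1", 1000 * i, 1000 * i + 500)))
        fs = feature_set(tes=tes)
        assignments = [DmrAssignment(
            dmr=dmr(1000 * i, 1000 * i + 100,
                    direction="hypo" if i % 2 else "hyper"),
            category=TE, te_ids=(f"t{i}",)) for i in range(10)]
        return fs, assignments

    def test_proportions(self):
        fs, assignments = self._fixture()
        table = superfamily_summary(assignments, fs).set_index(
            "superfamily")
        assert table.loc["LTR/Gypsy", "n_tes"] == 4
        assert table.loc["LTR/Gypsy", "proportion"] == pytest.approx(0.4)

    def test_direction_partition(self):
        fs, assignments = self._fixture()
        total = superfamily_summary(assignments, fs, "all")
        hypo = superfamily_summary(assignments, fs, "hypo")
        hyper = superfamily_summary(assignments, fs, "hyper")

        def as_dict(t):
            return dict(zip(t["superfamily"], t["n_tes"]))

        combined = as_dict(hypo)
        for sf, n in as_dict(hyper).items():
            combined[sf] = combined.get(sf, 0) + n
        assert combined == as_dict(total)

    def test_counts_equal_brute_force(self):
        fs, assignments = self._fixture()
        table = superfamily_summary(assignments, fs)
        lookup = fs.te_by_id()
        brute = {}
        seen = set()
        for a in assignments:
            for tid in a.te_ids:
                if tid not in seen:
                    seen.add(tid)
                    sf = lookup[tid].superfamily
                    brute[sf] = brute.get(sf, 0) + 1
        assert dict(zip(table["superfamily"], table["n_tes"])) == brute

    def test_missing_te_is_error(self):
        fs, _ = self._fixture()
        bad = [DmrAssignment(dmr=dmr(0, 100), category=TE,
                             te_ids=("nope",))]
        with pytest.raises(KeyError):
            superfamily_summary(bad, fs)

    def test_others_folding(self):
        fs, assignments = self._fixture()
        table = superfamily_summary(assignments, fs, min_proportion=0.35)
        assert set(table["superfamily"]) == {"LTR/Gypsy", "Others"}
        assert int(table.set_index("superfamily").loc["Others",
                                                      "n_tes"]) == 6


class TestFamilyRepresentation:
    def _fs(self, size, n_families=1):
        tes = []
        for f in range(n_families):
            for i in range(size):
                tes.append(TransposableElement(
                    f"t{f}_{i}", f"fam{f}", "SINE",
                    GenomicInterval("chr1", 1000 * (f * size + i),
                                    1000 * (f * size + i) + 500)))
        return feature_set(tes=tes, length=10_000_000)

    def _assign(self, te_ids, direction="hyper"):
        return [DmrAssignment(dmr=dmr(i * 10, i * 10 + 5,
                                      direction=direction),
                              category=TE, te_ids=(tid,))
                for i, tid in enumerate(te_ids)]

    def test_above_threshold_included(self):
        fs = self._fs(20)
        table = family_representation(
            self._assign(["t0_0", "t0_1", "t0_2"]), fs)
        assert table["family"].tolist() == ["fam0"]
        assert table["n_targeted"].iloc[0] == 3

    def test_exactly_at_threshold_excluded(self):
        fs = self._fs(20)
        table = family_representation(self._assign(["t0_0", "t0_1"]), fs)
        assert table.empty  # 2/20 == 10%, strict inequality required

    def test_result_order_invariant(self):
        fs = self._fs(20, n_families=2)
        ids = ["t0_0", "t0_1", "t0_2", "t1_0", "t1_5", "t1_9"]
        a = family_representation(self._assign(ids), fs)
        b = family_representation(self._assign(ids[::-1]), fs)
        assert a.equals(b)


class TestOverlapSummary:
    def test_hand_enumeration(self):
        s = overlap_summary({"A": {1, 2, 3}, "B": {3, 4}, "C": {4, 5}})
        assert s.unique("A") == 2
        assert s.unique_fraction("A") == "66.67% (2/3)"
        assert s.shared("A", "B") == 1
        assert s.shared("A", "B", "C") == 0

    def test_identical_sets(self):
        s = overlap_summary({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        for label in "ABC":
            assert s.unique(label) == 0
        assert s.shared("A", "B", "C") == 2

    def test_inclusion_exclusion_on_random_sets(self, rng):
        universe = np.arange(500)
        sets = {k: set(rng.choice(universe,
                                  size=rng.integers(20, 200),
                                  replace=False).tolist())
                for k in ("a", "b", "c")}
        s = overlap_summary(sets)
        assert sum(s.cells.values()) == len(sets["a"] | sets["b"]
                                            | sets["c"])
        # per genotype: unique + shared-with-one + shared-with-both == total
        for label in sets:
            total = sum(v for k, v in s.cells.items() if label in k)
            assert total == len(sets[label])

    def test_empty_set_gives_na(self):
        s = overlap_summary({"A": set(), "B": {1}})
        assert s.unique_fraction("A") == "NA"

    def test_requires_two_genotypes(self):
        with pytest.raises(ValueError):
            overlap_summary({"A": {1}})


class TestFormatting:
    def test_percent_rounding(self):
        assert percent(155, 231) == 67.1
        assert percent(57, 231) == 24.7
        assert np.isnan(percent(1, 0))

    def test_format_fraction(self):
        assert format_fraction(485, 814) == "59.58% (485/814)"
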