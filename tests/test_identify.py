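"""Best Match / Best Close Match / All Species Barcodes criteria and the
intraspecific-distance threshold."""

import math

import pytest

from barcodeid.identify import (
    CATEGORIES,
    all_species_barcodes,
    best_close_match,
    best_match,
    compute_threshold,
    identification_summary,
)

from conftest import make_matrix


def brute_percentile(values, q):
    """Linear-interpolation percentile, written independently."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    rank = q / 100 * (len(xs) - 1)
    lo = int(math.floor(rank))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (rank - lo) * (xs[hi] - xs[lo])


class TestThreshold:
    def test_single_pair_any_percentile(self):
        m = make_matrix(["a1", "a2"], {("a1", "a2"): 0.004})
        smap = {"a1": "spA", "a2": "spA"}
        for q in (5, 50, 95, 100):
            assert compute_threshold(m, smap, q) == pytest.approx(0.004)

    def test_interpolation_matches_brute_force(self):
        vals = {("a1", "a2"): 0.0, ("a1", "a3"): 0.0, ("a2", "a3"): 0.01}
        m = make_matrix(["a1", "a2", "a3"], vals)
        smap = {k: "spA" for k in ("a1", "a2", "a3")}
        for q in (50, 90, 95):
            assert compute_threshold(m, smap, q) == pytest.approx(
                brute_percentile([0.0, 0.0, 0.01], q), abs=1e-15)

    def test_all_zero_distances(self):
        m = make_matrix(["a1", "a2", "a3"], {}, default=0.0)
        smap = {k: "spA" for k in ("a1", "a2", "a3")}
        assert compute_threshold(m, smap) == 0.0

    def test_no_intraspecific_pairs_errors(self):
        m = make_matrix(["x", "y"], {})
        with pytest.raises(ValueError, match="singleton"):
            compute_threshold(m, {"x": "spA", "y": "spB"})


# three sequences, query q conspecific with c, allospecific b
TRIO = ["q", "c", "b"]
TRIO_MAP = {"q": "spA", "c": "spA", "b": "spB"}


class TestBestMatch:
    def test_nearest_conspecific_is_correct(self):
        m = make_matrix(TRIO, {("q", "c"): 0.01, ("q", "b"): 0.05})
        assert best_match("q", m, TRIO_MAP).category == "correct"

    def test_exact_tie_across_species_is_ambiguous(self):
        m = make_matrix(TRIO, {("q", "c"): 0.02, ("q", "b"): 0.02})
        res = best_match("q", m, TRIO_MAP)
        assert res.category == "ambiguous"
        assert res.matched_species == {"spA", "spB"}

    def test_nearest_allospecific_is_incorrect(self):
        m = make_matrix(TRIO, {("q", "c"): 0.05, ("q", "b"): 0.01})
        assert best_match("q", m, TRIO_MAP).category == "incorrect"

    def test_unknown_query_errors(self):
        m = make_matrix(TRIO, {})
        with pytest.raises(KeyError):
            best_match("zz", m, TRIO_MAP)


class TestBestCloseMatch:
    def test_best_beyond_threshold_is_no_match(self):
        m = make_matrix(TRIO, {("q", "c"): 0.02, ("q", "b"): 0.06})
        res = best_close_match("q", m, TRIO_MAP, threshold=0.0094)
        assert res.category == "no_match"

    def test_zero_distance_conspecific_is_correct(self):
        m = make_matrix(TRIO, {("q", "c"): 0.0, ("q", "b"): 0.06})
        res = best_close_match("q", m, TRIO_MAP, threshold=0.0094)
        assert res.category == "correct"

    def test_infinite_threshold_reduces_to_best_match(self, study_ingroup):
        from barcodeid.distances import distance_matrix
        m = distance_matrix(study_ingroup)
        smap = study_ingroup.species_map
        for query in m.ids:
            bm = best_match(query, m, smap)
            bcm = best_close_match(query, m, smap, math.inf)
            assert bcm.category == bm.category
            assert bcm.matched_species == bm.matched_species


class TestAllSpeciesBarcodes:
    M = make_matrix(["q", "c1", "c2", "b"],
                    {("q", "c1"): 0.004, ("q", "c2"): 0.006,
                     ("q", "b"): 0.07})
    MAP = {"q": "spA", "c1": "spA", "c2": "spA", "b": "spB"}

    def test_all_candidates_conspecific_is_correct(self):
        res = all_species_barcodes("q", self.M, self.MAP, threshold=0.01)
        assert res.category == "correct"

    def test_empty_candidate_set_is_no_match(self):
        res = all_species_barcodes("q", self.M, self.MAP, threshold=0.001)
        assert res.category == "no_match"

    def test_mixed_candidates_are_ambiguous(self):
        res = all_species_barcodes("q", self.M, self.MAP, threshold=0.1)
        assert res.category == "ambiguous"

    def test_only_allospecific_is_incorrect(self):
        m = make_matrix(["q", "c", "b"],
                        {("q", "c"): 0.05, ("q", "b"): 0.005})
        res = all_species_barcodes("q", m, TRIO_MAP, threshold=0.01)
        assert res.category == "incorrect"

    def test_single_conspecific_compat_mode(self):
        # a two-member species: under compat scoring, the lone conspecific
        # match makes the query ambiguous; without compat it is correct
        m = make_matrix(TRIO, {("q", "c"): 0.004, ("q", "b"): 0.07})
        compat = all_species_barcodes("q", m, TRIO_MAP, 0.01,
                                      compat_singleton_ambiguous=True)
        plain = all_species_barcodes("q", m, TRIO_MAP, 0.01,
                                     compat_singleton_ambiguous=False)
        assert compat.category == "ambiguous"
        assert plain.category == "correct"


class TestIdentificationSummary:
    def test_two_clean_species_fully_correct(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        smap = {i: ("spA" if i.startswith("a") else "spB") for i in ids}
        entries = {(x, y): 0.0 for x in ids for y in ids
                   if x < y and x[0] == y[0]}
        m = make_matrix(ids, entries, default=0.06)
        s = identification_summary(None, smap, matrix=m)
        for crit in ("BM", "BCM", "ASB"):
            assert s.counts[crit]["correct"] == 6
        assert s.n_with_conspecific == 6
        assert s.n_closest_at_zero == 6
        assert s.n_allospecific_at_zero == 0

    def test_counts_match_per_query_calls(self, study_ingroup):
        from barcodeid.distances import distance_matrix
        m = distance_matrix(study_ingroup)
        smap = study_ingroup.species_map
        s = identification_summary(None, smap, matrix=m)
        for crit, fn in (
            ("BM", lambda q: best_match(q, m, smap)),
            ("BCM", lambda q: best_close_match(q, m, smap, s.threshold)),
            ("ASB", lambda q: all_species_barcodes(q, m, smap,
                                                   s.threshold)),
        ):
            recount = {c: 0 for c in CATEGORIES}
            for q in m.ids:
                recount[fn(q).category] += 1
            assert s.counts[crit] == recount

    def test_categories_partition_queries(self, study_ingroup):
        s = identification_summary(study_ingroup)
        for crit, cats in s.counts.items():
            assert sum(cats.values()) == s.n_sequences
            pct = s.percentages()[crit]
            assert sum(pct.values()) == pytest.approx(100.0)

    def test_singleton_species_never_correct(self):
        ids = ["a1", "a2", "lone"]
        smap = {"a1": "spA", "a2": "spA", "lone": "spL"}
        m = make_matrix(ids, {("a1", "a2"): 0.002}, default=0.05)
        s = identification_summary(None, smap, matrix=m)
        assert s.n_with_conspecific == 2
        for crit in ("BM", "BCM", "ASB"):
            assert s.counts[crit]["correct"] <= 2
        assert best_match("lone", m, smap).category == "incorrect"

    def test_raising_threshold_never_increases_no_match(self, study_ingroup):
        from barcodeid.distances import distance_matrix
        m = distance_matrix(study_ingroup)
        smap = study_ingroup.species_map
        previous_bcm = previous_asb = None
        for threshold in (0.0, 0.001, 0.005, 0.01, 0.05, math.inf):
            s = identification_summary(None, smap, matrix=m,
                                       threshold=threshold)
            if previous_bcm is not None:
                assert s.counts["BCM"]["no_match"] <= previous_bcm
                assert s.counts["ASB"]["no_match"] <= previous_asb
            previous_bcm = s.counts["BCM"]["no_match"]
            previous_asb = s.counts["ASB"]["no_match"]

    def test_report_serialization(self, study_ingroup):
        s = identification_summary(study_ingroup)
        d = s.to_dict()
        assert d["n_sequences"] == 43
        assert set(d["criteria"]) == {"BM", "BCM", "ASB"}
        text = s.to_text()
        assert "Correct identifications" in text
        assert "No match closer than the calculated threshold" in text
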