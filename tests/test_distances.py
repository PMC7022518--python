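"""K2P distances, divergence summaries and barcode-gap assessment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeid.core import AlignedDataset, AlignedSequence
from barcodeid.distances import (
    barcode_gap_report,
    distance_matrix,
    divergence_summary,
    k2p_distance,
    p_distance,
)
from barcodeid.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


def k2p_reference(a: str, b: str):
    """Independent closed-form K2P evaluation (pure-python, per-site)."""
    purines, pyrimidines = set("AG"), set("CT")
    ts = tv = n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = ((x in purines and y in purines)
                      or (x in pyrimidines and y in pyrimidines))
        ts += same_class
        tv += not same_class
    if n == 0:
        return float("nan"), 0
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return float("nan"), n
    return (-0.5 * math.log(1 - 2 * p - q)
            - 0.25 * math.log(1 - 2 * q)), n


class TestK2PDistance:
    def test_identical_sequences(self):
        d, n = k2p_distance("A" * 100, "A" * 100)
        assert (d, n) == (0.0, 100)

    def test_single_transition_closed_form(self):
        a = "A" + "C" * 99
        b = "G" + "C" * 99
        d, n = k2p_distance(a, b)
        assert n == 100
        assert d == pytest.approx(-0.5 * math.log(0.98), abs=1e-15)
        assert d == pytest.approx(0.0101014, abs=5e-7)

    def test_two_transversions_closed_form(self):
        a = "TG" + "C" * 98
        b = "GT" + "C" * 98
        d, n = k2p_distance(a, b)
        assert d == pytest.approx(
            -0.5 * (math.log(0.98) + 0.5 * math.log(0.96)), abs=1e-15)
        assert d == pytest.approx(0.020307, abs=5e-7)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            k2p_distance("ACGT", "ACG")

    def test_pairwise_deletion_excludes_gaps_ns_ambiguities(self):
        # the disturbed columns must drop out, leaving the clean comparison
        a = "ACGTA" + "ACGT"
        b = "-CNRW" + "ACGT"  # gap, N, and ambiguity columns drop out
        d, n = k2p_distance(a, b)
        assert n == 5
        assert d == 0.0

    def test_saturation_yields_undefined_marker(self):
        d, n = k2p_distance("AG" * 50, "GA" * 50)  # all transitions
        assert math.isnan(d)
        assert n == 100

    def test_correction_never_below_p_distance(self, study_ingroup):
        rows = [s.residues for s in study_ingroup.sequences[:8]]
        for a, b in itertools.combinations(rows, 2):
            d, _ = k2p_distance(a, b)
            p, _ = p_distance(a, b)
            assert d >= p - 1e-12

    def test_small_p_transitions_only_near_linear(self):
        # with Q = 0 and small P the correction is second order:
        # d - P = P^2 + 4P^3/3 + ..., so it stays within 1.2 P^2 here
        for k in (1, 2, 3, 5):
            a = "A" * 100
            b = "G" * k + "A" * (100 - k)
            d, _ = k2p_distance(a, b)
            p = k / 100
            assert 0 < d - p <= 1.2 * p * p


@settings(derandomize=True, max_examples=60)
@given(st.data())
def test_k2p_symmetry_and_bounds_property(data):
    """Symmetry, non-negativity, and agreement with the reference."""
    alphabet = "ACGTN-"
    length = data.draw(st.integers(min_value=1, max_value=60))
    a = "".join(data.draw(st.lists(st.sampled_from(alphabet),
                                   min_size=length, max_size=length)))
    b = "".join(data.draw(st.lists(st.sampled_from(alphabet),
                                   min_size=length, max_size=length)))
    d_ab, n_ab = k2p_distance(a, b)
    d_ba, n_ba = k2p_distance(b, a)
    ref, n_ref = k2p_reference(a, b)
    assert n_ab == n_ba == n_ref
    if math.isnan(d_ab):
        assert math.isnan(d_ba) and math.isnan(ref)
    else:
        assert d_ab == d_ba
        assert d_ab >= 0.0
        assert d_ab == pytest.approx(ref, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        ds = AlignedDataset(tuple(
            AlignedSequence(f"s{i}", "spA", "ACGT" * 5) for i in range(3)))
        m = distance_matrix(ds)
        assert np.allclose(m.d, 0.0)

    def test_two_sequences_reduce_to_k2p(self):
        ds = AlignedDataset((AlignedSequence("x", "spA", "AAAA"),
                             AlignedSequence("y", "spB", "AGAA")))
        m = distance_matrix(ds)
        assert m.distance("x", "y") == k2p_distance("AAAA", "AGAA")[0]

    def test_matrix_equals_brute_force(self):
        cfg = SimulationConfig(
            species=tuple("ABCDE"), sample_sizes=(2, 2, 2, 2, 2),
            seed=7, length=300, spacer_patterns=None)
        ds, _ = simulate_dataset(cfg)
        m = distance_matrix(ds)
        assert np.allclose(m.d, m.d.T)
        assert np.allclose(np.diag(m.d), 0.0)
        rows = {s.seq_id: s.residues for s in ds.sequences}
        for a, b in itertools.combinations(ds.ids, 2):
            ref, n_ref = k2p_reference(rows[a], rows[b])
            assert m.distance(a, b) == pytest.approx(ref, abs=1e-12)
            ia, ib = m.index(a), m.index(b)
            assert m.sites[ia, ib] == n_ref

    def test_permutation_invariance(self):
        cfg = SimulationConfig(species=("A", "B"), sample_sizes=(2, 2),
                               seed=3, length=200, spacer_patterns=None)
        ds, _ = simulate_dataset(cfg)
        perm = AlignedDataset(tuple(reversed(ds.sequences)))
        m1, m2 = distance_matrix(ds), distance_matrix(perm)
        for a, b in itertools.combinations(ds.ids, 2):
            assert m1.distance(a, b) == m2.distance(a, b)

    def test_writers(self, tmp_path, toy_dataset):
        m = distance_matrix(toy_dataset)
        m.write_tsv(tmp_path / "m.tsv")
        m.write_phylip(tmp_path / "m.phy")
        assert (tmp_path / "m.tsv").read_text().startswith("\ta1\ta2")
        assert (tmp_path / "m.phy").read_text().splitlines()[0] == "4"


class TestDivergenceSummary:
    def test_identical_conspecifics_mean_zero(self):
        ds = AlignedDataset(tuple(
            AlignedSequence(f"s{i}", "spA", "ACGTACGT") for i in range(3)))
        m = distance_matrix(ds)
        s = divergence_summary(m, ds.species_map)
        assert s.intra_means["spA"] == 0.0

    def test_singletons_flagged_not_averaged(self):
        m = make_matrix(["x", "y"], {("x", "y"): 0.06})
        s = divergence_summary(m, {"x": "spA", "y": "spB"})
        assert s.intra_means == {"spA": None, "spB": None}
        assert s.singleton_species == ("spA", "spB")
        assert s.inter_means[("spA", "spB")] == pytest.approx(0.06)

    def test_brute_force_label_averaging(self, study_ingroup):
        m = distance_matrix(study_ingroup)
        smap = study_ingroup.species_map
        s = divergence_summary(m, smap)
        # independent re-averaging straight off the matrix
        ids = m.ids
        for sp, mean in s.intra_means.items():
            vals = [m.d[i, j]
                    for i, j in itertools.combinations(range(len(ids)), 2)
                    if smap[ids[i]] == smap[ids[j]] == sp]
            if mean is None:
                assert vals == []
            else:
                assert mean == pytest.approx(np.mean(vals), abs=1e-15)
        for (sa, sb), mean in s.inter_means.items():
            vals = [m.d[i, j]
                    for i, j in itertools.combinations(range(len(ids)), 2)
                    if {smap[ids[i]], smap[ids[j]]} == {sa, sb}]
            assert mean == pytest.approx(np.mean(vals), abs=1e-15)

    def test_undefined_distance_raises_unless_skipped(self):
        m = make_matrix(["x", "y", "z"], {("x", "y"): float("nan")})
        smap = {"x": "spA", "y": "spA", "z": "spB"}
        with pytest.raises(ValueError, match="undefined"):
            divergence_summary(m, smap)
        s = divergence_summary(m, smap, skip_undefined=True)
        assert s.intra_values["spA"].size == 0


class TestBarcodeGap:
    def test_clean_regime_has_gap(self):
        m = make_matrix(["a1", "a2", "b1", "b2"],
                        {("a1", "a2"): 0.012, ("b1", "b2"): 0.008},
                        default=0.05)
        s = divergence_summary(m, {"a1": "spA", "a2": "spA",
                                   "b1": "spB", "b2": "spB"})
        gap = barcode_gap_report(s)
        assert gap.gap_present
        assert gap.max_intra == pytest.approx(0.012)
        assert gap.min_inter == pytest.approx(0.05)

    def test_single_species_errors(self):
        m = make_matrix(["a1", "a2"], {("a1", "a2"): 0.01})
        s = divergence_summary(m, {"a1": "spA", "a2": "spA"})
        with pytest.raises(ValueError, match="interspecific"):
            barcode_gap_report(s)

    def test_forced_overlap_regime_has_no_gap(self):
        # inter target at the intra noise floor: species indistinguishable
        cfg = SimulationConfig(
            species=("A", "B", "C"), sample_sizes=(3, 3, 3), seed=5,
            intra_divergence=0.03, inter_divergence=0.02,
            length=800, spacer_patterns=None)
        ds, smap = simulate_dataset(cfg)
        s = divergence_summary(distance_matrix(ds), smap)
        assert not barcode_gap_report(s).gap_present
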