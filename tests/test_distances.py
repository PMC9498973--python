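import math
import warnings

import numpy as np
import pytest

from barcodekit.distances import (
    barcode_gap,
    group_means,
    k2p_distance,
    k2p_from_proportions,
    pairwise_matrix,
    summary_tables,
)
from barcodekit.seqio import SequenceError
from conftest import make_alignment

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def brute_force_k2p(a: str, b: str):
    """Independent per-pair recount with plain string handling."""
    ts = tv = valid = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        valid += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if valid == 0:
        return None
    P, Q = ts / valid, tv / valid
    arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        return P, Q, valid, None
    return P, Q, valid, -0.5 * math.log(arg1 * math.sqrt(arg2))


def test_identical_rows_give_zero_distance():
    pair = k2p_distance("ACGTACGT", "ACGTACGT")
    assert pair.P == pair.Q == 0.0
    assert pair.d == 0.0 and pair.defined


def test_closed_form_on_proportion_grid():
    for P in np.arange(0.0, 0.31, 0.05):
        for Q in np.arange(0.0, 0.31, 0.05):
            d, ok = k2p_from_proportions(P, Q)
            assert ok
            assert d == pytest.approx(
                -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
            )
    # example worked by hand: P=0.1, Q=0.05
    d, _ = k2p_from_proportions(0.1, 0.05)
    assert d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.90)))


def test_pairwise_deletion_of_gaps_and_ambiguity():
    pair = k2p_distance("ACGT-RCA", "ACGTTTNA")
    # columns 5 (gap), 6 (R) and 7 (N) are deleted pairwise
    assert pair.L_valid == 5
    assert pair.d == 0.0


def test_saturated_pair_is_flagged_undefined():
    pair = k2p_distance("AAAA", "CCCC")  # every site a transversion
    assert not pair.defined and math.isnan(pair.d)
    zero = k2p_distance("----", "AAAA")
    assert zero.L_valid == 0 and not zero.defined


def test_k2p_reduces_to_jukes_cantor_at_balanced_changes():
    # when transitions:transversions = 1:2 (P = p/3, Q = 2p/3) the K2P
    # distance collapses to the JC form -3/4 ln(1 - 4p/3)
    for p in (0.03, 0.12, 0.3):
        d, ok = k2p_from_proportions(p / 3, 2 * p / 3)
        assert ok
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))


def test_monotonicity_in_P_and_Q():
    base, _ = k2p_from_proportions(0.05, 0.05)
    up_p, _ = k2p_from_proportions(0.10, 0.05)
    up_q, _ = k2p_from_proportions(0.05, 0.10)
    assert up_p > base and up_q > base


def test_matrix_matches_brute_force_on_random_rows(rng):
    n, L = 10, 120
    chars = np.array(list("ACGT-RN"))
    rows = {
        f"r{i}": "".join(rng.choice(chars, size=L, p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.02, 0.02]))
        for i in range(n)
    }
    aln = make_alignment(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = pairwise_matrix(aln)
    assert np.allclose(np.diagonal(matrix.values), 0.0)
    labels = matrix.labels
    for i in range(n):
        for j in range(i + 1, n):
            expected = brute_force_k2p(rows[labels[i]], rows[labels[j]])
            got = matrix.values[i, j]
            np.testing.assert_array_equal(matrix.values[j, i], got)  # symmetry
            if expected is None or expected[3] is None:
                assert not matrix.defined[i, j]
            else:
                assert got == pytest.approx(expected[3])


def test_group_means_match_direct_average(rng):
    base = "".join(rng.choice(list("ACGT"), size=200))
    def mutate(seq, k):
        s = list(seq)
        for pos in rng.choice(len(s), size=k, replace=False):
            s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
        return "".join(s)

    rows = {
        "a1": base, "a2": mutate(base, 2), "a3": mutate(base, 3),
        "b1": mutate(base, 20), "b2": mutate(base, 22),
        "c1": mutate(base, 40),
    }
    species = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "c1": "C"}
    matrix = pairwise_matrix(make_alignment(rows))
    summary = group_means(matrix, species)
    # within(A): direct mean over the three unordered pairs
    pairs = [("a1", "a2"), ("a1", "a3"), ("a2", "a3")]
    direct = np.mean([matrix[p] for p in pairs])
    assert summary.within["A"] == pytest.approx(direct)
    assert "C" not in summary.within  # singleton species has no within-mean
    cross = [matrix[(x, y)] for x in ("a1", "a2", "a3") for y in ("b1", "b2")]
    assert summary.between[("A", "B")] == pytest.approx(np.mean(cross))


def test_frequency_weighted_means_differ():
    rows = {
        "a1": "A" * 20,
        "a2": "GG" + "A" * 18,
        "b1": "A" * 14 + "T" * 6,
    }
    species = {"a1": "A", "a2": "A", "b1": "B"}
    matrix = pairwise_matrix(make_alignment(rows))
    plain = group_means(matrix, species)
    weighted = group_means(matrix, species, weights={"a1": 9, "a2": 1, "b1": 1})
    assert plain.between[("A", "B")] != pytest.approx(weighted.between[("A", "B")])


def test_two_singleton_species_between_only():
    rows = {"a": "A" * 10 + "G" * 0 + "C" * 10, "b": "A" * 10 + "C" * 10}
    matrix = pairwise_matrix(make_alignment(rows))
    summary = group_means(matrix, {"a": "A", "b": "B"})
    assert summary.within == {}
    assert summary.between[("A", "B")] == pytest.approx(0.0)


def test_barcode_gap_report_allows_overlap():
    rows = {
        "a1": "A" * 20,
        "a2": "G" * 6 + "A" * 14,
        "b1": "A" * 19 + "G",
        "b2": "A" * 19 + "G",
    }
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    matrix = pairwise_matrix(make_alignment(rows))
    summary = group_means(matrix, species)
    report = barcode_gap(summary)
    assert report.gap == pytest.approx(report.min_between - report.max_within)
    assert report.gap < 0  # within exceeds between here: reported, not an error
    assert report.nearest_neighbor["A"][0] == "B"


def test_summary_tables_report_percent():
    rows = {"a1": "A" * 50, "a2": "A" * 45 + "G" * 5, "b1": "A" * 40 + "T" * 10}
    species = {"a1": "A", "a2": "A", "b1": "B"}
    summary = group_means(pairwise_matrix(make_alignment(rows)), species)
    within, between = summary_tables(summary)
    val = within.loc[within["species"] == "A", "within_pct"].iloc[0]
    assert val == pytest.approx(100 * summary.within["A"], abs=0.005)
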