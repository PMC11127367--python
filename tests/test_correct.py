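"""Barcode correction against independent step-by-step oracles.

The oracles re-enact the correction procedures naively (python loops over
explicit ranked lists) and are kept deliberately separate from the
vectorized implementations they check.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import scnoise as sc
from scnoise.correct import greedy_absorb
from scnoise.parse import TRIO_COLUMNS


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------- oracles


def oracle_rank_scan(non_wl, ranked_wl, max_dist):
    """Naive cell-barcode rule: walk the abundance-ranked whitelist and take
    the first entry within the radius."""
    mapping = {}
    for bc in non_wl:
        for wbc in ranked_wl:
            if hamming(bc, wbc) <= max_dist:
                mapping[bc] = wbc
                break
    return mapping


def oracle_greedy_loop(abundance, max_dist):
    """Naive locBC loop: repeatedly take the most abundant remaining barcode,
    absorb everything within the radius, remove the group, repeat."""
    remaining = sorted(abundance, key=lambda b: (-abundance[b], b))
    mapping = {}
    while remaining:
        top = remaining.pop(0)
        mapping[top] = top
        absorbed = [b for b in remaining if hamming(b, top) <= max_dist]
        for b in absorbed:
            mapping[b] = top
            remaining.remove(b)
    return mapping


def random_instance(rng, n_bc=40, length=6):
    bases = np.array(list("ACGT"))
    bcs = list({"".join(bases[rng.integers(0, 4, length)]) for _ in range(n_bc)})
    reads = rng.integers(1, 500, size=len(bcs))
    return pd.Series(reads, index=bcs).sort_index()


# ------------------------------------------------------------- unit tests


@pytest.mark.parametrize(
    "a,b,d", [("AAAA", "AAAA", 0), ("AAAA", "AAAT", 1), ("ACGT", "TGCA", 4)]
)
def test_hamming_distance(a, b, d):
    assert sc.hamming_distance(a, b) == d


def test_hamming_unequal_lengths():
    with pytest.raises(ValueError):
        sc.hamming_distance("AAA", "AAAA")


def _trios(rows):
    return pd.DataFrame(rows, columns=TRIO_COLUMNS + ["reads"])


class TestCellBarcodeCorrection:
    WL = {"A" * 16, "C" * 16, "G" * 16}

    def test_whitelisted_barcode_unchanged(self):
        trios = _trios([("A" * 16, "T" * 12, "G" * 16, 5)])
        out, rep = sc.correct_cell_barcodes(trios, self.WL)
        assert out["cell_barcode"].iloc[0] == "A" * 16
        assert rep["n_corrected"] == 0

    def test_distance_two_corrected(self):
        bad = "A" * 14 + "TT"
        trios = _trios(
            [("A" * 16, "T" * 12, "G" * 16, 5), (bad, "C" * 12, "G" * 16, 2)]
        )
        out, rep = sc.correct_cell_barcodes(trios, self.WL)
        assert set(out["cell_barcode"]) == {"A" * 16}
        assert out["reads"].sum() == 7  # reads conserved through the merge
        assert rep["n_corrected"] == 1

    def test_abundance_rank_decides_ties(self):
        # bad barcode within distance 2 of both whitelist entries; the more
        # abundant one (100 reads) must win over the 10-read one
        w1 = "A" * 16
        w2 = "A" * 12 + "TTTT"
        bad = "A" * 14 + "TT"
        assert hamming(bad, w1) == 2 and hamming(bad, w2) == 2
        trios = _trios(
            [(w1, "T" * 12, "G" * 16, 100), (w2, "T" * 12, "G" * 16, 10),
             (bad, "C" * 12, "G" * 16, 1)]
        )
        out, _ = sc.correct_cell_barcodes(trios, {w1, w2})
        merged = out.groupby("cell_barcode")["reads"].sum()
        assert merged[w1] == 101 and merged[w2] == 10

    def test_unmatched_dropped_and_reported(self):
        trios = _trios(
            [("A" * 16, "T" * 12, "G" * 16, 5), ("T" * 16, "C" * 12, "G" * 16, 3)]
        )
        out, rep = sc.correct_cell_barcodes(trios, self.WL)
        assert set(out["cell_barcode"]) == {"A" * 16}
        assert rep["n_dropped"] == 1 and rep["reads_dropped"] == 3

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            sc.correct_cell_barcodes(_trios([("A" * 16, "T" * 12, "G" * 16, 1)]), set())

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ab = random_instance(rng, n_bc=60, length=16)
        wl = set(ab.index[:20])
        trios = _trios([(bc, "T" * 12, "G" * 16, int(r)) for bc, r in ab.items()])
        once, _ = sc.correct_cell_barcodes(trios, wl)
        twice, _ = sc.correct_cell_barcodes(once, wl)
        pd.testing.assert_frame_equal(once, twice)


class TestLocBarcodeCorrection:
    def test_beyond_radius_survive(self):
        a, b = "AAAAAA", "TTTTTC"  # distance 5 > 4
        trios = _trios([("A" * 16, "T" * 12, a, 9), ("A" * 16, "C" * 12, b, 9)])
        out, rep = sc.correct_location_barcodes(trios, max_dist=4)
        assert set(out["loc_barcode"]) == {a, b}
        assert rep["n_corrected"] == 0

    def test_minor_variant_absorbed(self):
        x = "A" * 16
        x_err = "A" * 13 + "TTT"  # distance 3
        trios = _trios([("A" * 16, "T" * 12, x, 1000), ("A" * 16, "C" * 12, x_err, 4)])
        out, rep = sc.correct_location_barcodes(trios)
        assert set(out["loc_barcode"]) == {x}
        assert out["reads"].sum() == 1004
        assert rep["n_corrected"] == 1

    def test_greedy_chain_break(self):
        # d(A,B)=4, d(B,C)=4, d(A,C)=8: B absorbed by A, then C survives
        # because B is no longer available to bridge it
        A, B, C = "AAAAAAAA", "AAAACCCC", "CCCCCCCC"
        mapping = greedy_absorb(pd.Series({A: 100, B: 50, C: 40}), max_dist=4)
        assert mapping == {A: A, B: A, C: C}

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        ab = random_instance(rng, n_bc=50, length=8)
        trios = _trios([("A" * 16, "T" * 12, bc, int(r)) for bc, r in ab.items()])
        once, _ = sc.correct_location_barcodes(trios)
        twice, _ = sc.correct_location_barcodes(once)
        pd.testing.assert_frame_equal(once, twice)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_greedy_matches_oracle_loop(seed):
    rng = np.random.default_rng(seed)
    ab = random_instance(rng, n_bc=40, length=6)
    assert greedy_absorb(ab, max_dist=2) == oracle_greedy_loop(ab.to_dict(), 2)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_rank_scan_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    ab = random_instance(rng, n_bc=40, length=6)
    wl = set(list(ab.index)[::2])
    trios = _trios([(bc, "T" * 12, "G" * 16, int(r)) for bc, r in ab.items()])
    out, _ = sc.correct_cell_barcodes(trios, wl, max_dist=2)
    # oracle: ranked observed whitelist, first-in-radius scan
    obs_wl = ab[ab.index.isin(wl)]
    ranked = sorted(obs_wl.index, key=lambda b: (-obs_wl[b], b))
    expected = oracle_rank_scan([b for b in ab.index if b not in wl], ranked, 2)
    got = out.groupby("cell_barcode")["reads"].sum().to_dict()
    want = {}
    for bc, r in ab.items():
        tgt = bc if bc in wl else expected.get(bc)
        if tgt is not None:
            want[tgt] = want.get(tgt, 0) + int(r)
    assert got == want


def test_every_reassignment_within_radius():
    rng = np.random.default_rng(11)
    ab = random_instance(rng, n_bc=200, length=8)
    mapping = greedy_absorb(ab, max_dist=4)
    assert all(hamming(k, v) <= 4 for k, v in mapping.items())


class TestDistanceHistogram:
    def test_two_barcodes_single_pair(self):
        hist = sc.pairwise_distance_histogram(["AAAA", "AATT"])
        assert hist.to_dict() == {2: 1}

    def test_duplicates_give_mass_at_zero(self):
        hist = sc.pairwise_distance_histogram(["AAAA", "AAAA", "TTTT"])
        assert hist[0] == 1

    def test_random_16mers_rarely_close(self):
        # expected pair distance 12; P(d <= 6) ~ 6e-4, so >99% beyond 6
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        bcs = ["".join(bases[rng.integers(0, 4, 16)]) for _ in range(1000)]
        hist = sc.pairwise_distance_histogram(bcs, sample_pairs=200_000, seed=1)
        frac_gt6 = hist[hist.index > 6].sum() / hist.sum()
        assert frac_gt6 > 0.99

    def test_single_barcode_rejected(self):
        with pytest.raises(ValueError):
            sc.pairwise_distance_histogram(["AAAA"])
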