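"""Changepoint segmentation, CNA filtering, recurrence, label-reversal QC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgscore.errors import InputError
from dgscore.segmentation import (CnaSegment, RecurrentRegion,
                                  SegmentationParams, detect_label_reversal,
                                  detect_recurrent_regions, filter_segments,
                                  pelt, recurrence_threshold, segment_profile)

PARAMS = SegmentationParams()


def _probe_map(n, chrom="chr1", spacing=1000):
    return pd.DataFrame({"chrom": chrom, "pos": np.arange(n) * spacing},
                        index=[f"p{i}" for i in range(n)])


def _exhaustive_two_changepoint_fit(y):
    """Oracle: least-squares best (a, b) over all two-changepoint splits."""
    n = len(y)
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(i, j):
        return s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / (j - i)

    best, best_cost = None, np.inf
    for a in range(1, n - 1):
        for b in range(a + 1, n):
            c = sse(0, a) + sse(a, b) + sse(b, n)
            if c < best_cost:
                best, best_cost = (a, b), c
    return best


def test_null_profile_all_neutral(rng):
    pm = _probe_map(1000)
    segs = segment_profile(pm, rng.normal(0, 0.05, 1000), PARAMS)
    assert all(s.state == "neutral" for s in segs)
    assert filter_segments(segs, PARAMS) == []


def test_planted_shift_recovered_matches_exhaustive_oracle(rng):
    n = 2000
    y = rng.normal(0, 0.05, n)
    y[500:700] += 0.5
    pm = _probe_map(n)
    segs = segment_profile(pm, y, PARAMS)
    gains = [s for s in segs if s.state == "gain"]
    assert len(gains) == 1
    g = gains[0]
    a = g.start // 1000
    b = g.end // 1000 + (0 if g.end % 1000 else 0)
    b = (g.end - 1) // 1000 + 1  # last probe index + 1
    # oracle: exhaustive two-changepoint least squares on a subwindow around
    # the plant (full 2000^2 scan is wasteful; the window contains the truth)
    w0, w1 = 400, 800
    oa, ob = _exhaustive_two_changepoint_fit(y[w0:w1])
    assert abs(a - (w0 + oa)) <= 2 and abs(b - (w0 + ob)) <= 2
    assert abs(a - 500) <= 2 and abs(b - 700) <= 2
    assert abs(g.mean_lr - 0.5) < 0.05


@pytest.mark.parametrize("shift,state", [(0.10, "neutral"), (0.20, "gain"),
                                         (-0.10, "neutral"), (-0.20, "loss")])
def test_state_thresholds_at_plus_minus_015(rng, shift, state):
    n = 400
    y = rng.normal(0, 0.02, n)
    y[100:200] += shift
    segs = segment_profile(_probe_map(n), y, PARAMS)
    found = [s for s in segs if s.start == 100_000]
    assert found and found[0].state == state


def test_segment_means_equal_probe_means_and_partition(rng):
    pm = pd.DataFrame({
        "chrom": ["chr1"] * 300 + ["chr2"] * 200,
        "pos": np.concatenate([np.arange(300), np.arange(200)]) * 500,
    }, index=[f"p{i}" for i in range(500)])
    y = rng.normal(0, 0.05, 500)
    y[50:120] -= 0.4
    segs = segment_profile(pm, y, PARAMS)
    for chrom, nprobe in (("chr1", 300), ("chr2", 200)):
        cs = [s for s in segs if s.chromosome == chrom]
        assert sum(s.n_probes for s in cs) == nprobe
        starts = sorted(s.start for s in cs)
        assert len(set(starts)) == len(cs)  # disjoint pieces
    chrom1 = pm[pm["chrom"] == "chr1"]
    for s in segs:
        if s.chromosome != "chr1":
            continue
        m = (chrom1["pos"] >= s.start) & (chrom1["pos"] < s.end)
        assert s.mean_lr == pytest.approx(float(y[:300][m.to_numpy()].mean()))


def test_noiseless_piecewise_profile_recovered_exactly():
    y = np.concatenate([np.zeros(60), np.full(40, 0.5), np.zeros(50),
                        np.full(30, -0.8), np.zeros(20)])
    segs = segment_profile(_probe_map(len(y)), y, PARAMS)
    bounds = sorted((s.start // 1000, (s.end - 1) // 1000 + 1) for s in segs)
    assert bounds == [(0, 60), (60, 100), (100, 150), (150, 180), (180, 200)]


def test_sign_symmetry_swaps_gain_and_loss(rng):
    n = 800
    y = rng.normal(0, 0.05, n)
    y[100:200] += 0.4
    y[500:650] -= 0.3
    pm = _probe_map(n)
    a = segment_profile(pm, y, PARAMS)
    b = segment_profile(pm, -y, PARAMS)
    flip = {"gain": "loss", "loss": "gain", "neutral": "neutral"}
    assert [(s.start, s.end, flip[s.state]) for s in a] == \
           [(s.start, s.end, s.state) for s in b]


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.integers(10, 40),
                          st.sampled_from([-0.6, -0.3, 0.0, 0.4, 0.8])),
                min_size=2, max_size=6))
def test_pelt_idempotent_on_noiseless_pieces(pieces):
    # adjacent equal levels merge; build the expected maximal runs
    y = np.concatenate([np.full(n, lv) for n, lv in pieces])
    expected = []
    for n, lv in pieces:
        if expected and expected[-1][1] == lv:
            expected[-1][0] += n
        else:
            expected.append([n, lv])
    segs = segment_profile(_probe_map(len(y)), y, SegmentationParams())
    assert [s.n_probes for s in segs] == [n for n, _ in expected]
    assert [s.mean_lr for s in segs] == pytest.approx([lv for _, lv in expected])


def test_non_finite_input_rejected():
    y = np.zeros(50)
    y[3] = np.nan
    with pytest.raises(InputError):
        segment_profile(_probe_map(50), y, PARAMS)


def test_single_probe_chromosome_is_one_neutral_segment():
    pm = pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["p0"])
    segs = segment_profile(pm, np.array([0.9]), PARAMS)
    # with <2 probes there is nothing to segment or call: one neutral segment
    assert len(segs) == 1 and segs[0].state == "neutral"
    assert segs[0].n_probes == 1


def _seg(state="gain", n_probes=50, length=5000, q=1e-9):
    return CnaSegment(patient="P1", chromosome="chr1", start=0, end=length,
                      n_probes=n_probes, mean_lr=0.4 if state == "gain" else -0.4,
                      state=state, q_value=q)


@pytest.mark.parametrize("seg,kept", [
    (_seg(), True),
    (_seg(n_probes=9), False),  # too few probes
    (_seg(length=800), False),  # under 1 kb
    (_seg(q=1e-4), False),  # fails the FDR cut
    (_seg(state="neutral"), False),
])
def test_cna_filter_rules(seg, kept):
    assert (filter_segments([seg], PARAMS) == [seg]) is kept


def test_cna_filter_empty_input():
    assert filter_segments([], PARAMS) == []


def test_recurrence_threshold_ceil_rule():
    assert recurrence_threshold(48, 0.10) == 5
    assert recurrence_threshold(10, 0.20) == 2
    assert recurrence_threshold(145, 0.10) == 15


def test_recurrent_region_brute_force_toy():
    pm = _probe_map(100)
    # 3 patients share a gain over probes 20..39; threshold 2 with fraction 0.2
    def cna(pat, a, b, state="gain"):
        return CnaSegment(patient=pat, chromosome="chr1", start=a * 1000,
                          end=(b - 1) * 1000 + 1, n_probes=b - a,
                          mean_lr=0.4 if state == "gain" else -0.4,
                          state=state, q_value=0.0)
    cnas = {"A": [cna("A", 20, 40)], "B": [cna("B", 20, 40)],
            "C": [cna("C", 25, 35, "loss")],
            **{p: [] for p in "DEFGHIJ"}}
    regions = detect_recurrent_regions(cnas, 10, pm, recurrence_fraction=0.2)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (20_000, 39_001)
    assert r.n_carriers == 3
    assert r.carriers == {"A": "gain", "B": "gain", "C": "loss"}
    # brute force per-probe counting
    counts = np.zeros(100)
    for segs in cnas.values():
        cov = np.zeros(100, bool)
        for s in segs:
            cov |= (np.arange(100) * 1000 >= s.start) & (np.arange(100) * 1000 < s.end)
        counts += cov
    assert set(np.flatnonzero(counts >= 2)) == set(range(20, 40))


def test_recurrence_maximality(small_cohort, small_result):
    """Extending any region by one probe drops carriers below threshold."""
    pm = small_cohort.probe_map
    thr = recurrence_threshold(len(small_result.patients), 0.10)
    for reg in small_result.regions:
        chrom_probes = pm[pm["chrom"] == reg.chromosome]["pos"].to_numpy()

        def carrier_count(pos):
            n = 0
            for segs in small_result.cnas_by_patient.values():
                n += any(s.chromosome == reg.chromosome and s.start <= pos < s.end
                         for s in segs)
            return n
        before = chrom_probes[chrom_probes < reg.start]
        after = chrom_probes[chrom_probes >= reg.end]
        if len(before):
            assert carrier_count(before[-1]) < thr
        if len(after):
            assert carrier_count(after[0]) < thr


def test_no_cnas_gives_no_regions():
    pm = _probe_map(50)
    assert detect_recurrent_regions({"A": [], "B": []}, 2, pm, 0.1) == []


class TestLabelReversal:
    pm = _probe_map(40)
    locus = ("chr1", 10_000, 25_000)  # 15 probes

    def test_flipped_amplified_profile_flagged(self):
        y = np.zeros(40)
        y[10:25] = 0.6  # true amplification
        status, ev = detect_label_reversal(self.pm, -y, True, self.locus)
        assert status == "flagged" and ev == pytest.approx(0.6)
        # flipping the signs back clears the flag
        status2, _ = detect_label_reversal(self.pm, y, True, self.locus)
        assert status2 == "not_flagged"

    def test_non_amplified_never_flagged(self):
        y = np.zeros(40)
        y[10:25] = -0.6
        status, _ = detect_label_reversal(self.pm, y, False, self.locus)
        assert status == "not_flagged"

    def test_uncovered_locus_undetermined(self):
        status, ev = detect_label_reversal(self.pm, np.zeros(40), True,
                                           ("chr2", 0, 1000))
        assert status == "undetermined" and math.isnan(ev)
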