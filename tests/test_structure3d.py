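"""Compartment switches, insulation/boundaries, ISC, APA and loop ratios."""

import numpy as np
import pandas as pd
import pytest

from cohescan.genome import ValidationError
from cohescan.structure3d import (
    ContactMatrix,
    apa_compare,
    apa_score,
    boundary_call,
    compartment_switch_classify,
    insulation_score,
    isc_site_stats,
    loop_overlap_ratio,
    switch_class_proportions,
    vc_sqrt_normalize,
)
from cohescan.tracks import SignalTrack


def _site(start, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [start + 400]})


def _pc1(values, chrom="chr1", bin_size=50_000):
    return [{chrom: SignalTrack(chrom, bin_size, np.asarray(values, dtype=float))}]


class TestCompartmentSwitch:
    @pytest.mark.parametrize(
        "e_n,e_c,expected",
        [
            (-0.1, 0.1, "B-to-A"),
            (0.1, -0.1, "A-to-B"),
            (0.02, -0.02, "stable-B"),  # |delta| 0.04 fails the threshold
            (0.3, 0.5, "stable-A"),
            (np.nan, 0.5, "undefined"),
        ],
    )
    def test_rule_cases(self, e_n, e_c, expected):
        calls = compartment_switch_classify(_site(10_000), _pc1([e_c]), _pc1([e_n]))
        assert calls.iloc[0]["class"] == expected

    def test_site_outside_track_span_undefined(self):
        calls = compartment_switch_classify(_site(9_000_000), _pc1([0.5]), _pc1([0.5]))
        assert calls.iloc[0]["class"] == "undefined"

    def test_replicates_are_averaged(self):
        cancer = _pc1([0.3]) + _pc1([-0.1])  # mean +0.1
        normal = _pc1([-0.3]) + _pc1([0.1])  # mean -0.1
        calls = compartment_switch_classify(_site(10_000), cancer, normal)
        assert calls.iloc[0]["class"] == "B-to-A"
        assert calls.iloc[0]["e_cancer"] == pytest.approx(0.1)

    def test_proportions_sum_to_one_over_classifiable(self):
        sites = pd.concat([_site(10_000), _site(60_000), _site(9_000_000)], ignore_index=True)
        calls = compartment_switch_classify(sites, _pc1([0.3, -0.2]), _pc1([0.3, 0.2]))
        props = switch_class_proportions(calls)
        assert props.sum() == pytest.approx(1.0)
        assert props["A-to-B"] == pytest.approx(0.5)


class TestInsulation:
    def test_uniform_matrix_is_zero(self):
        m = ContactMatrix("chr1", 0, 50_000, np.ones((40, 40)))
        track = insulation_score(m, window_bins=5)
        finite = np.isfinite(track.values)
        assert np.allclose(track.values[finite], 0.0)
        assert (~finite[:5]).all() and (~finite[-5:]).all()

    def test_two_block_matrix_minimal_at_junction(self):
        n, b = 60, 30
        m = np.ones((n, n)) * 0.5
        m[:b, :b] = 5.0
        m[b:, b:] = 5.0
        track = insulation_score(ContactMatrix("chr1", 0, 50_000, m), window_bins=8)
        # the diamond excludes its own bin, so the junction minimum is
        # defined to +-1 bin
        assert abs(np.nanargmin(track.values) - b) <= 1

    def test_matches_double_loop_oracle(self, rng):
        raw = rng.random((50, 50))
        m = (raw + raw.T) / 2
        w = 6
        track = insulation_score(ContactMatrix("chr1", 0, 50_000, m), window_bins=w)
        diamonds = np.full(50, np.nan)
        for i in range(w, 50 - w):
            total = 0.0
            for a in range(i - w, i):
                for b in range(i + 1, i + w + 1):
                    total += m[a, b]
            diamonds[i] = total / (w * w)
        expected = np.log2(diamonds / np.nanmean(diamonds))
        np.testing.assert_allclose(track.values[w:-w], expected[w:-w], atol=1e-9)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            insulation_score(ContactMatrix("chr1", 0, 50_000, np.zeros((30, 30))), 5)


class TestBoundaryCall:
    def test_two_tad_matrix_yields_one_junction_boundary(self):
        n, b = 60, 30
        m = np.ones((n, n)) * 0.5
        m[:b, :b] = 5.0
        m[b:, b:] = 5.0
        track = insulation_score(ContactMatrix("chr1", 0, 50_000, m), window_bins=8)
        bounds = boundary_call(track)
        assert len(bounds) == 1
        assert abs(bounds.loc[0, "start"] - b * 50_000) <= 50_000

    def test_uniform_track_has_no_boundaries(self):
        track = SignalTrack("chr1", 50_000, np.zeros(30))
        assert len(boundary_call(track)) == 0

    def test_close_minima_keep_only_deepest(self):
        v = np.zeros(30)
        v[10], v[12] = -3.0, -4.0  # 2 bins apart, within min_sep
        bounds = boundary_call(SignalTrack("chr1", 50_000, v), depth_sd=1.0, min_sep_bins=3)
        assert len(bounds) == 1 and bounds.loc[0, "start"] == 12 * 50_000


class TestIsc:
    def test_identical_tracks_give_zero_isc(self):
        t = SignalTrack("chr1", 50_000, np.arange(20, dtype=float))
        sites = pd.concat([_site(100_000), _site(500_000)], ignore_index=True)
        per_site, summary = isc_site_stats(t, t, sites)
        assert (per_site["isc"] == 0).all()

    def test_boundary_stratification_rule(self):
        t = SignalTrack("chr1", 50_000, np.zeros(40))
        t2 = SignalTrack("chr1", 50_000, np.full(40, 0.3))
        boundaries = pd.DataFrame({"chrom": ["chr1"], "start": [500_000], "end": [550_000], "depth": [-2.0]})
        sites = pd.concat(
            [_site(510_000), _site(460_000), _site(700_000)], ignore_index=True
        )  # bin 10 (boundary), bin 9 (+-1 bin), bin 14 (within TAD)
        per_site, _ = isc_site_stats(t2, t, sites, boundaries)
        assert per_site["stratum"].tolist() == ["boundary", "boundary", "within-TAD"]
        assert np.allclose(per_site["isc"], 0.3)

    def test_missing_is_excluded_and_counted(self):
        v = np.zeros(20)
        v[2] = np.nan
        t = SignalTrack("chr1", 50_000, v)
        sites = pd.concat([_site(125_000), _site(300_000)], ignore_index=True)
        per_site, _ = isc_site_stats(t, t, sites)
        assert len(per_site) == 1 and per_site.attrs["n_missing"] == 1


def _loop_frame(pixels, resolution=50_000, chrom="chr1"):
    rows = []
    for bi, bj in pixels:
        rows.append((chrom, bi * resolution, (bi + 1) * resolution, chrom, bj * resolution, (bj + 1) * resolution))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])


class TestApa:
    def test_uniform_matrix_scores_one(self):
        m = ContactMatrix("chr1", 0, 50_000, np.ones((80, 80)))
        res = apa_score(m, _loop_frame([(20, 60)]))
        assert res.apa_score == pytest.approx(1.0)

    def test_planted_center_fold_recovered(self, rng):
        n = 100
        base = np.full((n, n), 2.0)
        pixels = [(20, 60), (30, 75), (15, 55)]
        for bi, bj in pixels:
            base[bi, bj] = base[bj, bi] = 10.0  # 5x the flat background
        m = ContactMatrix("chr1", 0, 50_000, base)
        res = apa_score(m, _loop_frame(pixels))
        assert res.apa_score == pytest.approx(5.0, rel=0.15)

    def test_pixels_near_edge_or_diagonal_skipped(self):
        m = ContactMatrix("chr1", 0, 50_000, np.ones((60, 60)))
        # (2,45): too close to the top edge; (15,20): separation within the
        # flank window; (12,45): usable
        res = apa_score(m, _loop_frame([(2, 45), (15, 20), (12, 45)]))
        assert res.n_pairs_used == 1 and res.n_pairs_skipped == 2
        with pytest.raises(ValidationError):
            apa_score(m, _loop_frame([(15, 20)]))

    def test_normal_condition_normalized_to_one(self):
        n = 100
        base = np.full((n, n), 2.0)
        base[20, 60] = base[60, 20] = 10.0
        normal = ContactMatrix("chr1", 0, 50_000, base)
        cancer_m = base.copy()
        cancer_m[20, 60] = cancer_m[60, 20] = 20.0
        cancer = ContactMatrix("chr1", 0, 50_000, cancer_m)
        out = apa_compare({"cancer": [cancer] * 2, "normal": [normal] * 2}, _loop_frame([(20, 60)]))
        out = out.set_index("condition")
        assert out.loc["normal", "normalized_ratio"] == pytest.approx(1.0)
        assert out.loc["cancer", "normalized_ratio"] > 1.5

    def test_vc_sqrt_preserves_symmetry(self, rng):
        raw = rng.random((30, 30))
        m = vc_sqrt_normalize(ContactMatrix("chr1", 0, 50_000, (raw + raw.T) / 2))
        np.testing.assert_allclose(m.matrix, m.matrix.T, atol=1e-12)


class TestLoopOverlapRatio:
    def test_identity_and_disjoint(self):
        cas = {"a": _site(1_000_000), "b": _site(5_000_000)}
        loops = {
            "a": _loop_frame([(20, 60)]),  # anchor 1 covers 1,000,000
            "b": _loop_frame([(100, 140)]),  # anchor 1 covers 5,000,000
        }
        m = loop_overlap_ratio(cas, loops, pad_bp=0)
        assert m.loc["a", "a"] == 1.0 and m.loc["b", "b"] == 1.0
        assert m.loc["a", "b"] == 0.0 and m.loc["b", "a"] == 0.0

    def test_matches_brute_force_counting(self, rng):
        tissues = ["x", "y"]
        cas, loops = {}, {}
        for t in tissues:
            starts = rng.integers(0, 5_000_000, 30)
            cas[t] = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 400})
            loops[t] = _loop_frame([tuple(sorted(rng.integers(0, 100, 2))) for _ in range(20)])
        pad = 5000
        m = loop_overlap_ratio(cas, loops, pad_bp=pad)
        for ti in tissues:
            counts = {}
            for tj in tissues:
                anchors = []
                for _, r in loops[tj].iterrows():
                    anchors.append((r["start1"] - pad, r["end1"] + pad))
                    anchors.append((r["start2"] - pad, r["end2"] + pad))
                n = 0
                for _, s in cas[ti].iterrows():
                    if any(s["start"] < hi and lo < s["end"] for lo, hi in anchors):
                        n += 1
                counts[tj] = n
            for tj in tissues:
                expected = counts[tj] / counts[ti] if counts[ti] else np.nan
                got = m.loc[ti, tj]
                assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)
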