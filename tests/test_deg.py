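"""Nearby-model (DRS) and loop-model DEG enrichment."""

import numpy as np
import pandas as pd
import pytest

from cohescan.deg import (
    DistanceProfile,
    _drs,
    casdeg_partition,
    connected_genes_per_site,
    deg_ratio_profile,
    drs_score,
    gene_site_distances,
    label_degs,
    loop_model_enrichment,
)
from cohescan.genome import ValidationError
from cohescan.simulate import generate_loops_to_genes, plant_loop_linked_degs


def _genes(tss_list, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(tss_list))],
            "chrom": chrom,
            "start": tss_list,
            "end": [t + 1000 for t in tss_list],
            "strand": "+",
            "tss": tss_list,
        }
    )


def _de(genes, is_deg, direction=None):
    de = pd.DataFrame({"gene_id": genes["gene_id"], "is_deg": is_deg})
    de["log2fc"] = np.where(is_deg, 2.0, 0.1)
    de["fdr"] = np.where(is_deg, 1e-5, 0.5)
    if direction is not None:
        de["direction"] = direction
    return de


class TestDegRatioProfile:
    def test_all_degs_ratio_one_everywhere(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([105_000, 150_000, 250_000])
        prof = deg_ratio_profile(sites, genes, _de(genes, [True] * 3))
        populated = prof.n_genes > 0
        assert np.allclose(prof.ratio[populated], 1.0)

    def test_no_degs_ratio_zero(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([105_000, 150_000])
        prof = deg_ratio_profile(sites, genes, _de(genes, [False, False]))
        assert np.nansum(prof.ratio) == 0

    def test_no_genes_in_range_errors(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([900_000])
        with pytest.raises(ValidationError):
            deg_ratio_profile(sites, genes, _de(genes, [True]))

    def test_matches_brute_force_counting(self, rng):
        sites = pd.DataFrame(
            {"chrom": "chr1", "start": rng.integers(0, 2_000_000, 40), "end": 0}
        )
        sites["end"] = sites["start"] + 400
        genes = _genes(sorted(rng.integers(0, 2_000_000, 300)))
        is_deg = rng.random(300) < 0.3
        de = _de(genes, is_deg)
        prof = deg_ratio_profile(sites, genes, de, max_bp=200_000, bin_bp=20_000)
        mids = ((sites["start"] + sites["end"]) // 2).to_numpy()
        for b in range(10):
            lo, hi = 20_000 * b, 20_000 * (b + 1)
            n_g = n_d = 0
            for gi, g in genes.iterrows():
                best = np.inf
                for mid, (_, s) in zip(mids, sites.iterrows()):
                    d = 0 if s["start"] <= g["tss"] < s["end"] else abs(int(g["tss"]) - int(mid))
                    best = min(best, d)
                # bin edges: nearest distance in [lo, hi); cap at 200 kb inclusive-last
                in_bin = (lo <= best < hi) or (b == 9 and best == 200_000)
                if in_bin:
                    n_g += 1
                    n_d += bool(is_deg[gi])
            assert prof.n_genes[b] == n_g
            if n_g:
                assert prof.ratio[b] == pytest.approx(n_d / n_g)

    def test_cumulative_profile_pools_genes_up_to_distance(self, rng):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000], "end": [1_000_400]})
        genes = _genes(sorted(rng.integers(800_000, 1_200_000, 200)))
        de = _de(genes, rng.random(200) < 0.3)
        per_bin = deg_ratio_profile(sites, genes, de)
        cum = deg_ratio_profile(sites, genes, de, cumulative=True)
        np.testing.assert_array_equal(cum.n_genes, np.cumsum(per_bin.n_genes))
        # last cumulative point is the overall DEG ratio within range
        total = per_bin.n_genes.sum()
        degs = np.nansum(per_bin.ratio * per_bin.n_genes)
        assert cum.ratio[-1] == pytest.approx(degs / total)

    def test_direction_filter_restricts_numerator(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([101_000, 102_000])
        de = _de(genes, [True, True], direction=["up", "down"])
        prof_up = deg_ratio_profile(sites, genes, de, direction_filter="up")
        assert np.nanmax(prof_up.ratio) == pytest.approx(0.5)


class TestDrs:
    def test_drs_arithmetic_cases(self):
        assert _drs(0.2, 0.2) == pytest.approx(0.0)
        assert _drs(0.3, 0.0) == pytest.approx(1.0)
        assert _drs(0.1, 0.2) == pytest.approx(-0.5)
        assert _drs(0.0, 0.0) == 0.0

    def test_drs_requires_enough_background_and_draws(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([105_000])
        de = _de(genes, [True])
        with pytest.raises(ValueError):
            drs_score(sites, sites, genes, de, n_draws=1)
        with pytest.raises(ValidationError):
            drs_score(pd.concat([sites, sites]), sites, genes, de)

    def test_drs_bounded_on_random_instances(self, rng):
        sites = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 3_000_000, 200), "end": 0})
        sites["end"] = sites["start"] + 400
        sites.index = [f"s{i}" for i in range(200)]
        genes = _genes(sorted(rng.integers(0, 3_000_000, 400)))
        for _ in range(5):
            de = _de(genes, rng.random(400) < rng.uniform(0.05, 0.6))
            res = drs_score(sites.iloc[:40], sites, genes, de, n_draws=20, seed=rng)
            assert -1.0 <= res.drs <= 1.0

    def test_null_cohort_drs_near_zero(self, small_cohort):
        # prob_near == prob_far is emulated by scoring a random subset of
        # the background against itself
        truth = small_cohort.truth
        de = small_cohort.de_tables["liver"]
        rng = np.random.default_rng(0)
        idx = rng.choice(len(truth.sites), 300, replace=False)
        res = drs_score(truth.sites.iloc[idx], truth.sites, small_cohort.genes, de, n_draws=100, seed=rng)
        assert abs(res.drs) < 0.1

    def test_s_integral_skips_empty_bins(self):
        prof = DistanceProfile(np.array([0, 10, 20]), np.array([0.5, np.nan]), np.array([4, 0]))
        assert prof.s_integral == pytest.approx(5.0)


class TestLoopModel:
    def _universe(self, rng, n_sites=300, n_genes=800, n_loops=500):
        sites = pd.DataFrame({"chrom": "chr1", "start": np.sort(rng.integers(0, 20_000_000, n_sites)), "end": 0})
        sites["end"] = sites["start"] + 400
        sites.index = [f"s{i}" for i in range(n_sites)]
        genes = _genes(sorted(rng.integers(0, 20_000_000, n_genes)))
        loops = generate_loops_to_genes(sites, genes, n_loops=n_loops, rng=rng)
        return sites, genes, loops

    def test_connection_requires_span_window(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000], "end": [1_000_400]})
        sites.index = ["s0"]
        genes = _genes([1_050_000])
        # 50 kb span: below the 200 kb loop-model floor
        loops = pd.DataFrame(
            {
                "chrom1": ["chr1"], "start1": [999_000], "end1": [1_001_000],
                "chrom2": ["chr1"], "start2": [1_049_000], "end2": [1_051_000],
            }
        )
        assert connected_genes_per_site(sites, loops, genes)["s0"] == set()
        wide = loops.assign(start2=1_500_000, end2=1_502_000)
        genes2 = _genes([1_501_000])
        assert connected_genes_per_site(sites, wide, genes2)["s0"] == {"g0"}

    def test_no_connected_genes_flags_undefined(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000], "end": [1_000_400]})
        sites.index = ["s0"]
        genes = _genes([5_000_000])
        loops = pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])
        res = loop_model_enrichment(sites, sites, loops, genes, _de(genes, [True]), n_draws=10)
        assert res.undefined

    def test_planted_connected_excess_detected(self, rng):
        sites, genes, loops = self._universe(rng)
        site_genes = connected_genes_per_site(sites, loops, genes)
        idx = rng.choice(len(sites), 60, replace=False)
        cas = sites.iloc[idx]
        connected = set().union(*(site_genes[i] for i in cas.index))
        de = plant_loop_linked_degs(genes, connected, prob_connected=0.6, prob_background=0.1, rng=rng)
        res = loop_model_enrichment(cas, sites, loops, genes, de, n_draws=499, seed=rng, site_genes=site_genes)
        assert res.wilcoxon_p < 0.01
        assert res.effect_size > 0.9

    def test_null_p_roughly_uniform(self, rng):
        sites, genes, loops = self._universe(rng)
        site_genes = connected_genes_per_site(sites, loops, genes)
        pvals = []
        for _ in range(100):
            de = plant_loop_linked_degs(genes, [], prob_background=0.2, rng=rng)
            idx = rng.choice(len(sites), 60, replace=False)
            res = loop_model_enrichment(
                sites.iloc[idx], sites, loops, genes, de, n_draws=99, seed=rng, site_genes=site_genes
            )
            pvals.append(res.wilcoxon_p)
        assert 0.2 < np.mean(pvals) < 0.8


class TestCasDegPartition:
    def test_partition_by_distance(self):
        cas = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([103_000, 150_000, 104_000, 160_000])
        de = _de(genes, [True, True, True, True])
        de["log2fc"] = [3.0, 1.5, 2.5, 1.6]
        part = casdeg_partition(cas, de, genes, near_bp=5000)
        assert set(part.cas_degs["gene_id"]) == {"g0", "g2"}
        assert set(part.other_degs["gene_id"]) == {"g1", "g3"}
        assert not part.undefined and part.mannwhitney_p <= 1.0

    def test_empty_partition_flagged(self):
        cas = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400]})
        genes = _genes([103_000])
        part = casdeg_partition(cas, _de(genes, [True]), genes)
        assert part.undefined

    def test_null_p_uniform_over_replicates(self, rng):
        cas = pd.DataFrame({"chrom": "chr1", "start": np.arange(20) * 500_000, "end": 0})
        cas["end"] = cas["start"] + 400
        genes = _genes(sorted(rng.integers(0, 10_000_000, 500)))
        pvals = []
        for _ in range(100):
            de = _de(genes, np.ones(500, dtype=bool))
            de["log2fc"] = rng.normal(2, 0.5, 500)  # same law both partitions
            pvals.append(casdeg_partition(cas, de, genes).mannwhitney_p)
        assert 0.3 < np.mean(pvals) < 0.7

    def test_planted_effect_detected(self, rng):
        cas = pd.DataFrame({"chrom": "chr1", "start": np.arange(20) * 500_000, "end": 0})
        cas["end"] = cas["start"] + 400
        genes = _genes(sorted(rng.integers(0, 10_000_000, 600)))
        hits = 0
        for _ in range(30):
            de = _de(genes, np.ones(600, dtype=bool))
            near = gene_site_distances(cas, genes, 5000).notna().to_numpy()
            de["log2fc"] = rng.normal(2, 0.5, 600) + 0.5 * near
            if casdeg_partition(cas, de, genes).mannwhitney_p < 0.01:
                hits += 1
        assert hits >= 27


class TestLabelDegs:
    def test_threshold_labeling(self):
        de = pd.DataFrame({"gene_id": ["a", "b", "c"], "log2fc": [2.0, -1.5, 0.5], "fdr": [1e-3, 1e-3, 1e-3]})
        out = label_degs(de)
        assert out["is_deg"].tolist() == [True, True, False]
        assert out["direction"].tolist() == ["up", "down", "none"]
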