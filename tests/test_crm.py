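"""TF enrichment, chromatin states, depletion response, methylation and
mutation statistics."""

import numpy as np
import pandas as pd
import pytest

from cohescan.crm import (
    chromatin_state_compare,
    conserved_sites,
    depletion_response_test,
    majority_state,
    methylation_differential,
    mutation_conserved_comparison,
    tf_enrichment,
)
from cohescan.genome import ValidationError
from tests.test_stats import fisher_two_sided_oracle


def _sites(n, spacing=10_000, width=400, chrom="chr1"):
    starts = spacing * (1 + np.arange(n))
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
    df.index = [f"site_{i}" for i in range(n)]
    return df


class TestTfEnrichment:
    def test_equal_fractions_give_p_near_one(self, rng):
        sites = _sites(400)
        cas = sites.iloc[:100]
        take = rng.random(400) < 0.3  # independent of CAS membership
        out = tf_enrichment(cas, sites, {"TF1": sites[take]})
        assert out.loc["TF1", "fisher_p"] > 0.05

    def test_strong_preference_detected_and_matches_enumeration(self):
        sites = _sites(200)
        cas = sites.iloc[:50]
        # TF covers 40/50 CAS and 10/150 background
        peaks = pd.concat([sites.iloc[:40], sites.iloc[50:60]])
        out = tf_enrichment(cas, sites, {"TF1": peaks})
        assert out.loc["TF1", "prop_cas"] == pytest.approx(0.8)
        assert out.loc["TF1", "fisher_p"] < 1e-10
        # one-sided enrichment p equals the hypergeometric upper tail
        from scipy.stats import hypergeom

        expected = hypergeom.sf(39, 200, 50, 50)
        assert out.loc["TF1", "fisher_p"] == pytest.approx(expected, abs=1e-12)

    def test_full_coverage_proportion_one(self):
        sites = _sites(50)
        out = tf_enrichment(sites.iloc[:10], sites, {"TF1": sites.copy()})
        assert out.loc["TF1", "prop_cas"] == 1.0

    def test_empty_tf_skipped(self):
        sites = _sites(20)
        out = tf_enrichment(sites.iloc[:5], sites, {"TFempty": sites.iloc[:0]})
        assert len(out) == 0


class TestChromatinState:
    def _segmentation(self, states, bin_bp=200, chrom="chr1"):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": bin_bp * np.arange(len(states)),
                "end": bin_bp * (1 + np.arange(len(states))),
                "state": states,
            }
        )

    def test_majority_bp_state(self):
        seg = self._segmentation([1, 2, 2, 3])
        site = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [650]})
        # covers 50 bp of state 1, 400 bp of state 2, 50 bp of state 3
        assert majority_state(site, seg).iloc[0] == 2

    def test_identical_segmentations_equal_proportions_p_one(self):
        seg = self._segmentation(np.tile([1, 5, 9, 13], 50))
        sites = _sites(30, spacing=1000, width=400)
        out = chromatin_state_compare(sites, seg, seg)
        pd.testing.assert_series_equal(out["proportions_normal"], out["proportions_cancer"])
        assert out["fisher_p"] == pytest.approx(1.0)
        assert out["proportions_normal"].sum() == pytest.approx(1.0)

    def test_planted_active_state_gain_detected(self):
        sites = _sites(60, spacing=1000, width=400)
        seg_n = self._segmentation(np.full(400, 9))  # inactive everywhere
        seg_c = self._segmentation(np.full(400, 7))  # active enhancer everywhere
        out = chromatin_state_compare(sites, seg_n, seg_c)
        assert out["fisher_p"] < 1e-10

    def test_uncovered_sites_counted_missing(self):
        seg = self._segmentation([1, 1])
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 90_000], "end": [200, 90_200]})
        out = chromatin_state_compare(sites, seg, seg)
        assert out["n_missing_normal"] == 1


class TestDepletionResponse:
    def _table(self, rng, n=500):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc": rng.normal(0, 1, n),
                "significant": rng.random(n) < 0.6,
            }
        )

    def test_identical_groups_equal_ratio_p_one(self, rng):
        dep = self._table(rng)
        genes = [f"g{i}" for i in range(100)]
        out = depletion_response_test({"a": genes, "b": list(genes)}, dep)
        assert out["ratios"]["a"] == out["ratios"]["b"]
        assert out["pairwise_fisher_p"].loc["a", "b"] == pytest.approx(1.0)

    def test_ratio_definition_and_fisher_oracle(self, rng):
        dep = self._table(rng)
        dec = (dep["log2fc"] < 0) & dep["significant"]
        ga = [f"g{i}" for i in range(0, 120)]
        gb = [f"g{i}" for i in range(120, 300)]
        out = depletion_response_test({"a": ga, "b": gb}, dep)
        ka = int(dec.iloc[0:120].sum())
        kb = int(dec.iloc[120:300].sum())
        assert out["ratios"]["a"] == pytest.approx(ka / 120)
        assert out["pairwise_fisher_p"].loc["a", "b"] == pytest.approx(
            fisher_two_sided_oracle(ka, 120 - ka, kb, 180 - kb), abs=1e-10
        )

    def test_absent_group_errors(self, rng):
        with pytest.raises(ValidationError):
            depletion_response_test({"a": ["nope"]}, self._table(rng))


class TestMethylation:
    def test_beta_outside_unit_interval_rejected(self, rng):
        sites = _sites(10)
        bad = rng.random((10, 4))
        bad[0, 0] = 1.2
        with pytest.raises(ValidationError):
            methylation_differential(sites, bad, rng.random((10, 4)), sites.iloc[:2], sites)

    def test_null_populations_ratio_matches_background(self, rng):
        sites = _sites(300)
        bc = rng.random((300, 20))
        bn = rng.random((300, 20))
        res = methylation_differential(sites, bc, bn, sites.iloc[:50], sites, n_draws=50, seed=1)
        assert res.significant.sum() == 0  # p<1e-7 unreachable under the null here
        assert res.cas_ratio == pytest.approx(res.envelope["q50"], abs=0.05)

    def test_planted_hypermethylation_detected_above_envelope(self, rng):
        sites = _sites(300)
        bn = rng.beta(2, 8, size=(300, 20))
        bc = rng.beta(2, 8, size=(300, 20))
        planted = np.arange(40)
        bc[planted] = rng.beta(30, 2, size=(40, 20))
        res = methylation_differential(
            sites, bc, bn, sites.iloc[planted], sites, direction="hyper", n_draws=100, seed=2
        )
        assert res.cas_ratio > res.envelope["q97.5"]
        assert res.cas_ratio > 0.5


class TestMutations:
    def test_conserved_site_definition(self):
        presence = pd.DataFrame(
            {
                "c1": [True, True, False],
                "c2": [True, True, True],
                "n1": [True, False, True],
                "n2": [True, True, True],
            },
            index=["s1", "s2", "s3"],
        )
        manifest = pd.DataFrame(
            {"sample_id": ["c1", "c2", "n1", "n2"], "condition": ["cancer", "cancer", "normal", "normal"]}
        )
        assert list(conserved_sites(presence, manifest, min_fraction=0.9)) == ["s1"]

    def test_uniform_mutations_flat_rates(self, rng):
        sites = _sites(300, spacing=5_000)
        muts = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 2_000_000, 40_000)})
        out = mutation_conserved_comparison(
            muts, {"cas": sites.iloc[:150], "other": sites.iloc[150:]}, {"chr1": 2_000_000}
        )
        ratio = out["rates"]["cas"] / out["rates"]["other"]
        assert ratio == pytest.approx(1.0, rel=0.25)
        assert out["pairwise_p"].loc["cas", "other"] > 0.01

    def test_planted_enrichment_fold_recovered(self, rng):
        sites = _sites(200, spacing=8_000)
        cas, other = sites.iloc[:100], sites.iloc[100:]
        base = rng.integers(0, 1_700_000, 30_000)
        extra_rows = rng.integers(0, 100, 2 * 30_000 * 100 * 400 // 1_700_000)
        extra = cas["start"].to_numpy()[extra_rows] + rng.integers(0, 400, len(extra_rows))
        muts = pd.DataFrame({"chrom": "chr1", "pos": np.concatenate([base, extra])})
        out = mutation_conserved_comparison(muts, {"cas": cas, "other": other}, {"chr1": 1_700_000})
        ratio = out["rates"]["cas"] / out["rates"]["other"]
        assert ratio == pytest.approx(3.0, rel=0.2)

    def test_zero_bp_class_errors(self, rng):
        sites = _sites(10)
        muts = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        with pytest.raises(ValidationError):
            mutation_conserved_comparison(muts, {"empty": sites.iloc[:0]}, {"chr1": 1_000_000})
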