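"""Gini/region statistics, metagene binning, site-centered profiles,
regression and random-site contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from structome import (
    ReactivityProfile,
    SiteRecord,
    TranscriptModel,
    annotate_and_window,
    condition_contrast,
    gini,
    metagene_delta,
    pearson_delta,
    random_site_contrast,
    region_summary,
    site_profile,
)
from structome.structure_stats import bin_of, delta_regression, site_delta, site_features


def _gini_oracle(x):
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())


class TestGini:
    def test_constant_vector_zero(self):
        assert gini(np.full(20, 3.0)) == pytest.approx(0.0)

    def test_one_hot_closed_form(self):
        # [0,0,0,1] has G = (n-1)/n = 0.75
        assert gini([0, 0, 0, 1], min_n=4) == pytest.approx(0.75)
        assert gini([0, 0, 0, 1], min_n=4) == pytest.approx(_gini_oracle([0, 0, 0, 1]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        assert gini(7.3 * x) == pytest.approx(gini(x))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            gini(np.array([-1.0] + [1.0] * 20))

    def test_min_n_rule(self):
        assert np.isnan(gini(np.ones(5)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(10, 200))
    def test_matches_double_loop_oracle(self, seed, n):
        x = np.random.default_rng(seed).random(n)
        assert gini(x) == pytest.approx(_gini_oracle(x), abs=1e-12)


def _flat_profiles(tx, wt_val, ko_val):
    return {
        (tx.transcript_id, "WT"): ReactivityProfile(tx.transcript_id, "WT",
                                                    np.full(tx.length, wt_val)),
        (tx.transcript_id, "KO"): ReactivityProfile(tx.transcript_id, "KO",
                                                    np.full(tx.length, ko_val)),
    }


class TestRegionSummary:
    def test_identical_conditions_fc_one(self, toy_transcript):
        rng = np.random.default_rng(1)
        vals = rng.random(toy_transcript.length)
        profiles = {
            ("toy", "WT"): ReactivityProfile("toy", "WT", vals),
            ("toy", "KO"): ReactivityProfile("toy", "KO", vals.copy()),
        }
        summary = region_summary(profiles, {"toy": toy_transcript})
        contrast = condition_contrast(summary)
        whole = contrast[(contrast.region == "whole")]
        np.testing.assert_allclose(whole.fc_ko_vs_wt, 1.0)
        assert whole.wilcoxon_p.isna().all()  # all-zero differences: no test

    def test_halved_ko_scales_mean_not_gini(self, toy_transcript):
        rng = np.random.default_rng(2)
        vals = rng.random(toy_transcript.length)
        profiles = {
            ("toy", "WT"): ReactivityProfile("toy", "WT", vals),
            ("toy", "KO"): ReactivityProfile("toy", "KO", 0.5 * vals),
        }
        summary = region_summary(profiles, {"toy": toy_transcript})
        contrast = condition_contrast(summary)
        row = contrast[(contrast.region == "whole") & (contrast.statistic == "mean_reactivity")]
        assert row.fc_ko_vs_wt.iloc[0] == pytest.approx(0.5)
        grow = contrast[(contrast.region == "whole") & (contrast.statistic == "gini")]
        assert grow.delta_mean.iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestMetagene:
    def test_bin_assignment_rule(self):
        assert [bin_of(p, 10, 5) for p in range(10)] == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_bins_total_and_onto(self):
        for ell in (5, 7, 23, 100):
            for B in (5,):
                if ell < B:
                    continue
                bins = [bin_of(p, ell, B) for p in range(ell)]
                assert set(bins) == set(range(B))

    def test_constant_conditions_zero_delta_degenerate_ci(self, toy_transcript):
        profiles = _flat_profiles(toy_transcript, 0.5, 0.5)
        out = metagene_delta(profiles, {"toy": toy_transcript})
        present = out[out.n > 0]
        assert (present.delta == 0).all()
        assert (present.ci_low == 0).all() and (present.ci_high == 0).all()

    def test_effect_confined_to_3utr(self, toy_transcript):
        rng = np.random.default_rng(3)
        n_tx = 15
        transcriptome, profiles = {}, {}
        for i in range(n_tx):
            tid = f"t{i}"
            tx = TranscriptModel(tid, "g", "A" * 300, 50, 200)
            transcriptome[tid] = tx
            wt = rng.random(300) + 0.5
            ko = wt.copy()
            ko[200:] -= 0.4
            profiles[(tid, "WT")] = ReactivityProfile(tid, "WT", wt)
            profiles[(tid, "KO")] = ReactivityProfile(tid, "KO", np.clip(ko, 0, None))
        out = metagene_delta(profiles, transcriptome)
        utr3 = out[out.region == "3UTR"].delta.abs().mean()
        utr5 = out[out.region == "5UTR"].delta.abs().mean()
        assert utr3 > 5 * utr5
        # CI contains the point estimate
        ok = out.dropna()
        assert ((ok.ci_low <= ok.delta) & (ok.delta <= ok.ci_high)).all()


class TestSiteProfile:
    def test_flat_profile_flat_curve(self, toy_transcript):
        profiles = _flat_profiles(toy_transcript, 0.4, 0.4)
        site = annotate_and_window(SiteRecord("toy", 150), toy_transcript)
        out = site_profile(profiles, [site])
        np.testing.assert_allclose(out.mean_WT, 0.4)
        np.testing.assert_allclose(out.mean_KO, 0.4)

    def test_clipping_near_start(self, toy_transcript):
        profiles = _flat_profiles(toy_transcript, 0.4, 0.4)
        site = annotate_and_window(SiteRecord("toy", 10), toy_transcript)
        out = site_profile(profiles, [site])
        # offsets -50..-11 have no in-bounds position
        assert (out[out.offset < -10].n_WT == 0).all()
        assert (out[out.offset >= -10].n_WT == 1).all()

    def test_constant_per_transcript_mean(self):
        txs, profiles, sites = {}, {}, []
        for i, c in enumerate([0.2, 0.6]):
            tid = f"t{i}"
            tx = TranscriptModel(tid, "g", "A" * 300, 0, 150)
            txs[tid] = tx
            profiles[(tid, "WT")] = ReactivityProfile(tid, "WT", np.full(300, c))
            profiles[(tid, "KO")] = ReactivityProfile(tid, "KO", np.full(300, c))
            sites.append(annotate_and_window(SiteRecord(tid, 150), tx))
        out = site_profile(profiles, sites)
        np.testing.assert_allclose(out.mean_WT, 0.4)


class TestRegression:
    def test_response_equal_to_predictor_recovers_unit_coef(self):
        rng = np.random.default_rng(4)
        txs, sites = {}, []
        for i in range(40):
            tid = f"t{i}"
            seq = "".join(rng.choice(list("ACGT"), size=400,
                                     p=[0.35 - i * 0.004, 0.15 + i * 0.004,
                                        0.15 + i * 0.004, 0.35 - i * 0.004]))
            tx = TranscriptModel(tid, "g", seq, 50, 250)
            txs[tid] = tx
            sites.append(annotate_and_window(SiteRecord(tid, int(rng.integers(250, 400))), tx))
        feats = site_features(sites, txs)
        deltas = feats[["transcript_id", "anchor", "region"]].copy()
        z = (feats.regional_gc - feats.regional_gc.mean()) / feats.regional_gc.std(ddof=0)
        deltas["delta"] = z
        coefs, corr = delta_regression(deltas, feats)
        row = coefs[(coefs.model == "all") & (coefs.term == "regional_gc")]
        assert row.coef.iloc[0] == pytest.approx(1.0, abs=1e-6)
        others = coefs[(coefs.model == "all") & (coefs.term != "regional_gc")]
        assert (others.coef.abs() < 1e-6).all()

    def test_pearson_anticorrelation(self):
        x = np.linspace(0, 1, 50)
        r, p = pearson_delta(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10


class TestRandomSiteContrast:
    def _setup(self, effect_in_window):
        rng = np.random.default_rng(9)
        txs, profiles, sites = {}, {}, []
        for i in range(60):
            tid = f"t{i}"
            tx = TranscriptModel(tid, "g", "A" * 600, 0, 100)
            txs[tid] = tx
            anchor = int(rng.integers(160, 540))
            site = annotate_and_window(SiteRecord(tid, anchor), tx)
            sites.append(site)
            wt = rng.random(600) * 0.2 + 0.4
            ko = wt + rng.normal(0, 0.01, 600)
            if effect_in_window:
                ko[site.window[0]: site.window[1]] -= 0.3
            else:
                ko[100:] -= 0.3  # region-wide
            profiles[(tid, "WT")] = ReactivityProfile(tid, "WT", wt)
            profiles[(tid, "KO")] = ReactivityProfile(tid, "KO", np.clip(ko, 0, None))
        return txs, profiles, sites

    def test_localized_effect_detected(self):
        txs, profiles, sites = self._setup(True)
        out = random_site_contrast(sites, txs, profiles, n_draws=5, seed=1)
        row = out[out.region == "3UTR"]
        assert row.ranksum_p.iloc[0] < 0.05
        assert row.real_median_absdelta.iloc[0] > row.random_median_absdelta.iloc[0]

    def test_regionwide_effect_not_flagged(self):
        txs, profiles, sites = self._setup(False)
        out = random_site_contrast(sites, txs, profiles, n_draws=5, seed=1)
        assert out[out.region == "3UTR"].ranksum_p.iloc[0] > 0.05

    def test_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            random_site_contrast([], {}, {}, n_draws=0)
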