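"""Fold changes, pFC classification, overlap statistics, Monte Carlo
enrichment and half-life degradation targets."""

import numpy as np
import pandas as pd
import pytest

from structome import (
    CountMatrix,
    HalfLifeTable,
    SimConfig,
    SiteRecord,
    TranscriptModel,
    annotate_and_window,
    classify_pfc,
    fold_changes,
    halflife_degradation_targets,
    hypergeometric_overlap,
    monte_carlo_enrichment,
    overlap_stats,
    simulate_expression,
    simulate_structurome,
)
from structome.abundance import overlap_percentage


def _cm(counts: dict[str, list[int]], genes=None):
    cols = list(counts)
    n = len(next(iter(counts.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    meta = []
    for col in cols:
        cond, rest = col.split("_", 1)
        frac, rep = rest.rsplit("_", 1)
        meta.append((col, cond, frac, int(rep)))
    samples = pd.DataFrame(meta, columns=["sample", "condition", "fraction", "replicate"]
                           ).set_index("sample")
    return CountMatrix(pd.DataFrame(counts, index=genes), samples)


class TestFoldChanges:
    def test_identical_conditions_unit_fc(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, 200)
        cm = _cm({
            "WT_chromatin_1": base, "WT_chromatin_2": base,
            "KO_chromatin_1": base, "KO_chromatin_2": base,
        })
        fc = fold_changes(cm)
        np.testing.assert_allclose(fc["FC_chromatin"], 1.0)

    def test_doubled_gene_approaches_two(self):
        n = 300
        rng = np.random.default_rng(1)
        base = rng.integers(10_000, 50_000, n)
        ko = base.copy()
        ko[0] = 2 * base[0]
        cm = _cm({
            "WT_chromatin_1": base, "WT_chromatin_2": base,
            "KO_chromatin_1": ko, "KO_chromatin_2": ko,
        })
        fc = fold_changes(cm)
        assert fc["FC_chromatin"].iloc[0] == pytest.approx(2.0, rel=0.01)

    def test_depth_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.integers(100, 1000, 150)
        ko1, ko2 = rng.integers(100, 1000, 150), rng.integers(100, 1000, 150)
        cm = _cm({
            "WT_chromatin_1": base, "WT_chromatin_2": base + 1,
            "KO_chromatin_1": ko1, "KO_chromatin_2": ko2,
        })
        cm2 = _cm({
            "WT_chromatin_1": base, "WT_chromatin_2": base + 1,
            "KO_chromatin_1": 2 * ko1, "KO_chromatin_2": 2 * ko2,
        })
        # doubling both KO libraries' depth cancels through size factors
        # (pseudocount off: the additive offset is not depth-equivariant)
        a = fold_changes(cm, pseudocount=0.0)
        b = fold_changes(cm2, pseudocount=0.0)
        np.testing.assert_allclose(a["FC_chromatin"], b["FC_chromatin"], rtol=1e-9)


class TestClassifyPfc:
    def _df(self, chr_fc, wc_fc):
        return pd.DataFrame({"FC_chromatin": chr_fc, "FC_whole_cell": wc_fc},
                            index=[f"g{i}" for i in range(len(chr_fc))])

    def test_examples(self):
        out = classify_pfc(self._df([1.0, 1.0, 1.0], [0.5, 1.8, 1.0]))
        assert list(out.pfc_class) == ["pDG", "pUG", "neither"]
        assert out.pFC.iloc[0] == pytest.approx(2.0)
        assert out.pFC.iloc[1] == pytest.approx(1 / 1.8)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        chr_fc = rng.lognormal(0, 0.5, 500)
        wc_fc = rng.lognormal(0, 0.5, 500)
        a = classify_pfc(self._df(chr_fc, wc_fc))
        b = classify_pfc(self._df(wc_fc, chr_fc))
        swap = {"pDG": "pUG", "pUG": "pDG", "neither": "neither"}
        assert list(b.pfc_class) == [swap[c] for c in a.pfc_class]

    def test_planted_classes_recovered(self):
        cfg = SimConfig(n_genes_expr=1000, expr_depth=500.0, seed=11)
        truth = type("T", (), {})()
        from structome import GroundTruth

        truth = GroundTruth({}, {}, {}, {}, [])
        cm, _ = simulate_expression(cfg, truth)
        out = classify_pfc(fold_changes(cm))
        agree = (out.pfc_class == truth.pfc_class.loc[out.index]).mean()
        assert agree >= 0.90


class TestOverlapStats:
    def test_printed_count_percentages(self):
        assert overlap_percentage(1998, 149) == pytest.approx(7.5, abs=0.05)
        assert overlap_percentage(1850, 517) == pytest.approx(27.9, abs=0.05)
        assert overlap_percentage(2886, 541) == pytest.approx(18.75, abs=0.005)

    def test_overlap_stats_on_sets(self):
        classified = pd.DataFrame(
            {"pfc_class": ["pDG"] * 10 + ["pUG"] * 10},
            index=[f"g{i}" for i in range(20)],
        )
        bound = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
        out = overlap_stats(classified, bound)
        assert out["classes"]["pDG"]["percent_bound"] == pytest.approx(50.0)
        # identical row proportions: chi-square statistic ~ 0, p ~ 1
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["chi2_p"] == pytest.approx(1.0)

    def test_hypergeometric_exact(self):
        universe = [f"g{i}" for i in range(10)]
        a = universe[:5]
        ov, p = hypergeometric_overlap(a, a, universe)
        assert ov == 5
        assert p == pytest.approx(1 / 252)


class TestMonteCarloEnrichment:
    def _fixture(self):
        txs, sites, feats = {}, [], []
        rng = np.random.default_rng(5)
        for i in range(20):
            tid = f"t{i}"
            tx = TranscriptModel(tid, "g", "A" * 1200, 0, 200)  # 1000nt 3'UTR
            txs[tid] = tx
            anchor = int(rng.integers(260, 1140))
            site = annotate_and_window(SiteRecord(tid, anchor), tx)
            sites.append(site)
            feats.append(SiteRecord(tid, anchor, "m6A"))
        return txs, sites, feats

    def test_extreme_enrichment_floor_p(self):
        txs, sites, feats = self._fixture()
        res = monte_carlo_enrichment(sites, feats, txs, n_sets=100, seed=0)
        assert res.observed == len(sites)
        assert res.p_value == pytest.approx(1 / 101)

    def test_saturated_features_p_one(self):
        txs, sites, _ = self._fixture()
        feats = [SiteRecord(tid, pos, "m6A") for tid in txs for pos in range(200, 1200, 50)]
        res = monte_carlo_enrichment(sites, feats, txs, n_sets=50, seed=0)
        assert res.p_value == 1.0

    def test_deterministic_and_order_invariant(self):
        txs, sites, feats = self._fixture()
        a = monte_carlo_enrichment(sites, feats, txs, n_sets=50, seed=3)
        b = monte_carlo_enrichment(list(reversed(sites)), feats, txs, n_sets=50, seed=3)
        assert a.p_value == b.p_value and a.observed == b.observed

    def test_empty_feature_set(self):
        txs, sites, _ = self._fixture()
        with pytest.warns(UserWarning, match="feature set empty"):
            res = monte_carlo_enrichment(sites, [], txs, n_sets=10, seed=0)
        assert res.p_value == 1.0

    def test_zero_sets_rejected(self):
        txs, sites, feats = self._fixture()
        with pytest.raises(ValueError):
            monte_carlo_enrichment(sites, feats, txs, n_sets=0)

    def test_colocation_enrichment_detected(self):
        cfg = SimConfig(n_transcripts=15, n_binding_sites=40, n_m6a=60, rho=20.0, seed=21,
                        site_region_probs={"5UTR": 0.0, "CDS": 0.0, "3UTR": 1.0})
        txome, truth, sites = simulate_structurome(cfg)
        res = monte_carlo_enrichment(sites, truth.m6a_sites, txome, n_sets=100, seed=2)
        assert res.p_value < 0.05
        assert res.z_score > 2


class TestHalfLife:
    def _hl(self, rows):
        return HalfLifeTable(pd.DataFrame(rows, columns=["gene_id", "replicate",
                                                         "wt_halflife", "ko_halflife"]))

    def test_boundary_fc_of_one_not_target(self):
        hl = self._hl([("g1", 1, 4.0, 4.0), ("g1", 2, 5.0, 5.0)])
        assert halflife_degradation_targets(hl)["targets"] == set()

    def test_averaged_replicate_ratios(self):
        hl = self._hl([("g1", 1, 1.0, 1.2), ("g1", 2, 1.0, 0.9), ("g1", 3, 1.0, 1.2)])
        out = halflife_degradation_targets(hl)
        assert out["overall_fc"]["g1"] == pytest.approx(1.1)
        assert out["targets"] == {"g1"}

    def test_planted_targets_recovered_at_zero_noise(self):
        cfg = SimConfig(n_genes_expr=300, halflife_noise=0.0, seed=13)
        from structome import GroundTruth

        truth = GroundTruth({}, {}, {}, {}, [])
        _, hl = simulate_expression(cfg, truth)
        out = halflife_degradation_targets(hl, candidate_genes=truth.degradation_targets,
                                           universe={f"gene{i:04d}" for i in range(300)})
        assert out["targets"] == truth.degradation_targets
        assert out["hypergeometric_p"] < 1e-10
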