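"""Synthetic structurome data with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* transcript sequences with per-region GC content (3'UTRs GC-poorer than
  5'UTRs by default);
* per-position accessibility a_i in [0,1] (Beta(2,2)) in WT; KO
  accessibility is compressed transcriptome-wide (the global structure
  gain of the depleted condition) and further reduced by a planted effect
  delta at binding-site windows plus a configurable spillover fraction of
  the host 3'UTR;
* RT stops that are negative-binomial around depth * background * (1 +
  k * a_i) in probe-treated libraries and depth * background in mock;
* m6A / YTHDF1 anchors placed in 3'UTRs, co-located with binding windows
  at a configurable enrichment rho;
* chromatin / whole-cell count matrices with planted post-transcriptional
  fold-change classes, and half-life tables with planted degradation
  targets;
* RBNS pools with planted k-mer R values.

Everything is driven by a single seed; identical configs give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import (
    CDS,
    FIVE_UTR,
    THREE_UTR,
    CountMatrix,
    HalfLifeTable,
    RTStopTable,
    SiteRecord,
    TranscriptModel,
    annotate_and_window,
)
from .rbns import all_kmers

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic structurome."""

    n_transcripts: int = 100
    # mean region lengths (nt); realized lengths are ~N(mean, 0.2*mean), floored
    len_utr5: int = 100
    len_cds: int = 500
    len_utr3: int = 400
    # per-region GC content; 3'UTR lower than 5'UTR by default
    gc: Mapping[str, float] = field(
        default_factory=lambda: {FIVE_UTR: 0.60, CDS: 0.50, THREE_UTR: 0.40}
    )
    n_binding_sites: int = 100
    site_region_probs: Mapping[str, float] = field(
        default_factory=lambda: {FIVE_UTR: 0.15, CDS: 0.25, THREE_UTR: 0.60}
    )
    # planted KO structuring effect. The default model is multiplicative:
    # KO accessibility is compressed by (1 - delta_global) transcriptome-wide
    # (the global structure gain of the depleted condition) and additionally
    # by (1 - delta) on affected intervals. The subtractive model instead
    # subtracts delta on affected intervals (floored at 0).
    delta: float = 0.4
    delta_global: float = 0.3
    effect_model: str = "multiplicative"
    spillover_frac: float = 0.2
    # sequencing model
    depth: float = 20.0
    dispersion: float = 0.1
    gain_k: float = 5.0
    n_replicates: int = 2
    chemistry: str = "shape"
    # m6A / YTHDF1 co-location
    n_m6a: int = 200
    n_ythdf1: int = 200
    rho: float = 3.0
    # expression / abundance model
    n_genes_expr: int = 1000
    expr_depth: float = 500.0
    expr_dispersion: float = 0.01
    pfc_effect: float = 2.0
    frac_pdg: float = 0.15
    frac_pug: float = 0.15
    # half-life model
    n_halflife_reps: int = 3
    frac_degradation_targets: float = 0.2
    halflife_effect: float = 1.5
    halflife_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("delta", "delta_global", "spillover_frac", "depth", "dispersion",
                     "gain_k", "expr_depth", "expr_dispersion", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.effect_model not in ("multiplicative", "subtractive"):
            raise ValueError("effect_model must be 'multiplicative' or 'subtractive'")


@dataclass
class GroundTruth:
    """Recovery targets for the planted effects."""

    acc_wt: dict[str, np.ndarray]
    acc_ko: dict[str, np.ndarray]
    affected: dict[str, np.ndarray]  # bool per position
    background: dict[str, np.ndarray]
    sites: list[SiteRecord]
    m6a_sites: list[SiteRecord] = field(default_factory=list)
    ythdf1_sites: list[SiteRecord] = field(default_factory=list)
    m6a_in_window: Optional[np.ndarray] = None
    pfc_class: Optional[pd.Series] = None
    true_pfc: Optional[pd.Series] = None
    degradation_targets: Optional[set] = None


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_sequence(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _region_length(rng, mean: int, minimum: int = 20) -> int:
    return max(minimum, int(round(rng.normal(mean, 0.2 * mean))))


def simulate_structurome(config: SimConfig):
    """Generate (transcriptome, GroundTruth, binding sites).

    Binding-site anchors are placed per the regional placement
    probabilities. Affected intervals are the binding windows plus a
    ``spillover_frac`` Bernoulli subset of the remaining 3'UTR positions of
    bound transcripts; KO accessibility there drops by the site-level delta
    on top of the transcriptome-wide ``delta_global`` compression (see
    ``SimConfig.effect_model``). m6A and YTHDF1 anchors land in 3'UTRs with
    weight rho inside binding windows.
    """
    rng_seq, rng_acc, rng_site, rng_feat = _rngs(config.seed, 4)
    transcriptome: dict[str, TranscriptModel] = {}
    acc_wt, acc_ko, affected, background = {}, {}, {}, {}
    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        parts = []
        lens = {}
        for region, mean in ((FIVE_UTR, config.len_utr5), (CDS, config.len_cds),
                             (THREE_UTR, config.len_utr3)):
            ell = _region_length(rng_seq, mean)
            lens[region] = ell
            parts.append(_sample_sequence(rng_seq, ell, config.gc[region]))
        seq = "".join(parts)
        transcriptome[tid] = TranscriptModel(
            tid, f"gene{i:04d}", seq, lens[FIVE_UTR], lens[FIVE_UTR] + lens[CDS]
        )
        L = len(seq)
        acc_wt[tid] = rng_acc.beta(2.0, 2.0, size=L)
        affected[tid] = np.zeros(L, dtype=bool)
        background[tid] = rng_acc.gamma(5.0, 0.2, size=L)  # mean 1 positional bias

    # binding sites
    tids = sorted(transcriptome)
    regions = list(config.site_region_probs)
    probs = np.array([config.site_region_probs[r] for r in regions], dtype=float)
    probs = probs / probs.sum()
    sites: list[SiteRecord] = []
    for j in range(config.n_binding_sites):
        for attempt in range(100):
            tid = tids[rng_site.integers(len(tids))]
            tx = transcriptome[tid]
            region = regions[rng_site.choice(len(regions), p=probs)]
            s, e = tx.region_bounds(region)
            if e - s < 1:
                continue
            anchor = int(rng_site.integers(s, e))
            site = annotate_and_window(
                SiteRecord(tid, anchor, "crosslink", f"crosslink{j:04d}"), tx
            )
            sites.append(site)
            break
        else:
            raise RuntimeError("could not place binding site after 100 attempts")

    # planted KO effect: windows plus 3'UTR spillover on bound transcripts
    bound_tids = {s.transcript_id for s in sites}
    for site in sites:
        ws, we = site.window
        affected[site.transcript_id][ws:we] = True
    for tid in sorted(bound_tids):
        tx = transcriptome[tid]
        u3s, u3e = tx.region_bounds(THREE_UTR)
        mask = np.zeros(tx.length, dtype=bool)
        mask[u3s:u3e] = True
        mask &= ~affected[tid]
        if config.spillover_frac > 0 and mask.any():
            hit = rng_site.random(tx.length) < config.spillover_frac
            affected[tid] |= mask & hit
    for tid in tids:
        aff = affected[tid]
        if config.effect_model == "multiplicative":
            ko = acc_wt[tid] * (1.0 - config.delta_global)
            ko[aff] *= 1.0 - config.delta
        else:
            ko = np.maximum(0.0, acc_wt[tid] - config.delta_global)
            ko[aff] = np.maximum(0.0, acc_wt[tid][aff] - config.delta)
        acc_ko[tid] = ko

    # m6A / YTHDF1 anchors in 3'UTRs, enriched rho-fold inside binding windows
    def place_features(n, rng, label):
        pool_tid, pool_pos, pool_w = [], [], []
        for tid in tids:
            tx = transcriptome[tid]
            u3s, u3e = tx.region_bounds(THREE_UTR)
            if u3e <= u3s:
                continue
            in_window = np.zeros(tx.length, dtype=bool)
            for s in sites:
                if s.transcript_id == tid:
                    in_window[s.window[0]: s.window[1]] = True
            pos = np.arange(u3s, u3e)
            pool_tid.extend([tid] * pos.size)
            pool_pos.append(pos)
            pool_w.append(np.where(in_window[pos], config.rho, 1.0))
        pos_all = np.concatenate(pool_pos)
        w = np.concatenate(pool_w)
        w = w / w.sum()
        picks = rng.choice(pos_all.size, size=n, replace=False, p=w)
        feats = []
        inside = []
        for idx, pick in enumerate(sorted(picks)):
            tid = pool_tid[pick]
            anchor = int(pos_all[pick])
            feats.append(
                annotate_and_window(
                    SiteRecord(tid, anchor, label, f"{label}{idx:04d}"),
                    transcriptome[tid],
                )
            )
            in_win = any(
                s.transcript_id == tid and s.window[0] <= anchor < s.window[1]
                for s in sites
            )
            inside.append(in_win)
        return feats, np.array(inside, dtype=bool)

    m6a, m6a_in = place_features(config.n_m6a, rng_feat, "m6A")
    ythdf1, _ = place_features(config.n_ythdf1, rng_feat, "YTHDF1")

    truth = GroundTruth(acc_wt, acc_ko, affected, background, sites,
                        m6a, ythdf1, m6a_in)
    return transcriptome, truth, sites


def _negbin(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean m and Var = m + dispersion * m^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_rtstops(
    transcriptome: Mapping[str, TranscriptModel],
    truth: GroundTruth,
    config: SimConfig,
) -> list[RTStopTable]:
    """RT-stop tables for treated and mock libraries of both conditions.

    Mock stops ~ NB(depth * b_i); treated stops ~ NB(depth * b_i *
    (1 + k * a_i)). In DMS chemistry the modification gain is zeroed at
    G/T positions.
    """
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    tables = []
    acc = {"WT": truth.acc_wt, "KO": truth.acc_ko}
    for tid in sorted(transcriptome):
        tx = transcriptome[tid]
        b = truth.background[tid]
        if config.chemistry == "dms":
            seq = np.frombuffer(tx.sequence.encode(), dtype="S1")
            gain_mask = np.isin(seq, [b"A", b"C"]).astype(float)
        else:
            gain_mask = np.ones(tx.length)
        for cond in ("WT", "KO"):
            a = acc[cond][tid]
            mean_treated = config.depth * b * (1.0 + config.gain_k * a * gain_mask)
            mean_mock = config.depth * b
            for rep in range(1, config.n_replicates + 1):
                tables.append(RTStopTable(
                    tid, cond, "treated", rep,
                    _negbin(rng, mean_treated, config.dispersion)))
                tables.append(RTStopTable(
                    tid, cond, "mock", rep,
                    _negbin(rng, mean_mock, config.dispersion)))
    return tables


def simulate_expression(
    config: SimConfig, truth: Optional[GroundTruth] = None
) -> tuple[CountMatrix, HalfLifeTable]:
    """Chromatin and whole-cell count matrices with planted pFC classes,
    plus half-life tables with planted degradation targets.

    Chromatin counts share a common KO/WT fold change per gene; whole-cell
    counts divide in the post-transcriptional effect so that the true pFC
    matches the assigned class. The planted classes, true pFC values and
    degradation targets are recorded on ``truth`` when supplied.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    n = config.n_genes_expr
    genes = [f"gene{i:04d}" for i in range(n)]
    n_pdg = int(round(config.frac_pdg * n))
    n_pug = int(round(config.frac_pug * n))
    classes = np.array(["pDG"] * n_pdg + ["pUG"] * n_pug + ["neither"] * (n - n_pdg - n_pug))
    rng.shuffle(classes)
    true_pfc = np.where(classes == "pDG", config.pfc_effect,
                        np.where(classes == "pUG", 1.0 / config.pfc_effect, 1.0))
    base = config.expr_depth * rng.lognormal(0.0, 0.5, size=n)
    fc_chr = rng.lognormal(0.0, 0.1, size=n)
    fc_wc = fc_chr / true_pfc
    cols, data, meta = [], [], []
    for fraction, fc in (("chromatin", fc_chr), ("whole_cell", fc_wc)):
        for cond, mult in (("WT", np.ones(n)), ("KO", fc)):
            for rep in (1, 2):
                col = f"{cond}_{fraction}_{rep}"
                cols.append(col)
                meta.append((col, cond, fraction, rep))
                data.append(_negbin(rng, base * mult, config.expr_dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(meta, columns=["sample", "condition", "fraction",
                                          "replicate"]).set_index("sample")
    cm = CountMatrix(counts, samples)

    n_targets = int(round(config.frac_degradation_targets * n))
    target_idx = rng.choice(n, size=n_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True
    sd = config.halflife_noise
    wt_hl = rng.lognormal(np.log(4.0), 0.3, size=n)
    hl_fc = np.where(is_target,
                     config.halflife_effect * rng.lognormal(0.0, sd, size=n),
                     rng.lognormal(0.0, sd, size=n))
    rows = []
    for rep in range(1, config.n_halflife_reps + 1):
        noise_wt = rng.lognormal(0.0, sd, size=n)
        noise_ko = rng.lognormal(0.0, sd, size=n)
        rows.append(pd.DataFrame({
            "gene_id": genes,
            "replicate": rep,
            "wt_halflife": wt_hl * noise_wt,
            "ko_halflife": wt_hl * hl_fc * noise_ko,
        }))
    hl = HalfLifeTable(pd.concat(rows, ignore_index=True))
    if truth is not None:
        truth.pfc_class = pd.Series(classes, index=genes)
        truth.true_pfc = pd.Series(true_pfc, index=genes)
        truth.degradation_targets = {g for g, t in zip(genes, is_target) if t}
    return cm, hl


def simulate_rbns(
    config: SimConfig,
    enrichment: Optional[Mapping[str, float]] = None,
    pool_size: int = 1_000_000,
    k: int = 6,
    concentrations=(5, 20, 80, 320, 1300),
) -> tuple[dict[str, int], dict[str, dict[str, int]]]:
    """Multinomial k-mer pools: input uniform over 4^k k-mers, bound pools
    resampled with probability proportional to the target R value. An empty
    enrichment spec is equivalent to all targets = 1."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])
    kmers = all_kmers(k)
    m = len(kmers)
    p_in = np.full(m, 1.0 / m)
    counts_in = rng.multinomial(pool_size, p_in)
    target_r = np.ones(m)
    if enrichment:
        index = {km: i for i, km in enumerate(kmers)}
        for km, r in enrichment.items():
            if r < 0:
                raise ValueError("target R values must be >= 0")
            target_r[index[km.upper().replace("U", "T")]] = r
    p_bound = p_in * target_r
    p_bound = p_bound / p_bound.sum()
    bound = {}
    for conc in concentrations:
        bound[str(conc)] = dict(zip(kmers, rng.multinomial(pool_size, p_bound)))
    return dict(zip(kmers, counts_in)), bound
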