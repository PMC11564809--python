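"""Post-transcriptional fold-change statistics and enrichment tests.

The post-transcriptional fold change of a gene is

    pFC = FC_chromatin / FC_wholecell       (each FC is KO/WT)

A pFC above the chromatin trend means the transcript is lost
post-transcriptionally in the KO: genes with pFC >= 1.5 are
post-transcriptionally downregulated (pDG), pFC <= 1/1.5 upregulated
(pUG). Count normalization uses median-of-ratios size factors; the
matched-random Monte Carlo test draws, per real binding-site window, a
random window of equal length from the same 3'UTR.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    THREE_UTR,
    CountMatrix,
    EnrichmentResult,
    HalfLifeTable,
    SiteRecord,
    TranscriptModel,
)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample. Genes with any zero count
    are excluded from the median."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = counts.gt(0).all(axis=1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no genes usable for size-factor estimation")
    if n_usable < 100:
        warnings.warn(f"only {n_usable} genes usable for size factors")
    ratios = log_counts.sub(log_geomean, axis=0)[usable]
    return np.exp(ratios.median(axis=0))


def fold_changes(cm: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene KO/WT fold change in each fraction after size-factor
    normalization: FC = (mean normalized KO + pc) / (mean normalized WT + pc)."""
    out = {}
    for fraction in sorted(cm.samples.fraction.unique()):
        cols = list(cm.samples.index[cm.samples.fraction == fraction])
        sub = cm.counts[cols]
        sf = size_factors(sub)
        norm = sub / sf
        ko_cols = cm.columns_for("KO", fraction)
        wt_cols = cm.columns_for("WT", fraction)
        fc = (norm[ko_cols].mean(axis=1) + pseudocount) / (
            norm[wt_cols].mean(axis=1) + pseudocount
        )
        out[f"FC_{fraction}"] = fc
    return pd.DataFrame(out)


def classify_pfc(
    fc: pd.DataFrame,
    threshold: float = 1.5,
    strict: bool = False,
    chromatin_col: str = "FC_chromatin",
    wholecell_col: str = "FC_whole_cell",
) -> pd.DataFrame:
    """Attach pFC = FC_chromatin / FC_wholecell and the pDG/pUG/neither
    class. Thresholds are inclusive (>= / <=) unless ``strict``. Genes with
    non-positive FCs are excluded with a warning."""
    df = fc.copy()
    ok = (df[chromatin_col] > 0) & (df[wholecell_col] > 0)
    if (~ok).any():
        warnings.warn(f"excluded {int((~ok).sum())} genes with non-positive FC")
        df = df[ok]
    df = df.assign(pFC=df[chromatin_col] / df[wholecell_col])
    lo = 1.0 / threshold
    if strict:
        pdg = df.pFC > threshold
        pug = df.pFC < lo
    else:
        pdg = df.pFC >= threshold
        pug = df.pFC <= lo
    df = df.assign(pfc_class=np.where(pdg, "pDG", np.where(pug, "pUG", "neither")))
    return df


def overlap_stats(
    classified: pd.DataFrame, bound_genes: Iterable[str]
) -> dict:
    """Per-class overlap with a bound-gene set, plus the 2x2 chi-square
    (bound/unbound x pDG/pUG, no continuity correction).

    Returns per class: size, bound count, and percentage 100*bound/size
    (NaN for an empty class).
    """
    bound = set(bound_genes)
    res = {"classes": {}}
    table = []
    for cls in ("pDG", "pUG", "neither"):
        genes = set(classified.index[classified.pfc_class == cls])
        n, b = len(genes), len(genes & bound)
        res["classes"][cls] = {
            "n": n,
            "bound": b,
            "percent_bound": 100.0 * b / n if n else float("nan"),
        }
        if cls in ("pDG", "pUG"):
            table.append([b, n - b])
    table = np.array(table)
    if table.size and table.sum(axis=1).all() and table.sum(axis=0).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        res["chi2"] = float(chi2)
        res["chi2_p"] = float(p)
    else:
        res["chi2"] = float("nan")
        res["chi2_p"] = float("nan")
    return res


def overlap_percentage(class_size: int, bound_count: int) -> float:
    """Percentage of a gene class overlapping a reference set."""
    if class_size <= 0:
        return float("nan")
    return 100.0 * bound_count / class_size


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric p of the overlap of two gene sets within a
    caller-supplied universe. Returns (overlap, p)."""
    u = set(universe)
    a = set(set_a) & u
    b = set(set_b) & u
    if not (set(set_a) <= u and set(set_b) <= u):
        raise ValueError("universe must contain both sets")
    ov = len(a & b)
    p = float(stats.hypergeom.sf(ov - 1, len(u), len(a), len(b)))
    return ov, p


def monte_carlo_enrichment(
    real_sites: Sequence[SiteRecord],
    feature_sites: Sequence[SiteRecord],
    transcriptome: Mapping[str, TranscriptModel],
    n_sets: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Monte Carlo enrichment of feature anchors within site windows.

    The observed statistic is the number of real windows containing at
    least one feature anchor. Each of ``n_sets`` null sets draws one random
    window per real site of the same length from the same 3'UTR (uniform
    start); when the 3'UTR cannot fit the window the draw falls back to the
    whole transcript (logged). Empirical p uses the +1 correction:
    p = (1 + #{null >= observed}) / (1 + n_sets).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    feats: dict[str, np.ndarray] = {}
    for f in feature_sites:
        feats.setdefault(f.transcript_id, []).append(f.anchor)
    feats = {k: np.asarray(sorted(v)) for k, v in feats.items()}
    sites = sorted(real_sites, key=lambda s: (s.transcript_id, s.anchor))

    def count_hits(windows):
        n = 0
        for tid, ws, we in windows:
            anchors = feats.get(tid)
            if anchors is None:
                continue
            i = np.searchsorted(anchors, ws, side="left")
            if i < anchors.size and anchors[i] < we:
                n += 1
        return n

    observed_windows = [(s.transcript_id, *s.window) for s in sites]
    observed = count_hits(observed_windows)
    if not feats:
        warnings.warn("feature set empty; p = 1")
        return EnrichmentResult(observed, 0.0, 0.0, 1.0, float("nan"), n_sets,
                                np.zeros(n_sets, dtype=int))
    # precompute the sampling span per site
    spans = []
    for s in sites:
        tx = transcriptome[s.transcript_id]
        wlen = s.window[1] - s.window[0]
        u3s, u3e = tx.region_bounds(THREE_UTR)
        if u3e - u3s >= wlen:
            spans.append((s.transcript_id, u3s, u3e - wlen, wlen))
        else:
            warnings.warn(
                f"site {s.name} on {s.transcript_id}: 3'UTR shorter than window; "
                "shuffling within the whole transcript"
            )
            spans.append((s.transcript_id, 0, tx.length - wlen, wlen))
    null_counts = np.empty(n_sets, dtype=int)
    for k in range(n_sets):
        windows = []
        for tid, lo, hi, wlen in spans:
            start = int(rng.integers(lo, hi + 1))
            windows.append((tid, start, start + wlen))
        null_counts[k] = count_hits(windows)
    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=1)) if n_sets > 1 else 0.0
    p = (1.0 + int(np.sum(null_counts >= observed))) / (1.0 + n_sets)
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    return EnrichmentResult(observed, null_mean, null_sd, float(p), float(z),
                            n_sets, null_counts)


def halflife_degradation_targets(
    halflife: HalfLifeTable,
    candidate_genes: Optional[Iterable[str]] = None,
    universe: Optional[Iterable[str]] = None,
) -> dict:
    """Degradation targets from half-life tables: per-gene per-replicate
    KO/WT half-life ratios are averaged to an overall fold change; genes
    with overall FC > 1 (strict) are targets. Optionally intersect with a
    candidate set (hypergeometric p when a universe is supplied)."""
    t = halflife.table
    fc = (t.ko_halflife / t.wt_halflife).groupby(t.gene_id).mean()
    targets = set(fc.index[fc > 1.0])
    out = {"overall_fc": fc, "targets": targets, "n_targets": len(targets)}
    if candidate_genes is not None:
        cand = set(candidate_genes)
        inter = targets & cand
        out["candidates"] = cand
        out["intersection"] = inter
        out["n_intersection"] = len(inter)
        if universe is not None:
            _, p = hypergeometric_overlap(targets, cand, universe)
            out["hypergeometric_p"] = p
    return out
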