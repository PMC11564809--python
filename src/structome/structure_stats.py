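"""Whole-transcript, regional, binned-metagene and site-centered structure
statistics, plus sequence-feature correlation/regression analyses.

The two cohort statistics are the mean reactivity (higher = more
accessible) and the Gini index of reactivity (higher = more heterogeneous,
i.e. more structured overall): G = sum_ij |x_i - x_j| / (2 n^2 xbar).
Condition contrasts are reported as KO/WT fold changes of the cohort mean
of each statistic, with paired Wilcoxon signed-rank p across transcripts.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .model import (
    CDS,
    FIVE_UTR,
    REGIONS,
    THREE_UTR,
    ReactivityProfile,
    SiteRecord,
    TranscriptModel,
)

DEFAULT_BINS = {FIVE_UTR: 5, CDS: 10, THREE_UTR: 5}

ProfileMap = Mapping[tuple[str, str], ReactivityProfile]


def gini(values, min_n: int = 10) -> float:
    """Gini index of non-negative values via the sorted-rank identity
    (equivalent to the mean-absolute-difference double sum).

    NaN when fewer than ``min_n`` non-missing values or zero mean; negative
    input raises (clamped profiles are expected upstream).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if np.any(x < 0):
        raise ValueError("gini requires non-negative values")
    n = x.size
    if n < min_n:
        return float("nan")
    total = x.sum()
    if total == 0:
        return float("nan")
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * xs) - (n + 1) * total) / (n * total))


def _region_slices(tx: TranscriptModel):
    yield "whole", 0, tx.length
    for region in REGIONS:
        s, e = tx.region_bounds(region)
        yield region, s, e


def region_summary(
    profiles: ProfileMap,
    transcriptome: Mapping[str, TranscriptModel],
    min_gini_n: int = 10,
) -> pd.DataFrame:
    """Per-transcript, per-region mean reactivity and Gini for each condition.

    Rows: transcript_id, region in {whole, 5UTR, CDS, 3UTR}, condition,
    mean_reactivity, gini, n_valid.
    """
    rows = []
    for (tid, cond), prof in sorted(profiles.items()):
        tx = transcriptome[tid]
        for region, s, e in _region_slices(tx):
            seg = prof.values[s:e]
            valid = seg[~np.isnan(seg)]
            rows.append(
                {
                    "transcript_id": tid,
                    "region": region,
                    "condition": cond,
                    "mean_reactivity": valid.mean() if valid.size else np.nan,
                    "gini": gini(valid, min_gini_n) if valid.size else np.nan,
                    "n_valid": valid.size,
                }
            )
    return pd.DataFrame(rows)


def condition_contrast(summary: pd.DataFrame) -> pd.DataFrame:
    """Cohort KO-vs-WT contrast per region and statistic.

    FC is the ratio of the cohort means of the statistic (KO over WT),
    restricted to transcripts present in both conditions; p is the paired
    Wilcoxon signed-rank across transcripts (NaN when all differences are
    zero — no test).
    """
    out = []
    for region in ["whole", *REGIONS]:
        sub = summary[summary.region == region]
        wide = sub.pivot_table(
            index="transcript_id", columns="condition",
            values=["mean_reactivity", "gini"], aggfunc="first",
        )
        for stat_name in ("mean_reactivity", "gini"):
            if stat_name not in wide.columns.get_level_values(0):
                continue
            sw = wide[stat_name]
            if "WT" not in sw.columns or "KO" not in sw.columns:
                continue
            paired = sw.dropna()
            if paired.empty:
                continue
            wt, ko = paired["WT"].to_numpy(), paired["KO"].to_numpy()
            fc = ko.mean() / wt.mean() if wt.mean() != 0 else np.nan
            diffs = ko - wt
            if np.allclose(diffs, 0):
                p = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = stats.wilcoxon(ko, wt, correction=True, method="approx")
            out.append(
                {
                    "region": region,
                    "statistic": stat_name,
                    "n_transcripts": paired.shape[0],
                    "mean_WT": wt.mean(),
                    "mean_KO": ko.mean(),
                    "fc_ko_vs_wt": fc,
                    "delta_mean": diffs.mean(),
                    "wilcoxon_p": p,
                }
            )
    return pd.DataFrame(out)


def bin_of(pos: int, region_len: int, n_bins: int) -> int:
    """Metagene bin of a 0-based position within a region of given length:
    floor(p*B/l), clipped to B-1."""
    return min(pos * n_bins // region_len, n_bins - 1)


def metagene_delta(
    profiles: ProfileMap,
    transcriptome: Mapping[str, TranscriptModel],
    bins_spec: Optional[dict[str, int]] = None,
    statistic: str = "mean",
    min_gini_n: int = 10,
) -> pd.DataFrame:
    """Binned KO-WT difference of per-bin mean reactivity (or Gini) across
    each region, with a 95% paired-t confidence interval per bin.

    Every transcript contributes its per-bin statistic in each condition;
    the bin's delta is the cross-transcript mean of (KO - WT) with
    CI = mean +/- t_{0.975, n-1} * sd / sqrt(n). Zero-variance bins get a
    degenerate CI equal to the mean.
    """
    bins_spec = bins_spec or DEFAULT_BINS
    tids = sorted({tid for (tid, cond) in profiles if (tid, "WT") in profiles and (tid, "KO") in profiles})
    per_bin: dict[tuple[str, int], list[float]] = {}
    for tid in tids:
        tx = transcriptome[tid]
        wt, ko = profiles[(tid, "WT")].values, profiles[(tid, "KO")].values
        for region, n_bins in bins_spec.items():
            s, e = tx.region_bounds(region)
            ell = e - s
            if ell == 0:
                continue
            idx = np.array([bin_of(p, ell, n_bins) for p in range(ell)])
            for b in range(n_bins):
                sel = idx == b
                if not sel.any():
                    continue
                w_seg, k_seg = wt[s:e][sel], ko[s:e][sel]
                if statistic == "mean":
                    w_stat = np.nanmean(w_seg) if np.any(~np.isnan(w_seg)) else np.nan
                    k_stat = np.nanmean(k_seg) if np.any(~np.isnan(k_seg)) else np.nan
                else:
                    w_stat = gini(w_seg, min_gini_n)
                    k_stat = gini(k_seg, min_gini_n)
                if np.isnan(w_stat) or np.isnan(k_stat):
                    continue
                per_bin.setdefault((region, b), []).append(k_stat - w_stat)
    rows = []
    for region, n_bins in bins_spec.items():
        for b in range(n_bins):
            deltas = np.asarray(per_bin.get((region, b), []), dtype=float)
            n = deltas.size
            if n == 0:
                rows.append({"region": region, "bin": b, "delta": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "n": 0})
                continue
            m = deltas.mean()
            sd = deltas.std(ddof=1) if n > 1 else 0.0
            if n > 1 and sd > 0:
                half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            else:
                half = 0.0
            rows.append({"region": region, "bin": b, "delta": m,
                         "ci_low": m - half, "ci_high": m + half, "n": n})
    return pd.DataFrame(rows)


def site_profile(
    profiles: ProfileMap,
    sites: Sequence[SiteRecord],
    halfwidth: int = 50,
) -> pd.DataFrame:
    """Site-centered metagene: mean reactivity at each offset from the
    anchor (position 0 = the anchor), per condition, over all sites whose
    offset position is in bounds and unmasked."""
    offsets = np.arange(-halfwidth, halfwidth + 1)
    sums = {c: np.zeros(offsets.size) for c in ("WT", "KO")}
    counts = {c: np.zeros(offsets.size, dtype=int) for c in ("WT", "KO")}
    any_site = False
    for site in sites:
        for cond in ("WT", "KO"):
            prof = profiles.get((site.transcript_id, cond))
            if prof is None:
                continue
            any_site = True
            pos = site.anchor + offsets
            ok = (pos >= 0) & (pos < prof.length)
            vals = np.full(offsets.size, np.nan)
            vals[ok] = prof.values[pos[ok]]
            good = ~np.isnan(vals)
            sums[cond][good] += vals[good]
            counts[cond][good] += 1
    if not any_site:
        warnings.warn("no site overlaps any profile; empty site profile")
        return pd.DataFrame(columns=["offset", "mean_WT", "mean_KO", "n_WT", "n_KO", "delta"])
    with np.errstate(invalid="ignore"):
        mean_wt = np.where(counts["WT"] > 0, sums["WT"] / np.maximum(counts["WT"], 1), np.nan)
        mean_ko = np.where(counts["KO"] > 0, sums["KO"] / np.maximum(counts["KO"], 1), np.nan)
    return pd.DataFrame(
        {
            "offset": offsets,
            "mean_WT": mean_wt,
            "mean_KO": mean_ko,
            "n_WT": counts["WT"],
            "n_KO": counts["KO"],
            "delta": mean_ko - mean_wt,
        }
    )


def site_delta(
    profiles: ProfileMap, sites: Sequence[SiteRecord]
) -> pd.DataFrame:
    """Per-site mean KO-WT reactivity difference over the site window."""
    rows = []
    for site in sites:
        wt = profiles.get((site.transcript_id, "WT"))
        ko = profiles.get((site.transcript_id, "KO"))
        if wt is None or ko is None:
            continue
        s, e = site.window
        d = ko.values[s:e] - wt.values[s:e]
        if np.all(np.isnan(d)):
            continue
        rows.append(
            {
                "transcript_id": site.transcript_id,
                "anchor": site.anchor,
                "region": site.region,
                "delta": np.nanmean(d),
            }
        )
    return pd.DataFrame(rows)


def site_features(
    sites: Sequence[SiteRecord], transcriptome: Mapping[str, TranscriptModel]
) -> pd.DataFrame:
    """Sequence covariates per site: GC fraction of the site window
    (localized GC), GC fraction of the host region (regional GC), and
    ln(length) of the host region."""
    rows = []
    for site in sites:
        tx = transcriptome[site.transcript_id]
        ws, we = site.window
        rs, re_ = tx.region_bounds(site.region)
        rows.append(
            {
                "transcript_id": site.transcript_id,
                "anchor": site.anchor,
                "region": site.region,
                "local_gc": tx.gc_fraction(ws, we),
                "regional_gc": tx.gc_fraction(rs, re_),
                "ln_region_length": np.log(re_ - rs) if re_ > rs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def delta_regression(
    deltas: pd.DataFrame, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS of the per-site reactivity change on z-scored sequence covariates.

    One model per site stratum (all sites, then each region). Returns
    (coefficient table with columns model/term/coef/p/n, pairwise predictor
    correlation table as the collinearity check). Zero-variance predictors
    are dropped with a warning; models with n <= p+1 are skipped.
    """
    df = deltas.merge(features, on=["transcript_id", "anchor", "region"]).dropna()
    predictors = ["local_gc", "regional_gc", "ln_region_length"]
    coef_rows, corr_rows = [], []
    strata = [("all", df)] + [(r, df[df.region == r]) for r in REGIONS]
    for model_name, sub in strata:
        keep = [p for p in predictors if sub[p].std(ddof=0) > 0]
        dropped = set(predictors) - set(keep)
        if dropped and len(sub) > 0:
            warnings.warn(f"{model_name}: dropped zero-variance predictors {sorted(dropped)}")
        if len(sub) <= len(keep) + 1 or not keep:
            continue
        y = _zscore(sub["delta"].to_numpy(dtype=float))
        X = np.column_stack([_zscore(sub[p].to_numpy(dtype=float)) for p in keep])
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for i, term in enumerate(keep, start=1):
            coef_rows.append(
                {"model": model_name, "term": term, "coef": fit.params[i],
                 "p": fit.pvalues[i], "n": int(fit.nobs)}
            )
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                r, _ = stats.pearsonr(sub[a], sub[b])
                corr_rows.append({"model": model_name, "a": a, "b": b, "pearson_r": r})
    return pd.DataFrame(coef_rows), pd.DataFrame(corr_rows)


def pearson_delta(x, y) -> tuple[float, float]:
    """Pearson correlation of a regional delta against a feature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def random_site_contrast(
    sites: Sequence[SiteRecord],
    transcriptome: Mapping[str, TranscriptModel],
    profiles: ProfileMap,
    n_draws: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare |reactivity change| at real sites against matched random
    windows (same length, same region, same transcript, uniform start).

    Sites whose host region cannot fit the window are skipped. Returns a
    per-region table with the rank-sum (Mann-Whitney) p of real vs random
    |delta| distributions.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    real = {r: [] for r in REGIONS}
    rand = {r: [] for r in REGIONS}
    for site in sites:
        tx = transcriptome[site.transcript_id]
        wt = profiles.get((site.transcript_id, "WT"))
        ko = profiles.get((site.transcript_id, "KO"))
        if wt is None or ko is None:
            continue
        ws, we = site.window
        wlen = we - ws
        rs, re_ = tx.region_bounds(site.region)
        if re_ - rs < wlen:
            continue
        delta = ko.values - wt.values
        d_real = np.nanmean(delta[ws:we])
        if np.isnan(d_real):
            continue
        real[site.region].append(abs(d_real))
        starts = rng.integers(rs, re_ - wlen + 1, size=n_draws)
        for s in starts:
            d = np.nanmean(delta[s : s + wlen])
            if not np.isnan(d):
                rand[site.region].append(abs(d))
    rows = []
    for region in REGIONS:
        a, b = np.asarray(real[region]), np.asarray(rand[region])
        if a.size == 0 or b.size == 0:
            continue
        _, p = stats.mannwhitneyu(a, b, alternative="greater")
        rows.append(
            {
                "region": region,
                "n_sites": a.size,
                "real_median_absdelta": float(np.median(a)),
                "random_median_absdelta": float(np.median(b)),
                "ranksum_p": float(p),
            }
        )
    return pd.DataFrame(rows)
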