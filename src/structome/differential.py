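"""Differentially reactive region (DRR) calling between conditions.

A deliberately simple, self-contained caller: per position it contrasts
the mean between-condition replicate difference with the mean
within-condition difference, averages the contrast over sliding windows,
and assesses each window against an empirical null built from
replicate-relabelings augmented with circular position shifts. Window p
values are Benjamini-Hochberg corrected; significant windows are merged
into DRRs.

With two replicates per condition the balanced relabeling space is tiny
(two non-identity splits), so the null is deliberately augmented with
seeded circular shifts of the pseudo-KO group; the caller trades exactness
for a usable empirical null and is not a reimplementation of any published
differential-reactivity test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.multitest import multipletests

from .model import DRR, REGIONS, ReactivityProfile, SiteRecord, TranscriptModel

# the two balanced non-identity splits of replicates [W1, W2, K1, K2]
_NULL_SPLITS = (((0, 2), (1, 3)), ((0, 3), (1, 2)))


def _pair_diffs(groups_a: np.ndarray, groups_b: np.ndarray) -> np.ndarray:
    """Mean |a_i - b_j| over all cross pairs, per position (NaN-aware)."""
    diffs = [
        np.abs(a - b)
        for a in groups_a
        for b in groups_b
    ]
    return np.nanmean(np.stack(diffs), axis=0)


def _tracks(stack: np.ndarray, idx_a, idx_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (d_between, d_within) for one replicate split."""
    a, b = stack[list(idx_a)], stack[list(idx_b)]
    d_between = _pair_diffs(a, b)
    d_within = np.nanmean(
        np.stack([np.abs(a[0] - a[1]), np.abs(b[0] - b[1])]), axis=0
    )
    return d_between, d_within


def _window_scores_from(contrast: np.ndarray, window: int) -> np.ndarray:
    if contrast.size < window:
        return np.array([])
    win = sliding_window_view(contrast, window)
    with np.errstate(invalid="ignore"):
        return np.nanmean(win, axis=1)


def _window_scores(stack: np.ndarray, idx_a, idx_b, window: int) -> np.ndarray:
    """Sliding-window mean of d_between - d_within for one replicate split."""
    d_between, d_within = _tracks(stack, idx_a, idx_b)
    return _window_scores_from(d_between - d_within, window)


def call_drrs(
    wt_reps: Mapping[str, Sequence[ReactivityProfile]],
    ko_reps: Mapping[str, Sequence[ReactivityProfile]],
    min_length: int = 5,
    q_max: float = 0.25,
    window: int = 11,
    n_shifts: int = 20,
    seed: int = 0,
) -> list[DRR]:
    """Call DRRs from per-replicate normalized profiles of both conditions.

    ``wt_reps``/``ko_reps`` map transcript_id to a list of (>=2) replicate
    profiles. Null window scores are pooled across transcripts from the two
    non-identity balanced replicate splits plus ``n_shifts`` random circular
    shifts of the pseudo-KO group under random splits (seeded).
    """
    if window < min_length:
        raise ValueError("window must be >= min_length")
    rng = np.random.default_rng(seed)
    tids = sorted(set(wt_reps) & set(ko_reps))
    obs_scores: list[np.ndarray] = []
    obs_meta: list[tuple[str, int]] = []
    null_scores: list[np.ndarray] = []
    deltas: dict[str, np.ndarray] = {}
    contrasts: dict[str, np.ndarray] = {}
    for tid in tids:
        wt, ko = list(wt_reps[tid]), list(ko_reps[tid])
        if len(wt) < 2 or len(ko) < 2:
            raise ValueError(f"{tid}: need >=2 replicates per condition")
        stack = np.stack([p.values for p in wt[:2] + ko[:2]])
        deltas[tid] = np.nanmean(stack[2:], axis=0) - np.nanmean(stack[:2], axis=0)
        d_between, d_within = _tracks(stack, (0, 1), (2, 3))
        contrasts[tid] = d_between - d_within
        scores = _window_scores_from(contrasts[tid], window)
        if scores.size == 0:
            continue
        obs_scores.append(scores)
        obs_meta.extend((tid, s) for s in range(scores.size))
        for split_a, split_b in _NULL_SPLITS:
            null_scores.append(_window_scores(stack, split_a, split_b, window))
        # shift augmentation: under each non-identity relabeling (which mixes
        # WT and KO inside each pseudo-condition, cancelling genuine effects)
        # roll the within-track relative to the between-track; both tracks
        # stay position-aligned with the transcript so baseline
        # heterogeneity does not inflate the null
        L = stack.shape[1]
        for _ in range(n_shifts):
            split_a, split_b = _NULL_SPLITS[rng.integers(2)]
            d_between, d_within = _tracks(stack, split_a, split_b)
            shift = int(rng.integers(1, L)) if L > 1 else 0
            null_scores.append(
                _window_scores_from(d_between - np.roll(d_within, shift), window)
            )
    if not obs_scores:
        return []
    obs = np.concatenate(obs_scores)
    null = np.concatenate([s for s in null_scores if s.size]) if null_scores else np.array([])
    null = null[~np.isnan(null)]
    valid = ~np.isnan(obs)
    null_sorted = np.sort(null)
    # one-sided empirical p with the +1 correction
    n_null = null_sorted.size
    p = np.ones(obs.size)
    if n_null:
        ge = n_null - np.searchsorted(null_sorted, obs[valid], side="left")
        p[valid] = (1.0 + ge) / (1.0 + n_null)
    reject = np.zeros(obs.size, dtype=bool)
    qvals = np.ones(obs.size)
    if valid.any():
        rej, q, _, _ = multipletests(p[valid], alpha=q_max, method="fdr_bh")
        reject[valid] = rej
        qvals[valid] = q
    # merge overlapping significant windows per transcript
    drrs: list[DRR] = []
    by_tid: dict[str, list[tuple[int, float, float]]] = {}
    for i, (tid, start) in enumerate(obs_meta):
        if reject[i]:
            by_tid.setdefault(tid, []).append((start, obs[i], qvals[i]))
    for tid in sorted(by_tid):
        wins = sorted(by_tid[tid])
        cur_s, cur_e = wins[0][0], wins[0][0] + window
        cur_score, cur_q = wins[0][1], wins[0][2]
        merged = []
        for s, sc, q in wins[1:]:
            if s < cur_e:
                cur_e = max(cur_e, s + window)
                cur_score = max(cur_score, sc)
                cur_q = min(cur_q, q)
            else:
                merged.append((cur_s, cur_e, cur_score, cur_q))
                cur_s, cur_e, cur_score, cur_q = s, s + window, sc, q
        merged.append((cur_s, cur_e, cur_score, cur_q))
        for s, e, sc, q in merged:
            # boundary refinement: merged windows overhang the true effect by
            # up to window-1 nt on each side; trim edge positions whose
            # per-position contrast falls below a quarter of the interval peak
            c = contrasts[tid]
            thr = 0.25 * np.nanmax(c[s:e])
            while s < e and not c[s] >= thr:
                s += 1
            while e > s and not c[e - 1] >= thr:
                e -= 1
            if e - s < min_length:
                continue
            d = np.nanmean(deltas[tid][s:e])
            direction = "gain_structure" if d < 0 else "loss_structure"
            drrs.append(DRR(tid, int(s), int(e), direction, float(sc), float(q)))
    return drrs


def drr_enrichment_summary(
    drrs: Sequence[DRR],
    sites: Sequence[SiteRecord],
    transcriptome: Mapping[str, TranscriptModel],
) -> dict:
    """Summarize DRRs relative to binding-site windows.

    Returns: fraction of DRRs overlapping >=1 nt of any site window;
    fraction of site windows containing >=1 DRR; per-region DRR counts,
    raw and divided by the number of binding events in that region; and
    the fraction of DRRs with the gain_structure direction.
    """
    windows_by_tid: dict[str, list[tuple[int, int]]] = {}
    region_events = {r: 0 for r in REGIONS}
    for s in sites:
        windows_by_tid.setdefault(s.transcript_id, []).append(s.window)
        if s.region in region_events:
            region_events[s.region] += 1
    n_drr = len(drrs)
    drr_hit = 0
    site_hit = {(s.transcript_id, s.window) for s in sites if any(
        d.transcript_id == s.transcript_id and d.start < s.window[1] and d.end > s.window[0]
        for d in drrs
    )}
    region_counts = {r: 0 for r in REGIONS}
    gain = 0
    for d in drrs:
        wins = windows_by_tid.get(d.transcript_id, [])
        if any(d.start < we and d.end > ws for ws, we in wins):
            drr_hit += 1
        if d.direction == "gain_structure":
            gain += 1
        tx = transcriptome.get(d.transcript_id)
        if tx is not None:
            mid = (d.start + d.end - 1) // 2
            region_counts[tx.region_of(mid)] += 1
    per_region = {
        r: {
            "n_drrs": region_counts[r],
            "n_binding_events": region_events[r],
            "drrs_per_event": (
                region_counts[r] / region_events[r] if region_events[r] else float("nan")
            ),
        }
        for r in REGIONS
    }
    n_sites = len(sites)
    return {
        "frac_drrs_in_sites": drr_hit / n_drr if n_drr else float("nan"),
        "frac_sites_with_drr": len(site_hit) / n_sites if n_sites else float("nan"),
        "per_region": per_region,
        "frac_gain_structure": gain / n_drr if n_drr else float("nan"),
        "n_drrs": n_drr,
    }


def drrs_to_frame(drrs: Sequence[DRR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": d.transcript_id,
                "start": d.start,
                "end": d.end,
                "direction": d.direction,
                "score": d.score,
                "q_value": d.q_value,
            }
            for d in sorted(drrs, key=lambda d: (d.transcript_id, d.start))
        ],
        columns=["transcript_id", "start", "end", "direction", "score", "q_value"],
    )
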