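"""RT-stop tables to normalized reactivity profiles.

The raw reactivity of nucleotide i contrasts log-scaled RT stops of the
probe-treated library (P) against the mock (M)::

    Reactivity_i = ln(1+P_i) / (sum_i ln(1+P_i) / L)
                 - alpha * ln(1+M_i) / (sum_i ln(1+M_i) / L)

with the library-size correction factor
``alpha = min(1, sum ln(1+P_i) / sum ln(1+M_i))``. Both terms have mean 1
over the transcript, so the unclamped raw profile has mean exactly
``1 - alpha``.

Normalization follows the 2-8% rule: from the scale-source (WT) raw
profile take the top 10% of values, drop the top 2%, average the
remaining 8%, and divide both conditions by that scale.

In DMS chemistry only A and C carry signal: G/T positions are masked and
excluded from all sums, with L replaced by the unmasked count.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ReactivityProfile, RTStopTable, TranscriptModel

log = logging.getLogger(__name__)

#: positions with more RT stops than this are outliers for replicate correlation
OUTLIER_STOPS = 1e5


def chemistry_mask(tx: TranscriptModel, chemistry: str) -> np.ndarray:
    """True where the position is masked (carries no probing signal)."""
    if chemistry == "shape":
        return np.zeros(tx.length, dtype=bool)
    if chemistry == "dms":
        seq = np.frombuffer(tx.sequence.encode(), dtype="S1")
        return ~np.isin(seq, [b"A", b"C"])
    raise ValueError(f"unknown chemistry {chemistry!r}")


def replicate_correlation(
    reps1: Sequence[RTStopTable], reps2: Sequence[RTStopTable]
) -> tuple[float, int]:
    """Pearson r of RT stops between two replicates, pooled across
    transcripts, after excluding outlier positions (> 1e5 stops in either).

    Returns (r, n_positions); r is NaN (and a warning is issued) when fewer
    than 3 positions survive.
    """
    by_id1 = {t.transcript_id: t for t in reps1}
    by_id2 = {t.transcript_id: t for t in reps2}
    if set(by_id1) != set(by_id2):
        raise ValueError("replicates cover different transcript sets")
    xs, ys = [], []
    for tid in sorted(by_id1):
        a, b = by_id1[tid].stops, by_id2[tid].stops
        if a.size != b.size:
            raise ValueError(f"{tid}: replicate length mismatch")
        keep = (a <= OUTLIER_STOPS) & (b <= OUTLIER_STOPS)
        xs.append(a[keep])
        ys.append(b[keep])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if x.size < 3:
        warnings.warn("replicate correlation undefined: fewer than 3 retained positions")
        return float("nan"), int(x.size)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), int(x.size)
    r, _ = stats.pearsonr(x.astype(float), y.astype(float))
    return float(r), int(x.size)


def average_coverage(table: RTStopTable, tx: Optional[TranscriptModel] = None,
                     chemistry: str = "shape") -> float:
    """Sum of RT stops divided by transcript length; in DMS chemistry the
    denominator counts only A/C positions (and only their stops are summed)."""
    if chemistry == "shape":
        return float(table.stops.sum()) / table.length
    if tx is None:
        raise ValueError("DMS coverage requires the transcript sequence")
    mask = chemistry_mask(tx, "dms")
    n_ac = int((~mask).sum())
    if n_ac == 0:
        return 0.0
    return float(table.stops[~mask].sum()) / n_ac


def coverage_filter(
    tables: Iterable[RTStopTable],
    threshold: float = 1.0,
    chemistry: str = "shape",
    transcriptome: Optional[dict[str, TranscriptModel]] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep transcripts whose average coverage exceeds ``threshold`` in every
    treated replicate of both conditions.

    Returns (kept transcript ids, per-transcript coverage report). Transcripts
    missing a treated sample in either condition are excluded, with the reason
    recorded in the report.
    """
    treated = defaultdict(list)
    conditions_seen = set()
    for t in tables:
        conditions_seen.add(t.condition)
        if t.treatment == "treated":
            treated[t.transcript_id].append(t)
    rows, kept = [], []
    for tid in sorted(treated):
        tabs = treated[tid]
        conds = {t.condition for t in tabs}
        tx = transcriptome.get(tid) if transcriptome else None
        covs = {
            f"{t.condition}_rep{t.replicate}": average_coverage(t, tx, chemistry)
            for t in tabs
        }
        if conds != conditions_seen:
            rows.append({"transcript_id": tid, "pass": False,
                         "reason": "missing treated condition", **covs})
            continue
        ok = all(c > threshold for c in covs.values())
        rows.append({"transcript_id": tid, "pass": ok,
                     "reason": "" if ok else "low coverage", **covs})
        if ok:
            kept.append(tid)
    report = pd.DataFrame(rows)
    return kept, report


def combine_replicates(tables: Sequence[RTStopTable]) -> RTStopTable:
    """Position-wise sum of replicate RT-stop tables (same transcript,
    condition and treatment)."""
    if not tables:
        raise ValueError("no tables to combine")
    first = tables[0]
    total = np.zeros(first.length, dtype=np.int64)
    for t in tables:
        if (t.transcript_id, t.condition, t.treatment) != (
            first.transcript_id, first.condition, first.treatment
        ):
            raise ValueError("tables to combine must share transcript/condition/treatment")
        if t.length != first.length:
            raise ValueError(f"{t.transcript_id}: replicate length mismatch")
        total += t.stops
    return RTStopTable(first.transcript_id, first.condition, first.treatment, 0, total)


def raw_reactivity(
    treated: RTStopTable,
    mock: RTStopTable,
    tx: TranscriptModel,
    chemistry: str = "shape",
    clamp: bool = True,
) -> ReactivityProfile:
    """Raw per-nucleotide reactivity from combined-replicate stop counts.

    Negative values are floored at 0 when ``clamp`` (the default). When the
    mock library has zero log-stop mass the mock term is defined as 0 and
    alpha recorded as 1; when the treated library has zero log-stop mass the
    whole profile is missing.
    """
    if treated.length != mock.length or treated.length != tx.length:
        raise ValueError(f"{tx.transcript_id}: table/transcript length mismatch")
    mask = chemistry_mask(tx, chemistry)
    lp = np.log1p(treated.stops.astype(float))
    lm = np.log1p(mock.stops.astype(float))
    lp[mask] = 0.0
    lm[mask] = 0.0
    n_eff = int((~mask).sum())
    values = np.full(tx.length, np.nan)
    sum_p, sum_m = lp.sum(), lm.sum()
    if n_eff == 0 or sum_p == 0:
        warnings.warn(f"{tx.transcript_id}: no treated signal; all-missing profile")
        return ReactivityProfile(tx.transcript_id, treated.condition, values,
                                 stage="raw", alpha=1.0, chemistry=chemistry)
    t_term = lp / (sum_p / n_eff)
    if sum_m == 0:
        alpha = 1.0
        m_term = np.zeros_like(lm)
    else:
        alpha = min(1.0, sum_p / sum_m)
        m_term = lm / (sum_m / n_eff)
    raw = t_term - alpha * m_term
    if clamp:
        raw = np.maximum(raw, 0.0)
    values[~mask] = raw[~mask]
    return ReactivityProfile(tx.transcript_id, treated.condition, values,
                             stage="raw", alpha=alpha, chemistry=chemistry)


def two_eight_scale(values: np.ndarray) -> float:
    """2-8% normalization scale: of the top ceil(10%) values, drop the top
    ceil(2%) and average the rest."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n == 0:
        return float("nan")
    v = np.sort(v)[::-1]
    top = math.ceil(0.10 * n)
    drop = math.ceil(0.02 * n)
    kept = v[drop:top]
    if kept.size == 0:
        return float("nan")
    return float(kept.mean())


def normalize_two_eight(
    profile: ReactivityProfile,
    scale_source: ReactivityProfile,
    min_positions: int = 50,
) -> Optional[ReactivityProfile]:
    """Divide a raw profile by the 2-8% scale of ``scale_source`` (the WT raw
    profile of the same transcript). Returns None, with a warning, when the
    source has fewer than ``min_positions`` unmasked values or a non-positive
    scale."""
    if profile.transcript_id != scale_source.transcript_id:
        raise ValueError("profile and scale source must be the same transcript")
    src = scale_source.values
    n_valid = int(np.sum(~np.isnan(src)))
    if n_valid < min_positions:
        warnings.warn(
            f"{profile.transcript_id}: only {n_valid} unmasked positions; skipped"
        )
        return None
    scale = two_eight_scale(src)
    if not scale > 0:
        warnings.warn(f"{profile.transcript_id}: non-positive normalization scale; skipped")
        return None
    return ReactivityProfile(
        profile.transcript_id,
        profile.condition,
        profile.values / scale,
        stage="normalized",
        alpha=profile.alpha,
        norm_scale=scale,
        chemistry=profile.chemistry,
    )


def splice_by_region(
    profile: ReactivityProfile, tx: TranscriptModel
) -> dict[str, np.ndarray]:
    """Split the per-nucleotide vector by the 5'UTR/CDS/3'UTR partition;
    masks are preserved. The concatenation of the three outputs reproduces
    the input."""
    if profile.length != tx.length:
        raise ValueError(f"{tx.transcript_id}: profile/transcript length mismatch")
    out = {}
    for region in ("5UTR", "CDS", "3UTR"):
        s, e = tx.region_bounds(region)
        out[region] = profile.values[s:e]
    return out


# -------------------------------------------------------- pipeline convenience

def reactivity_pipeline(
    tables: Sequence[RTStopTable],
    transcriptome: dict[str, TranscriptModel],
    chemistry: str = "shape",
    coverage_threshold: float = 1.0,
    clamp: bool = True,
    min_positions: int = 50,
    per_replicate: bool = False,
):
    """Coverage filter -> replicate combination -> raw reactivity -> 2-8%
    normalization by the WT scale, for every transcript passing the filter.

    Returns (normalized profiles {(transcript_id, condition): profile},
    coverage report). With ``per_replicate`` also returns
    {(transcript_id, condition): [per-replicate normalized profiles]} where
    replicate i's treated table is paired with replicate i's mock and every
    replicate is divided by the transcript's combined-WT 2-8% scale.
    """
    kept, report = coverage_filter(tables, coverage_threshold, chemistry, transcriptome)
    grouped = defaultdict(list)
    for t in tables:
        grouped[(t.transcript_id, t.condition, t.treatment)].append(t)
    normalized: dict[tuple[str, str], ReactivityProfile] = {}
    rep_profiles: dict[tuple[str, str], list[ReactivityProfile]] = {}
    for tid in kept:
        tx = transcriptome[tid]
        raw = {}
        for cond in ("WT", "KO"):
            tr = grouped.get((tid, cond, "treated"))
            mo = grouped.get((tid, cond, "mock"))
            if not tr or not mo:
                raw = {}
                break
            raw[cond] = raw_reactivity(
                combine_replicates(tr), combine_replicates(mo), tx, chemistry, clamp
            )
        if not raw:
            continue
        wt_raw = raw["WT"]
        scale_holder = normalize_two_eight(wt_raw, wt_raw, min_positions)
        if scale_holder is None:
            continue
        normalized[(tid, "WT")] = scale_holder
        ko_norm = normalize_two_eight(raw["KO"], wt_raw, min_positions)
        normalized[(tid, "KO")] = ko_norm
        if per_replicate:
            scale = scale_holder.norm_scale
            for cond in ("WT", "KO"):
                tr = sorted(grouped[(tid, cond, "treated")], key=lambda t: t.replicate)
                mo = {t.replicate: t for t in grouped[(tid, cond, "mock")]}
                profs = []
                for t in tr:
                    if t.replicate not in mo:
                        continue
                    p = raw_reactivity(t, mo[t.replicate], tx, chemistry, clamp)
                    profs.append(
                        ReactivityProfile(tid, cond, p.values / scale, "normalized",
                                          p.alpha, scale, chemistry)
                    )
                rep_profiles[(tid, cond)] = profs
    if per_replicate:
        return normalized, report, rep_profiles
    return normalized, report
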