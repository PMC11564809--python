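"""Pattern-based RNA G-quadruplex (rG4) detection and subtype classification.

Subtypes, in precedence order (a locus gets the highest-precedence class
it matches):

* ``canonical``   — four G-tracts of >=3 Gs, loops of 1-7 nt
* ``long_loop``   — four G-tracts of >=3 Gs, loops of 1-21 nt, at least
  one loop longer than 7
* ``bulge``       — canonical geometry in which exactly one tract carries
  a single 1-nt non-G bulge (e.g. GG·N·G), the combined tract holding
  >=3 Gs
* ``two_quartet`` — four G-tracts of exactly 2 Gs, loops of 1-7 nt
* ``G40``         — a >=50-nt stretch with G fraction >=0.40 and >=4
  G-runs of >=2 Gs, matching none of the above

Scanning is greedy left-to-right over non-overlapping loci: at each
cursor the earliest-starting candidate wins, precedence breaking ties.
These pattern definitions are this package's own; loop_max 21 follows the
common G4-prediction parameterization for long-loop quadruplexes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

SUBTYPES = ("canonical", "long_loop", "bulge", "two_quartet", "G40")
_PRECEDENCE = {s: i for i, s in enumerate(SUBTYPES)}

_G40_MIN_LEN = 50
_G40_MIN_FRAC = 0.40

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class RG4Call:
    transcript_id: str
    start: int
    end: int
    subtype: str
    sequence: str

    @property
    def stability(self) -> float:
        """Proxy stability ordinal: higher-precedence subtypes and shorter
        total loops rank higher. Not a thermodynamic score."""
        loops = self.end - self.start - self.sequence.count("G")
        return (len(SUBTYPES) - _PRECEDENCE[self.subtype]) * 1000 - loops


def _g_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"G+", seq)]


def _tracts_from(runs, i, seq):
    """Tract options starting at run i: ('plain', end) for a >=3 run,
    ('two', end) for an exactly-2 run, ('bulged', end) for two runs joined
    by a 1-nt non-G bulge totalling >=3 Gs."""
    opts = []
    s, e = runs[i]
    if e - s >= 3:
        opts.append(("plain", e, i))
    if e - s == 2:
        opts.append(("two", e, i))
    if i + 1 < len(runs):
        s2, e2 = runs[i + 1]
        if s2 - e == 1 and (e - s) + (e2 - s2) >= 3:
            opts.append(("bulged", e2, i + 1))
    return opts


def _match_four_tracts(seq, runs, start_idx, loop_max, allow, need):
    """Try to chain four tracts from runs[start_idx]; returns (end, kinds)
    of the first valid chain or None. ``allow`` is the set of permitted
    tract kinds, ``need`` a predicate on the kind multiset."""
    def rec(idx, n_done, kinds):
        for kind, end, last_run in _tracts_from(runs, idx, seq):
            if kind not in allow:
                continue
            if n_done == 3:
                if need(kinds + [kind]):
                    return end, kinds + [kind]
                continue
            for j in range(last_run + 1, len(runs)):
                loop = runs[j][0] - end
                if loop < 1:
                    continue
                if loop > loop_max:
                    break
                res = rec(j, n_done + 1, kinds + [kind])
                if res:
                    return res
        return None

    return rec(start_idx, 0, [])


def _candidate_at(seq, runs, i):
    """Best (highest-precedence) rG4 candidate whose first tract starts at
    run i; returns (subtype, start, end) or None."""
    start = runs[i][0]
    # canonical: loops 1-7, all plain
    res = _match_four_tracts(seq, runs, i, 7, {"plain"}, lambda k: True)
    if res:
        return "canonical", start, res[0]
    # long_loop: loops 1-21, all plain, at least one loop > 7 (checked by
    # re-running with the wider loop bound and excluding canonical hits)
    res = _match_four_tracts(seq, runs, i, 21, {"plain"}, lambda k: True)
    if res:
        return "long_loop", start, res[0]
    # bulge: loops 1-7, exactly one bulged tract
    res = _match_four_tracts(
        seq, runs, i, 7, {"plain", "bulged"},
        lambda kinds: kinds.count("bulged") == 1 if len(kinds) == 4 else True,
    )
    if res and res[1].count("bulged") == 1:
        return "bulge", start, res[0]
    # two_quartet: loops 1-7, all tracts exactly GG
    res = _match_four_tracts(seq, runs, i, 7, {"two"}, lambda k: True)
    if res:
        return "two_quartet", start, res[0]
    return None


def _g40_interval(seq, cursor):
    """Earliest maximal interval from cursor qualifying as G40."""
    n = len(seq)
    if n - cursor < _G40_MIN_LEN:
        return None
    g = [c == "G" for c in seq]
    pref = np.concatenate([[0], np.cumsum(g)])
    w = _G40_MIN_LEN
    starts = []
    for s in range(cursor, n - w + 1):
        if (pref[s + w] - pref[s]) / w >= _G40_MIN_FRAC:
            starts.append(s)
    if not starts:
        return None
    s0 = starts[0]
    e = s0 + w
    for s in starts[1:]:
        if s <= e:
            e = max(e, s + w)
        else:
            break
    runs2 = [r for r in _g_runs(seq[s0:e]) if r[1] - r[0] >= 2]
    if len(runs2) < 4:
        return None
    return s0, e


def find_rg4(sequence: str, transcript_id: str = "") -> list[RG4Call]:
    """Scan a sequence for rG4 loci (non-overlapping, greedy left-to-right)."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    runs = _g_runs(seq)
    calls: list[RG4Call] = []
    cursor = 0
    run_i = 0
    while True:
        # earliest structured candidate at or after cursor
        best = None
        while run_i < len(runs) and runs[run_i][1] <= cursor:
            run_i += 1
        j = run_i
        while j < len(runs):
            if runs[j][0] < cursor:
                j += 1
                continue
            cand = _candidate_at(seq, runs, j)
            if cand:
                best = cand
                break
            j += 1
        g40 = _g40_interval(seq, cursor)
        chosen = None
        if best and g40:
            # earlier start wins; structured subtypes outrank G40 on ties/overlap
            chosen = best if best[1] <= g40[0] or best[1] < g40[1] else ("G40", *g40)
        elif best:
            chosen = best
        elif g40:
            chosen = ("G40", *g40)
        if chosen is None:
            break
        subtype, s, e = chosen
        calls.append(RG4Call(transcript_id, s, e, subtype, seq[s:e]))
        cursor = e
    return calls


def rg4_fraction(windows: list[str]) -> float:
    """Fraction of sequence windows containing at least one rG4 locus."""
    if not windows:
        return float("nan")
    return sum(bool(find_rg4(w)) for w in windows) / len(windows)
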