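"""Domain types and coordinate conventions.

All coordinates are 0-based, half-open internally. A transcript is a
single-stranded sense sequence partitioned into 5'UTR [0, utr5_end),
CDS [utr5_end, cds_end) and 3'UTR [cds_end, L). Sequences are normalized
to the DNA alphabet (U -> T) at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

FIVE_UTR = "5UTR"
CDS = "CDS"
THREE_UTR = "3UTR"
REGIONS = (FIVE_UTR, CDS, THREE_UTR)

CONDITIONS = ("WT", "KO")
TREATMENTS = ("treated", "mock")
SITE_TYPES = ("crosslink", "m6A", "YTHDF1", "random")
CHEMISTRIES = ("shape", "dms")

#: half-width of the window derived around a single-nucleotide anchor
WINDOW_HALFWIDTH = 50

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript sequence with its 5'UTR/CDS/3'UTR partition."""

    transcript_id: str
    gene_id: str
    sequence: str
    utr5_end: int
    cds_end: int

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters in sequence: {sorted(bad)}"
            )
        if not 0 <= self.utr5_end <= self.cds_end <= len(seq):
            raise ValueError(
                f"{self.transcript_id}: region boundaries violate "
                f"0 <= utr5_end ({self.utr5_end}) <= cds_end ({self.cds_end}) "
                f"<= L ({len(seq)})"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_bounds(self, region: str) -> tuple[int, int]:
        if region == FIVE_UTR:
            return 0, self.utr5_end
        if region == CDS:
            return self.utr5_end, self.cds_end
        if region == THREE_UTR:
            return self.cds_end, self.length
        raise ValueError(f"unknown region {region!r}")

    def region_of(self, pos: int) -> str:
        """Region containing a 0-based position (half-open convention)."""
        if not 0 <= pos < self.length:
            raise ValueError(
                f"{self.transcript_id}: position {pos} outside [0, {self.length})"
            )
        if pos < self.utr5_end:
            return FIVE_UTR
        if pos < self.cds_end:
            return CDS
        return THREE_UTR

    def gc_fraction(self, start: int = 0, end: Optional[int] = None) -> float:
        """GC fraction of sequence[start:end]; NaN on an empty slice."""
        seg = self.sequence[start : self.length if end is None else end]
        if not seg:
            return float("nan")
        return sum(c in "GC" for c in seg) / len(seg)


@dataclass
class RTStopTable:
    """Per-nucleotide RT-stop counts for one (condition, treatment, replicate)."""

    transcript_id: str
    condition: str
    treatment: str
    replicate: int
    stops: np.ndarray

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        stops = np.asarray(self.stops)
        if stops.ndim != 1:
            raise ValueError("stops must be a 1-D vector")
        if not np.issubdtype(stops.dtype, np.integer):
            if not np.all(np.equal(np.mod(stops, 1), 0)):
                raise ValueError("stops must be integer-valued")
            stops = stops.astype(np.int64)
        if np.any(stops < 0):
            raise ValueError("stops must be non-negative")
        self.stops = stops.astype(np.int64)

    @property
    def length(self) -> int:
        return self.stops.size


@dataclass
class ReactivityProfile:
    """Per-nucleotide reactivity with a missing-value mask (NaN).

    ``alpha`` is the library-size correction factor of the raw-reactivity
    formula; ``norm_scale`` is the 2-8% normalization scale once the profile
    has been normalized.
    """

    transcript_id: str
    condition: str
    values: np.ndarray
    stage: str = "raw"
    alpha: float = float("nan")
    norm_scale: Optional[float] = None
    chemistry: str = "shape"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in ("raw", "normalized"):
            raise ValueError("stage must be 'raw' or 'normalized'")
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"chemistry must be one of {CHEMISTRIES}")
        if np.isfinite(self.alpha) and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.stage == "normalized" and not (
            self.norm_scale is not None and self.norm_scale > 0
        ):
            raise ValueError("normalized profiles require norm_scale > 0")

    @property
    def length(self) -> int:
        return self.values.size

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the value is missing."""
        return np.isnan(self.values)


@dataclass
class SiteRecord:
    """Single-nucleotide anchor (crosslink, m6A, YTHDF1, random) with its
    derived +/-50 nt window and host region, once annotated."""

    transcript_id: str
    anchor: int
    site_type: str = "crosslink"
    name: Optional[str] = None
    window_start: Optional[int] = None
    window_end: Optional[int] = None
    region: Optional[str] = None

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")
        if self.anchor < 0:
            raise ValueError("anchor must be >= 0")
        if self.name is None:
            self.name = self.site_type

    @property
    def window(self) -> tuple[int, int]:
        if self.window_start is None or self.window_end is None:
            raise ValueError(f"site {self.name} on {self.transcript_id} not annotated")
        return self.window_start, self.window_end


def annotate_and_window(site: SiteRecord, tx: TranscriptModel) -> SiteRecord:
    """Attach the clipped +/-50 nt window and the anchor's host region."""
    if not 0 <= site.anchor < tx.length:
        raise ValueError(
            f"site {site.name}: anchor {site.anchor} outside transcript "
            f"{tx.transcript_id} of length {tx.length}"
        )
    return replace(
        site,
        window_start=max(0, site.anchor - WINDOW_HALFWIDTH),
        window_end=min(tx.length, site.anchor + WINDOW_HALFWIDTH + 1),
        region=tx.region_of(site.anchor),
    )


@dataclass
class CountMatrix:
    """Gene-level counts (genes x samples) with per-sample labels.

    ``samples`` is indexed by column name of ``counts`` and carries
    ``condition`` (WT/KO), ``fraction`` (chromatin/whole_cell) and
    ``replicate`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not set(self.counts.columns) == set(self.samples.index):
            raise ValueError("counts columns and samples index must match")
        for col in ("condition", "fraction", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing column {col!r}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            raise ValueError("counts must be integer-valued")
        groups = self.samples.groupby(["condition", "fraction"]).size()
        if (groups < 2).any():
            bad = groups[groups < 2].index.tolist()
            raise ValueError(f"need >=2 replicates per (condition, fraction); got {bad}")

    def columns_for(self, condition: str, fraction: str) -> list[str]:
        sel = self.samples[
            (self.samples.condition == condition) & (self.samples.fraction == fraction)
        ]
        return list(sel.index)


@dataclass
class HalfLifeTable:
    """Per-gene mRNA half-lives (hours) in WT and KO, per replicate.

    ``table`` columns: gene_id, replicate, wt_halflife, ko_halflife.
    """

    table: pd.DataFrame

    def __post_init__(self):
        need = {"gene_id", "replicate", "wt_halflife", "ko_halflife"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"half-life table missing columns {sorted(missing)}")
        if (self.table.wt_halflife <= 0).any() or (self.table.ko_halflife <= 0).any():
            raise ValueError("half-lives must be positive")


@dataclass
class DRR:
    """A differentially reactive region between conditions."""

    transcript_id: str
    start: int
    end: int
    direction: str  # gain_structure (KO reactivity lower) or loss_structure
    score: float
    q_value: float

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("empty DRR interval")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q_value must lie in [0, 1]")
        if self.direction not in ("gain_structure", "loss_structure"):
            raise ValueError("bad direction label")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EnrichmentResult:
    """Monte Carlo enrichment of feature anchors inside site windows."""

    observed: int
    null_mean: float
    null_sd: float
    p_value: float
    z_score: float
    n_sets: int
    null_counts: np.ndarray = field(repr=False, default=None)
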