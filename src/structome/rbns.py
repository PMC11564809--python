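"""RNA bind-n-seq k-mer enrichment.

The R value of a k-mer is its frequency in a protein-bound pool divided
by its frequency in the input pool, computed per bound-pool concentration
with an additive pseudocount over the full 4^k k-mer space.
"""

from __future__ import annotations

from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"


def all_kmers(k: int = 6) -> list[str]:
    return ["".join(p) for p in product(BASES, repeat=k)]


def _freqs(counts: Mapping[str, float], kmers: list[str], pseudocount: float) -> np.ndarray:
    c = np.array([float(counts.get(km, 0)) for km in kmers]) + pseudocount
    if np.any(c < pseudocount):
        raise ValueError("negative k-mer counts")
    return c / c.sum()


def kmer_r_values(
    input_pool_counts: Mapping[str, float],
    bound_pool_counts: Mapping[str, Mapping[str, float]],
    k: int = 6,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """R value per k-mer and bound pool, plus the max across pools.

    ``bound_pool_counts`` maps a pool label (e.g. a concentration) to its
    k-mer counts. Rows are ordered by descending max R. Raises on an empty
    input pool.
    """
    kmers = all_kmers(k)
    total_input = sum(float(v) for v in dict(input_pool_counts).values())
    if total_input <= 0:
        raise ValueError("empty input pool")
    f_in = _freqs(input_pool_counts, kmers, pseudocount)
    df = pd.DataFrame({"kmer": kmers, "freq_input": f_in})
    r_cols = []
    for label in bound_pool_counts:
        f_b = _freqs(bound_pool_counts[label], kmers, pseudocount)
        df[f"freq_{label}"] = f_b
        col = f"R_{label}"
        df[col] = f_b / f_in
        r_cols.append(col)
    df["max_R"] = df[r_cols].max(axis=1) if r_cols else np.nan
    return df.sort_values("max_R", ascending=False, kind="mergesort").reset_index(drop=True)
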