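"""Readers and writers for every on-disk format the pipeline touches.

Formats are plain UTF-8 TSV (plus FASTA for sequences). Positions in
emitted reactivity tables are 1-based, matching common structure-probing
file conventions; everything in memory is 0-based half-open. Writers emit
deterministic row order (sorted by transcript/gene id, then position).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    CountMatrix,
    HalfLifeTable,
    ReactivityProfile,
    RTStopTable,
    SiteRecord,
    TranscriptModel,
    annotate_and_window,
    SITE_TYPES,
)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------- transcripts

def read_transcriptome(fasta_path, regions_tsv_path) -> dict[str, TranscriptModel]:
    """Load transcript sequences plus region boundaries.

    The regions TSV must carry transcript_id, gene_id, utr5_end, cds_end.
    FASTA ids and TSV ids must agree exactly; offenders are listed on error.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    regions = pd.read_csv(regions_tsv_path, sep="\t", dtype={"transcript_id": str})
    for col in ("transcript_id", "gene_id", "utr5_end", "cds_end"):
        if col not in regions.columns:
            raise ValueError(f"regions TSV missing column {col!r}")
    fasta_ids, tsv_ids = set(seqs), set(regions.transcript_id)
    if fasta_ids != tsv_ids:
        only_fasta = sorted(fasta_ids - tsv_ids)
        only_tsv = sorted(tsv_ids - fasta_ids)
        raise ValueError(
            f"FASTA/regions id mismatch: only in FASTA {only_fasta}; "
            f"only in regions TSV {only_tsv}"
        )
    out = {}
    for row in regions.itertuples(index=False):
        out[row.transcript_id] = TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=str(row.gene_id),
            sequence=seqs[row.transcript_id],
            utr5_end=int(row.utr5_end),
            cds_end=int(row.cds_end),
        )
    return out


def write_transcriptome(transcriptome: dict[str, TranscriptModel], fasta_path, regions_tsv_path) -> None:
    with open(fasta_path, "w") as fh:
        for tid in sorted(transcriptome):
            tx = transcriptome[tid]
            fh.write(f">{tid}\n")
            for i in range(0, tx.length, 70):
                fh.write(tx.sequence[i : i + 70] + "\n")
    rows = [
        (tid, tx.gene_id, tx.utr5_end, tx.cds_end)
        for tid, tx in sorted(transcriptome.items())
    ]
    pd.DataFrame(rows, columns=["transcript_id", "gene_id", "utr5_end", "cds_end"]).to_csv(
        regions_tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------- sites

def read_sites(path, transcriptome: Optional[dict[str, TranscriptModel]] = None) -> list[SiteRecord]:
    """Read single-nucleotide anchors from a 6-column BED-like TSV in
    transcript coordinates. When a transcriptome is supplied, anchors are
    validated against transcript length and windows/regions attached."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns, got {len(fields)}")
            tid, start, end, name, _score, strand = fields
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end != start + 1:
                raise ValueError(
                    f"{path}: line {lineno}: anchors are single-nucleotide (end must be start+1)"
                )
            if strand != "+":
                raise ValueError(f"{path}: line {lineno}: strand must be '+'")
            site_type = name if name in SITE_TYPES else "crosslink"
            rec = SiteRecord(transcript_id=tid, anchor=start, site_type=site_type, name=name)
            if transcriptome is not None:
                if tid not in transcriptome:
                    raise ValueError(f"{path}: line {lineno}: unknown transcript {tid!r}")
                tx = transcriptome[tid]
                if rec.anchor >= tx.length:
                    raise ValueError(
                        f"{path}: line {lineno}: site {name}: anchor {rec.anchor} >= "
                        f"transcript length {tx.length}"
                    )
                rec = annotate_and_window(rec, tx)
            records.append(rec)
    return records


def write_sites(records: Iterable[SiteRecord], path) -> None:
    recs = sorted(records, key=lambda r: (r.transcript_id, r.anchor, r.name))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.transcript_id}\t{r.anchor}\t{r.anchor + 1}\t{r.name}\t0\t+\n")


# --------------------------------------------------------------- typed tables

_SCHEMAS = ("rtstops", "react", "counts", "halflife", "kmer_counts")


def _require(df: pd.DataFrame, cols, path):
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")


def read_table(path, schema: str):
    """Read a typed TSV table. Schemas: rtstops, react, counts, halflife,
    kmer_counts. Positions on disk are 1-based."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {_SCHEMAS}")
    df = pd.read_csv(path, sep="\t")
    if schema == "rtstops":
        _require(df, ["transcript_id", "condition", "treatment", "replicate", "position", "stops"], path)
        if not np.issubdtype(df.stops.dtype, np.integer):
            raise ValueError(f"{path}: non-integer stop counts")
        if (df.stops < 0).any():
            raise ValueError(f"{path}: negative stop counts")
        tables = []
        for (tid, cond, trt, rep), grp in df.groupby(
            ["transcript_id", "condition", "treatment", "replicate"], sort=True
        ):
            grp = grp.sort_values("position")
            expected = np.arange(1, len(grp) + 1)
            if not np.array_equal(grp.position.to_numpy(), expected):
                raise ValueError(f"{path}: {tid}: positions must be contiguous 1..L")
            tables.append(
                RTStopTable(str(tid), str(cond), str(trt), int(rep), grp.stops.to_numpy())
            )
        return tables
    if schema == "react":
        _require(df, ["transcript_id", "condition", "stage", "chemistry", "alpha",
                      "norm_scale", "position", "reactivity"], path)
        profiles = []
        for (tid, cond, stage, chem), grp in df.groupby(
            ["transcript_id", "condition", "stage", "chemistry"], sort=True
        ):
            grp = grp.sort_values("position")
            ns = grp.norm_scale.iloc[0]
            profiles.append(
                ReactivityProfile(
                    transcript_id=str(tid),
                    condition=str(cond),
                    values=grp.reactivity.to_numpy(dtype=float),
                    stage=str(stage),
                    alpha=float(grp.alpha.iloc[0]),
                    norm_scale=None if pd.isna(ns) else float(ns),
                    chemistry=str(chem),
                )
            )
        return profiles
    if schema == "counts":
        _require(df, ["gene_id"], path)
        counts = df.set_index("gene_id")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.mod(vals, 1) == 0):
            raise ValueError(f"{path}: counts must be integer")
        if (vals < 0).any():
            raise ValueError(f"{path}: negative counts")
        # sample columns are named <condition>_<fraction>_<replicate>;
        # fraction itself may contain underscores (whole_cell)
        meta = []
        for col in counts.columns:
            try:
                cond, rest = col.split("_", 1)
                frac, rep = rest.rsplit("_", 1)
                meta.append((col, cond, frac, int(rep)))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: sample column {col!r} not of the form condition_fraction_replicate"
                ) from exc
        samples = pd.DataFrame(
            meta, columns=["sample", "condition", "fraction", "replicate"]
        ).set_index("sample")
        return CountMatrix(counts.astype(np.int64), samples)
    if schema == "halflife":
        _require(df, ["gene_id", "replicate", "wt_halflife", "ko_halflife"], path)
        return HalfLifeTable(df)
    # kmer_counts: a kmer column plus one count column per pool
    _require(df, ["kmer"], path)
    pools = {}
    for col in df.columns:
        if col == "kmer":
            continue
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative k-mer counts in pool {col!r}")
        pools[col] = pd.Series(df[col].to_numpy(), index=df.kmer.to_numpy(), name=col)
    return pools


def write_table(obj, path, schema: str) -> None:
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {_SCHEMAS}")
    if schema == "rtstops":
        rows = []
        for t in obj:
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": t.transcript_id,
                        "condition": t.condition,
                        "treatment": t.treatment,
                        "replicate": t.replicate,
                        "position": np.arange(1, t.length + 1),
                        "stops": t.stops,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True).sort_values(
            ["transcript_id", "condition", "treatment", "replicate", "position"],
            kind="mergesort",
        )
        df.to_csv(path, sep="\t", index=False)
        return
    if schema == "react":
        rows = []
        for p in obj:
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": p.transcript_id,
                        "condition": p.condition,
                        "stage": p.stage,
                        "chemistry": p.chemistry,
                        "alpha": p.alpha,
                        "norm_scale": np.nan if p.norm_scale is None else p.norm_scale,
                        "position": np.arange(1, p.length + 1),
                        "reactivity": p.values,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True).sort_values(
            ["transcript_id", "condition", "stage", "position"], kind="mergesort"
        )
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        return
    if schema == "counts":
        df = obj.counts.copy()
        df.insert(0, "gene_id", df.index)
        df.sort_values("gene_id", kind="mergesort").to_csv(path, sep="\t", index=False)
        return
    if schema == "halflife":
        obj.table.sort_values(["gene_id", "replicate"], kind="mergesort").to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
        return
    # kmer_counts
    kmers = sorted(next(iter(obj.values())).index)
    df = pd.DataFrame({"kmer": kmers})
    for pool in obj:
        df[pool] = obj[pool].reindex(kmers).fillna(0).astype(np.int64).to_numpy()
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
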