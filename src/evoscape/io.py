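"""Readers and writers for the pipeline's on-disk formats.

Everything on disk is plain text: competition series, variant tables and
genotype tables as TSV; depth profiles as BedGraph-style TSV (0-based
half-open externally, converted to the 1-based closed convention used
in memory at this boundary); coding sequences as FASTA (via Biopython);
estimates and reports as JSON.  Generators emit a JSON sidecar of the true
simulation parameters next to each synthetic dataset.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .competition_fitness import CompetitionTimeSeries
from .copy_number import DepthProfile
from .variant_filters import VariantRecord

__all__ = [
    "write_competition_tsv",
    "read_competition_tsv",
    "write_variant_tsv",
    "read_variant_tsv",
    "write_bedgraph",
    "read_bedgraph",
    "read_fasta",
    "write_json",
]

LN2 = math.log(2.0)


def write_competition_tsv(
    series_list, path, dilution_rate_per_h: float | None = None
) -> None:
    """Write competition series as TSV (replicate, hours, generations, counts)."""
    frames = []
    for ser in series_list:
        df = ser.to_frame()
        df.insert(
            1,
            "hours",
            df["generations"] * LN2 / dilution_rate_per_h
            if dilution_rate_per_h
            else np.nan,
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_competition_tsv(path) -> list[CompetitionTimeSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("generations")
        out.append(
            CompetitionTimeSeries(
                replicate=str(rep),
                generations=grp["generations"].to_numpy(float),
                count_mutant=grp["count_mutant"].to_numpy(float),
                count_reference=grp["count_reference"].to_numpy(float),
            )
        )
    return out


def _encode_indels(indels: dict) -> str:
    return ";".join(f"{a}:{c}" for a, c in sorted(indels.items())) if indels else "."


def _decode_indels(text: str) -> dict:
    if not isinstance(text, str) or text in (".", ""):
        return {}
    out = {}
    for item in text.split(";"):
        allele, _, count = item.rpartition(":")
        out[allele] = int(count)
    return out


def write_variant_tsv(records, path) -> None:
    """Write VariantRecords as a TSV allele-count table."""
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref_base": r.ref_base,
            "coverage": r.coverage,
            "sample": r.sample,
            **{b: r.count(b) for b in "ACGTN"},
            "indels": _encode_indels(r.indel_counts),
        }
        for r in records
    ]
    cols = ["chrom", "pos", "ref_base", "coverage", "sample", *"ACGTN", "indels"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return [
        VariantRecord(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_base=str(row["ref_base"]),
            coverage=int(row["coverage"]),
            base_counts={b: int(row[b]) for b in "ACGTN" if int(row[b]) > 0},
            indel_counts=_decode_indels(row["indels"]),
            sample=str(row["sample"]),
        )
        for _, row in df.iterrows()
    ]


def write_bedgraph(profile: DepthProfile, path) -> None:
    """Write a depth profile as BedGraph (0-based half-open, run-length merged)."""
    d = profile.depth
    breaks = np.nonzero(np.diff(d) != 0)[0] + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(d)]])
    offset = profile.start - 1  # 1-based internal -> 0-based external
    with open(path, "w") as fh:
        for i, j in zip(starts, ends):
            val = d[i]
            text = f"{int(val)}" if float(val).is_integer() else f"{val:g}"
            fh.write(f"{profile.chrom}\t{i + offset}\t{j + offset}\t{text}\n")


def read_bedgraph(path) -> DepthProfile:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        comment="t",  # skips optional 'track' header lines
    )
    if df.empty:
        raise ValueError(f"empty BedGraph file: {path}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("multi-chromosome BedGraph not supported")
    start0 = int(df["start"].iloc[0])
    if not (df["start"].iloc[1:].to_numpy() == df["end"].iloc[:-1].to_numpy()).all():
        raise ValueError("BedGraph intervals must be contiguous")
    length = int(df["end"].iloc[-1]) - start0
    depth = np.empty(length, dtype=float)
    for _, row in df.iterrows():
        depth[int(row["start"]) - start0 : int(row["end"]) - start0] = row["depth"]
    # 0-based half-open external -> 1-based internal
    return DepthProfile(chrom=str(chroms[0]), start=start0 + 1, depth=depth)


def read_fasta(path, first_only: bool = True):
    """Read sequences from FASTA; returns one string (default) or a dict."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if first_only:
        return str(records[0].seq)
    return {r.id: str(r.seq) for r in records}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"cannot serialise {type(obj)!r}")
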