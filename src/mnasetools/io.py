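"""Plain-text genomics I/O: chrom.sizes, BED, bedGraph, wiggle.

All in-memory coordinates are 0-based, half-open; wiggle input (1-based)
is converted on read.  Readers raise on malformed lines with the line
number; bedGraph readers reject overlapping intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeSizes
from .tracks import CoverageTrack

__all__ = [
    "GenomeSizes",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_wiggle",
    "track_from_bedgraph",
    "track_to_bedgraph",
    "read_track",
    "write_track",
]


class FormatError(ValueError):
    """Malformed input file."""


def _fmt(v: float) -> str:
    return f"{v:g}"


def read_chrom_sizes(path) -> GenomeSizes:
    items = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                items.append((fields[0], int(fields[1])))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from e
    return GenomeSizes(items)


def write_chrom_sizes(genome: GenomeSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome:
            fh.write(f"{name}\t{length}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3+ records as a DataFrame (chrom, start, end[, name, score, strand])."""
    rows = []
    ncols = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                row = [f[0], int(f[1]), int(f[2])] + f[3:6]
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from e
            ncols = max(ncols, len(row))
            rows.append(row)
    cols = ["chrom", "start", "end", "name", "score", "strand"][:ncols]
    df = pd.DataFrame([r + [None] * (ncols - len(r)) for r in rows], columns=cols)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph records (chrom, start, end, value); overlaps are an error."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad record") from e
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise FormatError(f"{path}: overlapping bedGraph intervals on {chrom}")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(df["chrom"], df["start"], df["end"], df["value"]):
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def read_wiggle(path) -> pd.DataFrame:
    """fixedStep / variableStep wiggle as (chrom, start, end, value),
    converted to 0-based half-open."""
    rows = []
    mode = None
    chrom = None
    span = 1
    step = start = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = line.split()[0]
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if mode == "fixedStep":
                    start = int(fields["start"]) - 1  # wiggle is 1-based
                    step = int(fields.get("step", span))
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before wiggle header")
            try:
                if mode == "fixedStep":
                    rows.append((chrom, start, start + span, float(line)))
                    start += step
                else:
                    pos_s, val_s = line.split()
                    pos = int(pos_s) - 1
                    rows.append((chrom, pos, pos + span, float(val_s)))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad wiggle record") from e
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def track_from_bedgraph(
    df: pd.DataFrame, genome: GenomeSizes, bin_bp: int = 10
) -> CoverageTrack:
    """Bin bedGraph-style interval values by length-weighted averaging."""
    data = {}
    for name, length in genome:
        perbase = np.zeros(length)
        sub = df[df["chrom"] == name]
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            perbase[max(0, int(start)) : min(length, int(end))] = value
        n_bins = -(-length // bin_bp)
        pad = np.full(n_bins * bin_bp - length, np.nan)
        data[name] = np.nanmean(
            np.concatenate([perbase, pad]).reshape(n_bins, bin_bp), axis=1
        )
    unknown = set(df["chrom"]) - set(genome.names)
    if unknown:
        raise FormatError(f"unknown chromosome(s) in bedGraph: {sorted(unknown)}")
    return CoverageTrack(genome=genome, bin_bp=bin_bp, data=data)


def track_to_bedgraph(track: CoverageTrack) -> pd.DataFrame:
    """CoverageTrack as bedGraph records, merging equal-valued runs."""
    rows = []
    for name, length in track.genome:
        a = track.data[name]
        if len(a) == 0:
            continue
        run_start = 0
        for i in range(1, len(a) + 1):
            if i == len(a) or a[i] != a[run_start]:
                s = run_start * track.bin_bp
                e = min(i * track.bin_bp, length)
                rows.append((name, s, e, a[run_start]))
                run_start = i
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_track(track: CoverageTrack, path) -> None:
    write_bedgraph(track_to_bedgraph(track), path)


def read_track(path, genome: GenomeSizes, bin_bp: int = 10) -> CoverageTrack:
    """Read a coverage track from bedGraph or wiggle (by extension)."""
    p = str(path)
    if p.endswith((".wig", ".wiggle")):
        df = read_wiggle(p)
    else:
        df = read_bedgraph(p)
    return track_from_bedgraph(df, genome, bin_bp=bin_bp)
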