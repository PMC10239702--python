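"""Readers and writers for the plain-text formats the pipeline exchanges.

BED (3-6 col), BEDPE (6+ col), bedGraph, TSV tables, two-column genome
layout, and dense contact matrices as triplet text with a JSON header.
All coordinates 0-based half-open; all round trips lossless for the
fields each dialect carries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cohescan.genome import ValidationError, sort_intervals
from cohescan.tracks import SignalTrack

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]


class ParseError(ValueError):
    """Malformed line in a standard-format file (carries the line number)."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 BED fields, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        if not (0 <= start < end):
            raise ParseError(path, lineno, f"invalid interval [{start},{end})")
        row = {"chrom": fields[0], "start": start, "end": end}
        if len(fields) > 3:
            row["name"] = fields[3]
        if len(fields) > 4:
            row["score"] = fields[4]
        if len(fields) > 5:
            if fields[5] not in ("+", "-", "."):
                raise ParseError(path, lineno, f"invalid strand {fields[5]!r}")
            row["strand"] = fields[5]
        rows.append(row)
    return sort_intervals(pd.DataFrame(rows)) if rows else pd.DataFrame(columns=["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    sort_intervals(df)[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected >=6 BEDPE fields, got {len(fields)}")
        try:
            coords = [int(x) for x in (fields[1], fields[2], fields[4], fields[5])]
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        s1, e1, s2, e2 = coords
        if not (0 <= s1 < e1) or not (0 <= s2 < e2):
            raise ParseError(path, lineno, "invalid anchor interval")
        row = dict(zip(BEDPE_COLUMNS[:6], [fields[0], s1, e1, fields[3], s2, e2]))
        if len(fields) > 6:
            row["name"] = fields[6]
        if len(fields) > 7:
            row["score"] = float(fields[7])
        rows.append(row)
    return (
        pd.DataFrame(rows).sort_values(["chrom1", "start1", "start2"], kind="mergesort").reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=BEDPE_COLUMNS[:6])
    )


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = [c for c in BEDPE_COLUMNS if c in df.columns]
    df.sort_values(["chrom1", "start1", "start2"], kind="mergesort")[cols].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> dict[str, SignalTrack]:
    """Read a bedGraph of uniformly binned values into per-chromosome tracks.

    Bins absent from the file come back as NaN.
    """
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 bedGraph fields, got {len(fields)}")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad field: {exc}") from None
    tracks: dict[str, SignalTrack] = {}
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, sub in df.groupby("chrom", sort=True):
        widths = (sub["end"] - sub["start"]).unique()
        if len(widths) != 1:
            raise ValidationError(f"{path}: {chrom}: non-uniform bedGraph bins {sorted(widths)}")
        bin_size = int(widths[0])
        if (sub["start"] % bin_size).any():
            raise ValidationError(f"{path}: {chrom}: bins not aligned to bin size {bin_size}")
        n = int(sub["end"].max() // bin_size)
        values = np.full(n, np.nan)
        values[(sub["start"] // bin_size).to_numpy()] = sub["value"].to_numpy()
        tracks[chrom] = SignalTrack(chrom, bin_size, values)
    return tracks


def write_bedgraph(tracks: dict[str, SignalTrack] | SignalTrack, path) -> None:
    if isinstance(tracks, SignalTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for i, v in enumerate(t.values):
                if np.isfinite(v):
                    s = t.start_offset + i * t.bin_size
                    fh.write(f"{chrom}\t{s}\t{s + t.bin_size}\t{v:.6g}\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def write_contact_matrix(matrix, path) -> None:
    """Dense symmetric matrix as 'bin_i bin_j value' triplets (upper triangle)
    under a JSON header line (chrom, start, resolution)."""
    header = {"chrom": matrix.chrom, "start": int(matrix.start_bp), "resolution": int(matrix.resolution)}
    m = matrix.matrix
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        iu = np.triu_indices(m.shape[0])
        for i, j in zip(*iu):
            v = m[i, j]
            if v != 0:
                fh.write(f"{i}\t{j}\t{v:.8g}\n")


def read_contact_matrix(path):
    from cohescan.structure3d import ContactMatrix

    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ParseError(path, 1, "missing JSON header line")
        header = json.loads(first[1:])
        triplets = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) != 3:
                raise ParseError(path, lineno, "expected 'bin_i bin_j value'")
            triplets.append((int(fields[0]), int(fields[1]), float(fields[2])))
    n = max(max(i, j) for i, j, _ in triplets) + 1 if triplets else 0
    m = np.zeros((n, n))
    for i, j, v in triplets:
        m[i, j] = v
        m[j, i] = v
    return ContactMatrix(header["chrom"], header["start"], header["resolution"], m)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
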