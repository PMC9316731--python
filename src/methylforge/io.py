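"""Readers and writers for the plain-text formats used throughout the package.

Internal coordinates are 0-based half-open everywhere.  CGmap files are
1-based; the shift happens here and only here.

Formats
-------
CGmap (CGmapTools style, 8 columns, tab separated)::

    chrom  nucleotide(C|G)  pos(1-based)  context(CG|CHG|CHH)  dinucleotide  level  mC  total

bedGraph+counts (Bismark-style coverage track)::

    chrom  start(0-based)  end  level_percent  methylated  unmethylated

Read records (one sequenced molecule per line)::

    read_id  chrom  start  end  pos:call[,pos:call...]   (call in {M,U})

BED6, gene x sample count TSVs ("ERCC-" prefix marks spike rows) and JSON
round-trip through pandas / the stdlib.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import ReadMethylationRecord

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "m", "total"]
_CONTEXTS = {"CG", "CHG", "CHH"}


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "context": pd.Series(dtype=str),
        "m": pd.Series(dtype=np.int64),
        "total": pd.Series(dtype=np.int64),
    })


def read_calls(path, dialect: str = "cgmap") -> pd.DataFrame:
    """Read per-cytosine methylation calls into the standard call table.

    Parameters
    ----------
    path : str or Path
    dialect : {"cgmap", "bedgraph"}
        ``bedgraph`` is the six-column counts dialect; it carries no strand or
        context, which are filled with ``.`` / ``CG``.

    Returns
    -------
    DataFrame with columns chrom, pos (0-based), strand, context, m, total.
    """
    path = Path(path)
    if dialect == "cgmap":
        return _read_cgmap(path)
    if dialect in ("bedgraph", "bedgraph+counts"):
        return _read_bedgraph_counts(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_cgmap(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{ln}: malformed CGmap line (expected 8 fields, got {len(parts)})")
            chrom, nuc, pos, ctx, _dinuc, _level, mc, total = parts
            if ctx not in _CONTEXTS:
                raise ValueError(f"{path}:{ln}: unknown context token {ctx!r}")
            try:
                pos_i, mc_i, tot_i = int(pos), int(mc), int(total)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed CGmap line ({exc})") from None
            strand = "+" if nuc == "C" else "-"
            rows.append((chrom, pos_i - 1, strand, ctx, mc_i, tot_i))
    if not rows:
        return _empty_calls()
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.astype({"pos": np.int64, "m": np.int64, "total": np.int64})


def write_cgmap(calls: pd.DataFrame, path) -> None:
    df = calls
    with open(path, "w") as fh:
        for chrom, pos, strand, ctx, m, total in zip(
            df["chrom"], df["pos"], df["strand"], df["context"], df["m"], df["total"]
        ):
            nuc = "C" if strand == "+" else "G"
            dinuc = ctx[:2] if ctx != "CG" else "CG"
            level = m / total if total else 0.0
            fh.write(f"{chrom}\t{nuc}\t{pos + 1}\t{ctx}\t{dinuc}\t{level:.6g}\t{m}\t{total}\n")


def _read_bedgraph_counts(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: malformed bedGraph+counts line (expected 6 fields)")
            chrom, start, _end, _pct, m, u = parts
            try:
                start_i, m_i, u_i = int(start), int(m), int(u)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed bedGraph+counts line ({exc})") from None
            rows.append((chrom, start_i, ".", "CG", m_i, m_i + u_i))
    if not rows:
        return _empty_calls()
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.astype({"pos": np.int64, "m": np.int64, "total": np.int64})


def write_bedgraph_counts(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, m, total in zip(calls["chrom"], calls["pos"], calls["m"], calls["total"]):
            pct = 100.0 * m / total if total else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pct:.6g}\t{m}\t{total - m}\n")


# ---------------------------------------------------------------- BED6 ----

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BED6_COLUMNS, dtype={"chrom": str, "name": str, "strand": str},
    )
    if df.empty:
        return pd.DataFrame(columns=BED6_COLUMNS)
    return df.astype({"start": np.int64, "end": np.int64})


def write_bed6(df: pd.DataFrame, path, name_col="name", score_col="score", strand_col="strand") -> None:
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df[name_col] if name_col in df else ".",
        "score": df[score_col] if score_col in df else 0,
        "strand": df[strand_col] if strand_col in df else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ------------------------------------------------------- read records ----

def write_read_records(records: Iterable[ReadMethylationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            pairs = ",".join(f"{p}:{c}" for p, c in zip(r.positions, r.calls))
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t{pairs}\n")


def read_read_records(path) -> list[ReadMethylationRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: malformed read record")
            read_id, chrom, start, end, pairs = parts
            if pairs:
                pos, calls = zip(*(p.split(":") for p in pairs.split(",")))
                positions = np.array([int(p) for p in pos], dtype=np.int64)
                call_arr = np.array(calls)
            else:
                positions = np.array([], dtype=np.int64)
                call_arr = np.array([], dtype="<U1")
            records.append(ReadMethylationRecord(read_id, chrom, int(start), int(end), positions, call_arr))
    return records


# ------------------------------------------------------------ counts ----

def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix, genes as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


# ------------------------------------------------------------- FASTA ----

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -------------------------------------------------------------- JSON ----

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
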