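"""Readers and writers for the plain-text formats used across the pipeline.

Fragments travel as headerless 5-column TSV (chrom, start, end, barcode,
count) with 0-based half-open coordinates, position-sorted -- the layout of a
10x-style fragments file.  Gene models are BED6, term maps two-column TSV,
whitelists one barcode per line, matrices MatrixMarket with BED/TSV sidecars.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def _opener(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> pd.DataFrame:
    """Load a fragments TSV (optionally gzipped) into a DataFrame."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "barcode": str, "count": np.int64},
    )
    return df


def write_fragments(df: pd.DataFrame, path) -> None:
    """Write fragments sorted by (chrom, start, end, barcode)."""
    out = df.sort_values(["chrom", "start", "end", "barcode"], kind="mergesort")
    with _opener(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False,
                   columns=FRAGMENT_COLUMNS)


def read_whitelist(path) -> list[str]:
    with _opener(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_whitelist(barcodes: Iterable[str], path) -> None:
    with _opener(path, "wt") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with _opener(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with _opener(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in ("chrom", "start", "end", "name", "score",
                                   "strand") if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "strand": str},
    )


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"],
                     dtype=str)
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(term, set()).add(gene)
    return out


def write_term_map(term_map: dict[str, set[str]], path) -> None:
    with _opener(path, "wt") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")


def write_json(obj, path) -> None:
    with _opener(path, "wt") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with _opener(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
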