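"""Readers and writers for the tabular and track formats the pipeline touches.

TSV with a header is the canonical tabular interchange (CSV accepted on
input by sniffing); BED6/bedGraph tracks are 0-based half-open; every table
written here carries a header comment with the tool version, config hash,
and seed so outputs are traceable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from . import __version__


def read_table(path) -> pd.DataFrame:
    """TSV/CSV sniffing reader; '#' lines are comments."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input table: {path}")
    with open(path) as fh:
        head = ""
        for line in fh:
            if not line.startswith("#"):
                head = line
                break
    delim = "\t"
    if head:
        try:
            delim = csv.Sniffer().sniff(head, delimiters="\t,").delimiter
        except csv.Error:
            pass
    return pd.read_csv(path, sep=delim, comment="#")


def write_table(
    df: pd.DataFrame, path, config_hash: str = "-", seed: int | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            f"# lncscreen v{__version__} config={config_hash} seed={seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"sample"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df


def read_counts(path) -> pd.DataFrame:
    df = read_table(path)
    if "guide_id" not in df.columns:
        raise ValueError(f"{path}: counts table needs a guide_id column")
    df = df.set_index("guide_id", drop=False)
    value_cols = [c for c in df.columns if c != "guide_id"]
    return df[value_cols].astype(int).set_axis(df.index)


def read_bed6(path) -> pd.DataFrame:
    """BED6 (or BED3/4) -> chrom/start/end[/name/score/strand], 0-based."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: df.shape[1]]
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "score"])
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_fasta_genome(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta_genome(path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome
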