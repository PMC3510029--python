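"""Genome annotation container and GFF3/BED/TSV interchange.

Elements (protein-coding genes and transposable elements) live in a pandas
DataFrame with 0-based half-open coordinates and boolean repeat-content
flags; dispersed/tandem repeats are a separate interval table.  GFF3 output
converts to the format's 1-based closed convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

ELEMENT_COLUMNS = ["id", "chrom", "start", "end", "strand", "feature",
                   "contains_dispersed_repeat", "contains_tandem_repeat",
                   "contains_te"]

FLAG_COLUMNS = ELEMENT_COLUMNS[6:]


def make_annotation(rows: Iterable[dict]) -> pd.DataFrame:
    """Build a validated element table."""
    df = pd.DataFrame(list(rows))
    for col in FLAG_COLUMNS:
        if col not in df.columns:
            df[col] = False
    df = df[ELEMENT_COLUMNS].copy()
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"element {bad['id']} has end <= start")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def genes(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation[annotation["feature"] == "gene"]


def transposons(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation[annotation["feature"] == "transposable_element"]


def write_gff3(annotation: pd.DataFrame, path: str | Path,
               source: str = "chromredist") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotation.iterrows():
            attrs = [f"ID={row['id']}"]
            for flag in FLAG_COLUMNS:
                if row[flag]:
                    attrs.append(f"{flag}=1")
            fh.write("\t".join([
                str(row["chrom"]), source, str(row["feature"]),
                str(int(row["start"]) + 1), str(int(row["end"])),  # 1-based closed
                ".", str(row["strand"]), ".", ";".join(attrs),
            ]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "source", "feature", "start", "end",
                            "score", "strand", "frame", "attributes"],
                     dtype={"chrom": str})
    rows = []
    for _, r in df.iterrows():
        attrs = dict(kv.split("=", 1) for kv in str(r["attributes"]).split(";") if "=" in kv)
        row = {
            "id": attrs.get("ID", f"{r['chrom']}:{r['start']}"),
            "chrom": r["chrom"], "start": int(r["start"]) - 1, "end": int(r["end"]),
            "strand": r["strand"], "feature": r["feature"],
        }
        for flag in FLAG_COLUMNS:
            row[flag] = attrs.get(flag, "0") == "1"
        rows.append(row)
    return make_annotation(rows)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """BED6 from a frame with chrom/start/end and optional name/score/strand."""
    with open(path, "w") as fh:
        for _, r in intervals.iterrows():
            fh.write("\t".join([
                str(r["chrom"]), str(int(r["start"])), str(int(r["end"])),
                str(r.get("name", ".")), str(r.get("score", 0)),
                str(r.get("strand", ".")),
            ]) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df = df.rename(columns=dict(enumerate(
        ["chrom", "start", "end", "name", "score", "strand"])))
    return df


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """(id, length, count) table."""
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["id", "length", "count"]].to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path) -> pd.DataFrame:
    """(chrom, pos [1-based], strand, context, m_count, t_count) table."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_methylation_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "pos", "strand", "context", "m_count", "t_count"]].to_csv(
        path, sep="\t", index=False)
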