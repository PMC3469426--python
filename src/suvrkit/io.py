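"""Readers and writers for the plain-text formats the toolkit exchanges.

All genomic coordinates are 0-based half-open in memory. On disk, GFF3 is
written 1-based inclusive, BED 0-based half-open, and the cytosine report
carries 1-based positions, following the usual dialect of each format.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_COLUMNS = ["chrom", "start", "end", "ip", "input"]
CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")


def write_gff3(path: str | Path, records: Iterable[Mapping]) -> None:
    """Write GFF3. Records carry 0-based half-open ``start``/``end``;
    the file gets the format's 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = rec.get("attributes", {})
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fields = [
                rec["seqid"],
                rec.get("source", "suvrkit"),
                rec["type"],
                str(rec["start"] + 1),
                str(rec["end"]),
                str(rec.get("score", ".")),
                rec.get("strand", "."),
                rec.get("phase", "."),
                attr_str,
            ]
            fh.write("\t".join(fields) + "\n")


def write_bed(path: str | Path, df: pd.DataFrame, score_col: str | None = None,
              name_col: str | None = None, scale: float = 1.0) -> None:
    """Write intervals as BED (3-6 columns depending on available fields)."""
    cols = [df["chrom"], df["start"].astype(int), df["end"].astype(int)]
    if name_col is not None or score_col is not None or "strand" in df.columns:
        names = df[name_col] if name_col else pd.Series(["."] * len(df), index=df.index)
        cols.append(names)
        if score_col is not None:
            cols.append((df[score_col] * scale).round().astype(int))
        else:
            cols.append(pd.Series([0] * len(df), index=df.index))
        cols.append(df["strand"] if "strand" in df.columns else pd.Series(["."] * len(df), index=df.index))
    out = pd.concat(cols, axis=1)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    return df


def write_probe_table(path: str | Path, df: pd.DataFrame) -> None:
    df.loc[:, PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine report; file positions are 1-based, returned 0-based."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CYTOSINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine report missing columns: {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_cytosine_report(path: str | Path, df: pd.DataFrame) -> None:
    out = df.loc[:, CYTOSINE_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_path: str | Path, params: Mapping, seed: int | None,
                     inputs: Mapping[str, str] | None = None) -> None:
    """Write a ``<file>.prov.json`` sidecar recording parameters, seed and
    the digests of the inputs that produced ``out_path``."""
    record = {
        "file": Path(out_path).name,
        "sha256": sha256_of(out_path),
        "params": dict(params),
        "seed": seed,
        "inputs": dict(inputs or {}),
    }
    with open(str(out_path) + ".prov.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
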