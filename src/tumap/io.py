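"""File formats: FASTA, GFF3, BED6, bedGraph, TSV.

Internal coordinates are 1-based inclusive; BED and bedGraph files use the
format's native 0-based half-open convention and are converted at the file
boundary.  Every writer states the coordinate convention in a header
comment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_HEADER = "##gff-version 3\n# coordinates: 1-based inclusive\n"


def write_fasta(path, sequence: str, name: str = "synthetic_chromosome") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> tuple[str, str]:
    """(name, sequence) of the first record."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def _gff_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) if attrs else "."


def write_gff3(path, records: list[dict], seqid: str = "synthetic_chromosome") -> None:
    """records: dicts with type, start, end, strand and optional score,
    source, attrs (a dict)."""
    with open(path, "w") as fh:
        fh.write(GFF_HEADER)
        for r in records:
            score = r.get("score")
            fh.write(
                "\t".join(
                    [
                        r.get("seqid", seqid),
                        r.get("source", "tumap"),
                        r["type"],
                        str(r["start"]),
                        str(r["end"]),
                        "." if score is None else f"{score:.4g}",
                        r["strand"],
                        ".",
                        _gff_attrs(r.get("attrs", {})),
                    ]
                )
                + "\n"
            )


def read_gff3(path, types=None) -> pd.DataFrame:
    """GFF3 as a DataFrame (seqid, source, type, start, end, score, strand,
    attributes dict)."""
    names = ["seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    if types is not None:
        df = df[df["type"].isin(types)].reset_index(drop=True)
    df["attributes"] = df["attributes"].map(
        lambda s: dict(kv.split("=", 1) for kv in str(s).split(";") if "=" in kv)
    )
    return df


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene-like features as (gene_id, strand, start, end)."""
    df = read_gff3(path, types=["gene", "CDS"])
    rows = []
    for i, row in df.iterrows():
        gid = row["attributes"].get("ID", row["attributes"].get("gene_id", f"gene{i}"))
        rows.append((gid, row["strand"], int(row["start"]), int(row["end"])))
    return pd.DataFrame(rows, columns=["gene_id", "strand", "start", "end"])


def write_bed6(path, rows: list[tuple], chrom: str = "synthetic_chromosome") -> None:
    """rows: (start, end, name, score, strand) with 1-based inclusive input."""
    with open(path, "w") as fh:
        fh.write("# BED6; coordinates converted to 0-based half-open\n")
        for start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score:.4g}\t{strand}\n")


def write_bedgraph(path, coverage: np.ndarray, chrom: str = "synthetic_chromosome") -> None:
    """Run-length encoded bedGraph (0-based half-open intervals)."""
    cov = np.asarray(coverage)
    with open(path, "w") as fh:
        fh.write('track type=bedGraph\n# coordinates: 0-based half-open\n')
        if len(cov) == 0:
            return
        change = np.nonzero(np.diff(cov))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(cov)]])
        for s, e in zip(starts, ends):
            v = cov[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, length: int) -> np.ndarray:
    cov = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            _, s, e, v = line.split()[:4]
            cov[int(s) : int(e)] = float(v)
    return cov


def write_probe_table(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# probe table; start/end 1-based inclusive\n")
        df.to_csv(fh, sep="\t", index=False)


def read_probe_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(path, df: pd.DataFrame, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
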