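"""Shared file-format I/O.

Conventions: coordinates are 0-based half-open in memory, BED on disk;
GFF3 is written 1-based inclusive with percent-encoded attribute values.
Write/read round-trips are lossless on the package's own outputs.
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_reads_fasta",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "read_bed",
    "write_tsv",
    "read_tsv",
]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict:
    """FASTA file -> {contig: sequence} (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list:
    """Read sequences from FASTA or FASTQ (by extension); returns a list.

    Collapsed records with an ``_xN`` suffix in the id (``>seq12_x40``)
    are expanded into (sequence, N) pairs; plain records count once.
    """
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    out = []
    for rec in SeqIO.parse(p, fmt):
        n = 1
        if "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                n = int(tail)
        out.append((str(rec.seq).upper(), n))
    return out


def write_reads_fasta(reads, path, expanded: bool = True) -> None:
    """Write (sequence, count) pairs as FASTA.

    ``expanded=True`` emits ``count`` copies of each sequence (one read per
    record, as a sequencer would); otherwise one record per unique
    sequence with the count in the id suffix (``>seq12_x40``).
    """
    with open(path, "w") as fh:
        i = 0
        for j, (seq, count) in enumerate(reads):
            if expanded:
                for _ in range(int(count)):
                    i += 1
                    fh.write(f">read{i}\n{seq}\n")
            else:
                fh.write(f">seq{j+1}_x{int(count)}\n{seq}\n")


# -- GFF3 -------------------------------------------------------------------

_GFF_COLS = ["feature_id", "contig", "start", "end", "strand", "category", "kog_class"]


def write_gff3(features: pd.DataFrame, path, source: str = "rdrnascan") -> None:
    """Write the feature table as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in features.itertuples(index=False):
            attrs = [f"ID={urllib.parse.quote(str(rec.feature_id), safe='')}"]
            attrs.append(f"category={urllib.parse.quote(str(rec.category), safe='')}")
            kog = getattr(rec, "kog_class", "")
            if kog:
                attrs.append(f"kog_class={urllib.parse.quote(str(kog), safe='')}")
            fh.write(
                "\t".join(
                    [
                        rec.contig,
                        source,
                        rec.category,
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Parse a GFF3 file back to the internal feature table (0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            for item in f[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = urllib.parse.unquote(v)
            rows.append(
                (
                    attrs.get("ID", ""),
                    f[0],
                    int(f[3]) - 1,
                    int(f[4]),
                    f[6],
                    attrs.get("category", f[2]),
                    attrs.get("kog_class", ""),
                )
            )
    return pd.DataFrame(rows, columns=_GFF_COLS)


# -- BED --------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, name_col: str, score_col: str,
              strand_col: str | None = None, extra_cols: list | None = None) -> None:
    """Write intervals as BED6 plus optional extra columns."""
    extra_cols = extra_cols or []
    with open(path, "w") as fh:
        for rec in df.itertuples(index=False):
            d = rec._asdict()
            row = [
                d["contig"],
                str(d["start"]),
                str(d["end"]),
                str(d[name_col]),
                str(d[score_col]),
                str(d[strand_col]) if strand_col else ".",
            ] + [str(d[c]) for c in extra_cols]
            fh.write("\t".join(row) + "\n")


def read_bed(path, extra_cols: list | None = None) -> pd.DataFrame:
    extra_cols = extra_cols or []
    cols = ["contig", "start", "end", "name", "score", "strand"] + extra_cols
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return df


# -- TSV --------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False,
              float_format: str = "%.6f") -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
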