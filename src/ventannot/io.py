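"""Plain-text readers/writers for the formats the pipeline exchanges.

Hit tables use the 12-column BLAST tabular dialect extended with two
columns, ``sframe`` (query reading frame of the alignment, BLASTx
convention) and ``staxid`` (subject taxon identifier). Tables carry no
header line, like ``-outfmt 6`` output.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "sframe", "staxid",
]

_HIT_DTYPES = {
    "qseqid": str, "sseqid": str, "pident": float, "length": int,
    "mismatch": int, "gapopen": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "evalue": float, "bitscore": float,
    "sframe": int, "staxid": int,
}


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at `width` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write a hit table in the extended tabular dialect (no header).

    Floats are written at full repr precision so that a write/read
    round-trip is lossless.
    """
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, dtype=_HIT_DTYPES)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def read_id_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_peptides(calls: Mapping[str, object], path, width: int = 70) -> None:
    """Write assigned peptides as FASTA; unassigned calls are skipped."""
    records = []
    for cid in sorted(calls):
        call = calls[cid]
        if getattr(call, "peptide", None):
            records.append((f"{cid} frame={call.frame:+d} tier={call.tier}",
                            call.peptide))
    write_fasta(records, path, width=width)
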