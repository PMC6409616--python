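"""FASTA/TSV/JSON helpers shared by the CLI and tests."""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaError

__all__ = ["read_fasta", "write_fasta", "write_tsv", "write_json"]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    Ids are the first whitespace-delimited header token (Biopython's
    convention). Empty files and duplicate ids are rejected.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r} in {path} has an empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    if not recs:
        raise FastaError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_tsv(
    path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    metadata: Mapping[str, object] | None = None,
) -> None:
    """TSV with '#'-prefixed metadata lines carrying the resolved config."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_json(path, payload, metadata: Mapping[str, object] | None = None) -> None:
    doc = {"metadata": dict(metadata or {}), "result": payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
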