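"""FASTA and tabular I/O helpers."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path: str | Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences by name; plain or gzip-compressed FASTA."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(
    seqs: Mapping[str, str] | Iterable[tuple[str, str]],
    path: str | Path,
    description: str = "",
) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [
        SeqRecord(Seq(s), id=name, description=description) for name, s in items
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
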