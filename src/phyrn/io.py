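"""FASTA and newick I/O with strict validation.

FASTA parsing is Bio.SeqIO's; this layer adds the package's contracts:
unique nonempty ids, nonempty records, residues restricted to the 20-letter
amino-acid alphabet (lowercase is uppercased with a warning), and parse
errors that name the offending record and its header line number.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dayhoff import ALPHABET
from .tree import PhyloTree

__all__ = ["FastaError", "read_fasta", "write_fasta", "read_newick", "write_newick"]

logger = logging.getLogger("phyrn")


class FastaError(ValueError):
    """Malformed FASTA input; carries record id and header line number."""

    def __init__(self, message: str, record_id: str | None = None,
                 line: int | None = None):
        where = ""
        if record_id is not None:
            where += f" (record {record_id!r}"
            where += f", line {line})" if line is not None else ")"
        super().__init__(message + where)
        self.record_id = record_id
        self.line = line


def _header_lines(path: Path) -> list[int]:
    lines = []
    with open(path) as fh:
        for i, text in enumerate(fh, start=1):
            if text.startswith(">"):
                lines.append(i)
    return lines


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping id -> uppercase amino-acid sequence."""
    path = Path(path)
    headers = _header_lines(path)
    seqs: dict[str, str] = {}
    allowed = set(ALPHABET)
    for k, record in enumerate(SeqIO.parse(str(path), "fasta")):
        line = headers[k] if k < len(headers) else None
        if not record.id:
            raise FastaError("empty sequence id", record_id="", line=line)
        if record.id in seqs:
            raise FastaError("duplicate sequence id", record_id=record.id,
                             line=line)
        seq = str(record.seq)
        if not seq:
            raise FastaError("empty sequence", record_id=record.id, line=line)
        if seq != seq.upper():
            logger.warning("lowercase residues in %r uppercased", record.id)
            seq = seq.upper()
        bad = set(seq) - allowed
        if bad:
            raise FastaError(
                f"illegal residues {sorted(bad)}", record_id=record.id, line=line
            )
        seqs[record.id] = seq
    if not seqs:
        raise FastaError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path,
                 include_support: bool = False) -> None:
    Path(path).write_text(tree.to_newick(include_support=include_support) + "\n")
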