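"""Sequence and table input/output.

FASTA/FASTQ readers auto-detect gzip compression (magic bytes) and
format (first record character), preserve record ids, and uppercase the
sequences. Table writers use deterministic ordering so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterator, TextIO

from Bio import SeqIO

from sfstools.search import SfsEmission, SfsTable

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path) -> TextIO:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: TextIO) -> str:
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            raise ValueError("empty sequence file")
        if line.strip():
            handle.seek(pos)
            break
    first = line.lstrip()[0]
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"unrecognized sequence format (first character {first!r})")


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, uppercased sequence)`` from a FASTA/FASTQ file,
    plain or gzipped. Duplicate ids are de-duplicated with a numeric
    suffix and a warning."""
    seen: dict[str, int] = {}
    with _open_text(path) as handle:
        fmt = _sniff_format(handle)
        for record in SeqIO.parse(handle, fmt):
            name = record.id
            if name in seen:
                seen[name] += 1
                new_name = f"{name}.{seen[name]}"
                logger.warning("%s: duplicate id %r renamed to %r",
                               path, name, new_name)
                name = new_name
            else:
                seen[name] = 0
            yield name, str(record.seq).upper()


# ---------------------------------------------------------------------
# specific-string tables and emission records
# ---------------------------------------------------------------------

TABLE_HEADER = "sequence\tcount\tcanonical"
EMISSIONS_HEADER = "target_id\tbegin\tend\tsequence"


def write_table(table: SfsTable, path) -> None:
    with open(path, "wt") as out:
        out.write(f"#tau={table.tau if table.tau is not None else 1}\n")
        out.write(TABLE_HEADER + "\n")
        for seq, count in table.sorted_items():
            out.write(f"{seq}\t{count}\t{seq}\n")


def read_table(path) -> SfsTable:
    table = SfsTable()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == TABLE_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: malformed table row")
            table.add(fields[0], int(fields[1]))
    return table


def write_table_fasta(table: SfsTable, path) -> None:
    """FASTA rendering: ``>sfs_<rank>#<count>`` headers, ranked by the
    deterministic table order."""
    with open(path, "wt") as out:
        for rank, (seq, count) in enumerate(table.sorted_items(), start=1):
            out.write(f">sfs_{rank}#{count}\n{seq}\n")


def write_emissions(emissions: list[SfsEmission], path) -> None:
    """BED-like per-emission records (0-based half-open)."""
    with open(path, "wt") as out:
        out.write(EMISSIONS_HEADER + "\n")
        for em in emissions:
            out.write(f"{em.target_id}\t{em.begin}\t{em.end}\t{em.sequence}\n")


def read_emissions(path) -> list[SfsEmission]:
    out: list[SfsEmission] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line == EMISSIONS_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: malformed emission row")
            tid, begin, end, seq = fields
            out.append(SfsEmission(seq, tid, int(begin), int(end)))
    return out


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "wt") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for k in range(0, len(seq), 80):
                out.write(seq[k:k + 80] + "\n")


def write_fastq(records: list[tuple[str, str]], path) -> None:
    with open(path, "wt") as out:
        for name, seq in records:
            out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
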