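"""FASTA reading.

Tolerant of line wrapping, embedded whitespace and numeric decoration
(common in hand-curated or journal-supplement FASTA): everything that is
not a letter is stripped from sequence lines.  Plain text or gzip.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path

from ..containers import SequenceRecord
from ..errors import FormatError

_LETTERS = re.compile(r"[^A-Za-z]")


def open_text(path) -> list[str]:
    """Read a text (optionally gzipped) file into lines; reject binary."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not a text file ({exc})") from None
    if "\x00" in text:
        raise FormatError(f"{path}: binary content")
    return text.splitlines()


def read_sequence(path, record_id: str | None = None) -> SequenceRecord:
    """Parse a FASTA file into a SequenceRecord.

    Returns the first record unless ``record_id`` selects one by header id
    (the token after '>'). Raises on empty files, on a missing or duplicate
    requested id, and on files with no FASTA header.
    """
    lines = open_text(path)
    records: list[tuple[str, list[str]]] = []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            header = line[1:].strip()
            rid = header.split()[0] if header else f"record{len(records) + 1}"
            records.append((rid, []))
        else:
            if not records:
                raise FormatError(
                    f"{path}, line {lineno}: sequence data before any '>' header"
                )
            records[-1][1].append(_LETTERS.sub("", line))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if record_id is None:
        rid, chunks = records[0]
    else:
        hits = [(r, c) for r, c in records if r == record_id]
        if not hits:
            raise FormatError(
                f"{path}: id {record_id!r} not found; ids: {[r for r, _ in records]}"
            )
        if len(hits) > 1:
            raise FormatError(f"{path}: id {record_id!r} occurs {len(hits)} times")
        rid, chunks = hits[0]
    residues = "".join(chunks)
    if not residues:
        raise FormatError(f"{path}: record {rid!r} has no residues")
    return SequenceRecord(id=rid, residues=residues)


def write_fasta(record: SequenceRecord, path, width: int = 60) -> None:
    seq = record.residues
    lines = [f">{record.id}"]
    lines += [seq[k : k + width] for k in range(0, len(seq), width)]
    Path(path).write_text("\n".join(lines) + "\n")
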