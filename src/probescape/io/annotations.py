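"""Region/site annotation formats: BED / narrowPeak and GFF3 / GTF.

BED coordinates are 0-based half-open on disk and converted to 1-based
inclusive on read; GFF/GTF are already 1-based inclusive.  Records whose
span is degenerate (start >= end in BED) are skipped with a warning.
"""

from __future__ import annotations

import warnings

from ..containers import Annotation, SequenceRecord
from ..errors import FormatError
from .sequence import open_text


def read_bed(path, sequence: SequenceRecord) -> list[Annotation]:
    """BED / narrowPeak (BED6+4): one spans-annotation per record."""
    out: list[Annotation] = []
    for lineno, line in enumerate(open_text(path), 1):
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise FormatError(f"{path}, line {lineno}: BED rows need >= 3 columns")
        try:
            start0, end0 = int(cols[1]), int(cols[2])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: non-integer coordinates") from None
        if start0 >= end0:
            warnings.warn(f"{path}, line {lineno}: skipped degenerate span "
                          f"[{start0},{end0})")
            continue
        start, end = start0 + 1, end0  # half-open -> 1-based inclusive
        if start < 1 or end > sequence.length:
            warnings.warn(f"{path}, line {lineno}: span [{start},{end}] outside "
                          f"1..{sequence.length}; skipped")
            continue
        name = cols[3] if len(cols) > 3 else f"region{lineno}"
        meta: dict = {"chrom": cols[0]}
        if len(cols) > 4:
            meta["score"] = float(cols[4])
        if len(cols) > 5:
            meta["strand"] = cols[5]
        if len(cols) >= 10:  # narrowPeak extras
            meta.update(signal=float(cols[6]), pvalue=float(cols[7]),
                        qvalue=float(cols[8]), peak=int(cols[9]))
        out.append(Annotation(name=name, category="spans",
                              entries=[(start, end)], sequence=sequence,
                              metadata=meta))
    return out


def parse_gff_attributes(field: str) -> dict[str, str]:
    """Parse both GFF3 (key=value;) and GTF (key "value";) attribute syntax."""
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:  # GFF3
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
        else:  # GTF: key "value"
            parts = chunk.split(None, 1)
            if len(parts) == 2:
                attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gff_records(path) -> list[dict]:
    """Raw GFF/GTF records as dicts (seqid, source, type, start, end, score,
    strand, attributes)."""
    records = []
    for lineno, line in enumerate(open_text(path), 1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise FormatError(f"{path}, line {lineno}: GFF rows need 9 columns")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: non-integer coordinates") from None
        records.append({
            "seqid": cols[0], "source": cols[1], "type": cols[2],
            "start": start, "end": end, "score": cols[5], "strand": cols[6],
            "attributes": parse_gff_attributes(cols[8]),
        })
    return records


def read_gff(path, sequence: SequenceRecord) -> list[Annotation]:
    """GFF/GTF features as spans-annotations on a same-coordinate sequence."""
    out = []
    for rec in read_gff_records(path):
        if rec["start"] < 1 or rec["end"] > sequence.length or rec["start"] > rec["end"]:
            warnings.warn(f"{path}: feature outside 1..{sequence.length}; skipped")
            continue
        attrs = rec["attributes"]
        name = attrs.get("ID") or attrs.get("gene_id") or rec["type"]
        meta = {"type": rec["type"], "strand": rec["strand"], **attrs}
        out.append(Annotation(name=name, category="spans",
                              entries=[(rec["start"], rec["end"])],
                              sequence=sequence, metadata=meta))
    return out


def read_annotations(path, tag: str, sequence: SequenceRecord) -> list[Annotation]:
    if sequence is None:
        raise FormatError(
            f"{path}: annotations index a sequence; supply one "
            "(e.g. load a FASTA in the same sample)"
        )
    if tag == "bed-narrowpeak":
        return read_bed(path, sequence)
    if tag == "gff-gtf":
        return read_gff(path, sequence)
    raise FormatError(f"unknown annotation tag {tag!r}")
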