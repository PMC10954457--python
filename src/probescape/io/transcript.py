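"""Transcript extraction from a local genome FASTA + GFF/GTF annotation.

Exons of the requested transcript are spliced 5'-to-3' (reverse
complemented for minus-strand genes).  CDS features and exon junctions are
emitted as annotations in transcript coordinates, and a genome-to-
transcript coordinate map is returned so genomic per-nucleotide tracks
(WIG/BED) can be carried onto the transcript.
"""

from __future__ import annotations

from ..containers import Annotation, SequenceRecord, reverse_complement
from ..errors import FormatError
from .annotations import read_gff_records
from .sequence import read_sequence


def _feature_transcript_id(rec: dict) -> set[str]:
    attrs = rec["attributes"]
    ids = set()
    for key in ("Parent", "transcript_id", "ID"):
        if key in attrs:
            ids.update(attrs[key].split(","))
    return ids


def extract_transcript(gff_path, fasta_path, transcript_id: str):
    """Splice a transcript out of genome coordinates.

    Returns ``(sequence, annotations, genome_to_transcript)`` where the map
    is a dict from genomic position to 1-based transcript position.
    """
    records = read_gff_records(gff_path)
    exons = [r for r in records
             if r["type"].lower() == "exon" and transcript_id in _feature_transcript_id(r)]
    if not exons:
        present = any(
            transcript_id in _feature_transcript_id(r) or
            r["attributes"].get("ID") == transcript_id
            for r in records
        )
        if not present:
            raise FormatError(f"{gff_path}: transcript id {transcript_id!r} not found")
        raise FormatError(
            f"{gff_path}: transcript {transcript_id!r} has no exon features"
        )
    seqids = {r["seqid"] for r in exons}
    strands = {r["strand"] for r in exons}
    if len(seqids) > 1 or len(strands) > 1:
        raise FormatError(
            f"{gff_path}: exons of {transcript_id!r} span multiple "
            "sequences or strands"
        )
    strand = strands.pop()
    try:
        genome = read_sequence(fasta_path, record_id=next(iter(seqids)))
    except FormatError:
        # single-record fasta whose header differs from the GFF seqid
        genome = read_sequence(fasta_path)

    exons = sorted(exons, key=lambda r: r["start"], reverse=(strand == "-"))
    chunks: list[str] = []
    genome_to_tx: dict[int, int] = {}
    tx_pos = 0
    junctions: list[int] = []
    for k, exon in enumerate(exons):
        gstart, gend = exon["start"], exon["end"]
        if gend > genome.length:
            raise FormatError(
                f"{gff_path}: exon [{gstart},{gend}] beyond genome length {genome.length}"
            )
        piece = genome.residues[gstart - 1 : gend]
        grange = range(gstart, gend + 1)
        if strand == "-":
            piece = reverse_complement(piece)
            grange = range(gend, gstart - 1, -1)
        chunks.append(piece)
        for g in grange:
            tx_pos += 1
            genome_to_tx[g] = tx_pos
        if k < len(exons) - 1:
            junctions.append(tx_pos)
    sequence = SequenceRecord(id=transcript_id, residues="".join(chunks))

    annotations: list[Annotation] = []
    if junctions:
        annotations.append(Annotation(
            name="exon-junctions", category="sites",
            entries=[(p, p) for p in junctions], sequence=sequence,
            metadata={"description": "last nt of each non-terminal exon"},
        ))
    for rec in records:
        if rec["type"].upper() not in ("CDS", "FIVE_PRIME_UTR", "THREE_PRIME_UTR", "UTR"):
            continue
        if transcript_id not in _feature_transcript_id(rec):
            continue
        mapped = sorted(
            genome_to_tx[g] for g in range(rec["start"], rec["end"] + 1)
            if g in genome_to_tx
        )
        if not mapped:
            continue
        # contiguous runs of mapped transcript positions become spans
        spans, run_start, prev = [], mapped[0], mapped[0]
        for p in mapped[1:]:
            if p != prev + 1:
                spans.append((run_start, prev))
                run_start = p
            prev = p
        spans.append((run_start, prev))
        annotations.append(Annotation(
            name=rec["type"], category="spans", entries=spans,
            sequence=sequence, metadata=dict(rec["attributes"]),
        ))
    return sequence, annotations, genome_to_tx
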