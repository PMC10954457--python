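"""Position mapping between sequences via global pairwise alignment.

Multi-condition experiments routinely probe slightly different constructs
(primer trimming, point mutants, truncations).  To plot such data on a
shared axis, positions of one sequence are carried onto another through an
end-gap-free global alignment (Needleman-Wunsch with free terminal gaps).
Aligned columns where both sequences have a residue map to each other,
matched or not; gapped positions are unmapped.  The resulting partial map
is strictly monotone, composable, and invertible on its image.

Default scores (match +1, mismatch -1, gap open -5, gap extend -1) favour
the near-identical alignments typical of probing comparisons; free end
gaps avoid penalising terminal truncations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .containers import (
    Annotation,
    InteractionSet,
    Profile,
    SecondaryStructure,
    SequenceRecord,
    TertiaryStructure,
    normalize_residues,
)
from .errors import MappingError


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


class PositionMapping:
    """A monotone partial map from positions of seq_a to positions of seq_b."""

    def __init__(self, seq_a: SequenceRecord, seq_b: SequenceRecord,
                 a_to_b: dict[int, int], score: float = 0.0) -> None:
        self.seq_a = seq_a
        self.seq_b = seq_b
        self.a_to_b = dict(sorted(a_to_b.items()))
        self.score = score
        keys = list(self.a_to_b)
        vals = [self.a_to_b[k] for k in keys]
        if any(v2 <= v1 for v1, v2 in zip(vals, vals[1:])):
            raise MappingError("position map is not strictly monotone")

    def __getitem__(self, i: int) -> int | None:
        return self.a_to_b.get(i)

    def inverse(self) -> "PositionMapping":
        return PositionMapping(self.seq_b, self.seq_a,
                               {v: k for k, v in self.a_to_b.items()}, self.score)

    def compose(self, other: "PositionMapping") -> "PositionMapping":
        """self: a->b composed with other: b->c gives a->c."""
        chained = {
            i: other.a_to_b[j]
            for i, j in self.a_to_b.items() if j in other.a_to_b
        }
        return PositionMapping(self.seq_a, other.seq_b, chained)

    @property
    def n_mapped(self) -> int:
        return len(self.a_to_b)


def identity_mapping(seq_a: SequenceRecord, seq_b: SequenceRecord) -> PositionMapping:
    n = seq_a.length
    return PositionMapping(seq_a, seq_b, {i: i for i in range(1, n + 1)},
                           score=float(n))


def align_positions(seq_a: SequenceRecord, seq_b: SequenceRecord,
                    params: AlignParams | None = None) -> PositionMapping:
    """Global end-gap-free alignment of two sequences (T == U throughout).

    Identical sequences short-circuit to the identity map.  Traceback is
    deterministic (the aligner's first optimal alignment is used), so
    repeated runs give identical maps.
    """
    if seq_a.matches(seq_b):
        return identity_mapping(seq_a, seq_b)
    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    for attr in ("end_insertion_score", "end_deletion_score"):
        try:  # biopython >= 1.86 naming; older releases use *_end_gap_score
            setattr(aligner, attr, 0.0)
        except AttributeError:
            pass
    a = normalize_residues(seq_a.residues)
    b = normalize_residues(seq_b.residues)
    alignment = aligner.align(a, b)[0]
    a_to_b: dict[int, int] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for k in range(a_end - a_start):
            a_to_b[int(a_start) + k + 1] = int(b_start) + k + 1
    return PositionMapping(seq_a, seq_b, a_to_b, score=float(alignment.score))


def _require_same_sequence(mapping: PositionMapping, data) -> None:
    seq = getattr(data, "sequence", data)
    if not seq.matches(mapping.seq_a):
        raise MappingError(
            f"data is on sequence {seq.id!r} but the mapping starts from "
            f"{mapping.seq_a.id!r}"
        )


def map_data(mapping: PositionMapping, data):
    """Carry a data object across a PositionMapping onto mapping.seq_b.

    Profiles: values land on mapped positions, unmapped targets become
    no-data.  Annotations: spans are clipped to their mapped extent.
    SecondaryStructure / InteractionSet: a pair or record survives only if
    both endpoints map (interaction records are kept but masked out, so the
    record count is preserved).  Drawing coordinates travel with their
    nucleotides.
    """
    if isinstance(data, SequenceRecord):
        _require_same_sequence(mapping, data)
        return mapping.seq_b
    _require_same_sequence(mapping, data)
    m = mapping.a_to_b
    seq_b = mapping.seq_b
    nb = seq_b.length

    if isinstance(data, Profile):
        values = np.full(nb, np.nan)
        nodata = np.ones(nb, dtype=bool)
        raw = np.full(nb, np.nan) if data.raw is not None else None
        stderr = np.full(nb, np.nan) if data.stderr is not None else None
        for i, j in m.items():
            values[j - 1] = data.values[i - 1]
            nodata[j - 1] = data.nodata[i - 1]
            if raw is not None:
                raw[j - 1] = data.raw[i - 1]
            if stderr is not None:
                stderr[j - 1] = data.stderr[i - 1]
        return Profile(seq_b, values, raw=raw, stderr=stderr, nodata=nodata,
                       metric=data.metric, breakpoints=data.breakpoints,
                       colors=data.colors)

    if isinstance(data, Annotation):
        entries = []
        for start, end in data.entries:
            if data.category == "primers" and start > end:
                lo, hi = end, start
            else:
                lo, hi = start, end
            mapped = [m[p] for p in range(lo, hi + 1) if p in m]
            if not mapped:
                continue
            new_lo, new_hi = min(mapped), max(mapped)
            if data.category == "primers" and start > end:
                entries.append((new_hi, new_lo))
            else:
                entries.append((new_lo, new_hi))
        return Annotation(name=data.name, category=data.category,
                          entries=entries, sequence=seq_b, color=data.color,
                          metadata=dict(data.metadata))

    if isinstance(data, SecondaryStructure):
        pairs = {
            (m[i], m[j]) for i, j in data.pairs if i in m and j in m
        }
        drawing = None
        if data.drawing is not None:
            drawing = np.full((nb, 2), np.nan)
            for i, j in m.items():
                drawing[j - 1] = data.drawing[i - 1]
        return SecondaryStructure(sequence=seq_b, pairs=pairs, drawing=drawing)

    if isinstance(data, InteractionSet):
        df = data.data.copy()
        mask = data.mask.copy()
        new_i, new_j = [], []
        for idx, row in df.iterrows():
            i, j = int(row["i"]), int(row["j"])
            if i in m and j in m:
                new_i.append(m[i])
                new_j.append(m[j])
            else:
                # endpoint lost: keep the record, mask it out, park the
                # coordinates at a harmless in-range placeholder
                new_i.append(1)
                new_j.append(min(2, nb))
                mask[idx] = False
        df["i"], df["j"] = new_i, new_j
        return InteractionSet(seq_b, df, mask, data.default_metric)

    if isinstance(data, TertiaryStructure):
        seq_map = {
            resnum: m[pos] for resnum, pos in data.seq_map.items() if pos in m
        }
        return TertiaryStructure(
            sequence=seq_b, chain_id=data.chain_id,
            residues={rn: data.residues[rn] for rn in seq_map},
            residue_names={rn: data.residue_names[rn] for rn in seq_map},
            seq_map=seq_map,
        )

    raise MappingError(f"cannot map object of type {type(data).__name__}")
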