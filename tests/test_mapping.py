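"""Sequence alignment and cross-sequence data transfer."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from probescape import (
    Annotation,
    InteractionSet,
    MappingError,
    Profile,
    SecondaryStructure,
    SequenceRecord,
    align_positions,
    map_data,
)
from probescape.mapping import identity_mapping


def oracle_best_score(a: str, b: str, match=1.0, mismatch=-1.0,
                      gap_open=-5.0, gap_extend=-1.0):
    """Exhaustive alignment oracle for tiny sequences.

    Recursively enumerates every alignment (match/deletion/insertion column
    sequence) with affine gaps; a gap run is free when the opposite
    sequence is exhausted or not yet started (end-gap-free semantics).
    Returns (best score, set of optimal position maps as frozensets).
    """
    n, m = len(a), len(b)
    best = {"score": -np.inf, "maps": set()}

    def rec(i, j, score, state, amap):
        if i == n and j == m:
            if score > best["score"]:
                best["score"], best["maps"] = score, set()
            if score == best["score"]:
                best["maps"].add(frozenset(amap))
            return
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M", amap + [(i + 1, j + 1)])
        if i < n:  # consume a: gap in b's row
            free = j == 0 or j == m
            cost = 0.0 if free else (gap_extend if state == "D" else gap_open)
            rec(i + 1, j, score + cost, "D" if not free else "d", amap)
        if j < m:  # consume b: gap in a's row
            free = i == 0 or i == n
            cost = 0.0 if free else (gap_extend if state == "I" else gap_open)
            rec(i, j + 1, score + cost, "I" if not free else "i", amap)

    rec(0, 0, 0.0, None, [])
    return best["score"], best["maps"]


def test_identical_sequences_short_circuit():
    a = SequenceRecord("a", "ACGU")
    b = SequenceRecord("b", "acgt")  # T == U, case-insensitive
    mapping = align_positions(a, b)
    assert mapping.a_to_b == {1: 1, 2: 2, 3: 3, 4: 4}


def test_single_insertion_alignment_matches_exhaustive_oracle():
    a, b = "ACGU", "ACGGU"
    mapping = align_positions(SequenceRecord("a", a), SequenceRecord("b", b))
    score, optimal_maps = oracle_best_score(a, b)
    assert mapping.score == score
    assert frozenset(mapping.a_to_b.items()) in optimal_maps


@pytest.mark.parametrize("a,b", [
    ("ACGUACG", "ACGACG"),
    ("GGGAAACCC", "GGGAAAACCC"),
    ("ACGU", "UUUU"),
    ("AAAA", "AAGAA"),
])
def test_alignment_optimality_on_toy_pairs(a, b):
    mapping = align_positions(SequenceRecord("a", a), SequenceRecord("b", b))
    score, optimal_maps = oracle_best_score(a, b)
    assert mapping.score == pytest.approx(score)
    assert frozenset(mapping.a_to_b.items()) in optimal_maps


def test_mapping_is_monotone_on_random_sequences(rng):
    bases = np.array(list("ACGU"))
    for _ in range(50):
        a = "".join(rng.choice(bases, rng.integers(5, 25)))
        b = "".join(rng.choice(bases, rng.integers(5, 25)))
        mapping = align_positions(SequenceRecord("a", a), SequenceRecord("b", b))
        keys = sorted(mapping.a_to_b)
        vals = [mapping.a_to_b[k] for k in keys]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


def _toy_profile(seq, values):
    return Profile(seq, values, stderr=np.full(len(values), 0.1))


def test_map_data_identity_is_identity(hairpin):
    seq = hairpin.sequence
    ident = identity_mapping(seq, seq)
    values = np.linspace(0, 1, seq.length)
    prof = _toy_profile(seq, values)
    mapped = map_data(ident, prof)
    assert np.allclose(mapped.values, prof.values)
    assert (mapped.nodata == prof.nodata).all()

    assert map_data(ident, hairpin).pairs == hairpin.pairs

    ann = Annotation(name="x", category="spans", entries=[(2, 5)], sequence=seq)
    assert map_data(ident, ann).entries == [(2, 5)]

    df = pd.DataFrame({"i": [2, 3], "j": [11, 10], "statistic": [1.0, -2.0]})
    iset = InteractionSet(seq, df)
    mapped = map_data(ident, iset)
    assert mapped.data[["i", "j"]].to_numpy().tolist() == [[2, 11], [3, 10]]
    assert mapped.mask.all()


def test_map_pairs_through_insertion_gap(hairpin):
    seq_b = SequenceRecord("b", "GGGGAAAAACCCC")  # A inserted at position 8
    mapping = align_positions(hairpin.sequence, seq_b)
    mapped = map_data(mapping, hairpin)
    # endpoints renumbered per the map
    expected = {(mapping.a_to_b[i], mapping.a_to_b[j]) for i, j in hairpin.pairs}
    assert mapped.pairs == expected


def test_unmapped_interaction_endpoint_masked_not_deleted():
    seq_a = SequenceRecord("a", "ACGUACGUGG")
    seq_b = SequenceRecord("b", "ACGUACGU")  # 3' truncation
    mapping = align_positions(seq_a, seq_b)
    df = pd.DataFrame({"i": [1, 2], "j": [5, 10], "statistic": [1.0, 2.0]})
    iset = InteractionSet(seq_a, df)
    mapped = map_data(mapping, iset)
    assert len(mapped) == 2          # record count preserved
    assert mapped.mask.tolist() == [True, False]


def test_composition_consistency_on_toy_triple():
    # nested constructs with unambiguous placement: a inside b inside c
    a = SequenceRecord("a", "ACGGUCA")
    b = SequenceRecord("b", "UUACGGUCA")
    c = SequenceRecord("c", "UUACGGUCAGG")
    ab = align_positions(a, b)
    bc = align_positions(b, c)
    ac = align_positions(a, c)
    composed = ab.compose(bc)
    shared = set(composed.a_to_b) & set(ac.a_to_b)
    assert shared  # the toy triple must overlap
    for i in shared:
        assert composed.a_to_b[i] == ac.a_to_b[i]


def test_no_value_invention():
    a = SequenceRecord("a", "ACGUACGU")
    b = SequenceRecord("b", "ACGAACGU")
    mapping = align_positions(a, b)
    values = np.arange(1.0, 9.0)
    mapped = map_data(mapping, _toy_profile(a, values))
    carried = mapped.values[~mapped.nodata]
    assert set(np.round(carried, 9)) <= set(np.round(values, 9))


def test_sequence_mismatch_names_both_ids():
    a = SequenceRecord("left", "ACGU")
    b = SequenceRecord("right", "ACGGU")
    c = SequenceRecord("other", "GGCC")
    mapping = align_positions(a, b)
    prof = _toy_profile(c, np.zeros(4))
    with pytest.raises(MappingError, match="other.*left"):
        map_data(mapping, prof)


def test_inverse_round_trip():
    a = SequenceRecord("a", "ACGUACGU")
    b = SequenceRecord("b", "ACGAACGU")
    mapping = align_positions(a, b)
    inv = mapping.inverse()
    for i, j in mapping.a_to_b.items():
        assert inv.a_to_b[j] == i
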