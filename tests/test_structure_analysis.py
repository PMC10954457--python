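"""Interaction filtering, model comparison, consensus and 3D distances."""

import numpy as np
import pandas as pd
import pytest

from probescape import (
    AnalysisError,
    InteractionSet,
    SecondaryStructure,
    SequenceRecord,
    TertiaryStructure,
)
from probescape import structure_analysis as sa


def seq_of(n):
    return SequenceRecord("s", ("ACGU" * (n // 4 + 1))[:n])


def iset_of(n, rows, columns=("i", "j", "statistic")):
    df = pd.DataFrame(rows, columns=list(columns))
    return InteractionSet(seq_of(n), df)


def toy_tertiary(coords, seq=None):
    """One atom (O2') per residue at the given xyz coordinates."""
    n = len(coords)
    seq = seq or seq_of(n)
    return TertiaryStructure(
        sequence=seq, chain_id="A",
        residues={k + 1: {"O2'": tuple(map(float, coords[k]))} for k in range(n)},
        residue_names={k + 1: seq.residues[k] for k in range(n)},
        seq_map={k + 1: k + 1 for k in range(n)},
    )


# --- filtering ---------------------------------------------------------------

def test_sign_filter():
    iset = iset_of(20, [(1, 5, 3.0), (2, 8, -2.0), (3, 9, 1.0)])
    count = sa.filter_interactions(iset, sa.FilterCriteria(sign="positive"))
    assert count == 2 and iset.mask.tolist() == [True, False, True]


def test_top_k_filter():
    iset = iset_of(20, [(1, 5, 3.0), (2, 8, -2.0), (3, 9, 1.0)])
    sa.filter_interactions(iset, sa.FilterCriteria(top_k=1))
    assert iset.mask.tolist() == [True, False, False]


def test_distance_filter_keeps_near_record():
    coords = [(0, 0, 0), (8, 0, 0), (20, 0, 0), (35, 0, 0)]
    tert = toy_tertiary(coords)
    iset = iset_of(4, [(1, 2, 1.0), (1, 4, 1.0)])
    count = sa.filter_interactions(
        iset, sa.FilterCriteria(max_distance=20.0), tertiary=tert)
    assert count == 1 and iset.mask.tolist() == [True, False]


def test_distance_filter_requires_tertiary():
    iset = iset_of(10, [(1, 5, 1.0)])
    with pytest.raises(AnalysisError, match="tertiary"):
        sa.filter_interactions(iset, sa.FilterCriteria(max_distance=20.0))


def test_unknown_statistic_lists_available():
    iset = iset_of(10, [(1, 5, 1.0)])
    with pytest.raises(AnalysisError, match="statistic"):
        sa.filter_interactions(
            iset, sa.FilterCriteria(bounds={"nope": (0, None)}))


def test_filtering_is_idempotent_and_nondestructive(rng):
    rows = []
    for _ in range(50):
        i = int(rng.integers(1, 90))
        rows.append((i, int(rng.integers(i + 1, 100)), float(rng.normal())))
    iset = iset_of(100, rows)
    crit = sa.FilterCriteria(sign="positive", region=(10, 80))
    c1 = sa.filter_interactions(iset, crit)
    first = iset.mask.copy()
    c2 = sa.filter_interactions(iset, crit)
    assert c1 == c2 and (iset.mask == first).all()
    assert len(iset) == 50  # records never deleted


def test_class_label_filter():
    df = pd.DataFrame({"i": [1, 2], "j": [8, 9],
                       "class_label": ["primary", "secondary"]})
    iset = InteractionSet(seq_of(10), df)
    sa.filter_interactions(iset, sa.FilterCriteria(class_label="primary"))
    assert iset.mask.tolist() == [True, False]


# --- pair classification -----------------------------------------------------

def _ss(n, pairs):
    return SecondaryStructure(sequence=seq_of(n), pairs=set(pairs))


def test_classify_pairs_example():
    predicted = _ss(12, {(1, 12), (2, 11), (5, 8)})
    accepted = _ss(12, {(1, 12), (2, 11), (3, 10)})
    result = sa.classify_pairs(predicted, accepted)
    assert result.counts == {"correct": 2, "incorrect": 1, "missing": 1}
    assert result.sensitivity == pytest.approx(2 / 3)
    assert result.ppv == pytest.approx(2 / 3)


def test_classify_identical_and_empty():
    ss = _ss(12, {(1, 12), (2, 11)})
    same = sa.classify_pairs(ss, ss)
    assert same.sensitivity == 1.0 and same.ppv == 1.0
    empty = sa.classify_pairs(_ss(12, set()), ss)
    assert empty.counts["missing"] == 2
    assert np.isnan(empty.ppv)


def test_classify_set_identities_on_random_pair_sets(rng):
    for _ in range(1000):
        n = 30
        def random_pairs():
            pairs, used = set(), set()
            for _ in range(rng.integers(0, 8)):
                i = int(rng.integers(1, n))
                j = int(rng.integers(i + 1, n + 1))
                if i not in used and j not in used:
                    pairs.add((i, j))
                    used.update((i, j))
            return pairs
        pred, acc = random_pairs(), random_pairs()
        res = sa.classify_pairs(_ss(n, pred), _ss(n, acc))
        assert len(res.correct) + len(res.incorrect) == len(pred)
        assert len(res.correct) + len(res.missing) == len(acc)
        assert len(res.correct) + len(res.incorrect) + len(res.missing) == \
            len(pred | acc)


def test_classify_slip_tolerance():
    predicted = _ss(12, {(2, 11)})
    accepted = _ss(12, {(1, 12)})
    strict = sa.classify_pairs(predicted, accepted)
    assert strict.counts["correct"] == 0
    slipped = sa.classify_pairs(predicted, accepted, slip=1)
    assert slipped.counts["correct"] == 1 and slipped.counts["missing"] == 0


# --- consensus ---------------------------------------------------------------

def test_consensus_identical_models():
    model = _ss(12, {(1, 12), (2, 11)})
    table = sa.consensus_pairs([model] * 4)
    assert table.fraction_shared_by_all == 1.0


def test_consensus_counting_example():
    A, B, C = (1, 12), (2, 11), (3, 10)
    models = [_ss(12, {A, B}), _ss(12, {A}), _ss(12, {A}), _ss(12, {A, C})]
    table = sa.consensus_pairs(models, min_support=3)
    assert table.union == {A, B, C}
    assert table.support == {A: 4, B: 1, C: 1}
    assert table.fraction_shared_by_all == pytest.approx(1 / 3)
    assert table.consensus == {A}


def test_consensus_needs_two_models():
    with pytest.raises(AnalysisError, match=">= 2"):
        sa.consensus_pairs([_ss(12, {(1, 12)})])


def test_consensus_support_sums_to_model_sizes(rng):
    for _ in range(200):
        models = []
        for _ in range(int(rng.integers(2, 6))):
            pairs, used = set(), set()
            for _ in range(rng.integers(0, 6)):
                i = int(rng.integers(1, 20))
                j = int(rng.integers(i + 1, 21))
                if i not in used and j not in used:
                    pairs.add((i, j))
                    used.update((i, j))
            models.append(_ss(20, pairs))
        table = sa.consensus_pairs(models, min_support=2)
        assert sum(table.support.values()) == sum(len(m.pairs) for m in models)


# --- distances ---------------------------------------------------------------

def test_contact_distance_3_4_5():
    tert = toy_tertiary([(0, 0, 0), (3, 4, 0)])
    assert sa.contact_distance(tert, 1, 2) == pytest.approx(5.0)
    assert sa.contact_distance(tert, 1, 1) == 0.0


def test_contact_distance_fallback_atom():
    seq = seq_of(2)
    tert = TertiaryStructure(
        sequence=seq, chain_id="A",
        residues={1: {"C1'": (0.0, 0.0, 0.0)}, 2: {"O2'": (6.0, 0.0, 0.0)}},
        residue_names={1: "A", 2: "C"}, seq_map={1: 1, 2: 2})
    xyz, used = tert.atom_xyz(1, "O2'", "C1'")
    assert used == "C1'"
    assert sa.contact_distance(tert, 1, 2) == pytest.approx(6.0)


def test_contact_distance_missing_atoms_is_nan():
    seq = seq_of(2)
    tert = TertiaryStructure(
        sequence=seq, chain_id="A",
        residues={1: {"N1": (0.0, 0.0, 0.0)}, 2: {"O2'": (6.0, 0.0, 0.0)}},
        residue_names={1: "A", 2: "C"}, seq_map={1: 1, 2: 2})
    assert np.isnan(sa.contact_distance(tert, 1, 2))


def test_distance_histogram_counts_and_background():
    coords = [(0, 0, 0), (5, 0, 0), (15, 0, 0), (100, 0, 0)]
    tert = toy_tertiary(coords)
    iset = iset_of(4, [(1, 2, 1.0), (1, 3, 1.0)])
    counts, bg, edges = sa.distance_histogram(
        iset, tert, bins=np.array([0.0, 10.0, 20.0]), gap=0)
    assert counts.tolist() == [1, 1]
    # background enumerates all 6 pairs; distances 5,15,100,10,95,85 ->
    # in-range: 5 (bin 0) and 15, 10 (bin 1); numpy puts 10 in the second bin
    assert bg.tolist() == [1, 2]


def test_distance_histogram_empty_mask():
    tert = toy_tertiary([(0, 0, 0), (5, 0, 0)])
    iset = iset_of(2, [(1, 2, 1.0)])
    iset.mask[:] = False
    counts, bg, edges = sa.distance_histogram(iset, tert, gap=0)
    assert counts.sum() == 0


def test_density_heatmap_binning_and_mass(rng):
    iset = iset_of(100, [(10, 50, 1.0), (12, 52, 1.0)])
    grid = sa.density_heatmap(iset, bin_size=5)
    assert grid[10 // 5, 50 // 5] == 2.0  # integer division lands both here
    assert grid.sum() == 2.0
    with pytest.raises(AnalysisError):
        sa.density_heatmap(iset, bin_size=0)
    # mass conservation under random masks
    rows = [(int(i), int(j), 0.0) for i, j in
            ((rng.integers(1, 50), rng.integers(51, 100)) for _ in range(40))]
    iset = iset_of(100, rows)
    iset.mask = rng.random(40) < 0.5
    assert sa.density_heatmap(iset, bin_size=7).sum() == iset.mask.sum()
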