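"""Transcript-centric data classes.

Every piece of RNA structural information is held in one of five classes —
:class:`Annotation`, :class:`SecondaryStructure`, :class:`TertiaryStructure`,
:class:`Profile` and :class:`InteractionSet` — each anchored to a
:class:`SequenceRecord`.  A :class:`Sample` groups keyword-accessible data
objects describing one RNA under one experimental condition.

Coordinates are 1-based inclusive throughout.  T and U compare equal and
sequence identity is case-insensitive, so DNA-alphabet inputs mix freely
with RNA.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import AnalysisError, ProbescapeError

#: default low/mid/high reactivity colour breakpoints
REACTIVITY_BREAKPOINTS = (0.4, 0.85)
REACTIVITY_COLORS = ("black", "orange", "red")

_COMPLEMENT = str.maketrans("ACGUTNacgutn", "UGCAANugcaan")


def normalize_residues(residues: str) -> str:
    """Canonical form used for identity checks: uppercase, T mapped to U."""
    return residues.upper().replace("T", "U")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named primary sequence; the anchor for every other data object."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ProbescapeError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def matches(self, other: "SequenceRecord") -> bool:
        """Identity under the T==U, case-insensitive convention."""
        return normalize_residues(self.residues) == normalize_residues(other.residues)


@dataclass
class Annotation:
    """Regions, sites, nucleotide groups or primer-binding sites.

    ``entries`` are 1-based inclusive ``[start, end]`` spans.  For the
    ``sites`` and ``group`` categories every span has start == end; for
    ``primers`` start > end marks a reverse-strand primer.
    """

    name: str
    category: str  # spans | sites | group | primers
    entries: list[tuple[int, int]]
    sequence: SequenceRecord
    color: str = "blue"
    metadata: dict[str, Any] = field(default_factory=dict)

    _CATEGORIES = ("spans", "sites", "group", "primers")

    def __post_init__(self) -> None:
        if self.category not in self._CATEGORIES:
            raise ProbescapeError(
                f"annotation category {self.category!r} not one of {self._CATEGORIES}"
            )
        n = self.sequence.length
        for start, end in self.entries:
            lo, hi = min(start, end), max(start, end)
            if lo < 1 or hi > n:
                raise ProbescapeError(
                    f"annotation {self.name!r}: span [{start},{end}] outside 1..{n}"
                )
            if self.category in ("sites", "group") and start != end:
                raise ProbescapeError(
                    f"annotation {self.name!r}: {self.category} entries need start == end"
                )
            if self.category != "primers" and start > end:
                raise ProbescapeError(
                    f"annotation {self.name!r}: start {start} > end {end}"
                )

    def positions(self) -> set[int]:
        out: set[int] = set()
        for start, end in self.entries:
            lo, hi = min(start, end), max(start, end)
            out.update(range(lo, hi + 1))
        return out


@dataclass
class SecondaryStructure:
    """A base-pair list plus optional 2D drawing coordinates.

    ``pairs`` holds unordered (i, j) with i < j, each position in at most
    one pair.  ``drawing`` is an (n, 2) array of per-nucleotide (x, y)
    coordinates in arbitrary drawing units, or None.
    """

    sequence: SequenceRecord
    pairs: set[tuple[int, int]]
    drawing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = self.sequence.length
        seen: set[int] = set()
        norm = set()
        for i, j in self.pairs:
            if i > j:
                i, j = j, i
            if not (1 <= i < j <= n):
                raise ProbescapeError(f"pair ({i},{j}) outside 1 <= i < j <= {n}")
            if i in seen or j in seen:
                raise ProbescapeError(f"position in pair ({i},{j}) already paired")
            seen.update((i, j))
            norm.add((i, j))
        self.pairs = norm
        if self.drawing is not None:
            self.drawing = np.asarray(self.drawing, dtype=float)
            if self.drawing.shape != (n, 2):
                raise ProbescapeError(
                    f"drawing has shape {self.drawing.shape}, expected ({n}, 2)"
                )

    def partner(self, i: int) -> int:
        """Pairing partner of position i, or 0 if unpaired."""
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return 0

    def paired_mask(self) -> np.ndarray:
        mask = np.zeros(self.sequence.length, dtype=bool)
        for i, j in self.pairs:
            mask[i - 1] = True
            mask[j - 1] = True
        return mask


@dataclass
class TertiaryStructure:
    """Atomic coordinates for one nucleic-acid model.

    ``residues`` maps residue number -> {atom name: (x, y, z) in Angstrom};
    ``seq_map`` maps residue number -> 1-based transcript position and is
    injective.
    """

    sequence: SequenceRecord
    chain_id: str
    residues: dict[int, dict[str, tuple[float, float, float]]]
    residue_names: dict[int, str]
    seq_map: dict[int, int]

    def __post_init__(self) -> None:
        mapped = list(self.seq_map.values())
        if len(mapped) != len(set(mapped)):
            raise ProbescapeError("tertiary seq_map is not injective")
        for resnum in self.seq_map:
            if not self.residues.get(resnum):
                raise ProbescapeError(f"mapped residue {resnum} has no atoms")

    def atom_xyz(self, position: int, atom: str = "O2'", fallback: str = "C1'"):
        """Coordinates of ``atom`` at a transcript position, falling back to
        ``fallback``; returns (xyz, atom_used) or (None, None)."""
        for resnum, pos in self.seq_map.items():
            if pos == position:
                atoms = self.residues[resnum]
                if atom in atoms:
                    return np.asarray(atoms[atom]), atom
                if fallback in atoms:
                    return np.asarray(atoms[fallback]), fallback
                return None, None
        return None, None

    def mapped_positions(self) -> set[int]:
        return set(self.seq_map.values())


class Profile:
    """Per-nucleotide measurements with errors and a no-data mask.

    ``values`` is the working metric (e.g. normalized reactivity); ``raw``
    and ``stderr`` are optional companions.  ``nodata`` marks positions
    excluded from every statistic (parsers map the -999 sentinel and
    non-numeric entries here).
    """

    def __init__(
        self,
        sequence: SequenceRecord,
        values: Iterable[float],
        raw: Optional[Iterable[float]] = None,
        stderr: Optional[Iterable[float]] = None,
        nodata: Optional[Iterable[bool]] = None,
        metric: str = "reactivity",
        breakpoints: tuple[float, float] = REACTIVITY_BREAKPOINTS,
        colors: tuple[str, str, str] = REACTIVITY_COLORS,
        extras: Optional[pd.DataFrame] = None,
    ) -> None:
        n = sequence.length
        self.sequence = sequence
        self.values = np.asarray(list(values), dtype=float)
        if self.values.shape != (n,):
            raise ProbescapeError(
                f"profile has {self.values.size} values for a {n}-nt sequence"
            )
        self.raw = None if raw is None else np.asarray(list(raw), dtype=float)
        self.stderr = None if stderr is None else np.asarray(list(stderr), dtype=float)
        for name, arr in (("raw", self.raw), ("stderr", self.stderr)):
            if arr is not None and arr.shape != (n,):
                raise ProbescapeError(f"profile {name} array length != {n}")
        if nodata is None:
            nodata = ~np.isfinite(self.values)
        self.nodata = np.asarray(list(nodata), dtype=bool)
        if self.nodata.shape != (n,):
            raise ProbescapeError(f"profile nodata mask length != {n}")
        self.nodata |= ~np.isfinite(self.values)
        self.metric = metric
        self.breakpoints = tuple(breakpoints)
        self.colors = tuple(colors)
        self.extras = extras

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.sequence.length + 1)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata]

    def color_class(self, value: float) -> int:
        """0 (low), 1 (mid) or 2 (high) by the metric breakpoints."""
        lo, hi = self.breakpoints
        if value < lo:
            return 0
        if value < hi:
            return 1
        return 2

    def copy(self) -> "Profile":
        return copy.deepcopy(self)


class InteractionSet:
    """Internucleotide records (RINGs, PAIRs, pairing probabilities ...).

    Backed by a DataFrame with columns ``i`` and ``j`` (1-based, i < j),
    one column per named statistic, and an optional ``class_label`` column
    (PAIR confidence classes ``primary``/``secondary``).  Filtering only
    toggles the boolean ``mask``; records are never deleted.
    """

    RESERVED = ("i", "j", "class_label")

    def __init__(
        self,
        sequence: SequenceRecord,
        records: pd.DataFrame,
        mask: Optional[np.ndarray] = None,
        default_metric: Optional[str] = None,
    ) -> None:
        self.sequence = sequence
        df = records.reset_index(drop=True).copy()
        if "i" not in df.columns or "j" not in df.columns:
            raise ProbescapeError("interaction records need columns 'i' and 'j'")
        df["i"] = df["i"].astype(int)
        df["j"] = df["j"].astype(int)
        flip = df["i"] > df["j"]
        df.loc[flip, ["i", "j"]] = df.loc[flip, ["j", "i"]].to_numpy()
        n = sequence.length
        bad = (df["i"] < 1) | (df["j"] > n) | (df["i"] >= df["j"])
        if bad.any():
            row = df[bad].iloc[0]
            raise ProbescapeError(
                f"interaction ({row['i']},{row['j']}) violates 1 <= i < j <= {n}"
            )
        self.data = df
        self.mask = (
            np.ones(len(df), dtype=bool) if mask is None else np.asarray(mask, bool)
        )
        if self.mask.shape != (len(df),):
            raise ProbescapeError("interaction mask length != record count")
        self.default_metric = default_metric or next(
            (c for c in df.columns if c not in self.RESERVED), None
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def statistic_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    def masked(self) -> pd.DataFrame:
        """The records currently passing the filter."""
        return self.data[self.mask]

    def copy(self) -> "InteractionSet":
        return InteractionSet(
            self.sequence,
            self.data.copy(),
            self.mask.copy(),
            self.default_metric,
        )


DATA_CLASSES = (
    SequenceRecord,
    Annotation,
    SecondaryStructure,
    TertiaryStructure,
    Profile,
    InteractionSet,
)


class Sample:
    """Keyword -> data-object grouping for one experimental condition."""

    def __init__(self, label: str) -> None:
        self.label = label
        self.store: dict[str, Any] = {}

    def add(self, keyword: str, obj: Any) -> None:
        if keyword in self.store:
            raise ProbescapeError(
                f"sample {self.label!r} already has keyword {keyword!r}"
            )
        if not isinstance(obj, DATA_CLASSES) and not (
            isinstance(obj, list) and all(isinstance(o, Annotation) for o in obj)
        ):
            raise ProbescapeError(f"object for {keyword!r} is not a data class")
        self.store[keyword] = obj

    def get(self, keyword: str) -> Any:
        if keyword not in self.store:
            raise AnalysisError(
                f"sample {self.label!r} has no keyword {keyword!r}; "
                f"available: {sorted(self.store)}"
            )
        return self.store[keyword]

    def keywords_of(self, cls: type) -> list[str]:
        return [k for k, v in self.store.items() if isinstance(v, cls)]

    def __contains__(self, keyword: str) -> bool:
        return keyword in self.store

    def __repr__(self) -> str:
        kinds = {k: type(v).__name__ for k, v in self.store.items()}
        return f"Sample({self.label!r}, {kinds})"
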