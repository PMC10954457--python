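"""Internucleotide measurement formats: RING/PAIR tables and pairing-
probability dotplots.

RING and PAIR tables are whitespace-separated with one header line whose
first two columns are the nucleotide indices; every further column is kept
as a named statistic (forward compatibility with new correlation metrics).
Dotplot text stores -log10(probability); probabilities are reconstructed
as 10**(-column) and must land in (0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..containers import InteractionSet, SequenceRecord
from ..errors import FormatError
from .sequence import open_text

PAIR_CLASSES = {1: "primary", 2: "secondary"}


def _read_table(path, sequence: SequenceRecord):
    lines = [ln for ln in open_text(path) if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty interaction table")
    header = lines[0].split()
    if len(header) < 2:
        raise FormatError(f"{path}: header needs at least columns i and j")
    rows = []
    dropped = 0
    for lineno, line in enumerate(lines[1:], 2):
        cols = line.split()
        if len(cols) != len(header):
            raise FormatError(
                f"{path}, line {lineno}: {len(cols)} columns for {len(header)} headers"
            )
        try:
            i, j = int(cols[0]), int(cols[1])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: non-integer indices") from None
        if i > j:
            i, j = j, i
        if i == j:
            dropped += 1
            continue
        rows.append([i, j] + cols[2:])
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} records with j <= i")
    df = pd.DataFrame(rows, columns=["i", "j"] + header[2:])
    return df, header


def read_ring(path, sequence: SequenceRecord) -> InteractionSet:
    df, header = _read_table(path, sequence)
    for col in df.columns[2:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    metric = "statistic" if "statistic" in df.columns else (
        df.columns[2] if len(df.columns) > 2 else None
    )
    return InteractionSet(sequence, df, default_metric=metric)


def read_pair(path, sequence: SequenceRecord) -> InteractionSet:
    df, header = _read_table(path, sequence)
    class_col = next((c for c in df.columns if c.lower() == "class"), None)
    if class_col is not None:
        labels = df[class_col].apply(
            lambda v: PAIR_CLASSES.get(int(float(v)), None)
            if str(v).replace(".", "").lstrip("-").isdigit()
            else (str(v) if str(v) in ("primary", "secondary") else None)
        )
        df = df.drop(columns=[class_col])
        df["class_label"] = labels
    for col in df.columns:
        if col not in ("i", "j", "class_label"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return InteractionSet(sequence, df)


def read_pairprob_dp(path, sequence: SequenceRecord) -> InteractionSet:
    """Pairing-probability dotplot text: length line, header, then rows of
    i, j, -log10(p)."""
    lines = [ln for ln in open_text(path) if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated dotplot file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise FormatError(f"{path}, line 1: dotplot must start with the length") from None
    if n != sequence.length:
        raise FormatError(
            f"{path}: dotplot length {n} != sequence length {sequence.length}"
        )
    rows = []
    for lineno, line in enumerate(lines[2:], 3):
        cols = line.split()
        if len(cols) < 3:
            raise FormatError(f"{path}, line {lineno}: dotplot rows need i j -log10(p)")
        i, j, neglog = int(cols[0]), int(cols[1]), float(cols[2])
        p = 10.0 ** (-neglog)
        if not (0.0 < p <= 1.0):
            raise FormatError(
                f"{path}, line {lineno}: probability {p} outside (0, 1]"
            )
        rows.append((min(i, j), max(i, j), p))
    df = pd.DataFrame(rows, columns=["i", "j", "probability"])
    return InteractionSet(sequence, df, default_metric="probability")


def read_interactions(path, tag: str, sequence: SequenceRecord) -> InteractionSet:
    readers = {"ring": read_ring, "pair": read_pair, "pairprob-dp": read_pairprob_dp}
    if tag not in readers:
        raise FormatError(f"unknown interaction tag {tag!r}; use {sorted(readers)}")
    if sequence is None:
        raise FormatError(
            f"{path}: {tag!r} files carry no sequence; supply one "
            "(e.g. load a FASTA, profile or structure in the same sample)"
        )
    return readers[tag](path, sequence)


def write_pairprob_dp(iset: InteractionSet, path) -> None:
    lines = [str(iset.sequence.length), "i\tj\t-log10(Probability)"]
    for _, row in iset.data.iterrows():
        neglog = -np.log10(row["probability"])
        lines.append(f"{int(row['i'])}\t{int(row['j'])}\t{neglog:.6f}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
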