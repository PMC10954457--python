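"""Per-nucleotide measurement formats.

All readers map the -999 sentinel and non-numeric entries to the
profile's no-data mask.  When the file carries its own sequence
(shapemapper-profile, map, rnaframework-xml, dance-reactivities) it is
reconstructed from the file; otherwise (shape, wig) the caller supplies
the sequence.  A caller-supplied sequence whose length disagrees with the
file is an error naming both lengths.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from ..containers import Profile, SequenceRecord
from ..errors import FormatError
from .sequence import open_text

SENTINEL = -999.0


def _to_float(token: str) -> float:
    try:
        v = float(token)
    except ValueError:
        return np.nan
    return np.nan if v == SENTINEL else v


def _check_length(path, n_file: int, sequence: SequenceRecord | None) -> None:
    if sequence is not None and sequence.length != n_file:
        raise FormatError(
            f"{path}: file has {n_file} positions but the supplied sequence "
            f"{sequence.id!r} has {sequence.length}"
        )


def read_shapemapper_profile(path, sequence: SequenceRecord | None = None) -> Profile:
    """Tab-separated profile table with headers.

    Required columns: Nucleotide, Sequence, Norm_profile, Norm_stderr.
    Extra numeric columns are preserved as named auxiliary tracks.
    """
    text = "\n".join(open_text(path))
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as tab-separated table: {exc}") from None
    required = ["Nucleotide", "Sequence", "Norm_profile", "Norm_stderr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df.sort_values("Nucleotide")
    n = len(df)
    _check_length(path, n, sequence)
    seq = SequenceRecord(id=Path(path).stem, residues="".join(df["Sequence"].astype(str)))
    values = df["Norm_profile"].apply(lambda v: np.nan if v == SENTINEL else v).to_numpy(float)
    stderr = df["Norm_stderr"].apply(lambda v: np.nan if v == SENTINEL else v).to_numpy(float)
    raw = None
    if "HQ_profile" in df.columns:
        raw = df["HQ_profile"].to_numpy(float)
    extras = df[[c for c in df.columns if c not in required]]
    return Profile(seq, values, raw=raw, stderr=stderr,
                   extras=extras if len(extras.columns) else None)


def read_map(path, sequence: SequenceRecord | None = None) -> Profile:
    """Headerless 4-column table: position, value, stderr, base."""
    rows = []
    for lineno, line in enumerate(open_text(path), 1):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 4:
            raise FormatError(f"{path}, line {lineno}: map rows need 4 columns")
        rows.append((int(cols[0]), _to_float(cols[1]), _to_float(cols[2]), cols[3]))
    if not rows:
        raise FormatError(f"{path}: empty map file")
    rows.sort()
    _check_length(path, len(rows), sequence)
    seq = SequenceRecord(id=Path(path).stem, residues="".join(r[3] for r in rows))
    return Profile(seq,
                   np.array([r[1] for r in rows]),
                   stderr=np.array([r[2] for r in rows]))


def read_shape(path, sequence: SequenceRecord) -> Profile:
    """Two-column position/value reactivity table (no sequence in file)."""
    values = np.full(0, np.nan)
    rows = []
    for lineno, line in enumerate(open_text(path), 1):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 2:
            raise FormatError(f"{path}, line {lineno}: shape rows need 2 columns")
        rows.append((int(cols[0]), _to_float(cols[1])))
    if not rows:
        raise FormatError(f"{path}: empty shape file")
    _check_length(path, max(r[0] for r in rows), sequence)
    values = np.full(sequence.length, np.nan)
    for pos, v in rows:
        values[pos - 1] = v
    return Profile(sequence, values)


def read_rnaframework_xml(path, sequence: SequenceRecord | None = None) -> Profile:
    """RNA-Framework-style XML: transcript element with sequence + reactivity."""
    try:
        root = ElementTree.parse(str(path)).getroot()
    except ElementTree.ParseError as exc:
        raise FormatError(f"{path}: XML parse failure: {exc}") from None
    transcript = root if root.tag == "transcript" else root.find(".//transcript")
    if transcript is None:
        raise FormatError(f"{path}: no <transcript> element")
    seq_el = transcript.find("sequence")
    react_el = transcript.find("reactivity")
    if seq_el is None or react_el is None:
        raise FormatError(f"{path}: transcript needs <sequence> and <reactivity>")
    residues = "".join((seq_el.text or "").split())
    tokens = (react_el.text or "").replace(",", " ").split()
    values = np.array([_to_float(t) for t in tokens])
    if len(values) != len(residues):
        raise FormatError(
            f"{path}: {len(values)} reactivities for {len(residues)} nt"
        )
    _check_length(path, len(residues), sequence)
    seq = SequenceRecord(id=transcript.get("id", Path(path).stem), residues=residues)
    err_el = transcript.find("error")
    stderr = None
    if err_el is not None:
        stderr = np.array([_to_float(t) for t in (err_el.text or "").replace(",", " ").split()])
    return Profile(seq, values, stderr=stderr)


def read_dance_reactivities(path, sequence: SequenceRecord | None = None,
                            component: int = 0) -> Profile:
    """Ensemble-deconvolution reactivities: one column per inferred state.

    Header block: line 1 = number of states, line 2 = population fractions,
    then a column-headed table (Position, Sequence, one reactivity column
    per state).  ``component`` selects the state.
    """
    lines = [ln for ln in open_text(path) if ln.strip()]
    if len(lines) < 4:
        raise FormatError(f"{path}: truncated ensemble-reactivities file")
    try:
        n_states = int(lines[0].split()[0])
        populations = [float(t) for t in lines[1].split()]
    except ValueError:
        raise FormatError(f"{path}: header must give state count then populations") from None
    if len(populations) != n_states:
        raise FormatError(f"{path}: {len(populations)} populations for {n_states} states")
    if not (0 <= component < n_states):
        raise FormatError(f"{path}: component {component} outside 0..{n_states - 1}")
    header = lines[2].split()
    rows = [ln.split() for ln in lines[3:]]
    df = pd.DataFrame(rows, columns=header)
    state_cols = [c for c in header if c not in ("Position", "Sequence")]
    _check_length(path, len(df), sequence)
    seq = SequenceRecord(id=Path(path).stem, residues="".join(df["Sequence"]))
    values = df[state_cols[component]].map(_to_float).to_numpy(float)
    prof = Profile(seq, values, metric=f"reactivity_state{component}")
    prof.population = populations[component]
    return prof


def read_wig(path, sequence: SequenceRecord) -> Profile:
    """WIG track (fixedStep and variableStep) on a caller-supplied sequence."""
    values = np.full(sequence.length, np.nan)
    mode, pos, step, span = None, None, 1, 1

    def put(p: int, v: float) -> None:
        for k in range(p, p + span):
            if 1 <= k <= sequence.length:
                values[k - 1] = v

    for lineno, line in enumerate(open_text(path), 1):
        line = line.strip()
        if not line or line.startswith(("track", "#", "browser")):
            continue
        if line.startswith("fixedStep") or line.startswith("variableStep"):
            fields = dict(tok.split("=", 1) for tok in line.split()[1:])
            span = int(fields.get("span", 1))
            if line.startswith("fixedStep"):
                mode = "fixed"
                pos = int(fields["start"])
                step = int(fields.get("step", 1))
            else:
                mode = "variable"
            continue
        cols = line.split()
        if mode == "fixed":
            put(pos, _to_float(cols[0]))
            pos += step
        elif mode == "variable":
            if len(cols) < 2:
                raise FormatError(f"{path}, line {lineno}: variableStep rows need 2 columns")
            put(int(cols[0]), _to_float(cols[1]))
        else:
            raise FormatError(f"{path}, line {lineno}: data before a step declaration")
    return Profile(sequence, values, metric="track")


def read_profile(path, tag: str, sequence: SequenceRecord | None = None,
                 **kwargs) -> Profile:
    """Read any supported per-nucleotide format into a Profile."""
    if tag == "shapemapper-profile":
        return read_shapemapper_profile(path, sequence)
    if tag == "map":
        return read_map(path, sequence)
    if tag == "shape":
        if sequence is None:
            raise FormatError("'shape' files carry no sequence; supply one")
        return read_shape(path, sequence)
    if tag == "rnaframework-xml":
        return read_rnaframework_xml(path, sequence)
    if tag == "dance-reactivities":
        return read_dance_reactivities(path, sequence, **kwargs)
    if tag == "wig":
        if sequence is None:
            raise FormatError("'wig' files carry no sequence; supply one")
        return read_wig(path, sequence)
    raise FormatError(f"unknown profile tag {tag!r}")
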