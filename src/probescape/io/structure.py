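"""Secondary-structure formats: connectivity tables (CT) and dot-bracket.

CT follows the RNAstructure flavour: a header line with the nucleotide
count and a title, then six whitespace-separated columns (index, base,
index-1, index+1, pairing partner or 0, natural numbering).  Dot-bracket
files carry an optional '>' header, a sequence line and a structure line;
pseudoknots use escalating bracket families () [] {} <>.

Drawing dialects (VARNA, XRNA, FORNA, R2DT, NSD) live in ``drawing.py``
and are dispatched through :func:`read_secondary_structure`.
"""

from __future__ import annotations

from pathlib import Path

from ..containers import SecondaryStructure, SequenceRecord
from ..errors import FormatError
from .sequence import open_text

BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_OPEN_OF = {v: k for k, v in BRACKET_PAIRS.items()}
FAMILIES = ["()", "[]", "{}", "<>"]


def read_ct(path) -> SecondaryStructure:
    lines = [ln for ln in open_text(path) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}, line 1: CT header must start with a count") from None
    if len(lines) < n + 1:
        raise FormatError(f"{path}: header declares {n} rows, found {len(lines) - 1}")
    bases = [""] * n
    partner = [0] * n
    for lineno, line in enumerate(lines[1 : n + 1], 2):
        cols = line.split()
        if len(cols) < 6:
            raise FormatError(f"{path}, line {lineno}: CT rows need 6 columns")
        try:
            idx, pair = int(cols[0]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: non-integer index column") from None
        if not (1 <= idx <= n):
            raise FormatError(f"{path}, line {lineno}: index {idx} outside 1..{n}")
        bases[idx - 1] = cols[1]
        partner[idx - 1] = pair
    # reciprocity: if i says j then j must say i
    pairs: set[tuple[int, int]] = set()
    for i, j in enumerate(partner, 1):
        if j == 0:
            continue
        if not (1 <= j <= n) or partner[j - 1] != i:
            says = partner[j - 1] if 1 <= j <= n else "nothing"
            raise FormatError(
                f"{path}: CT integrity error: {i} pairs with {j} but {j} says {says}"
            )
        if i < j:
            pairs.add((i, j))
    title = " ".join(header[1:]) or Path(path).stem
    seq = SequenceRecord(id=title, residues="".join(bases))
    return SecondaryStructure(sequence=seq, pairs=pairs)


def write_ct(ss: SecondaryStructure, path) -> None:
    n = ss.sequence.length
    seq = ss.sequence.residues
    lines = [f"{n}\t{ss.sequence.id}"]
    for i in range(1, n + 1):
        j = ss.partner(i)
        lines.append(
            f"{i}\t{seq[i - 1]}\t{i - 1}\t{(i + 1) if i < n else 0}\t{j}\t{i}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_dotbracket_string(db: str, origin: str = "dot-bracket") -> set[tuple[int, int]]:
    """Decode a multi-layer dot-bracket string into a pair set.

    Bracket families (), [], {}, <> and letter layers (A pairs with a) are
    each matched with their own stack.  Raises with the 1-based position of
    the first unbalanced bracket.
    """
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db, 1):
        if ch in ".-_,:":
            continue
        if ch in BRACKET_PAIRS or ch.isalpha() and ch.isupper():
            stacks.setdefault(ch, []).append(pos)
        elif ch in _OPEN_OF or ch.isalpha() and ch.islower():
            opener = _OPEN_OF.get(ch, ch.upper())
            stack = stacks.get(opener, [])
            if not stack:
                raise FormatError(
                    f"{origin}: unbalanced closing {ch!r} at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        else:
            raise FormatError(f"{origin}: invalid character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(
                f"{origin}: unbalanced opening {opener!r} at position {stack[-1]}"
            )
    return pairs


def read_dotbracket(path) -> SecondaryStructure:
    lines = [ln.strip() for ln in open_text(path) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty dot-bracket file")
    title = Path(path).stem
    if lines[0].startswith(">"):
        title = lines[0][1:].strip() or title
        lines = lines[1:]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a sequence line and a structure line")
    seq_line, db_line = lines[0], lines[1].split()[0]  # trailing energy tolerated
    if len(db_line) != len(seq_line):
        raise FormatError(
            f"{path}: sequence length {len(seq_line)} != structure length {len(db_line)}"
        )
    pairs = parse_dotbracket_string(db_line, origin=str(path))
    seq = SequenceRecord(id=title, residues=seq_line)
    return SecondaryStructure(sequence=seq, pairs=pairs)


def pairs_to_dotbracket(pairs: set[tuple[int, int]], n: int) -> str:
    """Encode pairs as dot-bracket, colouring the crossing graph greedily.

    Pairs are taken 5'-to-3'; each goes to the lowest bracket family it
    does not cross.  More than four mutually crossing layers exceed the
    bracket alphabet and raise.
    """
    ordered = sorted(pairs)
    assigned: list[list[tuple[int, int]]] = [[] for _ in FAMILIES]
    for i, j in ordered:
        placed = False
        for layer, members in enumerate(assigned):
            if not any(a < i < b < j or i < a < j < b for a, b in members):
                members.append((i, j))
                placed = True
                break
        if not placed:
            raise FormatError(
                f"pair ({i},{j}) requires a fifth bracket family; "
                "more than 4 mutually crossing layers are not encodable"
            )
    out = ["."] * n
    for layer, members in enumerate(assigned):
        op, cl = FAMILIES[layer]
        for i, j in members:
            out[i - 1], out[j - 1] = op, cl
    return "".join(out)


def write_dotbracket(ss: SecondaryStructure, path) -> None:
    db = pairs_to_dotbracket(ss.pairs, ss.sequence.length)
    Path(path).write_text(f">{ss.sequence.id}\n{ss.sequence.residues}\n{db}\n")


def read_secondary_structure(path, tag: str = "ct") -> SecondaryStructure:
    """Read any supported secondary-structure dialect."""
    from . import drawing  # deferred: lxml only needed for drawing dialects

    readers = {
        "ct": read_ct,
        "dotbracket": read_dotbracket,
        "varna": drawing.read_varna,
        "xrna": drawing.read_xrna,
        "forna": drawing.read_forna,
        "r2dt": drawing.read_r2dt,
        "nsd": drawing.read_nsd,
    }
    if tag not in readers:
        raise FormatError(f"unknown secondary-structure tag {tag!r}; use {sorted(readers)}")
    return readers[tag](path)


def write_secondary_structure(ss: SecondaryStructure, path, tag: str = "ct") -> None:
    writers = {"ct": write_ct, "dotbracket": write_dotbracket}
    if tag not in writers:
        raise FormatError(f"no writer for tag {tag!r}; use {sorted(writers)}")
    writers[tag](ss, path)
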