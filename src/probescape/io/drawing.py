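"""Secondary-structure drawing dialects: VARNA, XRNA, FORNA, R2DT, NSD.

Each dialect is parsed for sequence, base pairs and per-nucleotide (x, y)
drawing coordinates only; fonts, colours and styling are ignored.  For the
JSON dialects only the nucleotide-coordinate layout sub-schema is
supported; other sub-schemas are rejected with an explanatory message.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from lxml import etree

from ..containers import SecondaryStructure, SequenceRecord
from ..errors import FormatError
from .sequence import open_text


def _build(path, title, bases, coords, pairs) -> SecondaryStructure:
    if not bases:
        raise FormatError(f"{path}: no nucleotides found")
    seq = SequenceRecord(id=title, residues="".join(bases))
    drawing = np.asarray(coords, dtype=float)
    return SecondaryStructure(sequence=seq, pairs=set(pairs), drawing=drawing)


def _parse_xml(path):
    try:
        return etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: XML parse failure: {exc}") from None


def read_varna(path) -> SecondaryStructure:
    """VARNA session XML: <nt num base x y> children plus <basepair i j>."""
    root = _parse_xml(path)
    nts = sorted(
        root.iter("nt"), key=lambda el: int(el.get("num", 0))
    )
    if not nts:
        raise FormatError(f"{path}: no <nt> elements; unsupported VARNA sub-schema")
    bases, coords = [], []
    for el in nts:
        bases.append(el.get("base", "N"))
        coords.append((float(el.get("x", 0)), float(el.get("y", 0))))
    pairs = [
        (int(el.get("i")), int(el.get("j"))) for el in root.iter("basepair")
    ]
    title = root.get("name", Path(path).stem)
    return _build(path, title, bases, coords, pairs)


def read_xrna(path) -> SecondaryStructure:
    """XRNA document: <NucListData> 'base x y' lines and <BasePairs> helices.

    A <BasePairs nucID=i length=l bpNucID=j> element encodes the helix
    (i+k, j-k) for k = 0 .. l-1.
    """
    root = _parse_xml(path)
    nucdata = next(iter(root.iter("NucListData")), None)
    if nucdata is None or not (nucdata.text or "").strip():
        raise FormatError(f"{path}: no <NucListData> section")
    start = int(nucdata.get("StartNucID", 1))
    bases, coords = [], []
    for line in nucdata.text.strip().splitlines():
        cols = line.split()
        if len(cols) < 3:
            raise FormatError(f"{path}: NucListData line {line!r} needs 'base x y'")
        bases.append(cols[0])
        coords.append((float(cols[1]), float(cols[2])))
    pairs = []
    for el in root.iter("BasePairs"):
        i = int(el.get("nucID")) - start + 1
        j = int(el.get("bpNucID")) - start + 1
        length = int(el.get("length", 1))
        pairs += [(i + k, j - k) for k in range(length)]
    mol = next(iter(root.iter("RNAMolecule")), None)
    title = (mol.get("name") if mol is not None else None) or Path(path).stem
    return _build(path, title, bases, coords, pairs)


def read_forna(path) -> SecondaryStructure:
    """FORNA layout JSON: sequence + dot-bracket structure + positions."""
    from .structure import parse_dotbracket_string

    obj = _load_json(path)
    if not {"sequence", "structure", "positions"} <= set(obj):
        raise FormatError(
            f"{path}: unsupported FORNA sub-schema; need keys "
            "'sequence', 'structure' and 'positions'"
        )
    seqtext = obj["sequence"]
    pairs = parse_dotbracket_string(obj["structure"], origin=str(path))
    coords = obj["positions"]
    if len(coords) != len(seqtext):
        raise FormatError(f"{path}: {len(coords)} positions for {len(seqtext)} nt")
    return _build(path, obj.get("name", Path(path).stem), list(seqtext), coords, pairs)


def read_r2dt(path) -> SecondaryStructure:
    """R2DT layout JSON (rnaComplexes -> rnaMolecules -> sequence/basePairs)."""
    obj = _load_json(path)
    try:
        mol = obj["rnaComplexes"][0]["rnaMolecules"][0]
        residues = mol["sequence"]
    except (KeyError, IndexError, TypeError):
        raise FormatError(
            f"{path}: unsupported R2DT sub-schema; only the nucleotide-"
            "coordinate layout (rnaComplexes/rnaMolecules) is supported"
        ) from None
    residues = sorted(residues, key=lambda r: int(r["residueIndex"]))
    bases = [r["residueName"] for r in residues]
    coords = [(float(r["x"]), float(r["y"])) for r in residues]
    pairs = [
        (int(bp["residueIndex1"]), int(bp["residueIndex2"]))
        for bp in mol.get("basePairs", [])
    ]
    return _build(path, mol.get("name", Path(path).stem), bases, coords, pairs)


def read_nsd(path) -> SecondaryStructure:
    """StructureEditor NSD text: 'Nucleotide' and 'Pair' records.

    Nucleotide lines are 'index base x y'; pair lines are 'i j'; section
    headers 'Nucleotides' / 'Pairs' switch record type.
    """
    lines = open_text(path)
    section = None
    entries: dict[int, tuple[str, float, float]] = {}
    pairs: list[tuple[int, int]] = []
    title = Path(path).stem
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        low = line.lower()
        if low.startswith("name:"):
            title = line.split(":", 1)[1].strip()
        elif low.startswith("nucleotides"):
            section = "nuc"
        elif low.startswith("pairs"):
            section = "pair"
        elif section == "nuc":
            cols = line.split()
            if len(cols) < 4:
                raise FormatError(
                    f"{path}, line {lineno}: nucleotide lines need 'index base x y'"
                )
            entries[int(cols[0])] = (cols[1], float(cols[2]), float(cols[3]))
        elif section == "pair":
            cols = line.split()
            if len(cols) < 2:
                raise FormatError(f"{path}, line {lineno}: pair lines need 'i j'")
            pairs.append((int(cols[0]), int(cols[1])))
        else:
            raise FormatError(f"{path}, line {lineno}: data before a section header")
    order = sorted(entries)
    if order != list(range(1, len(order) + 1)):
        raise FormatError(f"{path}: nucleotide indices are not contiguous from 1")
    bases = [entries[k][0] for k in order]
    coords = [(entries[k][1], entries[k][2]) for k in order]
    return _build(path, title, bases, coords, pairs)


def _load_json(path):
    try:
        return json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: JSON parse failure: {exc}") from None


# writers used by the fixture generator (one per dialect, inverse of the readers)

def write_varna(ss: SecondaryStructure, path) -> None:
    root = etree.Element("RNA", name=ss.sequence.id)
    for k, base in enumerate(ss.sequence.residues, 1):
        x, y = ss.drawing[k - 1]
        etree.SubElement(root, "nt", num=str(k), base=base, x=f"{x:.3f}", y=f"{y:.3f}")
    for i, j in sorted(ss.pairs):
        etree.SubElement(root, "basepair", i=str(i), j=str(j))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def write_xrna(ss: SecondaryStructure, path) -> None:
    root = etree.Element("ComplexDocument")
    mol = etree.SubElement(etree.SubElement(root, "Complex"), "RNAMolecule",
                           name=ss.sequence.id)
    nl = etree.SubElement(mol, "NucListData", StartNucID="1")
    nl.text = "\n" + "\n".join(
        f"{b} {x:.3f} {y:.3f}"
        for b, (x, y) in zip(ss.sequence.residues, ss.drawing)
    ) + "\n"
    for i, j in sorted(ss.pairs):
        etree.SubElement(mol, "BasePairs", nucID=str(i), length="1", bpNucID=str(j))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def write_forna(ss: SecondaryStructure, path) -> None:
    from .structure import pairs_to_dotbracket

    obj = {
        "name": ss.sequence.id,
        "sequence": ss.sequence.residues,
        "structure": pairs_to_dotbracket(ss.pairs, ss.sequence.length),
        "positions": [[round(x, 3), round(y, 3)] for x, y in ss.drawing],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def write_r2dt(ss: SecondaryStructure, path) -> None:
    residues = [
        {"residueIndex": k, "residueName": b,
         "x": round(float(x), 3), "y": round(float(y), 3)}
        for k, (b, (x, y)) in enumerate(zip(ss.sequence.residues, ss.drawing), 1)
    ]
    bps = [
        {"residueIndex1": i, "residueIndex2": j} for i, j in sorted(ss.pairs)
    ]
    obj = {"rnaComplexes": [{"rnaMolecules": [
        {"name": ss.sequence.id, "sequence": residues, "basePairs": bps}
    ]}]}
    Path(path).write_text(json.dumps(obj, indent=1))


def write_nsd(ss: SecondaryStructure, path) -> None:
    lines = [f"name: {ss.sequence.id}", "Nucleotides"]
    for k, b in enumerate(ss.sequence.residues, 1):
        x, y = ss.drawing[k - 1]
        lines.append(f"{k} {b} {x:.3f} {y:.3f}")
    lines.append("Pairs")
    lines += [f"{i} {j}" for i, j in sorted(ss.pairs)]
    Path(path).write_text("\n".join(lines) + "\n")
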