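"""Tertiary-structure input (PDB and mmCIF) via gemmi.

The first model is used.  Nucleic-acid residues are grouped by residue
number; for alternate locations the first altloc encountered is kept.
``seq_map`` translates residue numbers to 1-based transcript positions via
a caller-adjustable offset (transcript position = residue number + offset).
"""

from __future__ import annotations

from pathlib import Path

import gemmi

from ..containers import SequenceRecord, TertiaryStructure
from ..errors import FormatError

_NUC_NAMES = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
}


def read_tertiary(path, tag: str = "pdb", chain: str | None = None,
                  offset: int = 0) -> TertiaryStructure:
    """Read a PDB/mmCIF file into a TertiaryStructure.

    ``chain`` selects a chain id (default: first chain containing nucleic
    residues); a missing requested chain raises listing the available ones.
    """
    if tag not in ("pdb", "cif"):
        raise FormatError(f"unknown tertiary tag {tag!r}; use 'pdb' or 'cif'")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure file: {exc}") from None
    if len(structure) == 0:
        raise FormatError(f"{path}: no models in structure file")
    model = structure[0]
    chains = {}
    for ch in model:
        residues = {}
        names = {}
        for res in ch:
            name = res.name.strip().upper()
            if name not in _NUC_NAMES:
                continue
            resnum = res.seqid.num
            atoms = residues.setdefault(resnum, {})
            names[resnum] = _NUC_NAMES[name]
            for atom in res:
                aname = atom.name.strip()
                if aname not in atoms:  # first altloc wins
                    atoms[aname] = (atom.pos.x, atom.pos.y, atom.pos.z)
        if residues:
            chains[ch.name] = (residues, names)
    if not chains:
        raise FormatError(
            f"{path}: no nucleic-acid chains found "
            f"(chains present: {[ch.name for ch in model]})"
        )
    if chain is None:
        chain = next(iter(chains))
    elif chain not in chains:
        raise FormatError(
            f"{path}: chain {chain!r} absent; nucleic chains: {sorted(chains)}"
        )
    residues, names = chains[chain]
    resnums = sorted(residues)
    seq_map = {rn: rn + offset for rn in resnums if rn + offset >= 1}
    n = max(seq_map.values())
    bases = ["N"] * n
    for rn, pos in seq_map.items():
        bases[pos - 1] = names[rn]
    seq = SequenceRecord(id=f"{Path(path).stem}:{chain}", residues="".join(bases))
    return TertiaryStructure(
        sequence=seq,
        chain_id=chain,
        residues={rn: residues[rn] for rn in seq_map},
        residue_names={rn: names[rn] for rn in seq_map},
        seq_map=seq_map,
    )
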