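"""Format and plot-kind registries.

The input registry maps each of the 21 supported format tags to a
description, the data class it produces, and its reader.  The plot
registry declares, for each of the 18 plot kinds, which data classes a
sample must hold for the kind to be renderable; ``plot_options`` checks a
sample's store against those requirements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Optional

from .containers import (
    Annotation,
    InteractionSet,
    Profile,
    Sample,
    SecondaryStructure,
    SequenceRecord,
    TertiaryStructure,
)
from .errors import RegistryError
from . import io as _io


@dataclass(frozen=True)
class InputFormat:
    tag: str
    description: str
    produces: type
    reader: Callable


def _seq_reader(tag):
    def read(path, sequence=None, **kw):
        return _io.read_sequence(path, **kw)
    return read


def _ss_reader(tag):
    def read(path, sequence=None, **kw):
        return _io.read_secondary_structure(path, tag=tag, **kw)
    return read


def _profile_reader(tag):
    def read(path, sequence=None, **kw):
        return _io.read_profile(path, tag=tag, sequence=sequence, **kw)
    return read


def _inter_reader(tag):
    def read(path, sequence=None, **kw):
        return _io.read_interactions(path, tag=tag, sequence=sequence, **kw)
    return read


def _tertiary_reader(tag):
    def read(path, sequence=None, **kw):
        return _io.read_tertiary(path, tag=tag, **kw)
    return read


def _annot_reader(tag):
    def read(path, sequence=None, **kw):
        return _io.read_annotations(path, tag=tag, sequence=sequence, **kw)
    return read


_FORMAT_ROSTER: list[tuple[str, str, type, Callable]] = [
    ("fasta", "primary sequence (FASTA, wrapped/decorated tolerated)",
     SequenceRecord, _seq_reader("fasta")),
    ("ct", "connectivity-table secondary structure (RNAstructure flavour)",
     SecondaryStructure, _ss_reader("ct")),
    ("dotbracket", "dot-bracket secondary structure, multi-layer pseudoknots",
     SecondaryStructure, _ss_reader("dotbracket")),
    ("varna", "VARNA drawing XML (sequence, pairs, 2D coordinates)",
     SecondaryStructure, _ss_reader("varna")),
    ("xrna", "XRNA drawing document (NucListData + BasePairs helices)",
     SecondaryStructure, _ss_reader("xrna")),
    ("forna", "FORNA layout JSON (sequence, dot-bracket, positions)",
     SecondaryStructure, _ss_reader("forna")),
    ("r2dt", "R2DT layout JSON (rnaComplexes nucleotide-coordinate schema)",
     SecondaryStructure, _ss_reader("r2dt")),
    ("nsd", "StructureEditor NSD drawing text",
     SecondaryStructure, _ss_reader("nsd")),
    ("pdb", "PDB tertiary structure (first model, nucleic chains)",
     TertiaryStructure, _tertiary_reader("pdb")),
    ("cif", "mmCIF tertiary structure (first model, nucleic chains)",
     TertiaryStructure, _tertiary_reader("cif")),
    ("shapemapper-profile", "per-nucleotide reactivity profile table "
     "(Nucleotide/Sequence/Norm_profile/Norm_stderr)",
     Profile, _profile_reader("shapemapper-profile")),
    ("map", "4-column position/value/stderr/base reactivity table",
     Profile, _profile_reader("map")),
    ("shape", "2-column position/value reactivity table",
     Profile, _profile_reader("shape")),
    ("rnaframework-xml", "RNA-Framework-style transcript reactivity XML",
     Profile, _profile_reader("rnaframework-xml")),
    ("ring", "correlated-modification (RING) table with named statistics",
     InteractionSet, _inter_reader("ring")),
    ("pair", "base-pairing smCCP (PAIR) table with primary/secondary classes",
     InteractionSet, _inter_reader("pair")),
    ("dance-reactivities", "ensemble-deconvolution per-state reactivities",
     Profile, _profile_reader("dance-reactivities")),
    ("pairprob-dp", "pairing-probability dotplot text (i, j, -log10 p)",
     InteractionSet, _inter_reader("pairprob-dp")),
    ("bed-narrowpeak", "BED / narrowPeak region annotations (0-based half-open)",
     Annotation, _annot_reader("bed-narrowpeak")),
    ("wig", "WIG per-nucleotide track (fixedStep and variableStep)",
     Profile, _profile_reader("wig")),
    ("gff-gtf", "GFF3 / GTF feature annotations",
     Annotation, _annot_reader("gff-gtf")),
]

INPUT_FORMATS: dict[str, InputFormat] = {
    tag: InputFormat(tag, desc, produces, reader)
    for tag, desc, produces, reader in _FORMAT_ROSTER
}


def list_input_formats() -> dict[str, str]:
    """Stable-ordered mapping of format tag -> description."""
    return {tag: fmt.description for tag, fmt in INPUT_FORMATS.items()}


# ---------------------------------------------------------------------------
# plot-kind registry: each kind declares data-class requirements as a list of
# (acceptable classes, count) items, all of which must be satisfiable from a
# sample's store.

_REQ = tuple[tuple[type, ...], int]

PLOT_KINDS: dict[str, dict[str, Any]] = {
    "profile-bars": {
        "description": "coloured per-nucleotide bar graph of one profile",
        "requires": [((Profile,), 1)],
    },
    "skyline": {
        "description": "stepped-line per-nucleotide graph for comparing profiles",
        "requires": [((Profile,), 1)],
    },
    "arcs": {
        "description": "interactions/base pairs as semicircles over the sequence",
        "requires": [((SecondaryStructure, InteractionSet), 1)],
    },
    "arcs-compare": {
        "description": "two arc tracks (above/below axis) for model comparison",
        "requires": [((SecondaryStructure, InteractionSet), 2)],
    },
    "circle": {
        "description": "nucleotides on a circle, interactions as chords",
        "requires": [((SecondaryStructure, InteractionSet), 1)],
    },
    "ss-diagram": {
        "description": "secondary-structure diagram using drawing coordinates",
        "requires": [((SecondaryStructure,), 1)],
    },
    "molecule": {
        "description": "3D backbone projection with interaction cylinders",
        "requires": [((TertiaryStructure,), 1)],
    },
    "heatmap-density": {
        "description": "2D density heatmap of interaction record positions",
        "requires": [((InteractionSet,), 1)],
    },
    "contour": {
        "description": "smoothed contour plot of interaction density",
        "requires": [((InteractionSet,), 1)],
    },
    "distance-histogram": {
        "description": "3D contact distances of interactions vs background",
        "requires": [((InteractionSet,), 1), ((TertiaryStructure,), 1)],
    },
    "regression-kde": {
        "description": "profile-vs-profile KDE with linear regression",
        "requires": [((Profile,), 2)],
    },
    "windowed-auroc": {
        "description": "windowed AUROC of a profile against a structure model",
        "requires": [((Profile,), 1), ((SecondaryStructure,), 1)],
    },
    "deltashape-panel": {
        "description": "smoothed reactivity difference with detected sites",
        "requires": [((Profile,), 2)],
    },
    "lowss-panel": {
        "description": "stacked windowed reactivity/entropy with structure arcs",
        "requires": [((Profile,), 1), ((InteractionSet,), 1),
                     ((SecondaryStructure,), 1)],
    },
    "alignment-overview": {
        "description": "per-position mapped/unmapped track between two sequences",
        "requires": [((SequenceRecord, Profile, SecondaryStructure,
                       InteractionSet, TertiaryStructure), 2)],
    },
    "annotation-track": {
        "description": "annotated regions/sites along the sequence axis",
        "requires": [((Annotation,), 1)],
    },
    "consensus-summary": {
        "description": "pie chart of base-pair support across models",
        "requires": [((SecondaryStructure,), 2)],
    },
    "profile-difference": {
        "description": "per-nucleotide difference bars between two profiles",
        "requires": [((Profile,), 2)],
    },
}


def list_plot_kinds() -> dict[str, str]:
    """Stable-ordered mapping of plot kind -> description."""
    return {kind: spec["description"] for kind, spec in PLOT_KINDS.items()}


def _store_objects(sample: Sample) -> list[Any]:
    objs = []
    for value in sample.store.values():
        if isinstance(value, list):
            objs.extend(value)
        else:
            objs.append(value)
    return objs


def requirements_met(sample: Sample, kind: str) -> bool:
    if kind not in PLOT_KINDS:
        raise RegistryError(
            f"unknown plot kind {kind!r}; valid kinds: {sorted(PLOT_KINDS)}"
        )
    objs = _store_objects(sample)
    used = [False] * len(objs)
    for classes, count in PLOT_KINDS[kind]["requires"]:
        need = count
        for idx, obj in enumerate(objs):
            if need == 0:
                break
            if not used[idx] and isinstance(obj, classes):
                used[idx] = True
                need -= 1
        if need > 0:
            return False
    return True


def plot_options(sample: Sample) -> list[str]:
    """Plot kinds renderable from this sample's store (sorted, unique)."""
    return sorted(k for k in PLOT_KINDS if requirements_met(sample, k))


#: formats whose files do not embed the transcript sequence and therefore
#: need one supplied (directly or from another object in the same sample)
NEEDS_SEQUENCE = {"shape", "wig", "ring", "pair", "pairprob-dp",
                  "bed-narrowpeak", "gff-gtf"}


def create_sample(label: str, inputs: Optional[dict] = None,
                  sequence: Optional[SequenceRecord] = None) -> Sample:
    """Build a Sample by parsing ``keyword -> (path, format-tag)`` inputs.

    Formats that carry no sequence of their own (shape, wig, ring, pair,
    pairprob-dp, bed-narrowpeak, gff-gtf) are parsed against ``sequence``
    if given, otherwise against the first sequence-bearing object in the
    sample; sequence-carrying inputs are parsed first so the keyword order
    does not matter.
    """
    sample = Sample(label)
    if not inputs:
        return sample
    for keyword, entry in inputs.items():
        if entry[1] not in INPUT_FORMATS:
            raise RegistryError(
                f"unknown format tag {entry[1]!r} for keyword {keyword!r}; "
                f"valid tags: {sorted(INPUT_FORMATS)}"
            )
    ordered = sorted(inputs.items(), key=lambda kv: kv[1][1] in NEEDS_SEQUENCE)
    parsed: dict[str, Any] = {}
    for keyword, entry in ordered:
        path, tag = entry[0], entry[1]
        kwargs = entry[2] if len(entry) > 2 else {}
        seq = sequence
        if seq is None:
            for obj in parsed.values():
                for o in (obj if isinstance(obj, list) else [obj]):
                    anchor = getattr(o, "sequence", o)
                    if isinstance(anchor, SequenceRecord):
                        seq = anchor
                        break
                if seq is not None:
                    break
        parsed[keyword] = INPUT_FORMATS[tag].reader(path, sequence=seq, **kwargs)
    for keyword in inputs:  # preserve the caller's keyword order
        sample.add(keyword, parsed[keyword])
    return sample
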