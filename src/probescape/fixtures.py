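"""Deterministic synthetic toy-RNA dataset in every supported format.

The generator builds one coherent truth — a sequence, a nested secondary
structure of tandem hairpins plus one pseudoknot, an idealized helical 3D
model, and per-/internucleotide measurements statistically tied to that
structure — and serializes it in all 21 roster formats, so the whole
package builds and tests without downloading anything.

Reactivity model: paired nucleotides draw from a low-mean distribution
(normal, mean 0.15, sd 0.10) and unpaired nucleotides from a high-mean one
(mean 0.90, sd 0.40), both clipped at 0.  The distributions overlap, so a
profile separates pairing classes well (windowed AUROC clearly above 0.5)
but not perfectly, mirroring the contrast real probing data shows without
claiming realism.  Pairing probabilities concentrate on the true pairs
(0.95 inside helices, 0.70 at helix ends, with weak 0.10 alternatives
registered at helix ends), so Shannon entropy is low inside helices and
higher at their ends.  RING records cluster near the pseudoknot (the
designed tertiary contact) over a random background; PAIR records sit on
true helices (primary) and one-off-register neighbours (secondary).

Same seed, same bytes: every file is formatted with fixed precision from a
single seeded generator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    InteractionSet,
    Profile,
    SecondaryStructure,
    SequenceRecord,
)
from .errors import AnalysisError
from .io import drawing as _drawing
from .io.interactions import write_pairprob_dp
from .io.sequence import write_fasta
from .io.structure import write_ct, write_dotbracket

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class FixtureSpec:
    seed: int = 1
    n: int = 120
    pseudoknot: bool = True
    paired_mean: float = 0.15
    paired_sd: float = 0.10
    unpaired_mean: float = 0.90
    unpaired_sd: float = 0.40
    stem: int = 6
    loop: int = 4
    linker: int = 5

    def __post_init__(self) -> None:
        if self.n < 20:
            raise AnalysisError(f"fixture needs n >= 20, got {self.n}")


def _truth_structure(spec: FixtureSpec, rng: np.random.Generator):
    """Tile hairpins along the sequence; return (residues, pairs, pk_pairs)."""
    n = spec.n
    unit = 2 * spec.stem + spec.loop + spec.linker
    residues = ["N"] * n
    pairs: set[tuple[int, int]] = set()
    hairpins = []
    cursor = 3  # short 5' tail
    while cursor + 2 * spec.stem + spec.loop <= n - 3:
        a = cursor + 1
        close = a + 2 * spec.stem + spec.loop - 1
        for k in range(spec.stem):
            pairs.add((a + k, close - k))
        hairpins.append((a, close))
        cursor = close + spec.linker
    unpaired_alphabet = np.array(list("AACGU"))
    paired_positions = {p for pair in pairs for p in pair}
    for pos in range(1, n + 1):
        if pos not in paired_positions:
            residues[pos - 1] = str(rng.choice(unpaired_alphabet))
    bases = np.array(list("ACGU"))
    for i, j in sorted(pairs):
        b = str(rng.choice(bases))
        residues[i - 1] = b
        residues[j - 1] = _COMP[b]
    # pseudoknot: two pairs from the first hairpin loop into its 3' linker
    pk_pairs: set[tuple[int, int]] = set()
    if spec.pseudoknot and len(hairpins) >= 2:
        a, close = hairpins[0]
        loop_start = a + spec.stem
        linker_start = close + 1
        for k in range(2):
            i, j = loop_start + k, linker_start + 1 + k
            if j < hairpins[1][0]:
                b = str(rng.choice(bases))
                residues[i - 1] = b
                residues[j - 1] = _COMP[b]
                pk_pairs.add((i, j))
    return "".join(residues), pairs, pk_pairs, hairpins


def _helical_coords(n: int):
    """Idealized A-form-like helix: 11 nt/turn, 2.8 A rise, 10 A radius."""
    k = np.arange(n)
    theta = 2 * np.pi * k / 11.0
    o2 = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), 2.8 * k])
    c1 = np.column_stack([11 * np.cos(theta), 11 * np.sin(theta), 2.8 * k + 0.5])
    p = np.column_stack([12 * np.cos(theta + 0.2), 12 * np.sin(theta + 0.2),
                         2.8 * k + 1.2])
    return o2, c1, p


def _circle_layout(n: int) -> np.ndarray:
    k = np.arange(1, n + 1)
    r = n / (2 * np.pi)
    theta = 2 * np.pi * k / n
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


class FixtureTruth:
    """In-memory ground truth behind a generated fixture directory."""

    def __init__(self, spec: FixtureSpec) -> None:
        rng = np.random.default_rng(spec.seed)
        residues, pairs, pk_pairs, hairpins = _truth_structure(spec, rng)
        self.spec = spec
        self.sequence = SequenceRecord(id="toyRNA", residues=residues)
        self.pairs = pairs
        self.pk_pairs = pk_pairs
        self.hairpins = hairpins
        n = spec.n
        paired = np.zeros(n, dtype=bool)
        for i, j in pairs | pk_pairs:
            paired[i - 1] = paired[j - 1] = True
        self.paired = paired
        react = np.where(
            paired,
            rng.normal(spec.paired_mean, spec.paired_sd, n),
            rng.normal(spec.unpaired_mean, spec.unpaired_sd, n),
        ).clip(0)
        self.reactivity = react
        self.stderr = 0.04 + 0.08 * react * np.abs(rng.normal(1, 0.2, n))
        self.nodata = np.zeros(n, dtype=bool)
        self.nodata[:2] = True  # primer-masked 5' end
        self.nodata[-2:] = True
        self.conservation = np.clip(rng.beta(5, 2, n), 0, 1)
        # pairing probabilities concentrated on the truth
        rows = []
        for i, j in sorted(pairs):
            helix_end = not (
                any((i - 1, j + 1) == q for q in pairs)
                and any((i + 1, j - 1) == q for q in pairs)
            )
            rows.append((i, j, 0.70 if helix_end else 0.95))
            if helix_end and j - 1 > i + 1:
                rows.append((i + 1, j + 1, 0.10) if (i + 1, j + 1) not in pairs
                            else (i, j, 0.10))
        seen = set()
        uniq = []
        for i, j, p in rows:
            if (i, j) not in seen and j <= n:
                uniq.append((i, j, p))
                seen.add((i, j))
        self.pairprob_rows = uniq
        # RINGs: signal near the pseudoknot, noise elsewhere
        ring_rows = []
        for i, j in sorted(pk_pairs):
            for di in (-1, 0, 1):
                ring_rows.append((i + di, j + di,
                                  float(rng.normal(5, 1)), float(rng.normal(4, 1))))
        for _ in range(15):
            i = int(rng.integers(1, n - 10))
            j = int(rng.integers(i + 5, n + 1))
            ring_rows.append((i, j, float(rng.normal(0, 1)), float(rng.normal(0, 1))))
        self.ring_rows = [(i, j, s, z) for i, j, s, z in ring_rows if 1 <= i < j <= n]
        # PAIRs: primary on true helix middles, secondary one register off
        pair_rows = []
        for a, close in hairpins:
            mid = spec.stem // 2
            i, j = a + mid, close - mid
            pair_rows.append((i, j, 1))
            pair_rows.append((i - 1, j + 1, 2))
        self.pair_rows = [(i, j, c) for i, j, c in pair_rows if 1 <= i < j <= n]
        self.o2, self.c1, self.p = _helical_coords(n)
        self.drawing = _circle_layout(n)
        # a second condition for two-profile analyses: same truth, new noise,
        # plus a genuine reactivity gain over one linker (a binding footprint)
        react_b = np.where(
            paired,
            rng.normal(spec.paired_mean, spec.paired_sd, n),
            rng.normal(spec.unpaired_mean, spec.unpaired_sd, n),
        ).clip(0)
        if hairpins:
            close = hairpins[0][1]
            lo, hi = close + 1, min(close + spec.linker, n)
            react_b[lo - 1 : hi] += 1.5
        self.reactivity_b = react_b

    def secondary_structure(self, with_pk: bool = True,
                            with_drawing: bool = False) -> SecondaryStructure:
        pairs = self.pairs | (self.pk_pairs if with_pk else set())
        return SecondaryStructure(
            sequence=self.sequence, pairs=set(pairs),
            drawing=self.drawing.copy() if with_drawing else None)

    def profile(self) -> Profile:
        values = np.where(self.nodata, np.nan, self.reactivity)
        return Profile(self.sequence, values, stderr=self.stderr,
                       nodata=self.nodata.copy())

    def profile_b(self) -> Profile:
        values = np.where(self.nodata, np.nan, self.reactivity_b)
        return Profile(self.sequence, values, stderr=self.stderr,
                       nodata=self.nodata.copy())

    def pairing_probabilities(self) -> InteractionSet:
        df = pd.DataFrame(self.pairprob_rows, columns=["i", "j", "probability"])
        return InteractionSet(self.sequence, df, default_metric="probability")


def _fmt(v: float) -> str:
    return "-999" if not np.isfinite(v) else f"{v:.6f}"


def generate_fixture(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Write the toy dataset in all 21 formats; returns a manifest
    (format tag -> file name) and writes manifest.json with checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = FixtureTruth(spec)
    seq = truth.sequence
    n = spec.n
    manifest: dict[str, str] = {}

    def note(tag: str, name: str) -> Path:
        manifest[tag] = name
        return outdir / name

    write_fasta(seq, note("fasta", "toy.fa"))
    ss = truth.secondary_structure(with_pk=True, with_drawing=True)
    write_ct(ss, note("ct", "toy.ct"))
    write_dotbracket(ss, note("dotbracket", "toy.db"))
    _drawing.write_varna(ss, note("varna", "toy.varna"))
    _drawing.write_xrna(ss, note("xrna", "toy.xrna"))
    _drawing.write_forna(ss, note("forna", "toy_forna.json"))
    _drawing.write_r2dt(ss, note("r2dt", "toy_r2dt.json"))
    _drawing.write_nsd(ss, note("nsd", "toy.nsd"))

    # tertiary structure: PDB and mmCIF with O2'/C1'/P per residue
    pdb_lines = []
    serial = 0
    for k in range(n):
        for aname, xyz in (("O2'", truth.o2[k]), ("C1'", truth.c1[k]),
                           ("P", truth.p[k])):
            serial += 1
            name4 = aname if len(aname) == 4 else f" {aname:<3s}"
            pdb_lines.append(
                f"ATOM  {serial:5d} {name4} {seq.residues[k]:>3s} A{k + 1:4d}"
                f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           {aname[0]}"
            )
    pdb_lines.append("END")
    note("pdb", "toy.pdb").write_text("\n".join(pdb_lines) + "\n")
    import gemmi

    st = gemmi.read_structure(str(outdir / "toy.pdb"))
    st.name = "toy"
    st.setup_entities()
    st.make_mmcif_document().write_file(str(note("cif", "toy.cif")))

    # per-nucleotide tables
    vals = np.where(truth.nodata, np.nan, truth.reactivity)
    rows = ["Nucleotide\tSequence\tNorm_profile\tNorm_stderr"]
    rows += [
        f"{k + 1}\t{seq.residues[k]}\t{_fmt(vals[k])}\t{_fmt(truth.stderr[k])}"
        for k in range(n)
    ]
    note("shapemapper-profile", "toy_profile.txt").write_text("\n".join(rows) + "\n")
    rows = [
        f"{k + 1}\t{_fmt(vals[k])}\t{_fmt(truth.stderr[k])}\t{seq.residues[k]}"
        for k in range(n)
    ]
    note("map", "toy.map").write_text("\n".join(rows) + "\n")
    rows = [f"{k + 1}\t{_fmt(vals[k])}" for k in range(n)]
    note("shape", "toy.shape").write_text("\n".join(rows) + "\n")
    react_csv = ",".join(_fmt(v) if np.isfinite(v) else "NaN" for v in vals)
    err_csv = ",".join(_fmt(e) for e in truth.stderr)
    note("rnaframework-xml", "toy_rf.xml").write_text(
        "<data>\n"
        f'<transcript id="{seq.id}" length="{n}">\n'
        f"<sequence>\n{seq.residues}\n</sequence>\n"
        f"<reactivity>\n{react_csv}\n</reactivity>\n"
        f"<error>\n{err_csv}\n</error>\n"
        "</transcript>\n</data>\n"
    )
    vals_b = np.where(truth.nodata, np.nan, truth.reactivity_b)
    rows = ["2", "0.600000 0.400000", "Position\tSequence\tstate0\tstate1"]
    rows += [
        f"{k + 1}\t{seq.residues[k]}\t{_fmt(vals[k])}\t{_fmt(vals_b[k])}"
        for k in range(n)
    ]
    note("dance-reactivities", "toy_dance.txt").write_text("\n".join(rows) + "\n")
    wig = ["track type=wiggle_0 name=conservation", "fixedStep chrom=toyRNA start=1 step=1"]
    wig += [f"{v:.4f}" for v in truth.conservation]
    note("wig", "toy.wig").write_text("\n".join(wig) + "\n")

    # internucleotide tables
    rows = ["i\tj\tstatistic\tzscore"]
    rows += [f"{i}\t{j}\t{s:.4f}\t{z:.4f}" for i, j, s, z in truth.ring_rows]
    note("ring", "toy.ring").write_text("\n".join(rows) + "\n")
    rows = ["i\tj\tClass"]
    rows += [f"{i}\t{j}\t{c}" for i, j, c in truth.pair_rows]
    note("pair", "toy.pair").write_text("\n".join(rows) + "\n")
    write_pairprob_dp(truth.pairing_probabilities(), note("pairprob-dp", "toy.dp"))

    # annotations on the transcript
    bed = []
    if truth.hairpins:
        a, close = truth.hairpins[0]
        bed.append(f"toyRNA\t{a - 1}\t{close}\thairpin1\t100\t+")
        loop_start = a + spec.stem
        bed.append(
            f"toyRNA\t{loop_start - 1}\t{loop_start + spec.loop - 1}\tloop1\t"
            "200\t+\t5.0\t3.0\t2.0\t1"
        )
    note("bed-narrowpeak", "toy.bed").write_text("\n".join(bed) + "\n")

    # a 2-exon parent gene: intron inserted mid-transcript
    split = n // 2
    intron = "GU" + "A" * 16 + "AG"
    genome = seq.residues[:split] + intron + seq.residues[split:]
    write_fasta(SequenceRecord(id="toygenome", residues=genome),
                outdir / "toy_genome.fa")
    manifest["genome-fasta"] = "toy_genome.fa"
    e1s, e1e = 1, split
    e2s, e2e = split + len(intron) + 1, n + len(intron)
    gff = [
        "##gff-version 3",
        f"toygenome\tfixture\tgene\t{e1s}\t{e2e}\t.\t+\t.\tID=gene1",
        f"toygenome\tfixture\tmRNA\t{e1s}\t{e2e}\t.\t+\t.\tID=tx1;Parent=gene1",
        f"toygenome\tfixture\texon\t{e1s}\t{e1e}\t.\t+\t.\tID=exon1;Parent=tx1",
        f"toygenome\tfixture\texon\t{e2s}\t{e2e}\t.\t+\t.\tID=exon2;Parent=tx1",
        f"toygenome\tfixture\tCDS\t10\t{e1e}\t.\t+\t0\tID=cds1;Parent=tx1",
        f"toygenome\tfixture\tCDS\t{e2s}\t{e2e - 10}\t.\t+\t0\tID=cds1;Parent=tx1",
    ]
    note("gff-gtf", "toy.gff").write_text("\n".join(gff) + "\n")

    checksums = {
        tag: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        for tag, name in manifest.items()
    }
    (outdir / "manifest.json").write_text(json.dumps(
        {"spec": {"seed": spec.seed, "n": spec.n}, "files": manifest,
         "sha256": checksums}, indent=1))
    return manifest
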