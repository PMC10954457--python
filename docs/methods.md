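# Methods

This note documents the models, conventions and numerical choices behind
`probescape`, in the spirit of the methods documentation that accompanies
mature scientific Python packages.

## Coordinates, sequences and identity

All positions are 1-based inclusive.  The single exception is BED /
narrowPeak input, whose 0-based half-open spans are converted on read
(start+1); connectivity tables, probing tables and GFF are natively
1-based.  Sequence identity is case-insensitive and treats T and U as
equal, because probing pipelines routinely mix DNA-alphabet references
with RNA-alphabet outputs.  Every data object carries its own sequence;
objects from different constructs are reconciled explicitly through
position mapping, never silently.

## Input formats

One reader exists per roster tag; writers exist for CT and dot-bracket.
Points worth knowing:

- **FASTA** is read tolerantly: anything that is not a letter is stripped
  from sequence lines, so wrapped, numbered or space-decorated records
  parse to the intended sequence.  Binary content is rejected.
- **CT** follows the RNAstructure flavour (count + title header, six
  columns).  Partner reciprocity is enforced: if row *i* claims partner
  *j*, row *j* must claim *i*, otherwise the file is corrupt and parsing
  stops with an integrity error rather than guessing.
- **Dot-bracket** supports the bracket families `()`, `[]`, `{}`, `<>` and
  uppercase/lowercase letter layers, each matched with its own stack.  The
  writer colours the pair-crossing graph greedily (pairs taken 5′→3′, each
  assigned to the lowest non-crossing family); more than four mutually
  crossing layers exceed the bracket alphabet and raise.
- **Drawing dialects** (VARNA, XRNA, FORNA, R2DT, NSD) are parsed for
  sequence, pairs and per-nucleotide (x, y) only; fonts and colours are
  ignored because the data model needs geometry, nothing else.  For the
  JSON dialects only the nucleotide-coordinate layout sub-schema is
  accepted; other sub-schemas are rejected with a message naming the
  supported one.  XRNA helices (`nucID`, `length`, `bpNucID`) expand to
  (i+k, j−k) runs.
- **Profile tables**: the −999 sentinel and non-numeric entries become
  no-data, excluded from every downstream statistic.  Formats that embed
  the sequence (profile tables, map, transcript XML, ensemble
  reactivities) reconstruct it; formats that do not (shape, wig) require a
  caller-supplied sequence, and any length disagreement is an error naming
  both lengths.
- **Interaction tables** (RING/PAIR style) are whitespace-separated with a
  single header line; the first two columns are the nucleotide indices and
  every further column is kept as a named statistic, so new correlation
  metrics pass through without code changes.  Records with j ≤ i after
  normalization are dropped with a warning count.  Pairing-probability
  dotplot rows store −log10(p); probabilities are reconstructed as
  10^(−x) and must fall in (0, 1].
- **PDB/mmCIF** go through gemmi.  The first model is used, residues are
  grouped by number, the first alternate location wins, and the
  residue-number → transcript-position map is injective with an
  adjustable offset.  Files without a nucleic-acid chain are rejected.
- **GFF3/GTF** attributes are parsed for both dialects.  Transcript
  extraction splices exons 5′→3′ (reverse-complementing minus-strand
  genes), emits exon-junction and CDS annotations in transcript
  coordinates, and returns the genome→transcript position map so genomic
  per-nucleotide tracks can be carried onto the transcript.
- Malformed trailing lines fail loudly everywhere: probing files are
  machine-generated, so corruption means an upstream failure that should
  not be truncated away silently.

## Position mapping

Cross-construct comparisons use global end-gap-free pairwise alignment
(Needleman–Wunsch, affine gaps) via Biopython's `PairwiseAligner`.
Defaults: match +1, mismatch −1, gap open −5, gap extend −1, terminal gaps
free.  These favour the near-identical alignments typical of probing
comparisons, where constructs differ by primer trimming or point changes;
free end gaps avoid penalizing terminal truncations.  Aligned columns map
to each other whether matched or mismatched; gapped positions are
unmapped.  The map is strictly monotone, composable and invertible on its
image.  Identical sequences short-circuit to the identity map.  When
several alignments are co-optimal the aligner's first traceback is used,
which is deterministic across runs; the parameters are all overridable.

Data transfer semantics: profile values land on mapped positions and
unmapped targets become no-data (no interpolation — values are never
invented); annotation spans are clipped to their mapped extent; a base
pair survives only if both endpoints map; an interaction record with a
lost endpoint is kept but masked out, so record counts are stable across
mappings; drawing coordinates and 3D residue maps travel with their
nucleotides.

## Per-nucleotide analytics

**Normalization.**  `boxplot`: values above Q3 + 1.5·IQR are excluded as
outliers (capped at 10% of the data), and all values are divided by the
mean of the top 10% of what remains.  `percentile`: divide by the mean of
values between the 90th and 99th percentiles.  Both require at least 10
finite values.  Normalized reactivities are unitless, with conventional
colour breakpoints at 0.4 and 0.85 (low/mid/high).

**Windowed medians** use centred, odd-length windows (default 51 nt, the
standard smoothing scale for long-RNA analyses).  No-data positions are
excluded per window; an all-no-data window yields no-data.  Edge policy is
either `truncate` (windows shrink at the ends; the default) or `nodata`
(positions whose window would be incomplete are undefined).

**Shannon entropy** of pairing probabilities is
s_i = −Σ_j p_ij·log₁₀ p_ij over every recorded partner of i in either
orientation.  Log base 10 is the convention under which the 0.15 lowSS
threshold is meaningful.  The unpaired-probability term is deliberately
excluded: dotplot files record pairing probabilities only, so the sum runs
over what the file states.  Positions with no recorded partner have
entropy 0 — with pruned dotplots (which drop negligible probabilities)
this reads as "no appreciable pairing uncertainty", which is the intended
semantics for lowSS calling.

**lowSS regions.**  A position is *low* iff its windowed median reactivity
is strictly below `r_max` (default 0.4) *and* its windowed median entropy
is strictly below `s_max` (default 0.15).  Maximal runs of low positions
become regions numbered 5′→3′.  Region boundaries are reported at window
centers (the position whose window median crossed the threshold), not at
full-window extents.  `merge_gap` (default 0, i.e. no merging) optionally
fuses runs separated by fewer than that many nucleotides — merging is not
part of the base definition, so off is the least surprising default.

**Two-condition difference calling** follows the deltaSHAPE recipe:
values and standard errors of both profiles are smoothed over centred
5-nt windows; the smoothed difference d_i receives a Z-factor
1 − 1.96·(SEM_a + SEM_b)/|d_i| and a standard score from the distribution
of d; a position is a site when its Z-factor is positive, its |standard
score| ≥ 1, and at least 3 of the 5 surrounding positions also qualify.
All five constants are parameters.

**Windowed AUROC** computes, per centred window, the area under the ROC
curve of reactivity classifying unpaired (positive class) against paired
nucleotides, with ties credited ½ (the Mann–Whitney U equivalence, which
makes the statistic testable by exhaustive pair counting).  Windows
missing either class are undefined.

**Profile regression** is ordinary least squares plus Pearson r over
positions valid in both profiles (≥ 3 required); the paired-value table is
returned for kernel-density rendering.

## Interaction and structure-model analytics

Filter criteria — statistic bounds, correlation sign, confidence class,
region restriction, 3D contact-distance bounds and top-k by a statistic —
compose conjunctively, and the mask is recomputed from scratch on each
call, so filtering is idempotent and never destroys records.  Contact
distances are Euclidean distances between O2′ atoms (C1′ fallback), a
ribose-centric choice matching where probing adducts form; both atom names
are parameters.  Distance histograms compare masked-in records against the
background of all position pairs with j > i + 10 (the gap hides trivially
close backbone neighbours; adjustable).  Density heatmaps accumulate
masked-in records into square bins by integer division of the endpoint
positions; total mass always equals the filter pass count.

Pair-model classification is exact set algebra: correct = predicted ∩
accepted, incorrect = predicted − accepted, missing = accepted −
predicted; sensitivity = correct/(correct+missing), PPV =
correct/(correct+incorrect), undefined ratios reported as NaN.  An
optional ±1 slip tolerance exists but is off by default and for every
number this package reports.  Consensus tables count, over the union of
all models' pairs, how many models predict each pair; the
"shared-by-all" fraction uses the union as denominator, the only reading
under which a single percentage is well defined.

## Plotting

Eighteen plot kinds render through one entry point, each declaring which
data classes it needs; `plot_options` evaluates those requirements against
a sample.  Every renderer returns a layout report listing each drawn
element in data coordinates — tests assert on reports, never on pixels.
Geometry is closed-form: an arc for pair (i, j) is the semicircle with
center (i+j)/2 and radius (j−i)/2 (second dataset below the axis in
compare mode); a circle plot places nucleotide k of n at angle 2πk/n on
the unit circle; structure diagrams draw glyphs at the drawing
coordinates with aspect preserved.  Pairing-probability arcs are binned
into the community's discrete classes (≥ 0.8, 0.6–0.8, 0.3–0.6, 0.1–0.3;
lower probabilities are not drawn).  Colour assignment is a pure function
of (value, breakpoints).  3D rendering is a static x/y projection plus a
viewer-ready export (per-atom coordinates, per-nucleotide colour classes,
one cylinder per masked-in interaction whose endpoints are exactly the
contact-distance atoms); interactive widgets are out of scope.  Default
palettes are aesthetic choices and all overridable.

## Synthetic data generator

The generator builds one coherent ground truth and serializes it in all 21
formats, so the package installs, tests and demos offline.  The toy RNA
tiles hairpins (6-bp stems, 4-nt loops, 5-nt linkers) along the sequence
and adds a 2-pair pseudoknot from the first loop into the following
linker.  Reactivities: paired positions ~ N(0.15, 0.10), unpaired ~
N(0.90, 0.40), clipped at 0 — overlapping distributions, so profiles
separate pairing classes well (windowed AUROC ≈ 0.96–0.98 across seeds)
but not perfectly.  Standard errors grow with the value; the terminal two
positions at each end are no-data, mimicking primer masking.  Pairing
probabilities concentrate on true pairs (0.95 inside helices, 0.70 at
helix ends, weak 0.10 alternatives at the ends), so entropy is low inside
helices and higher at their boundaries.  RING records cluster around the
pseudoknot over a random background with sign-carrying statistics; PAIR
records mark helix middles (primary) and one-off-register neighbours
(secondary).  3D coordinates are an idealized helix (11 nt/turn, 2.8 Å
rise) with O2′/C1′/P atoms per residue, written as PDB and, through gemmi,
mmCIF.  A two-exon parent gene (intron inserted mid-transcript) exercises
the genomic route.  The same seed yields byte-identical files.

What the generator does **not** emulate: sequence-dependent probe
chemistry, read-depth-dependent error structure, long-range tertiary
contacts beyond the single pseudoknot, alternative conformations beyond a
perturbed second profile, or realistic dotplot density.  Passing tests
therefore demonstrate correctness of the machinery (parsing, statistics,
geometry, transfer), not biological realism of any particular dataset.

## Numerical and design notes

- Statistics exclude no-data positions everywhere; empty inputs return
  empty results or NaN rather than raising, except where a minimum sample
  size is part of the method's definition (normalization, regression).
- AUROC ties use average ranks (scipy `rankdata`); medians follow numpy
  semantics (mean of the two central values for even windows).
- Pair identity in comparisons is exact (i, j) equality by default.
- Density-heatmap bin index is `position // bin_size`.
- The test suite checks every statistic against an independent
  brute-force oracle on ~1000 random toy instances per statistic, and
  checks plot geometry against the closed forms; problem sizes (toy RNA of
  120 nt, oracle instances of ≤ 40 nt) were chosen so the whole suite runs
  in well under a minute while still exercising every code path.

## Known limitations

- Alignment-based mapping assumes globally colinear constructs; there is
  no local or multiple alignment, and rearranged sequences produce sparse
  maps rather than errors.
- Only the drawing sub-schemas described above are parsed; sessions
  from other tool versions may need conversion.
- Ensemble (multi-state) data are consumed per state; the package does not
  deconvolute ensembles itself.
- No thermodynamic folding, partition functions or raw-read processing;
  those belong to the upstream tools whose outputs this package consumes.
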