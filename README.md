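# probescape

Integrative exploration of RNA chemical-probing datasets.

Chemical probing experiments (SHAPE, DMS and related MaP protocols) report
per-nucleotide reactivities that track local nucleotide flexibility, and
single-molecule correlated probing adds internucleotide signals — PAIRs
(base-pairing signatures) and RINGs (through-space communication).
Interpreting any one of these layers usually requires the others: secondary
structure models, pairing probabilities, 3D coordinates, and annotations of
functional elements.  `probescape` is a Python library plus CLI that parses
the RNA community's standard file formats into five transcript-centric data
classes, reconciles data measured on slightly different sequences through
pairwise alignment, runs the field's standard automated analyses, and
renders the community's standard visualizations.

It is aimed at bench scientists and computational biologists who already
run upstream tools (ShapeMapper-style reactivity callers, RingMapper/
PairMapper-style correlation callers, RNAstructure/ViennaRNA folding) and
need to explore, compare and plot the results together.  It never refolds
RNA or reprocesses raw reads.

## Data model

Every input becomes one of five classes, each anchored to a sequence
(1-based coordinates; `T` and `U` compare equal everywhere):

| class               | holds                                            |
|---------------------|--------------------------------------------------|
| `Annotation`        | regions, sites, groups, primer-binding spans     |
| `SecondaryStructure`| base-pair set + optional 2D drawing coordinates  |
| `TertiaryStructure` | atomic coordinates with a residue→position map   |
| `Profile`           | per-nucleotide values, errors, no-data mask      |
| `InteractionSet`    | internucleotide records with named statistics    |

A `Sample` groups keyword-accessible objects for one experimental
condition.  21 input formats are supported (`probescape formats list`) and
18 plot kinds (`probescape plots list`); `plot_options(sample)` reports
which kinds a given sample can render.

## Core analyses

- **lowSS detection** — positions where the 51-nt windowed median
  reactivity is below 0.4 *and* the windowed median Shannon entropy
  (s_i = −Σ_j p_ij·log₁₀ p_ij over recorded pairing probabilities) is below
  0.15 form contiguous low-reactivity/low-entropy regions, a signature
  enriched for functional structure in long RNAs.
- **Windowed AUROC** — per-window area under the ROC curve for reactivity
  classifying unpaired vs paired nucleotides (Mann–Whitney tie handling),
  a running measure of agreement between a profile and a structure model.
- **deltaSHAPE-style difference calling** — smoothed, error-aware
  two-condition comparison: Z-factor 1 − 1.96·(SEM_a+SEM_b)/|Δ| plus a
  standard score on Δ, with a 3-of-5 consecutiveness rule.
- **Model comparison and consensus** — predicted vs accepted pairs
  classified correct/incorrect/missing with sensitivity and PPV; support
  counts for pair sets across k models with a consensus threshold.
- **Interaction filtering** — statistic bounds, correlation sign,
  confidence class, region, top-k, and 3D contact-distance criteria
  (O2′ atoms, C1′ fallback) applied conjunctively to a mask; records are
  never deleted.
- **Position mapping** — global end-gap-free pairwise alignment carries
  profiles, structures, interactions, annotations and 3D maps onto a
  shared axis across constructs.

## Worked example

The built-in generator writes a coherent synthetic toy RNA (tandem hairpins
plus a pseudoknot) in every supported format, so the example runs with no
downloads:

```sh
probescape fixtures make --seed 1 --n 120 --out fixdemo/
probescape analyze lowss --profile fixdemo/toy_profile.txt \
    --dp fixdemo/toy.dp --window 51 --rmax 0.4 --smax 0.15 \
    --out fixdemo/regions.bed
# -> 1 lowSS region(s) -> fixdemo/regions.bed
cat fixdemo/regions.bed
# -> toy_profile    0    86    lowSS_1
```

The toy RNA's hairpins concentrate low reactivities and well-defined
pairing probabilities in its 5′ three-quarters, so one lowSS region
covering positions 1–86 is called (BED output is 0-based half-open).  The
same data through the library:

```python
from probescape import create_sample, plot_options
from probescape import profile_analysis as pa

sample = create_sample("toy", {
    "profile": ("fixdemo/toy_profile.txt", "shapemapper-profile"),
    "ss":      ("fixdemo/toy.ct", "ct"),
    "probs":   ("fixdemo/toy.dp", "pairprob-dp"),
})
entropy = pa.shannon_entropy(sample.get("probs"))
regions = pa.find_lowss(sample.get("profile"), entropy, pa.LowSSParams())
print([(r.index, r.start, r.end) for r in regions])   # [(1, 1, 86)]

track = pa.windowed_auroc(sample.get("profile"), sample.get("ss"),
                          pa.WindowParams(w=51))
import numpy as np
print(round(float(np.nanmean(track.values)), 3))      # 0.982
```

The mean windowed AUROC of 0.982 says the generated reactivities separate
unpaired from paired nucleotides almost perfectly — by construction of the
generator's reactivity model.  Plotting goes through one entry point, e.g.

```python
from probescape import PlotRequest, render
report = render(PlotRequest(kind="lowss-panel", samples=[sample],
                            options={"out": "lowss.svg"}))
```

Every renderer returns a layout report enumerating each drawn element in
data coordinates (arc centers and radii, circle angles, glyph positions,
cylinder endpoints), which is what the test suite asserts on.

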