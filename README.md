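# dpiscreen

Design and evaluation toolkit for DPI-ELISA screens — plate-based
*de novo* discovery of the DNA-binding motifs of transcription factors
and other DNA-binding proteins.

In a DPI-ELISA screen, biotinylated double-stranded DNA probes are
immobilized one per well of a streptavidin-coated 384-well plate, probed
with an epitope-tagged protein extract, and bound protein is detected
photometrically. The dry-lab work this package covers:

- **Library design.** A backtracking designer distributes all 4096
  hexanucleotides (2080 double-strand equivalence classes, since a dsDNA
  probe presents a k-mer and its reverse complement simultaneously) over
  ≤ 352 probes of 11–20 bp, such that each motif class sits on ≥ 2
  probes and the set of probes containing a motif — its *signature* —
  identifies it uniquely. Construction is two-step: three 1600 bp
  "masterstrands" grown base by base with cut-marks that partition them
  into 15–20 bp probes, then a greedy completion step that packs the
  remaining motifs into short extra probes. An independent validator
  checks every constraint.
- **Plate model.** Oligo assembly (6 bp/4 bp adenyl linkers around the
  variable region, 5'-biotinylated forward strand), deterministic
  384-well layout with 6 positive and 26 negative control wells, and
  readout CSV I/O (grid and long dialects).
- **Screen evaluation.** Relative normalized absorbance (well / plate
  mean), rank sorting (S-plot), a 2σ significance border with strict
  positive calling, replicate concordance (Pearson r, reproducible
  positives), and percent relative binding with errors for quantitative
  single-probe assays.
- **Motif decoding.** Exact signature-containment decoding, exhaustive
  hypergeometric enrichment of all 2080 motif classes
  (positives vs library), and greedy alignment of the enriched classes
  into an IUPAC consensus (e.g. TTGACC + TTGACT → TTGACY, the W-box).
- **Simulation.** A binder-affinity + plate-noise model that generates
  readouts with known ground truth, used by the test suite to verify the
  pipeline end to end (including the exact-decodability guarantee for
  every single motif class).

See `docs/methods.md` for the model, parameters and design choices.

## Worked example

```python
from dpiscreen import *
from dpiscreen.decode import support_frame

cfg = DesignConfig(seed=1)                 # k=6, 3x1600 bp, 384-well budget
lib = design_library(cfg)
report = validate_library(lib, cfg)

layout = build_plate_layout(lib)           # probes + 32 controls on the plate
binder = BinderModel(consensus="TTGACY")   # a W-box binder
readout = simulate_readout(layout, binder, NoiseModel(sd=0.05, seed=7))
result = analyze_readout(readout, layout)

ids = {layout.probe_at(w).probe_id for w in result.positives}
supports = enrich_motifs(ids, lib)
consensus = build_consensus(supports, ids, lib)
```

Output of the steps above:

```text
library: 337 probes (241 from masterstrands, 96 completion)
validator passed: True; wells used: 369/384
threshold: 2.899 (sigma 0.950); positives: ['O5', 'M6', 'A5', 'C15']
exact decode: ['AGTCAA', 'GGTCAA']
 motif reverse_complement  n_positive  n_library  enrichment_p
AGTCAA             TTGACT           2          2      0.000106
GGTCAA             TTGACC           2          2      0.000106
AAATTG             CAATTT           1          2      0.023633
consensus: RGTCAA
```

Reading this: the designed library fits the plate with room for the 32
control wells; after normalization the 2σ border sits at 2.899 and four
wells clear it; those four wells are exactly the signatures of the two
motif classes AGTCAA/TTGACT and GGTCAA/TTGACC (each class is a
k-mer *and* its reverse complement — the library encodes one orientation
per probe); enrichment ranks precisely those two classes first
(p ≈ 1.1e-4 each); and their alignment yields RGTCAA, whose reverse
complement is TTGACY — the W-box consensus the simulated binder was
given.

The same workflow is available as a CLI:

```sh
dpiscreen design --seed 1 --outdir design_out
dpiscreen layout design_out/library.tsv --outdir layout_out
dpiscreen simulate layout_out/layout.tsv --consensus TTGACY --seed 7 --outdir sim_out
dpiscreen analyze sim_out/readout_grid.csv --layout layout_out/layout.tsv --outdir ana_out
dpiscreen decode ana_out/screen_result.tsv --library design_out/library.tsv --outdir dec_out
```

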