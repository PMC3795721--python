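# Methods

## The problem

A DNA-binding protein (DBP) that recognizes a short element of ~6 bp can
be characterized *de novo* by probing it against double-stranded DNA
probes on an ELISA plate: biotinylated dsDNA probes are immobilized one
per well on a streptavidin-coated 384-well plate, the plate is probed
with an epitope-tagged protein extract, and bound protein is detected
photometrically. The computational substance of such a screen is
two-fold: (i) designing a probe library in which *every* hexanucleotide
motif is present and *identifiable* from the pattern of positive wells,
and (ii) turning a plate of absorbances into positive calls, motifs and
a degenerate binding consensus. `dpiscreen` implements both, plus a
simulator that generates readouts with known ground truth so the whole
pipeline can be exercised and falsified end to end.

## Double-stranded motif arithmetic

A dsDNA probe presents every window of its forward strand and, on the
complementary strand, the reverse complement of every window. A "motif"
is therefore the equivalence class `{m, revcomp(m)}`; the class
representative is the lexicographic minimum of the pair (any fixed
orientation works; min is conventional). For hexamers there are
`(4096 - 64)/2 + 64 = 2080` classes, 64 of them palindromic
(`m == revcomp(m)`, possible only for even k). A 20 bp variable region
has 15 hexamer windows; when these are pairwise non-equivalent the
region covers 30 distinct hexanucleotide sequences counting both
strands. User-facing reports follow this both-strand counting, with
canonical class counts alongside. Window coordinates are 0-based
half-open internally and 1-based in reports.

## Library design

### Constraints

Per probe (variable region): (1) each directed k-mer occurs at most
once; (2) a k-mer and its reverse complement never co-occur; (4) at most
one palindromic window. Globally: (3) if two non-palindromic k-mers
co-occur on a probe, their reverse complements must not co-occur on
*any* probe — the strict reading; the looser same-probe-only reading
leaves pairs of two-probe signatures indistinguishable and defeats the
point of the design. Probe lengths: masterstrand-derived probes 15–20
bp, completion probes 11–20 bp. Library probes plus 32 control wells
(6 positive, 26 negative) must fit the 384-well plate.

A library is *decodable* when each motif class lies on at least two
probes and the family of signatures (motif → set of containing probes)
identifies each class. Identification needs more than pairwise distinct
signatures: if `sig(m1) ⊂ sig(m2)`, a binder of `m2` lights up a
superset of `m1`'s signature and the signature-containment decoder
reports both. The designer therefore maintains the stronger invariant
that signatures of satisfied classes form an **antichain** (no signature
contains another); the ambiguity report lists such `dominated` pairs
alongside plain collisions, and the validator checks all of it.

### Two-step construction

**Masterstrands.** Three 1600 bp strands are grown base by base, with
cut-marks placed on the fly that partition each strand into probe-sized
segments (windows never span a cut). Elongation is greedy-guided
backtracking. Each candidate base forms a window; the window is accepted
only if it passes constraints (1)(2)(4) within the open segment, the
global pair rule (3) against all existing probes, and the antichain
check. Among passing candidates the order of preference is:

1. *gains* — windows whose class still needs probe placements
   (support < 2), tie-broken by how many still-needed k-mers extend the
   successor 5-mer context (a one-step lookahead kept as an incremental
   prefix index), then by fixed base order A<C<G<T;
2. *bridges* — neutral windows whose successor context is the prefix of
   some needed k-mer (one base away from needed sequence space);
3. a cut-mark, allowed when the open segment is ≥ 15 bp and the
   remaining strand length is still partitionable into 15–20 bp
   segments, and forced at 20 bp or when waiting longer would make the
   remainder unpartitionable;
4. other neutral windows.

The lookahead tie-break matters quantitatively: with plain base-order
ties the design needs ~350–365 probes and grazes or busts the well
budget; with it, ~333–338 probes, in line with a published 341-probe
array built to the same constraints. After a cut, the next segment is
seeded with a whole needed k-mer (candidates shuffled by the run's RNG,
which is what makes different seeds explore different strands). Dead
ends (no candidate passes and the segment is too short to cut) backtrack
through the decision stack, bounded by `max_backtrack_steps` (default
10^6) with up to 10 reseeded restarts — both unconstrained by any
external reference and chosen generously; in practice a default-scale
design completes in seconds with few backtracks.

**Greedy completion.** After cutting, remaining deficits (classes with
support < 2) are packed into fresh 11–20 bp probes by a depth-first
packer: needed k-mers are appended with maximal suffix overlap (ties:
higher remaining ambiguity first, then chainability of the successor
context, then lexicographic); below the 11 bp floor single neutral
filler bases may re-anchor a wedged tail; a fully wedged probe backs out
of its last extension (budget 500 steps per probe). Every appended
window passes the same constraint checks as masterstrand windows, so
completion preserves validity and the antichain invariant; the loop
terminates when the total placement deficit reaches zero, or raises if
the well budget is exhausted or a probe stops reducing the deficit.
Overlap-first packing (rather than strictly ambiguity-ordered motif
placement) is what keeps the completion block near ~100 probes; the
ambiguity priority survives as the within-tier order.

### Validation

`validate_library` re-derives everything from the probe table alone:
per-probe scans for (1)(2)(4), the full pairwise scan for (3), length
bounds by probe source, coverage of all classes, ≥2-probe support,
signature uniqueness and subset-freeness, and the well budget. The test
suite additionally checks designed libraries against a brute-force
validator written independently from the constraint definitions, at toy
scale (k=2, k=3) where exhaustive scanning is instant.

## Plate model

Forward oligo = `AAAAAA + region + AAAA`, reverse oligo its exact
reverse complement; only the forward strand is 5'-biotinylated. Layout
is a deterministic column-major fill (A1, B1, … P1, A2, …): library
probes first, then 6 positive and 26 negative controls; the exact
four-stock-plate pipetting interleave of a robot run is configuration,
not science, so a custom layout can be supplied instead. Readouts are
CSV in two dialects (16×24 grid with A–P/1–24 labels, or long
`well,value`); both round-trip losslessly. The published control
sequences are not redistributed here; the defaults are synthetic
stand-ins (W-box-bearing positives, AT-repeat negatives) that only fix
classes and well usage.

## Screen evaluation

Relative normalized absorbance = raw value / plate mean, the mean taken
over **all** wells probed with the extract (controls and empties
included — the published ranked plots include them; a flag excludes
controls if wanted). The significance border is `1 + 2σ` with σ the
standard deviation of the normalized values; "above" is strictly
greater; only library wells are eligible positives by default. Under a
Gaussian null this one-sided 2σ border passes ~2.3% of wells (the
two-sided 5% convention), which the suite confirms by Monte Carlo
(10^4 plates × 384 wells). Normalization makes every downstream call
scale-invariant, and raising a well's raw value can only move it up the
ranking — both are property-tested.

Replicate concordance is the Pearson correlation of normalized values
over shared wells (the estimator is not named in the field's usage;
Pearson is the natural reading of a scatter of replicate values), plus
the intersection of the positive sets. For quantitative single-probe
assays, absorbances are normalized per replicate to the empty-vector
control mean, expressed as percent of a reference probe, with error =
half the range for two technical replicates and maximum deviation from
the mean otherwise; the p < 0.05 flag is a two-sided Welch test against
the empty-vector values and is explicitly advisory at n = 2.

## Decoding and consensus

*Exact decoding*: all classes whose full signature is contained in the
positive set; with a validator-clean library this returns exactly the
bound motif for a noise-free single-motif binder — verified exhaustively
for all 2080 classes in the acceptance suite.

*Enrichment*: the candidate space is the closed set of 2080 classes, so
discriminative motif discovery reduces to an exact test — for each class
on K of the N library probes with k of the n positives, the
hypergeometric upper tail P(X ≥ k). No heuristic motif search is needed
where an exhaustive exact test is feasible; this fills the same
positive-versus-library discriminative role for which screens of this
kind have used DREME.

*Consensus*: classes with p ≤ 0.01 (a conventional discovery threshold;
the procedure is insensitive to it because true classes land many
orders below) are merged in rank order onto the top class by ungapped
alignment (both orientations, shifts up to ±2, maximizing identity, ties
to larger overlap, smaller shift, forward orientation). Columns covered
by every aligned k-mer form the core; each column's IUPAC symbol is the
minimal base set covering the observed bases (no frequency weighting:
TTGACC + TTGACT → TTGACY). A candidate is merged **only if the merged
pattern's own discriminative enrichment does not degrade** (probes with
a window matching the pattern on either strand, positives vs library).
This guard exists because the positive set of a screen is the union of
the true classes' signatures, and with ~45 classes per probe there is a
~30% chance per screen that some unrelated class has both its probes in
that union by coincidence (p ≈ 5·10⁻⁴, beating any fixed threshold);
unconditional merging would corrupt roughly every third consensus.
Re-scoring the generalized pattern is the same move DREME makes when it
grows a degenerate word. Consensus output is orientation-normalized only
by its anchor; `consensus_matches` compares patterns up to reverse
complement.

## Simulator

`affinity(class) = scale · penalty^(min mismatches of either orientation
to the consensus)`, with optional explicit per-class affinities (used
for the exhaustive decodability loop: one class at full scale, all
others zero). A probe's signal is background + the **max** over its
windows (monomeric single-site binding; `sum` is available for
avidity-like behavior), positive controls background + full scale,
negative controls and empty wells background. Noise is additive Gaussian
(default) or median-centered lognormal, clipped at zero absorbance.
Reference conditions: background 0.1, scale 1.0 (ten-fold signal over
background), penalty 0.2, noise sd 0.05 (half the background). Under
these conditions a TTGACY binder's perfect-match probes sit at ~6× the
plate mean, one-mismatch probes at ~1.6× against a ~3× threshold — the
separation that makes consensus recovery succeed in ≥95/100 seeds, which
the acceptance suite measures.

What the simulator does *not* model: HRP kinetics and stop-time choice,
washing, spatial plate gradients, saturated wells, probe-synthesis
failures, cooperative/multimeric binding, DNA shape readout. Passing the
simulation-based tests therefore shows the pipeline's logic and
statistics are sound under the stated noise model, not that any
particular wet screen will reach the same numbers.

## Numerical and degenerate-input choices

- Zero-variance plates warn and return no positives; all-zero plates
  raise (normalization undefined).
- Negative absorbances in input files are kept (instrument baselines can
  dip below zero after blanking).
- Ranking ties break by well coordinate; all orderings are total and
  deterministic.
- All RNG use (design restarts, seed shuffles, noise) derives from
  explicit integer seeds; identical seeds give byte-identical outputs.
- Problem sizes used by the test and acceptance suites: full-scale
  design (3×1600 bp, 2080 classes), the complete 2080-binder decode
  loop, 10^4-plate Monte Carlo, 100-seed recovery — all chosen to test
  the published scale directly rather than a scaled-down surrogate.

## Known limitations

- The designer is a heuristic; it makes no optimality claim about probe
  count, and a given seed's library (335–340 probes) is one member of a
  large solution family. Sequence-identical reproduction of any specific
  published array is out of scope; the validator, not sequence identity,
  is the contract.
- Probes are not screened for synthesis-relevant features (GC extremes,
  hairpins); the linker architecture, not computation, is relied on for
  hybridization behavior.
- The quantitative assay's significance flag at two replicates has
  essentially no power and is labelled advisory.
- Real replicate raw data for the published screens are not bundled, so
  replicate-concordance behavior is demonstrated on simulated replicates
  with stated noise.
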