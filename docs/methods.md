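# Methods

## The problem

Topologically associating domains (TADs) are separated by boundary regions
that are, in most cases, clusters of oriented CTCF binding sites (CBSs).
Three quantitative questions drive this package:

1. How does the strength of a boundary (measured as the depth of the local
   insulation minimum) depend on the number and orientation class of the
   CBSs it contains?
2. How should loop anchors and loop pairs be classified by the orientation
   of their CBSs relative to the loops they engage — in particular, when do
   *nonconvergent* loops (loops lacking a properly oriented CBS at an
   anchor) appear?
3. Can such nonconvergent loops be produced by *loop interference*: a
   cohesin complex stalled at a CBS sterically blocking a second complex,
   thereby stabilising a paired loop in the opposite direction?

Real genome-wide answers require deeply sequenced Hi-C, called loops and
motif-annotated CTCF peaks.  This package instead closes the whole loop at
desk scale: a synthetic generator with known ground truth drives every
analysis stage, so each claim is a recovery test rather than an anecdote.

## The loop-extrusion generator (`simgen`)

A 1D lattice of `n_bins` bins (default 400 bins of 10 kb, i.e. a 4 Mb
region) carries `n_extruders` cohesin complexes (default 40).  Each complex
has a left and a right leg; per time step every non-stalled leg moves one
bin outward.  Stalling is one-sided and orientation-dependent: a
forward-oriented CBS captures left-moving legs with probability
`capture_prob` (so forward CBSs become the *left* anchors of rightward
loops), a reverse-oriented CBS captures right-moving legs.  This is the
convergent-loop rule of the loop-extrusion model.  CBS-stalled legs never
release spontaneously; complexes unload with probability `unload_prob` per
step (default 0.002) and reload with both legs co-located at a uniformly
random bin.  A leg that reaches a lattice end slides off: the complex
unloads (when unloading is disabled entirely, the ends reflect instead so
that small deterministic runs stay closed).

**Loop interference.** With `interference_enabled` a moving leg may never
enter a bin occupied by another complex's stalled leg; it stalls in the
adjacent bin and remains stalled while the blocker persists.  Because
blocked legs themselves block, stalled legs nucleate queues ("roadblocks")
that obstruct traffic in *both* directions.  This single rule reproduces
the paired convergent/nonconvergent loop signature: a complex stalled at a
forward CBS (left anchor of a convergent loop) blocks right-moving legs
arriving from the other side, pinning them one bin short of the CBS and
creating a leftward loop anchored at a site with no reverse motif.

**Rendering.** Snapshots are taken every `steps_per_snapshot` (default 10)
steps after a burn-in (default 500 steps).  The contact map is the sum of

* a deterministic distance-decay background
  `background_weight * (|i-j|+1)^-background_exponent` (defaults 5, 1.0),
* one count per complex per snapshot at its (left, right) loop-base pixel,
* `intra_loop_samples` (default 2) uniformly random contacts inside each
  extruded interval per complex per snapshot, emulating the compacted loop
  interior,

symmetrised, with planted low-mappability bins zeroed.  Snapshot spacing
matters: each surviving complex deposits `lifetime / steps_per_snapshot`
correlated counts on one pixel, so sparser snapshots reduce the lumpiness
of transient loops relative to planted persistent ones.

**What the generator emulates, and what it does not.** It reproduces
distance decay, TADs delimited by oriented CBS clusters with heterogeneous
occupancy, convergent loop pixels, interference-induced nonconvergent
partners, masked bins and exact ground truth.  It does not model 3D polymer
physics, CTCF/cohesin residence-time kinetics, replication of any real
locus, trans contacts, or sequencing noise models (the background is
deterministic, not Poisson).  Passing recovery tests therefore demonstrates
the internal consistency of the analysis stack under the extrusion model's
assumptions, not its performance on experimental libraries.

**Scenarios.** `two_tads` plants a reverse/forward CBS pair at bins
199/201 (junction 200) with flanking anchors at bins 15 and 385 and two
masked bins; `forward_only_boundary` plants a single forward CBS at the
junction (the interference testbed); `ep_boundary_like` plants six sites
ordered R,R,F,R,F,R with heterogeneous occupancies (0.9, 0.5, 0.9, 0.6,
0.9, 0.3), echoing a prototypical divergent boundary of four reverse and
two forward sites; `divergent_vs_nondivergent_panel` parameterises the
junction's composition.  Flank anchors sit one aggregation window inside
the lattice ends so every planted loop pixel supports a full
strength/aggregate window.

## Contact-matrix handling (`contacts`)

Matrices are dense in memory (desk scale), sparse upper-triangle triplet
TSV on disk.  Balancing is the symmetric Sinkhorn–Knopp fixed point, which
converges to the same balanced matrix as Knight–Ruiz normalisation: weights
`w` with `w_i C_ij w_j` having uniform row sums on unmasked bins.  The
target row sum is the mean unmasked raw marginal, bins with zero marginal
are masked before iterating, and the iteration stops when the relative
row-sum spread falls below `tol` (default 1e-8, `max_iter` 1000;
non-convergence raises rather than returning silently).  Expected-by-
distance is the mean balanced value over unmasked pixels of each diagonal;
observed/expected divides by it.  Coverage equalisation divides each matrix
by its own total (each pair counted once), giving unit totals.

## Insulation and boundaries (`insulation`)

The insulation score of bin *i* is the mean balanced signal in the square
`[i-w, i-1] x [i+1, i+w]` (default window 250 kb; at 25-kb bins w = 10, at
the generator's 10-kb bins w = 25), log2-scaled relative to the arithmetic
track mean.  Bins within *w* of the edge or with more than half of the
window masked are invalid.  Boundaries are strict local minima (plateaus
report their leftmost bin); the boundary score (BS) is the depth below the
lower of the two nearest flanking maxima.  The flank walk tolerates dips up
to 0.5 log2 units below the running maximum before declaring the flank
ended; without this prominence tolerance, stochastic micro-wiggles on the
floor of a wide insulation valley truncate the flank and assign the deepest
minimum a near-zero score.  The tolerance leaves hand-computable small
tracks unchanged.

Low-mappability bins are flagged by a two-component Gaussian mixture on
log1p marginal counts of the *raw* matrix (scikit-learn EM, 5 restarts):
bins with posterior > 0.5 for the low-mean component are flagged, unless
the two means differ by less than one pooled standard deviation (then no
separable low class exists).  Boundary calls within 125 kb of a flagged bin
are filtered.  On maps whose coverage is structured but never near zero
(e.g. the synthetic composition panels, which plant no masked bins) the
mixture can latch onto benign coverage modes; the panel pipelines therefore
skip this filter, which is exercised where it belongs — scenarios with
planted dead bins.

## Motif orientation and composition (`motifs`)

JASPAR raw-count matrices are converted to probabilities with a +0.25
pseudocount per cell; scanning scores every offset on both strands with
`sum log2(p/bg)` (order-0 background, uniform by default; N scores -inf)
and keeps the single best hit per peak — ties resolve to the leftmost
offset, then the + strand.  Forward orientation means the best hit lies on
the + strand.  Boundary composition collects CBSs overlapping the boundary
bin ± a 100-kb flank; a *divergent pair* is any reverse-oriented CBS
strictly upstream of a forward-oriented CBS (adjacency not required), and a
boundary is divergent when at least one such pair exists.  Summaries report
count, median and linearly interpolated quartiles with 1.5 IQR whiskers per
(CBS count, divergence class) stratum.

## Loop classification and strength (`loops`)

Anchors merge when their intervals overlap after one-bin padding.  An
anchor is *rightward* for a loop when it is the lower-coordinate anchor.
Categories: `no_ctcf` (no CBS), `nonconvergent` (at least one loop in a
direction lacking a directional CBS — forward for rightward loops, reverse
for leftward), else `convergent_only`.  A loop is *convergent* when its
left anchor carries a forward CBS and its right anchor a reverse CBS.  Five
loop categories follow from what the anchors do in the opposite direction,
with precedence convergent-associated > double-sided > single-sided so the
interference-paired class is never absorbed by the broader one.

Loop strength is aggregate-peak-analysis style: log2 of the mean obs/exp in
a 3x3 centre over the mean of the two corner 3x3 squares (lower-left and
upper-right of the 21x21 window — the corners along the diagonal
direction).  The bidirectionality scheme is a chi-squared omnibus on the
category-by-bidirectional table, pairwise post-hoc chi-squared (no
continuity correction) with Benjamini–Hochberg adjustment over exactly the
post-hoc set; distances use Kruskal–Wallis followed by BH-corrected
pairwise Mann–Whitney U only when the omnibus is significant.

A deliberately simple loop caller closes the synthetic pipeline: obs/exp
local maxima above a threshold, more than 2 bins off-diagonal, with
Chebyshev non-max suppression.  It is not an FDR-controlled caller.  On
maps from this generator the pipeline presets use threshold 25: planted
persistent loops sit at obs/exp 60–200, whereas transient complexes leave
lumps of 5–25.

## Comparison views (`views`)

Subtraction maps equalise coverage, subtract element-wise, and z-score each
sub-diagonal separately (population standard deviation); diagonals with
fewer than 3 defined pixels or zero spread are flagged and set to z = 0, so
ultra-short diagonals cannot produce spurious extremes.  Virtual 4C is the
mean balanced profile of a viewpoint (default exclusion: 2 bins around the
viewpoint), normalised to sum 1 over defined bins; a quantification window
reports its share of the normalised signal.

## The two headline experiments (`pipeline`)

**Composition panel.** For CBS counts 0–10 and both orientation classes,
the panel plants the sites at 2-bin spacing around the junction, simulates,
balances, scores insulation and reports the BS of the call nearest the
junction.  Panel sites use capture 0.3 per site: with moderate occupancy
every added site lowers the extruder crossing probability appreciably
(roughly `(1-p)^k`), producing a graded dose-response instead of a
saturated one.  The panel (and the weakening series below) runs with
interference off: a stalled leg blocks traffic in both directions and
nucleates a roadblock queue, so with interference a single site already
saturates insulation and the compositional signal disappears.  Interference
remains the default everywhere else and is precisely the treatment of the
interference experiment.

**Interference experiment.** The `forward_only_boundary` scenario is run
with interference on and off (20 replicates per arm in the standard
conditions), loops are called at threshold 25, anchors classified against
the planted CBS annotations and pooled per arm.  The on-arm shows the
paired-loop signature: the boundary anchor engages a rightward convergent
loop and a leftward nonconvergent one, so the nonconvergent category is
almost entirely bidirectional, while convergent-only anchors are not; the
off-arm produces essentially no nonconvergent anchors (the comparison is
then reported as p = 1, no evidence of elevation).  Strengths of
convergent-associated vs nonconvergent-associated partners are compared
with a one-sided Mann–Whitney U test.

**Weakening series.** Starting from the six-site divergent boundary
(uniform capture 0.55), sites are removed one at a time; each level is
simulated on the *same* simulator seed within a replicate (common random
numbers, a standard paired-simulation variance-reduction design), and the
cross-boundary share of a virtual-4C profile (viewpoint bins 280–284 in the
right TAD, quantification window bins 100–160 in the left TAD) is recorded.
The share rises monotonically within replicates as insulation is dismantled.

## Determinism and problem sizes

All randomness flows from explicit seeds through `numpy` `SeedSequence`
substreams; dataset generation is byte-identical across reruns with equal
seeds.  The standard study conditions used by the test suite are: 100
replicates for boundary recovery, 1,000 random toy sets for the
classification cross-check, 6 replicates per panel cell, 20 per
interference arm and 20 weakening replicates.  `scripts/acceptance.py`
re-measures the same quantities at 50/5/20/20 replicates, completing in a
few minutes on one CPU.

## Known limitations

* The boundary-score formula (depth to the lower flanking maximum with a
  0.5 prominence tolerance) is one of several reasonable definitions;
  absolute BS values are comparable only within this package.
* Interference kinetics are schematic: blocked legs behave exactly like
  CBS-stalled legs while the blocker persists, and release instantly when
  it unloads; no residence-time distribution is modelled.
* The simple loop caller has no statistical error control; its threshold is
  generator-calibrated, not transferable to experimental maps.
* The GMM mappability filter assumes a clearly separated near-zero coverage
  class; structured-but-finite coverage can confuse it (see above).
* Anchor merging by padded overlap can chain through queue pixels adjacent
  to a CBS; this is intended (queued legs belong to the same anchor
  element) but means merged anchors can span several bins.
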