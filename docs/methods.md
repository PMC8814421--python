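# Methods

This note records the models, numerical choices and assumptions behind
each stage of the pipeline, and what the synthetic data does and does not
establish.

## Motif model and exact match p-values

A motif is a 4 × w count matrix (JASPAR text format, rows normalized to
A, C, G, T). Scoring uses log2 odds against a zero-order i.i.d.
background; the pseudocount (default 0.1) is distributed across bases in
proportion to the background, so a column of background-equal
probabilities scores 0 for every base, column minima/maxima sum to the
matrix score range, and a zero count is only an error when the pseudocount
is 0.

The match p-value of a score s is P(S ≥ s) for a single random background
window. It is computed exactly, not estimated: each column's four scores
are rounded to a grid (default 1/1000 bit) and the probability mass
function of their sum is built by column-wise convolution, linear in width
times the integer score range. Scanning never rounds twice — each window's
integer score bin is summed from the same per-column bins that built the
distribution, so the vectorized hit test (`bin ≥ threshold_bin`) is
exactly equivalent to `p ≤ threshold`. The float-score API
(`score_pvalue`) quantizes the query and snaps it to the nearest
achievable window score within the accumulated rounding tolerance (half a
bin per column); its answers are exact up to one grid bin, which the test
suite checks against exhaustive enumeration of all 4^w windows for w ≤ 8.

Conventions, chosen once and fixed:

* hit iff p ≤ threshold (thresholds like 1e-3 are inclusive);
* background defaults to uniform; a zero-order background can be
  estimated from the scanned sequence (`Background.from_sequence`);
* both strands scanned by default; reverse-strand windows are scored with
  the reverse-complemented matrix and reported in forward 1-based
  inclusive coordinates (0-based half-open internally, converted in one
  place); a separate distribution is compiled for the reverse matrix so
  non-symmetric backgrounds stay correct;
* windows containing non-ACGT characters are skipped, not
  ambiguity-averaged;
* per-window tests are not multiple-testing corrected — the scan
  threshold is used raw, as it is in practice when selecting candidate
  sites.

## Knockout design

Only transition substitutions (A↔G, C↔T) are proposed: they preserve
length, motif spacing and purine/pyrimidine identity, and disrupt
palindromic and non-palindromic motifs alike. "Important" motif positions
are operationalized as the columns of highest information content
(2 + Σ p log2 p bits, uniform convention), ties to the leftmost column.

For one target hit the search is iterative deepening on the number of
substitutions, combinations ordered by summed column information content
and then by leftmost position — fully deterministic, first feasible plan
wins. Success requires that **no window overlapping the original hit**
(either strand) matches the target motif at threshold; killing only the
original frame is not enough, because a shifted window can survive.
Because of that criterion, when several hits of the same motif overlap
they are treated as one cluster: candidate positions span the cluster's
columns (capped at the 12 most informative) and the budget is k_max
(default 4, matching the practice of mutating 2–4 nucleotides per site)
per cluster hit. Protected sites must survive at identical coordinates
and strand with p ≤ threshold — the score may change, since flanking-base
edits near a shared core are exactly the intended escape route — unless a
hit is explicitly listed as allowed collateral, the mechanism for
core-sharing conflicts that cannot be avoided. Candidates are vetted
locally (a window around the edits, padded by the widest watched motif,
rescanned with every watched matrix) and the finished construct is
verified by a full rescan: passed ⇔ no surviving target hit, no new hit
of any watched motif, and all lost protected hits allowlisted. Multi-site
constructs are designed left to right with a rescan after every
application; if global verification still fails, the combination nearest
the offending hit is excluded and the design restarts (bounded).
Infeasible sites return the set of protected hits every otherwise-lethal
candidate would have destroyed.

## Dual-reporter quantitation

Stacks are flattened by sum projection, which conserves total intensity;
ROI aggregation uses the **mean** over pixels whose centers fall inside
the polygon (even-odd rule via `matplotlib.path` — deterministic and
standard). The mean, unlike an integral, is invariant to padding an ROI
over uniform background, which matches the ratio semantics.

The per-embryo ratio reporter/control cancels anything multiplicative per
embryo — electroporation efficiency above all. Normalization is **per
replicate** (each electroporation day is one experiment): every
replicate must contain wildtype embryos and its wildtype mean maps to 1
exactly. Lineage columns are normalized against the wildtype lineage
means the same way; the primary/secondary ratio is the plain per-embryo
ratio of the two lineage reporter/control ratios, so it needs no
normalization at all. Embryos without internal-control signal are
rejected with an error rather than silently dropped.

Pairwise construct comparisons use t statistics with a single standard
deviation pooled across **all** groups (df = N − k, the default behavior
of R's `pairwise.t.test`), Benjamini–Hochberg adjustment over the full
pair set, and star labels at adjusted p < 0.05 / 0.01 / 0.001. A per-pair
Welch option exists but is off by default. Tests are run on per-embryo
normalized ratios pooled across replicates; replicate is not modeled as a
factor. No background subtraction is applied by default.

## Single-cell analysis

Cells are split on internal-control intensity strictly above 256
(8 in log2; a cell at exactly 256 is non-expressing). Log2 transforms
floor intensities at 1 so zeros stay finite while 256 → 8 exactly. The
mosaicism/graded decomposition reports, per construct:

* the fraction of control-expressing cells whose reporter exceeds the
  reporter threshold (default: the same 256) — tracks mosaicism;
* the mean log2 reporter/control ratio among cells above **both**
  thresholds — tracks the per-cell expression level.

Conditioning the log-ratio on reporter expression is deliberate: it is
what makes the two archetypes separable (a pure-mosaicism mutant moves
only the fraction, Δ ≈ −0.5 when half the cells go dark; a pure graded
2-fold loss moves only the log ratio, Δ ≈ −1 bit). An unconditioned mean
would smear baseline cells into the level estimate and conflate the two.
The reporter-on-control regression is fit by OLS on raw intensities
(a log-space option exists), and errors on constant control values.

## Synthetic data: what it emulates

`generate_enhancer` draws i.i.d. background at 35% GC — typical of
AT-rich tunicate non-coding sequence — over 377 bp (the length of the
dissected proximal enhancer fragment), plants motif instances (consensus
or sampled from the matrix), and rejection-cleans the background: any
accidental library-motif hit outside the planted intervals has its
window's bases redrawn and the sequence is rescanned, until clean.
Redrawing only offending windows converges orders of magnitude faster
than whole-sequence rejection (whose acceptance probability is ~1% with a
six-motif library at threshold 1e-3 over 377 bp) and leaves the accepted
background i.i.d. outside the plants.

The expression model, per cell i of embryo j carrying construct c:

* efficiency E_j ~ LogNormal(0, σ_E²), shared by both channels — the
  multiplicative nuisance the dual-reporter design exists to cancel;
* transgene uptake: one uniform draw per cell couples the channels
  (maximally correlated by default, since co-electroporated plasmids
  co-segregate — an assumption, configurable to independent); the
  reporter expresses with probability m_c, the control with its own
  probability;
* expressed intensities: scale · a_c · s_c^[secondary] · E_j · ε with
  ε ~ LogNormal(0, σ_cell²) per cell and channel; non-expressing cells
  emit a constant staining baseline;
* embryos aggregate 32 primary and 8 secondary notochord cells by
  lineage means.

Defaults: σ_E = 1 and σ_cell = 1 (several-fold embryo-to-embryo spread;
after averaging 40 cells, most wildtype normalized ratios fall between
roughly 0.5 and 2), channel scales 2000, baseline 32 (so the control
histogram is bimodal with modes ≳ 6 log2 units apart), mosaicism 1,
10 embryos × 3 replicates. The true magnitudes of efficiency spread and
mosaicism in real electroporations are not known precisely; these values
are assumptions chosen to reproduce the qualitative spread of real
dual-reporter data and are exposed, not hard-coded.

`render_stack` places per-cell Gaussian blobs (normalized over the
volume, so each blob's sum projection integrates to exactly the cell's
channel intensity up to edge truncation) in a two-channel stack with
optional Poisson noise, and emits rectangular whole/primary/secondary ROI
polygons. It exercises the projection/ROI code path; it does not attempt
embryo morphology, staining chemistry, optics, or the occasional
unexplained replicate batch effect seen in real data. Passing tests on
synthetic data therefore establish the *statistical identities* of the
pipeline (cancellation, anchoring, recovery, discrimination) — not that
any particular biological effect size would be detected in real images.

## Problem sizes and tolerances in the test suite

The suite and the acceptance script run at desk scale: 25 random matrices
of width ≤ 8 for the enumeration oracle (exact equality on the discrete
distribution; one accumulated grid bin for float queries), 50 seeded
enhancers with 3–6 planted sites for the designer soundness sweep (every
pass independently rescanned), 200 embryos per construct for strength
recovery (0.3 ± 0.03), 100 for the lineage attenuation median (2.0 ±
15% — the median of a ratio over only 8 secondary cells is noisy and
slightly biased upward by log-normal skew), and 480 cells per construct
for the archetype signatures (±0.1 on the fraction, ±0.2 bits on the log
ratio). The whole suite runs in well under a minute.

## Known limitations

* Zero-order background only; no higher-order Markov models, q-values, or
  motif discovery.
* The designer never proposes transversions or indels and does not
  optimize affinity (no site strengthening), and the exact substitutions
  a human designer chose for a given enhancer are not reproduced — only
  the constraint logic is.
* ROIs are inputs; there is no notochord segmentation, nucleus detection,
  or mid-notochord slice reconstruction — per-cell disk-ROI means are
  consumed directly.
* Matrix choice matters: site counts at a fixed threshold depend on which
  database matrices are used, so counts from differently sourced matrices
  are not comparable. The `SYN_*` matrices shipped for demonstrations are
  synthetic constructions emulating the relevant factor families, not
  database entries.
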