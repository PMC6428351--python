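# Methods

This note records the statistical model behind `phosmod`, the defaults
and why they are what they are, what the synthetic generator does and
does not emulate, and the numerical choices that matter for
reproducibility.

## Response classification

Input is one log2 fold-change per peptide, strain and biological
replicate, for a single condition contrast (e.g. anaerobic vs aerobic
growth); the contrast itself is data preparation and lives outside the
package.  Profiles are replicate-averaged per strain and classified
with threshold rules rather than formal tests: with only two replicates
per strain a per-peptide moderated test has essentially no power, and
threshold rules are transparent and directly comparable across strains.

A "1.5-fold difference" between log2 values is applied as a *difference
of logs*: v − u ≥ log₂ 1.5 ≈ 0.585.  Multiplying a log2 value by 1.5
would depend on the arbitrary zero point and misbehaves near zero.
Class B's requirement that the first two strains show "no significant
difference" is operationalized as fold-equivalence, |v₂ − v₁| <
log₂ 1.5, for the same two-replicate reason; the bound is configurable
(`b_equality_threshold`).  Class A takes precedence over Class B when
loosened thresholds make both rules fire; under the defaults the two
cannot overlap.  Peptides missing a strain are labelled `none` and
logged, never silently dropped.

The gene-level progressive-induction rule used for transcript panels is
the Class A-increasing branch of the same classifier applied to gene
profiles — one code path, exercised by a shared test.  The
paired-replicate contrast rule (`classify_reproducible_contrast`)
requires *every* replicate pair to clear the threshold, trading recall
for reproducibility when only duplicates exist.

## Motif modules

The extraction loop follows the published greedy motif-extraction
scheme for aligned phospho-windows: width 13, central s*/t*, minimum 10
occurrences, binomial significance 10⁻⁶.  The inner test is the
one-sided binomial tail of the foreground count against the *running*
background frequency — the background is re-restricted after every
fixation, so later fixations are conditional on earlier ones.  Whether
to freeze the background at the start or recompute it is genuinely
open; the running-background choice matches the reference
implementation of the algorithm and makes successive fixations
conditionally calibrated.

Numerical/determinism choices:

* Ties on the minimal p-value are broken by larger foreground count,
  then smaller |position offset|, then position and residue
  lexicographically, so builds are reproducible.
* Pad characters ('-') beyond protein termini are excluded from both
  the numerator and denominator at their position; a column that is all
  pads cannot be fixed.
* Serine- and threonine-centred windows form separate foregrounds and
  separate backgrounds; module identifiers embed the rendered pattern
  (e.g. `A_inc:...R..s......`), which is unique within a class.
* Emission requires at least one fixed position and at least
  `min_occurrences` matching members; matched windows are removed and
  extraction restarts on the remainder, which bounds the number of
  iterations by width × foreground size.

## Shared-interactor enrichment

For module M and candidate c ∉ M, the overlap between c's distinct
interaction partners (any edge type or direction) and M's proteins is
scored with the exact hypergeometric upper tail, computed with integer
combinatorics (`math.comb` and exact rationals) so that enumeration
checks agree to machine precision.  Choices the underlying model does
not dictate:

* The population excludes the candidate itself (a protein cannot be
  its own partner), so N = |nodes| − 1.
* BH correction is applied jointly across all (candidate, module)
  pairs of one response class.  Correcting per module would make
  q-values incomparable between modules of the same class; correcting
  across classes would couple analyses users may run separately.
* Candidates with overlap < 2 are never reported (configurable): a
  single shared edge cannot be enriched in any meaningful sense and
  only destabilizes the BH family.
* Degree counts distinct partners, not edge multiplicity; the
  directionality statistic (`toward_fraction`) counts *directed* edges
  only, and an interactor with no directed module edges passes the
  filter (undirected evidence is non-committal about direction).
  "Primarily directed toward" is a majority, ≥ 0.5.

Directed kinase→substrate edges count in the hypergeometric draws like
any other interaction; excluding them would blind the search to
exactly the edge type that carries regulatory signal.

## Kinase specificity matching

Spot-array intensity matrices are normalized per column after adding a
pseudocount (default 0.01) to every cell; module PWMs are residue
frequencies over member windows with the same pseudocount, pads
excluded.  The match score is the Kullback–Leibler divergence
D(module ‖ kinase) in bits over the intersection of position sets; the
central position is excluded (a fixed S/T carries no information).
Direction matters and is not dictated by the model: with the kinase
PWM as the (strictly positive, pseudocounted) reference, zeros in the
module PWM are harmless and the score is always finite.  The log base
only scales scores and leaves rankings and empirical FDRs unchanged.

The null distribution shuffles each library PWM 1000 times — values
permuted independently within each column, then the column order
permuted.  Permutation (rather than re-drawing values) preserves
column-stochasticity exactly, so no renormalization is needed.  The
null is pooled across the whole library per module (null size =
1000 × library size), which matches treating the library as the
reference population of plausible specificities; a per-kinase null is
available (`null="per-kinase"`).  The empirical FDR is the *fraction*
of null scores strictly smaller (better) than the observed score; ties
do not count against a match.  Phosphatases have no spot-array
specificities, so they are retained on shared-interactor and
directionality evidence alone.

Module PWMs use all member windows, not only the motif's fixed
positions: the fixed positions dominate the divergence, but flanking
preferences contribute signal that the motif string discards.

## Synthetic data generator

The generator emulates the structure the pipeline assumes: a
three-strain panel measured in biological duplicate, sharp kinase
specificities, and a mixed directed/undirected background network.
Defaults (4 kinases × 40 substrates, 400 decoys, 800 network nodes,
edge probability 0.01, Dirichlet concentration 0.05, class effect 1.0
log2 units, replicate noise 0.2 log2 units) define the benchmark
scenario used by the acceptance checks; 0.2 is the scale at which
duplicate fold-change estimates remain well correlated, as in typical
duplicate designs.

Each planted kinase is assigned one response class (so its substrates
form a coherent class × motif module) with substrate windows sampled
column-wise from its PWM; decoys get uniform windows and a flat
response, though replicate noise lets occasional decoys cross the
classification thresholds, which is realistic contamination.  Proteins
are synthetic 61-mers with the window embedded at the recorded site,
so re-extracting windows from the emitted proteome reproduces the
table exactly.  Spot-array intensities are the PWMs rescaled to a
0–100 intensity scale so the normalization path is exercised
nontrivially.

What it does **not** emulate: missing values, multi-site peptides and
multi-peptide proteins (each synthetic protein carries one site, which
sidesteps the ambiguity of proteins belonging to several modules),
mass-spec identification error, correlated replicate noise, hub
structure in the interaction network, or overlapping kinase
specificities drawn from real families.  Passing the planted-recovery
benchmark therefore shows the inference chain is sound under its own
assumptions, not that it will reach the same sensitivity on real
phosphoproteomes.

## Benchmark scoring

A reported regulator edge K → M is attributed to K when at least 25%
of M's member peptides are K's planted substrates.  The threshold
tolerates modules that legitimately merge substrates of kinases with
overlapping sampled specificities (both kinases are then genuine
regulators of the merged module) while still flagging regulators
foreign to a module as false calls.

## Determinism

Everything stochastic flows from explicit seeds: the generator derives
independent substreams for PWMs, truth assignment, the peptide table,
the network and the proteome from one root seed, and the matcher
spawns one substream per module (in sorted module order), so adding
modules or shuffles in one place never perturbs another.  Output
tables are sorted on a fixed column priority, floats are rendered with
six significant digits, and the run manifest records the config hash
(output directory excluded), seed and SHA-256 checksums of all inputs
and outputs — no timestamps — so identical config + seed reproduces
every output byte for byte.

## Problem sizes in the checks

The acceptance checks run the benchmark scenario over ten seeds,
calibrate the match FDR on 200 null modules against a 10-kinase
library, calibrate the SI FDR on 100 unstructured 150-node networks,
and verify the hypergeometric tail exhaustively for populations up to
12.  These sizes give stable Monte-Carlo estimates (binomial standard
errors below one percentage point for the calibration rates) while the
whole suite completes in well under a minute per check.

## Known limitations

* Threshold classification is sensitive to the fold cut-off near the
  boundary; peptides with true effects just under log₂ 1.5 per step
  are invisible by design.
* The motif extractor fixes one residue per position; degenerate
  motifs (e.g. basophilic R/K at −3) split across modules rather than
  merging.
* The empirical FDR has resolution 1/null_size; with the default
  pooled null of 1000 × library size, FDRs below ~10⁻⁴ are reported
  as 0.
* Shared-interactor enrichment inherits ascertainment bias from the
  background network: heavily studied proteins have more edges and
  more chances to appear enriched.
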