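# Methods

This note documents the models, conventions and design choices behind
modseek, in the spirit of a package's statistical/methods appendix. It
states no empirical result that the test suite or the acceptance script
does not itself compute.

## Homology search and E-values

The screen needs a presence/absence criterion, not calibrated
statistics, so the aligner is an exact affine-gap Smith–Waterman
(delegated to scikit-bio's pairwise engine) scored with BLOSUM62 and
the BLAST gap convention: a gap of length *L* costs
`gap_open + L * gap_extend` with defaults 11/1. The expected number of
chance hits is the Karlin–Altschul form E = K·m·n·e^(−λS) with the
standard gapped BLOSUM62 constants λ = 0.267, K = 0.041, *m* the query
length and *n* the total residue count of the searched protein set; no
finite-size length corrections are applied. The inclusion threshold
defaults to E ≤ 1e-10.

Searching is seeded: subjects that share no exact word of
`seed_length` (default 3) with the query are skipped without
alignment. Skipped ids are reported on the result
(`SearchHits.skipped_no_seed`) so the heuristic is visible rather than
silent; any subject that could pass the E-value threshold shares many
seed words in practice, and the seeded-vs-full equivalence is covered
by tests. Externally produced hits in the 12-column tabular dialect
(BLAST "outfmt 6") can be substituted for the internal aligner.

"Presence" is a one-way hit from reference gene into target proteome at
the threshold; no reciprocal-best or synteny requirement is imposed,
and any qualifying paralog counts. Candidate ordering always follows
the reference gene order, making reports byte-reproducible. Because
annotation sources are external, the keyword rules are shipped as data
(ordered category → keyword sets, first match wins) and can be
overridden. The screen report prints the count at every funnel stage
(total → shared-with-positives → after subtraction → after annotation
filter) rather than privileging any single stage's number.

## RNA model and substrate rules

Sequences are ordered residues (base + optional modification code from
a registry) with explicit 5' (OH / monophosphate / triphosphate) and 3'
(OH / linear phosphate / 2',3'-cyclic phosphate) terminal chemistries.
tRNA constructs carry a map from residue indices to canonical
cloverleaf position labels instead of a full Sprinzl coordinate system:
only positions 6/67 and 73–76 matter to the rules, and truncated
constructs have no natural Sprinzl numbering. Acceptor-stem pairing is
position *i* ↔ 73 − *i* for *i* in 1..7.

The substrate predicate is the conjunction of three experimentally
grounded rules: R1, the 3' end reads C,C,A (the enzyme's
tRNA-gripping THUMP domain requires the CCA end — a CCA-less
transcript is neither methylated nor even bound, as its failure to
inhibit shows); R2, the base at position 6 is not guanine (the G6-C67
swap abolishes methylation while A6-U67 and U6-A67 are accepted, so
G6 acts as a negative determinant); R3, at least one arm beyond the
acceptor stem is present (single- and double-arm truncations remain
substrates but the bare acceptor micro-helix is not). R3 is a
descriptive structural-minimum rule, not a mechanistic claim — the
precise recognized feature is unresolved, and the micro-helix
observation could in principle also be explained by CCA-end
presentation. Discriminator identity is deliberately **not** a rule:
the tested deletion removed ACCA as a block, so the evidence does not
separate position 73 from the CCA requirement. A position 6 that is
already 2'-O-methylated is reported as the product state with its own
code rather than folded into R2.

## Digestion

RNase T1 cleaves after G, RNase A after C/U; both act through the
ribose 2'-OH, so a 2'-O-methyl on the residue 5' of the scissile bond
blocks the site. Base methylations (m5C, m5U, m1A) never block.
Products carry 5'-OH and a 3'-phosphate; the default product is the
**linear** 3'-phosphate with the 2',3'-cyclic intermediate available by
option, because the observed one-hour digests correspond to the
hydrolyzed end state. Alkaline phosphatase, when enabled, removes all
terminal phosphates (it is nonspecific), which is what puts the RNase A
missed-cleavage octamer into its 5'-OH/3'-OH state. Partial digestion
is modeled only combinatorially: `partial_missed_cleavages = k`
additionally emits every fragment spanning ≤ k deliberately skipped
sites, flagged as partial; modification blocking is not counted as a
missed cleavage. Fragments always tile the parent exactly, a property
the suite checks against a naive quadratic oracle and by a hypothesis
invariant.

## Mass arithmetic and matching

Only monoisotopic masses are used (H 1.0078250319, C 12 exactly,
N 14.0030740052, O 15.9949146221, P 30.97376151): the reference
fragment ions match monoisotopic arithmetic to < 0.02 m/z.
Compositions are additive — nucleoside formulas (C: C9H13N3O5,
U: C9H12N2O6, A: C10H13N5O4, G: C10H13N5O5) plus HPO3 − H2O per
linkage, HPO3 per terminal phosphate (cyclic = linear − H2O,
triphosphate = 3×HPO3), plus each modification's delta (CH2 =
+14.015650 Da for every methyl). Deprotonated ions use the proton mass
1.0072765 with no electron-mass refinement, far below the 0.05 Da at
which printed two-decimal values are compared. The default instrument
window is 600–2000 m/z (negative mode) with charge states 1–5, and the
default matching tolerance is 20 ppm; each observed peak is assigned to
at most one theoretical ion (smallest |ppm| error, ties to lower
charge). Whether printed reference m/z values are observed centroids
or rounded theory is unknowable from text alone — the ~0.02 offset on
the trinucleotide ion is consistent with a centroid — hence the 0.05 Da
comparison cap.

Localization compares control and modified digests of the same parent.
Blocking evidence: a modified-digest fragment spans a run of *k*+1
adjacent control fragments and its mass exceeds the merged control
masses (each junction replaces a 3'-group/5'-group pair by one
linkage, HPO3 − H2O) by exactly *k*×14.0157 Da; all *k* blocked sites
are then called exactly. Mass-shift evidence: a fragment at unchanged
coordinates reappears +14.0157 Da heavier; the methyl lies inside the
fragment but the residue is not resolved from mass alone, so the call
carries the range, not a position. Masses default to theoretical
values; observed (deconvoluted) masses can be passed in their place.

Relative modification level is
100 × (sample analyte/normalizer) / (reference analyte/normalizer),
guanosine being the default normalizer; the double ratio cancels
injection amount and instrument response, and losing one of four
methylated positions yields exactly 75% under equal response factors.

## Kinetics

All four models are fitted by deterministic damped least squares
(Levenberg–Marquardt, relative tolerance 1e-12, ≤ 500 iterations per
start). Rather than a blind multi-start over all parameters, the
nonlinear parameter (k_obs, K_m, IC50) is profiled on a 25-point
log-spaced grid spanning the data range, with the linear parameters
(A, B; V_max) solved exactly at each grid point, and the best start
refined jointly — equivalent in coverage to a 5×5 grid but exact in
the linear directions. Standard errors come from the linearized
covariance at the optimum; with replicated data the spread across
replicate fits is the more honest uncertainty, and both routes are
available.

Conventions and caveats: concentrations in µM, time in minutes (hours
for growth), rates in 1/min. Michaelis–Menten constants are labeled
*apparent* because the emulated assays run at enzyme concentrations
comparable to substrate. The IC50 model is a one-site hyperbolic
decay with Hill slope fixed at 1 — the simplest model consistent with
a competitive RNA inhibitor; the titration must include a
zero-inhibitor point, to which activities are normalized, and
non-decreasing activity returns a distinct no-inhibition status
instead of a forced parameter. Initial velocity defaults to the
zero-anchored least-squares slope over t ≤ t_linear; a single-point
variant f(t)/t is provided because assay write-ups sometimes mean
that. Doubling time is ln 2/slope of ln OD vs time over either a
caller-chosen window or the longest window with log-linear R² ≥ 0.99
and positive slope. Monotone linear saturation data yield a
no-saturation flag (fitted K_m beyond 10× the top concentration)
rather than a spurious constant.

## Synthetic data

The generators encode the study conditions rather than tunable
benchmarks. The genome panel defaults to 2 trait-positive plus 3
trait-negative genomes of 60 genes each, one planted candidate family
present (as mutated copies, per-site substitution probability 0.1) in
every positive genome and absent from negatives, a 20% housekeeping
fraction present everywhere, and the rest genome-private; amino acid
composition is uniform with gene lengths 80–160 aa (domain-scale
proteins; lengths are the package's choice since no source states
them). The screen logic is composition-agnostic, so no codon or GC
realism is attempted.

The wild-type tRNA fixture is an explicitly synthetic 76-nt tRNA-like
sequence constrained by every printed sequence fact — acceptor-stem
prefix G,G,G,G,G,C,G,U (so C6 pairs G67) and 3'-terminal A-C-C-A —
with arbitrary but Watson–Crick-consistent arms; no unprinted natural
residue is invented. The twelve-construct panel (wild type, three
6-67 pair swaps, six arm truncations, the ACCA deletion, the
micro-helix) carries its expected verdicts as truth labels.

Peak-list fixtures place true peaks at theoretical fragment-ion m/z
perturbed by Gaussian ppm noise and add uniform decoys kept ≥ 50 ppm
from any true ion, so matching at 20 ppm has an unambiguous truth.
Kinetic fixtures use the assay grids (time 0–40 min; tRNA 0.25–32 µM;
SAM 0.25–64 µM; inhibitor 0–80 µM) with multiplicative Gaussian noise
and three replicates by default. What the fixtures do **not** emulate:
genome evolution beyond i.i.d. substitution, isotope envelopes,
chromatography, adducts, or heteroscedastic instrument noise — so
passing tests demonstrate the correctness of the analysis logic under
its stated assumptions, not robustness to real-instrument artifacts.

## Problem sizes and reproducibility

The suite runs the screen-recovery check over 100 seeded five-genome
panels at the default 60 genes/genome, the localization soundness
check over 100 random parents with 1–3 planted methylations, and the
noisy parameter-recovery checks over 200 replicates per model — sizes
at which all stochastic claims stabilize while the whole suite stays
desk-scale. Every random draw flows through an explicit integer seed
(numpy `default_rng`); identical configs produce identical bytes, and
the CLI writes its resolved configuration next to every output.

## Known limitations

The E-value is uncalibrated (no length corrections), adequate for a
presence criterion but not for borderline-homology inference. The
one-way presence criterion cannot distinguish orthologs from paralogs.
R3 of the substrate rules is descriptive, as discussed above.
Localization from mass alone cannot place a methyl within an unchanged
fragment (mass-shift calls are range-level), and co-eluting isomers
are out of scope, as are isotope-envelope deconvolution and MS/MS
ladders. The kinetics module fits initial-rate and single-phase
models only; progress-curve (substrate-depletion) modeling is out of
scope.
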