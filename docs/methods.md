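# Methods

## Overview

`resevol` studies the linear relationship between a residue's relative
solvent accessibility (RSA) and the selective constraint on it (dN/dS),
and how that relationship is modulated by whole-protein core size and
expression level. The analysis is deliberately two-step: rates are first
estimated independently per RSA bin, then straight lines are fitted to
the per-bin estimates and compared; no joint likelihood across bins is
attempted, trading some efficiency for transparency of each stage.

## Solvent accessibility

Per-atom solvent-accessible surface area is computed by Shrake–Rupley
sampling: 960 deterministic golden-spiral points on each atom's
probe-expanded sphere (probe 1.4 Å), a point counting as accessible when
outside every neighbor's expanded sphere. Van der Waals radii are the
Bondi (1964) element radii (table name recorded in output metadata);
hydrogens are dropped on PDB read. The sphere-point set is fixed, so
results are exactly reproducible; halving the point count changes
per-residue SASA by well under 2% on test fixtures.

Raw SASA is normalized per residue type to the 99th percentile of raw
SASA of that type over a reference set — by default computed empirically
from the profiles being normalized, with a user-supplied table (e.g., a
theoretical maximum-SASA table) accepted instead; values above the
normalizer are capped at 100% and counted. RSA is carried from a template
structure to a homologous target protein through an explicit
template→target residue map, on the assumption that site-specific RSA
depends mainly on backbone conformation and is conserved between close
homologs. Unmapped (gapped) positions are marked missing (NaN, never 0 —
RSA 0 means fully buried) and excluded downstream.

## Binning and groups

A residue record joins a target position's RSA with its aligned codon
column across the four taxa; a record is usable ("gapless") only when
every taxon shows an unambiguous sense codon and RSA is present (N/X
ambiguity and stop codons disqualify a column like gaps do). Proteins are
ranked by average residue RSA (core-size axis) and by an expression proxy
(expression axis) independently; the bottom/top `fraction` (default 1/3;
0.25 and 0.5 supported as controls) become the contrast groups, ties
broken by protein ID for determinism. Residues of each group are
partitioned into RSA bins with edges shared across groups — default ten
10%-wide bins; the packaged fold-change studies use six broad,
occupancy-balanced bins (0, 15, 30, 45, 60, 80, 100) because per-bin
estimates in sparse extreme bins are noisy enough to distort ratio
curves. Each bin's representative x is its members' mean RSA for
per-group fits (midpoint optional); fold-change curves use the bin
midpoint, which is identical across groups by construction. The bin's
codon columns are concatenated, sorted by protein then position, into one
alignment per bin.

## Rate estimation

Each bin's alignment is analyzed under the Goldman–Yang codon model with
a single ω shared by all sites: 61 sense-codon states, single-nucleotide
changes only, target-frequency πⱼ factors, κ for transitions, ω for
nonsynonymous changes, matrix scaled to one expected substitution per
codon per unit branch length. The likelihood is computed by Felsenstein
pruning on the unrooted 4-taxon topology (tips must match the alignment;
the likelihood is root-invariant by reversibility), with alignment
columns compressed to unique patterns and transition matrices obtained
from the symmetric eigendecomposition of the π-rescaled generator.
ω, κ and the five branch lengths are optimized jointly by L-BFGS-B on
log-parameters (relative tolerance 1e-8) from three ω starts
(0.1, 0.5, 1.5). dN and dS are derived from the MLE matrix with
mutational-opportunity site counts — the ω = 1 matrix defines the
nonsynonymous/synonymous site split — so dN/dS equals ω̂ exactly; the
absolute dS scale depends on this convention, but the between-group dS
ratios the analysis relies on do not. Alignments without variation, or
with a synonymous rate estimate below 1e-7, are flagged undefined and
excluded from fits with a warning rather than imputed.

Codon frequencies: the estimator offers F3×4 (position-specific
nucleotide frequencies), empirical-61 (pseudo-counted observed codon
frequencies) and uniform. The pipeline default is **empirical-61**: under
strong within-family codon usage bias (which the synthetic expression
classes have by design), F3×4 cannot represent the stationary
distribution and produced a systematic, RSA-dependent upward bias of ω̂
of order 25% in high-bias groups; empirical-61 removes it at the cost of
more frequency parameters, which the pseudo-count (0.5) regularizes.

An independent Nei–Gojobori (1986) counting estimator — exhaustive
per-codon site enumeration with stop-producing changes excluded,
difference counts averaged over all shortest mutational pathways,
Jukes–Cantor correction — serves as a cross-check oracle for the
likelihood estimator at low divergence; it shares no code with it.

## Bootstrap standard errors

Per-bin standard errors come from a codon-column bootstrap: B resampled
alignments of identical column count (multinomial resampling of pattern
weights, equivalent in distribution to sampling columns with
replacement), each re-estimated, SE = SD of the replicate estimates;
replicates with undefined rates are counted and a majority of them (or of
replicates pinned at the ω search boundary) marks the SE unreliable.
Default `method="full"` (B = 100) re-optimizes every parameter per
replicate, warm-started at the full-data MLE. `method="profile"`
evaluates two shared per-pattern log-likelihood grids — ω with nuisance
parameters fixed at the MLE, and a tree-scale factor at ω̂ — so each
replicate's ω̂_b and scale ĉ_b are grid-argmax values with quadratic
refinement, and dN/dS/dN/dS follow in closed form. Profile replicates are
~100× cheaper and calibrate within ~20–30% of the full method and of the
Monte-Carlo truth (tested); the large simulation studies use it so that
tens of thousands of replicate fits stay tractable. The pipeline can also
share κ and branch lengths across the bins of a group
(`rates_mode="shared_tree"`, profiling only ω per bin) — defensible since
all bins of a group share one underlying species tree — which the null
calibration study uses.

## Line fits and tests

With per-point errors σᵢ known, the straight line minimizes
χ² = Σ((yᵢ − b − m xᵢ)/σᵢ)². Implementation uses the centered form of the
closed-form normal-equation solution (tᵢ = (xᵢ − Sx/S)/σᵢ), algebraically
identical to the textbook sums (s_m² = S/Δ, s_b² = S_xx/Δ with
Δ = S·S_xx − S_x²) but immune to catastrophic cancellation when weights
are large; at least 3 finite points are required and points with
undefined values or non-positive errors are excluded with a warning.
Two lines are compared on a parameter by t = Δ/√(s₁² + s₂²) against the
two-tailed t distribution with n₁ + n₂ − 4 df; one parameter against a
null value with n − 2 df. Fold-change curves divide two groups' per-bin
estimates (delta-method errors, written so that a zero numerator stays
finite; bins with non-positive denominators dropped with a warning) and
are fitted with the same weighted procedure; their natural nulls are
slope 0 (structure-independent effect) and intercept 1 (no effect among
buried residues). p-values are reported unadjusted.

## Synthetic data

The generator emulates the study design with four protein cells
(core size × expression). Per residue, RSA ~ 100·Beta(a, b) with
class-specific shapes — large-core (1.7, 4.3), mean ≈ 28%; small-core
(2.5, 3.6), mean ≈ 41%. The cell's true line is
ω(RSA) = E_e · (b₀ + m_c·RSA), floored at 0.01: core size sets the slope
(m = 0.0050 vs 0.0006 per %RSA), expression rescales the whole line
(E = 1.0 low, 0.40 high), so expression fold changes are uniform in RSA
by construction. Defaults b₀ = 0.12 and the slope pair were chosen —
following the principle that the defaults should yield recoverable,
realistically sized effects at desk scale — so that the ratio of the two
lines stays near-linear over the observed RSA range: the ratio of two
lines saturates early whenever the denominator's slope·100 is comparable
to its intercept, which would make the fold-change intercept/slope
pattern unrecoverable at any realistic precision.

Expression additionally (i) biases the stationary codon distribution
toward each family's preferred codon (weight 1+γ, γ = 4 for high
expression, 0 for low; amino-acid marginals kept uniform) and
(ii) rescales the entire substitution clock by s (0.70 for high
expression) relative to a fixed neutral scale — the simplest mechanism
producing a uniform dS deflation; because rates are normalized to the
neutral (ω = 1, s = 1) flux, branch lengths keep a neutral-clock meaning
across sites and dN/dS remains exactly the configured line. The tree is
the 4-taxon yeast topology with ≈ 1.2 neutral substitutions/codon total
(realistic for the quartet), κ = 2.5. Simulation is exact per-site
Gillespie CTMC sampling along each branch (no matrix exponentials), so
realized synonymous/nonsynonymous event counts are available for flux
checks. Randomness derives from one mandatory seed via per-protein
spawned substreams, making protein-level outputs independent of
processing order.

The expression proxy emitted for each protein is the CAI of its focal
(first-taxon) sequence computed with the generator's own adaptiveness
table (w = 1 preferred, 1/(1+γ) otherwise), closing the loop the real
analysis closes with codonw. What the generator does *not* emulate:
indels (the pipeline consumes gapless columns only), residue-type/RSA
correlation, among-site κ or frequency variation, translational-error or
misfolding mechanisms, and real structural error in RSA transfer. Passing
tests therefore demonstrate the statistical machinery recovers the
generative structure, not that real data satisfy these idealizations.

## Packaged studies

`studies.four_cell_study_config` fixes the four-cell joint-effects study:
64 proteins/cell of 200–300 residues (realistic template lengths, sized
so the packaged effect structure is detectable with adequate power),
broad bins, per-bin ML rates, profile bootstrap B = 200.
Expected pattern: core fold-change slope > 0 with intercept ≈ 1,
expression fold-change intercept > 1 with slope ≈ 0, dS fold-change
intercept > 1 for expression only, and the large-core/low-expression cell
steepest among the four with significant slope differences versus both
single-change cells.

`studies.null_slope_pvalue` is the reduced-size null study behind the
type-I calibration: two groups of 16 proteins × 120 residues simulated
from one identical line (b = 0.15, m = 0.0025), ~16 shared 6%-wide bins
per group (≥ 30 codons each), shared-tree rates with profile bootstrap
B = 400, weighted fits, slope-equality t-test. Bin count matters here:
with bootstrap-known σ the t statistic is nearly standard normal, so the
t-distribution reference is conservative at small df; ~15 usable bins per
group (df ≈ 26) brings the nominal two-tailed 5% test to its expected
operating range.

## Numerical choices and limitations

* ω search bounds [1e-4, 50], κ [0.05, 100], branch lengths [1e-9, 10],
  all log-transformed; multi-start on ω guards against local optima.
* Pattern compression makes likelihood cost scale with unique columns.
* Per-bin ω̂ of a concatenated alignment is a flux-weighted average over
  the bin's site-specific ratios; with heterogeneous ω inside a bin it
  sits slightly above the arithmetic mean (Jensen-type effect), one
  reason broad-but-not-too-broad bins are preferred.
* Tie-breaking by protein ID makes rankings deterministic; tie counts are
  warned about (the synthetic CAI proxy has a lattice structure, so ties
  occur there by design).
* Absolute dS depends on the site-counting convention; only dS ratios are
  interpreted.
* The two-step fit-then-test approach ignores uncertainty correlation
  across bins induced by shared nuisance parameters in shared-tree mode;
  the null calibration shows the slope-equality test still holds its
  nominal level at the packaged study sizes.
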