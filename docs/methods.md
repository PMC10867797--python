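# Methods

## Scope and model

`scfaquant` implements the computational side of a targeted UHPLC-QqQ-MS
assay for gut-microbial carboxylic-acid metabolites — short-chain fatty
acids (SCFAs), their branched isomers, and indole acids — measured as
2-picolylamine (2-PA) amide derivatives in dynamic multiple reaction
monitoring (dMRM) mode, including full ¹³C isotopologue panels for
stable-isotope tracer experiments.

### Derivatization chemistry

Each carboxyl group condenses with 2-PA: the derivative gains C6H8N2 and
loses H2O per site (net +90.0582 Da). Diacids (succinic) derivatize at both
sites. For deuterated standards, the carboxyl O–D is exchangeable and
leaves with the condensation water: exactly one fixed ²H is removed per
derivatized site that carries one. This reproduces the nominal precursors
of the deuterated standards (d4-acetic acid: 3 ²H retained, [M+H]⁺ 154;
d2-indole-3-propionic acid: both chain ²H retained, 282).

Precursors are [M+H]⁺: monoisotopic mass + 1.007276 Da, reported both
exact and nominal (`round`). All 21 panel entries sit ≥ 0.05 from a .5
rounding boundary, so nominal m/z is unambiguous.

### Transitions

The default quantifier product is protonated 2-PA (C6H8N2·H⁺, nominal
109), which contains no acid carbons and is therefore invariant under ¹³C
labeling of the substrate. Registry overrides cover the analytes whose
optimized fragment differs (succinic 191 — neutral 2-PA loss from the
bis-amide; indole-3-propionic 201 — pyridine loss; the deuterated
standards 110/130). Qualifiers are either a fixed registry m/z, a
water-loss fragment (precursor − 18.0106, nominal), or absent. On
isotopologue expansion (k = 0..n acid carbons, precursor +k nominal),
water-loss qualifiers shift with the precursor; fixed-m/z qualifiers are
not expanded because their acid-carbon content is not specified.

dMRM windows default to RT ± 0.5 min, clipped to the 17-min run; the
schedule reports the maximum number of concurrently acquired transitions
(a boundary-event sweep, closing windows before opening coincident ones).

### Isotope distributions

Natural-abundance isotopologue patterns are aggregated by nominal mass
shift — the correct resolution model for a unit-resolution triple
quadrupole, where ¹³C and ¹⁵N substitutions share a +1 channel. Each
element's shift pattern (abundance vs integer mass offset) is raised to
its atom count by repeated convolution and convolved across elements.
Atoms pinned to a heavy isotope (tracer ¹³C, standard ²H) are excluded
from the expansion; their mass is part of the species' monoisotopic mass.
Isotope masses and abundances are IUPAC 2013 representative values pinned
in `isotopes.py` for cross-version reproducibility. Fine isotope structure
is deliberately out of scope.

## Synthetic chromatograms

The simulator exists so that every downstream stage is testable against
known truth without instrument data. Per transition it renders an
exponentially modified Gaussian (EMG) — Gaussian ⊗ exponential, the
standard model for slightly tailing LC peaks — whose closed-form area
provides the integration oracle.

Defaults (package choices; real widths and noise depend on the column,
gradient, and detector):

| parameter | default | rationale |
|---|---|---|
| σ | 0.015 min | UHPLC-realistic width (FWHM ≈ 0.035 min); base-resolves the closest isobaric pair (RT 8.10 vs 8.25 min) at the integrator's 1% bound |
| τ | 0.006 min | mild tailing, tail < 1% of a comparable neighbour's height at 0.15 min |
| sampling | 0.01 min | ≥ 10 points across the narrowest peak; trapezoid error ≪ 0.5% |
| response factors | 1e6 / geometric mid of each calibration range | mid-range areas ≈ 1e6 counts |
| qualifier response | 0.3 × quantifier | typical secondary-fragment yield |
| noise | 20 counts SD, baseline 100 counts | high-S/N targeted assay |
| acetate background | 5e4 counts·min (≈ 2.5 μg/mL equiv.) | persistent environmental acetate |

Modeled features: (1) each species' natural-abundance bleed into heavier
label channels (full distribution, so a species' own channel carries its
monoisotopic fraction p0); (2) the acetate background, present identically
in *every* injection — calibrants, samples, and blanks — because it is
environmental contamination, which is exactly what makes blank subtraction
the correct remedy; (3) a per-sample multiplicative matrix factor applied
equally to analytes and internal standards, the effect IS-ratio
calibration is designed to cancel; (4) cross-talk between isobaric
analytes whose identical (precursor, product) transitions have overlapping
RT windows.

Calibration series are log-spaced over each analyte's own range (e.g.
acetate 5–500, caproate 0.001–1 μg/mL), all analytes pooled per level,
with the internal-standard mix (100/50/10 μg/mL stocks, 1:10 v/v spike →
11-fold dilution) in every injection.

Not modeled (hence not demonstrated by passing tests): retention-time
drift, detector saturation, carryover, co-eluting interferences sharing a
transition within one peak, electrospray ionization nonlinearity, and
tracer impurity (< 100% ¹³C enrichment).

## Peak integration

Deterministic and intentionally simple. Baseline = median of the
lowest-decile intensities in the window's flanks (outer 15% each side).
Candidate apexes are local maxima (prominence ≥ 3× the robust flank noise
SD, width ≥ 3 samples — a single-sample spike is not a chromatographic
peak) within ±0.1 min of the scheduled RT; constraining the apex to the
schedule is what separates isobars sharing a window, and a trace
containing only a neighbour's flank yields `no_peak` rather than a stolen
area. Plateau ties resolve to the earliest time. Bounds walk outward from
the apex until intensity ≤ 1% of height (window edge ⇒ `edge_truncated`);
the area is the trapezoidal sum of baseline-subtracted, zero-floored
intensities on the native grid. `no_peak` is flagged when the apex rises
less than 3 noise SDs above the flank median. At that threshold an extreme
noise draw occasionally qualifies as a peak (it carries a low SNR and is
normally removed downstream by blank correction); raising the threshold
trades this against sensitivity at the LOD.

## Quantitation

Signals are quantifier peak areas. Per channel, the mean blank area is
subtracted (floored at zero, flagged). The analyte/IS area ratio is
regressed on concentration by weighted least squares — 1/x weighting by
default, since ranges span up to three orders of magnitude and unweighted
fits let the top standards dominate; `none` and `1/x²` are available.
Unknowns are read off the k = 0 curve for every label channel (the labeled
species' response is assumed equal to the unlabeled derivative's).
Flags: `below_lod`, `below_range`, `above_range`, `clipped_negative`,
`is_missing`. LOD = 3.9 · SD(blank signals) / slope, computed in the
ratio domain; CV = sample SD / mean over replicates; spike recovery =
measured / (base + nominal spike).

### Natural-abundance correction

Channel k of an analyte receives, besides the k-labeled species, the
natural-abundance bleed of every lighter species j < k. Because all
channels are quantified against the unlabeled calibration curve (whose
slope already contains the monoisotopic fraction), each species
contributes to heavier channels in proportion to its distribution
*relative to its own monoisotopic channel*. Ascending in k:

    c_corr[k] = c_obs[k] − Σ_{j<k} c_corr[j] · M[k,j] / M[j,j]

with M[i,j] the distribution of the j-labeled derivative shifted by j
(lower-triangular, diagonal = each species' p0). This is algebraically a
unit-diagonal triangular solve, hence exact on bleed-consistent input and
idempotent (re-inflating a corrected vector and correcting again is a
no-op). Negative results floor at zero with a flag — concentrations are
physical. A `monoisotopic_only` mode subtracts only the unlabeled
species' distribution — the minimal correction when only unlabeled
background matters; the full cascade is the default because it is exact when
several labeled species coexist. Residual bias of the cascade is the
p0(j)/p0(0) = 0.9893⁻ʲ factor (+1.1% per label, +2.2% at ¹³C₂), well
inside the assay's validation bounds; a fully exact variant would require
per-isotopologue calibration curves, which the assay does not use.

## Statistics

Two-group comparisons: two-sided Student's t-test, pooled variance by
default ("Student's" read literally; Welch via flag). Multi-group:
one-way ANOVA with Tukey HSD pairwise contrasts. Significance stars:
* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001. Dixon's Q (r10 = gap to
nearest neighbour / range, n = 3..10, default 95% confidence, single
pass, at most one rejection) screens small replicate sets; r10 at 95% is
the common convention for triplicates. Degenerate inputs are defined:
zero-variance equal groups give p = 1 (unequal: p = 0), a zero-range
replicate list keeps all values.

## Problem sizes

Simulated studies use 5–6 calibration levels, 4 pseudoblanks, 6
replicates, and single-figure labeled samples at 0.01-min sampling over
±0.5-min windows; these sizes make every oracle comparison exact enough
to test the stated tolerances while a full run (simulate → integrate →
quantify → correct) completes in seconds.
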