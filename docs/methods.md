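# Methods

## Sequence conventions

All sequences are held as uppercase DNA; RNA input is normalized (U→T).
Codon and nucleotide positions are 1-based with closed intervals, so a
10-codon window starting at codon 229 of the 239-codon eGFP ORF spans
codons 229–238 and is the last admissible placement (230 placements in
total). A terminal stop codon is trimmed on load and recorded; windows
never touch the stop, and an internal stop is rejected with its position.

## Elongation-rate table

No published per-codon elongation-rate set accompanies the experimental
design this package models, so the default table is derived from human
codon-usage frequencies: the rate of a codon is its relative synonymous
codon usage (usage divided by the mean usage of its synonym family), which
has mean exactly 1 over the 61 sense codons. This preserves the ordinal
optimal/non-optimal structure that window design needs without claiming
absolute dwell times; it is a stand-in, clearly labelled, and any
user-supplied TSV (`codon`, `rate` columns) is accepted. The simulator
multiplies the table by `omega_scale` (default 5 codons/s) to set absolute
time units.

`slowest_synonym` maps each codon to the minimum-rate member of its family;
ties break to the lexicographically smallest codon for determinism, and
single-codon families (Met, Trp) are returned unchanged.

## siRNA guides and seed matching

The two bundled guides are **synthetic reconstructions**: exact reverse
complements of the eGFP ORF at the documented target positions (19-nt sites
starting at nucleotides 122 and 433). They reproduce the target-site
geometry exactly but are not the vendor's oligo sequences, so
sequence-peripheral observations (e.g. the genome-wide distribution of
incidental seed matches along the ORF) should not be read off them.
Seed matching uses guide positions 2–8 (the standard minimal 7-mer),
perfect complementarity, no G:U wobble; the span is configurable. A full
site starting at s with guide length m implies a seed match at s + m − 8,
and such hits are flagged `full`.

## Ribosome-traffic model

The exclusion process: ribosomes are extended particles of `footprint`
codons (default 10 ≈ 30 nt). In A-site coordinates, distinct ribosomes keep
gaps ≥ footprint; initiation (rate α_on, default 0.1/s) places an A-site at
codon 1 iff codons 1..footprint are clear; a ribosome at codon i hops to
i+1 at the rate of the codon being entered iff the gap ahead permits;
drop-off (γ, default 2×10⁻⁴/s) removes any ribosome; termination (α_off,
default 2/s) removes a ribosome from the **last codon** — the A-site walks
all the way to codon L, with positions beyond the lattice treated as clear.
Defaults are physiological orders of magnitude; the qualitative density
signature of slow windows is robust to the initiation rate within such
limits.

Density is reported in the A-site convention (probability codon i is an
A-site) with a parallel coverage profile (codon covered by any part of a
footprint); which of the two a given plotting convention uses is not
standardized, so both are exported.

Simulation is the Gillespie direct method (numba kernel), burn-in
defaulting to 10× the empty-lattice traversal time, then `sample_time`
split into 20 batches. Per-codon standard errors come from batch means;
**regional** means use the batch-means of the regional average, because MC
noise is strongly correlated along the lattice (flux fluctuations move
whole regions coherently) and summing per-codon errors would understate the
uncertainty several-fold.

The exact oracle enumerates all lattice configurations (gap-constrained
A-site sets), builds the full generator matrix and solves the stationary
linear system (sparse LU; capped at 10⁵ configurations). It mirrors the
kernel's dynamics exactly and anchors the Gillespie tests; it also proves
small-instance monotonicity (slowing a window never increases flux)
exactly, without Monte-Carlo ambiguity.

### Flux-matched selection and the downstream density signature

Variants are ranked by |J − J_ref|/J_ref (ties by window position).
Selecting flux-matched variants has a structural consequence: downstream of
a window the steady-state density is ≈ J/ω, so variants chosen for matched
flux can reduce downstream density only by their (small) true flux deficit.
The slow window itself elevates density strongly at and immediately
upstream of the window — tens of Monte-Carlo standard errors — while the
downstream comparison is an inequality (variant ≤ reference) that holds
within MC error at matched flux. The strict monotone flux decrease under
window slowing is established separately through the exact oracle.

## Three-stage expression model

The closed form of the cascade mRNA → nascent → mature is
`scale · k_m · k_TL · m₀ · f[δ, β+k_m, β](t − t₀)`, where `f[a,b,c]` is the
second divided difference of x ↦ exp(−x·s). The divided-difference view
gives the degenerate limits directly: nodes closer than a relative 10⁻⁸ are
merged and evaluated by the confluent formula (L'Hôpital limits), keeping
the trajectory accurate to ~10⁻⁸ relative everywhere including the
δ ≈ β + k_m neighbourhood. Values at and before t₀ are exactly zero.

Fitting fixes k_m (default 1.2/h) and β (default 0.03/h) — in the
laboratory these come from independent translational-arrest measurements;
the defaults are order-of-magnitude eGFP maturation/stability values and
are configurable. Free parameters are δ (bounds 10⁻⁴–20/h), the amplitude
`scale·m₀·k_TL` (the only identifiable combination, profiled out linearly
at every step — variable projection), and t₀ (bounds 0–5 h; trajectories
begin near zero and onset varies per cell). Initialization: t₀ from the
first 5%-of-peak crossing, δ from the late-phase log-slope when the tail
decays (else 0.1/h), amplitude from the peak; up to 5 deterministic jittered
restarts, stopping early once a restart fails to improve a good fit by >1%.
Least squares is unweighted. Trajectories whose full range is within 7
robust noise scales (noise estimated from successive differences) are
flagged non-expressing and never fitted; all-zero input falls in this
class. Asymptotic standard errors come from the (δ, amplitude, t₀)
Jacobian at the optimum.

## Synthetic cells

The generator emulates a dual-reporter transfection experiment on a
10-minute grid over 30 h. Per cell: a shared lipoplex count
N ~ Poisson(3) (zeros redrawn); per channel m₀ ~ Poisson(N·150) conditioned
≥ 1; k_TL lognormal (mean 50 proteins/mRNA/h, CV 0.4); δ lognormal around
the channel base rate (eGFP 0.15/h, CayRFP 0.12/h; CV 0.4) times the
condition's multiplier, drawn independently per channel; onset
t₀ ~ U(0.25, 2) h shared by both channels. The shared N induces a positive
cross-channel correlation of m₀·k_TL while δ stays uncorrelated — the
correlation structure characteristic of dual-reporter data. Measurement
noise is multiplicative lognormal (CV 5%, mean-1 parameterization) plus
additive Gaussian background (σ = 1 a.u.); a 5% fraction of cells is
non-expressing (baseline only), exercising the fitter's rejection path.
The cell-to-cell CVs are generator choices for recovery benchmarks, not
measurements; and the generator makes no attempt at image-level realism
(no segmentation errors, photobleaching, division or death).

Condition tables are plain records (construct × siRNA × cell line ×
experiment) whose only mechanistic content is a δ multiplier (and
optionally a k_TL multiplier) on the eGFP channel — sufficient to encode a
full design of constructs, control/targeting siRNAs and cell lines.

## Planted end-to-end study

The recovery study builds a six-construct panel — unmutated eGFP plus
windows at codons 48, 64, 119, 160 and 229 (four canonical early/mid/late
placements plus one mid-late position for spread) — simulates their
density profiles, and derives the planted biology deterministically from
those profiles: without functional siRNA, a construct's stability fold
change decreases exponentially in its mean early-ORF (first 70 codons)
density excess, scaled so the densest construct reaches 0.66; under siRNA,
all eGFP mRNAs are destabilized tenfold, mitigated by a protection factor
increasing linearly in the same early-density excess up to 2.2. This plants
the early-negative / late-positive density–stability correlation structure
as ground truth.

The pipeline then runs blind: trajectory generation → per-cell fits →
normalization ladder → construct-level fold changes. Recovery intervals are
percentile bootstraps of the **entire ladder** — every group entering a
ratio (construct and reference, control and targeting siRNA) is resampled —
because the reference medians contribute as much uncertainty as the
numerator groups; intervals use the 99% level since fifteen planted values
are checked simultaneously. The correlation sign structure is read out at
the earliest and latest window regions (density pooled over the window
before correlating): those are the positions where the panel has real
cross-construct density variance, while codons untouched by any window
carry only Monte-Carlo noise and an r made of six noisy points is
uninformative there.

Default problem sizes — 120 cells per condition, 10⁵ s of sampled
simulation time per study profile, 1000 bootstrap draws — keep the full
study around a minute on one CPU while leaving all planted effects several
interval-widths away from null.

## Statistics

Mann-Whitney U is exact (own null-distribution recursion) for tie-free
pooled samples up to n = 16, otherwise the normal approximation with tie
and continuity corrections; two-sided p = 2·min(tail probabilities), capped
at 1. Star labels: **** p<10⁻⁴, *** p<10⁻³, ** p<10⁻², * p<0.05, ns
otherwise, with boundary values in the less significant class. P-values are
reported raw (no multiplicity correction), matching common practice for
per-construct panels; the star mapping makes that explicit. MAD is unscaled
(no 1.4826 factor). Correlation profiles use the per-construct median as
the central stability measure (per-cell correlation would inflate n; the
choice is switchable), flag zero-variance positions as undefined, and
optionally attach t-distribution p-values.

## Known limitations

- The elongation-rate table is ordinal, not calibrated; absolute densities
  and fluxes are in model units.
- The kinetic model has no transcriptional component, no photobleaching,
  and absorbs the fluorescence calibration into the amplitude.
- Survivorship: under strong knockdown a few percent of cells fall below
  the expression threshold and are dropped with counts; medians of the
  survivors are slightly stability-biased, as in the corresponding real
  experiments.
- Passing recovery tests show the pipeline recovers effects of the planted
  form under the stated noise model — not that real microscopy data meet
  those assumptions.
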