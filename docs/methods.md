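# Methods

This note defines the models and estimators implemented in `chromarch`,
the defaults and why they were chosen, and what the synthetic benchmark
does and does not establish about real data.

## Coordinate model

Coordinates are 0-based half-open throughout; bins are labeled by start
and the last bin of a chromosome may be short. The centromere is an
interval (matching BED annotations); the bins overlapping it are
"centromeric" for masking purposes, while rescaling and arm assignment
anchor on its midpoint. Each bin carries its arm (P left of the
centromere midpoint, Q right), its distance from the centromere midpoint
`d`, its distance from the nearest chromosome end `e`, and the relative
arm position `r = d / arm length` evaluated at the **bin midpoint**, so
`r` spans (0, 1) at half-bin offsets and is monotone along each arm.
A chromosome is eligible for aggregate analysis iff both arms span at
least two bins (metacentric/submetacentric); acrocentric chromosomes are
excluded from aggregation but retained everywhere else. The telomeric
extent defaults to one bin.

Region sets per eligible arm: CEN is `r < cen_fraction`, TEL is
`r ≥ 1 − tel_fraction`, ARM the rest, with a guaranteed minimum of one
bin per set (defaults `cen_fraction = tel_fraction = 0.1`). How far
"telomeric" extends is not something the aggregate-analysis literature
fixes; a fraction of arm length keeps the sets meaningful across
chromosome sizes.

## Normalization

**ICE balancing.** Symmetric iterative correction: divide by the
marginal over its mean until the maximum relative marginal deviation is
below `tol` (default 1e-6, `max_iter` 200). The bias gauge follows the
mean-marginal convention; an already-balanced matrix is a fixed point
and is returned unchanged. All-zero bins and the lowest-coverage
quantile of nonzero bins (default 2%) are masked first; a disconnected
all-zero unmasked block is reported as a convergence failure, never
silently.

**Observed/expected.** Cis: balanced values divided by one pooled
genome-wide decay curve (mean balanced value per bin separation); the
pooled curve is far more stable than per-chromosome curves on small
genomes, and a per-chromosome option exists. Trans: values divided by
the per-chromosome-pair block mean, computed on **raw** counts —
equivalently, a balanced-layer expectation proportional to
`1/(b_i·b_j)`. The reason is a genuine artifact: marginals vary along a
chromosome because of the cis distance decay (end bins see fewer close
neighbors), and balancing that *biological* variation away inflates the
balanced trans values of chromosome-end bins, which fakes telomere
clustering in any flat-expectation trans O/E. Taking the trans
expectation to honor the coverage profile removes the artifact exactly
for maps without technical bias, at the cost of absorbing any genuinely
separable (rank-1) trans preference; on real data with strong technical
coverage bias this choice conflates the two, which is a documented
limitation. Missing values propagate as NaN; every downstream mean is a
masked mean, never zero-filled.

## Aggregate chromosome analysis

Each eligible chromosome is mapped onto a common axis of `2m` bins
(default `m = 20` per arm): the P arm linearly onto 0..m−1 with the
telomere at 0, the Q arm onto m..2m−1 with the telomere at 2m−1. Every
rescaled cell is the fractional-overlap-weighted masked mean of the
source O/E cells mapping into it, so the transform is exact averaging
(identity when arms already have m bins, plain block means for integer
ratios). The aggregate cis map is the unweighted mean over eligible
chromosomes; the trans map is the mean over unordered eligible pairs,
each pair block rescaled on both axes and symmetrized. Unweighted
averaging reflects that aggregation treats chromosomes as replicates of
a common architecture, not as length-weighted contributions.

## Architecture scores

The four scores are this package's concrete instantiation — the
upstream literature describes the architectures pictorially and via an
aggregate-analysis procedure whose exact score formulas are not public.
Design requirements: zero expectation under a structure-free map,
invariance to global count rescaling, and *specificity* (each score
responds to its own architecture component, not its neighbors).

On the rescaled axis let CEN be the central `⌈2m·cen_fraction⌉`
positions around the centromere, TEL the first and last
`⌈m·tel_fraction⌉`, ARM the rest, `r_u` the relative arm position of
rescaled index u, and the **band** B the cell set
`|r_u − r_v| ≤ w/m` with `w = ⌈m·tel_fraction⌉`. The band covers both
the main diagonal and the P/Q mirror anti-diagonal of the trans map —
all cells whose two positions sit at the same relative point of an arm.

- `s_cencen = log2( mean CEN×CEN / mean (B ∩ ARM×ARM) )`
- `s_teltel = log2( mean TEL×TEL / mean (B ∩ ARM×ARM) )`
- `s_centel_axis = log2( mean (B ∩ ARM×ARM) / mean (B̄ ∩ ARM×ARM) )`
- `s_ct = log2( mean balanced cis (off-diagonal) / mean balanced trans )`

The matched-band control is the load-bearing choice. Centromere bins of
different chromosomes all share `r ≈ 0` (telomere bins `r ≈ 1`), so a
polarized-axis signal mechanically enriches CEN×CEN and TEL×TEL; a naive
ARM×ARM denominator would convert a pure axis signal into spurious
clustering scores. Measuring each cluster block against band cells at
ARM positions (same |Δr|, different absolute position) cancels the axis
component; restricting the control to ARM×ARM keeps clustering-kernel
tails out of it. The plain-ARM control remains available
(`control="arm"`). An alternative axis readout via CEN×TEL corner
depletion was considered and rejected as redundant with the band
formulation.

`s_ct` deliberately uses balanced counts, not O/E: it measures the
cis/trans partition of the signal itself. It is therefore *not*
independent of trans clustering — at fixed sequencing depth, strong
trans clustering (in particular a genome-wide polarized axis) must
depress the cis share, so Rabl-dominant maps score negative `s_ct`.
That coupling is physical, not an estimator defect, and it is the
reason Rabl and territory scores move in opposite directions along a
developmental series. Scores over empty regions are reported missing,
never zero, and scores are comparable only within one `(m,
cen_fraction, tel_fraction)` parameterization.

## Subcompartments

**Compartment eigenvector.** Per chromosome, E1 is the leading
eigenvector of the Pearson correlation matrix of cis O/E rows over
usable bins. Bins within `cen_flank` (default 500 kb) of the centromere
interval can be masked first (default on): centromere-proximal Rabl
structure polarizes the eigenvector along the arm, and masking
demonstrably reduces the correlation between E1 and centromere distance.
The sign is oriented positive-active by correlation with the active
mark when tracks are given; otherwise the largest-magnitude entry is
made positive (arbitrary but deterministic). Chromosomes with fewer
than 10 usable bins report E1 missing.

**State inference.** Each usable bin's profile is its trans O/E vector
to all bins of other chromosomes. Profiles are compared by
pairwise-complete Pearson correlation; the correlation matrix is
reduced to its top 10 eigenvectors (scaled by √eigenvalue) and
clustered by k-means with K=5 and 20 restarts at a fixed seed. K is
fixed at 5 to match the A1/A2/B1/B2/B3 scheme; no model selection is
attempted. Two technical guarantees: eigenvector signs are fixed by a
permutation-invariant rule and rows are fed to k-means in a canonical
(lexicographic) order, so the inference is exactly equivariant under
bin permutations and deterministic given the seed.

Before correlation, profiles are **positionally detrended** (default
on): every trans cell is divided by the mean of its arm-position
band pair (10 bands of `r`). All Rabl components are smooth functions
of the two bins' arm positions, and without detrending a
Rabl-configured map drives the clustering into position bands rather
than compartments — the trans analogue of the centromere-masking
problem in eigenvector calling. Detrending removes position-driven
structure while leaving the (position-independent) compartment
checkerboard intact; its cost is partial absorption of the planted
positional enrichment of B2/B3, visible as slightly reduced recovery of
those states.

**Labeling.** States are pooled by the sign of their mean E1 (A if
positive); if the pools are not of size 2 and 3, the states with mean
E1 nearest zero move to the deficient pool (equivalently: the top two
states by mean E1 form the A pool). Within A, the higher mean active
mark is A1. Within B, the highest polycomb mark is B1; of the remaining
two, the more repeat-dense is B2, with near-ties (< 0.05) broken toward
the centromere-proximal state; the other is B3. Without tracks the call
falls back to plain A/B and is flagged. The per-state evidence table
(bin counts, mean E1, mean track levels) is always reported so a
reviewer can audit the mapping.

**Compartmentalization strength.** For label s:
`strength(s) = log2( mean O/E over pairs both labeled s / mean O/E over
pairs with exactly one bin labeled s )`, restricted to cis pairs at
least 2 Mb apart plus all trans pairs. The long-range restriction (the
conventional short/long split at 2 Mb) keeps residual distance-decay
structure out of the ratio. Labels with fewer than 5 bins report
missing.

## Synthetic data

The generator is the package's ground-truth engine. Expected rates are

```
mu_ij = Z · base_ij · comp_ij · arch_ij          counts ~ Poisson(mu)
```

with cis `base = (|mid_i − mid_j| + s0)^(−alpha)` and flat trans base
`b_t`; `comp = 1 + epsilon·(affinity[s_i,s_j] − mean affinity)`, times
`(1 + a1_boost)` for A1–A1 pairs; `arch` adds a Gaussian wing kernel in
`|d_i − d_j|` on opposite-arm cis pairs and, on trans pairs,
exponential centromere/telomere clustering kernels in `d_i + d_j` /
`e_i + e_j` plus a Gaussian axis kernel in `r_i − r_j`; cis is finally
multiplied by the territory factor `t ≥ 1`. `Z` fixes the expected
total over unique pairs. Functional forms are invented — the real
architectures are defined pictorially — and are the simplest shapes
that reproduce each visual signature with a single weight each, which
is what makes the monotonicity and specificity tests meaningful.

Key defaults, with rationale:

| parameter | default | why |
|---|---|---|
| genome | 3 chromosomes × 100 bins of 100 kb, metacentric | large enough for 2 Mb-threshold statistics, seconds-scale to simulate |
| `alpha` | 1.0 | typical Hi-C decay regime |
| `s0` | one bin (100 kb) | regularizes the diagonal |
| `b_t` | mean cis base rate | the structure-free genome mixes uniformly, so the null territory score is 0 by construction |
| `sigma_wing` | 1 Mb | wings are broad, arm-scale features |
| `lambda_clust` | 500 kb | ~10% of a desk-scale arm: clustering stays pericentromeric/telomeric (the phenomenon being modeled) instead of bleeding over half the arm into the control regions |
| `sigma_axis` | 0.15 r-units | a few rescaled bins of alignment width |
| `total_contacts` | 1e7 | deep enough that sampling noise is negligible against 0.1-level calibration bounds |
| `state_affinity` | A/B block matrix (0.5 within pools) | plants the compartment checkerboard whose leading eigenvector separates A from B, with the five states as nested refinements — the structure subcompartment callers assume |
| track means | A1 > A2 active/expression; B1 polycomb; B2/B3 het/repeats, B2 more repeat-dense | encodes the known epigenetic ordering of the five states |
| states | geometric blocks, mean 5 bins; B2 ×3 likelier near centromeres, B3 ×3 near telomeres | contiguous domains with the pericentromeric-B2/telomeric-B3 association |

Presets: `null` (everything off), `rabl` (wings + clustering + axis at
weight 5, `t = 1.2`, `epsilon = 0.3`), `ct` (clustering off, `t = 4`,
`epsilon = 0.7`, `a1_boost = 1`), `mixed` (intermediate — the two
families do co-occur in real nuclei, and the preset is illustrative
only). A developmental series interpolates weights, `t`, `epsilon` and
`a1_boost` linearly between two presets with a distinct seed per stage.
The unit-diagonal constraint on the affinity matrix is kept; increasing
A1 self-association across a series is expressed through `a1_boost`.

What the generator does **not** emulate: technical coverage bias (so
ICE is exercised on biological marginal variation only), overdispersion
(counts are Poisson, not negative binomial — no downstream stage needs
the extra variance), TADs, loops, polymer/loop-extrusion physics, or
replicate-level biological variability. Passing the benchmark therefore
shows the estimators recover what they claim from maps with the right
first-order statistical structure; it does not certify performance
against real-data artifacts such as mappability bias or
restriction-fragment effects, which are handled upstream of this
package.

## Series statistics

Interaction fractions (cis < 2 Mb, cis ≥ 2 Mb, trans) are computed on
raw counts — they describe the composition of the sequencing signal,
not the normalized map — and sum to 1 per sample. Cross-stage
correlation uses the Pearson test (Spearman available given the tiny
n), always reporting n alongside r and the exact t-based two-sided p,
with no multiple-testing correction on the two-entry table. Constant
inputs report r as missing rather than 0.

## Problem sizes and determinism

The benchmark battery runs on the desk-scale genome (300 bins) at 10⁷
contacts per map, with 5 seed replicates for every median or
fraction-of-replicates claim and 5 stages per series; the full
acceptance run completes in well under a minute on one CPU. Every
random draw flows from a single integer seed (per-stage and per-task
seeds are derived additively), and the pipeline's file outputs are
bytewise reproducible for a fixed config and seed.

## Known limitations

- Score formulas are this package's own instantiation; absolute values
  are comparable only within one parameterization, not across tools.
- The trans O/E expectation treats marginal variation as biological;
  on real data with technical bias this undercorrects (see
  Normalization).
- `s_ct` is depth-composition coupled to trans clustering (see
  Architecture scores).
- Subcompartments are called per sample independently; cross-sample
  label agreement is reported rather than enforced, and no
  reference-profile adjustment (as is done for human data against
  GM12878 calls) is provided — the evidence table is the audit
  mechanism instead.
- Positional detrending slightly attenuates genuinely
  position-associated compartment signal (B2/B3).
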