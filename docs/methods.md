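# Methods

## The model

Chromatin is represented as a bead-spring polymer, one bead per fixed
genomic bin (nominally 100 kb), in reduced units: bead diameter
sigma = 1, thermal energy k_B T = 1 at the reference temperature T = 1.
The potential energy is

```
U(r) = U_HP(r)
     + sum_{k >= l} alpha_kl  sum_{i in k, j in l} f(r_ij)
     + sum_{d=3}^{d_cutoff} gamma(d) sum_i f(r_{i,i+d})
```

* `U_HP` is a generic homopolymer backbone: finitely-extensible (FENE)
  bonds between consecutive beads of one chromosome (k_bond = 30,
  R0 = 1.5 sigma), a bending term k_angle (1 - cos theta) with
  k_angle = 2, and a soft-core excluded-volume repulsion
  (1/2) k_ev (r_ev - r)^2 for r < r_ev = 1 sigma with k_ev = 100
  acting on every bead pair. The soft core is finite at r = 0, so
  topology changes are rare but not impossible — intentional for
  equilibration at coarse resolution.
* The second term drives A/B phase separation: `alpha_kl` (k_B T) is
  the contact energy between chromatin types k and l, applied to all
  inter-chromosomal pairs and to intra-chromosomal pairs at separation
  d >= 3 bins (matching where the lengthwise-compaction term starts, so
  the two terms share one pair-eligibility rule).
* The third, "ideal chromosome" term depends only on genomic distance
  d and models motor-driven lengthwise compaction; `gamma(d)` is
  defined for d = 3..d_cutoff (default d_cutoff = 50 bins or the
  chromosome length, whichever is smaller).
* `f(r) = (1 + tanh(mu (r_c - r))) / 2` is the crosslink kernel with
  mu = 3.22 / sigma and r_c = 1.78 sigma (both configurable); the same
  kernel renders in-silico contact maps, so energy features and map
  features live on one scale.

Forces are analytic. Because the non-bonded terms all factor through
f(r_ij), a per-pair coefficient matrix C_ij (alpha of the pair types
plus gamma of the pair separation) is precomputed once per system, and
each force evaluation reduces to elementwise work on the distance
matrix.

## The nucleus

The envelope is a spheroid whose polar axis joins two anchoring poles:
confinement is a half-harmonic penalty (1/2) k_wall (s - 1)^2 on the
spheroidal coordinate s = (x_ax / (L/2))^2 + (r_eq / R_eq)^2 for s > 1,
with k_wall = 50 k_B T / sigma^2. Telomere beads are tethered by
harmonic springs (k_anchor = 50) to the pole at -L/2 on the axis,
centromere beads to the pole at +L/2; tether points sit one bead
diameter inside the wall (`anchor_inset = 1 sigma`) so anchored beads
rest against, rather than straddle, the envelope. Polarized anchoring
is what folds each metacentric chromosome into the hairpin (Rabl)
arrangement; setting k_anchor = 0 removes it.

Nuclear deformation rescales the pole separation by (1 + strain); by
default the equatorial radius rescales to conserve volume (a
fixed-equator variant is a switch). Anchor poles move with the wall.

The reference single-chromosome geometry uses L = 38 sigma for a
3102-bead chromosome at 100 kb/bead; desk-scale systems keep that
volume fraction (5.7%) by scaling L with the cube root of the bead
count. Deformation experiments instead use a nucleus at genome-like
packing (fill fraction 0.23, the value implied by a ~12,800-bead
genome in the same 38-sigma envelope): in a dilute nucleus wall strain
mostly changes the chain's own density, whereas at genome packing it
couples to chain conformation, which is the regime the deformation
analysis addresses.

## Dynamics

Langevin dynamics with the BAOAB splitting, timestep 0.01 reduced time,
friction 0.1, bead mass 1; thermal noise is seeded and trajectories are
bit-reproducible for a fixed configuration. Initial layouts are either
a folded hairpin (two helical arms per chromosome spanning the poles,
telomeric ends at one pole, centromere at the other) or an unpolarized
random coil near the centre; both are followed by a capped-step
steepest-descent relaxation (300 steps, max displacement 0.05 sigma per
step) that removes placement strain before integration. Quenching runs
consecutive segments at non-increasing temperatures.

## Maximum-entropy training

Training matches the simulated ensemble's sufficient statistics to a
target map: mean contact probability per unordered type pair and per
genomic distance d = 3..d_cutoff. Each iteration simulates the current
parameters (continuing from the previous iteration's final frame, with
a short within-iteration burn-in excluded from statistics), renders the
contact map as the frame-average of f(r_ij), aggregates both maps, and
updates

```
alpha_kl <- alpha_kl + eta (<f>_sim,kl - <f>_target,kl)
gamma(d) <- gamma(d) + eta (<f>_sim,d  - <f>_target,d)
```

so over-contacting features become more repulsive; simulated statistics
equal to the target are a fixed point. Defaults: eta = 8 k_B T per unit
contact-probability mismatch, decayed stepwise (halved after 8
iterations, et cetera), with per-feature steps clipped at 0.3 k_B T per
iteration. The learning rate is set by the scale of the problem: the
observed statistic mismatches are of order 0.01-0.1 while the couplings
to be recovered are of order 0.1-1 k_B T, so the effective inverse
susceptibility is around 5-20; eta = 8 with clipping recovers
0.9-k_B T couplings within the 20-iteration budget while remaining
stable. Training starts from the pure homopolymer (alpha = gamma = 0)
and from an unpolarized coil; starting from a pre-folded layout would
make the initial homopolymer statistics spuriously resemble a
Rabl-like target and silence the early gradients.

Two estimator choices matter on a workstation budget. First, a single
trajectory visits few independent global conformations, so ensemble
contact maps used as targets or for evaluation are averaged over
several independently seeded replicas (default 6 x 5000 steps after
2000 equilibration steps each). Second, the stochastic-gradient
iterates fluctuate with each iteration's sampling noise; the evaluation
ensemble therefore uses the average of the last 10 iterations'
parameters (tail averaging) rather than the final iterate. Experimental
targets in arbitrary frequency units are first rescaled so their mean
nearest-neighbour contact matches the simulation's (then clipped to
[0, 1]); synthetic targets already in probability units skip this.

## Contact-map processing

Knight-Ruiz balancing uses the Newton/inner-CG scheme with a Sinkhorn
fallback, operating on the unmasked block (bins with zero marginals are
masked) and normalizing so row sums agree to a relative tolerance
(default 1e-6) while preserving the mean contact frequency. A/B
compartments are the sign of the leading eigenvector of the
per-chromosome Pearson correlation matrix of the observed/expected map
(O/E by default; raw balanced counts are a switch). The eigenvector
sign is oriented so A bins have the higher mean accessibility when a
track is given; otherwise the sign group with the larger summed
within-group O/E enrichment becomes A. Chromosomes without contact
structure (constant correlation, or an eigenvector without sign
changes) yield all-NA labels.

## Ensemble analyses

* Orientation order O_OP(d): mean over frames and positions of the dot
  product between unit vectors spanning beads [i, i+4] and
  [i+d, i+d+4], within one chromosome; its spectrum is the magnitude of
  the DFT of the mean-subtracted profile, reported against period in
  Mb, with peaks above 3x the median amplitude.
* Cylindrical density: per-category histograms of distance from the
  polar axis, normalized per shell volume and frame count, optionally
  in five axial sections.
* Exposed area: direction sampling on a sphere of radius
  (bead + probe) around each bead with probe radius = bead radius
  (0.5 sigma); a direction is occluded when its test point falls within
  the contact radius of another bead. 92 golden-spiral directions by
  default; values in [0, 1] and validated against the two-sphere
  spherical-cap formula.
* Territory metrics: gyration-tensor elongation sqrt(l_max/l_min),
  cross-chain proximity fraction (beads within 1 sigma of another
  chain), centromere-telomere centroid distance, and coarse-backbone
  (10-bead block average) contour length.
* Unit conversion assumes constant chromatin density across bin sizes:
  sigma(res) = 0.165 um x (res / 50 kb)^(1/3), giving
  sigma_100kb = 0.20789 um.
* Accessibility classification: inclusive 95th/5th percentile
  thresholds on non-missing values; ties fall into the extreme classes.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not sequencing artifacts:

* Genomes: alternating A/B blocks (default 20 bins, +/-20% seeded
  jitter), telomere beads at both chain ends, a centromere block at
  mid-chain.
* Parameter styles: `aedes_like` has strong short-range lengthwise
  compaction (gamma amplitude 0.9 k_B T, decay length 8 bins);
  `mammal_like` is weak and long-ranged (0.15 k_B T, 24 bins — a
  factor-3 contrast in decay length). Both phase-separate
  (alpha_AA = -0.15, alpha_BB = -0.20, alpha_AB = -0.05, 2% seeded
  jitter).
* Target maps are forward-simulated with the engine itself, so
  recovery experiments have exactly known generating parameters.
* The checkerboard fixture is analytic: p_in/p_out block structure
  times a 1/(1+s) distance decay plus truncated Gaussian noise — any
  decreasing kernel works for the eigenvector test.
* Accessibility tracks are log-normal with the A-bin mean multiplied
  by an enrichment factor (default 4).

What passing tests on these fixtures shows — and does not. The
generators produce clean block compartments, a single fold-back
geometry, and noise-free contact rendering through the same kernel the
trainer assumes; real Hi-C carries coverage biases, translocations,
unmappable regions and a kernel mismatch between crosslinking chemistry
and any smooth f(r). Tests passing here validate the algorithms and
their implementations, not the biological fidelity of any particular
trained parameter set.

## Experiment protocols and problem sizes

All desk-scale experiments use 200-bead single chromosomes unless
stated, a size at which the full acceptance workflow completes on one
CPU in well under half an hour:

* Recovery: replica-averaged target (6 x 5000 steps), 20 training
  iterations of 2000 steps (50-frame burn-in), replica-averaged
  evaluation under tail-averaged parameters. Agreement is the Pearson
  correlation over unmasked upper-triangle entries; the replica
  correlation of two independent ensembles at the true parameters
  (~0.95 at this depth) bounds what any trained model can reach.
* Rabl phenotype: three ensembles from one unpolarized coil start
  (8000 steps, first 2000 discarded): anchored aedes-like, unanchored
  aedes-like, anchored mammal-like. Statistics: mean contact frequency
  in the anti-diagonal band |i + j - (N-1)| <= 5 excluding separations
  < 20, and P(s = 10) from the P(1)-normalized scaling curve. The coil
  start makes the band a formation test rather than a memory test.
* Deformation: hairpin starts in the crowded (0.23-fill) nucleus,
  5000-step rest-shape equilibration, then 12000 steps in the deformed
  envelope (first 3000 discarded), three replicate seeds per style;
  statistic: sum of contacts at s > N/4 over sum at s <= N/4,
  seed-averaged. The hairpin start is the rest-state architecture, so
  strain responses are measured from a common relaxed baseline.

## Numerical choices and degenerate inputs

* Symmetry of contact maps is enforced at 1e-9 relative tolerance;
  text inputs are symmetrized by averaging with the transpose.
* O/E diagonals with zero mean, separations with no valid pairs, type
  pairs with no eligible pairs, and single-chain overlap metrics all
  return NA rather than raising.
* KR balancing falls back to Sinkhorn if the Newton scheme stalls and
  raises with the residual if neither converges.
* FENE bonds beyond R0 raise immediately, naming the bead pair;
  integration divergence raises with the last stable frame index.
* Zero-length tangent segments in O_OP are skipped with a warning.

## Known limitations

* Homologous pairing is not modelled; homologs interact only through
  the generic type term.
* The type term and ideal-chromosome term share the d >= 3
  eligibility; models trained elsewhere with a different bonded
  exclusion will shift alpha by a near-diagonal offset.
* Anchors are pole-point springs, not a distributed lamina shell; a
  spherical-cap attachment would soften the polarization geometry.
* At 200 beads the fold-back band is a large fraction of all
  long-range pairs, so band-sensitive statistics are size-dependent;
  directional claims are asserted, magnitudes are not.
* The soft-core repulsion permits rare strand crossings; entanglement
  statistics are out of scope.
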