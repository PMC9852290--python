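# rablchrom

Data-driven polymer modelling of **Rabl-configured genomes** — genomes
whose centromeres cluster at one nuclear pole and telomeres at the
opposite pole, folding each chromosome into a hairpin. The package was
built around the genome of the mosquito *Aedes aegypti*, whose Hi-C
maps show an unusually wide main diagonal (strong lengthwise
compaction), a secondary anti-diagonal (the fold-back), and elongated,
liquid-crystal-like chromosome territories. It is aimed at researchers
in chromatin polymer physics who want to train an energy function on a
contact map, simulate the resulting ensemble in a polarized nucleus,
and interrogate its structure.

## What it does

1. **Hi-C processing** (`rablchrom.hic`) — dense-matrix I/O,
   Knight-Ruiz balancing, observed/expected normalization, A/B
   compartment calling from the leading eigenvector of the correlation
   matrix, contact-probability scaling P(s), and map comparison.
2. **Chromatin energy function** (`rablchrom.michrom`) — a MiChroM-type
   potential: homopolymer backbone U_HP, chromatin-type interactions
   alpha_kl, and an "ideal chromosome" lengthwise-compaction profile
   gamma(d), all coupled through the crosslink kernel
   f(r) = (1 + tanh(mu (r_c − r)))/2, with analytic forces.
3. **Simulation engine** (`rablchrom.engine`) — BAOAB Langevin dynamics
   in a deformable spheroidal nucleus with telomere/centromere pole
   anchors, quenching schedules, strain experiments, and multi-chain
   (full-nucleus) assembly.
4. **Maximum-entropy training** (`rablchrom.maxent`) — iterative fits
   of (alpha, gamma) so the simulated ensemble's contact statistics
   match a target map:
   `alpha_kl += eta (⟨f⟩_sim,kl − ⟨f⟩_target,kl)`, and likewise per
   genomic distance for gamma(d).
5. **Ensemble analyses** (`rablchrom.analysis`) — orientation order
   parameter O_OP(d) and its period spectrum, cylindrical densities
   around the centromere-telomere axis, per-bead exposed area,
   territory metrics, accessibility-signal classification, and
   reduced-to-physical unit conversion
   (sigma_100kb = 2^(1/3) × 0.165 μm = 0.20789 μm).
6. **Synthetic data** (`rablchrom.synth`) — seeded generators for
   genomes, ground-truth parameters (`aedes_like` vs `mammal_like`
   styles), forward-simulated target maps, checkerboard compartment
   fixtures, and accessibility tracks, so the entire pipeline is
   testable without downloads.

The numbered scripts under `analysis/` run the study workflow over the
synthetic scenario (each takes an optional seed argument and writes
under `results/`):

| script | what it does |
| --- | --- |
| `01_synthesize_scenario.py` | ground-truth genome, parameters, target map, accessibility track |
| `02_train_maxent.py` | parameter recovery from a pure homopolymer start |
| `03_rabl_phenotype.py` | anchored/unanchored and aedes/mammal map contrasts |
| `04_deformation.py` | ±30% nuclear strain sweep for both parameter styles |
| `05_structure_statistics.py` | quench, orientation order + spectrum, densities, exposure, territories |

`rablchrom` is also a CLI
(`process-hic, synth, train, simulate, quench, deform, analyze`).

## Worked example

Recover known interaction parameters from a synthetic target map
(about four minutes on one CPU):

```bash
python analysis/02_train_maxent.py 1
```

prints

```
final Pearson r (sim vs target): 0.919
median per-distance residual: 0.0252 -> 0.0114 over 20 iterations
```

The target map was forward-simulated from known aedes-like parameters
on a 200-bead two-type chromosome; training starts from a pure
homopolymer (alpha = gamma = 0). The Pearson r compares the
replica-averaged in-silico map under the trained parameters with the
target over all bin pairs — 0.92 here against a sampling-noise ceiling
of about 0.95 at this ensemble depth — and the residual line shows the
median per-distance contact mismatch halving over the 20 iterations.

The Rabl-phenotype contrast (`python analysis/03_rabl_phenotype.py 1`)
prints

```
fold-back band mean: anchored 0.0506 vs unanchored 0.0081 (ratio 6.27)
P(s=10): aedes-like 0.345 vs mammal-like 0.141 (ratio 2.45)
```

anchoring the telomeres and centromere to opposite poles creates the
secondary-diagonal band (absent without anchors), and the strong
short-range compaction of the aedes-like style more than doubles the
contact probability at 1 Mb separation relative to the mammal-like
control.

## Real-data recipes (optional, not covered by tests)

The deposited *Aedes aegypti* data can be run through the same CLI:
Hi-C (GEO GSE113256, BioProject PRJNA318737) dumped to a dense text
matrix at 100 kb feeds `rablchrom process-hic` and `rablchrom train`;
binned ATAC-seq signal (SRX3580386, aligned to AaegL5.0) supplies the
compartment orientation track and the accessibility classes for
`rablchrom analyze`. Figure-level values reported for those data (map
correlation 0.957, 64%/59% accessibility-compartment overlaps, 0.6 Mb
and 8 Mb spectral periods) require that full-scale input and
cluster-scale sampling; the synthetic experiments here assert the same
phenomena directionally at desk scale.
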