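"""Structural statistics of a quenched and a thermal ensemble.

Simulates the aedes-like chromosome, quenches a copy to low temperature,
and computes: contact-probability scaling, the orientation order
parameter and its period spectrum, cylindrical densities of high/low
accessibility beads around the polar axis, per-bead exposed area, and
territory metrics with physical-unit conversions. Writes results/structure/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from rablchrom.analysis import (
    classify_signal_bins,
    coarsen_backbone,
    cylindrical_density,
    exposed_area,
    oop_spectrum,
    orientation_order_parameter,
    territory_metrics,
    to_physical_units,
)
from rablchrom.engine import SimulationConfig, Trajectory, quench, run_langevin
from rablchrom.hic import contact_probability_curve
from rablchrom.maxent import simulated_contact_map
from rablchrom.synth import (
    default_geometry,
    make_ground_truth_params,
    make_synthetic_genome,
    synth_atac_signal,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "structure"
OUT.mkdir(parents=True, exist_ok=True)

spec = make_synthetic_genome(n_beads=200, seed=SEED)
params = make_ground_truth_params("aedes_like", seed=SEED, d_cutoff=50)
geometry = default_geometry(200)

traj = run_langevin(spec, params, geometry,
                    SimulationConfig(seed=SEED, n_steps=6000, save_every=20))
ensemble = Trajectory(frames=traj.frames[100:], spec=spec)

xq = quench(spec, params, geometry, SimulationConfig(seed=SEED + 1),
            schedule=[(1.0, 1000), (0.5, 1500), (0.1, 1500), (0.01, 1500)],
            initial_coords=traj.final)

cm = simulated_contact_map(ensemble, params.mu, params.r_c)
ps = contact_probability_curve(cm)
ps.to_tsv(OUT / "contact_probability.tsv")

oop_therm = orientation_order_parameter(ensemble, spec)
oop_quench = orientation_order_parameter(xq, spec)
oop_therm.to_tsv(OUT / "oop_thermal.tsv")
oop_quench.to_tsv(OUT / "oop_quenched.tsv")
spec_q, peaks_q = oop_spectrum(oop_quench, spec.bin_size)
spec_q.to_tsv(OUT / "oop_spectrum_quenched.tsv")

atac = synth_atac_signal(spec.type_of, seed=SEED)
labels = classify_signal_bins(atac)
dens = cylindrical_density(ensemble, spec, geometry, labels, n_radial_bins=15)
for cat, prof in dens.items():
    prof.to_tsv(OUT / f"radial_density_{cat}.tsv")

ea = exposed_area(traj.final, spec)
np.savetxt(OUT / "exposed_area.tsv", ea, fmt="%.6g")

tm = territory_metrics(ensemble, spec, geometry)
coarse = coarsen_backbone(xq, spec, window=10)
contour_sigma = float(np.linalg.norm(np.diff(coarse, axis=0), axis=1).sum())

summary = {
    "seed": SEED,
    "oop_peak_periods_mb_quenched": list(map(float, peaks_q)),
    "elongation": float(tm["elongation"][0]),
    "cen_tel_distance_sigma": float(tm["cen_tel_distance"][0]),
    "cen_tel_distance_um": to_physical_units(float(tm["cen_tel_distance"][0]),
                                             spec.bin_size),
    "quenched_contour_length_sigma": contour_sigma,
    "quenched_contour_length_um": to_physical_units(contour_sigma,
                                                    spec.bin_size),
    "mean_exposed_area_high": float(ea[labels == "high"].mean()),
    "mean_exposed_area_low": float(ea[labels == "low"].mean()),
}
with open(OUT / "summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print(f"quenched spectrum peak periods (Mb): {summary['oop_peak_periods_mb_quenched']}")
print(f"territory elongation {summary['elongation']:.1f}; centromere-telomere "
      f"distance {summary['cen_tel_distance_um']:.2f} um")
print(f"coarse-backbone contour length {summary['quenched_contour_length_um']:.2f} um")
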