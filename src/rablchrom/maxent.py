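"""Maximum-entropy inverse problem: fit the type couplings alpha_kl and
the ideal-chromosome profile gamma(d) so that the simulated ensemble's
contact probabilities reproduce a target contact map.

Each iteration simulates the current model, renders an in-silico contact
map through the crosslink kernel, reduces both maps to the sufficient
statistics of the two trainable terms (per-type-pair and per-genomic-
distance mean contact probabilities), and moves each parameter along the
mismatch: where the simulation over-contacts relative to the target, the
corresponding coupling becomes more repulsive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import (
    NucleusGeometry,
    SimulationConfig,
    Trajectory,
    initialize_conformation,
    run_langevin,
)
from .hic import ContactMap, compare_maps
from .michrom import GenomeSpec, MiChroMParameters, crosslink_probability
from .michrom import _pair_eligibility

__all__ = [
    "TrainingState",
    "simulated_contact_map",
    "aggregate_by_types",
    "aggregate_by_distance",
    "update_parameters",
    "rescale_target_map",
    "train",
]


@dataclass
class TrainingState:
    """History of one MaxEnt optimisation."""

    iteration: int
    params: MiChroMParameters
    sim_map: ContactMap | None
    objective: list = field(default_factory=list)  # per-iteration dicts
    params_history: list = field(default_factory=list)
    learning_rate: float = 8.0

    @property
    def pearson_history(self) -> np.ndarray:
        return np.array([o["pearson_r"] for o in self.objective])

    @property
    def distance_residual_history(self) -> np.ndarray:
        return np.array([o["median_distance_residual"] for o in self.objective])

    def tail_averaged_params(self, window: int = 10) -> MiChroMParameters:
        """Average of the last ``window`` iterations' parameters.

        Stochastic-gradient iterates fluctuate around the optimum with
        the sampling noise of each iteration's ensemble; averaging the
        tail gives a lower-variance estimate than the last iterate."""
        if not self.params_history:
            return self.params.copy()
        tail = self.params_history[-window:]
        out = tail[-1].copy()
        out.alpha = np.mean([p.alpha for p in tail], axis=0)
        out.gamma = np.mean([p.gamma for p in tail], axis=0)
        return out


def simulated_contact_map(traj: Trajectory, mu: float = 3.22,
                          r_c: float = 1.78) -> ContactMap:
    """In-silico contact map: entry (i, j) is the crosslink probability
    f(r_ij) averaged over frames; the diagonal is 1 by convention."""
    frames = np.asarray(traj.frames)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("trajectory must contain at least one frame")
    n = frames.shape[1]
    acc = np.zeros((n, n))
    for fr in frames:
        diff = fr[:, None, :] - fr[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        acc += crosslink_probability(r, mu, r_c)
    acc /= len(frames)
    acc = 0.5 * (acc + acc.T)
    np.fill_diagonal(acc, 1.0)
    spec = traj.spec
    offsets = spec.chrom_starts.tolist() if spec is not None else [0]
    return ContactMap(matrix=acc, bin_size=spec.bin_size if spec else 0,
                      chrom_offsets=offsets,
                      provenance={"n_frames": len(frames),
                                  "mu": mu, "r_c": r_c})


def aggregate_by_types(cmap: ContactMap, spec: GenomeSpec,
                       types: list[str] | None = None) -> dict:
    """Mean contact probability per unordered type pair over all pairs
    eligible for the type term (inter-chromosomal pairs and
    intra-chromosomal pairs at separation >= 3), restricted to unmasked
    bins. Pairs with no eligible entries map to NaN."""
    types = types or sorted(set(np.asarray(spec.type_of).tolist()))
    elig = _pair_eligibility(spec)
    m = cmap.mask
    elig = elig & m[:, None] & m[None, :]
    out = {}
    t = np.asarray(spec.type_of)
    for a_i, ta in enumerate(types):
        for tb in types[a_i:]:
            sel = elig & (
                ((t[:, None] == ta) & (t[None, :] == tb))
                | ((t[:, None] == tb) & (t[None, :] == ta))
            )
            iu = np.triu_indices(spec.n_beads, k=1)
            chosen = sel[iu]
            out[(ta, tb)] = (float(cmap.matrix[iu][chosen].mean())
                             if chosen.any() else np.nan)
    return out


def aggregate_by_distance(cmap: ContactMap, spec: GenomeSpec,
                          d_cutoff: int) -> np.ndarray:
    """Mean contact probability per genomic distance d = 3..d_cutoff over
    unmasked intra-chromosomal pairs; NaN where no chromosome reaches d."""
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [spec.n_beads]])
    out = np.full(d_cutoff - 2, np.nan)
    m = cmap.mask
    for d in range(3, d_cutoff + 1):
        vals = []
        for a, b in zip(starts.tolist(), stops.tolist()):
            nb = b - a
            if d >= nb:
                continue
            i = np.arange(a, b - d)
            valid = m[i] & m[i + d]
            if valid.any():
                vals.append(cmap.matrix[i[valid], i[valid] + d])
        if vals:
            out[d - 3] = float(np.concatenate(vals).mean())
    return out


def update_parameters(params: MiChroMParameters, sim_type_stats: dict,
                      target_type_stats: dict, sim_dist_stats: np.ndarray,
                      target_dist_stats: np.ndarray, learning_rate: float,
                      max_step: float = 0.3) -> MiChroMParameters:
    """Gradient step on the MaxEnt Lagrangian sufficient statistics:

    alpha_kl += eta (<f>_sim,kl - <f>_target,kl)
    gamma(d) += eta (<f>_sim,d  - <f>_target,d)

    Over-contacting features make the coupling more repulsive. Steps are
    clipped to ``max_step`` (k_B T) per feature per iteration; NaN
    features leave their parameter untouched.
    """
    if set(sim_type_stats) != set(target_type_stats):
        raise ValueError("type-pair feature sets do not match")
    if len(sim_dist_stats) != len(target_dist_stats):
        raise ValueError("distance feature ranges do not match")
    new = params.copy()
    lut = {t: i for i, t in enumerate(params.types)}
    for (ta, tb), sim_val in sim_type_stats.items():
        tgt = target_type_stats[(ta, tb)]
        if not (np.isfinite(sim_val) and np.isfinite(tgt)):
            continue
        step = np.clip(learning_rate * (sim_val - tgt), -max_step, max_step)
        i, j = lut[ta], lut[tb]
        new.alpha[i, j] += step
        if i != j:
            new.alpha[j, i] += step
    ok = np.isfinite(sim_dist_stats) & np.isfinite(target_dist_stats)
    step = np.clip(learning_rate * (sim_dist_stats - target_dist_stats),
                   -max_step, max_step)
    new.gamma[ok] += step[ok]
    return new


def rescale_target_map(target: ContactMap, reference: ContactMap) -> ContactMap:
    """Rescale an experimental-frequency map to contact-probability units
    by matching its mean nearest-neighbour (d = 1) contact to that of a
    reference simulated map, then clipping to [0, 1]."""
    spec_like_offsets = list(target.chrom_offsets)

    def d1_mean(cm: ContactMap) -> float:
        bounds = spec_like_offsets + [cm.n_bins]
        vals = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            i = np.arange(a, b - 1)
            valid = cm.mask[i] & cm.mask[i + 1]
            vals.append(cm.matrix[i[valid], i[valid] + 1])
        return float(np.concatenate(vals).mean())

    scale = d1_mean(reference) / max(d1_mean(target), 1e-300)
    m = np.clip(target.matrix * scale, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return ContactMap(matrix=m, bin_size=target.bin_size,
                      chrom_offsets=spec_like_offsets, mask=target.mask,
                      provenance={**target.provenance,
                                  "probability_rescale": scale})


def train(spec: GenomeSpec, target_map: ContactMap,
          geometry: NucleusGeometry, sim_config: SimulationConfig,
          n_iterations: int = 20, learning_rate: float = 8.0,
          initial_params: MiChroMParameters | None = None,
          equilibration_steps: int = 0,
          rescale_target: bool = True,
          burn_in_frames: int = 0,
          checkpoint_dir=None, resume: bool = False,
          callback=None) -> TrainingState:
    """Iterative MaxEnt fit of (alpha, gamma) to a target contact map.

    Starts from a pure homopolymer (alpha = gamma = 0) unless warm-start
    parameters are given; each iteration continues the previous
    iteration's final frame. The per-iteration objective records the
    Pearson correlation between the simulated and target maps and the
    median per-distance residual.
    """
    params = (initial_params.copy() if initial_params is not None
              else MiChroMParameters(types=sorted(set(np.asarray(spec.type_of).tolist())),
                                     d_cutoff=min(50, spec.n_beads - 1)))
    target = target_map
    target_type = None
    target_dist = None
    state = TrainingState(iteration=0, params=params, sim_map=None,
                          learning_rate=learning_rate)
    # unbiased (unpolarized coil) start: a pre-folded layout would make
    # the initial homopolymer statistics spuriously resemble the target
    from .engine import relax

    coords = relax(spec, params, geometry,
                   initialize_conformation(spec, geometry,
                                           seed=sim_config.seed, style="coil"))
    vel = None
    start_iteration = 0
    if resume and checkpoint_dir is not None:
        loaded = _load_checkpoint(checkpoint_dir, state, params)
        if loaded is not None:
            start_iteration, params, coords, vel = loaded
            state.params = params
    if equilibration_steps > 0 and start_iteration == 0:
        from dataclasses import replace

        eq = replace(sim_config, n_steps=equilibration_steps,
                     save_every=equilibration_steps)
        traj = run_langevin(spec, params, geometry, eq, initial_coords=coords)
        coords = traj.final.copy()
        vel = traj.provenance["final_velocities"]

    for it in range(start_iteration, n_iterations):
        from dataclasses import replace

        cfg = replace(sim_config, seed=sim_config.seed + 1 + it)
        try:
            traj = run_langevin(spec, params, geometry, cfg,
                                initial_coords=coords, initial_velocities=vel)
        except FloatingPointError as err:
            warnings.warn(f"simulation failed at iteration {it}: {err}; "
                          "returning partial history")
            state.iteration = it
            return state
        coords = traj.final.copy()
        vel = traj.provenance["final_velocities"]
        kept = (Trajectory(frames=traj.frames[burn_in_frames:], spec=spec)
                if burn_in_frames else traj)
        sim_map = simulated_contact_map(kept, params.mu, params.r_c)
        sim_map.mask = target_map.mask.copy()
        if it == 0 and rescale_target:
            target = rescale_target_map(target_map, sim_map)
            # pre-scaled targets (e.g. synthetic probability maps) pass
            # rescale_target=False and are used as-is
        if target_type is None:
            target_type = aggregate_by_types(target, spec, params.types)
            target_dist = aggregate_by_distance(target, spec, params.d_cutoff)
        sim_type = aggregate_by_types(sim_map, spec, params.types)
        sim_dist = aggregate_by_distance(sim_map, spec, params.d_cutoff)
        cmp = compare_maps(sim_map, target)
        resid = np.abs(sim_dist - target_dist)
        state.objective.append({
            "iteration": it,
            "pearson_r": cmp["r"],
            "median_distance_residual": float(np.nanmedian(resid)),
            "type_stats_sim": sim_type,
            "type_stats_target": target_type,
        })
        # step-decayed learning rate: large early moves, then settling
        eta = learning_rate / (1.0 + it // 8)
        params = update_parameters(params, sim_type, target_type,
                                   sim_dist, target_dist, eta)
        state.params = params
        state.params_history.append(params.copy())
        state.sim_map = sim_map
        state.iteration = it + 1
        if checkpoint_dir is not None:
            _write_checkpoint(checkpoint_dir, it, params, coords, vel,
                              state.objective[-1])
        if callback is not None:
            callback(state)
    return state


def _write_checkpoint(checkpoint_dir, it, params, coords, vel, objective):
    import json
    from pathlib import Path

    d = Path(checkpoint_dir) / f"iteration_{it:03d}"
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "alpha.tsv", params.alpha, fmt="%.17g", delimiter="\t",
               header="\t".join(params.types))
    np.savetxt(d / "gamma.tsv", params.gamma, fmt="%.17g")
    np.savetxt(d / "coords.tsv", coords, fmt="%.17g")
    np.savetxt(d / "velocities.tsv", vel, fmt="%.17g")
    with open(d / "objective.json", "w") as fh:
        json.dump({"iteration": objective["iteration"],
                   "pearson_r": objective["pearson_r"],
                   "median_distance_residual":
                       objective["median_distance_residual"]}, fh)


def _load_checkpoint(checkpoint_dir, state, params):
    """Load the latest per-iteration checkpoint; returns
    (next_iteration, params, coords, velocities) or None."""
    import json
    from pathlib import Path

    d = Path(checkpoint_dir)
    if not d.exists():
        return None
    iters = sorted(p for p in d.iterdir() if p.name.startswith("iteration_"))
    if not iters:
        return None
    last = iters[-1]
    it = int(last.name.split("_")[1])
    new = params.copy()
    new.alpha = np.loadtxt(last / "alpha.tsv", delimiter="\t", ndmin=2)
    new.gamma = np.atleast_1d(np.loadtxt(last / "gamma.tsv"))
    coords = np.loadtxt(last / "coords.tsv")
    vel = np.loadtxt(last / "velocities.tsv")
    # rebuild objective history from checkpoints for continuity
    for p in iters:
        with open(p / "objective.json") as fh:
            state.objective.append(json.load(fh))
        a = np.loadtxt(p / "alpha.tsv", delimiter="\t", ndmin=2)
        g = np.atleast_1d(np.loadtxt(p / "gamma.tsv"))
        hist = params.copy()
        hist.alpha, hist.gamma = a, g
        state.params_history.append(hist)
    state.iteration = it + 1
    return it + 1, new, coords, vel
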