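"""Langevin dynamics of chromatin chains in a polarized spheroidal nucleus.

The nucleus is a soft-walled spheroid whose polar axis joins the two
anchoring poles: telomere beads are tethered by harmonic springs to one
pole, centromere beads to the opposite pole, reproducing the polarized
(Rabl-like) arrangement in which chromosomes fold over as hairpins
between the two poles. Dynamics use the BAOAB splitting of the Langevin
equation in reduced units (sigma = 1, k_B T = 1, bead mass = 1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .michrom import (
    GenomeSpec,
    MiChroMParameters,
    coupling_matrix,
    forces,
    total_energy,
)

__all__ = [
    "NucleusGeometry",
    "SimulationConfig",
    "Trajectory",
    "confinement_energy",
    "confinement_forces",
    "anchor_energy",
    "anchor_forces",
    "initialize_conformation",
    "relax",
    "run_langevin",
    "quench",
    "deform_nucleus",
    "build_full_nucleus",
]

_ENERGY_DIVERGENCE = 1e8


@dataclass(frozen=True)
class NucleusGeometry:
    """Spheroidal nuclear envelope with anchoring poles on its axis.

    The centromere pole sits at +pole_separation/2 along ``pole_axis``
    from the origin, the telomere pole at -pole_separation/2; the wall
    is the spheroid through both poles with the given equatorial radius.
    """

    pole_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    pole_separation: float = 38.0
    equatorial_radius: float = 19.0
    wall_stiffness: float = 50.0
    anchor_stiffness: float = 50.0
    # tether points sit one bead diameter inside the envelope so anchored
    # beads rest against, not across, the wall
    anchor_inset: float = 1.0

    def __post_init__(self):
        axis = np.asarray(self.pole_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("pole_axis must be non-zero")
        object.__setattr__(self, "pole_axis", axis / norm)
        if self.pole_separation <= 0 or self.equatorial_radius <= 0:
            raise ValueError("nucleus dimensions must be positive")

    @property
    def centromere_pole(self) -> np.ndarray:
        return (0.5 * self.pole_separation - self.anchor_inset) * self.pole_axis

    @property
    def telomere_pole(self) -> np.ndarray:
        return -(0.5 * self.pole_separation - self.anchor_inset) * self.pole_axis

    def spheroidal_coordinate(self, coords: np.ndarray) -> np.ndarray:
        """s = (x_axial / (L/2))^2 + (r_equatorial / R_eq)^2; s = 1 on the wall."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        ax = coords @ self.pole_axis
        perp = coords - ax[:, None] * self.pole_axis
        return (ax / (0.5 * self.pole_separation)) ** 2 + (
            np.einsum("ij,ij->i", perp, perp) / self.equatorial_radius**2
        )


@dataclass(frozen=True)
class SimulationConfig:
    timestep: float = 0.01
    friction: float = 0.1
    temperature: float = 1.0
    seed: int = 0
    n_steps: int = 1000
    save_every: int = 10

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered coordinate frames (sigma units) with provenance."""

    frames: np.ndarray  # (n_frames, N, 3)
    spec: GenomeSpec
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def final(self) -> np.ndarray:
        return self.frames[-1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            h.create_dataset("frames", data=np.asarray(self.frames))
            h.create_dataset("chrom_of", data=self.spec.chrom_of)
            h.attrs["provenance"] = json.dumps(
                {k: v for k, v in self.provenance.items()
                 if not isinstance(v, np.ndarray)})

    def to_pdb(self, path) -> None:
        """One MODEL per frame; bead index as residue number, chromosome
        as chain id."""
        chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        with open(path, "w") as fh:
            for m, fr in enumerate(self.frames, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for i, (x, y, z) in enumerate(fr):
                    c = chains[int(self.spec.chrom_of[i]) % len(chains)]
                    fh.write(
                        f"ATOM  {i + 1:5d}  CA  BEA {c}{(i % 9999) + 1:4d}"
                        f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                    )
                fh.write("ENDMDL\n")


def _provenance_hash(config: SimulationConfig, params: MiChroMParameters) -> str:
    blob = json.dumps(
        {
            "config": [config.timestep, config.friction, config.temperature,
                       config.seed, config.n_steps, config.save_every],
            "alpha": params.alpha.tolist(),
            "gamma": params.gamma.tolist(),
            "kernel": [params.mu, params.r_c],
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def confinement_energy(coords: np.ndarray, geometry: NucleusGeometry) -> float:
    """Half-harmonic wall: (k_wall / 2) (s - 1)^2 per bead outside (s > 1)."""
    s = geometry.spheroidal_coordinate(coords)
    out = np.clip(s - 1.0, 0.0, None)
    return float(0.5 * geometry.wall_stiffness * (out**2).sum())


def confinement_forces(coords: np.ndarray, geometry: NucleusGeometry) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    ax = coords @ geometry.pole_axis
    perp = coords - ax[:, None] * geometry.pole_axis
    half_l = 0.5 * geometry.pole_separation
    s = (ax / half_l) ** 2 + np.einsum("ij,ij->i", perp, perp) / geometry.equatorial_radius**2
    duds = geometry.wall_stiffness * np.clip(s - 1.0, 0.0, None)
    ds_dr = (2.0 * ax / half_l**2)[:, None] * geometry.pole_axis + (
        2.0 / geometry.equatorial_radius**2
    ) * perp
    return -duds[:, None] * ds_dr


def anchor_energy(coords: np.ndarray, spec: GenomeSpec,
                  geometry: NucleusGeometry) -> float:
    """Harmonic tethers: telomere beads to the telomere pole, centromere
    beads to the centromere pole; (k_anchor / 2) |r - pole|^2 each."""
    if len(spec.telomere_beads) == 0 or len(spec.centromere_beads) == 0:
        raise ValueError(
            "polarization requires non-empty telomere and centromere bead sets"
        )
    coords = np.asarray(coords, dtype=float)
    k = geometry.anchor_stiffness
    dt = coords[spec.telomere_beads] - geometry.telomere_pole
    dc = coords[spec.centromere_beads] - geometry.centromere_pole
    return float(0.5 * k * ((dt**2).sum() + (dc**2).sum()))


def anchor_forces(coords: np.ndarray, spec: GenomeSpec,
                  geometry: NucleusGeometry) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    f = np.zeros_like(coords)
    k = geometry.anchor_stiffness
    f[spec.telomere_beads] -= k * (coords[spec.telomere_beads] - geometry.telomere_pole)
    f[spec.centromere_beads] -= k * (
        coords[spec.centromere_beads] - geometry.centromere_pole
    )
    return f


def initialize_conformation(spec: GenomeSpec, geometry: NucleusGeometry,
                            seed: int = 0, min_separation: float = 0.5,
                            max_retries: int = 20,
                            style: str = "hairpin") -> np.ndarray:
    """Initial bead layout inside the nucleus.

    ``style='hairpin'`` (default): each chain runs from the telomere pole
    toward the centromere pole and back as a pair of helical arms, so
    telomeric ends start near one pole and the mid-chain centromere near
    the other. ``style='coil'``: an unpolarized compact random coil near
    the nuclear centre (useful as an unbiased start when testing whether
    anchoring forms the folded architecture). Placement is seeded and
    retried until no two beads are closer than ``min_separation``.
    """
    if style == "coil":
        return _coil_conformation(spec, geometry, seed, min_separation,
                                  max_retries)
    rng = np.random.default_rng(seed)
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [spec.n_beads]])
    n_chains = len(starts)
    axis = geometry.pole_axis
    # orthonormal frame for lateral offsets
    probe = np.array([1.0, 0.0, 0.0])
    if abs(axis @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    span = 0.9 * geometry.pole_separation
    bead_spacing = 0.9  # along the helical path, ~ bond rest length

    def helix_arm(n, z0, z1, rho, phi0):
        """n beads on a helix from axial z0 to z1 at radius rho; the
        angular step keeps consecutive beads ~bead_spacing apart."""
        if n == 0:
            return np.empty((0, 3)), phi0
        z = np.linspace(z0, z1, n)
        dz = abs(z1 - z0) / max(n - 1, 1)
        c = np.sqrt(max(bead_spacing**2 - dz**2, 0.04))
        dphi = c / rho
        phi = phi0 + dphi * np.arange(n)
        return (z[:, None] * axis
                + rho * np.cos(phi)[:, None] * e1
                + rho * np.sin(phi)[:, None] * e2), phi[-1]

    # chain centers on a circle wide enough to keep chains apart
    outer = 3.3  # outer-arm helix radius + margin
    if n_chains == 1:
        centers = [np.zeros(3)]
    else:
        ring = max((2 * outer + 1.0) / (2 * np.sin(np.pi / n_chains)), outer)
        centers = [ring * (np.cos(2 * np.pi * m / n_chains) * e1
                           + np.sin(2 * np.pi * m / n_chains) * e2)
                   for m in range(n_chains)]

    for attempt in range(max_retries):
        coords = np.empty((spec.n_beads, 3))
        for m, (a, b) in enumerate(zip(starts, stops)):
            n = b - a
            half = (n + 1) // 2
            # pick arm radii so successive helix turns stay > ~0.8 apart
            dz_up = span / max(half - 1, 1)
            rho_in = max(0.85, np.sqrt(max(bead_spacing**2 - dz_up**2, 0.04))
                         / (2 * np.pi) * np.ceil(0.8 / max(dz_up, 1e-6)))
            rho_out = rho_in + 0.9
            phi0 = rng.uniform(0, 2 * np.pi)
            up, phi_end = helix_arm(half, -span / 2, span / 2, rho_in, phi0)
            down, _ = helix_arm(n - half, span / 2, -span / 2, rho_out,
                                phi_end + 0.15)
            chain = np.concatenate([up, down])
            # converge chain centers toward the poles (Rabl-like cone) so
            # anchored ends start near their tether points
            z_rel = 2.0 * (chain @ axis) / max(span, 1e-9)
            taper = 0.55 + 0.45 * np.clip(1.0 - z_rel**2, 0.0, 1.0)
            coords[a:b] = chain + taper[:, None] * centers[m]
        coords += 0.04 * rng.standard_normal(coords.shape)
        d = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= min_separation:
            return coords
    raise RuntimeError(
        f"could not place {spec.n_beads} beads without overlap "
        f"after {max_retries} retries"
    )


def _coil_conformation(spec, geometry, seed, min_separation, max_retries):
    """Dense random-walk layout confined near the nuclear centre."""
    rng = np.random.default_rng(seed)
    r_box = 0.75 * min(0.5 * geometry.pole_separation,
                       geometry.equatorial_radius)
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [spec.n_beads]])
    for attempt in range(max_retries):
        coords = np.empty((spec.n_beads, 3))
        for a, b in zip(starts.tolist(), stops.tolist()):
            x = rng.uniform(-0.3, 0.3, 3) * r_box
            for k in range(a, b):
                for _ in range(200):
                    step = rng.standard_normal(3)
                    step *= 0.9 / np.linalg.norm(step)
                    cand = x + step
                    if np.linalg.norm(cand) > r_box:
                        continue
                    lo = max(a, k - 400)
                    if k > a:
                        d2 = ((coords[lo:k] - cand) ** 2).sum(axis=1)
                        if d2.min() < min_separation**2:
                            continue
                    break
                coords[k] = cand
                x = cand
        d = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= min_separation:
            return coords
    raise RuntimeError("could not place a coil conformation without overlap")


def relax(spec: GenomeSpec, params: MiChroMParameters,
          geometry: NucleusGeometry, coords: np.ndarray,
          n_steps: int = 300, max_disp: float = 0.05) -> np.ndarray:
    """Deterministic capped-step steepest-descent relaxation under the
    full potential; removes initial-placement strain before dynamics."""
    x = np.array(coords, dtype=float)
    coupling = coupling_matrix(spec, params)
    for _ in range(n_steps):
        f = _total_forces(x, spec, params, geometry, coupling)
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        step = 0.02 * f
        scale = np.minimum(1.0, max_disp / np.maximum(0.02 * norm, 1e-12))
        x = x + step * scale
    return x


def _total_forces(coords, spec, params, geometry, coupling):
    f = forces(coords, spec, params, coupling=coupling)
    f += confinement_forces(coords, geometry)
    if geometry.anchor_stiffness > 0:
        f += anchor_forces(coords, spec, geometry)
    return f


def run_langevin(spec: GenomeSpec, params: MiChroMParameters,
                 geometry: NucleusGeometry, config: SimulationConfig,
                 initial_coords: np.ndarray | None = None,
                 initial_velocities: np.ndarray | None = None) -> Trajectory:
    """BAOAB-discretized Langevin dynamics under the full potential
    (chromatin energy + confinement + anchors). Deterministic for a
    fixed (config, spec, params, initial state)."""
    if initial_coords is None:
        x = relax(spec, params, geometry,
                  initialize_conformation(spec, geometry, seed=config.seed))
    else:
        x = np.array(initial_coords, dtype=float)
    v = (np.zeros_like(x) if initial_velocities is None
         else np.array(initial_velocities, dtype=float))
    rng = np.random.default_rng(config.seed)
    dt = config.timestep
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt(max(config.temperature, 0.0) * (1.0 - c1**2))
    coupling = coupling_matrix(spec, params)

    frames = []
    f = _total_forces(x, spec, params, geometry, coupling)
    for step in range(1, config.n_steps + 1):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f = _total_forces(x, spec, params, geometry, coupling)
        v += 0.5 * dt * f
        if step % config.save_every == 0:
            if not np.all(np.isfinite(x)) or np.abs(x).max() > _ENERGY_DIVERGENCE:
                raise FloatingPointError(
                    f"integration diverged at step {step}; "
                    f"last stable frame at step {step - config.save_every}"
                )
            frames.append(x.copy())

    return Trajectory(
        frames=np.array(frames),
        spec=spec,
        provenance={
            "hash": _provenance_hash(config, params),
            "seed": config.seed,
            "n_steps": config.n_steps,
            "save_every": config.save_every,
            "temperature": config.temperature,
            "final_velocities": v,
        },
    )


def quench(spec: GenomeSpec, params: MiChroMParameters,
           geometry: NucleusGeometry, config: SimulationConfig,
           schedule: list[tuple[float, int]],
           initial_coords: np.ndarray | None = None) -> np.ndarray:
    """Anneal through a non-increasing temperature schedule, removing
    thermal disorder to expose the ordered minima of the energy
    landscape; returns the final frame."""
    temps = [t for t, _ in schedule]
    if any(b > a for a, b in zip(temps, temps[1:])):
        raise ValueError("quench schedule temperatures must be non-increasing")
    x = (initialize_conformation(spec, geometry, seed=config.seed)
         if initial_coords is None else np.array(initial_coords, dtype=float))
    v = None
    for i, (t, n_steps) in enumerate(schedule):
        if n_steps == 0:
            continue
        seg = replace(config, temperature=t, n_steps=n_steps,
                      save_every=n_steps, seed=config.seed + i)
        traj = run_langevin(spec, params, geometry, seg,
                            initial_coords=x, initial_velocities=v)
        x = traj.final.copy()
        v = traj.provenance["final_velocities"]
    return x


def deform_nucleus(geometry: NucleusGeometry, strain: float,
                   preserve_volume: bool = True) -> NucleusGeometry:
    """Stretch (strain > 0) or compress (strain < 0) the nucleus along
    the pole axis: pole separation and polar semi-axis scale by
    (1 + strain); the equatorial radius rescales to conserve the
    spheroid volume (or stays fixed if preserve_volume is False). The
    anchoring poles move with the wall."""
    if strain <= -1:
        raise ValueError("strain must exceed -1")
    scale = 1.0 + strain
    r_eq = (geometry.equatorial_radius / np.sqrt(scale)
            if preserve_volume else geometry.equatorial_radius)
    return replace(geometry, pole_separation=geometry.pole_separation * scale,
                   equatorial_radius=r_eq)


def build_full_nucleus(specs: list[GenomeSpec], copies: int = 2) -> GenomeSpec:
    """Concatenate chromosome specs into a multi-chain nucleus spec
    (default: maternal + paternal copies). Chains interact only through
    the non-bonded terms; no bonds or ideal-chromosome pairs cross a
    chain boundary."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    chrom_of, type_of, tel, cen = [], [], [], []
    offset = 0
    chain_id = 0
    bin_size = specs[0].bin_size
    for _ in range(copies):
        for s in specs:
            chrom_of.append(np.full(s.n_beads, chain_id))
            type_of.append(s.type_of)
            tel.append(s.telomere_beads + offset)
            cen.append(s.centromere_beads + offset)
            offset += s.n_beads
            chain_id += 1
    return GenomeSpec(
        n_beads=offset,
        bin_size=bin_size,
        chrom_of=np.concatenate(chrom_of),
        type_of=np.concatenate(type_of),
        telomere_beads=np.concatenate(tel),
        centromere_beads=np.concatenate(cen),
    )
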