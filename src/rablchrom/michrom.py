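"""MiChroM-type coarse-grained chromatin energy function.

The potential combines three terms over a bead-spring chromatin fiber
(one bead per genomic bin, reduced units sigma = 1, k_B T = 1):

* a generic homopolymer backbone (finitely-extensible bonds, a bending
  term, and a soft-core excluded-volume repulsion),
* a chromatin-type pair interaction ``alpha_kl * sum f(r_ij)`` driving
  A/B phase separation, and
* an "ideal chromosome" term ``gamma(d) * sum_i f(r_i, r_{i+d})`` acting
  only along the chain, modelling motor-driven lengthwise compaction as
  a function of genomic separation d (in bins).

``f(r) = (1 + tanh(mu * (r_c - r))) / 2`` is the crosslink kernel: a
smooth, sigmoidal map from 3D distance to contact probability used both
in the energy and to render in-silico contact maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "GenomeSpec",
    "MiChroMParameters",
    "crosslink_probability",
    "crosslink_probability_gradient",
    "coupling_matrix",
    "homopolymer_energy",
    "type_interaction_energy",
    "ideal_chromosome_energy",
    "total_energy",
    "forces",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Bead-level description of the modelled genome.

    Beads are ordered; each belongs to exactly one chromosome (contiguous
    index range) and carries one chromatin-type label. Telomere and
    centromere bead sets mark the regions tethered to the nuclear poles.
    """

    n_beads: int
    bin_size: int
    chrom_of: np.ndarray  # int, per bead
    type_of: np.ndarray  # str labels, per bead
    telomere_beads: np.ndarray
    centromere_beads: np.ndarray

    def __post_init__(self):
        chrom_of = np.asarray(self.chrom_of)
        type_of = np.asarray(self.type_of)
        object.__setattr__(self, "chrom_of", chrom_of)
        object.__setattr__(self, "type_of", type_of)
        object.__setattr__(
            self, "telomere_beads", np.asarray(self.telomere_beads, dtype=int)
        )
        object.__setattr__(
            self, "centromere_beads", np.asarray(self.centromere_beads, dtype=int)
        )
        if len(chrom_of) != self.n_beads or len(type_of) != self.n_beads:
            raise ValueError("chrom_of/type_of length must equal n_beads")
        # chromosomes must occupy contiguous index ranges
        change = np.flatnonzero(np.diff(chrom_of) != 0)
        starts = np.concatenate([[0], change + 1])
        if len(np.unique(chrom_of[starts])) != len(starts):
            raise ValueError("chromosome bead ranges must be contiguous")
        tel = set(self.telomere_beads.tolist())
        cen = set(self.centromere_beads.tolist())
        if tel & cen:
            raise ValueError("telomere and centromere bead sets must be disjoint")

    @property
    def n_chroms(self) -> int:
        return len(np.unique(self.chrom_of))

    @property
    def chrom_starts(self) -> np.ndarray:
        change = np.flatnonzero(np.diff(self.chrom_of) != 0)
        return np.concatenate([[0], change + 1])

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) consecutive-bead pairs, never across chromosomes."""
        i = np.arange(self.n_beads - 1)
        keep = self.chrom_of[i] == self.chrom_of[i + 1]
        return np.column_stack([i[keep], i[keep] + 1])

    @property
    def types(self) -> list[str]:
        return sorted(np.unique(self.type_of).tolist())


@dataclass
class MiChroMParameters:
    """Interaction parameters of the chromatin energy function.

    ``alpha`` is a symmetric matrix over the type alphabet (energies in
    k_B T); ``gamma[d - 3]`` is the ideal-chromosome energy at genomic
    separation ``d`` bins for d = 3..d_cutoff. ``mu`` (1/sigma) and
    ``r_c`` (sigma) set the crosslink kernel. Homopolymer constants:
    FENE bond strength/extensibility, bending stiffness, and a soft-core
    half-harmonic repulsion (finite at r = 0, zero beyond ``ev_cutoff``).
    """

    types: list[str] = field(default_factory=lambda: ["A", "B"])
    alpha: np.ndarray = None
    gamma: np.ndarray = None
    d_cutoff: int = 50
    mu: float = 3.22
    r_c: float = 1.78
    bond_k: float = 30.0
    bond_r0: float = 1.5
    angle_k: float = 2.0
    ev_k: float = 100.0
    ev_cutoff: float = 1.0

    def __post_init__(self):
        nt = len(self.types)
        if self.alpha is None:
            self.alpha = np.zeros((nt, nt))
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (nt, nt):
            raise ValueError("alpha must be square over the type alphabet")
        if not np.allclose(self.alpha, self.alpha.T):
            raise ValueError("alpha must be symmetric")
        if self.gamma is None:
            self.gamma = np.zeros(max(self.d_cutoff - 2, 0))
        self.gamma = np.asarray(self.gamma, dtype=float)
        if len(self.gamma) != self.d_cutoff - 2:
            raise ValueError("gamma must cover d = 3..d_cutoff")
        if self.mu <= 0 or self.r_c <= 0:
            raise ValueError("mu and r_c must be positive")

    def type_index(self, labels: np.ndarray) -> np.ndarray:
        lut = {t: i for i, t in enumerate(self.types)}
        try:
            return np.array([lut[t] for t in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"bead type {e} missing from parameter alphabet")

    def gamma_at(self, d) -> np.ndarray:
        """gamma(d), zero outside 3..d_cutoff."""
        d = np.asarray(d)
        out = np.zeros(d.shape, dtype=float)
        ok = (d >= 3) & (d <= self.d_cutoff)
        out[ok] = self.gamma[d[ok] - 3]
        return out

    def copy(self) -> "MiChroMParameters":
        return replace(self, alpha=self.alpha.copy(), gamma=self.gamma.copy(),
                       types=list(self.types))

    @property
    def bond_rest_length(self) -> float:
        """Minimizer of FENE bond + soft-core repulsion between the pair."""
        def u(r):
            fene = -0.5 * self.bond_k * self.bond_r0**2 * np.log(
                1 - (r / self.bond_r0) ** 2
            )
            ev = 0.5 * self.ev_k * max(self.ev_cutoff - r, 0.0) ** 2
            return fene + ev

        res = minimize_scalar(u, bounds=(1e-6, self.bond_r0 * 0.999),
                              method="bounded")
        return float(res.x)


def crosslink_probability(r, mu: float = 3.22, r_c: float = 1.78):
    """Contact (crosslinking) probability f(r) = (1 + tanh(mu (r_c - r))) / 2."""
    r = np.asarray(r, dtype=float)
    return 0.5 * (1.0 + np.tanh(mu * (r_c - r)))


def crosslink_probability_gradient(r, mu: float = 3.22, r_c: float = 1.78):
    """df/dr = -(mu/2) sech^2(mu (r_c - r))."""
    r = np.asarray(r, dtype=float)
    return -0.5 * mu / np.cosh(mu * (r_c - r)) ** 2


def _pair_eligibility(spec: GenomeSpec) -> np.ndarray:
    """Boolean (N, N): pairs entering the crosslink-kernel terms.

    Intra-chromosomal pairs need |i - j| >= 3 (consistent with the
    ideal-chromosome term starting at d = 3); all inter-chromosomal
    pairs are eligible. Diagonal excluded.
    """
    n = spec.n_beads
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    same = spec.chrom_of[i] == spec.chrom_of[j]
    d = np.abs(i - j)
    return (~same) | (same & (d >= 3))


def coupling_matrix(spec: GenomeSpec, params: MiChroMParameters) -> np.ndarray:
    """Per-pair coefficient of f(r_ij): alpha(type_i, type_j) on eligible
    pairs plus gamma(|i - j|) on intra-chromosomal pairs with
    3 <= d <= d_cutoff. Constant for a fixed (spec, params): precomputing
    it reduces both energy and force evaluation to elementwise work on
    the distance matrix."""
    n = spec.n_beads
    ti = params.type_index(spec.type_of)
    c = params.alpha[ti[:, None], ti[None, :]].astype(float)
    c *= _pair_eligibility(spec)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    same = spec.chrom_of[i] == spec.chrom_of[j]
    d = np.abs(i - j)
    c += np.where(same, params.gamma_at(d), 0.0)
    np.fill_diagonal(c, 0.0)
    return c


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def homopolymer_energy(coords: np.ndarray, spec: GenomeSpec,
                       params: MiChroMParameters) -> float:
    """Backbone energy: FENE bonds + bending + soft-core excluded volume.

    The excluded-volume repulsion acts on every bead pair (bonded pairs
    included, counted once); bonds and angles never span a chromosome
    boundary.
    """
    coords = np.asarray(coords, dtype=float)
    bonds = spec.bonds()
    e = 0.0
    if len(bonds):
        rb = np.linalg.norm(coords[bonds[:, 1]] - coords[bonds[:, 0]], axis=1)
        if np.any(rb >= params.bond_r0):
            k = int(np.argmax(rb >= params.bond_r0))
            raise FloatingPointError(
                f"bond {tuple(bonds[k])} at length {rb[k]:.3f} exceeds the "
                f"finite extensibility limit R0 = {params.bond_r0}"
            )
        e += float(-0.5 * params.bond_k * params.bond_r0**2
                   * np.log(1 - (rb / params.bond_r0) ** 2).sum())
    # bending: consecutive bond pairs within one chromosome
    trip = _angle_triplets(spec)
    if len(trip):
        v1 = coords[trip[:, 1]] - coords[trip[:, 0]]
        v2 = coords[trip[:, 2]] - coords[trip[:, 1]]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        e += float(params.angle_k * (1.0 - np.clip(cosang, -1, 1)).sum())
    # soft-core repulsion over unordered pairs
    r = _distance_matrix(coords)
    iu = np.triu_indices(spec.n_beads, k=1)
    overlap = np.clip(params.ev_cutoff - r[iu], 0.0, None)
    e += float(0.5 * params.ev_k * (overlap**2).sum())
    return e


def _angle_triplets(spec: GenomeSpec) -> np.ndarray:
    i = np.arange(spec.n_beads - 2)
    keep = (spec.chrom_of[i] == spec.chrom_of[i + 1]) & (
        spec.chrom_of[i + 1] == spec.chrom_of[i + 2]
    )
    return np.column_stack([i[keep], i[keep] + 1, i[keep] + 2])


def type_interaction_energy(coords, spec: GenomeSpec, alpha: np.ndarray,
                            mu: float, r_c: float,
                            types: list[str] | None = None) -> float:
    """Phase-separation term: sum over unordered eligible pairs of
    alpha(type_i, type_j) * f(r_ij); inter-chromosomal pairs included."""
    params = MiChroMParameters(types=types or sorted(set(spec.type_of)),
                               alpha=alpha, mu=mu, r_c=r_c, d_cutoff=2,
                               gamma=np.zeros(0))
    ti = params.type_index(spec.type_of)
    c = params.alpha[ti[:, None], ti[None, :]] * _pair_eligibility(spec)
    r = _distance_matrix(np.asarray(coords, dtype=float))
    f = crosslink_probability(r, mu, r_c)
    iu = np.triu_indices(spec.n_beads, k=1)
    return float((c[iu] * f[iu]).sum())


def ideal_chromosome_energy(coords, spec: GenomeSpec, gamma: np.ndarray,
                            d_cutoff: int, mu: float, r_c: float) -> float:
    """Lengthwise-compaction term: sum_{d=3}^{d_cutoff} gamma(d) sum_i
    f(r_{i,i+d}), intra-chromosomal pairs only."""
    coords = np.asarray(coords, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    e = 0.0
    for start, stop in _chrom_ranges(spec):
        n = stop - start
        for d in range(3, min(d_cutoff, n - 1) + 1):
            g = gamma[d - 3]
            if g == 0.0:
                continue
            r = np.linalg.norm(
                coords[start + d:stop] - coords[start:stop - d], axis=1
            )
            e += g * crosslink_probability(r, mu, r_c).sum()
    return float(e)


def _chrom_ranges(spec: GenomeSpec):
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [spec.n_beads]])
    return list(zip(starts.tolist(), stops.tolist()))


def total_energy(coords, spec: GenomeSpec, params: MiChroMParameters) -> float:
    """U = U_homopolymer + U_types + U_ideal_chromosome (confinement and
    anchor restraints are added by the simulation engine)."""
    return (
        homopolymer_energy(coords, spec, params)
        + type_interaction_energy(coords, spec, params.alpha, params.mu,
                                  params.r_c, types=params.types)
        + ideal_chromosome_energy(coords, spec, params.gamma, params.d_cutoff,
                                  params.mu, params.r_c)
    )


def forces(coords, spec: GenomeSpec, params: MiChroMParameters,
           coupling: np.ndarray | None = None) -> np.ndarray:
    """Analytic forces -grad U for the full chromatin potential.

    ``coupling`` may be passed to reuse the precomputed per-pair
    coefficient matrix across many evaluations of the same system.
    """
    coords = np.asarray(coords, dtype=float)
    n = spec.n_beads
    f = np.zeros_like(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(r, 1.0)  # avoid 0/0; diagonal pairs carry no force

    # crosslink-kernel terms: dU/dr_ij = C_ij * f'(r_ij)
    if coupling is None:
        coupling = coupling_matrix(spec, params)
    dudr = coupling * crosslink_probability_gradient(r, params.mu, params.r_c)
    # soft-core excluded volume on all pairs: dU/dr = -k (cut - r) for r < cut
    overlap = np.clip(params.ev_cutoff - r, 0.0, None)
    np.fill_diagonal(overlap, 0.0)
    dudr = dudr - params.ev_k * overlap
    # force on i from pair (i,j): -dU/dr * (r_i - r_j)/r
    f -= np.einsum("ij,ijk->ik", dudr / r, diff)

    # FENE bonds
    bonds = spec.bonds()
    if len(bonds):
        bv = coords[bonds[:, 1]] - coords[bonds[:, 0]]
        rb = np.linalg.norm(bv, axis=1)
        if np.any(rb >= params.bond_r0):
            raise FloatingPointError("bond beyond finite extensibility limit")
        dudr_b = params.bond_k * rb / (1 - (rb / params.bond_r0) ** 2)
        fb = (dudr_b / rb)[:, None] * bv
        np.add.at(f, bonds[:, 0], fb)
        np.add.at(f, bonds[:, 1], -fb)

    # bending: U = k (1 - cos theta), cos theta = v1.v2 / |v1||v2|
    trip = _angle_triplets(spec)
    if len(trip):
        a, b, c = trip[:, 0], trip[:, 1], trip[:, 2]
        v1 = coords[b] - coords[a]
        v2 = coords[c] - coords[b]
        n1 = np.linalg.norm(v1, axis=1)[:, None]
        n2 = np.linalg.norm(v2, axis=1)[:, None]
        u1, u2 = v1 / n1, v2 / n2
        cosang = np.einsum("ij,ij->i", u1, u2)[:, None]
        # d(cos)/dv1 = (u2 - cos * u1)/|v1| ; d(cos)/dv2 = (u1 - cos * u2)/|v2|
        dc_dv1 = (u2 - cosang * u1) / n1
        dc_dv2 = (u1 - cosang * u2) / n2
        # U = k (1 - cos) -> force = k * d(cos)/d(position)
        np.add.at(f, a, -params.angle_k * dc_dv1)
        np.add.at(f, b, params.angle_k * (dc_dv1 - dc_dv2))
        np.add.at(f, c, params.angle_k * dc_dv2)

    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on bead {bad}")
    return f
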