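"""Structural statistics of simulated chromatin ensembles.

Covers the liquid-crystalline orientation order parameter and its
spectrum, backbone coarsening, cylindrical (radial) density profiles
around the centromere-telomere axis, per-bead surface exposure,
chromosome-territory metrics, accessibility-signal classification, and
conversion from reduced length units to micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .engine import NucleusGeometry, Trajectory
from .michrom import GenomeSpec

__all__ = [
    "AnalysisProfile",
    "orientation_order_parameter",
    "oop_spectrum",
    "coarsen_backbone",
    "cylindrical_density",
    "exposed_area",
    "territory_metrics",
    "to_physical_units",
    "classify_signal_bins",
    "compartment_overlap",
]

SIGMA_50KB_UM = 0.165  # bead diameter at 50 kb/bead, micrometres


@dataclass
class AnalysisProfile:
    """1D curve keyed by genomic distance, radius, or period."""

    x: np.ndarray
    y: np.ndarray
    kind: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.x, self.y]),
                   delimiter="\t", header=f"x\t{self.kind}")


def _frames(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return np.asarray(traj.frames)
    arr = np.asarray(traj, dtype=float)
    return arr[None] if arr.ndim == 2 else arr


def orientation_order_parameter(traj, spec: GenomeSpec,
                                span: int = 4) -> AnalysisProfile:
    """Orientation order parameter O_OP(d): mean over frames and chain
    positions of the dot product between unit vectors joining beads
    [i, i+span] and [i+d, i+d+span], within one chromosome. Oscillations
    with d indicate helical (fibril) order."""
    frames = _frames(traj)
    n = spec.n_beads
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [n]])
    max_d = max(int(stop - start) - span - 1 for start, stop in zip(starts, stops))
    if max_d < 1:
        raise ValueError("chromosomes too short for the requested span")
    sums = np.zeros(max_d + 1)
    counts = np.zeros(max_d + 1)
    for fr in frames:
        for start, stop in zip(starts.tolist(), stops.tolist()):
            seg = fr[start:stop]
            v = seg[span:] - seg[:-span]
            norm = np.linalg.norm(v, axis=1)
            ok = norm > 1e-12
            if not ok.all():
                warnings.warn("zero-length segment vector skipped")
            u = np.zeros_like(v)
            u[ok] = v[ok] / norm[ok, None]
            m = len(u)
            for d in range(1, m):
                val = np.einsum("ij,ij->i", u[:-d], u[d:])
                w = ok[:-d] & ok[d:]
                sums[d] += val[w].sum()
                counts[d] += w.sum()
    d = np.arange(1, max_d + 1)
    with np.errstate(invalid="ignore"):
        y = np.where(counts[1:] > 0, sums[1:] / np.maximum(counts[1:], 1), np.nan)
    return AnalysisProfile(x=d.astype(float), y=y, kind="OOP",
                           metadata={"span": span, "bin_size": spec.bin_size})


def oop_spectrum(profile: AnalysisProfile, bin_size: int,
                 prominence_factor: float = 3.0):
    """Magnitude spectrum of the mean-subtracted O_OP(d) with the x axis
    expressed as spatial period in megabases; returns the spectrum
    profile and the detected peak periods (local maxima whose prominence
    exceeds ``prominence_factor`` times the median amplitude)."""
    if profile.kind != "OOP":
        raise ValueError("expected an OOP profile")
    y = np.asarray(profile.y, dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    if len(y) < 8:
        raise ValueError("profile too short for spectral analysis")
    y = y - y.mean()
    amp = np.abs(np.fft.rfft(y))[1:]  # drop the zero-frequency bin
    k = np.arange(1, len(amp) + 1)
    period_mb = (len(y) / k) * bin_size / 1e6
    order = np.argsort(period_mb)
    spectrum = AnalysisProfile(x=period_mb[order], y=amp[order], kind="spectrum",
                               metadata={"bin_size": bin_size})
    med = np.median(amp) if np.median(amp) > 0 else amp.max() * 1e-3
    peaks, _ = find_peaks(spectrum.y, prominence=prominence_factor * med)
    # also admit boundary maxima (longest-period end of the spectrum)
    if len(spectrum.y) > 1 and spectrum.y[-1] > spectrum.y[-2] and (
        spectrum.y[-1] > prominence_factor * med
    ):
        peaks = np.append(peaks, len(spectrum.y) - 1)
    peak_periods = spectrum.x[peaks]
    return spectrum, peak_periods


def coarsen_backbone(coords: np.ndarray, spec: GenomeSpec,
                     window: int = 10) -> np.ndarray:
    """Average non-overlapping blocks of ``window`` consecutive beads per
    chromosome (trailing partial block averaged over its members)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    coords = np.asarray(coords, dtype=float)
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [spec.n_beads]])
    out = []
    for a, b in zip(starts.tolist(), stops.tolist()):
        for lo in range(a, b, window):
            out.append(coords[lo:min(lo + window, b)].mean(axis=0))
    return np.array(out)


def cylindrical_density(traj, spec: GenomeSpec, geometry: NucleusGeometry,
                        labels: np.ndarray, n_radial_bins: int = 20,
                        n_sections: int = 1, r_max: float | None = None):
    """Radial density of beads around the centromere-telomere axis.

    For each label category, histogram of bead distances from the polar
    axis, normalized per cylindrical-shell volume (proportional to
    r dr) and per frame; optionally split into ``n_sections`` equal
    axial slabs (then each category maps to a list of profiles, one per
    slab, ordered from the telomere to the centromere pole).
    """
    frames = _frames(traj)
    labels = np.asarray(labels)
    if len(labels) != spec.n_beads:
        raise ValueError("labels must cover all beads")
    if geometry.pole_separation <= 0:
        raise ValueError("degenerate axis: poles coincide")
    axis = geometry.pole_axis
    flat = frames.reshape(-1, 3)
    ax = flat @ axis
    perp = flat - ax[:, None] * axis
    radius = np.linalg.norm(perp, axis=1)
    if r_max is None:
        r_max = max(radius.max(), 1e-9) * (1 + 1e-9)
    edges = np.linspace(0.0, r_max, n_radial_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    half_l = 0.5 * geometry.pole_separation
    sec_edges = np.linspace(-half_l, half_l, n_sections + 1)
    cat_of = np.tile(labels, len(frames))
    out = {}
    for cat in np.unique(labels):
        sel_cat = cat_of == cat
        profiles = []
        for s in range(n_sections):
            if n_sections == 1:
                sel = sel_cat
            else:
                in_slab = (ax >= sec_edges[s]) & (ax < sec_edges[s + 1])
                if s == n_sections - 1:
                    in_slab = (ax >= sec_edges[s]) & (ax <= sec_edges[s + 1])
                sel = sel_cat & in_slab
            counts, _ = np.histogram(radius[sel], bins=edges)
            dens = counts / shell / len(frames)
            profiles.append(AnalysisProfile(
                x=mids, y=dens, kind="radial_density",
                metadata={"category": str(cat), "section": s,
                          "raw_counts": counts, "n_frames": len(frames)},
            ))
        out[cat] = profiles[0] if n_sections == 1 else profiles
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def exposed_area(coords: np.ndarray, spec: GenomeSpec,
                 bead_radius: float = 0.5, n_directions: int = 92) -> np.ndarray:
    """Normalized solvent-exposed area per bead in [0, 1].

    Direction-sampling estimator: test points are placed on a sphere of
    radius (bead radius + probe radius) around each bead, with the probe
    radius equal to the bead radius; a point is occluded if it lies
    within that same contact radius of any other bead centre. The value
    is the unoccluded fraction of directions (1 = isolated bead).
    """
    if n_directions < 32:
        raise ValueError("n_directions must be >= 32")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    contact_r = 2.0 * bead_radius  # bead radius + probe radius
    dirs = fibonacci_sphere(n_directions)
    tree = cKDTree(coords)
    neighbors = tree.query_ball_point(coords, r=2.0 * contact_r)
    out = np.ones(n)
    for i in range(n):
        nb = [j for j in neighbors[i] if j != i]
        if not nb:
            continue
        if np.any(np.all(coords[nb] == coords[i], axis=1)):
            warnings.warn(f"bead {i} overlaps an identical coordinate")
        pts = coords[i] + contact_r * dirs  # (D, 3)
        diff = pts[:, None, :] - coords[nb][None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        occluded = (d2 < contact_r**2).any(axis=1)
        out[i] = 1.0 - occluded.mean()
    return out


def territory_metrics(traj, spec: GenomeSpec,
                      geometry: NucleusGeometry | None = None,
                      coarse_window: int = 10) -> dict:
    """Per-chain shape and mixing statistics, averaged over frames.

    * ``elongation``: sqrt(lambda_max / lambda_min) of each chain's
      gyration tensor (1 for a sphere-like blob, large for a rod).
    * ``overlap``: fraction of a chain's beads lying within 1 sigma of a
      bead from another chain (NaN for single-chain systems).
    * ``cen_tel_distance``: distance between centromere and telomere
      bead centroids, per chain.
    * ``contour_length``: summed segment length of the coarse backbone.
    """
    frames = _frames(traj)
    starts = spec.chrom_starts
    stops = np.concatenate([starts[1:], [spec.n_beads]])
    n_chains = len(starts)
    elong = np.zeros(n_chains)
    contour = np.zeros(n_chains)
    ct_dist = np.zeros(n_chains)
    overlap = np.zeros(n_chains)
    for fr in frames:
        for c, (a, b) in enumerate(zip(starts.tolist(), stops.tolist())):
            x = fr[a:b]
            centered = x - x.mean(axis=0)
            gyr = centered.T @ centered / len(x)
            w = np.linalg.eigvalsh(gyr)
            elong[c] += np.sqrt(w[-1] / max(w[0], 1e-300))
            coarse = coarsen_backbone(
                x,
                GenomeSpec(n_beads=len(x), bin_size=spec.bin_size,
                           chrom_of=np.zeros(len(x), dtype=int),
                           type_of=np.array(["A"] * len(x)),
                           telomere_beads=np.array([], dtype=int),
                           centromere_beads=np.array([], dtype=int)),
                window=coarse_window,
            )
            contour[c] += np.linalg.norm(np.diff(coarse, axis=0), axis=1).sum()
            tel = spec.telomere_beads[(spec.telomere_beads >= a)
                                      & (spec.telomere_beads < b)]
            cen = spec.centromere_beads[(spec.centromere_beads >= a)
                                        & (spec.centromere_beads < b)]
            if len(tel) and len(cen):
                ct_dist[c] += np.linalg.norm(fr[tel].mean(axis=0)
                                             - fr[cen].mean(axis=0))
        if n_chains > 1:
            chain_of = spec.chrom_of
            tree = cKDTree(fr)
            pairs = tree.query_pairs(r=1.0, output_type="ndarray")
            close = np.zeros(spec.n_beads, dtype=bool)
            if len(pairs):
                other = chain_of[pairs[:, 0]] != chain_of[pairs[:, 1]]
                close[pairs[other, 0]] = True
                close[pairs[other, 1]] = True
            for c, (a, b) in enumerate(zip(starts.tolist(), stops.tolist())):
                overlap[c] += close[a:b].mean()
    nf = len(frames)
    return {
        "elongation": elong / nf,
        "overlap": overlap / nf if n_chains > 1 else np.full(n_chains, np.nan),
        "cen_tel_distance": ct_dist / nf,
        "contour_length": contour / nf,
    }


def to_physical_units(length_in_sigma: float, resolution: int = 100_000) -> float:
    """Convert a reduced-unit length to micrometres.

    The bead diameter scales with bin size at constant chromatin density:
    sigma(res) = sigma_50kb * (res / 50 kb)^(1/3), sigma_50kb = 0.165 um;
    hence sigma_100kb = 2^(1/3) * 0.165 = 0.20789 um.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    sigma_um = SIGMA_50KB_UM * (resolution / 50_000.0) ** (1.0 / 3.0)
    return float(length_in_sigma) * sigma_um


def classify_signal_bins(signal: np.ndarray, hi_pct: float = 95.0,
                         lo_pct: float = 5.0) -> np.ndarray:
    """Label bins by signal intensity: 'high' at or above the hi_pct
    percentile, 'low' at or below the lo_pct percentile, 'mid' between;
    NaN bins get 'NA'. Percentiles are computed on non-NaN values and
    both thresholds are inclusive."""
    signal = np.asarray(signal, dtype=float)
    ok = np.isfinite(signal)
    if not ok.any():
        raise ValueError("signal is all-NA")
    hi = np.percentile(signal[ok], hi_pct)
    lo = np.percentile(signal[ok], lo_pct)
    out = np.full(len(signal), "mid", dtype=object)
    out[ok & (signal >= hi)] = "high"
    out[ok & (signal <= lo)] = "low"
    out[~ok] = "NA"
    return out


def compartment_overlap(labels_signal: np.ndarray,
                        labels_compartment: np.ndarray) -> dict:
    """Joint distribution of signal classes and compartments.

    Returns P(compartment = A | signal = high), P(compartment = B |
    signal = low), and the full contingency table (rows A/B/NA, columns
    high/mid/low).
    """
    sig = np.asarray(labels_signal, dtype=object)
    comp = np.asarray(labels_compartment, dtype=object)
    if len(sig) != len(comp):
        raise ValueError("label tracks must be aligned")
    table = {c: {s: int(((comp == c) & (sig == s)).sum())
                 for s in ("high", "mid", "low")}
             for c in ("A", "B", "NA")}
    n_high = sum(table[c]["high"] for c in table)
    n_low = sum(table[c]["low"] for c in table)
    if n_high == 0 or n_low == 0:
        warnings.warn("no high or no low bins; fractions set NA")
    p_a_high = table["A"]["high"] / n_high if n_high else np.nan
    p_b_low = table["B"]["low"] / n_low if n_low else np.nan
    return {"p_A_given_high": p_a_high, "p_B_given_low": p_b_low,
            "table": table}
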