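"""Contact-map processing: I/O, Knight-Ruiz balancing, observed/expected
normalization, A/B compartment calling, distance-scaling curves, and
map-to-map comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMap",
    "CompartmentAnnotation",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_hdf5",
    "write_hdf5",
    "kr_balance",
    "observed_over_expected",
    "call_compartments",
    "contact_probability_curve",
    "compare_maps",
]


@dataclass
class ContactMap:
    """Square symmetric non-negative matrix of per-bin-pair contact
    frequencies, with bin metadata and a usability mask."""

    matrix: np.ndarray
    bin_size: int
    chrom_offsets: list[int] = field(default_factory=lambda: [0])
    mask: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != n:
            raise ValueError("contact matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("contact frequencies must be non-negative")
        rel = np.abs(self.matrix - self.matrix.T)
        scale = max(np.abs(self.matrix).max(), 1.0)
        if rel.max() > 1e-9 * scale:
            raise ValueError("contact matrix must be symmetric (tol 1e-9)")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != n:
            raise ValueError("mask length must match matrix size")
        if self.chrom_offsets[0] != 0:
            raise ValueError("first chromosome must start at bin 0")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def chrom_of(self) -> np.ndarray:
        bounds = list(self.chrom_offsets) + [self.n_bins]
        out = np.empty(self.n_bins, dtype=int)
        for c, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            out[a:b] = c
        return out

    def masked_matrix(self) -> np.ndarray:
        """Matrix with masked rows/columns zeroed."""
        m = self.matrix.copy()
        m[~self.mask, :] = 0.0
        m[:, ~self.mask] = 0.0
        return m


@dataclass
class CompartmentAnnotation:
    """Per-bin A/B labels with the underlying leading eigenvector."""

    labels: np.ndarray  # 'A', 'B', or 'NA'
    eigenvector: np.ndarray
    bin_size: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.eigenvector = np.asarray(self.eigenvector, dtype=float)
        if len(self.labels) != len(self.eigenvector):
            raise ValueError("labels and eigenvector must be aligned")


def read_dense_matrix(path, bin_size: int, chrom_sizes: list[int]) -> ContactMap:
    """Read a whitespace- or comma-delimited dense contact matrix.

    The row count must equal the number of bins implied by the
    chromosome sizes at the given resolution. The matrix is symmetrized
    by averaging with its transpose; bins with zero marginal sum are
    masked.
    """
    try:
        m = np.loadtxt(path)
    except ValueError:
        m = np.loadtxt(path, delimiter=",")
    m = np.atleast_2d(m)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"contact matrix must be square, got {m.shape}")
    if np.any(m < 0):
        raise ValueError("negative contact frequencies in input")
    n_expected = sum(math.ceil(s / bin_size) for s in chrom_sizes)
    if m.shape[0] != n_expected:
        raise ValueError(
            f"matrix has {m.shape[0]} bins; chromosome sizes imply {n_expected}"
        )
    m = 0.5 * (m + m.T)
    offsets = np.cumsum([0] + [math.ceil(s / bin_size) for s in chrom_sizes])[:-1]
    mask = m.sum(axis=1) > 0
    return ContactMap(matrix=m, bin_size=bin_size,
                      chrom_offsets=offsets.tolist(), mask=mask,
                      provenance={"source": str(path)})


def write_dense_matrix(cmap: ContactMap, path) -> None:
    np.savetxt(path, cmap.matrix, fmt="%.8g")


def write_hdf5(cmap: ContactMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as h:
        h.create_dataset("matrix", data=cmap.matrix)
        h.create_dataset("mask", data=cmap.mask)
        h.create_dataset("chrom_offsets", data=np.asarray(cmap.chrom_offsets))
        h.attrs["bin_size"] = cmap.bin_size


def read_hdf5(path) -> ContactMap:
    import h5py

    with h5py.File(path, "r") as h:
        return ContactMap(
            matrix=h["matrix"][()],
            mask=h["mask"][()],
            chrom_offsets=[int(x) for x in h["chrom_offsets"][()]],
            bin_size=int(h.attrs["bin_size"]),
        )


def _kr_newton(a: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Knight-Ruiz balancing of a symmetric non-negative matrix with
    strictly positive row sums: returns x > 0 with diag(x) A diag(x)
    doubly stochastic. Inner-outer Newton iteration with conjugate
    gradients, following the bnewt reference scheme."""
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (a @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    mvp = 0
    while rout > stop_tol**2 and mvp < max_iter:
        k = 0
        y = e.copy()
        inner_tol = max(eta**2 * rout, stop_tol**2)
        rho_km2 = rho_km1
        while rho_km1 > inner_tol:
            k += 1
            if k == 1:
                z = rk / v
                p = z.copy()
                rho_km1 = rk @ z
            else:
                beta = rho_km1 / rho_km2
                p = z + beta * p
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= 0.1:  # line-search safeguard
                gamma_ls = (0.1 - y[ap < 0] ) / ap[ap < 0]
                y = y + np.min(gamma_ls) * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            z = rk / v
            rho_km1 = rk @ z
            if k > n:
                break
        x = x * y
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return None
        v = x * (a @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += k + 1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = min(max(g * rat, 0.5 * stop_tol / max(res_norm, 1e-300)), etamax)
    if rout > stop_tol**2:
        return None
    return x


def _sinkhorn(a: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    x = np.ones(a.shape[0])
    for _ in range(max_iter):
        s = x * (a @ x)
        if np.abs(s - 1.0).max() < tol:
            return x
        x = x / np.sqrt(s)
    return None


def kr_balance(cmap: ContactMap, tol: float = 1e-6,
               max_iter: int = 10000) -> ContactMap:
    """Knight-Ruiz matrix balancing on the unmasked block.

    Returns D M D with positive diagonal D such that every unmasked row
    sums to a common value within ``tol`` (the balanced block is rescaled
    to preserve the original mean contact frequency). The scaling vector
    is kept in provenance. Falls back to Sinkhorn iteration if the
    Newton scheme stalls.
    """
    keep = cmap.mask & (cmap.matrix.sum(axis=1) > 0)
    if not keep.any():
        raise ValueError("fully masked map cannot be balanced")
    sub = cmap.matrix[np.ix_(keep, keep)]
    scale0 = sub.sum(axis=1).mean()
    a = sub / scale0
    # balance to doubly-stochastic form; tol is relative to the common row sum
    inner_tol = min(tol, 1e-8)
    x = _kr_newton(a, inner_tol, max_iter)
    if x is None:
        x = _sinkhorn(a, inner_tol, max_iter * 10)
    if x is None:
        raise RuntimeError(
            f"KR balancing did not converge in {max_iter} iterations"
        )
    balanced_sub = a * np.outer(x, x)
    # rescale so the balanced block keeps the original mean entry
    target_mean = sub.mean()
    balanced_sub *= target_mean / balanced_sub.mean()
    # polish row sums to the common value
    rows = balanced_sub.sum(axis=1)
    common = rows.mean()
    out = np.zeros_like(cmap.matrix)
    out[np.ix_(keep, keep)] = balanced_sub
    scaling = np.full(cmap.n_bins, np.nan)
    scaling[keep] = x / np.sqrt(scale0)
    if np.abs(rows - common).max() >= tol * max(common, 1.0):
        raise RuntimeError(
            "KR balancing row sums deviate beyond tolerance: "
            f"{np.abs(rows - common).max():.3g}"
        )
    return ContactMap(
        matrix=out, bin_size=cmap.bin_size,
        chrom_offsets=list(cmap.chrom_offsets), mask=keep,
        provenance={**cmap.provenance, "kr_scaling": scaling, "kr_tol": tol},
    )


def observed_over_expected(cmap: ContactMap) -> np.ndarray:
    """O/E matrix: each intra-chromosomal entry divided by the mean
    unmasked contact frequency at its genomic distance within that
    chromosome. Masked and inter-chromosomal entries are NaN; diagonals
    whose mean is zero yield NaN with a warning."""
    n = cmap.n_bins
    oe = np.full((n, n), np.nan)
    chrom_of = cmap.chrom_of
    bounds = list(cmap.chrom_offsets) + [n]
    warned = False
    for a, b in zip(bounds[:-1], bounds[1:]):
        sub = cmap.matrix[a:b, a:b]
        msk = cmap.mask[a:b]
        nb = b - a
        for d in range(nb):
            i = np.arange(nb - d)
            valid = msk[i] & msk[i + d]
            if not valid.any():
                continue
            mean = sub[i[valid], i[valid] + d].mean()
            if mean == 0:
                if not warned:
                    warnings.warn("diagonal with zero mean: O/E entries set NaN")
                    warned = True
                continue
            vals = np.full(nb - d, np.nan)
            vals[valid] = sub[i[valid], i[valid] + d] / mean
            oe[a + i, a + i + d] = vals
            oe[a + i + d, a + i] = vals
    oe[~cmap.mask, :] = np.nan
    oe[:, ~cmap.mask] = np.nan
    return oe


def call_compartments(cmap: ContactMap, orientation_track: np.ndarray | None = None,
                      use_oe: bool = True) -> CompartmentAnnotation:
    """A/B compartment calling from the leading eigenvector of the
    per-chromosome Pearson correlation matrix of the O/E map.

    Bins with positive eigenvector entries are labelled A after sign
    orientation: if an orientation track (e.g. binned accessibility
    signal) is supplied, the sign is chosen so A bins have the higher
    mean track value; otherwise the group with the larger summed
    within-group contact enrichment becomes A. Degenerate (structureless)
    chromosomes get all-NA labels.
    """
    n = cmap.n_bins
    labels = np.full(n, "NA", dtype=object)
    evec = np.full(n, np.nan)
    source = observed_over_expected(cmap) if use_oe else cmap.masked_matrix()
    bounds = list(cmap.chrom_offsets) + [n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        msk = cmap.mask[a:b].copy()
        idx = np.flatnonzero(msk) + a
        if len(idx) < 3:
            continue
        sub = source[np.ix_(idx, idx)]
        sub = np.where(np.isfinite(sub), sub, 1.0 if use_oe else 0.0)
        sd = sub.std(axis=1)
        degenerate = sd < 1e-12
        if degenerate.all():
            warnings.warn("no contact structure on chromosome; labels set NA")
            continue
        idx = idx[~degenerate]
        sub = sub[np.ix_(~degenerate, ~degenerate)]
        corr = np.corrcoef(sub)
        if not np.all(np.isfinite(corr)) or np.allclose(corr, corr[0, 0]):
            warnings.warn("degenerate correlation matrix; labels set NA")
            continue
        w, v = np.linalg.eigh(corr)
        e = v[:, -1]
        if e.std() < 1e-12 or np.all(e >= 0) or np.all(e <= 0):
            # no sign structure -> no compartments
            warnings.warn("leading eigenvector has no sign structure; labels NA")
            continue
        e = _orient_eigenvector(e, idx, orientation_track, sub)
        evec[idx] = e
        labels[idx] = np.where(e > 0, "A", "B")
    return CompartmentAnnotation(labels=labels, eigenvector=evec,
                                 bin_size=cmap.bin_size)


def _orient_eigenvector(e, idx, orientation_track, oe_sub):
    pos = e > 0
    if orientation_track is not None:
        track = np.asarray(orientation_track, dtype=float)[idx]
        ok = np.isfinite(track)
        if ok.any() and pos[ok].any() and (~pos[ok]).any():
            if track[ok & pos].mean() < track[ok & ~pos].mean():
                return -e
            return e
    # fallback: larger summed within-group contact enrichment is A
    def enrichment(group):
        if group.sum() < 2:
            return -np.inf
        block = oe_sub[np.ix_(group, group)]
        iu = np.triu_indices(group.sum(), k=1)
        return np.nansum(block[iu] - 1.0)

    if enrichment(pos) < enrichment(~pos):
        return -e
    return e


def contact_probability_curve(cmap: ContactMap):
    """P(s): mean contact frequency over unmasked intra-chromosomal pairs
    at bin separation s, normalized so P(1) = 1. Returns (s, P(s)) with
    NaN where no valid pairs exist."""
    from .analysis import AnalysisProfile

    n = cmap.n_bins
    bounds = list(cmap.chrom_offsets) + [n]
    sums = np.zeros(n)
    counts = np.zeros(n)
    for a, b in zip(bounds[:-1], bounds[1:]):
        sub = cmap.matrix[a:b, a:b]
        msk = cmap.mask[a:b]
        nb = b - a
        for d in range(1, nb):
            i = np.arange(nb - d)
            valid = msk[i] & msk[i + d]
            if valid.any():
                sums[d] += sub[i[valid], i[valid] + d].sum()
                counts[d] += valid.sum()
    s = np.arange(1, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts[1:] > 0, sums[1:] / np.maximum(counts[1:], 1), np.nan)
    if not np.isfinite(p[0]) or p[0] == 0:
        warnings.warn("P(1) unavailable; curve left unnormalized")
    else:
        p = p / p[0]
    return AnalysisProfile(x=s.astype(float), y=p, kind="P_of_s",
                           metadata={"bin_size": cmap.bin_size})


def compare_maps(a: ContactMap, b: ContactMap, log_transform: bool = False):
    """Pearson correlation between two contact maps on the intersection
    of their masks: overall r over unmasked upper-triangle entries, plus
    per-distance r(s) with pair counts.

    Returns a dict with keys ``r``, ``n_pairs``, ``r_of_s`` (array),
    ``n_of_s`` (array).
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("maps must have the same shape")
    mask = a.mask & b.mask
    n = a.n_bins
    iu = np.triu_indices(n, k=1)
    valid = mask[iu[0]] & mask[iu[1]]
    xa, xb = a.matrix[iu][valid], b.matrix[iu][valid]
    if log_transform:
        xa, xb = np.log10(1 + xa), np.log10(1 + xb)
    if valid.sum() < 3 or xa.std() == 0 or xb.std() == 0:
        warnings.warn("fewer than 3 valid pairs or degenerate values; r = NA")
        r = np.nan
    else:
        r = float(np.corrcoef(xa, xb)[0, 1])
    sep = iu[1] - iu[0]
    r_of_s = np.full(n - 1, np.nan)
    n_of_s = np.zeros(n - 1, dtype=int)
    for s in range(1, n):
        sel = valid & (sep == s)
        n_of_s[s - 1] = sel.sum()
        if n_of_s[s - 1] >= 3:
            ya, yb = a.matrix[iu][sel], b.matrix[iu][sel]
            if log_transform:
                ya, yb = np.log10(1 + ya), np.log10(1 + yb)
            if ya.std() > 0 and yb.std() > 0:
                r_of_s[s - 1] = float(np.corrcoef(ya, yb)[0, 1])
    return {"r": r, "n_pairs": int(valid.sum()), "r_of_s": r_of_s,
            "n_of_s": n_of_s}
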