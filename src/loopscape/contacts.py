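"""Contact-matrix computations: Knight-Ruiz balancing, observed/expected
transform, A/B compartment eigenvector, and virtual-4C (EIS) profiles.

A/B compartments are recovered from the leading eigenvector of the Pearson
correlation matrix of the balanced observed/expected map; the eigenvector sign
is arbitrary, so it is oriented against a reference track of known polarity
(e.g. an activity or methylation-derived compartment track) with positive
values denoting the A (open) compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomicInterval

_STATES = ("raw", "balanced", "oe")


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact matrix at fixed resolution."""

    chrom: str
    resolution: int
    matrix: np.ndarray
    total_valid_pairs: float
    state: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("matrix must be square")
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}")
        finite = self.matrix[np.isfinite(self.matrix)]
        if np.any(finite < 0):
            raise ValueError("matrix entries must be non-negative")
        if not np.allclose(
            np.nan_to_num(self.matrix), np.nan_to_num(self.matrix.T),
            rtol=1e-8, atol=1e-8,
        ):
            raise ValueError("matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, interval: GenomicInterval) -> int:
        if interval.chrom != self.chrom:
            raise ValueError(f"anchor on {interval.chrom}, matrix is {self.chrom}")
        mid = (interval.start + interval.end) // 2
        b = mid // self.resolution
        if not 0 <= b < self.n_bins:
            raise ValueError(f"anchor {interval} outside matrix")
        return int(b)


@dataclass
class Virtual4CProfile:
    """Smoothed, valid-pair-normalized interaction profile of one anchor bin."""

    anchor_bin: int
    values: np.ndarray
    window_bins: int
    chrom: str = ""
    resolution: int = 0


def _kr_core(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz balancing of a symmetric positive matrix.

    Inner-outer Newton iteration with conjugate-gradient inner solves
    (Knight & Ruiz's bnewt scheme). Returns x with diag(x) A diag(x)
    doubly stochastic (row sums 1).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    n_outer = 0
    mvp = 0

    while np.sqrt(rout) > stop_tol:
        n_outer += 1
        if n_outer > max_iter:
            raise RuntimeError(
                f"KR balancing did not converge after {max_iter} outer "
                f"iterations (residual {np.sqrt(rout):.3e})"
            )
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, stop_tol**2)
        rho_km2 = rho_km1

        Z = rk / v
        p = Z.copy()
        rho_km1 = rk @ Z
        while rho_km1 > innertol:
            k += 1
            if k > 1:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            mvp += 1
            denom = p @ w
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k >= n or mvp > max_iter * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = min(eta, etamax)
        if res_norm > 0:
            eta = max(eta, stop_tol / res_norm)
    return x


def kr_balance(
    cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000
) -> tuple[ContactMatrix, np.ndarray]:
    """Knight-Ruiz balance a raw matrix so unmasked row sums equal 1.

    Bins with zero marginal (no signal) are masked out of the solve; their
    rows/columns come back as NaN and their scaling entries as NaN. Returns
    the balanced matrix and the per-bin scaling vector.
    """
    if cm.state != "raw":
        raise ValueError(f"kr_balance expects a raw matrix, got {cm.state!r}")
    M = cm.matrix
    marginal = np.nansum(M, axis=1)
    mask = marginal > 0
    if mask.sum() < 2:
        raise ValueError("fewer than 2 non-empty bins; cannot balance")
    A = M[np.ix_(mask, mask)]
    # pre-scale to unit mean row sum: the balanced matrix is invariant and
    # the Newton iteration's step bounds assume row sums near 1
    m = A.sum(axis=1).mean()
    x = _kr_core(A / m, tol=tol, max_iter=max_iter) / np.sqrt(m)
    resid = np.max(np.abs(x * (A @ x) - 1.0))
    if resid > tol:
        raise RuntimeError(
            f"KR balancing converged poorly: max |row sum - 1| = {resid:.3e}"
        )
    scale = np.full(cm.n_bins, np.nan)
    scale[mask] = x
    balanced = np.full_like(M, np.nan)
    balanced[np.ix_(mask, mask)] = A * np.outer(x, x)
    return (
        ContactMatrix(
            chrom=cm.chrom,
            resolution=cm.resolution,
            matrix=_symmetrize(balanced),
            total_valid_pairs=cm.total_valid_pairs,
            state="balanced",
        ),
        scale,
    )


def _symmetrize(m: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (m + m.T) / 2.0


def oe_transform(cm: ContactMatrix) -> ContactMatrix:
    """Observed/expected: divide each entry by the mean of its diagonal.

    Diagonal means are computed over unmasked (finite) bins only; an all-zero
    diagonal yields NaN entries on that diagonal.
    """
    if cm.state != "balanced":
        raise ValueError(f"oe_transform expects a balanced matrix, got {cm.state!r}")
    n = cm.n_bins
    out = np.full((n, n), np.nan)
    M = cm.matrix
    for d in range(n):
        diag = np.diagonal(M, offset=d)
        finite = np.isfinite(diag)
        if not np.any(finite):
            continue
        mean = diag[finite].mean()
        if mean == 0:
            continue
        idx = np.arange(n - d)
        out[idx, idx + d] = diag / mean
        out[idx + d, idx] = diag / mean
    return ContactMatrix(
        chrom=cm.chrom,
        resolution=cm.resolution,
        matrix=out,
        total_valid_pairs=cm.total_valid_pairs,
        state="oe",
    )


def compartment_eigenvector(
    cm: ContactMatrix, reference_track: np.ndarray
) -> np.ndarray:
    """Signed per-bin compartment eigenvector from an O/E matrix.

    The leading eigenvector of the Pearson correlation matrix of O/E columns
    (unmasked bins) is computed and its sign flipped when its correlation with
    ``reference_track`` is negative, so positive values follow the track's
    polarity (A compartment). Masked bins are NaN in the output.
    """
    if cm.state != "oe":
        raise ValueError(f"expects an O/E matrix, got {cm.state!r}")
    reference_track = np.asarray(reference_track, dtype=float)
    if reference_track.shape[0] != cm.n_bins:
        raise ValueError("reference track length must equal n_bins")
    M = cm.matrix
    mask = np.isfinite(M).sum(axis=1) >= 2
    sub = M[np.ix_(mask, mask)]
    # Any residual NaN inside unmasked block (isolated all-zero diagonals):
    # replace with column mean so the correlation stays defined.
    col_mean = np.nanmean(sub, axis=0)
    nan_pos = ~np.isfinite(sub)
    if nan_pos.any():
        sub = np.where(nan_pos, np.broadcast_to(col_mean, sub.shape), sub)
    if np.allclose(sub.std(axis=0), 0):
        raise ValueError("degenerate O/E matrix: constant columns")
    corr = np.corrcoef(sub, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix (zero-variance bins)")
    if np.allclose(corr, corr.flat[0]):
        raise ValueError("degenerate (constant) correlation matrix")
    vals, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1]
    ev = np.full(cm.n_bins, np.nan)
    ev[mask] = lead
    both = np.isfinite(ev) & np.isfinite(reference_track)
    if both.sum() >= 2 and np.std(ev[both]) > 0 and np.std(reference_track[both]) > 0:
        r = np.corrcoef(ev[both], reference_track[both])[0, 1]
        if r < 0:
            ev = -ev
    return ev


def virtual_4c(
    cm: ContactMatrix,
    anchor: GenomicInterval,
    window_bins: int = 5,
) -> Virtual4CProfile:
    """Virtual-4C / EIS profile of the bin containing ``anchor``.

    The anchor row is divided by the total number of valid pairs and smoothed
    with a centered rolling mean of ``window_bins`` (shrunken at the edges).
    """
    if cm.state != "raw":
        raise ValueError("virtual_4c operates on the raw matrix")
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be a positive odd integer")
    if cm.total_valid_pairs <= 0:
        raise ValueError("total_valid_pairs must be positive")
    b = cm.bin_of(anchor)
    row = cm.matrix[b] / cm.total_valid_pairs
    smoothed = (
        pd.Series(row)
        .rolling(window=window_bins, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return Virtual4CProfile(
        anchor_bin=b,
        values=smoothed,
        window_bins=window_bins,
        chrom=cm.chrom,
        resolution=cm.resolution,
    )
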