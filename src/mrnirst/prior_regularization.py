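"""Grayscale-weighted direct regularization for MRI-guided NIRST.

The anatomical prior enters the inversion through a sparse weighting matrix
L built from the grayscale values gamma_i of a co-registered MR slice
sampled onto the FEM nodes:

    L_ij = 1                                           (i = j)
    L_ij = -(1/M_i) exp(-|gamma_i - gamma_j|^2 / (2 sigma_g^2))
                    theta(sigma_d - |r_i - r_j| / max|r_i - r_j|)   (i != j)

with M_i the sum of the row's unnormalized Gaussian weights, so every row
with at least one in-range neighbor sums to zero and the penalty ||L x||^2
vanishes on spatially uniform images.  sigma_g is the characteristic
grayscale difference (on intensities normalized to [0, 1]) and sigma_d the
distance of influence as a fraction of the mesh diameter; the Heaviside
cutoff theta is taken strictly (theta(0) = 0).  Defaults sigma_g = 0.01 and
sigma_d = 0.4 follow the values used clinically.

The regularization parameter of the update equation is
lambda = lambda_scale * max(diag(J^T J)) with lambda_scale = 10 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import pdist, squareform

from .phantom_synth import GrayscalePrior, InvalidParameterError, Mesh

__all__ = [
    "RegularizationParams",
    "PriorWeights",
    "DegenerateJacobianError",
    "sample_prior_to_nodes",
    "build_L",
    "regularization_lambda",
    "write_prior_weights_mtx",
]


class DegenerateJacobianError(ValueError):
    """The Jacobian is identically zero; no regularization scale exists."""


@dataclass(frozen=True)
class RegularizationParams:
    """sigma_g: characteristic grayscale difference (normalized intensity);
    sigma_d: distance of influence as a fraction of the mesh diameter;
    lambda_scale: multiplier on max(diag(J^T J))."""

    sigma_g: float = 0.01
    sigma_d: float = 0.4
    lambda_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_g <= 0:
            raise InvalidParameterError("sigma_g must be > 0")
        if not 0.0 < self.sigma_d <= 1.0:
            raise InvalidParameterError("sigma_d must lie in (0, 1]")
        if self.lambda_scale <= 0:
            raise InvalidParameterError("lambda_scale must be > 0")


@dataclass(frozen=True)
class PriorWeights:
    """The assembled weighting matrix with its ingredients."""

    L: sparse.csr_matrix
    M: np.ndarray
    gamma: np.ndarray
    max_pair_distance: float


def sample_prior_to_nodes(prior: GrayscalePrior, mesh: Mesh,
                          method: str = "nearest") -> np.ndarray:
    """Sample the grayscale raster at the mesh nodes, returning nodal values
    in [0, 1] (raw 16-bit counts are divided by 65535).

    ``method`` is "nearest" (default) or "bilinear".
    """
    frac = prior.mm_to_pixel(mesh.nodes)       # (n, 2) as (col, row)
    h, w = prior.pixels.shape
    if method == "nearest":
        cols = np.rint(frac[:, 0]).astype(int)
        rows = np.rint(frac[:, 1]).astype(int)
        bad = (cols < 0) | (cols >= w) | (rows < 0) | (rows >= h)
        if bad.any():
            raise InvalidParameterError(
                f"nodes outside the prior raster: {np.flatnonzero(bad).tolist()}")
        vals = prior.pixels[rows, cols]
    elif method == "bilinear":
        from scipy.ndimage import map_coordinates
        bad = ((frac[:, 0] < -0.5) | (frac[:, 0] > w - 0.5)
               | (frac[:, 1] < -0.5) | (frac[:, 1] > h - 0.5))
        if bad.any():
            raise InvalidParameterError(
                f"nodes outside the prior raster: {np.flatnonzero(bad).tolist()}")
        vals = map_coordinates(prior.pixels, [frac[:, 1], frac[:, 0]],
                               order=1, mode="nearest")
    else:
        raise InvalidParameterError(f"unknown sampling method {method!r}")
    if prior.normalized:
        return np.asarray(vals, float)
    return np.asarray(vals, float) / 65535.0


def build_L(gamma: np.ndarray, node_positions: np.ndarray,
            params: RegularizationParams | None = None) -> PriorWeights:
    """Assemble the grayscale-weighted matrix L.

    Unnormalized weights w_ij = exp(-|gamma_i - gamma_j|^2 / (2 sigma_g^2))
    are applied to node pairs whose distance, normalized by the maximum
    inter-node distance, is strictly below sigma_d; M_i = sum_{j != i} w_ij;
    L_ii = 1 and L_ij = -w_ij / M_i.  Rows with no in-range neighbor keep
    only their unit diagonal (a warning is emitted if all rows are isolated).
    """
    if params is None:
        params = RegularizationParams()
    gamma = np.asarray(gamma, float)
    pos = np.asarray(node_positions, float)
    n = len(gamma)
    if pos.shape[0] != n:
        raise InvalidParameterError("gamma length must equal node count")
    if n == 1:
        return PriorWeights(L=sparse.identity(1, format="csr"),
                            M=np.zeros(1), gamma=gamma, max_pair_distance=0.0)

    dist = squareform(pdist(pos))
    dmax = float(dist.max())
    if dmax == 0.0:
        raise InvalidParameterError("all node positions coincide")
    within = (dist / dmax) < params.sigma_d
    np.fill_diagonal(within, False)

    gdiff = gamma[:, None] - gamma[None, :]
    w = np.exp(-(gdiff ** 2) / (2.0 * params.sigma_g ** 2))
    w = np.where(within, w, 0.0)
    m = w.sum(axis=1)
    if (m == 0).all():
        warnings.warn("sigma_d below minimum node spacing: L is the identity",
                      stacklevel=2)
    off = np.zeros_like(w)
    connected = m > 0
    off[connected] = -w[connected] / m[connected, None]
    lmat = sparse.csr_matrix(off) + sparse.identity(n, format="csr")
    return PriorWeights(L=lmat.tocsr(), M=m, gamma=gamma,
                        max_pair_distance=dmax)


def regularization_lambda(J: np.ndarray,
                          params: RegularizationParams | None = None) -> float:
    """lambda = lambda_scale * max(diag(J^T J)), the scaling rule used for
    the prior penalty in the update equation."""
    if params is None:
        params = RegularizationParams()
    J = np.asarray(J, float)
    if J.size == 0:
        raise DegenerateJacobianError("empty Jacobian")
    col_sq = np.einsum("ij,ij->j", J, J)
    peak = float(col_sq.max())
    if peak == 0.0:
        raise DegenerateJacobianError("Jacobian is identically zero")
    return params.lambda_scale * peak


def write_prior_weights_mtx(weights: PriorWeights, path) -> None:
    """Export L in MatrixMarket sparse format for inspection."""
    from scipy.io import mmwrite

    mmwrite(str(path), weights.L.tocoo())
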