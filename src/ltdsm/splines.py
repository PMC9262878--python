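"""Low-rank thin-plate regression splines.

A thin-plate spline in d dimensions (d = 1 or 2, penalty order m = 2)
represents a smooth as a radial-basis expansion on the data points plus
a low-order polynomial null space, penalised by the bending energy.
The full basis has one function per data point; here the radial part is
eigen-truncated to rank ``k`` so that the smooth costs O(k) coefficients
while retaining the optimality properties of the full spline for the
dominant eigen-directions of the penalty.

Construction (for data points x_1..x_n):
  * E_ij = eta(||x_i - x_j||) with eta(r) = r^3 / 12 (d = 1) or
    r^2 log r / (8 pi) (d = 2);
  * E = U D U'; keep the k eigenvectors of largest magnitude;
  * absorb the orthogonality constraint T' U_k delta = 0 (T the
    polynomial null-space model matrix) into the basis via a QR step;
  * penalised design X_s = E U_k Z with penalty S = Z' D_k Z;
  * identifiability with an intercept elsewhere in the model: the
    constant is dropped from the null space and every retained column
    is centred to sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThinPlateSmooth", "tps_eta"]


def tps_eta(r: np.ndarray, d: int) -> np.ndarray:
    """Thin-plate radial basis function for penalty order 2 in d dims."""
    r = np.asarray(r, dtype=float)
    if d == 1:
        return r ** 3 / 12.0
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r * r * np.log(r) / (8.0 * np.pi)
        return np.where(r > 0, out, 0.0)
    raise ValueError("only 1- or 2-dimensional smooths are supported")


def _null_space(x: np.ndarray) -> np.ndarray:
    """Polynomial null-space model matrix T = [1, x (, y)]."""
    n = x.shape[0]
    return np.column_stack([np.ones(n), x])


@dataclass
class ThinPlateSmooth:
    """One thin-plate regression spline term over 1 or 2 covariates.

    Parameters
    ----------
    x : (n, d) array of covariate values at the fitting points.
    k : total basis dimension (penalised rank + null space), k >= 3.

    Attributes after construction
    -----------------------------
    design : (n, k - 1) centred model-matrix block (penalised columns
        followed by the linear null-space columns; constant dropped).
    penalty : (k - 1, k - 1) positive semi-definite penalty matrix
        (zero rows/columns on the null-space part).
    """

    x: np.ndarray
    k: int = 10
    design: np.ndarray = field(init=False, repr=False)
    penalty: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2 or x.shape[1] not in (1, 2):
            raise ValueError("x must be (n,), (n, 1) or (n, 2)")
        n, d = x.shape
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")
        n_distinct = np.unique(x, axis=0).shape[0]
        if self.k > n_distinct:
            raise ValueError(
                f"k = {self.k} exceeds the {n_distinct} distinct covariate points"
            )
        # standardise inputs (common isotropic scale for d = 2)
        self._shift = x.mean(axis=0)
        xc = x - self._shift
        scale = float(np.sqrt((xc ** 2).sum(axis=1).mean()))
        self._scale = scale if scale > 0 else 1.0
        z = xc / self._scale
        self._knots = z
        self._d = d

        M = d + 1  # null-space dimension for m = 2
        E = tps_eta(_pairwise_dist(z, z), d)
        T = _null_space(z)
        evals, evecs = np.linalg.eigh(E)
        order = np.argsort(np.abs(evals))[::-1]
        kk = min(self.k, n)
        Uk = evecs[:, order[:kk]]
        Dk = evals[order[:kk]]
        # absorb T' Uk delta = 0:  Z spans the null space of (T' Uk)
        q, _ = np.linalg.qr((Uk.T @ T), mode="complete")
        Zc = q[:, M:]
        Xs = E @ Uk @ Zc
        S = Zc.T @ (Dk[:, None] * Zc)
        # symmetrise + clip tiny negative ripple
        S = 0.5 * (S + S.T)
        w, V = np.linalg.eigh(S)
        S = (V * np.clip(w, 0.0, None)) @ V.T

        self._Uk = Uk
        self._Zc = Zc
        # centred design: penalised block then linear null-space columns
        lin = T[:, 1:]
        self._col_means = np.concatenate([Xs.mean(axis=0), lin.mean(axis=0)])
        design = np.column_stack([Xs, lin]) - self._col_means
        p = design.shape[1]
        penalty = np.zeros((p, p))
        penalty[: S.shape[0], : S.shape[0]] = S
        self.design = design
        self.penalty = penalty

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    def basis(self, x_new: np.ndarray) -> np.ndarray:
        """Evaluate the centred basis at new covariate values."""
        x_new = np.asarray(x_new, dtype=float)
        if x_new.ndim == 1:
            x_new = x_new[:, None]
        z = (x_new - self._shift) / self._scale
        E = tps_eta(_pairwise_dist(z, self._knots), self._d)
        Xs = E @ self._Uk @ self._Zc
        lin = _null_space(z)[:, 1:]
        return np.column_stack([Xs, lin]) - self._col_means


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))
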