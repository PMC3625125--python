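"""Mass-univariate general linear model and standardized residual fields.

At every in-mask site the N observations y are modelled as y = X b + e.
The ordinary least-squares fit yields per-site effect estimates and
residuals; the residuals are standardized so that each site's N-vector has
sum of squares equal to the error degrees of freedom nu = N - p, making
each residual field a unit-variance (Z-like) random field — the premise of
the regression LKC estimator.

Sites with (numerically) zero residual variance cannot be standardized;
they are removed from the mask for all downstream computation, since both
the Euler characteristic and the intrinsic volumes are defined relative to
the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LatticeField",
    "DesignMatrix",
    "ResidualSet",
    "SPMField",
    "fit_glm",
    "standardize_residuals",
    "one_sample_t",
]


@dataclass
class LatticeField:
    """Real values on the in-mask sites of a regular D-dimensional grid.

    ``values`` is the flat vector of in-mask values in C (row-major) order —
    the order produced by ``full_array[mask]`` and used for the vertices of
    :func:`spmtopo.topology.build_complex` on the same mask.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask.ndim not in (1, 2, 3):
            raise ValueError("mask dimension must be 1, 2 or 3")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.values.shape != (int(self.mask.sum()),):
            raise ValueError("values must be the flat vector of in-mask sites")

    @property
    def shape(self):
        return self.mask.shape

    @property
    def dim(self) -> int:
        return self.mask.ndim

    def to_array(self, fill=np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = self.values
        return out

    @classmethod
    def from_array(cls, arr: np.ndarray, mask: np.ndarray | None = None) -> "LatticeField":
        arr = np.asarray(arr, dtype=float)
        if mask is None:
            mask = np.isfinite(arr)
        return cls(values=arr[np.asarray(mask, bool)], mask=mask)


@dataclass
class DesignMatrix:
    """N x p design matrix; must be full column rank with N > p >= 1."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n, p = self.matrix.shape
        if p < 1 or n <= p:
            raise ValueError(f"need N > p >= 1, got N={n}, p={p}")
        if np.linalg.matrix_rank(self.matrix) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ResidualSet:
    """N standardized residual fields over a common mask.

    ``data`` is (N, n_sites); per site the N-vector has sum of squares df
    (to numerical tolerance), with df = N - p the error degrees of freedom.
    """

    data: np.ndarray
    mask: np.ndarray
    df: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 2 or self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("data must be (N, n_in_mask_sites)")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    def field(self, n: int) -> LatticeField:
        return LatticeField(values=self.data[n], mask=self.mask)


@dataclass
class SPMField:
    """A statistical parametric map with its statistic type and dof."""

    field: LatticeField
    stat_type: str
    dof: tuple

    def __post_init__(self):
        st = self.stat_type.upper()
        self.stat_type = st
        dof = self.dof if isinstance(self.dof, tuple) else (self.dof,)
        self.dof = dof
        if st == "T" and (len(dof) != 1 or dof[0] <= 0):
            raise ValueError("T statistic needs one positive dof")
        if st == "F" and (len(dof) != 2 or min(dof) <= 0):
            raise ValueError("F statistic needs two positive dofs")
        if st not in ("Z", "T", "F"):
            raise ValueError(f"unsupported stat_type {st!r}")


def _as_site_matrix(data, mask):
    """Coerce observations to (N, n_sites) given an optional mask."""
    data = np.asarray(data, dtype=float)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if data.ndim == mask.ndim + 1:
            data = data.reshape(data.shape[0], -1)[:, mask.ravel()]
        elif data.ndim != 2 or data.shape[1] != int(mask.sum()):
            raise ValueError("data shape incompatible with mask")
    else:
        if data.ndim < 2:
            raise ValueError("data must have an observation axis plus sites")
        mask = np.ones(data.shape[1:], dtype=bool)
        data = data.reshape(data.shape[0], -1)
    return data, mask


def fit_glm(data: np.ndarray, design: DesignMatrix | np.ndarray,
            mask: np.ndarray | None = None):
    """Site-wise OLS fit of y = X b + e.

    Parameters
    ----------
    data : (N, n_sites) matrix or (N, *mask.shape) stack of observations.
    design : the N x p design matrix.
    mask : optional boolean array selecting sites when ``data`` is a stack.

    Returns
    -------
    beta : (p, n_sites) effect estimates.
    residuals : (N, n_sites) raw residuals, orthogonal to the design columns.
    """
    if not isinstance(design, DesignMatrix):
        design = DesignMatrix(design)
    data, _ = _as_site_matrix(data, mask)
    if data.shape[0] != design.n:
        raise ValueError(f"data has {data.shape[0]} observations, design has {design.n} rows")
    X = design.matrix
    beta = np.linalg.pinv(X) @ data
    residuals = data - X @ beta
    return beta, residuals


def standardize_residuals(residuals: np.ndarray, p: int,
                          mask: np.ndarray | None = None) -> ResidualSet:
    """Scale per-site residual vectors to squared norm nu = N - p.

    r = sqrt(nu) * e / ||e|| at each site.  Sites with zero residual norm
    (constant data) are dropped from the mask with a logged warning.
    """
    residuals, mask = _as_site_matrix(residuals, mask)
    n = residuals.shape[0]
    nu = n - p
    if nu < 1:
        raise ValueError("need N > p")
    norms = np.linalg.norm(residuals, axis=0)
    ok = norms > 1e-12 * max(1.0, float(np.max(norms, initial=0.0)))
    if not ok.all():
        n_bad = int((~ok).sum())
        logger.warning("standardize_residuals: %d degenerate site(s) removed from mask", n_bad)
        new_mask = mask.copy()
        new_mask[mask] = ok
        mask = new_mask
        residuals = residuals[:, ok]
        norms = norms[ok]
    if not mask.any():
        raise ValueError("all sites degenerate; nothing to standardize")
    r = np.sqrt(nu) * residuals / norms
    return ResidualSet(data=r, mask=mask, df=nu)


def one_sample_t(data: np.ndarray, mask: np.ndarray | None = None):
    """Site-wise one-sample t-test for a non-zero mean.

    Equivalent to an intercept-only GLM: t = mean / (sd / sqrt(N)) with
    N - 1 dof.  Returns the SPM{t} and the standardized residual set from
    the same fit (zero-variance sites are masked out of both).

    Returns
    -------
    spm : SPMField with stat_type 'T' and dof (N - 1,).
    residuals : ResidualSet with df N - 1.
    """
    data, mask = _as_site_matrix(data, mask)
    n = data.shape[0]
    if n < 2:
        raise ValueError("one-sample t-test needs at least 2 observations")
    design = DesignMatrix(np.ones((n, 1)))
    beta, resid = fit_glm(data, design)
    rset = standardize_residuals(resid, p=1, mask=mask)
    keep = rset.mask[mask] if rset.mask.shape == mask.shape else None
    if keep is not None and keep.size and not keep.all():
        beta = beta[:, keep]
        resid = resid[:, keep]
    sd = np.sqrt((resid ** 2).sum(axis=0) / (n - 1))
    t = beta[0] / (sd / np.sqrt(n))
    spm = SPMField(field=LatticeField(values=t, mask=rset.mask), stat_type="T", dof=(n - 1,))
    return spm, rset
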