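"""Euler-characteristic densities for Gaussian, t and F random fields.

The expected EC of the excursion set of a unit-variance random field above
threshold ``u`` is given by the Gaussian Kinematic Formula

    E[phi(A_u)] = sum_{d=0}^{D} L_d(S) * rho_d(u)

where ``L_d`` are the Lipschitz-Killing curvatures of the search space and
``rho_d`` the EC densities of the field type.  Densities here use the
*unit-roughness (LKC) parameterization*, so the formula above holds with no
(4 ln 2) factors; the traditional resel parameterization differs by the
factor (4 ln 2)^(d/2), applied explicitly by ``rho(..., parameterization=
"resel")`` and the resel conversion helpers in :mod:`spmtopo.lkc`.

Closed forms follow the standard random-field-theory literature (Adler's
and Worsley's EC densities for Z, t and F fields up to dimension 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["FieldSpec", "DensityMatrix", "rho", "density_matrix", "threshold_grid"]

_LN4LN2 = np.log(4.0 * np.log(2.0))


@dataclass(frozen=True)
class FieldSpec:
    """Statistic type of a random field: 'Z', 'T' (dof nu) or 'F' (nu1, nu2)."""

    stat_type: str
    dof: tuple | None = None

    def __post_init__(self):
        st = self.stat_type.upper()
        object.__setattr__(self, "stat_type", st)
        if st == "Z":
            if self.dof not in (None, ()):
                raise ValueError("Z fields take no degrees of freedom")
        elif st == "T":
            dof = self.dof if isinstance(self.dof, tuple) else (self.dof,)
            if len(dof) != 1 or dof[0] is None or dof[0] <= 0:
                raise ValueError("T fields need one positive dof")
            object.__setattr__(self, "dof", (float(dof[0]),))
        elif st == "F":
            if self.dof is None or len(self.dof) != 2 or min(self.dof) <= 0:
                raise ValueError("F fields need two positive dofs (nu1, nu2)")
            object.__setattr__(self, "dof", (float(self.dof[0]), float(self.dof[1])))
        else:
            raise ValueError(f"unsupported stat_type {self.stat_type!r}")


@dataclass
class DensityMatrix:
    """EC densities rho_d(u_h) tabulated on a threshold grid.

    ``matrix`` has shape (H, D) with column d-1 holding rho_d; ``rho0`` is
    the separate zero-dimensional density (upper-tail probability).
    """

    thresholds: np.ndarray
    matrix: np.ndarray
    rho0: np.ndarray
    spec: FieldSpec


def _rho_z(d: int, u: np.ndarray) -> np.ndarray:
    if d == 0:
        return stats.norm.sf(u)
    # (2 pi)^-((d+1)/2) * He_{d-1}(u) * exp(-u^2/2), probabilist's Hermite
    return ((2.0 * np.pi) ** (-(d + 1) / 2.0)
            * special.eval_hermitenorm(d - 1, u) * np.exp(-u ** 2 / 2.0))


def _rho_t(d: int, u: np.ndarray, nu: float) -> np.ndarray:
    if d == 0:
        return stats.t.sf(u, nu)
    c = (1.0 + u ** 2 / nu) ** ((1.0 - nu) / 2.0)
    if d == 1:
        return c / (2.0 * np.pi)
    if d == 2:
        g = np.exp(special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0))
        return c * u * g / np.sqrt(nu / 2.0) / (2.0 * np.pi) ** 1.5
    if d == 3:
        return c * ((nu - 1.0) * u ** 2 / nu - 1.0) / (2.0 * np.pi) ** 2


def _rho_f(d: int, u: np.ndarray, k: float, nu: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if d == 0:
        return stats.f.sf(u, k, nu)
    if np.any(u < 0):
        raise ValueError("F-field thresholds must be non-negative")
    lnb = special.gammaln(nu / 2.0) + special.gammaln(k / 2.0)
    x = k * u / nu
    with np.errstate(divide="ignore", invalid="ignore"):
        if d == 1:
            out = (np.exp(special.gammaln((nu + k - 1.0) / 2.0) - lnb) * np.sqrt(2.0)
                   * x ** ((k - 1.0) / 2.0) * (1.0 + x) ** (-(nu + k - 2.0) / 2.0)
                   / np.sqrt(2.0 * np.pi))
        elif d == 2:
            out = (np.exp(special.gammaln((nu + k - 2.0) / 2.0) - lnb)
                   * x ** ((k - 2.0) / 2.0) * (1.0 + x) ** (-(nu + k - 2.0) / 2.0)
                   * ((nu - 1.0) * x - (k - 1.0)) / (2.0 * np.pi))
        else:
            poly = ((nu - 1.0) * (nu - 2.0) * x ** 2
                    - (2.0 * nu * k - nu - k - 1.0) * x
                    + (k - 1.0) * (k - 2.0))
            out = (np.exp(special.gammaln((nu + k - 3.0) / 2.0) - lnb) / np.sqrt(2.0)
                   * x ** ((k - 3.0) / 2.0) * (1.0 + x) ** (-(nu + k - 2.0) / 2.0)
                   * poly / (2.0 * np.pi) ** 1.5)
    return np.where(np.isfinite(out), out, 0.0)


def rho(spec: FieldSpec, d: int, u, parameterization: str = "lkc"):
    """EC density rho_d(u) of the field type in ``spec``.

    Parameters
    ----------
    spec : field type and degrees of freedom.
    d : density dimension, 0..3.
    u : threshold (scalar or array).
    parameterization : 'lkc' (unit-roughness, default) or 'resel'; the
        resel form is the lkc form times (4 ln 2)^(d/2).
    """
    if not 0 <= d <= 3:
        raise ValueError("density dimension d must be in 0..3")
    u_arr = np.asarray(u, dtype=float)
    if spec.stat_type == "Z":
        out = _rho_z(d, u_arr)
    elif spec.stat_type == "T":
        out = _rho_t(d, u_arr, spec.dof[0])
    else:
        out = _rho_f(d, u_arr, spec.dof[0], spec.dof[1])
    if parameterization == "resel":
        out = out * np.exp(d / 2.0 * _LN4LN2)
    elif parameterization != "lkc":
        raise ValueError("parameterization must be 'lkc' or 'resel'")
    return out if np.ndim(u) else float(out)


def density_matrix(spec: FieldSpec, thresholds: np.ndarray, D: int) -> DensityMatrix:
    """Tabulate rho_1..rho_D (columns) and rho_0 on a threshold grid."""
    if D not in (1, 2, 3):
        raise ValueError("D must be 1, 2 or 3")
    thresholds = np.asarray(thresholds, dtype=float)
    if np.unique(thresholds).size != thresholds.size:
        raise ValueError("duplicate thresholds in grid")
    matrix = np.column_stack([rho(spec, d, thresholds) for d in range(1, D + 1)])
    rho0 = rho(spec, 0, thresholds)
    return DensityMatrix(thresholds=thresholds, matrix=matrix, rho0=rho0, spec=spec)


def threshold_grid(lo: float = -4.0, hi: float = 4.0, step: float = 0.1) -> np.ndarray:
    """Inclusive arithmetic threshold grid; default (-4, 4, 0.1) has 81 values.

    Built with ``linspace`` so the endpoints are exact rather than the
    result of accumulated floating-point increments.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, lo + (n - 1) * step, n)
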