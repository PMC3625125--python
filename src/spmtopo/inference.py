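"""Set-level inference: classical threshold-based RFT tests and the
threshold-free multivariate test on Lipschitz-Killing curvatures.

Classical route: the Gaussian Kinematic Formula gives the expected EC of
the excursion set at a feature-defining threshold; at high thresholds this
approximates the probability of any supra-threshold peak (family-wise
error), and the Poisson clumping heuristic turns the expected EC into a
p-value for observing C or more clusters.

Threshold-free route: the regression LKC estimate of the test SPM is
compared with the N per-observation residual-field estimates using a
two-group multivariate GLM.  With a single-degree-of-freedom contrast,
Rao's F approximation to Wilks' lambda is exact and coincides with a
one-observation-versus-group Hotelling T-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from spmtopo.fields_glm import SPMField
from spmtopo.lkc import LKCVector
from spmtopo.rft_density import FieldSpec, rho
from spmtopo.topology import SimplicialComplex, count_clusters

logger = logging.getLogger(__name__)

__all__ = [
    "SetTestResult",
    "ClusterTestResult",
    "expected_ec",
    "p_peak",
    "p_clusters",
    "fwe_threshold",
    "lkc_set_test",
    "mardia_test",
    "classical_set_test",
]


@dataclass
class SetTestResult:
    """Outcome of the multivariate LKC set-level test.

    ``beta_m`` is the 2 x D coefficient matrix of the two-group model:
    row 0 the test-SPM LKC estimate, row 1 the mean residual-field LKC.
    """

    wilks_lambda: float
    f_stat: float
    df: tuple
    p_value: float
    beta_m: np.ndarray

    def to_dict(self) -> dict:
        return {
            "lambda": self.wilks_lambda,
            "F": self.f_stat,
            "df": list(self.df),
            "p": self.p_value,
            "lkc_test": self.beta_m[0].tolist(),
            "lkc_residual_mean": self.beta_m[1].tolist(),
        }


@dataclass
class ClusterTestResult:
    """Outcome of a classical cluster-count set-level test at threshold u."""

    threshold: float
    expected_ec: float
    observed: int
    p_value: float


def expected_ec(lkc: LKCVector, spec: FieldSpec, u) -> float:
    """Expected EC of the excursion set: sum_d l_d * rho_d(u) (GKF)."""
    if lkc.parameterization != "lkc":
        raise ValueError("expected_ec needs the lkc parameterization; convert resels first")
    u_arr = np.asarray(u, dtype=float)
    out = np.zeros_like(u_arr)
    for d in range(lkc.D + 1):
        out = out + lkc.values[d] * rho(spec, d, u_arr)
    return out if np.ndim(u) else float(out)


def p_peak(lkc: LKCVector, spec: FieldSpec, u: float) -> float:
    """P(global max >= u), the high-threshold EC approximation.

    Valid when the expected EC is small (no holes); a warning is logged when
    the expected EC exceeds 1, where the bound saturates.
    """
    lam = expected_ec(lkc, spec, u)
    if lam > 1.0:
        logger.warning("p_peak: expected EC %.3g > 1 at u=%.3g; p-value saturated", lam, u)
    return min(1.0, max(0.0, float(lam)))


def p_clusters(lam: float, C: int) -> float:
    """P(c_max >= C) under the Poisson clumping heuristic with mean lam."""
    if C < 1:
        raise ValueError("C must be >= 1")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return float(stats.poisson.sf(C - 1, lam))


def fwe_threshold(lkc: LKCVector, spec: FieldSpec, alpha: float) -> float:
    """Smallest threshold with expected EC <= alpha (family-wise level).

    A coarse grid scan locates the crossing, refined by bisection to 1e-6.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lo = 0.0 if spec.stat_type == "F" else -10.0
    hi = 50.0
    grid = np.linspace(lo, hi, 2001)
    vals = np.asarray(expected_ec(lkc, spec, grid))
    # the expected-EC curve need not be monotone (odd densities change
    # sign); the FWE threshold is the final downward crossing of alpha
    above = vals > alpha
    if not above.any():
        return float(grid[0])
    i = int(len(vals) - 1 - np.argmax(above[::-1]))  # last index above alpha
    if i == len(vals) - 1:
        raise ValueError(f"expected EC never drops to alpha={alpha} on the search range")
    f = lambda u: expected_ec(lkc, spec, u) - alpha
    return float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-6))


def lkc_set_test(l_test: LKCVector | np.ndarray, l_residuals: np.ndarray) -> SetTestResult:
    """Threshold-free multivariate test: test-SPM LKC versus residual LKCs.

    The single test-SPM estimate (L_1..L_D) is stacked over the N residual
    rows in a two-group multivariate GLM; the group contrast is assessed
    with Wilks' lambda.  With one contrast degree of freedom Rao's F
    approximation is exact: F = ((1 - L)/L) * (v - D + 1)/D with
    v = (N + 1) - 2, on (D, v - D + 1) degrees of freedom.  L_0 is excluded:
    it is identical for test and residuals by construction (same mask) and
    would make the scatter singular.
    """
    if isinstance(l_test, LKCVector):
        x = np.asarray(l_test.values[1:], dtype=float)
    else:
        x = np.asarray(l_test, dtype=float).ravel()
    Y = np.asarray(l_residuals, dtype=float)
    if Y.ndim != 2:
        raise ValueError("l_residuals must be an N x D matrix")
    n, D = Y.shape
    if x.shape != (D,):
        raise ValueError(f"test vector has length {x.size}, residual matrix has D={D}")
    if n <= D + 1:
        raise ValueError(f"need N > D + 1 residual fields (got N={n}, D={D})")

    mean_res = Y.mean(axis=0)
    E = (Y - mean_res).T @ (Y - mean_res)          # within-group scatter, df = N - 1
    diff = x - mean_res
    H = np.outer(diff, diff) / (1.0 + 1.0 / n)     # hypothesis scatter for the group contrast
    sign, logdet_e = np.linalg.slogdet(E)
    sign_eh, logdet_eh = np.linalg.slogdet(E + H)
    if sign <= 0 or sign_eh <= 0:
        raise ValueError("singular within-group scatter; more residual fields needed")
    lam = float(np.exp(logdet_e - logdet_eh))
    v = (n + 1) - 2
    df1, df2 = D, v - D + 1
    f_stat = (1.0 - lam) / lam * df2 / df1
    p = float(stats.f.sf(f_stat, df1, df2))
    beta_m = np.vstack([x, mean_res])
    return SetTestResult(wilks_lambda=lam, f_stat=float(f_stat), df=(df1, df2),
                         p_value=p, beta_m=beta_m)


def mardia_test(l_residuals: np.ndarray):
    """Mardia's multivariate normality tests on an N x D sample.

    Returns (skewness p, kurtosis p): N*b1/6 against chi-square with
    D(D+1)(D+2)/6 df, and the kurtosis z-score
    (b2 - D(D+2)) * sqrt(N / (8 D (D+2))) against a standard normal
    (two-sided).  Uses the maximum-likelihood covariance (divisor N).
    Advisory only — never a gate on the set-level p-value.
    """
    Y = np.asarray(l_residuals, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, D = Y.shape
    if n <= D:
        raise ValueError("need N > D observations")
    centered = Y - Y.mean(axis=0)
    S = centered.T @ centered / n
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("singular covariance matrix")
    G = centered @ np.linalg.solve(S, centered.T)
    b1 = float((G ** 3).sum()) / n ** 2
    b2 = float((np.diag(G) ** 2).sum()) / n
    skew_stat = n * b1 / 6.0
    skew_df = D * (D + 1) * (D + 2) / 6.0
    p_skew = float(stats.chi2.sf(skew_stat, skew_df))
    z_kurt = (b2 - D * (D + 2)) * np.sqrt(n / (8.0 * D * (D + 2)))
    p_kurt = float(2.0 * stats.norm.sf(abs(z_kurt)))
    return p_skew, p_kurt


def classical_set_test(spm: SPMField, lkc: LKCVector, feature_p: float,
                       complex: SimplicialComplex) -> ClusterTestResult:
    """Classical set-level test at an uncorrected feature-defining threshold.

    The threshold is the upper-tail quantile of the SPM statistic at
    ``feature_p``; the expected cluster count there comes from the GKF, and
    the p-value from the Poisson clumping heuristic applied to the observed
    cluster count.  Zero observed clusters give p = 1 by convention.
    """
    if not 0.0 < feature_p < 1.0:
        raise ValueError("feature_p must be in (0, 1)")
    spec = FieldSpec(spm.stat_type, spm.dof if spm.stat_type != "Z" else None)
    if spm.stat_type == "T":
        u = float(stats.t.isf(feature_p, spm.dof[0]))
    elif spm.stat_type == "F":
        u = float(stats.f.isf(feature_p, *spm.dof))
    else:
        u = float(stats.norm.isf(feature_p))
    lam = max(0.0, expected_ec(lkc, spec, u))
    observed = count_clusters(spm.field.values, complex, u)
    p = 1.0 if observed == 0 else p_clusters(lam, observed)
    return ClusterTestResult(threshold=u, expected_ec=lam, observed=observed, p_value=p)
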