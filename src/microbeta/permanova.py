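"""Pseudo-F permutation tests on a distance matrix.

The statistic is the trace ratio ``F = tr(HGH) / tr((I-H) G (I-H))`` where
``G`` is the Gower-centered element-wise squared distance matrix and ``H``
the hat matrix of the (centered) covariate.  For a univariate centered x the
traces collapse to quadratic forms, ``tr(HGH) = x'Gx / x'x`` and
``tr((I-H)G(I-H)) = tr(G) - x'Gx / x'x``, which is what the vectorised
permutation path uses.

Confounder adjustment permutes residuals of x on the confounders: residual
permutation with refitting for continuous x, and a parametric bootstrap of
the fitted logistic model for binary x.  Stratified designs restrict the
permutation (of labels or residuals) to within-stratum shuffles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .core_io import DistanceMatrix, ValidationError


class PerfectSeparationError(ValidationError):
    """Logistic fit of x on the confounders separated perfectly."""


@dataclass
class TestSpec:
    """Covariate of interest, optional confounders/strata, and the
    permutation budget for a single test."""

    x: np.ndarray
    kind: str = "continuous"  # or "binary"
    z: Optional[np.ndarray] = None
    strata: Optional[np.ndarray] = None
    b: int = 999
    seed: int = 0

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1:
            raise ValidationError("covariate x must be a 1-D vector")
        if np.isnan(x).any():
            raise ValidationError("covariate x has missing values")
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"kind must be 'continuous' or 'binary', got {self.kind!r}")
        if self.kind == "binary":
            vals = np.unique(x)
            if not set(vals).issubset({0.0, 1.0}) or len(vals) != 2:
                raise ValidationError("binary x must take exactly the two values 0 and 1")
        self.x = x
        if self.z is not None:
            z = np.asarray(self.z, dtype=float)
            if z.ndim == 1:
                z = z[:, None]
            if z.shape[0] != x.shape[0]:
                raise ValidationError("confounder matrix row count does not match x")
            self.z = z
        if self.strata is not None:
            strata = np.asarray(self.strata)
            if strata.shape[0] != x.shape[0]:
                raise ValidationError("strata length does not match x")
            _, counts = np.unique(strata, return_counts=True)
            if (counts < 2).any():
                raise ValidationError("every stratum must contain at least 2 samples")
            self.strata = strata
        if self.b < 1:
            raise ValidationError("number of permutations must be >= 1")

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class SingleTestResult:
    """Observed pseudo-F, its permutation null draws and the p-value.

    ``p_value`` uses the add-one convention ``(1 + #{F(b) >= F_obs}) / (B+1)``
    (ties count as exceedances); ``p_value_raw`` is the literal proportion of
    permuted statistics strictly larger than the observed one.
    """

    f_observed: float
    permuted_f: np.ndarray
    p_value: float
    p_value_raw: float

    @property
    def b(self) -> int:
        return len(self.permuted_f)


# ---------------------------------------------------------------------------
# algebraic core

def _as_matrix(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.values
    return np.asarray(d, dtype=float)


def gower_center(d) -> np.ndarray:
    """G = -1/2 (I - 11'/n) D^2 (I - 11'/n), D^2 element-wise."""
    dm = _as_matrix(d)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()

def _center(x: np.ndarray, strata: Optional[np.ndarray] = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if strata is None:
        return x - x.mean()
    out = x.copy()
    for s in np.unique(strata):
        idx = strata == s
        out[idx] -= out[idx].mean()
    return out


def hat_matrix(x: np.ndarray) -> np.ndarray:
    x = _center(x)
    ss = x @ x
    if ss == 0:
        raise ValidationError("covariate is constant after centering")
    return np.outer(x, x) / ss


def _f_from_quadratic(q: float, tr_g: float) -> float:
    num = q
    den = tr_g - q
    if den == 0:
        if num > 0:
            return np.inf
        raise ValidationError("degenerate distance matrix: both trace terms are zero")
    if den < 0:
        warnings.warn(
            "negative denominator trace (strongly non-Euclidean distance matrix); "
            "pseudo-F is reported as the literal trace ratio",
            UserWarning,
            stacklevel=3,
        )
    return num / den


def pseudo_f(d, x) -> float:
    """Trace-ratio pseudo-F of a centered covariate against a distance
    matrix.  Returns +inf for perfect separation (zero residual trace with a
    positive model trace)."""
    g = gower_center(d)
    x = _center(np.asarray(x, dtype=float))
    ss = x @ x
    if ss == 0:
        raise ValidationError("covariate is constant")
    q = x @ g @ x / ss
    return _f_from_quadratic(q, float(np.trace(g)))


def _f_stats(g: np.ndarray, r_obs: np.ndarray, r_mat: np.ndarray):
    """Observed F and vector of permuted F from a Gower matrix and residual
    columns (vectorised).

    The observed vector rides through the same vectorised path as column 0,
    so a permutation that reproduces the observed assignment yields a
    bitwise-identical statistic and ties are counted deterministically.
    """
    tr_g = float(np.trace(g))
    ss_obs = float(r_obs @ r_obs)
    if ss_obs == 0:
        raise ValidationError("covariate/residual is constant")
    rm = np.concatenate([r_obs[:, None], r_mat], axis=1)
    gm = g @ rm
    ss = np.einsum("ij,ij->j", rm, rm)
    q = np.einsum("ij,ij->j", rm, gm)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ss > 0, q / np.where(ss > 0, ss, 1.0), 0.0)
        den = tr_g - q
        f = np.where(den != 0, q / np.where(den != 0, den, 1.0), np.where(q > 0, np.inf, 0.0))
    if den[0] == 0 and q[0] == 0:
        raise ValidationError("degenerate distance matrix: both trace terms are zero")
    return float(f[0]), f[1:]


def _p_values(f_obs: float, f_perm: np.ndarray):
    b = len(f_perm)
    count_ge = int((f_perm >= f_obs).sum())
    count_gt = int((f_perm > f_obs).sum())
    return (1 + count_ge) / (b + 1), count_gt / b


# ---------------------------------------------------------------------------
# permutation / bootstrap residual schemes

def _permutation_matrix(values: np.ndarray, strata: Optional[np.ndarray], b: int, rng) -> np.ndarray:
    """n x b matrix whose columns are permutations of ``values`` (within each
    stratum when strata are given)."""
    n = len(values)
    out = np.empty((n, b))
    if strata is None:
        keys = rng.random((b, n))
        order = np.argsort(keys, axis=1)
        out[:] = values[order].T
    else:
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            sub = values[idx]
            keys = rng.random((b, len(idx)))
            order = np.argsort(keys, axis=1)
            out[idx, :] = sub[order].T
    return out


def _ols_fit(zd: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(zd, y, rcond=None)
    if rank < zd.shape[1]:
        # identify collinear columns via QR diagonal
        _, r = np.linalg.qr(zd)
        bad = [j for j in range(zd.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValidationError(f"confounder matrix is rank deficient (collinear column index(es) {bad})")
    return beta


def _logistic_fit(zd: np.ndarray, y: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Newton-Raphson logistic MLE; raises on perfect separation."""
    beta = np.zeros(zd.shape[1])
    for _ in range(max_iter):
        eta = np.clip(zd @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = zd.T @ (y - mu)
        h = (zd * w[:, None]).T @ zd + 1e-10 * np.eye(zd.shape[1])
        step = np.linalg.solve(h, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    if np.max(np.abs(beta)) > 15:
        raise PerfectSeparationError(
            "logistic regression of x on the confounders separates perfectly; "
            "remove or coarsen confounder columns"
        )
    return beta


def _logistic_fit_batch(zd: np.ndarray, y_mat: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Fitted probabilities for many response columns at once.

    Degenerate columns are stabilised by a small ridge and probability
    clipping rather than raising; they contribute near-zero residuals.
    """
    n, p = zd.shape
    b = y_mat.shape[1]
    beta = np.zeros((p, b))
    eye = 1e-8 * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(zd @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = zd.T @ (y_mat - mu)  # (p, b)
        h = np.einsum("np,nb,nq->bpq", zd, w, zd) + eye
        step = np.linalg.solve(h, grad.T[:, :, None])[:, :, 0].T
        np.clip(step, -10, 10, out=step)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    np.clip(beta, -30, 30, out=beta)
    return expit(np.clip(zd @ beta, -30, 30))


def _with_intercept(z: Optional[np.ndarray], n: int) -> np.ndarray:
    if z is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), z])


def null_design(spec: TestSpec, b: int, rng) -> tuple:
    """Observed residual vector and an n x b matrix of null residual draws.

    Three schemes: plain label permutation (no confounders), residual
    permutation with refitting (continuous x with confounders), and a
    parametric bootstrap of the logistic fit (binary x with confounders).
    The same columns are meant to be shared across every distance matrix of
    a multi-distance test.
    """
    n = spec.n
    if spec.z is None:
        r_obs = _center(spec.x, spec.strata)
        if not r_obs.any():
            raise ValidationError("covariate is constant (within strata)")
        return r_obs, _permutation_matrix(r_obs, spec.strata, b, rng)
    zd = _with_intercept(spec.z, n)
    if spec.kind == "continuous":
        beta = _ols_fit(zd, spec.x)
        fitted = zd @ beta
        r_obs = spec.x - fitted
        r_star = _permutation_matrix(r_obs, spec.strata, b, rng)
        # refitting x* = fitted + r* on Z leaves exactly the projection of r*
        # off the column space of [1 Z]
        proj = zd @ np.linalg.pinv(zd)
        r_null = r_star - proj @ r_star
        return r_obs, r_null
    # binary: parametric bootstrap
    beta = _logistic_fit(zd, spec.x)
    mu = expit(np.clip(zd @ beta, -30, 30))
    r_obs = spec.x - mu
    x_star = (rng.random((n, b)) < mu[:, None]).astype(float)
    mu_star = _logistic_fit_batch(zd, x_star)
    return r_obs, x_star - mu_star


# ---------------------------------------------------------------------------
# public single-distance tests

def _run_test(d, spec: TestSpec) -> SingleTestResult:
    g = gower_center(d)
    rng = np.random.default_rng(spec.seed)
    r_obs, r_mat = null_design(spec, spec.b, rng)
    f_obs, f_perm = _f_stats(g, r_obs, r_mat)
    p, p_raw = _p_values(f_obs, f_perm)
    return SingleTestResult(f_obs, f_perm, p, p_raw)


def unadjusted_test(d, spec: TestSpec) -> SingleTestResult:
    """Permutation test without confounders: permute x (within strata if
    given) and recompute F each time."""
    if spec.z is not None:
        raise ValidationError("unadjusted_test does not accept confounders; use the adjusted tests")
    return _run_test(d, spec)


def freedman_lane_test(d, spec: TestSpec) -> SingleTestResult:
    """Residual-permutation test for a continuous covariate with
    confounders."""
    if spec.z is None:
        raise ValidationError("freedman_lane_test requires a confounder matrix")
    if spec.kind != "continuous":
        raise ValidationError("freedman_lane_test is for continuous x; use parametric_bootstrap_test")
    return _run_test(d, spec)


def parametric_bootstrap_test(d, spec: TestSpec) -> SingleTestResult:
    """Parametric-bootstrap test for a binary covariate with confounders:
    null covariates are redrawn from the fitted logistic model."""
    if spec.z is None:
        raise ValidationError("parametric_bootstrap_test requires a confounder matrix")
    if spec.kind != "binary":
        raise ValidationError("parametric_bootstrap_test is for binary x; use freedman_lane_test")
    return _run_test(d, spec)


def exact_permutation_p(d, x) -> float:
    """Full-enumeration permutation p-value (all n! orderings); oracle for
    small n."""
    x = _center(np.asarray(x, dtype=float))
    g = gower_center(d)
    tr_g = float(np.trace(g))
    ss = float(x @ x)
    f_obs = _f_from_quadratic(float(x @ g @ x) / ss, tr_g)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(x))):
        xp = x[list(perm)]
        f = _f_from_quadratic(float(xp @ g @ xp) / ss, tr_g)
        count += f >= f_obs
        total += 1
    return count / total
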