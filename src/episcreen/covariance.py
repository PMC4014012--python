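"""Residual covariance structures for repeated leaf measurements.

The leaves of one rosette are measured on the same plant, so their
residuals are correlated. Four classical repeated-measures structures
are supported, ordered by parameter count for tie-breaking:

=====  ==========================  ==============================
tag    name                        parameters (m traits)
=====  ==========================  ==============================
CS     compound symmetry           2 (variance, common rho)
AR1    first-order autoregressive  2 (variance, lag-1 rho)
TOEP   Toeplitz (banded)           m (variance, m-1 band rhos)
UN     unstructured                m(m+1)/2
=====  ==========================  ==============================

Each structure maps an unconstrained parameter vector to a covariance
matrix (for optimisation) and can initialise itself from an empirical
residual covariance.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz as _toeplitz
from scipy.special import expit, logit

STRUCTURE_ORDER = ["CS", "AR1", "TOEP", "UN"]


# ---------------------------------------------------------------------------
# plain matrix builders (used by the synthetic-data generator)

def cs_matrix(variance: float, rho: float, m: int) -> np.ndarray:
    """Compound-symmetry covariance: equal variance, equal correlation."""
    if not -1.0 / (m - 1) < rho < 1.0:
        raise ValueError(f"CS correlation {rho} not in (-1/(m-1), 1) for m={m}")
    return variance * ((1.0 - rho) * np.eye(m) + rho * np.ones((m, m)))


def ar1_matrix(variance: float, rho: float, m: int) -> np.ndarray:
    """AR(1) covariance: correlation decays geometrically with lag."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"AR1 correlation {rho} not in (-1, 1)")
    return variance * rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))


def toeplitz_matrix(variance: float, band_rhos, m: int) -> np.ndarray:
    """Banded Toeplitz covariance from per-lag correlations."""
    band_rhos = np.asarray(band_rhos, float)
    if band_rhos.shape != (m - 1,):
        raise ValueError(f"need {m - 1} band correlations, got {band_rhos.shape}")
    sigma = variance * _toeplitz(np.concatenate([[1.0], band_rhos]))
    _assert_pd(sigma)
    return sigma


def _assert_pd(sigma: np.ndarray) -> None:
    sigma = np.asarray(sigma, float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(sigma, sigma.T):
        raise ValueError("covariance must be symmetric")
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc


def validate_pd(sigma: np.ndarray) -> np.ndarray:
    """Return sigma as float array after a symmetry + positive-definite check."""
    sigma = np.asarray(sigma, float)
    _assert_pd(sigma)
    return sigma


def psd_factor(sigma: np.ndarray) -> np.ndarray:
    """A factor F with F F' = sigma for positive *semi*-definite sigma.

    Admits the exact noise-free limit (zero matrix); raises for
    indefinite input.
    """
    sigma = np.asarray(sigma, float)
    if not np.allclose(sigma, sigma.T):
        raise ValueError("covariance must be symmetric")
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("covariance is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# parameterised structures for likelihood fitting

class CovarianceStructure:
    """Maps an unconstrained vector x to a covariance matrix Sigma(x)."""

    tag: str

    def __init__(self, m: int):
        self.m = m

    def n_params(self) -> int:
        raise NotImplementedError

    def build(self, x: np.ndarray) -> np.ndarray:
        """May raise numpy.linalg.LinAlgError for non-PD parameter points."""
        raise NotImplementedError

    def init(self, emp_cov: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _corr(emp_cov):
    d = np.sqrt(np.clip(np.diag(emp_cov), 1e-12, None))
    return emp_cov / np.outer(d, d)


class CompoundSymmetry(CovarianceStructure):
    tag = "CS"

    def n_params(self):
        return 2

    def _rho_bounds(self):
        return -1.0 / (self.m - 1) + 1e-4, 1.0 - 1e-4

    def build(self, x):
        lo, hi = self._rho_bounds()
        rho = lo + (hi - lo) * expit(x[1])
        return cs_matrix(np.exp(x[0]), rho, self.m)

    def init(self, emp_cov):
        lo, hi = self._rho_bounds()
        v = float(np.mean(np.diag(emp_cov)))
        r = _corr(emp_cov)
        rho = float(np.mean(r[np.triu_indices(self.m, 1)]))
        rho = np.clip(rho, lo + 1e-3, hi - 1e-3)
        return np.array([np.log(max(v, 1e-10)), logit((rho - lo) / (hi - lo))])


class AR1(CovarianceStructure):
    tag = "AR1"

    def n_params(self):
        return 2

    def build(self, x):
        rho = np.tanh(x[1]) * (1.0 - 1e-6)
        return ar1_matrix(np.exp(x[0]), rho, self.m)

    def init(self, emp_cov):
        v = float(np.mean(np.diag(emp_cov)))
        r = _corr(emp_cov)
        lag1 = float(np.mean(np.diag(r, 1)))
        lag1 = np.clip(lag1, -0.95, 0.95)
        return np.array([np.log(max(v, 1e-10)), np.arctanh(lag1)])


class Toeplitz(CovarianceStructure):
    """Homogeneous-variance banded Toeplitz.

    Band correlations are mapped through tanh; positive definiteness is
    not guaranteed for every parameter point, so :meth:`build` raises
    LinAlgError outside the PD region and the optimiser treats that
    point as infeasible.
    """

    tag = "TOEP"

    def n_params(self):
        return self.m

    def build(self, x):
        rhos = np.tanh(x[1:]) * (1.0 - 1e-6)
        sigma = np.exp(x[0]) * _toeplitz(np.concatenate([[1.0], rhos]))
        np.linalg.cholesky(sigma)  # raises if outside the PD region
        return sigma

    def init(self, emp_cov):
        v = float(np.mean(np.diag(emp_cov)))
        r = _corr(emp_cov)
        bands = np.array([np.mean(np.diag(r, k)) for k in range(1, self.m)])
        bands = np.clip(bands, -0.9, 0.9) * 0.95
        x = np.concatenate([[np.log(max(v, 1e-10))], np.arctanh(bands)])
        try:
            self.build(x)
        except np.linalg.LinAlgError:
            x[1:] *= 0.5  # pull towards diagonal until PD
        return x


class Unstructured(CovarianceStructure):
    """Free covariance via the log-Cholesky parameterisation (always PD)."""

    tag = "UN"

    def n_params(self):
        return self.m * (self.m + 1) // 2

    def build(self, x):
        L = np.zeros((self.m, self.m))
        idx = np.tril_indices(self.m)
        L[idx] = x
        L[np.diag_indices(self.m)] = np.exp(np.diag(L))
        return L @ L.T

    def init(self, emp_cov):
        emp_cov = np.asarray(emp_cov, float)
        w, v = np.linalg.eigh((emp_cov + emp_cov.T) / 2)
        floor = max(1e-6 * float(np.mean(np.diag(emp_cov))), 1e-10)
        sigma = (v * np.clip(w, floor, None)) @ v.T
        L = np.linalg.cholesky(sigma)
        L[np.diag_indices(self.m)] = np.log(np.diag(L))
        return L[np.tril_indices(self.m)]


_STRUCTURES = {
    "CS": CompoundSymmetry,
    "AR1": AR1,
    "TOEP": Toeplitz,
    "UN": Unstructured,
}


def get_structure(tag: str, m: int) -> CovarianceStructure:
    try:
        cls = _STRUCTURES[tag.upper()]
    except KeyError:
        raise ValueError(
            f"unknown covariance structure {tag!r}; choose from {STRUCTURE_ORDER}"
        ) from None
    return cls(m)
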