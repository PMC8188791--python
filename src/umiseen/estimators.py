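"""Unseen-molecule estimators on a single copies-per-UMI histogram.

All three estimators answer the same question: given the histogram ``h(i)``
of read copies per observed molecule, how many distinct molecules would be
seen if the total number of reads were multiplied by ``t + 1``?

* :class:`GoodToulmin` — the alternating series ``U = -sum (-t)^i h(i)``;
  distribution-free, accurate for ``t <= 1``, unstable beyond.
* :class:`ZeroTruncatedNB` — fits a negative binomial to the histogram by
  EM, treating the zero-copy bin as missing data, then extrapolates by
  scaling the mean with depth while holding the size parameter fixed.
* :class:`PreseqDS` — stabilizes the Good-Toulmin power series with a
  rational-function (Pade) approximant built from the histogram truncated
  at copy level ``mt``, with pole checks and degree back-off.

The classes follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``); thin module-level functions wrap them for
pipeline use.
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
from scipy.interpolate import pade
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator

from .exceptions import DegenerateHistogramError, EstimatorUnstableError
from .types import CUHistogram, DSConfig, PredictionResult

HistLike = Union[CUHistogram, dict]


def _as_hist(h: HistLike) -> CUHistogram:
    if isinstance(h, CUHistogram):
        return h
    return CUHistogram("", dict(h))


# ---------------------------------------------------------------------------
# negative binomial in mean/size parameterization
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mu: float, size: float) -> np.ndarray:
    """log pmf of NB with mean ``mu`` and size (dispersion) ``size``.

    pmf(k) = C(k+s-1, k) (s/(s+mu))^s (mu/(s+mu))^k; pmf(0) = (s/(s+mu))^s.
    """
    k = np.asarray(k, dtype=np.float64)
    s = size
    log_p = math.log(s) - math.log(s + mu)      # log s/(s+mu)
    log_q = math.log(mu) - math.log(s + mu)     # log mu/(s+mu)
    return gammaln(k + s) - gammaln(s) - gammaln(k + 1) + s * log_p + k * log_q


def _nb_pmf0(mu: float, size: float) -> float:
    """NB probability of a zero count, (s/(s+mu))^s."""
    return math.exp(size * (math.log(size) - math.log(size + mu)))


# ---------------------------------------------------------------------------
# Good-Toulmin
# ---------------------------------------------------------------------------

class GoodToulmin(BaseEstimator):
    """Good-Toulmin unseen-molecule estimator.

    Predicts ``U(t) = -sum_i (-t)^i h(i)`` new molecules when reads are
    scaled by ``t + 1``.  Makes no distributional assumption but is only
    stable for ``t <= 1``; larger ``t`` requires
    ``allow_extrapolation=True``.
    """

    def __init__(self, allow_extrapolation: bool = False):
        self.allow_extrapolation = allow_extrapolation

    def fit(self, h: HistLike) -> "GoodToulmin":
        hist = _as_hist(h)
        self.copies_, self.h_ = hist.as_arrays()
        self.n_observed_ = float(self.h_.sum())
        return self

    def predict(self, t: float) -> float:
        """Predicted distinct molecules at depth factor ``t + 1``.

        Clamped below at zero (the alternating sum can undershoot ``-N``);
        ``clamped_`` records whether clamping occurred.
        """
        if t < 0:
            raise ValueError("t must be >= 0")
        if t > 1 and not self.allow_extrapolation:
            raise ValueError(
                "Good-Toulmin is unstable for t > 1; pass allow_extrapolation=True "
                "to override"
            )
        signs = np.where(self.copies_ % 2 == 1, 1.0, -1.0)
        with np.errstate(over="ignore"):
            u = float(np.sum(signs * np.power(float(t), self.copies_) * self.h_))
        distinct = self.n_observed_ + u
        self.clamped_ = distinct < 0
        return max(distinct, 0.0)


# ---------------------------------------------------------------------------
# zero-truncated negative binomial (EM)
# ---------------------------------------------------------------------------

class ZeroTruncatedNB(BaseEstimator):
    """Zero-truncated negative binomial fit to a CU histogram, by EM.

    The observed histogram is the nonzero part of an NB sample whose
    zero-count bin (unsequenced molecules) is missing.  Each EM iteration:

    * E-step: from current ``(mu, s)``, estimate the library size
      ``L = N / (1 - pmf(0))`` and the zero bin ``z = L pmf(0)``; update the
      mean ``mu = sum i h(i) / L``.
    * M-step: maximize the complete-data log-likelihood
      ``ll(s) = sum_{i>=0} h(i) log pmf(i; mu, s)`` over the size ``s`` with
      L-BFGS-B, using the analytic gradient
      ``pd(s) = sum h(i) digamma(i+s)/L - digamma(s) + log s - log(s+mu)``.

    Starting values mu=0.5, s=1.  Iteration stops when the relative
    log-likelihood change drops below ``tol``.

    Histograms with a single copy level or fewer than ``min_molecules``
    molecules raise :class:`DegenerateHistogramError`; such genes are left
    uncorrected by pipeline callers, since prediction from lowly expressed
    genes is unreliable.

    Fitted attributes: ``mu_``, ``size_``, ``total_molecules_`` (L),
    ``unseen_`` (z = L - N), ``n_observed_`` (N), ``loglik_``,
    ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        tol: float = 1e-4,
        max_iter: int = 1000,
        min_molecules: int = 20,
        mu_init: float = 0.5,
        size_init: float = 1.0,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.min_molecules = min_molecules
        self.mu_init = mu_init
        self.size_init = size_init

    def fit(self, h: HistLike) -> "ZeroTruncatedNB":
        hist = _as_hist(h)
        copies, counts = hist.as_arrays()
        n_obs = float(counts.sum())
        if len(copies) < 2:
            raise DegenerateHistogramError(
                f"histogram has {len(copies)} distinct copy level(s); need >= 2"
            )
        if n_obs < self.min_molecules:
            raise DegenerateHistogramError(
                f"histogram has N={n_obs:g} molecules; need >= {self.min_molecules}"
            )

        total_reads = float(np.sum(copies * counts))
        mu, s = float(self.mu_init), float(self.size_init)
        prev_ll = None
        ll = np.nan
        converged = False
        i_all = np.concatenate(([0], copies)).astype(np.float64)

        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E-step: library size, zero bin and mean at the current size.
            # L and mu are mutually dependent, so their update is iterated to
            # self-consistency; updating the size against a stale zero bin
            # can drive it to the Poisson boundary (a spurious optimum).
            for _ in range(500):
                L = n_obs / (1.0 - _nb_pmf0(mu, s))
                mu_new = total_reads / L
                if abs(mu_new - mu) <= 1e-12 * mu:
                    mu = mu_new
                    break
                mu = mu_new
            p0 = _nb_pmf0(mu, s)
            L = n_obs / (1.0 - p0)
            z = L * p0
            h_all = np.concatenate(([z], counts))
            s, ll = self._optimize_size(i_all, h_all, L, mu, s)
            if prev_ll is not None and abs(ll - prev_ll) < self.tol * abs(ll):
                converged = True
                break
            prev_ll = ll

        p0 = _nb_pmf0(mu, s)
        self.mu_ = mu
        self.size_ = s
        self.n_observed_ = n_obs
        self.total_molecules_ = n_obs / (1.0 - p0)
        self.unseen_ = self.total_molecules_ - n_obs
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    @staticmethod
    def _optimize_size(i_all, h_all, L, mu, s0):
        """M-step: maximize ll(s) at fixed mu over the completed histogram."""

        def neg_ll(sv):
            s = float(sv[0])
            return -float(np.dot(h_all, _nb_logpmf(i_all, mu, s))) / L

        def neg_grad(sv):
            s = float(sv[0])
            pd = (
                float(np.dot(h_all, digamma(i_all + s))) / L
                - digamma(s)
                + math.log(s)
                - math.log(s + mu)
            )
            return np.array([-pd])

        # objective is scaled by 1/L, so per-molecule gradients are small;
        # the default pgtol would stop the solver before it moves
        res = minimize(
            neg_ll,
            x0=[s0],
            jac=neg_grad,
            method="L-BFGS-B",
            bounds=[(1e-8, 1e8)],
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        s = float(res.x[0])
        return s, -float(res.fun) * L

    def predict(self, t: float) -> float:
        """Predicted distinct molecules when reads are scaled by ``t + 1``.

        The size parameter is held fixed and the mean scales with depth:
        ``L (1 - pmf(0; mu (t+1), s))``.  Monotone in ``t``, equal to N at
        ``t = 0`` and approaching L as ``t`` grows.
        """
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return self.n_observed_
        p0 = _nb_pmf0(self.mu_ * (1.0 + t), self.size_)
        return self.total_molecules_ * (1.0 - p0)


# ---------------------------------------------------------------------------
# Preseq-style rational function estimator
# ---------------------------------------------------------------------------

class PreseqDS(BaseEstimator):
    """Rational-function stabilization of the Good-Toulmin series.

    The histogram is truncated to copy levels ``<= mt`` (default 2) and the
    truncated series ``S(t) = sum_j (-1)^{j+1} h(j) t^j`` is rewritten as
    ``t * P(t)`` with ``P`` a polynomial.  ``P`` is replaced by its Pade
    approximant, which extends the radius of convergence far beyond the
    alternating series' own.  Denominator degree starts at the maximum the
    truncated series supports (capped by ``max_degree``) and is reduced when
    the approximant has a pole on the evaluation interval or is not
    monotone; if every degree fails, :class:`EstimatorUnstableError` is
    raised.

    With the default ``mt = 2`` the approximant is the degree-[0/1] form
    ``S(t) = h1 t / (1 + (h2/h1) t)``, whose large-t asymptote is
    ``h1^2 / h2`` new molecules.
    """

    #: t beyond which the analytic asymptote replaces naive evaluation
    LARGE_T = 1e6

    def __init__(self, mt: int = 2, max_degree: Optional[int] = None):
        self.mt = mt
        self.max_degree = max_degree

    def fit(self, h: HistLike) -> "PreseqDS":
        hist = _as_hist(h)
        self.n_observed_ = hist.n_molecules
        trunc = hist.truncate(self.mt)
        if not trunc.counts:
            raise DegenerateHistogramError(
                f"no copy levels <= mt={self.mt} in histogram"
            )
        j_max = max(trunc.counts)
        # series coefficients of P(t) = S(t)/t, dense over j = 1..j_max
        coeffs = np.zeros(j_max)
        for j, hj in trunc.counts.items():
            coeffs[j - 1] = (-1.0) ** (j + 1) * hj
        self.series_ = coeffs
        return self

    def _candidate_degrees(self):
        n_coef = len(self.series_)
        m0 = n_coef // 2
        if self.max_degree is not None:
            m0 = min(m0, self.max_degree)
        return range(m0, -1, -1)

    def _evaluate(self, p: np.poly1d, q: np.poly1d, t: np.ndarray) -> np.ndarray:
        return t * p(t) / q(t)

    def _asymptote(self, p: np.poly1d, q: np.poly1d) -> float:
        """Limit of t p(t)/q(t) as t -> inf."""
        diff = (p.order + 1) - q.order
        if diff < 0:
            return 0.0
        if diff == 0:
            return float(p.coeffs[0] / q.coeffs[0])
        return math.inf

    def predict(self, t: float) -> float:
        """Predicted distinct molecules at depth factor ``t + 1``.

        For ``t`` beyond :data:`LARGE_T` the approximant's analytic
        asymptote is returned in place of naive polynomial evaluation.
        """
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return self.n_observed_
        t_eff = min(t, self.LARGE_T)
        grid = np.geomspace(max(t_eff * 1e-6, 1e-9), t_eff, 50)
        failures = []
        for m in self._candidate_degrees():
            n = len(self.series_) - 1 - m
            try:
                p, q = pade(self.series_, m, n)
            except (np.linalg.LinAlgError, ValueError) as exc:
                failures.append(f"[{n}/{m}]: {exc}")
                continue
            # defect: pole on the evaluation interval
            roots = q.roots
            real = roots[np.abs(roots.imag) < 1e-9 * (np.abs(roots) + 1e-300)].real
            if np.any((real > 0) & (real <= t_eff * 1.0001)):
                failures.append(f"[{n}/{m}]: pole on (0, t]")
                continue
            vals = self._evaluate(p, q, grid)
            if not np.all(np.isfinite(vals)):
                failures.append(f"[{n}/{m}]: non-finite values")
                continue
            scale = max(np.max(np.abs(vals)), 1.0)
            if np.any(vals < -1e-8 * scale) or np.any(np.diff(vals) < -1e-8 * scale):
                failures.append(f"[{n}/{m}]: not monotone nonnegative")
                continue
            if t > self.LARGE_T:
                asym = self._asymptote(p, q)
                if math.isfinite(asym):
                    if asym < vals[-1] * (1 - 1e-8):
                        failures.append(f"[{n}/{m}]: asymptote below interior values")
                        continue
                    delta = asym
                else:
                    delta = float(self._evaluate(p, q, np.array([t]))[0])
            else:
                delta = float(self._evaluate(p, q, np.array([t]))[0])
            return self.n_observed_ + max(delta, 0.0)
        raise EstimatorUnstableError(
            "no stable rational approximant: " + "; ".join(failures)
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def good_toulmin(
    h: HistLike, t: float, allow_extrapolation: bool = False
) -> PredictionResult:
    """Good-Toulmin prediction at depth factor ``t + 1`` (default ``t <= 1``)."""
    est = GoodToulmin(allow_extrapolation=allow_extrapolation).fit(h)
    distinct = est.predict(t)
    return PredictionResult(
        method="good_toulmin",
        t=t,
        distinct_molecules=distinct,
        new_molecules=distinct - est.n_observed_,
        clamped=est.clamped_,
    )


def ztnb_fit(
    h: HistLike, tol: float = 1e-4, max_iter: int = 1000, min_molecules: int = 20
) -> ZeroTruncatedNB:
    """Fit a zero-truncated NB to a histogram; returns the fitted estimator."""
    return ZeroTruncatedNB(
        tol=tol, max_iter=max_iter, min_molecules=min_molecules
    ).fit(h)


def ztnb_predict(fit: ZeroTruncatedNB, t: float) -> PredictionResult:
    """Predict distinct molecules at depth factor ``t + 1`` from a ZTNB fit."""
    distinct = fit.predict(t)
    return PredictionResult(
        method="ztnb",
        t=t,
        distinct_molecules=distinct,
        new_molecules=distinct - fit.n_observed_,
    )


def ds_predict(
    h: HistLike, t: float, config: Optional[DSConfig] = None
) -> PredictionResult:
    """Rational-function prediction at depth factor ``t + 1``."""
    config = config or DSConfig()
    est = PreseqDS(mt=config.mt, max_degree=config.max_degree).fit(h)
    distinct = est.predict(t)
    return PredictionResult(
        method="ds",
        t=t,
        distinct_molecules=distinct,
        new_molecules=distinct - est.n_observed_,
        mt=config.mt,
    )
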