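"""(epsilon, delta) accounting for the subsampled Gaussian mechanism.

Three layers of machinery:

* the classical Gaussian-mechanism calibration
  sigma = sqrt(2 ln(1.25/delta)) * sensitivity / epsilon, valid for
  epsilon in (0, 1);
* naive sequential composition, (epsilon, delta) -> (k epsilon, k delta);
* the moments accountant: per-step log moments alpha(lambda) of the
  privacy-loss random variable of one Poisson-subsampled Gaussian query
  (sampling rate q, noise multiplier sigma), accumulated additively over
  training steps and converted to epsilon at a target delta by the tail
  bound  epsilon = min_lambda (sum alpha(lambda) + ln(1/delta)) / lambda.

The per-step log moment is computed exactly for the mixture pair
mu0 = N(0, sigma^2) versus mu = (1-q) mu0 + q N(1, sigma^2)
(add/remove-one adjacency, unit L2 sensitivity):

    E2 = E_{z~mu0}[(mu/mu0)^(lambda+1)]   -- closed form, a binomial sum,
    E1 = E_{z~mu0}[(mu0/mu)^lambda]       -- adaptive quadrature,
    alpha(lambda) = log max(E1, E2).

At q = 1 this reduces to the pure Gaussian moment lambda(lambda+1)/(2 sigma^2).
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
from scipy import integrate
from scipy.special import gammaln, logsumexp

DEFAULT_ORDERS = np.arange(1, 65)


class PrivacyError(ValueError):
    """Invalid privacy parameters."""


def gaussian_sigma(epsilon: float, delta: float, sensitivity: float = 1.0) -> float:
    """Noise multiplier calibrating one Gaussian-mechanism release to (eps, delta)-DP.

    sigma = sqrt(2 ln(1.25/delta)) * sensitivity / epsilon. The guarantee is
    stated for epsilon in (0, 1); outside that range a warning is emitted and
    the same formula returned.
    """
    if epsilon <= 0 or not math.isfinite(epsilon):
        raise PrivacyError("epsilon must be positive and finite")
    if not 0 < delta < 1:
        raise PrivacyError("delta must be in (0, 1)")
    if sensitivity <= 0:
        raise PrivacyError("sensitivity must be positive")
    if epsilon >= 1:
        warnings.warn(
            "Gaussian-mechanism calibration is only guaranteed for epsilon < 1",
            stacklevel=2,
        )
    return math.sqrt(2.0 * math.log(1.25 / delta)) * sensitivity / epsilon


def gaussian_epsilon(sigma: float, delta: float, sensitivity: float = 1.0) -> float:
    """Inverse of :func:`gaussian_sigma`: per-release epsilon at given sigma."""
    if sigma <= 0:
        raise PrivacyError("sigma must be positive")
    if not 0 < delta < 1:
        raise PrivacyError("delta must be in (0, 1)")
    return math.sqrt(2.0 * math.log(1.25 / delta)) * sensitivity / sigma


def sequential_composition(k: int, epsilon: float, delta: float) -> tuple[float, float]:
    """Naive composition of k mechanisms: (k * epsilon, k * delta)."""
    if k < 1:
        raise PrivacyError("k must be >= 1")
    return k * epsilon, k * delta


def naive_composition_epsilon(sigma: float, delta: float, steps: int, sensitivity: float = 1.0) -> float:
    """Epsilon from naive sequential composition of per-step Gaussian releases.

    Each step's epsilon comes from inverting the Theorem-style calibration at
    the same delta; subsampling amplification is ignored, which is exactly
    what makes this the loose baseline the moments accountant improves on.
    """
    return steps * gaussian_epsilon(sigma, delta, sensitivity)


# ---------------------------------------------------------------------------
# Moments of the subsampled Gaussian privacy loss


def _log_e2(q: float, sigma: float, lam: int) -> float:
    """log E_{z~mu0}[(mu/mu0)^(lam+1)] via the binomial expansion.

    mu/mu0 = (1 - q) + q exp((2z - 1) / (2 sigma^2)) and
    E_{z~N(0,sigma^2)}[exp(k (2z-1)/(2 sigma^2))] = exp(k(k-1)/(2 sigma^2)).
    """
    m = lam + 1
    if q == 1.0:
        return lam * m / (2.0 * sigma**2)
    ks = np.arange(m + 1)
    log_binom = gammaln(m + 1) - gammaln(ks + 1) - gammaln(m - ks + 1)
    terms = (
        log_binom
        + (m - ks) * math.log1p(-q)
        + ks * math.log(q)
        + ks * (ks - 1) / (2.0 * sigma**2)
    )
    return float(logsumexp(terms))


def _log_e1(q: float, sigma: float, lam: int) -> float:
    """log E_{z~mu0}[(mu0/mu)^lam] by adaptive quadrature."""
    if q == 1.0:
        # (mu0/mu1)^lam under mu0: same Gaussian moment by symmetry
        return lam * (lam + 1) / (2.0 * sigma**2)
    inv_two_s2 = 1.0 / (2.0 * sigma**2)

    log_1mq = math.log1p(-q)
    log_q = math.log(q)

    def integrand(z: float) -> float:
        log_pdf0 = -z * z * inv_two_s2 - math.log(sigma * math.sqrt(2 * math.pi))
        # log((1-q) + q exp(x)) computed stably for large |x|
        log_ratio = np.logaddexp(log_1mq, log_q + (2.0 * z - 1.0) * inv_two_s2)
        return float(np.exp(log_pdf0 - lam * log_ratio))

    val = 0.0
    for a, b in ((-np.inf, 0.0), (0.0, 1.0), (1.0, np.inf)):
        part, _ = integrate.quad(integrand, a, b, limit=200)
        val += part
    return math.log(val)


def step_log_moments(q: float, sigma: float, orders=DEFAULT_ORDERS) -> np.ndarray:
    """Log moment alpha(lambda) of one subsampled-Gaussian step per order."""
    if not 0 < q <= 1:
        raise PrivacyError("q must be in (0, 1]")
    if sigma <= 0:
        raise PrivacyError("sigma must be > 0 (no noise gives infinite moments)")
    orders = np.asarray(orders, dtype=np.int64)
    if orders.size == 0 or np.any(orders < 1):
        raise PrivacyError("orders must be integers >= 1")
    out = np.empty(orders.size)
    for i, lam in enumerate(orders):
        lam = int(lam)
        out[i] = max(_log_e1(q, sigma, lam), _log_e2(q, sigma, lam))
    return out


def moments_epsilon(log_moments: np.ndarray, orders, delta: float) -> float:
    """Tail conversion: epsilon = min_lambda (alpha(lambda) + ln(1/delta)) / lambda."""
    if not 0 < delta < 1:
        raise PrivacyError("delta must be in (0, 1)")
    orders = np.asarray(orders, dtype=float)
    log_moments = np.asarray(log_moments, dtype=float)
    return float(np.min((log_moments + math.log(1.0 / delta)) / orders))


class PrivacyLedger:
    """Accumulated log moments of a DP training run.

    Intended to be written only by the private optimizer step; everything
    else merely reads it (post-processing consumes no privacy).
    """

    def __init__(
        self,
        q: float,
        sigma: float,
        delta: float,
        orders=DEFAULT_ORDERS,
    ) -> None:
        if not 0 < delta < 1:
            raise PrivacyError("delta must be in (0, 1)")
        self.q = q
        self.sigma = sigma
        self.delta = delta
        self.orders = np.asarray(orders, dtype=np.int64)
        if self.orders.size == 0:
            raise PrivacyError("ledger needs at least one moment order")
        self._per_step = step_log_moments(q, sigma, self.orders)
        self.log_moments = np.zeros(self.orders.size)
        self.steps = 0

    def record_step(self, n_steps: int = 1) -> None:
        if n_steps < 1:
            raise PrivacyError("n_steps must be >= 1")
        self.log_moments += n_steps * self._per_step
        self.steps += n_steps

    def epsilon(self, delta: float | None = None) -> float:
        """Current (epsilon, delta) guarantee; uses the ledger delta by default."""
        delta = self.delta if delta is None else delta
        if self.steps == 0:
            warnings.warn("no steps taken; epsilon reported as 0", stacklevel=2)
            return 0.0
        return moments_epsilon(self.log_moments, self.orders, delta)

    @property
    def minimizing_order(self) -> int:
        vals = (self.log_moments + math.log(1.0 / self.delta)) / self.orders
        return int(self.orders[int(np.argmin(vals))])

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "sigma": self.sigma,
            "delta": self.delta,
            "steps": self.steps,
            "orders": self.orders.tolist(),
            "log_moments": self.log_moments.tolist(),
            "epsilon": self.epsilon() if self.steps else 0.0,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def epsilon_from_ledger(ledger: PrivacyLedger, delta: float | None = None) -> float:
    """Convenience wrapper: the ledger's current epsilon."""
    return ledger.epsilon(delta)


def accountant_epsilon(
    q: float, sigma: float, steps: int, delta: float, orders=DEFAULT_ORDERS
) -> float:
    """Epsilon certified by the moments accountant for a full training run."""
    if steps < 1:
        raise PrivacyError("steps must be >= 1")
    per_step = step_log_moments(q, sigma, orders)
    return moments_epsilon(steps * per_step, orders, delta)


def sigma_for_epsilon(
    target_epsilon: float,
    q: float,
    steps: int,
    delta: float,
    orders=DEFAULT_ORDERS,
    rtol: float = 0.02,
    sigma_bounds: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Smallest noise multiplier whose accountant epsilon is within rtol of target.

    Bisection over sigma; epsilon is strictly decreasing in sigma.
    """
    if target_epsilon <= 0:
        raise PrivacyError("target epsilon must be positive")
    lo, hi = sigma_bounds
    if accountant_epsilon(q, lo, steps, delta, orders) < target_epsilon:
        raise PrivacyError("target epsilon unattainably large even at minimal sigma")
    if accountant_epsilon(q, hi, steps, delta, orders) > target_epsilon:
        raise PrivacyError("target epsilon unattainably small within sigma bounds")
    for _ in range(100):
        mid = math.sqrt(lo * hi)
        eps = accountant_epsilon(q, mid, steps, delta, orders)
        if abs(eps - target_epsilon) <= rtol * target_epsilon:
            return mid
        if eps > target_epsilon:
            lo = mid
        else:
            hi = mid
    return mid
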