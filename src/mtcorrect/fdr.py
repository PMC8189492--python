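"""False-discovery-rate control: BH, BY, Storey's pFDR, PFP and q-values.

Where FWER procedures bound the probability of *any* false positive, FDR
procedures bound the expected proportion of false positives among the
rejected tests, ``FDR = E[V/R]`` (with ``V/R := 0`` when nothing is
rejected).  With thousands of simultaneous tests this is usually the
relevant guarantee: an FDR of 5% means that of 100 reported discoveries,
five are expected to be truly null.

Procedures
----------
* Benjamini–Hochberg (BH): compare the k-th smallest p-value against the
  critical value ``(k/n) * level``; reject ranks 1..k* for the largest k*
  whose p-value beats its critical value.  Adjusted values are
  ``min_{j>=k} min(1, (n/j) p_(j))``.
* Benjamini–Yekutieli (BY): BH with critical values shrunk by
  ``c(n) = sum_{i<=n} 1/i``, valid under arbitrary dependence; under
  positive dependence ``c(n) = 1`` and BY coincides with BH.
* Storey's positive FDR: ``FDR(t) = pi0 * m * t / S(t)`` at a rejection
  threshold ``t``, where ``S(t)`` counts p-values at or below ``t`` and
  ``pi0`` estimates the proportion of true nulls.
* q-values: ``q(p_i) = min_{t >= p_i} FDR(t)`` — the smallest FDR at which
  test ``i`` would be called significant; with ``pi0 = 1`` they reduce
  exactly to BH-adjusted p-values.
* PFP: the proportion of false positives ``E(V)/E(R)`` with numerator and
  denominator estimated separately (``V_hat = pi0*m*t``, ``R_hat = S(t)``),
  which under these estimators coincides numerically with Storey's pFDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .containers import AdjustmentResult, PValueCollection, validate_pvalues
from .fwer import BaseCorrection

__all__ = [
    "Pi0Estimate",
    "FdrCurve",
    "QValueResult",
    "PI0_ESTIMATORS",
    "estimate_pi0",
    "bh_critical_values",
    "BenjaminiHochberg",
    "BenjaminiYekutieli",
    "QValues",
    "bh_reject",
    "by_adjust",
    "storey_fdr",
    "qvalues",
    "pfp_estimate",
    "expected_false_positives",
    "fdr_curve",
    "harmonic_number",
]

PI0_ESTIMATORS = ("count_above_half", "twice_mean_p")


@dataclass(frozen=True)
class Pi0Estimate:
    """Estimated proportion of true null hypotheses, with provenance.

    ``value`` is clamped into ``[1/n_used, 1]`` so that downstream
    divisions never hit zero and the twice-mean estimator cannot exceed 1.
    """

    value: float
    estimator: str
    n_used: int


@dataclass(frozen=True)
class FdrCurve:
    """Estimated FDR and rejection count over a grid of thresholds."""

    thresholds: np.ndarray
    fdr_at: np.ndarray
    s_at: np.ndarray


@dataclass
class QValueResult:
    """q-values with the pi0 estimate used and per-level rejection counts."""

    qvalues: np.ndarray
    pvalues: np.ndarray
    pi0: Pi0Estimate
    fdr_level_rejections: Mapping[float, int] = field(default_factory=dict)
    ids: tuple[str, ...] | None = None


def harmonic_number(n: int) -> float:
    """``c(n) = 1 + 1/2 + ... + 1/n``, the BY arbitrary-dependence factor."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def estimate_pi0(pv, estimator: str = "count_above_half") -> Pi0Estimate:
    """Estimate the proportion of true null hypotheses.

    Under the null, p-values are uniform on [0, 1]; alternatives pile up
    near zero.  Both estimators exploit that the upper half of [0, 1] (or
    the overall mean) is dominated by nulls:

    * ``count_above_half``: ``(2/n) * #{p_i > 0.5}``
    * ``twice_mean_p``: ``2 * mean(p)``

    The estimate is clamped into ``[1/n, 1]``.
    """
    pv = validate_pvalues(pv)
    p = pv.pvalues
    n = pv.n
    if estimator == "count_above_half":
        value = 2.0 / n * np.count_nonzero(p > 0.5)
    elif estimator == "twice_mean_p":
        value = 2.0 * float(np.mean(p))
    else:
        raise ValueError(
            f"unknown pi0 estimator {estimator!r}; choose from {PI0_ESTIMATORS}"
        )
    value = min(1.0, max(1.0 / n, value))
    return Pi0Estimate(value=value, estimator=estimator, n_used=n)


def bh_critical_values(pv, fdr_level: float = 0.05) -> np.ndarray:
    """BH critical values ``(k/n) * fdr_level`` for ascending ranks k=1..n.

    The k-th smallest p-value is significant at the stated FDR level when
    it falls strictly below the k-th critical value (subject to the
    step-up search for the highest qualifying rank).
    """
    pv = validate_pvalues(pv)
    if not 0.0 < fdr_level < 1.0:
        raise ValueError("fdr_level must lie in (0, 1)")
    n = pv.n
    return np.arange(1, n + 1) / n * fdr_level


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """BH-adjusted values min over tail of min(1, (n/j) p_(j)), input order."""
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (n / np.arange(1, n + 1))
    stepped = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(n)
    out[order] = stepped
    return out


def _bh_reject_mask(p: np.ndarray, crit: np.ndarray) -> np.ndarray:
    """Step-up rejection: ranks 1..k* where k* is the largest k with
    p_(k) strictly below its critical value."""
    n = p.size
    order = np.argsort(p, kind="stable")
    below = np.flatnonzero(p[order] < crit)
    mask = np.zeros(n, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


class BenjaminiHochberg(BaseCorrection):
    """Benjamini–Hochberg step-up FDR control.

    ``fit`` computes BH-adjusted p-values and the step-up rejection set at
    ``fdr_level``.  The rejection set is found by the critical-value scan
    (strictly below ``(k/n)*level``, searching for the highest qualifying
    rank); the adjusted values are the usual min-over-tail form.  Fitted
    attributes additionally include ``critical_values_`` aligned with
    ascending ranks.
    """

    method = "bh"

    def __init__(self, fdr_level: float = 0.05):
        self.fdr_level = fdr_level

    def _level(self) -> float:
        return self.fdr_level

    def _c(self, n: int) -> float:
        return 1.0

    def _adjust(self, p: np.ndarray) -> np.ndarray:
        c = self._c(p.size)
        return np.minimum(1.0, _bh_adjusted(p) * c)

    def _reject(self, p: np.ndarray, adjusted: np.ndarray) -> np.ndarray:
        n = p.size
        self.critical_values_ = (
            np.arange(1, n + 1) / n * self._level() / self._c(n)
        )
        return _bh_reject_mask(p, self.critical_values_)


class BenjaminiYekutieli(BenjaminiHochberg):
    """Benjamini–Yekutieli FDR control under general dependence.

    Under ``dependence="positive"`` the correction factor is ``c(n) = 1``
    and the procedure is identical to BH.  Under ``dependence="arbitrary"``
    the critical values are divided by the harmonic number
    ``c(n) = sum 1/i`` (equivalently, adjusted values are multiplied by
    ``c(n)`` and capped), buying validity under any correlation structure
    at the price of conservatism.
    """

    method = "by"

    def __init__(self, fdr_level: float = 0.05, dependence: str = "arbitrary"):
        self.fdr_level = fdr_level
        self.dependence = dependence

    def _c(self, n: int) -> float:
        if self.dependence == "positive":
            return 1.0
        if self.dependence == "arbitrary":
            return harmonic_number(n)
        raise ValueError(
            f"dependence must be 'positive' or 'arbitrary', got {self.dependence!r}"
        )

    def _params(self) -> dict[str, Any]:
        return {"dependence": self.dependence, "c_n": self._c(self.n_tests_)}


def storey_fdr(pv, t: float, pi0: Pi0Estimate | float) -> float:
    """Storey's estimated (positive) FDR at rejection threshold ``t``.

    ``FDR(t) = pi0 * m * t / S(t)`` with ``m`` the total number of tests
    and ``S(t) = #{p_i <= t}``, capped at 1.  The pFDR conditions on at
    least one rejection, so ``S(t) = 0`` is an error.
    """
    pv = validate_pvalues(pv)
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold t must lie in (0, 1]")
    pi0_value = pi0.value if isinstance(pi0, Pi0Estimate) else float(pi0)
    m = pv.n
    s_t = int(np.count_nonzero(pv.pvalues <= t))
    if s_t == 0:
        raise ValueError(f"no rejections at threshold t={t}: pFDR is undefined")
    return min(1.0, pi0_value * m * t / s_t)


def pfp_estimate(pv, t: float, pi0: Pi0Estimate | float) -> float:
    """Estimated proportion of false positives ``E(V)/E(R)`` at threshold t.

    The numerator and denominator are estimated separately as
    ``V_hat = pi0 * m * t`` and ``R_hat = S(t)``; with these estimators the
    quantity coincides numerically with :func:`storey_fdr`, though PFP is
    defined as a ratio of expectations rather than an expected ratio and
    does not depend on the dependence structure or the number of tests.
    """
    pv = validate_pvalues(pv)
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold t must lie in (0, 1]")
    pi0_value = pi0.value if isinstance(pi0, Pi0Estimate) else float(pi0)
    m = pv.n
    r_hat = int(np.count_nonzero(pv.pvalues <= t))
    if r_hat == 0:
        raise ValueError(f"no rejections at threshold t={t}: PFP is undefined")
    v_hat = pi0_value * m * t
    return min(1.0, v_hat / r_hat)


def fdr_curve(pv, pi0: Pi0Estimate | float = 1.0) -> FdrCurve:
    """Estimated FDR and rejection counts over the observed thresholds.

    Thresholds are the distinct observed p-values in ascending order
    (the minimum over continuous t is always attained at an observed
    p-value, so no finer grid is needed).
    """
    pv = validate_pvalues(pv)
    pi0_value = pi0.value if isinstance(pi0, Pi0Estimate) else float(pi0)
    p = pv.pvalues
    m = pv.n
    thresholds = np.unique(p)
    s_at = np.searchsorted(np.sort(p), thresholds, side="right")
    fdr_at = np.minimum(1.0, pi0_value * m * thresholds / s_at)
    return FdrCurve(thresholds=thresholds, fdr_at=fdr_at, s_at=s_at)


class QValues(BaseCorrection):
    """Storey q-values: the minimum FDR at which each test is significant.

    ``q(p_i) = min over thresholds t >= p_i of FDR(t)``, with t ranging
    over the observed p-values.  Equivalently the pi0-scaled BH-adjusted
    values with a running minimum from the largest p-value; q-values are
    nondecreasing in p, and with ``pi0`` forced to 1 they equal the
    BH-adjusted p-values exactly.

    Parameters
    ----------
    pi0_estimator : {"count_above_half", "twice_mean_p"}
        Which pi0 estimator to apply (ignored when ``pi0`` is given).
    pi0 : float, optional
        Fix pi0 instead of estimating it.
    fdr_levels : sequence of float
        FDR levels at which to report rejection counts (#{q <= level}).
    """

    method = "qvalue"

    def __init__(
        self,
        pi0_estimator: str = "count_above_half",
        pi0: float | None = None,
        fdr_levels: Sequence[float] = (0.01, 0.05, 0.10),
    ):
        self.pi0_estimator = pi0_estimator
        self.pi0 = pi0
        self.fdr_levels = fdr_levels

    def _level(self) -> float:
        return 0.05  # rejection flags in result_ use the 5% FDR convention

    def fit(self, X, y=None):
        pv = validate_pvalues(X)
        if self.pi0 is not None:
            pi0 = Pi0Estimate(
                value=min(1.0, max(1.0 / pv.n, float(self.pi0))),
                estimator="fixed",
                n_used=pv.n,
            )
        else:
            pi0 = estimate_pi0(pv, self.pi0_estimator)
        p = pv.pvalues
        m = pv.n
        order = np.argsort(p, kind="stable")
        p_sorted = p[order]
        # S(t) at t = p_(k) counts ties: number of p-values <= p_(k)
        s_at = np.searchsorted(p_sorted, p_sorted, side="right")
        # p * (pi0*m/S) so that with pi0=1 and no ties the products are
        # bit-identical to the BH adjusted values p * (n/j)
        fdr_at = np.minimum(1.0, p_sorted * (pi0.value * m / s_at))
        q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
        q = np.empty(m)
        q[order] = q_sorted
        self.n_tests_ = m
        self.pi0_ = pi0
        self.qvalues_ = q
        self.adjusted_ = q
        self.rejected_ = q <= self._level()
        rejections = {
            float(level): int(np.count_nonzero(q <= level))
            for level in self.fdr_levels
        }
        self.result_ = QValueResult(
            qvalues=q,
            pvalues=np.asarray(p),
            pi0=pi0,
            fdr_level_rejections=rejections,
            ids=pv.ids,
        )
        return self

    def transform(self, X) -> np.ndarray:
        X_arr = np.asarray(X, dtype=float)
        q = type(self)(**self.get_params()).fit(X).qvalues_
        if X_arr.ndim == 2:
            return q.reshape(-1, 1)
        return q


def expected_false_positives(threshold: float, m: int) -> float:
    """Expected number of false positives ``threshold * m``.

    With ``m`` tests whose nulls are all true, calling significance at a
    p-value cut-off ``threshold`` yields ``threshold * m`` false positives
    in expectation; applied to a q-value cut-off, ``m`` is instead the
    number of tests called significant at that cut-off.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return threshold * m


def bh_reject(pv, fdr_level: float = 0.05) -> AdjustmentResult:
    """Benjamini–Hochberg adjustment and step-up rejection at ``fdr_level``."""
    return BenjaminiHochberg(fdr_level=fdr_level).fit(pv).result_


def by_adjust(
    pv, dependence: str = "arbitrary", fdr_level: float = 0.05
) -> AdjustmentResult:
    """Benjamini–Yekutieli adjustment under the stated dependence mode."""
    return BenjaminiYekutieli(fdr_level=fdr_level, dependence=dependence).fit(pv).result_


def qvalues(
    pv, estimator: str = "count_above_half", pi0: float | None = None
) -> QValueResult:
    """Compute Storey q-values for a collection of p-values."""
    return QValues(pi0_estimator=estimator, pi0=pi0).fit(pv).result_
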