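"""Family-wise error rate control: single-step and sequential corrections.

When a family of ``C`` independent tests is each run at a per-comparison
level ``alpha_pc``, the probability of at least one false positive — the
family-wise error rate — is ``1 - (1 - alpha_pc)**C``, which grows quickly
with the family size.  The corrections here shrink each test's effective
level so that the family-wise rate stays below a nominal ``alpha``:

* Bonferroni — multiply each p-value by the number of tests ``n``.
* Šidák — ``1 - (1 - p)**n``; exact under independence, always at or below
  the Bonferroni value.
* Holm — step-down: the k-th smallest p-value is multiplied by
  ``n - k + 1``, scanning from the smallest p upward and stopping at the
  first non-rejection.
* Hochberg — step-up: same multipliers, but scanning from the largest
  p-value down; the first rejection implies rejection of everything smaller.

All corrections are exposed as sklearn-style transformers over a 1-d vector
of p-values, plus thin functional wrappers returning an
:class:`~mtcorrect.containers.AdjustmentResult`.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AdjustmentResult, PValueCollection, validate_pvalues

__all__ = [
    "fwer",
    "bonferroni_threshold",
    "BonferroniCorrection",
    "SidakCorrection",
    "HolmCorrection",
    "HochbergCorrection",
    "HochbergVariantCorrection",
    "bonferroni_adjust",
    "sidak_adjust",
    "holm_adjust",
    "hochberg_adjust",
    "hochberg_variant_adjust",
]


def fwer(alpha_pc: float, c: int) -> float:
    """Family-wise error rate for ``c`` independent comparisons.

    Parameters
    ----------
    alpha_pc : float in (0, 1) (0 and 1 allowed as limits)
        Per-comparison error rate.
    c : int
        Number of comparisons, at least 1.

    Returns
    -------
    float
        ``1 - (1 - alpha_pc)**c``; monotone nondecreasing in both arguments.
    """
    if c < 1:
        raise ValueError("number of comparisons must be a positive integer")
    if not 0.0 <= alpha_pc <= 1.0:
        raise ValueError("per-comparison rate must lie in [0, 1]")
    return float(1.0 - (1.0 - alpha_pc) ** c)


def bonferroni_threshold(alpha: float, n: int) -> float:
    """Per-test significance cut-off ``alpha / n``.

    A raw p-value is declared significant iff it is strictly below the
    returned threshold (the open-interval convention for the threshold
    formulation; the adjusted-value formulation uses ``n*p <= alpha``).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n < 1:
        raise ValueError("number of tests must be a positive integer")
    return alpha / n


class BaseCorrection(TransformerMixin, BaseEstimator):
    """Base class for p-value corrections in the sklearn estimator idiom.

    ``fit(X)`` validates the p-values and computes the fitted attributes
    ``adjusted_``, ``rejected_``, ``n_tests_`` and ``result_``;
    ``transform(X)`` returns the adjusted p-values for ``X`` in input shape
    (the adjustment depends only on the vector passed in, so ``transform``
    is stateless and ``fit_transform`` is the natural entry point).
    """

    method: str = ""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    # -- subclass hooks -------------------------------------------------
    def _adjust(self, p: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _reject(self, p: np.ndarray, adjusted: np.ndarray) -> np.ndarray:
        return adjusted <= self._level()

    def _level(self) -> float:
        return self.alpha

    def _params(self) -> dict[str, Any]:
        return {}

    # -- estimator API --------------------------------------------------
    def fit(self, X: Sequence[float] | np.ndarray | PValueCollection, y=None):
        level = self._level()
        if not 0.0 < level < 1.0:
            raise ValueError("significance level must lie in (0, 1)")
        pv = validate_pvalues(X)
        self.n_tests_ = pv.n
        self.adjusted_ = self._adjust(pv.pvalues)
        self.rejected_ = self._reject(pv.pvalues, self.adjusted_)
        self.result_ = AdjustmentResult(
            method=self.method,
            pvalues=np.asarray(pv.pvalues),
            adjusted=self.adjusted_,
            rejected=self.rejected_,
            alpha=level,
            params=self._params(),
            ids=pv.ids,
        )
        return self

    def transform(self, X) -> np.ndarray:
        X_arr = np.asarray(X, dtype=float)
        pv = validate_pvalues(X)
        adjusted = self._adjust(pv.pvalues)
        if X_arr.ndim == 2:
            return adjusted.reshape(-1, 1)
        return adjusted

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "result_")


class BonferroniCorrection(BaseCorrection):
    """Single-step Bonferroni correction: ``adjusted_i = min(1, n * p_i)``."""

    method = "bonferroni"

    def _adjust(self, p: np.ndarray) -> np.ndarray:
        return np.minimum(1.0, p * p.size)


class SidakCorrection(BaseCorrection):
    """Single-step Šidák correction: ``adjusted_i = 1 - (1 - p_i)**n``.

    Exact FWER control under independence; element-wise at or below the
    Bonferroni adjustment on every input.
    """

    method = "sidak"

    def _adjust(self, p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):  # log1p(-1) = -inf maps to adjusted 1
            return -np.expm1(p.size * np.log1p(-p))


class HolmCorrection(BaseCorrection):
    """Holm step-down correction.

    Sorting ascending, rank ``k`` is multiplied by ``n - k + 1``; a running
    maximum down the ranks makes the adjusted values monotone so that
    "reject iff adjusted <= alpha" reproduces the sequential stop rule
    (once a rank fails, every larger rank fails too).
    """

    method = "holm"

    def _adjust(self, p: np.ndarray) -> np.ndarray:
        n = p.size
        order = np.argsort(p, kind="stable")
        mult = n - np.arange(n)  # n, n-1, ..., 1
        stepped = np.minimum(1.0, np.maximum.accumulate(p[order] * mult))
        out = np.empty(n)
        out[order] = stepped
        return out


class HochbergCorrection(BaseCorrection):
    """Hochberg step-up correction (standard 1988 form).

    Ascending rank ``k`` is multiplied by ``n - k + 1``; the adjusted value
    is the running minimum from the largest p-value down, so scanning from
    the top the first significant rank drags every smaller p-value along.
    Rejects at least as much as Holm on every input.
    """

    method = "hochberg"

    def _adjust(self, p: np.ndarray) -> np.ndarray:
        n = p.size
        order = np.argsort(p, kind="stable")
        mult = n - np.arange(n)
        stepped = np.minimum(
            1.0, np.minimum.accumulate((p[order] * mult)[::-1])[::-1]
        )
        out = np.empty(n)
        out[order] = stepped
        return out


class HochbergVariantCorrection(BaseCorrection):
    """Non-standard step-up variant with rank-proportional multipliers.

    The k-th smallest p-value is multiplied by ``k`` (so the largest
    p-value is multiplied by ``n``, the second largest by ``n - 1``, ...),
    scanning from the largest down; the first significant rank triggers
    rejection of it and all smaller p-values.  This walkthrough variant
    circulates in tutorials but is far more conservative than the standard
    Hochberg step-up procedure and is provided for comparison only; its
    output is flagged ``standard=False``.
    """

    method = "hochberg_variant"

    def _adjust(self, p: np.ndarray) -> np.ndarray:
        n = p.size
        order = np.argsort(p, kind="stable")
        mult = np.arange(1, n + 1)  # rank k multiplier k
        stepped = np.minimum(
            1.0, np.minimum.accumulate((p[order] * mult)[::-1])[::-1]
        )
        out = np.empty(n)
        out[order] = stepped
        return out

    def _params(self) -> dict[str, Any]:
        return {"standard": False}


def _run(cls, pv, alpha: float) -> AdjustmentResult:
    return cls(alpha=alpha).fit(pv).result_


def bonferroni_adjust(pv, alpha: float = 0.05) -> AdjustmentResult:
    """Bonferroni-adjust a collection of p-values."""
    return _run(BonferroniCorrection, pv, alpha)


def sidak_adjust(pv, alpha: float = 0.05) -> AdjustmentResult:
    """Šidák-adjust a collection of p-values."""
    return _run(SidakCorrection, pv, alpha)


def holm_adjust(pv, alpha: float = 0.05) -> AdjustmentResult:
    """Holm step-down adjustment of a collection of p-values."""
    return _run(HolmCorrection, pv, alpha)


def hochberg_adjust(pv, alpha: float = 0.05) -> AdjustmentResult:
    """Standard Hochberg step-up adjustment of a collection of p-values."""
    return _run(HochbergCorrection, pv, alpha)


def hochberg_variant_adjust(pv, alpha: float = 0.05) -> AdjustmentResult:
    """Rank-multiplier step-up variant (non-standard; see class docs)."""
    return _run(HochbergVariantCorrection, pv, alpha)
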