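"""Validated p-value input and adjustment-result containers.

Every procedure in this package consumes a :class:`PValueCollection` — an
ordered vector of raw p-values with optional string identifiers — and most
produce an :class:`AdjustmentResult` holding per-test adjusted values and
rejection flags at a stated significance (or FDR) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class PValueCollection:
    """An ordered, validated collection of raw p-values.

    Attributes
    ----------
    pvalues : ndarray of shape (n,)
        Raw p-values in input order, each in [0, 1].
    ids : tuple of str or None
        Optional unique identifiers aligned with ``pvalues``.
    """

    pvalues: np.ndarray
    ids: tuple[str, ...] | None = None

    @property
    def n(self) -> int:
        """Number of simultaneous tests in the family."""
        return int(self.pvalues.shape[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n


def validate_pvalues(
    raw: Sequence[float] | np.ndarray | "PValueCollection",
    ids: Sequence[str] | None = None,
) -> PValueCollection:
    """Validate raw p-values and wrap them in a :class:`PValueCollection`.

    Parameters
    ----------
    raw : sequence of float, ndarray, or PValueCollection
        The raw p-values. A 2-d column array of shape (n, 1) is accepted
        and flattened. An existing collection passes through unchanged.
    ids : sequence of str, optional
        Unique identifiers, one per p-value.

    Returns
    -------
    PValueCollection
        Validated collection; input order is preserved.

    Raises
    ------
    ValueError
        If the input is empty, contains a non-finite or non-numeric entry,
        or any value falls outside [0, 1]. The error message names the
        offending index.
    """
    if isinstance(raw, PValueCollection):
        return raw
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-d vector of p-values, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty input: at least one p-value is required")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(f"non-numeric or missing p-value at index {bad[0]}")
    bad = np.flatnonzero((arr < 0.0) | (arr > 1.0))
    if bad.size:
        raise ValueError(
            f"p-value out of range at index {bad[0]}: {arr[bad[0]]!r} not in [0, 1]"
        )
    id_tuple: tuple[str, ...] | None = None
    if ids is not None:
        id_tuple = tuple(str(i) for i in ids)
        if len(id_tuple) != arr.size:
            raise ValueError(
                f"ids length {len(id_tuple)} does not match {arr.size} p-values"
            )
        if len(set(id_tuple)) != len(id_tuple):
            raise ValueError("ids must be unique")
    arr = arr.copy()
    arr.flags.writeable = False
    return PValueCollection(pvalues=arr, ids=id_tuple)


@dataclass
class AdjustmentResult:
    """Per-test adjusted p-values and rejection decisions.

    Attributes
    ----------
    method : str
        Name of the correction procedure.
    pvalues : ndarray
        The raw p-values, in input order.
    adjusted : ndarray
        Adjusted p-values aligned with the input, capped at 1 and
        order-preserving in the raw values.
    rejected : ndarray of bool
        Rejection flag per test at level ``alpha``.
    alpha : float
        Significance level (FWER methods) or FDR level (FDR methods).
    params : mapping
        Method parameters (dependence mode, pi0, estimator, ...).
    ids : tuple of str or None
        Identifiers carried through from the input collection.
    """

    method: str
    pvalues: np.ndarray
    adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float
    params: Mapping[str, Any] = field(default_factory=dict)
    ids: tuple[str, ...] | None = None

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.rejected))
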