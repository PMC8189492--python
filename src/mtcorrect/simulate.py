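"""Synthetic p-value mixtures and Monte-Carlo error-control evaluation.

The generator draws one-sided z-test p-values from a two-group mixture:
a fraction ``pi0`` of tests are true nulls (statistic ``N(0,1)``, p-value
exactly uniform) and the rest are alternatives whose statistic is shifted
by ``effect``.  Positive dependence is induced by an equicorrelated
Gaussian construction, ``z_i = sqrt(rho) * Z_common + sqrt(1-rho) * Z_i``
(+ effect for alternatives), which preserves uniform null marginals while
giving every pair of tests correlation ``rho``.

``evaluate`` replays any of the implemented correction methods over many
replicates and reports empirical FWER (fraction of replicates with at
least one null rejected), empirical FDR (mean false-discovery proportion
V/R, with 0/0 := 0), the conditional pFDR (mean of V/R over replicates
with R > 0), and power (mean fraction of true alternatives rejected),
each with a Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .fdr import BenjaminiHochberg, BenjaminiYekutieli, QValues
from .fwer import (
    BonferroniCorrection,
    HochbergCorrection,
    HochbergVariantCorrection,
    HolmCorrection,
    SidakCorrection,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "MethodPerformance",
    "METHODS",
    "make_method",
    "generate",
    "evaluate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic p-value mixture.

    Defaults model a mid-sized expression screen: m=1000 tests of which
    80% are true nulls, alternatives shifted by 3 null standard deviations
    (clearly detectable individually, not trivially so after correction),
    independent tests, 100 replicates.
    """

    m: int = 1000
    pi0: float = 0.8
    effect: float = 3.0
    rho: float = 0.0
    seed: int = 0
    reps: int = 100

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if self.effect < 0.0:
            raise ValueError("effect must be nonnegative")
        if not 0.0 <= self.rho <= 0.9:
            raise ValueError("rho must lie in [0, 0.9]")
        if self.reps < 1:
            raise ValueError("reps must be a positive integer")

    @property
    def m0(self) -> int:
        """Number of true nulls per replicate: round(m * pi0)."""
        return int(round(self.m * self.pi0))


@dataclass(frozen=True)
class SyntheticTruth:
    """Generated p-values with their ground-truth null/alternative labels.

    ``pvalues`` has shape (reps, m); ``is_null`` is the shared label
    vector (the first m0 positions are nulls in every replicate).
    """

    pvalues: np.ndarray
    is_null: np.ndarray
    config: SyntheticConfig


@dataclass
class MethodPerformance:
    """Empirical error rates and power of one method over the replicates."""

    method: str
    empirical_fwer: float
    empirical_fdr: float
    empirical_pfdr: float
    power: float
    mc_se: Mapping[str, float] = field(default_factory=dict)
    reps: int = 0


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw ``config.reps`` replicates of the synthetic mixture.

    Test statistics are ``z_i = sqrt(rho)*Z_common + sqrt(1-rho)*Z_i +
    effect * 1[alternative]`` and p-values are the one-sided upper-tail
    probabilities under the standard normal null.  Bit-identical output
    for identical seeds.
    """
    rng = np.random.default_rng(config.seed)
    reps, m, m0 = config.reps, config.m, config.m0
    z_common = rng.standard_normal((reps, 1))
    z = rng.standard_normal((reps, m))
    z = np.sqrt(config.rho) * z_common + np.sqrt(1.0 - config.rho) * z
    is_null = np.zeros(m, dtype=bool)
    is_null[:m0] = True
    z[:, ~is_null] += config.effect
    pvalues = stats.norm.sf(z)
    return SyntheticTruth(pvalues=pvalues, is_null=is_null, config=config)


#: Method registry: name -> estimator factory taking the rejection level.
METHODS = {
    "bonferroni": lambda level: BonferroniCorrection(alpha=level),
    "sidak": lambda level: SidakCorrection(alpha=level),
    "holm": lambda level: HolmCorrection(alpha=level),
    "hochberg": lambda level: HochbergCorrection(alpha=level),
    "hochberg_variant": lambda level: HochbergVariantCorrection(alpha=level),
    "bh": lambda level: BenjaminiHochberg(fdr_level=level),
    "by": lambda level: BenjaminiYekutieli(fdr_level=level, dependence="arbitrary"),
    "qvalue": lambda level: QValues(fdr_levels=(level,)),
}


def make_method(name: str, level: float):
    """Instantiate a correction estimator by registry name."""
    try:
        factory = METHODS[name]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; choose from {sorted(METHODS)}"
        ) from None
    return factory(level)


def _rejections(name: str, level: float, p: np.ndarray) -> np.ndarray:
    est = make_method(name, level).fit(p)
    if name == "qvalue":
        return est.qvalues_ <= level
    return est.rejected_


def evaluate(
    config: SyntheticConfig,
    methods: Sequence[str],
    alpha_or_level: float = 0.05,
) -> "pandas.DataFrame":
    """Measure empirical FWER, FDR, pFDR and power of each method.

    Every method is applied to the same replicates, so rows are directly
    comparable (and rejection-set dominance holds replicate by replicate).
    Returns a DataFrame with one row per method; the per-method
    :class:`MethodPerformance` records are attached as ``df.attrs["performance"]``.
    """
    import pandas as pd

    for name in methods:
        if name not in METHODS:
            raise ValueError(
                f"unknown method {name!r}; choose from {sorted(METHODS)}"
            )
    truth = generate(config)
    is_null = truth.is_null
    n_alt = int(np.count_nonzero(~is_null))
    records: list[MethodPerformance] = []
    for name in methods:
        fwer_ind = np.empty(config.reps)
        fdp = np.empty(config.reps)
        pfdp: list[float] = []
        power = np.empty(config.reps)
        for r in range(config.reps):
            rej = _rejections(name, alpha_or_level, truth.pvalues[r])
            v = int(np.count_nonzero(rej & is_null))
            n_rej = int(np.count_nonzero(rej))
            fwer_ind[r] = 1.0 if v >= 1 else 0.0
            fdp[r] = v / n_rej if n_rej else 0.0
            if n_rej:
                pfdp.append(v / n_rej)
            power[r] = (
                np.count_nonzero(rej & ~is_null) / n_alt if n_alt else np.nan
            )
        se = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        records.append(
            MethodPerformance(
                method=name,
                empirical_fwer=float(np.mean(fwer_ind)),
                empirical_fdr=float(np.mean(fdp)),
                empirical_pfdr=float(np.mean(pfdp)) if pfdp else np.nan,
                power=float(np.mean(power)) if n_alt else np.nan,
                mc_se={
                    "fwer": se(fwer_ind),
                    "fdr": se(fdp),
                    "power": se(power) if n_alt else np.nan,
                },
                reps=config.reps,
            )
        )
    df = pd.DataFrame(
        {
            "method": [r.method for r in records],
            "empirical_fwer": [r.empirical_fwer for r in records],
            "empirical_fdr": [r.empirical_fdr for r in records],
            "empirical_pfdr": [r.empirical_pfdr for r in records],
            "power": [r.power for r in records],
            "fwer_se": [r.mc_se["fwer"] for r in records],
            "fdr_se": [r.mc_se["fdr"] for r in records],
            "power_se": [r.mc_se["power"] for r in records],
            "reps": [r.reps for r in records],
        }
    )
    df.attrs["performance"] = records
    df.attrs["config"] = config
    return df
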