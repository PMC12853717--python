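"""Left-censored variables and the censoring operator.

A variable is *below the lower limit of quantification* (BLOQ) when the assay
cannot measure it precisely and only the event ``value <= LLOQ`` is recorded.
This module provides the core container :class:`CensoredVector`, the censoring
operator :func:`apply_lloq`, and the quantile rule :func:`lloq_for_proportion`
used by the simulation engine to pick a threshold that censors a target
fraction of clean draws.

Conventions
-----------
* Ties are censored: ``value == lloq`` counts as below the limit.
* Censored slots in :attr:`CensoredVector.values` hold the sentinel ``lloq``
  (never NaN), so substitution-style consumers always read a defined number.
  Every consumer must branch on the ``censored`` flag, not on the value.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CensoringError",
    "Dist",
    "CensoredVector",
    "apply_lloq",
    "lloq_for_proportion",
    "read_censored_table",
    "write_censored_table",
]


class CensoringError(ValueError):
    """Invalid censoring construction (bad threshold, flags, or family)."""


@dataclasses.dataclass(frozen=True)
class Dist:
    """Parametric distribution spec for covariate generation and quantiles.

    Supported families: ``beta(a, b)``, ``normal(mu, sd)`` (second parameter is
    the standard deviation) and ``bernoulli(p)``.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = self.family
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if fam == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise CensoringError(f"beta parameters must be positive, got {p}")
        elif fam == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise CensoringError(f"normal needs (mu, sd > 0), got {p}")
        elif fam == "bernoulli":
            if len(p) != 1 or not 0.0 < p[0] < 1.0:
                raise CensoringError(f"bernoulli needs p in (0,1), got {p}")
        else:
            raise CensoringError(f"unsupported family {fam!r}")

    # -- sampling / quantiles -------------------------------------------------
    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, n)
        if self.family == "normal":
            mu, sd = self.params
            return rng.normal(mu, sd, n)
        p = self.params[0]
        return (rng.random(n) < p).astype(float)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if self.family == "beta":
            return stats.beta.ppf(q, *self.params)
        if self.family == "normal":
            mu, sd = self.params
            return mu + sd * stats.norm.ppf(q)
        p = self.params[0]
        return (q > 1.0 - p).astype(float)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "beta":
            return stats.beta.cdf(x, *self.params)
        if self.family == "normal":
            mu, sd = self.params
            return stats.norm.cdf(x, mu, sd)
        return stats.bernoulli.cdf(x, self.params[0])

    @property
    def is_continuous(self) -> bool:
        return self.family in ("beta", "normal")


@dataclasses.dataclass(frozen=True)
class CensoredVector:
    """Numeric values with per-element left-censoring flags and a threshold.

    Invariants enforced at construction:

    * ``len(values) == len(censored)``
    * ``lloq > 0`` and finite
    * every uncensored value is strictly above ``lloq``
    * censored slots are normalised to the sentinel ``lloq``
    """

    values: np.ndarray
    censored: np.ndarray
    lloq: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).copy()
        censored = np.asarray(self.censored, dtype=bool).copy()
        lloq = float(self.lloq)
        if values.ndim != 1 or censored.ndim != 1:
            raise CensoringError("values and censored must be 1-D")
        if len(values) != len(censored):
            raise CensoringError(
                f"length mismatch: {len(values)} values vs {len(censored)} flags"
            )
        if not np.isfinite(lloq) or lloq <= 0:
            raise CensoringError(f"lloq must be a positive finite real, got {lloq}")
        if not np.all(np.isfinite(values[~censored])):
            raise CensoringError("uncensored values must be finite")
        if np.any(values[~censored] <= lloq):
            raise CensoringError(
                "uncensored values must lie strictly above lloq "
                "(ties are censored by convention)"
            )
        values[censored] = lloq  # sentinel
        values.flags.writeable = False
        censored.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "censored", censored)
        object.__setattr__(self, "lloq", lloq)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def proportion_censored(self) -> float:
        return float(self.censored.mean()) if len(self) else 0.0

    @property
    def uncensored_values(self) -> np.ndarray:
        return self.values[~self.censored]


def apply_lloq(x: Iterable[float], lloq: float) -> CensoredVector:
    """Censor clean values at ``lloq`` (``x <= lloq`` becomes censored)."""
    x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise CensoringError("input values must be finite")
    censored = x <= lloq
    return CensoredVector(values=x, censored=censored, lloq=lloq)


def lloq_for_proportion(dist: Dist, p: float) -> float:
    """Threshold whose censoring of clean draws from ``dist`` has expectation ``p``.

    This is the theoretical ``p``-quantile of the generating distribution, so a
    scenario's LLOQ is constant across simulation replicates.
    """
    if not 0.0 < p < 1.0:
        raise CensoringError(f"proportion must be in (0,1), got {p}")
    if not dist.is_continuous:
        raise CensoringError(f"no quantile rule for family {dist.family!r}")
    q = float(dist.ppf(p))
    if not np.isfinite(q) or q <= 0:
        raise CensoringError(
            f"quantile {q} is not a valid positive threshold for {dist}"
        )
    return q


# -- delimited-text interface -------------------------------------------------

def read_censored_table(
    path, bloq_var: str, lloq: float
) -> tuple[pd.DataFrame, CensoredVector]:
    """Read a CSV with one column per variable.

    Censoring flags come from a companion boolean column ``<bloq_var>_censored``
    when present; otherwise the sentinel convention ``value <= lloq`` is used.
    The returned frame has the flag column filled in and censored slots
    normalised to the sentinel.
    """
    df = pd.read_csv(path)
    if bloq_var not in df.columns:
        raise CensoringError(f"column {bloq_var!r} not found in {path}")
    flag_col = f"{bloq_var}_censored"
    values = df[bloq_var].to_numpy(dtype=float)
    if flag_col in df.columns:
        censored = df[flag_col].astype(bool).to_numpy()
        cv = CensoredVector(values=values, censored=censored, lloq=lloq)
    else:
        cv = apply_lloq(values, lloq)
    df = df.copy()
    df[bloq_var] = cv.values
    df[flag_col] = cv.censored
    return df, cv


def write_censored_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
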