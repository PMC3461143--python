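"""Family-correlated survival diagnostics via the index of variability.

For an offspring age class with mean family size ``k`` and variance ``V``,
the index of variability is ``R = V/k`` (1 under Poisson reproduction).
Scaling to the value expected if purely random (binomial) survival reduced
the mean family size to 2 — replacement in a stable population — gives

    R* = 1 + (2/k) * (R - 1),

the standard random-binomial-survival result: thinning a family-size
distribution multiplies the excess index ``R - 1`` by the survival fraction.
The corresponding effective-to-census ratio is ``Nb/N = 2/(1 + R*)``, and
comparing R* between the age-1 and age-3 offspring classes measures how much
family-size variation accrued through that life stage: under fully random
survival R* is unchanged in expectation, while family-correlated mortality
inflates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import UndefinedInputError

__all__ = [
    "StageIndex",
    "index_of_variability",
    "scale_to_k2",
    "ratio_from_index",
    "stage_change",
]


def index_of_variability(k: float, v: float) -> float:
    """R = V/k, the variance-to-mean ratio of family size."""
    if k <= 0:
        raise UndefinedInputError("index of variability undefined for k <= 0")
    if v < 0:
        raise UndefinedInputError("variance must be non-negative")
    return v / k


def scale_to_k2(k: float, r: float) -> float:
    """Scale an index of variability to its expected value at mean family
    size 2, assuming random survival from the measured stage.

    May legitimately fall below 0 for r < 1 and k < 2; callers should treat
    a negative result as inadmissible (flagged by :class:`StageIndex`).
    """
    if k <= 0:
        raise UndefinedInputError("scaling undefined for k <= 0")
    r_star = 1.0 + (2.0 / k) * (r - 1.0)
    if r_star < 0:
        warnings.warn(
            f"scaled index {r_star:.3f} < 0 (k={k}, R={r}); inadmissible",
            RuntimeWarning, stacklevel=2,
        )
    return r_star


def ratio_from_index(r_star: float) -> float:
    """Effective-to-census ratio 2/(1 + R*) at replacement mean family size."""
    if r_star <= -1:
        raise UndefinedInputError("ratio undefined for R* <= -1")
    return 2.0 / (1.0 + r_star)


def stage_change(r_star_1: float, r_star_3: float) -> float:
    """Percent change of the Nb/N ratio between the age-1 and age-3 classes.

    Positive values mean a further reduction of Nb/N between the stages
    (family-correlated survival); negative values an increase (survival more
    even than random).
    """
    ratio_1 = ratio_from_index(r_star_1)
    ratio_3 = ratio_from_index(r_star_3)
    return 100.0 * (ratio_1 - ratio_3) / ratio_1


@dataclass
class StageIndex:
    """Index-of-variability summary for one offspring age class."""

    age_class: int
    k: float
    v: float
    r: float
    r_star: float
    nb_over_n: float
    admissible: bool

    @classmethod
    def from_moments(cls, age_class: int, k: float, v: float) -> "StageIndex":
        r = index_of_variability(k, v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r_star = scale_to_k2(k, r)
        admissible = r_star > -1
        nb_over_n = ratio_from_index(r_star) if admissible else float("nan")
        return cls(age_class=age_class, k=k, v=v, r=r, r_star=r_star,
                   nb_over_n=nb_over_n, admissible=admissible and r_star >= 0)
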