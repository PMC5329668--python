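"""Validation statistics: log deltas, deviation fractions, percentile spreads.

Epitope counts act on alloreactivity roughly logarithmically — going from 1
to 10 epitopes matters more than going from 200 to 210 — so observed and
reference values are compared on the natural-log scale:

    delta = ln(observed) - ln(reference)

A delta beyond +-1 (one full log unit) is flagged as a high deviation.
Because weighted epitope values of zero occur (fully matched couples), the
zero-count policy is explicit: either such couples are excluded and counted,
or a ln(x+1) transform is applied to both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

HIGH_DEVIATION = 1.0

#: Two-sided percentile levels reported by summaries.
SPREAD_LEVELS = (50.0, 75.0, 95.0, 99.0, 99.9)

#: |delta| below this counts as "no deviation": after frequency-weighted
#: summation exact float equality is meaningless, but a candidate set that
#: collapses to the true genotype produces a delta at rounding level.
ZERO_TOLERANCE = 1e-12

DEFAULT_THRESHOLDS = (0.0, 0.1, 1.0)


@dataclass(frozen=True)
class CoupleDelta:
    """ln(observed) - ln(reference) for one couple and engine."""

    delta: float
    ln_observed: float
    ln_reference: float
    couple_id: Optional[str] = None
    engine: Optional[str] = None
    zero_handled: bool = False  # a raw count was 0 and the add_one policy applied

    @property
    def high_deviation(self) -> bool:
        return abs(self.delta) > HIGH_DEVIATION


def ln_delta(
    observed: float,
    reference: float,
    zero_policy: str = "exclude",
    couple_id: Optional[str] = None,
    engine: Optional[str] = None,
) -> Optional[CoupleDelta]:
    """Log-scale delta between observed and reference epitope values.

    Returns ``None`` (the excluded marker) when either value is zero under
    the ``exclude`` policy; under ``add_one`` both sides get a ln(x+1)
    transform and the couple is kept, flagged via ``zero_handled``.
    """
    if observed < 0 or reference < 0:
        raise ValueError("epitope values must be nonnegative")
    if observed > 0 and reference > 0:
        lo, lr = math.log(observed), math.log(reference)
        return CoupleDelta(
            delta=lo - lr, ln_observed=lo, ln_reference=lr,
            couple_id=couple_id, engine=engine,
        )
    if zero_policy == "exclude":
        return None
    if zero_policy == "add_one":
        lo, lr = math.log1p(observed), math.log1p(reference)
        return CoupleDelta(
            delta=lo - lr, ln_observed=lo, ln_reference=lr,
            couple_id=couple_id, engine=engine, zero_handled=True,
        )
    raise ValueError(f"unknown zero policy {zero_policy!r}")


def percentile_spread(deltas: Sequence[float], level: float) -> tuple[float, float]:
    """Two-sided spread around the median covering ``level`` % of deltas.

    Returns the empirical quantiles at (50 - level/2)% and (50 + level/2)%,
    i.e. how far the central ``level`` % of deltas stretches below and above
    the median.  Quantiles use linear interpolation between order statistics.
    """
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a spread on an empty delta list")
    if not 0 < level <= 100:
        raise ValueError(f"level must be in (0, 100], got {level}")
    lower = float(np.quantile(arr, (50.0 - level / 2.0) / 100.0, method="linear"))
    upper = float(np.quantile(arr, (50.0 + level / 2.0) / 100.0, method="linear"))
    return lower, upper


@dataclass
class DeltaSummary:
    """Descriptive summary of a set of couple deltas."""

    n_total: int
    n_unimputable: int
    n_zero_excluded: int
    fraction_zero_delta: float
    fraction_within: dict  # threshold -> fraction with |delta| <= threshold
    n_high_positive: int
    n_high_negative: int
    spreads: dict  # level -> (lower, upper)
    quantile_method: str = "linear"
    zero_tolerance: float = ZERO_TOLERANCE

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_unimputable": self.n_unimputable,
            "n_zero_excluded": self.n_zero_excluded,
            "fraction_zero_delta": self.fraction_zero_delta,
            "fraction_within": {str(k): v for k, v in self.fraction_within.items()},
            "n_high_positive": self.n_high_positive,
            "n_high_negative": self.n_high_negative,
            "spreads": {str(k): list(v) for k, v in self.spreads.items()},
            "quantile_method": self.quantile_method,
            "zero_tolerance": self.zero_tolerance,
        }


def summarize(
    deltas: Iterable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    zero_tolerance: float = ZERO_TOLERANCE,
    n_unimputable: int = 0,
    n_zero_excluded: int = 0,
) -> DeltaSummary:
    """Summarize couple deltas: zero fraction, threshold fractions, spreads.

    ``deltas`` may be floats or :class:`CoupleDelta` objects.  A couple
    counts as zero-delta iff |delta| < ``zero_tolerance``; a threshold of 0
    in ``thresholds`` uses the same rule.
    """
    values = np.asarray(
        [d.delta if isinstance(d, CoupleDelta) else float(d) for d in deltas],
        dtype=float,
    )
    if values.size == 0:
        raise ValueError("cannot summarize an empty delta list")
    fraction_zero = float(np.mean(np.abs(values) < zero_tolerance))
    fraction_within = {}
    for t in thresholds:
        if t == 0:
            fraction_within[t] = fraction_zero
        else:
            fraction_within[t] = float(np.mean(np.abs(values) <= t))
    spreads = {level: percentile_spread(values, level) for level in SPREAD_LEVELS}
    return DeltaSummary(
        n_total=int(values.size),
        n_unimputable=n_unimputable,
        n_zero_excluded=n_zero_excluded,
        fraction_zero_delta=fraction_zero,
        fraction_within=fraction_within,
        n_high_positive=int(np.sum(values > HIGH_DEVIATION)),
        n_high_negative=int(np.sum(values < -HIGH_DEVIATION)),
        spreads=spreads,
    )


def deltas_from_evaluation(evaluation, zero_policy: str = "exclude"):
    """Turn a :class:`~epimatch.scoring.CoupleEvaluation` into deltas.

    Returns (list of CoupleDelta, n_zero_excluded).
    """
    out = []
    n_zero_excluded = 0
    for couple_index, observed, reference in evaluation.observed:
        d = ln_delta(
            observed,
            reference,
            zero_policy=zero_policy,
            couple_id=str(couple_index),
            engine=evaluation.engine,
        )
        if d is None:
            n_zero_excluded += 1
        else:
            out.append(d)
    return out, n_zero_excluded
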