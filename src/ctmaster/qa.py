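"""Radiologist acceptance rates and exact comparison between scanners.

A customized protocol is clinically validated by comparing its radiologist
acceptance rate (good reads / all reads) against the reference scanner the
protocol was customized from.  Comparisons use the two-tailed Fisher exact
test on the 2x2 good/bad table, with significance at p < 0.005.  Because a
large sample can make a clinically negligible difference significant, the
report also flags whether the rate difference falls within a
practical-equivalence margin (1 percentage point by default).

The two-sided p-value follows the minimum-likelihood convention: the sum of
hypergeometric probabilities of all tables (with the observed margins) whose
probability does not exceed that of the observed table.  The summation is
done in exact integer arithmetic, so probability ties are handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .core import InvalidInputError

__all__ = [
    "UndefinedRateError",
    "FisherResult",
    "acceptance_rate",
    "fisher_exact_two_tailed",
    "compare_protocol_acceptance",
]


class UndefinedRateError(InvalidInputError):
    """Acceptance rate requested for zero records."""


def acceptance_rate(n_good: int, n_bad: int) -> float:
    """Percent acceptance: good reads over all reads, in percent."""
    for name, v in (("n_good", n_good), ("n_bad", n_bad)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")
    total = n_good + n_bad
    if total == 0:
        raise UndefinedRateError("acceptance rate undefined for zero records")
    return 100.0 * n_good / total


@dataclass(frozen=True)
class FisherResult:
    """Exact two-tailed p-value with its significance call."""

    p_value: float
    significant: bool
    alpha: float


def _validate_counts(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise InvalidInputError(f"expected a 2x2 table, got shape {arr.shape}")
    flat = []
    for v in arr.ravel():
        fv = float(v)
        if not (math.isfinite(fv) and fv >= 0 and fv == int(fv)):
            raise InvalidInputError(f"counts must be non-negative integers, got {v!r}")
        flat.append(int(fv))
    return tuple(flat)  # type: ignore[return-value]


def fisher_exact_two_tailed(table, alpha: float = 0.005) -> FisherResult:
    """Two-tailed Fisher exact test on a 2x2 count table.

    Sums the hypergeometric probabilities of every table sharing the observed
    margins whose probability is less than or equal to that of the observed
    table (minimum-likelihood two-sided rule).  Integer arithmetic makes the
    tie comparison exact; only the final ratio is a float.

    Parameters
    ----------
    table : array_like, shape (2, 2)
        Non-negative integer counts; at least one margin must be non-zero.
    alpha : float
        Significance level (default 0.005).

    Returns
    -------
    FisherResult
        ``p_value`` in (0, 1] and ``significant = p_value < alpha``.
    """
    a, b, c, d = _validate_counts(table)
    n_total = a + b + c + d
    if n_total == 0:
        raise InvalidInputError("table is all zero; at least one margin must be non-zero")
    r1, r2 = a + b, c + d
    c1 = a + c
    if min(r1, r2, c1, b + d) == 0:
        # Only one table is compatible with the margins.
        return FisherResult(p_value=1.0, significant=False, alpha=alpha)
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(a_min, a_max + 1)]
    observed = weights[a - a_min]
    numerator = sum(w for w in weights if w <= observed)
    p = numerator / comb(n_total, c1)
    return FisherResult(p_value=min(float(p), 1.0), significant=p < alpha, alpha=alpha)


def compare_protocol_acceptance(reference: tuple[int, int],
                                others,
                                alpha: float = 0.005,
                                equivalence_margin_pct: float = 1.0) -> pd.DataFrame:
    """Compare each scanner's acceptance rate against the reference scanner.

    Parameters
    ----------
    reference : (n_good, n_bad)
        QA counts on the scanner the protocols were customized from.
    others : sequence of (label, n_good, n_bad)
        QA counts per customized platform.
    alpha : float
        Significance level for the Fisher tests.
    equivalence_margin_pct : float
        Rate differences within this many percentage points are flagged as
        practically equivalent even when statistically significant.

    Returns
    -------
    pandas.DataFrame
        One row per platform (reference first) with acceptance %, exact
        p-value against the reference, the significance flag, and the
        equivalence flag.
    """
    ref_good, ref_bad = reference
    ref_rate = acceptance_rate(ref_good, ref_bad)
    rows = [{"label": "reference", "n_good": ref_good, "n_bad": ref_bad,
             "acceptance_pct": ref_rate, "p_value": 1.0, "significant": False,
             "rate_diff_pct": 0.0, "within_equivalence_margin": True}]
    for label, good, bad in others:
        rate = acceptance_rate(good, bad)
        res = fisher_exact_two_tailed([[ref_good, ref_bad], [good, bad]], alpha=alpha)
        diff = rate - ref_rate
        rows.append({"label": label, "n_good": good, "n_bad": bad,
                     "acceptance_pct": rate, "p_value": res.p_value,
                     "significant": res.significant, "rate_diff_pct": diff,
                     "within_equivalence_margin": abs(diff) <= equivalence_margin_pct})
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["equivalence_margin_pct"] = equivalence_margin_pct
    return df
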