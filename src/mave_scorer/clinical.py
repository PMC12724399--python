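"""Case-control risk ratios and splice-disruption score aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["RiskRatio", "risk_ratio", "spliceai_aggregate", "spliceai_max_aggregate"]


@dataclass
class RiskRatio:
    rr: float
    ci_low: float
    ci_high: float
    ci_level: float
    one_sided: bool = False  # True when a = 0 and only an upper bound exists


def risk_ratio(a: int, b: int, c: int, d: int, ci_level: float = 0.95) -> RiskRatio:
    """Risk ratio ``(a/(a+c)) / (b/(b+d))`` with a Katz log-normal CI.

    a = cases with the variant class, b = controls with it, c = cases
    without, d = controls without.  The CI is
    ``exp(ln RR +/- z * sqrt(1/a - 1/(a+c) + 1/b - 1/(b+d)))``.
    A zero ``a`` yields RR 0 with a one-sided flag; a zero ``b`` makes the
    ratio undefined and raises.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if a + c <= 0 or b + d <= 0:
        raise ValueError("need at least one case and one control")
    if b == 0:
        raise ValueError("risk ratio undefined when no control carries the variant")
    if a == 0:
        return RiskRatio(rr=0.0, ci_low=0.0, ci_high=np.inf, ci_level=ci_level,
                         one_sided=True)
    rr = (a / (a + c)) / (b / (b + d))
    z = norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(1 / a - 1 / (a + c) + 1 / b - 1 / (b + d))
    return RiskRatio(
        rr=float(rr),
        ci_low=float(rr * np.exp(-z * se)),
        ci_high=float(rr * np.exp(z * se)),
        ci_level=ci_level,
    )


def spliceai_aggregate(
    ag: float, al: float, dg: float, dl: float, as_product: bool = False
) -> float:
    """Aggregate the four splice sub-scores into one disruption probability.

    The four inputs are the probabilities of acceptor gain/loss and donor
    gain/loss.  The default returns
    ``1 - (1-AG)(1-AL)(1-DG)(1-DL)`` — the probability that at least one
    splice alteration occurs, monotone increasing in every component.
    ``as_product`` returns the bare product ``(1-AG)(1-AL)(1-DG)(1-DL)``
    (the probability of *no* disruption) instead.
    """
    vals = (ag, al, dg, dl)
    for name, v in zip(("AG", "AL", "DG", "DL"), vals):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    product = float(np.prod([1.0 - v for v in vals]))
    return product if as_product else 1.0 - product


def spliceai_max_aggregate(
    table: pd.DataFrame, by: str = "variant", as_product: bool = False
) -> pd.Series:
    """Per-variant maximum aggregate score over alternative records.

    ``table`` carries one row per (variant, transcript/coordinate) with
    columns AG, AL, DG, DL.
    """
    agg = table.apply(
        lambda r: spliceai_aggregate(r["AG"], r["AL"], r["DG"], r["DL"],
                                     as_product=as_product),
        axis=1,
    )
    return agg.groupby(table[by]).max()
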