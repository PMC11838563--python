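"""Relating RT advance to nascent transcription across conditions.

A condition series is an ordered set of experimental conditions (e.g.
doxycycline doses or induction times), each carrying a domain-level RT
advance and the target gene's nascent expression.  Because the dose
response saturates (both transcription and RT advance plateau), the
association is summarized with a Spearman rank correlation rather than a
linear fit, plus a descriptive plateau onset.  The reversibility report
checks whether an induced advance returns to baseline after inducer
withdrawal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .advance import RTAdvance
from .errors import ConfigError

__all__ = [
    "Condition",
    "AssociationResult",
    "advance_vs_expression",
    "ReversibilityReport",
    "reversibility_report",
]


@dataclass
class Condition:
    """One point of a dose-response or time-course series."""

    label: str
    covariate: float  # e.g. Dox ug/ml, or hours of induction
    advance: RTAdvance
    expression_rpkm: float


@dataclass
class AssociationResult:
    spearman_rho: float  # NaN when undefined (constant input)
    spearman_p: float
    plateau_covariate: float | None
    table: pd.DataFrame

    @property
    def is_defined(self) -> bool:
        return not np.isnan(self.spearman_rho)


def advance_vs_expression(
    series: Sequence[Condition],
    plateau_tolerance_fraction: float = 0.1,
) -> AssociationResult:
    """Spearman correlation of RT advance against nascent expression.

    Needs >= 3 conditions.  With constant advance or constant expression
    the rank correlation is undefined; it is reported as NaN with a
    warning rather than an error, since a flat series is a legitimate
    experimental outcome (e.g. a promoterless control).  The plateau onset
    is the smallest covariate beyond which successive advances differ by
    less than ``plateau_tolerance_fraction * max|advance|`` (descriptive
    only; None when the series never settles).
    """
    if len(series) < 3:
        raise ConfigError("advance_vs_expression needs >= 3 conditions")
    table = pd.DataFrame(
        {
            "label": [c.label for c in series],
            "covariate": [c.covariate for c in series],
            "advance": [c.advance.delta for c in series],
            "range_lo": [c.advance.replicate_range[0] for c in series],
            "range_hi": [c.advance.replicate_range[1] for c in series],
            "expression_rpkm": [c.expression_rpkm for c in series],
        }
    ).sort_values("covariate", kind="stable", ignore_index=True)

    adv = table["advance"].to_numpy()
    expr = table["expression_rpkm"].to_numpy()
    if np.allclose(adv, adv[0]) or np.allclose(expr, expr[0]):
        warnings.warn(
            "Spearman correlation undefined: constant advance or expression; reporting NA",
            stacklevel=2,
        )
        rho, pval = float("nan"), float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, pval = _sstats.spearmanr(adv, expr)
        rho, pval = float(rho), float(pval)

    tol = plateau_tolerance_fraction * float(np.max(np.abs(adv))) if np.any(adv != 0) else 0.0
    plateau: float | None = None
    diffs = np.abs(np.diff(adv))
    for i in range(len(diffs)):
        if tol > 0 and np.all(diffs[i:] < tol):
            plateau = float(table["covariate"].iloc[i])
            break
    return AssociationResult(rho, pval, plateau, table)


@dataclass
class ReversibilityReport:
    reversible: bool
    ranges_overlap: bool
    significant_windows: dict[str, int]
    deltas: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "arm": arm,
                "delta": self.deltas[arm],
                "n_significant": self.significant_windows[arm],
            }
            for arm in ("induced", "withdrawn", "baseline")
        ]
        df = pd.DataFrame(rows)
        df["reversible"] = self.reversible
        return df


def _ranges_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def reversibility_report(
    on_condition: RTAdvance,
    off_condition: RTAdvance,
    baseline: RTAdvance,
) -> ReversibilityReport:
    """Did the RT advance revert after inducer withdrawal?

    Reversible iff the withdrawn condition's replicate range overlaps the
    never-induced baseline's range *and* its count of significant windows
    within the domain has returned to at most the baseline's.
    """
    for name, arm in (
        ("induced", on_condition),
        ("withdrawn", off_condition),
        ("baseline", baseline),
    ):
        if arm is None:
            raise ConfigError(f"missing arm: {name}")
        if arm.per_window is None:
            raise ConfigError(f"arm {name!r} lacks per-window significance")
    overlap = _ranges_overlap(off_condition.replicate_range, baseline.replicate_range)
    n_sig = {
        "induced": on_condition.n_significant(),
        "withdrawn": off_condition.n_significant(),
        "baseline": baseline.n_significant(),
    }
    reversible = overlap and n_sig["withdrawn"] <= n_sig["baseline"]
    return ReversibilityReport(
        reversible=reversible,
        ranges_overlap=overlap,
        significant_windows=n_sig,
        deltas={
            "induced": on_condition.delta,
            "withdrawn": off_condition.delta,
            "baseline": baseline.delta,
        },
    )
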