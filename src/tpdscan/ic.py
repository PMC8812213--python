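"""Information Component statistics with Bayesian shrinkage.

The Information Component (IC) is the log2 of the shrinkage-regularised
observed-to-expected ratio of event counts,

    IC = log2((O + 0.5) / (E + 0.5)),

the log posterior mean of a Gamma(O + 0.5, rate E + 0.5) posterior for the
incidence-rate ratio. The 0.5 shrinkage in numerator and denominator damps
volatility for rare events, and the same Gamma posterior supplies the 95%
credible interval (IC025, IC975).

The temporal-association summary ICΔ contrasts a post-exposure surveillance
window v against a pre-exposure control window u. The expected surveillance
count is the observed control count rescaled by the cohort-size ratio and the
shift in the all-drugs background event rate between the two periods:

    E* = CXY(u) · [CX(v) / CX(u)] · [(CY(v)/C(v)) / (CY(u)/C(u))]
    ICΔ = log2((CXY(v) + 0.5) / (E* + 0.5))

so a pair is flagged (ICΔ025 > 0) only when its surveillance count exceeds
what its own pre-exposure history predicts after calibrating for systematic
rate differences between calendar periods. With a simultaneous control
period (several candidate control windows) the lowest ICΔ is retained, which
raises specificity at some cost in sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

from .counts import BinGrid, CountStore, DayWindow
from .errors import UndefinedExpectedError

logger = logging.getLogger(__name__)

SHRINKAGE = 0.5


@dataclass(frozen=True)
class ICEstimate:
    """IC point estimate with 95% credible bounds for one observed/expected cell."""

    observed: int
    expected: float
    ic: float
    ic025: float
    ic975: float


def ic(observed: int | float, expected: float) -> ICEstimate:
    """Shrinkage IC and its Gamma-posterior 95% credible interval.

    The posterior for the incidence-rate ratio is Gamma with shape
    ``observed + 0.5`` and rate ``expected + 0.5``; its mean is exactly
    ``(O + 0.5)/(E + 0.5)``, so ``ic`` is the log posterior mean and the
    bounds are the log2 of its 2.5% and 97.5% quantiles.
    """
    if observed < 0 or expected < 0:
        raise ValueError(f"counts must be non-negative (O={observed}, E={expected})")
    shape = observed + SHRINKAGE
    rate = expected + SHRINKAGE
    point = math.log2(shape / rate)
    lo, hi = stats.gamma.ppf([0.025, 0.975], a=shape, scale=1.0 / rate)
    return ICEstimate(
        observed=observed,
        expected=expected,
        ic=point,
        ic025=math.log2(lo),
        ic975=math.log2(hi),
    )


def expected_count(store: CountStore, drug, condition, window: DayWindow) -> float:
    """Expected pair count from the marginals: E = CX · CY / C.

    A zero baseline count C makes the expectation undefined (raises), which is
    distinct from a legitimately zero expectation when a marginal is empty.
    """
    c = store.c(window)
    if c == 0:
        raise UndefinedExpectedError(f"C{window} = 0: expected count undefined")
    cx = store.cx(drug, window)
    cy = store.cy(condition, window)
    if cx == 0:
        logger.warning("drug %r has no index units in window %s", drug, window)
    return cx * cy / c


def chronograph_series(
    store: CountStore, drug, condition, grid: BinGrid
) -> dict[int, ICEstimate]:
    """Per-bin IC estimates for one drug-condition pair over a bin grid.

    Bins whose baseline count C is zero are omitted (missing, not zero).
    """
    series: dict[int, ICEstimate] = {}
    for m, w in grid.windows().items():
        if store.c(w) == 0:
            continue
        observed = store.cxy(drug, condition, w)
        series[m] = ic(observed, expected_count(store, drug, condition, w))
    return series


@dataclass(frozen=True)
class AnalysisSetting:
    """One or more pre-exposure control windows plus a surveillance window."""

    name: str
    control_windows: tuple[DayWindow, ...]
    surveillance_window: DayWindow

    def __post_init__(self) -> None:
        if not self.control_windows:
            raise ValueError("at least one control window required")
        for w in self.control_windows:
            if w.end_day > -1:
                raise ValueError(f"control window {w} must end before day 0")
        if self.surveillance_window.start_day < 1:
            raise ValueError(
                f"surveillance window {self.surveillance_window} must start after day 0"
            )

    @property
    def windows(self) -> tuple[DayWindow, ...]:
        return self.control_windows + (self.surveillance_window,)


#: The four shipped analytical settings: control period(s) / surveillance period.
SETTINGS: dict[str, AnalysisSetting] = {
    "setting1": AnalysisSetting("setting1", (DayWindow(-180, -1),), DayWindow(1, 30)),
    "setting2": AnalysisSetting("setting2", (DayWindow(-180, -1),), DayWindow(1, 360)),
    "setting3": AnalysisSetting(
        "setting3", (DayWindow(-180, -1), DayWindow(-30, -1)), DayWindow(1, 30)
    ),
    "setting4": AnalysisSetting(
        "setting4", (DayWindow(-180, -1), DayWindow(-30, -1)), DayWindow(1, 360)
    ),
}


@dataclass(frozen=True)
class ICDeltaResult:
    """ICΔ for one drug-condition pair under one analytical setting."""

    drug_id: object
    condition_id: object
    setting: AnalysisSetting
    observed_v: int = 0
    expected_star: float = float("nan")
    icdelta: float = float("nan")
    icdelta025: float = float("nan")
    icdelta975: float = float("nan")
    chosen_control: DayWindow | None = None
    signal: bool = False
    incalculable: bool = False
    reason: str | None = None


def icdelta(
    store: CountStore,
    drug,
    condition,
    control: DayWindow,
    surveillance: DayWindow,
    setting: AnalysisSetting | None = None,
) -> ICDeltaResult:
    """ICΔ contrast of a surveillance window against one control window.

    A zero denominator among CX(u), C(u), C(v), CY(u) makes the contrast
    incalculable; such results are flagged (never silently treated as
    non-signals) so downstream metrics can exclude them with a reason.
    """
    setting = setting or AnalysisSetting("custom", (control,), surveillance)
    cxy_u = store.cxy(drug, condition, control)
    cx_u = store.cx(drug, control)
    cx_v = store.cx(drug, surveillance)
    c_u = store.c(control)
    c_v = store.c(surveillance)
    cy_u = store.cy(condition, control)
    cy_v = store.cy(condition, surveillance)

    zeros = [
        name
        for name, value in (
            (f"CX{control}", cx_u),
            (f"C{control}", c_u),
            (f"C{surveillance}", c_v),
            (f"CY{control}", cy_u),
        )
        if value == 0
    ]
    if zeros:
        return ICDeltaResult(
            drug_id=drug,
            condition_id=condition,
            setting=setting,
            chosen_control=control,
            incalculable=True,
            reason="zero denominator: " + ", ".join(zeros),
        )

    expected_star = cxy_u * (cx_v / cx_u) * ((cy_v / c_v) / (cy_u / c_u))
    observed_v = store.cxy(drug, condition, surveillance)
    est = ic(observed_v, expected_star)
    return ICDeltaResult(
        drug_id=drug,
        condition_id=condition,
        setting=setting,
        observed_v=observed_v,
        expected_star=expected_star,
        icdelta=est.ic,
        icdelta025=est.ic025,
        icdelta975=est.ic975,
        chosen_control=control,
        signal=est.ic025 > 0,
    )


def icdelta_simultaneous(
    store: CountStore,
    drug,
    condition,
    setting: AnalysisSetting,
    pick: str = "point",
) -> ICDeltaResult:
    """ICΔ under a setting, taking the lowest over its control windows.

    With one control window this reduces to :func:`icdelta`. ``pick``
    selects the minimised quantity: the ICΔ point estimate (default) or the
    lower credible bound (``"lower"``).
    """
    if pick not in ("point", "lower"):
        raise ValueError("pick must be 'point' or 'lower'")
    results = [
        icdelta(store, drug, condition, u, setting.surveillance_window, setting=setting)
        for u in setting.control_windows
    ]
    calculable = [r for r in results if not r.incalculable]
    if not calculable:
        return ICDeltaResult(
            drug_id=drug,
            condition_id=condition,
            setting=setting,
            incalculable=True,
            reason="; ".join(r.reason or "" for r in results),
        )
    key = (lambda r: r.icdelta) if pick == "point" else (lambda r: r.icdelta025)
    return min(calculable, key=key)
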