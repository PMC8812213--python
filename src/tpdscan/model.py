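"""Model/Results facade over the temporal-pattern-discovery pipeline.

`TemporalPatternDiscovery` is built from a cohort (three longitudinal
tables); `fit()` materialises the window counts and ICΔ estimates for every
requested drug-condition pair under one or more analytical settings,
returning a `TPDResults` that carries the estimates, their credible
intervals, a summary table, chronograph plotting and the control-based
evaluation harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import chronograph as _chronograph
from .counts import BinGrid, CountStore, DayWindow, compute_counts
from .evaluation import SettingComparison, compare_settings
from .ic import SETTINGS, AnalysisSetting, icdelta_simultaneous
from .io import Cohort, read_cohort, validate_cohort
from .simulate import GroundTruth


class TemporalPatternDiscovery:
    """Temporal pattern discovery screen over a longitudinal cohort.

    Parameters
    ----------
    cohort : Cohort
        Validated exposures, condition occurrences and observation periods.
    mode : {"distinct", "all"}
        Counting unit: one index per (person, drug) at first exposure
        (``distinct``, the self-controlled default) or one per exposure
        occurrence (``all``).

    Examples
    --------
    >>> model = TemporalPatternDiscovery(cohort)
    >>> res = model.fit(settings=["setting1", "setting2"])
    >>> print(res.summary())
    """

    def __init__(self, cohort: Cohort, mode: str = "distinct"):
        self.cohort = cohort
        self.mode = mode

    @classmethod
    def from_frames(
        cls,
        exposures: pd.DataFrame,
        conditions: pd.DataFrame,
        observation: pd.DataFrame,
        mode: str = "distinct",
    ) -> "TemporalPatternDiscovery":
        """Build from internal-schema frames (integer day columns)."""
        return cls(validate_cohort(exposures, conditions, observation), mode=mode)

    @classmethod
    def from_files(
        cls,
        exposure_path: str,
        condition_path: str,
        observation_path: str,
        format: str = "csv",
        mode: str = "distinct",
    ) -> "TemporalPatternDiscovery":
        """Build from the three OMOP-style tables on disk."""
        return cls(read_cohort(exposure_path, condition_path, observation_path, format), mode=mode)

    def _resolve_settings(self, settings) -> list[AnalysisSetting]:
        if settings is None:
            return list(SETTINGS.values())
        out = []
        for s in settings:
            out.append(SETTINGS[s] if isinstance(s, str) else s)
        return out

    def fit(
        self,
        settings=None,
        pairs: list[tuple] | None = None,
        grid: BinGrid | None = None,
        pick: str = "point",
    ) -> "TPDResults":
        """Compute counts and ICΔ estimates.

        Parameters
        ----------
        settings : list of AnalysisSetting or preset names, optional
            Defaults to the four shipped settings.
        pairs : list of (drug_id, condition_id), optional
            Defaults to every drug x condition combination present in the
            cohort (an open screening scan).
        grid : BinGrid, optional
            If given, chronograph bins are counted too so `TPDResults.
            chronograph` works without recounting.
        pick : {"point", "lower"}
            Quantity minimised over simultaneous control windows.
        """
        setting_list = self._resolve_settings(settings)
        windows: set[DayWindow] = set()
        for s in setting_list:
            windows.update(s.windows)
        if grid is not None:
            windows.update(grid.windows().values())
        store = compute_counts(self.cohort, sorted(windows), mode=self.mode)

        if pairs is None:
            drugs = sorted(self.cohort.exposures["drug_id"].unique())
            conditions = sorted(self.cohort.conditions["condition_id"].unique())
            pairs = [(d, c) for d in drugs for c in conditions]

        rows = []
        for s in setting_list:
            for drug, condition in pairs:
                r = icdelta_simultaneous(store, drug, condition, s, pick=pick)
                rows.append(
                    {
                        "setting": s.name,
                        "drug_id": drug,
                        "condition_id": condition,
                        "observed_v": r.observed_v,
                        "expected_star": r.expected_star,
                        "icdelta": r.icdelta,
                        "icdelta025": r.icdelta025,
                        "icdelta975": r.icdelta975,
                        "chosen_control": str(r.chosen_control) if r.chosen_control else "",
                        "signal": r.signal,
                        "incalculable": r.incalculable,
                    }
                )
        estimates = pd.DataFrame(rows)
        return TPDResults(
            model=self, store=store, settings=setting_list, estimates=estimates, grid=grid
        )


@dataclass
class TPDResults:
    """Fitted ICΔ estimates with uncertainty, diagnostics and plotting."""

    model: TemporalPatternDiscovery
    store: CountStore
    settings: list[AnalysisSetting]
    estimates: pd.DataFrame
    grid: BinGrid | None = None

    @property
    def signals(self) -> pd.DataFrame:
        """Pairs crossing the ICΔ025 > 0 threshold, strongest first."""
        df = self.estimates
        return df[df.signal].sort_values("icdelta025", ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        n_pairs = len(self.estimates[["drug_id", "condition_id"]].drop_duplicates())
        lines = [
            "Temporal Pattern Discovery Results",
            "=" * 66,
            f"persons: {self.model.cohort.n_persons}   counting mode: {self.model.mode}",
            f"drug-condition pairs screened: {n_pairs}   settings: "
            + ", ".join(s.name for s in self.settings),
            f"signals (ICΔ025 > 0): {int(self.estimates.signal.sum())}   "
            f"incalculable: {int(self.estimates.incalculable.sum())}",
            "-" * 66,
        ]
        cols = [
            "setting", "drug_id", "condition_id", "observed_v",
            "expected_star", "icdelta", "icdelta025", "icdelta975", "signal",
        ]
        top = self.estimates.sort_values(
            ["signal", "icdelta025"], ascending=[False, False]
        ).head(15)
        lines.append(top[cols].to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
        lines.append("-" * 66)
        return "\n".join(lines)

    def chronograph(self, drug, condition, grid: BinGrid | None = None, path: str | None = None):
        """Chronograph panel for one pair; renders to ``path`` if given."""
        grid = grid or self.grid
        if grid is None:
            grid = _chronograph.DEFAULT_GRID
        use_store = self.store
        if any(w not in self.store.C for w in grid.windows().values()):
            use_store = compute_counts(self.model.cohort, grid, mode=self.model.mode)
        panel = _chronograph.build_panel(use_store, drug, condition, grid)
        if path is not None:
            fmt = "svg" if path.endswith(".svg") else "png"
            _chronograph.render(panel, path, format=fmt)
        return panel

    def evaluate(self, truth: GroundTruth, pick: str = "point") -> SettingComparison:
        """Operating characteristics against labelled control pairs."""
        return compare_settings(self.store, truth, self.settings, pick=pick)
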