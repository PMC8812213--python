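"""Two-tier chronograph assembly, rendering and tabular export.

The chronograph visualises one drug-condition pair around the first
prescription date: the top tier plots the per-bin IC with its 95% credible
ribbon (relative excess/deficit of events), the bottom tier the observed bar
counts against the expected line (absolute scale). Bins where the baseline
count is zero appear as gaps, never as zeros.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import BinGrid, CountStore
from .errors import InputError
from .ic import chronograph_series

DEFAULT_GRID = BinGrid(bin_width_days=30, min_bin=-12, max_bin=12)

TABLE_COLUMNS = [
    "bin_start_day",
    "bin_end_day",
    "observed",
    "expected",
    "ic",
    "ic025",
    "ic975",
]


@dataclass
class ChronographPanel:
    """All numbers behind one chronograph: per-bin IC tier and count tier."""

    drug_id: object
    condition_id: object
    grid: BinGrid
    table: pd.DataFrame  # one row per bin, columns TABLE_COLUMNS, NaN = missing bin


def build_panel(store: CountStore, drug, condition, grid: BinGrid | None = None) -> ChronographPanel:
    """Assemble the panel table from stored counts; deterministic per store.

    A pair absent from the store yields a flat, valid panel: observed 0
    everywhere with the expected line from the marginals.
    """
    grid = grid or DEFAULT_GRID
    series = chronograph_series(store, drug, condition, grid)
    rows = []
    for m, w in grid.windows().items():
        if m in series:
            est = series[m]
            rows.append(
                (w.start_day, w.end_day, est.observed, est.expected, est.ic, est.ic025, est.ic975)
            )
        else:
            rows.append((w.start_day, w.end_day, np.nan, np.nan, np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return ChronographPanel(drug_id=drug, condition_id=condition, grid=grid, table=table)


def export_table(panel: ChronographPanel, path: str) -> str:
    """Write the panel table as CSV; missing bins keep their row with empty
    numeric cells. Full float precision is preserved for round-trips."""
    panel.table.to_csv(path, index=False)
    return path


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def render(panel: ChronographPanel, path: str, format: str = "png") -> str:
    """Render the two-tier chronograph to ``path`` (png or svg)."""
    if format not in ("png", "svg"):
        raise ValueError(f"unsupported format {format!r}")
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise InputError(f"output directory does not exist: {directory}")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = panel.table
    mid = (t.bin_start_day + t.bin_end_day) / 2.0
    width = panel.grid.bin_width_days * 0.85

    fig, (top, bottom) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 5), gridspec_kw={"height_ratios": [2, 1]}
    )
    present = t.ic.notna()
    top.fill_between(
        mid[present], t.ic025[present], t.ic975[present], alpha=0.3, color="#4878a8",
        label="95% credible interval",
    )
    top.plot(mid[present], t.ic[present], "o-", color="#2c4f6e", ms=3, label="IC")
    top.axhline(0.0, color="grey", lw=0.8)
    top.axvline(0.0, color="black", lw=1.0)
    limit = np.nanmax(np.abs(t[["ic025", "ic975"]].to_numpy())) if present.any() else 1.0
    if not math.isfinite(limit) or limit == 0:
        limit = 1.0
    top.set_ylim(-1.1 * limit, 1.1 * limit)  # symmetric for cross-pair comparability
    top.set_ylabel("IC (log2 O/E)")
    top.legend(fontsize=7, loc="upper left")
    top.set_title(
        f"Chronograph: drug {panel.drug_id} / condition {panel.condition_id}", fontsize=10
    )

    bottom.bar(mid, t.observed.fillna(0).where(present, np.nan), width=width,
               color="#c0c0c0", label="observed")
    bottom.plot(mid[present], t.expected[present], "-", color="#b04030", label="expected")
    bottom.axvline(0.0, color="black", lw=1.0)
    bottom.set_xlabel("days since first exposure")
    bottom.set_ylabel("events")
    bottom.legend(fontsize=7, loc="upper left")

    fig.tight_layout()
    try:
        fig.savefig(path, format=format)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path
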