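"""Time-binned marginal counts relative to first-exposure index dates.

For every analytic window (a closed interval of day offsets excluding the
index day 0) four counts are materialised:

* ``C``   — index units whose observation period overlaps the window,
* ``CX``  — those belonging to a given drug,
* ``CY``  — index units (any drug) with at least one occurrence of a given
  condition inside the window,
* ``CXY`` — drug-specific index units with at least one occurrence.

Counting units come in two modes. ``distinct`` anchors one unit per
(person, drug) at the first exposure date — the self-controlled design's
native unit. ``all`` treats every (person, drug, exposure date) occurrence as
its own index unit. A baseline cache lets ``C``/``CY`` (the expensive,
drug-independent marginals) be reused across drug-specific queries, guarded
by a cohort fingerprint so stale caches fail loudly instead of silently.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import StaleCacheError, TpdError
from .io import Cohort

MODES = ("all", "distinct")


@dataclass(frozen=True, order=True)
class DayWindow:
    """Closed interval of day offsets relative to the index date.

    Day 0 (the index day itself) belongs to no analytic window, so the
    interval must lie entirely before or entirely after it.
    """

    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError(f"empty window [{self.start_day}, {self.end_day}]")
        if self.start_day <= 0 <= self.end_day:
            raise ValueError(
                f"window [{self.start_day}, {self.end_day}] may not contain day 0"
            )

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    def __str__(self) -> str:
        return f"[{self.start_day},{self.end_day}]"


@dataclass(frozen=True)
class BinGrid:
    """Uniform grid of day-offset bins straddling the index date.

    Bin m >= 1 covers offsets [(m-1)*w + 1, m*w]; bin m <= -1 covers
    [m*w, (m+1)*w - 1]; there is no bin 0, so day 0 is never counted.
    """

    bin_width_days: int = 30
    min_bin: int = -12
    max_bin: int = 12

    def __post_init__(self) -> None:
        if self.bin_width_days < 1:
            raise ValueError("bin_width_days must be >= 1")
        if not (self.min_bin <= -1 and self.max_bin >= 1):
            raise ValueError("grid must span at least bins -1 and 1")

    @property
    def bins(self) -> tuple[int, ...]:
        return tuple(b for b in range(self.min_bin, self.max_bin + 1) if b != 0)

    def window(self, m: int) -> DayWindow:
        w = self.bin_width_days
        if m >= 1:
            return DayWindow((m - 1) * w + 1, m * w)
        if m <= -1:
            return DayWindow(m * w, (m + 1) * w - 1)
        raise ValueError("bin 0 does not exist")

    def windows(self) -> dict[int, DayWindow]:
        return {m: self.window(m) for m in self.bins}


def as_windows(windows: Iterable[DayWindow] | BinGrid) -> tuple[DayWindow, ...]:
    if isinstance(windows, BinGrid):
        return tuple(windows.windows().values())
    return tuple(windows)


def cohort_fingerprint(cohort: Cohort) -> str:
    """Order-insensitive content fingerprint of a cohort.

    Format: ``n_exposures:n_conditions:n_persons:hash16``. Any change to the
    underlying rows changes the hash, invalidating count caches.
    """
    digest = hashlib.sha256()
    for df, cols in (
        (cohort.exposures, ["person_id", "drug_id", "day"]),
        (cohort.conditions, ["person_id", "condition_id", "day"]),
        (cohort.observation, ["person_id", "start_day", "end_day"]),
    ):
        row_hashes = pd.util.hash_pandas_object(
            df[cols].astype(str).agg("|".join, axis=1), index=False
        ).to_numpy()
        row_hashes.sort()
        digest.update(row_hashes.tobytes())
    return (
        f"{len(cohort.exposures)}:{len(cohort.conditions)}:"
        f"{cohort.n_persons}:{digest.hexdigest()[:16]}"
    )


@dataclass
class CountStore:
    """Materialised per-window counts with provenance metadata."""

    mode: str
    windows: tuple[DayWindow, ...]
    C: dict[DayWindow, int] = field(default_factory=dict)
    CX: dict[tuple, int] = field(default_factory=dict)  # (drug, window) -> n
    CY: dict[tuple, int] = field(default_factory=dict)  # (condition, window) -> n
    CXY: dict[tuple, int] = field(default_factory=dict)  # (drug, condition, window)
    fingerprint: str = ""

    def c(self, window: DayWindow) -> int:
        return int(self.C.get(window, 0))

    def cx(self, drug, window: DayWindow) -> int:
        return int(self.CX.get((drug, window), 0))

    def cy(self, condition, window: DayWindow) -> int:
        return int(self.CY.get((condition, window), 0))

    def cxy(self, drug, condition, window: DayWindow) -> int:
        return int(self.CXY.get((drug, condition, window), 0))

    @property
    def drugs(self) -> list:
        return sorted({k[0] for k in self.CX})

    @property
    def conditions(self) -> list:
        return sorted({k[0] for k in self.CY})

    def validate(self) -> None:
        """Assert the dominance chain CXY <= min(CX, CY) <= C per cell."""
        for w in self.windows:
            c = self.c(w)
            for (x, wx), v in self.CX.items():
                if wx == w and not 0 <= v <= c:
                    raise TpdError(f"CX({x},{w})={v} exceeds C={c}")
            for (y, wy), v in self.CY.items():
                if wy == w and not 0 <= v <= c:
                    raise TpdError(f"CY({y},{w})={v} exceeds C={c}")
        for (x, y, w), v in self.CXY.items():
            bound = min(self.cx(x, w), self.cy(y, w))
            if not 0 <= v <= bound:
                raise TpdError(f"CXY({x},{y},{w})={v} exceeds min(CX,CY)={bound}")

    def equals(self, other: "CountStore") -> bool:
        return (
            self.mode == other.mode
            and set(self.windows) == set(other.windows)
            and self.C == other.C
            and self.CX == other.CX
            and self.CY == other.CY
            and self.CXY == other.CXY
            and self.fingerprint == other.fingerprint
        )


def derive_index_exposures(cohort: Cohort) -> pd.DataFrame:
    """One index exposure per (person, drug): the earliest exposure date.

    Returns a frame with columns person_id, drug_id, index_day.
    """
    return (
        cohort.exposures.groupby(["person_id", "drug_id"], as_index=False, sort=True)["day"]
        .min()
        .rename(columns={"day": "index_day"})
    )


def _index_units(cohort: Cohort, mode: str) -> pd.DataFrame:
    """Index units for the requested counting mode, one row per unit."""
    if mode == "distinct":
        units = derive_index_exposures(cohort)
    elif mode == "all":
        units = (
            cohort.exposures.drop_duplicates(["person_id", "drug_id", "day"])
            .rename(columns={"day": "index_day"})
            .sort_values(["person_id", "drug_id", "index_day"])
            .reset_index(drop=True)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return units.reset_index(drop=True)


def is_observed(index_day: int, window: DayWindow, start_day: int, end_day: int) -> bool:
    """True iff the window, anchored at index_day, overlaps the observation
    period [start_day, end_day] by at least one calendar day."""
    return index_day + window.start_day <= end_day and index_day + window.end_day >= start_day


def compute_counts(
    cohort: Cohort,
    windows: Iterable[DayWindow] | BinGrid,
    mode: str = "distinct",
    baseline_cache: CountStore | None = None,
    skip_baseline: bool = False,
) -> CountStore:
    """Materialise C, CX, CY, CXY for every window in one vectorised pass.

    The drug-condition event offsets are pre-aggregated once and sliced per
    window, so adding windows is cheap. With ``skip_baseline`` the
    drug-independent marginals C and CY are copied from ``baseline_cache``
    after verifying its mode, windows and cohort fingerprint; any mismatch
    raises :class:`StaleCacheError` rather than silently reusing stale counts.
    """
    window_list = as_windows(windows)
    fp = cohort_fingerprint(cohort)
    store = CountStore(mode=mode, windows=window_list, fingerprint=fp)

    if skip_baseline:
        if baseline_cache is None:
            raise StaleCacheError("skip_baseline requested but no cache supplied")
        if baseline_cache.mode != mode:
            raise StaleCacheError(
                f"cache mode {baseline_cache.mode!r} != requested {mode!r}"
            )
        if set(baseline_cache.windows) != set(window_list):
            raise StaleCacheError("cache windows differ from requested windows")
        if baseline_cache.fingerprint != fp:
            raise StaleCacheError(
                "cache fingerprint does not match cohort "
                f"({baseline_cache.fingerprint} != {fp})"
            )

    units = _index_units(cohort, mode)
    units = units.merge(cohort.observation, on="person_id", how="left")
    units["unit"] = np.arange(len(units))

    events = cohort.conditions.drop_duplicates(["person_id", "condition_id", "day"])
    merged = units[["unit", "person_id", "drug_id", "index_day"]].merge(
        events, on="person_id", how="inner"
    )
    merged["offset"] = merged["day"] - merged["index_day"]

    index_day = units["index_day"].to_numpy()
    obs_start = units["start_day"].to_numpy()
    obs_end = units["end_day"].to_numpy()
    offsets = merged["offset"].to_numpy()

    for w in window_list:
        observed = (index_day + w.start_day <= obs_end) & (index_day + w.end_day >= obs_start)
        if not skip_baseline:
            store.C[w] = int(observed.sum())
        for drug, n in units.loc[observed].groupby("drug_id").size().items():
            store.CX[(drug, w)] = int(n)

        in_w = merged.loc[(offsets >= w.start_day) & (offsets <= w.end_day)]
        pairs = in_w.drop_duplicates(["unit", "condition_id"])
        if not skip_baseline:
            for cond, n in pairs.groupby("condition_id").size().items():
                store.CY[(cond, w)] = int(n)
        for (drug, cond), n in pairs.groupby(["drug_id", "condition_id"]).size().items():
            store.CXY[(drug, cond, w)] = int(n)

    if skip_baseline:
        store.C = dict(baseline_cache.C)
        store.CY = dict(baseline_cache.CY)

    store.validate()
    return store


def brute_force_counts(
    cohort: Cohort,
    windows: Iterable[DayWindow] | BinGrid,
    mode: str = "distinct",
) -> CountStore:
    """Naive per-person, per-window oracle with the same contract as
    :func:`compute_counts`. No pre-aggregation; intended for small cohorts."""
    window_list = as_windows(windows)
    store = CountStore(mode=mode, windows=window_list, fingerprint=cohort_fingerprint(cohort))

    periods = {
        row.person_id: (row.start_day, row.end_day)
        for row in cohort.observation.itertuples()
    }
    events_by_person: dict = {}
    for row in cohort.conditions.itertuples():
        events_by_person.setdefault(row.person_id, set()).add((row.condition_id, row.day))

    units = _index_units(cohort, mode)
    for row in units.itertuples():
        start, end = periods[row.person_id]
        person_events = events_by_person.get(row.person_id, ())
        for w in window_list:
            if not is_observed(row.index_day, w, start, end):
                continue
            store.C[w] = store.C.get(w, 0) + 1
            store.CX[(row.drug_id, w)] = store.CX.get((row.drug_id, w), 0) + 1
        for w in window_list:
            hit = set()
            for cond, day in person_events:
                if w.start_day <= day - row.index_day <= w.end_day:
                    hit.add(cond)
            for cond in hit:
                store.CY[(cond, w)] = store.CY.get((cond, w), 0) + 1
                key = (row.drug_id, cond, w)
                store.CXY[key] = store.CXY.get(key, 0) + 1

    store.validate()
    return store


def save_counts(store: CountStore, path: str) -> str:
    """Persist a CountStore as a CSV table plus a JSON metadata sidecar."""
    rows = []
    for w, n in sorted(store.C.items()):
        rows.append(("C", "", "", w.start_day, w.end_day, n))
    for (x, w), n in sorted(store.CX.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        rows.append(("CX", str(x), "", w.start_day, w.end_day, n))
    for (y, w), n in sorted(store.CY.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        rows.append(("CY", "", str(y), w.start_day, w.end_day, n))
    for (x, y, w), n in sorted(
        store.CXY.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]), kv[0][2])
    ):
        rows.append(("CXY", str(x), str(y), w.start_day, w.end_day, n))
    table = pd.DataFrame(
        rows,
        columns=["kind", "drug_id", "condition_id", "window_start", "window_end", "count"],
    )
    table.insert(0, "mode", store.mode)
    table.to_csv(path, index=False)

    sample_drug = next(iter(store.CX), (None,))[0]
    sample_cond = next(iter(store.CY), (None,))[0]
    meta = {
        "mode": store.mode,
        "fingerprint": store.fingerprint,
        "windows": [[w.start_day, w.end_day] for w in store.windows],
        "id_type": "int" if isinstance(sample_drug, (int, np.integer)) or isinstance(
            sample_cond, (int, np.integer)
        ) else "str",
    }
    with open(path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def load_counts(path: str) -> CountStore:
    """Inverse of :func:`save_counts`."""
    meta_path = path + ".meta.json"
    if not os.path.exists(path) or not os.path.exists(meta_path):
        raise TpdError(f"count store not found at {path} (+ .meta.json)")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
        table = pd.read_csv(
            path,
            dtype={"drug_id": "string", "condition_id": "string"},
            keep_default_na=False,
        )
    except (json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise TpdError(f"corrupt count store at {path}: {exc}") from exc
    required = {"mode", "kind", "drug_id", "condition_id", "window_start", "window_end", "count"}
    if not required.issubset(table.columns):
        raise TpdError(f"corrupt count store at {path}: missing columns")

    def _id(value: str):
        return int(value) if meta.get("id_type") == "int" else value

    table = table.rename(columns={"count": "n"})
    store = CountStore(
        mode=meta["mode"],
        windows=tuple(DayWindow(a, b) for a, b in meta["windows"]),
        fingerprint=meta["fingerprint"],
    )
    for row in table.itertuples():
        w = DayWindow(int(row.window_start), int(row.window_end))
        n = int(row.n)
        if row.kind == "C":
            store.C[w] = n
        elif row.kind == "CX":
            store.CX[(_id(row.drug_id), w)] = n
        elif row.kind == "CY":
            store.CY[(_id(row.condition_id), w)] = n
        elif row.kind == "CXY":
            store.CXY[(_id(row.drug_id), _id(row.condition_id), w)] = n
        else:
            raise TpdError(f"corrupt count store: unknown kind {row.kind!r}")
    return store
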