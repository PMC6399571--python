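"""Sliding-window labeling of admissions, patient-level splitting, and
class balancing.

Labeling rule: a nonfaller contributes one negative 24-hour window per
whole hospital day, anchored at admission. A faller contributes exactly one
positive window per fall — the 24 hours ending at the fall time — and
nothing else: earlier data cannot be labeled with confidence (the patient
did eventually fall), and post-final-fall data are excluded by default
because the care process changes after an event (configurable).

Evidence temporality is last-observation-carried-forward within the
admission: each window carries the latest observation of every variable at
or before the window's end, so e.g. a risk score remains in effect until
reassessment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWindow",
    "SplitPlan",
    "DataIntegrityError",
    "SplitError",
    "BalancingError",
    "build_windows",
    "build_all_windows",
    "split_by_patient",
    "oversample_positives",
    "monte_carlo_folds",
    "fold_seed",
    "write_windows",
    "read_windows",
]


class DataIntegrityError(ValueError):
    pass


class SplitError(ValueError):
    pass


class BalancingError(ValueError):
    pass


@dataclass(frozen=True)
class DailyWindow:
    """One labeled 24-hour slice of one admission.

    ``start_day`` is in days since admission; the interval is the half-open
    ``[start_day, start_day + 1)``. ``evidence`` holds the carried-forward
    state of every observed variable; ``label`` is 1 for a fall in the
    window.
    """

    patient_id: int
    admission_id: int
    window_index: int
    start_day: float
    label: int
    evidence: dict = field(hash=False)

    @property
    def end_day(self) -> float:
        return self.start_day + 1.0


def _max_obs_day(end_day: float) -> int:
    # observations are day-indexed at the start of each day; an observation
    # on day d enters windows whose interval extends past time d. Day-0
    # observations are charted at admission and precede every window, so
    # the cutoff never drops below day 0 (a fall in the first charted hour
    # of the stay still sees the admission assessment).
    return max(int(math.floor(end_day - 1e-9)), 0)


def build_windows(
    admission,
    events: Sequence = (),
    keep_post_fall: bool = False,
    carry_horizon: int | None = None,
) -> list[DailyWindow]:
    """Label one admission's stay into daily windows.

    ``admission`` needs ``patient_id``, ``admission_id``, ``length_of_stay``
    and ``daily_observations`` (day -> {variable: state}); ``events`` are
    this admission's fall events, ordered by time.
    """
    los = int(admission.length_of_stay)
    for ev in events:
        if ev.admission_id != admission.admission_id:
            raise DataIntegrityError(
                f"event for admission {ev.admission_id} passed to admission "
                f"{admission.admission_id}"
            )
        if not (0 <= ev.day_index < los and 0 <= ev.hour < 24):
            raise DataIntegrityError(
                f"fall event at day {ev.day_index} hour {ev.hour} outside "
                f"stay of {los} days (admission {admission.admission_id})"
            )

    def evidence_at(end_day: float) -> dict:
        max_day = _max_obs_day(end_day)
        lo = 0 if carry_horizon is None else max_day - carry_horizon + 1
        out: dict = {}
        for day in range(max(lo, 0), max_day + 1):
            obs = admission.daily_observations.get(day)
            if obs:
                out.update(obs)
        return out

    windows: list[DailyWindow] = []
    if not events:
        for d in range(los):
            windows.append(
                DailyWindow(
                    patient_id=admission.patient_id,
                    admission_id=admission.admission_id,
                    window_index=d,
                    start_day=float(d),
                    label=0,
                    evidence=evidence_at(d + 1.0),
                )
            )
        return windows

    ordered = sorted(events, key=lambda e: (e.day_index, e.hour))
    idx = 0
    for ev in ordered:
        end = ev.day_index + ev.hour / 24.0
        windows.append(
            DailyWindow(
                patient_id=admission.patient_id,
                admission_id=admission.admission_id,
                window_index=idx,
                start_day=end - 1.0,
                label=1,
                evidence=evidence_at(end),
            )
        )
        idx += 1
    if keep_post_fall:
        last = ordered[-1]
        for d in range(last.day_index + 1, los):
            windows.append(
                DailyWindow(
                    patient_id=admission.patient_id,
                    admission_id=admission.admission_id,
                    window_index=idx,
                    start_day=float(d),
                    label=0,
                    evidence=evidence_at(d + 1.0),
                )
            )
            idx += 1
    return windows


def build_all_windows(
    cohort,
    keep_post_fall: bool = False,
) -> list[DailyWindow]:
    """Vectorized window construction for a whole cohort.

    Equivalent to :func:`build_windows` admission by admission (asserted in
    the test suite), but performs carry-forward with one pivot over the
    cohort's long-format observations.
    """
    static = cohort.static
    if len(static) == 0:
        return []
    obs = cohort.observations
    wide = (
        obs.pivot_table(
            index=["admission_id", "day"],
            columns="variable",
            values="value",
            aggfunc="last",
        )
        .groupby(level=0)
        .ffill()
    )
    variables = list(wide.columns)
    wide_np = wide.to_numpy()
    row_of = {key: i for i, key in enumerate(wide.index)}

    ev = cohort.events
    events_by_adm: dict[int, list[tuple[int, int]]] = {}
    for r in ev.itertuples():
        events_by_adm.setdefault(int(r.admission_id), []).append(
            (int(r.day), int(r.hour))
        )

    def evidence_for(adm: int, max_day: int) -> dict:
        # LOCF: take the ffilled row at the last day <= max_day with data
        d = max_day
        while d >= 0 and (adm, d) not in row_of:
            d -= 1
        if d < 0:
            return {}
        row = wide_np[row_of[(adm, d)]]
        return {
            v: row[j]
            for j, v in enumerate(variables)
            if isinstance(row[j], str) or not pd.isna(row[j])
        }

    windows: list[DailyWindow] = []
    for srow in static.itertuples():
        adm = int(srow.admission_id)
        pat = int(srow.patient_id)
        los = int(srow.length_of_stay)
        falls = sorted(events_by_adm.get(adm, []))
        if not falls:
            for d in range(los):
                windows.append(
                    DailyWindow(pat, adm, d, float(d), 0, evidence_for(adm, d))
                )
            continue
        idx = 0
        for day, hour in falls:
            if not 0 <= day < los:
                raise DataIntegrityError(
                    f"fall event at day {day} outside stay of {los} days "
                    f"(admission {adm})"
                )
            end = day + hour / 24.0
            windows.append(
                DailyWindow(
                    pat, adm, idx, end - 1.0, 1,
                    evidence_for(adm, _max_obs_day(end)),
                )
            )
            idx += 1
        if keep_post_fall:
            for d in range(falls[-1][0] + 1, los):
                windows.append(
                    DailyWindow(pat, adm, idx, float(d), 0, evidence_for(adm, d))
                )
                idx += 1
    return windows


@dataclass(frozen=True)
class SplitPlan:
    """A patient-level train/test partition."""

    train_patients: frozenset
    test_patients: frozenset
    seed: int

    def __post_init__(self) -> None:
        if self.train_patients & self.test_patients:
            raise SplitError("train and test patient sets overlap")

    def train_windows(self, windows: Iterable[DailyWindow]) -> list[DailyWindow]:
        return [w for w in windows if w.patient_id in self.train_patients]

    def test_windows(self, windows: Iterable[DailyWindow]) -> list[DailyWindow]:
        return [w for w in windows if w.patient_id in self.test_patients]


def split_by_patient(
    windows: Sequence[DailyWindow], test_fraction: float, seed: int
) -> SplitPlan:
    """Randomly partition *patients* (every window follows its patient)."""
    if not 0 < test_fraction < 1:
        raise SplitError("test_fraction must be in (0, 1)")
    patients = sorted({w.patient_id for w in windows})
    if len(patients) < 2:
        raise SplitError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    n_test = int(round(len(patients) * test_fraction))
    n_test = min(max(n_test, 1), len(patients) - 1)
    test = frozenset(patients[i] for i in perm[:n_test])
    train = frozenset(patients[i] for i in perm[n_test:])
    return SplitPlan(train_patients=train, test_patients=test, seed=seed)


def oversample_positives(
    windows: Sequence[DailyWindow], seed: int
) -> list[DailyWindow]:
    """Duplicate positive windows until the classes are balanced.

    Each positive is replicated whole ``negatives // positives`` times; the
    remainder is assigned to positives chosen at random without
    replacement. The output order is a seeded shuffle.
    """
    pos = [w for w in windows if w.label == 1]
    neg = [w for w in windows if w.label == 0]
    if not pos or not neg:
        raise BalancingError("need at least one window of each class")
    if len(pos) > len(neg):
        raise BalancingError("positives already outnumber negatives")
    rng = np.random.default_rng(seed)
    base, rem = divmod(len(neg), len(pos))
    extra = set(rng.choice(len(pos), size=rem, replace=False).tolist())
    out: list[DailyWindow] = list(neg)
    for i, w in enumerate(pos):
        out.extend([w] * (base + (1 if i in extra else 0)))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def fold_seed(master_seed: int, fold: int) -> int:
    """Documented per-fold seed derivation (fixed affine counter scheme)."""
    return (master_seed * 1_000_003 + fold) % (2**31)


def monte_carlo_folds(
    windows: Sequence[DailyWindow],
    k: int = 10,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> list[SplitPlan]:
    """``k`` independent patient-level splits (repeated random subsampling,
    not a partition): the same patient may land in several folds' test
    sets. Fold seeds derive from the master seed via :func:`fold_seed`."""
    if k < 1:
        raise SplitError("k must be >= 1")
    return [
        split_by_patient(windows, 1.0 - train_fraction, fold_seed(seed, i))
        for i in range(k)
    ]


# ---------------------------------------------------------------------------
# wide-format CSV interface (one row per window, blank = missing)


def write_windows(
    windows: Sequence[DailyWindow], path: str | Path
) -> pd.DataFrame:
    variables = sorted({v for w in windows for v in w.evidence})
    rows = [
        {
            "patient_id": w.patient_id,
            "admission_id": w.admission_id,
            "window_index": w.window_index,
            "start_day": w.start_day,
            "label": w.label,
            **{v: w.evidence.get(v, "") for v in variables},
        }
        for w in windows
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def read_windows(path: str | Path) -> list[DailyWindow]:
    frame = pd.read_csv(path, float_precision="round_trip")
    meta = ["patient_id", "admission_id", "window_index", "start_day", "label"]
    variables = [c for c in frame.columns if c not in meta]
    out = []
    for r in frame.itertuples(index=False):
        d = r._asdict()
        out.append(
            DailyWindow(
                patient_id=int(d["patient_id"]),
                admission_id=int(d["admission_id"]),
                window_index=int(d["window_index"]),
                start_day=float(d["start_day"]),
                label=int(d["label"]),
                evidence={
                    v: str(d[v]) for v in variables
                    if not pd.isna(d[v]) and d[v] != ""
                },
            )
        )
    return out
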