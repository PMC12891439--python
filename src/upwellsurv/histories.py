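"""Capture records, encounter histories, and the m-array sufficient statistic.

A capture record is one sighting of one tagged animal.  Records for a
(site, species) cell are collapsed onto the monthly occasion calendar to
give an encounter-history matrix ``y`` (individuals x occasions, 0/1) with
a 1-based first-capture index per individual — the standard input of the
Cormack-Jolly-Seber model.  The m-array tabulates releases by occasion of
first recapture and is the sufficient statistic for time-structured CJS
likelihoods; it is used both as a fast likelihood path and as an
equivalence oracle for the per-history likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from .calendars import SITES, SPECIES, OccasionCalendar

__all__ = [
    "CaptureRecord",
    "EncounterHistories",
    "MArray",
    "read_records",
    "build_histories",
    "restrict_window",
    "m_array",
    "capture_summary",
]

RECORD_COLUMNS = [
    "tag_id",
    "species",
    "site",
    "date",
    "length_mm",
    "buoyant_weight_mg",
    "smr_mgO2_per_h_per_g",
    "heart_rate_bpm",
]

_OPTIONAL_MEASUREMENTS = RECORD_COLUMNS[4:]


@dataclass(frozen=True)
class CaptureRecord:
    """One field sighting of a tagged individual.

    Optional measurements (length, buoyant weight, standard metabolic rate,
    heart rate) were taken in the laboratory after capture and may be
    missing; when present they must be strictly positive.
    """

    tag_id: str
    species: str
    site: str
    date: _date
    length_mm: float | None = None
    buoyant_weight_mg: float | None = None
    smr_mgO2_per_h_per_g: float | None = None
    heart_rate_bpm: float | None = None

    def __post_init__(self) -> None:
        if not str(self.tag_id):
            raise ValueError("tag_id must be non-empty")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        for name in _OPTIONAL_MEASUREMENTS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


def read_records(path) -> list[CaptureRecord]:
    """Read capture records from CSV (schema: ``RECORD_COLUMNS``; '' = missing)."""
    df = pd.read_csv(path, dtype={"tag_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            d = pd.Timestamp(row.date)
            if pd.isna(d):
                raise ValueError("missing date")
            opt = {
                name: (None if pd.isna(getattr(row, name)) else float(getattr(row, name)))
                for name in _OPTIONAL_MEASUREMENTS
            }
            records.append(
                CaptureRecord(
                    tag_id=str(row.tag_id),
                    species=str(row.species).lower(),
                    site=str(row.site).lower(),
                    date=d.date(),
                    **opt,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid record at line {i} of {path}: {exc}") from exc
    return records


@dataclass
class EncounterHistories:
    """Binary detection matrix for one (site, species) cell.

    Attributes
    ----------
    y
        (n, T) 0/1 matrix; ``y[i, t]`` is detection of individual ``i`` at
        occasion ``t+1`` (storage is 0-based, the contract is 1-based).
    first
        1-based occasion of first capture, length n.
    searched
        Boolean length-T effort mask; ``y`` is identically zero in
        unsearched months.
    covariates
        Per-individual measurements taken at first capture (may have NaN).
    """

    y: np.ndarray
    first: np.ndarray
    tag_ids: list[str]
    site: str
    species: str
    searched: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.first = np.asarray(self.first, dtype=int)
        self.searched = np.asarray(self.searched, dtype=bool)
        n, T = self.y.shape
        if n < 1 or T < 2:
            raise ValueError("need n >= 1 individuals and T >= 2 occasions")
        if self.first.shape != (n,):
            raise ValueError("first has wrong length")
        if self.searched.shape != (T,):
            raise ValueError("searched has wrong length")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("y must be binary")
        cols = np.arange(1, T + 1)
        if not (self.y[np.arange(n), self.first - 1] == 1).all():
            raise ValueError("y[i, first[i]] must be 1")
        if (self.y * (cols[None, :] < self.first[:, None])).any():
            raise ValueError("detections before first capture")
        if self.y[:, ~self.searched].any():
            raise ValueError("detection in unsearched month")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        T = self.n_occasions
        df = pd.DataFrame(self.y, columns=[f"h{t}" for t in range(1, T + 1)])
        df.insert(0, "first", self.first)
        df.insert(0, "tag_id", self.tag_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_inp(self, path) -> None:
        """Write MARK-style .inp: one '0101...0 1;' line per individual."""
        with open(path, "w") as fh:
            for row in self.y:
                fh.write("".join(str(int(v)) for v in row) + " 1;\n")


def build_histories(
    records: list[CaptureRecord],
    calendar: OccasionCalendar,
    site: str,
    species: str,
) -> EncounterHistories:
    """Collapse capture records onto the calendar for one (site, species) cell.

    Each tag becomes one row; multiple records within a calendar month give
    a single detection; covariates are taken from the record at first
    capture.  A record dated in a month flagged unsearched signals a
    calendar/effort mismatch and raises.
    """
    searched = calendar.searched_for(site, species)
    T = calendar.n_occasions
    per_tag: dict[str, list[tuple[int, CaptureRecord]]] = {}
    for rec in records:
        if rec.site != site or rec.species != species:
            raise ValueError(
                f"record {rec.tag_id} is ({rec.site}, {rec.species}), "
                f"expected ({site}, {species})"
            )
        t = calendar.occasion_of(rec.date)  # raises outside calendar
        if not searched[t - 1]:
            raise ValueError(
                f"detection in unsearched month: tag {rec.tag_id} on {rec.date} "
                f"(occasion {t}) — calendar/effort mismatch"
            )
        per_tag.setdefault(rec.tag_id, []).append((t, rec))
    if not per_tag:
        raise ValueError("no records")
    tag_ids = sorted(per_tag)
    n = len(tag_ids)
    y = np.zeros((n, T), dtype=np.int8)
    first = np.zeros(n, dtype=int)
    cov_rows = []
    for i, tag in enumerate(tag_ids):
        events = sorted(per_tag[tag], key=lambda e: e[0])
        for t, _ in events:
            y[i, t - 1] = 1
        first[i] = events[0][0]
        rec0 = events[0][1]
        cov_rows.append(
            {name: getattr(rec0, name) for name in _OPTIONAL_MEASUREMENTS}
        )
    covariates = pd.DataFrame(cov_rows, index=tag_ids, dtype=float)
    return EncounterHistories(
        y=y, first=first, tag_ids=tag_ids, site=site, species=species,
        searched=searched, covariates=covariates,
    )


def restrict_window(
    histories: EncounterHistories, start_occasion: int, width: int = 6
) -> EncounterHistories:
    """Keep occasions [start, start+width-1]; drop individuals first captured
    outside the window; re-index ``first`` to the new grid.

    Used to fit covariate models over a short span during which body size
    and physiological state can be treated as constant.
    """
    T = histories.n_occasions
    if start_occasion < 1 or start_occasion + width - 1 > T:
        raise ValueError(
            f"window [{start_occasion}, {start_occasion + width - 1}] exceeds "
            f"calendar of {T} occasions"
        )
    sl = slice(start_occasion - 1, start_occasion - 1 + width)
    keep = (histories.first >= start_occasion) & (
        histories.first <= start_occasion + width - 1
    )
    if not keep.any():
        raise ValueError("no individual first captured inside the window")
    y = histories.y[keep][:, sl]
    first = histories.first[keep] - (start_occasion - 1)
    tags = [t for t, k in zip(histories.tag_ids, keep) if k]
    return EncounterHistories(
        y=y, first=first, tag_ids=tags, site=histories.site,
        species=histories.species, searched=histories.searched[sl],
        covariates=histories.covariates.loc[tags],
    )


@dataclass
class MArray:
    """Reduced m-array: releases by occasion of first recapture.

    ``released[i]`` counts detections at occasion i+1 (0-based storage,
    occasions 1..T-1); ``recaptured[i, j]`` counts animals released at
    occasion i+1 first recaptured at occasion j+1; ``never_seen`` is the
    balance.  A detection at the final occasion is terminal — it is not a
    release and contributes a likelihood factor of 1.
    """

    released: np.ndarray
    recaptured: np.ndarray
    never_seen: np.ndarray

    def __post_init__(self) -> None:
        self.released = np.asarray(self.released, dtype=int)
        self.recaptured = np.asarray(self.recaptured, dtype=int)
        self.never_seen = np.asarray(self.never_seen, dtype=int)
        Tm1 = self.released.shape[0]
        if self.recaptured.shape != (Tm1, Tm1):
            raise ValueError("recaptured must be (T-1, T-1)")
        # storage column j holds recaptures at occasion j+2, so entries are
        # confined to the diagonal and above
        if np.tril(self.recaptured, k=-1).any():
            raise ValueError("recapture cannot precede release")
        if (self.released != self.recaptured.sum(axis=1) + self.never_seen).any():
            raise ValueError("row sums do not balance")

    @property
    def n_occasions(self) -> int:
        return self.released.shape[0] + 1


def m_array(histories: EncounterHistories) -> MArray:
    """Tabulate the m-array of an encounter-history set.

    Every detection at occasion i < T is a release attributed to the next
    recapture occasion j (``recaptured[i, j]``) or to ``never_seen[i]``.
    """
    T = histories.n_occasions
    released = np.zeros(T - 1, dtype=int)
    recaptured = np.zeros((T - 1, T - 1), dtype=int)
    never = np.zeros(T - 1, dtype=int)
    for row in histories.y:
        det = np.flatnonzero(row)  # 0-based occasions
        for a, b in zip(det, det[1:]):
            released[a] += 1
            recaptured[a, b - 1] += 1  # column b-1 holds recaptures at occasion b
        last = det[-1]
        if last < T - 1:  # a release at the final occasion carries no information
            released[last] += 1
            never[last] += 1
    return MArray(released=released, recaptured=recaptured, never_seen=never)


def capture_summary(calendar: OccasionCalendar) -> pd.DataFrame:
    """Per-cell capture accounting from an effort-attached calendar.

    Returns one row per (site, species) with total captures, number of
    sampling events, and median captures per event, plus per-species,
    per-site and grand totals (rows labelled ``total``).
    """
    if not calendar.counts:
        raise ValueError("calendar has no effort counts attached")
    rows = []
    for (site, sp), arr in calendar.counts.items():
        vals = arr[~np.isnan(arr)]
        rows.append(
            {
                "site": site,
                "species": sp,
                "total_captures": int(vals.sum()),
                "n_events": int(len(vals)),
                "median_per_event": float(np.median(vals)),
            }
        )
    df = pd.DataFrame(rows)
    totals = []
    for sp, g in df.groupby("species"):
        totals.append({"site": "total", "species": sp,
                       "total_captures": int(g.total_captures.sum())})
    for site, g in df.groupby("site"):
        totals.append({"site": site, "species": "total",
                       "total_captures": int(g.total_captures.sum())})
    totals.append({"site": "total", "species": "total",
                   "total_captures": int(df.total_captures.sum())})
    return pd.concat([df, pd.DataFrame(totals)], ignore_index=True)
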