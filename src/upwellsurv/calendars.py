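"""Monthly occasion calendars with site/species-specific search effort.

Capture-mark-recapture sampling in this study is organised on a grid of
consecutive calendar months ("occasions").  Field searches did not happen
every month at every site for every species; months without a search carry
no detection information, and downstream the detection probability for
those occasions is pinned to zero.  The :class:`OccasionCalendar` holds the
month grid together with a boolean "searched" vector per (site, species)
cell, plus the raw capture counts when effort has been attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "SPECIES",
    "OccasionCalendar",
    "build_calendar",
    "attach_effort",
]

SITES = ("talcaruca", "quintay")
SPECIES = ("chiton_granosus", "scurria_zebrina")


def _validate_site_species(site: str, species: str) -> tuple[str, str]:
    site = str(site).lower()
    species = str(species).lower()
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    return site, species


@dataclass
class OccasionCalendar:
    """Ordered grid of monthly occasions plus per-cell search effort.

    Parameters
    ----------
    months
        Ordered list of ``(year, month)`` pairs, consecutive with no gaps.
    searched
        Map from ``(site, species)`` to a boolean array of length ``len(months)``;
        ``True`` where a field search took place.
    counts
        Map from ``(site, species)`` to a float array of capture counts, with
        ``nan`` in unsearched months.  Present once effort is attached.
    """

    months: list[tuple[int, int]]
    searched: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.months) < 1:
            raise ValueError("calendar must contain at least one month")
        for (y0, m0), (y1, m1) in zip(self.months, self.months[1:]):
            if (y1 * 12 + m1) - (y0 * 12 + m0) != 1:
                raise ValueError("months must be strictly increasing with no gaps")
        for key, vec in self.searched.items():
            vec = np.asarray(vec, dtype=bool)
            if vec.shape != (len(self.months),):
                raise ValueError(f"searched vector for {key} has wrong length")
            if not vec.any():
                raise ValueError(f"no searched occasion for {key}")
            self.searched[key] = vec

    @property
    def n_occasions(self) -> int:
        return len(self.months)

    def occasion_of(self, date) -> int:
        """1-based occasion index of the month containing ``date``.

        Raises ``ValueError`` for dates outside the calendar.
        """
        ts = pd.Timestamp(date)
        try:
            return self.months.index((ts.year, ts.month)) + 1
        except ValueError:
            raise ValueError(
                f"date {ts.date()} falls outside the calendar "
                f"({self.months[0]} .. {self.months[-1]})"
            ) from None

    def searched_for(self, site: str, species: str) -> np.ndarray:
        key = _validate_site_species(site, species)
        if key not in self.searched:
            raise KeyError(f"no effort attached for {key}")
        return self.searched[key]

    def month_labels(self) -> list[str]:
        return [f"{y:04d}-{m:02d}" for y, m in self.months]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: year, month, site, species, searched, count."""
        rows = []
        for (site, species), vec in self.searched.items():
            cnt = self.counts.get((site, species))
            for t, (y, m) in enumerate(self.months):
                rows.append(
                    {
                        "year": y,
                        "month": m,
                        "site": site,
                        "species": species,
                        "searched": int(vec[t]),
                        "count": (np.nan if cnt is None else cnt[t]),
                    }
                )
        return pd.DataFrame(rows)


def build_calendar(start: tuple[int, int], end: tuple[int, int]) -> OccasionCalendar:
    """Consecutive monthly occasions from ``start`` to ``end`` inclusive.

    Searched flags are initialised all-true for every (site, species) cell;
    use :func:`attach_effort` to mark unsearched months.
    """
    y0, m0 = start
    y1, m1 = end
    if not (1 <= m0 <= 12 and 1 <= m1 <= 12):
        raise ValueError("month must be in 1..12")
    a, b = y0 * 12 + (m0 - 1), y1 * 12 + (m1 - 1)
    if b < a:
        raise ValueError(f"end {end} precedes start {start}")
    months = [(k // 12, k % 12 + 1) for k in range(a, b + 1)]
    searched = {
        (site, sp): np.ones(len(months), dtype=bool) for site in SITES for sp in SPECIES
    }
    return OccasionCalendar(months=months, searched=searched)


def attach_effort(
    calendar: OccasionCalendar,
    counts: dict[tuple[str, str], list],
) -> OccasionCalendar:
    """Attach per-cell capture counts; ``None``/NaN entries mean "no search".

    Returns a new calendar whose ``searched`` flags are True exactly where a
    count is present, with the counts retained for capture summaries.
    """
    T = calendar.n_occasions
    new_searched: dict[tuple[str, str], np.ndarray] = dict(calendar.searched)
    new_counts: dict[tuple[str, str], np.ndarray] = dict(calendar.counts)
    for key, vec in counts.items():
        key = _validate_site_species(*key)
        if len(vec) != T:
            raise ValueError(
                f"effort vector for {key} has length {len(vec)}, expected {T}"
            )
        arr = np.array(
            [np.nan if v is None else float(v) for v in vec], dtype=float
        )
        present = ~np.isnan(arr)
        if (arr[present] < 0).any():
            raise ValueError(f"negative capture count for {key}")
        if not present.any():
            raise ValueError(f"no searched occasion for {key}")
        new_searched[key] = present
        new_counts[key] = arr
    return OccasionCalendar(
        months=list(calendar.months), searched=new_searched, counts=new_counts
    )
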