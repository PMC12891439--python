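"""In-study field data: the monthly capture calendar and water-chemistry means.

The capture calendar records, for each (site, species) cell, the number of
individuals captured in each of the 26 monthly occasions from November 2019
to December 2021; ``None`` marks a month in which no search was performed.
Totals per cell are 233 and 303 for Chiton granosus at Talcaruca and
Quintay, and 59 and 188 for Scurria zebrina (grand total 783).

Water-chemistry entries are the site-level means of the discrete-sample
campaign (pH on the total scale, total alkalinity in umol/kg, SST in deg C,
salinity in psu) and are convenient inputs for the carbonate-system solver.
"""

from __future__ import annotations

from .calendars import OccasionCalendar, attach_effort, build_calendar

__all__ = [
    "STUDY_START",
    "STUDY_END",
    "CAPTURE_COUNTS",
    "WATER_MEANS",
    "study_calendar",
]

STUDY_START = (2019, 11)
STUDY_END = (2021, 12)

# Monthly capture counts, Nov 2019 .. Dec 2021 (26 entries per cell).
# None = no search that month.
_ = None
CAPTURE_COUNTS: dict[tuple[str, str], list] = {
    ("talcaruca", "chiton_granosus"): [
        42, 16, 21, _, _, _, _, _, _, _, _, _, _, 27, 35, _, _, _, 25, 4, 21, _, _, 13, 29, _,
    ],
    ("talcaruca", "scurria_zebrina"): [
        13, _, 24, _, _, _, _, _, _, _, _, _, _, 12, 5, _, _, _, _, 2, 3, _, _, _, _, _,
    ],
    ("quintay", "chiton_granosus"): [
        37, 28, 20, _, 31, _, 12, _, _, _, _, _, _, 21, 27, _, 27, _, 28, 12, 36, 10, _, 14, _, _,
    ],
    ("quintay", "scurria_zebrina"): [
        11, 29, 16, _, 20, _, 22, _, _, _, _, _, _, 19, 27, _, 10, _, 3, 17, 12, 2, _, _, _, _,
    ],
}
del _

# Site-mean water chemistry: pH (total scale), TA (umol/kg), SST (C), salinity (psu).
WATER_MEANS: dict[str, dict[str, float]] = {
    "talcaruca": {"ph_total": 8.04, "ta_umol_kg": 2273.8, "temperature_c": 13.20, "salinity_psu": 33.53},
    "quintay": {"ph_total": 7.99, "ta_umol_kg": 2171.92, "temperature_c": 13.04, "salinity_psu": 33.34},
}


def study_calendar() -> OccasionCalendar:
    """The 26-month study calendar with the field capture effort attached."""
    cal = build_calendar(STUDY_START, STUDY_END)
    return attach_effort(cal, CAPTURE_COUNTS)
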