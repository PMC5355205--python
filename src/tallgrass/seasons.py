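"""Growing-season calendar arithmetic.

The study season runs 1 April – 30 September; forage surfaces are projected
on strict 14-day blocks anchored at 1 April ("biweekly periods"), the last
block truncated at 1 October. A timestamp is assigned to the block
containing it.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

PERIOD_DAYS = 14


def season_start(year: int) -> dt.date:
    return dt.date(year, 4, 1)


def season_end(year: int) -> dt.date:
    """First day past the season (1 October)."""
    return dt.date(year, 10, 1)


def biweekly_periods(year: int) -> list[dt.date]:
    """Start dates of the biweekly blocks covering 1 Apr – 1 Oct."""
    start, end = season_start(year), season_end(year)
    out = []
    d = start
    while d < end:
        out.append(d)
        d += dt.timedelta(days=PERIOD_DAYS)
    return out

def period_of(when: dt.date | dt.datetime) -> int:
    """Index of the biweekly block containing ``when`` (0-based).

    Raises ValueError outside the 1 Apr – 1 Oct window.
    """
    d = when.date() if isinstance(when, dt.datetime) else when
    start, end = season_start(d.year), season_end(d.year)
    if not (start <= d < end):
        raise ValueError(f"{d} outside the 1 Apr - 1 Oct season window")
    return (d - start).days // PERIOD_DAYS


def julian_terms(when: dt.date | dt.datetime) -> tuple[float, float]:
    """(sin, cos) of day-of-year rescaled to 0-2π radians (day/365 × 2π)."""
    d = when.date() if isinstance(when, dt.datetime) else when
    ang = d.timetuple().tm_yday / 365.0 * 2.0 * np.pi
    return float(np.sin(ang)), float(np.cos(ang))
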