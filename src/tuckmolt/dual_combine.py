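"""Fusion of corrected immersion series from two loggers on one bird.

If either leg's logger reads wet, the bird was on the water: a dry reading on
the other leg at the same instant is leg tucking that the light-based
correction missed.  Fusion therefore keeps, per fix interval, the *higher*
wet proportion of the two loggers.  Because the paired loggers may differ in
resolution and phase, series are merged to the nearest timestamp, with the
finer-interval series as the base, and the result depends (slightly) on which
logger serves as the base — so both directions are run and reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo_io import ImmersionSeries

logger = logging.getLogger(__name__)


def align_pair(base: ImmersionSeries, other: ImmersionSeries) -> pd.DataFrame:
    """Nearest-timestamp pairing of two immersion series.

    Returns a frame indexed by the base timestamps with columns ``p_base`` and
    ``p_other`` (wet proportions); ``p_other`` is NaN where the nearest record
    of the other series lies beyond half the other's fix interval (gaps must
    not be bridged by stale values).  Ties go to the earlier record.
    """
    bt = base.times.asi8
    ot = other.times.asi8
    if len(bt) == 0 or len(ot) == 0:
        raise ValueError("cannot align an empty series")
    if bt[-1] + base.fix_interval * 60e9 < ot[0] or ot[-1] + other.fix_interval * 60e9 < bt[0]:
        raise ValueError("no temporal overlap between the two series")
    pos = np.searchsorted(ot, bt)
    left = np.clip(pos - 1, 0, len(ot) - 1)
    right = np.clip(pos, 0, len(ot) - 1)
    dl = np.abs(bt - ot[left])
    dr = np.abs(ot[right] - bt)
    take_left = dl <= dr           # tie -> earlier record
    nearest = np.where(take_left, left, right)
    dist = np.where(take_left, dl, dr)
    tol = other.fix_interval * 60e9 / 2.0
    p_other = other.wet_proportion[nearest]
    p_other = np.where(dist <= tol, p_other, np.nan)
    return pd.DataFrame({"p_base": base.wet_proportion, "p_other": p_other},
                        index=base.times)


def combine_max_wet(paired: pd.DataFrame, template: ImmersionSeries) -> ImmersionSeries:
    """Retain the higher wet proportion per record (base value where partner absent)."""
    p = np.fmax(paired["p_base"].to_numpy(), paired["p_other"].to_numpy())
    # round away float noise from the proportion round-trip (count/scale*scale)
    data = pd.DataFrame({"wet_count": np.round(p * template.scale_max, 9)},
                        index=paired.index)
    return ImmersionSeries(logger_id=f"{template.logger_id}+combined", leg="unknown",
                           data=data, fix_interval=template.fix_interval,
                           scale_max=template.scale_max)


def combine_pair(base: ImmersionSeries, other: ImmersionSeries) -> ImmersionSeries:
    """Align then combine, with ``base`` as the merge basis."""
    return combine_max_wet(align_pair(base, other), base)


def combine_both_directions(left: ImmersionSeries, right: ImmersionSeries) -> dict[str, ImmersionSeries]:
    """Run the fusion with each logger as the base.

    The finer-resolution logger is the natural base; both directions are
    returned so downstream molt detection can report per-bird date/duration
    ranges across the two bases.
    """
    return {
        "left": combine_pair(left, right),
        "right": combine_pair(right, left),
    }
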