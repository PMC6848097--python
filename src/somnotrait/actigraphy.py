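"""Per-subject actigraphy summaries: means and night-to-night ISDs.

Each retained subject contributes 14 variables: the mean and the
intraindividual standard deviation (ISD, sample SD across the subject's
nights) of seven parameters -- sleep-onset latency, sleep-onset time,
sleep-offset time, sleep duration, number of awakenings (NWAK), wake
after sleep onset (WASO), and sleep efficiency (duration divided by
time in bed, where time in bed = latency + duration + WASO).

Clock times wrap midnight, so onset/offset times are linearized as
minutes elapsed since a 12:00 reference before any aggregation: typical
evening onsets and morning offsets are then each continuous on the
linear axis.  This is a linear (not circular) treatment and is
documented as a limitation for free-running rhythms.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientNightsError, InvalidRecordError

logger = logging.getLogger(__name__)

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})$")

#: summary panel order (Table-1 order): mean block then ISD block
PARAMS = (
    "sleep_onset_latency",
    "sleep_onset_time",
    "sleep_offset_time",
    "sleep_duration",
    "nwak",
    "waso",
    "sleep_efficiency",
)

ACTIGRAPHY_VARIABLES = tuple(f"mean_{p}" for p in PARAMS) + tuple(f"isd_{p}" for p in PARAMS)


def parse_clock(t: str) -> int:
    """Parse an ``HH:MM`` 24 h clock string to minutes after midnight."""
    m = _CLOCK_RE.match(str(t).strip())
    if not m:
        raise DataError(f"malformed clock time: {t!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh >= 24 or mm >= 60:
        raise DataError(f"clock time out of range: {t!r}")
    return hh * 60 + mm


def linearize_clock_time(t, reference: str = "12:00"):
    """Minutes elapsed from ``reference`` to ``t``, in [0, 1440).

    With the default noon reference, evening sleep onsets and morning
    offsets each map to a contiguous stretch of the linear axis even
    when they straddle midnight.
    """
    ref = parse_clock(reference)
    if np.ndim(t) == 0:
        return (parse_clock(t) - ref) % 1440
    vals = np.array([parse_clock(x) for x in np.asarray(t).ravel()])
    return (vals - ref) % 1440


def sleep_efficiency(sleep_duration, sleep_onset_latency, waso):
    """Nightly sleep efficiency: duration / (latency + duration + WASO)."""
    duration = np.asarray(sleep_duration, dtype=float)
    tib = duration + np.asarray(sleep_onset_latency, dtype=float) + np.asarray(waso, dtype=float)
    if np.any(tib <= 0):
        raise InvalidRecordError("time in bed must be positive")
    return duration / tib


def isd(values) -> float:
    """Intraindividual standard deviation: sample SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientNightsError(f"ISD requires >= 2 nights, got {v.size}")
    return float(np.std(v, ddof=1))


def _night_matrix(nights: pd.DataFrame) -> pd.DataFrame:
    """Attach linearized times and nightly efficiency to a nights table."""
    df = nights.copy()
    df["sleep_onset_time"] = linearize_clock_time(nights["sleep_onset_time"].to_numpy())
    df["sleep_offset_time"] = linearize_clock_time(nights["sleep_offset_time"].to_numpy())
    df["sleep_efficiency"] = sleep_efficiency(
        df["sleep_duration"], df["sleep_onset_latency"], df["waso"]
    )
    return df


def summarize_subject(nights: pd.DataFrame, min_nights: int = 5):
    """Summary row for one subject's nights, or ``None`` if excluded.

    Subjects with fewer than ``min_nights`` recorded nights yield no
    summary.  Onset/offset clock times are linearized before
    aggregation; efficiency is computed per night and then aggregated.
    """
    ids = nights["subject_id"].unique()
    if len(ids) != 1:
        raise DataError(f"summarize_subject received {len(ids)} subject ids")
    if len(nights) < min_nights:
        return None
    df = _night_matrix(nights)
    row = {"subject_id": ids[0], "n_nights": len(df)}
    for p in PARAMS:
        v = df[p].to_numpy(dtype=float)
        row[f"mean_{p}"] = float(np.mean(v))
        row[f"isd_{p}"] = isd(v)
    return row


def summarize_cohort(nights: pd.DataFrame, min_nights: int = 5) -> pd.DataFrame:
    """Per-subject summary table; drops subjects under ``min_nights``.

    Exclusions are logged, never imputed.
    """
    df = _night_matrix(nights)
    counts = df.groupby("subject_id", sort=False)["night_index"].size()
    keep = counts[counts >= min_nights].index
    dropped = len(counts) - len(keep)
    if dropped:
        logger.info("excluding %d subjects with < %d nights", dropped, min_nights)
    df = df[df["subject_id"].isin(keep)]

    g = df.groupby("subject_id", sort=False)
    out = pd.DataFrame({"subject_id": counts.loc[keep].index, "n_nights": counts.loc[keep].to_numpy()})
    out = out.set_index("subject_id")
    for p in PARAMS:
        out[f"mean_{p}"] = g[p].mean()
        out[f"isd_{p}"] = g[p].std(ddof=1)
    return out.reset_index()
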