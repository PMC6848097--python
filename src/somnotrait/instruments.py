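"""Questionnaire scoring: HPS sum-scores and PSQI components.

The 44-item hypomanic personality scale (HPS) is scored as a keyed sum
on the hypomanic pole (reverse-keyed items count non-endorsement), and
as three unweighted subscale sums -- hypomanic core, social vitality,
ordinariness -- each summed on the subscale's *own* pole, so that
subscale scores keep the sign convention of the factor scores (the
ordinariness subscale measures ordinariness, not its reverse).

The PSQI is scored into seven 0-3 components and a 0-21 total via
cut-points shipped in an editable config file
(:data:`DEFAULT_PSQI_TABLE`), plus the single-item variables used in
the association panel (reported latency, bedtime, get-up time,
duration, habitual efficiency, daytime sleepiness).  Higher PSQI scores
mean worse sleep quality.

Missing-data policy is exclusion with a log entry, never imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
import yaml

from .actigraphy import linearize_clock_time
from .config import CohortConfig
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

DEFAULT_PSQI_TABLE = files("somnotrait.data") / "psqi_scoring.yaml"

#: PSQI-derived variables of the association panel, Table-1 order
PSQI_VARIABLES = (
    "psqi_latency",
    "psqi_bedtime",
    "psqi_getup_time",
    "psqi_duration",
    "psqi_efficiency",
    "psqi_sleepiness",
    "psqi_total",
)

_DISTURB_ITEMS = [f"disturb_{j}" for j in range(1, 10)]
_REQUIRED_PSQI = (
    ["bedtime", "latency_min", "getup_time", "duration_h", "freq_latency", "quality"]
    + _DISTURB_ITEMS
    + ["medication", "sleepiness", "enthusiasm"]
)


# ---------------------------------------------------------------------------
# scoring key
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyEntry:
    direction: int          # +1 / -1 w.r.t. the hypomanic pole (total score)
    subscale: str | None    # core / vitality / ordinariness / None


@dataclass(frozen=True)
class ScoringKey:
    """Item keying: direction for the total, and subscale assignment."""

    entries: dict[str, KeyEntry]

    def __post_init__(self):
        for item, e in self.entries.items():
            if e.direction not in (+1, -1):
                raise ConfigurationError(f"item {item}: direction must be +1 or -1")
            if e.subscale not in (None, "core", "vitality", "ordinariness"):
                raise ConfigurationError(f"item {item}: unknown subscale {e.subscale!r}")

    @property
    def items(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_config(cls, config: CohortConfig) -> "ScoringKey":
        return cls(
            {
                it.item: KeyEntry(direction=+1 if it.keyed_positive else -1, subscale=it.factor)
                for it in config.items
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "direction": [self.entries[i].direction for i in self.items],
                "subscale": [self.entries[i].subscale or "none" for i in self.items],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoringKey":
        return cls(
            {
                r.item: KeyEntry(
                    direction=int(r.direction),
                    subscale=None if r.subscale in ("none", None) else r.subscale,
                )
                for r in df.itertuples()
            }
        )


def _keyed(responses: pd.DataFrame, key: ScoringKey) -> tuple[pd.DataFrame, np.ndarray]:
    """Complete-case response matrix in key order, plus kept-row mask."""
    missing_cols = [i for i in key.items if i not in responses.columns]
    if missing_cols:
        raise DataError(f"item columns absent from responses: {missing_cols}")
    X = responses[key.items]
    complete = X.notna().all(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("excluding %d subjects with incomplete item responses", n_excluded)
    X = X[complete]
    vals = X.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise DataError("item responses must be binary (0/1) or missing")
    return X, complete


def score_hps_total(responses: pd.DataFrame, key: ScoringKey) -> pd.DataFrame:
    """Keyed HPS total (0..44); incomplete subjects are excluded."""
    X, complete = _keyed(responses, key)
    vals = X.to_numpy(dtype=float)
    d = np.array([key.entries[i].direction for i in key.items])
    keyed = np.where(d > 0, vals, 1.0 - vals)
    return pd.DataFrame(
        {
            "subject_id": responses.loc[complete, "subject_id"].to_numpy(),
            "hps_total": keyed.sum(axis=1).astype(int),
        }
    )


def score_hps_subscales_sum(responses: pd.DataFrame, key: ScoringKey) -> pd.DataFrame:
    """Unweighted subscale sums, each on the subscale's own pole.

    For the default key every item is keyed positively on its own
    subscale; items assigned to no subscale contribute to none.
    """
    X, complete = _keyed(responses, key)
    vals = X.to_numpy(dtype=float)
    out = {"subject_id": responses.loc[complete, "subject_id"].to_numpy()}
    for sub in ("core", "vitality", "ordinariness"):
        cols = [j for j, i in enumerate(key.items) if key.entries[i].subscale == sub]
        out[f"sum_{sub}"] = vals[:, cols].sum(axis=1).astype(int) if cols else 0
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# PSQI
# ---------------------------------------------------------------------------

def load_psqi_table(path=None) -> dict:
    src = DEFAULT_PSQI_TABLE if path is None else path
    with open(str(src)) as fh:
        table = yaml.safe_load(fh)
    required = {
        "latency_minutes_bands",
        "latency_sum_bands",
        "duration_hours_bands",
        "efficiency_bands",
        "disturbance_sum_bands",
        "dysfunction_sum_bands",
    }
    missing = required - set(table)
    if missing:
        raise ConfigurationError(f"PSQI scoring table missing keys: {sorted(missing)}")
    return table


def _band_leq(x: np.ndarray, bounds) -> np.ndarray:
    """0..3 by increasing upper bounds: x <= bounds[i] -> i."""
    return np.searchsorted(np.asarray(bounds, dtype=float), x, side="left").astype(int)


def _band_geq(x: np.ndarray, bounds) -> np.ndarray:
    """0..3 by decreasing lower bounds: x >= bounds[i] -> i (else 3)."""
    b = np.asarray(bounds, dtype=float)
    out = np.full(x.shape, len(b), dtype=int)
    for i in range(len(b) - 1, -1, -1):
        out[x >= b[i]] = i
    return out


def score_psqi(psqi_items: pd.DataFrame, table: dict | None = None) -> pd.DataFrame:
    """Seven PSQI components, the 0-21 total, and the panel variables.

    Habitual efficiency is reported duration over time in bed, with
    time in bed computed from bedtime and get-up time (linearized
    against the noon reference so the interval spans midnight).
    """
    if table is None:
        table = load_psqi_table()
    complete = psqi_items[_REQUIRED_PSQI].notna().all(axis=1).to_numpy()
    n_excl = int((~complete).sum())
    if n_excl:
        logger.info("excluding %d subjects with incomplete PSQI items", n_excl)
    df = psqi_items[complete].reset_index(drop=True)

    bed = linearize_clock_time(df["bedtime"].to_numpy())
    getup = linearize_clock_time(df["getup_time"].to_numpy())
    tib_min = np.asarray((getup - bed) % 1440, dtype=float)
    if np.any(tib_min <= 0):
        raise DataError("time in bed (bedtime to get-up) must be positive")
    duration_h = df["duration_h"].to_numpy(dtype=float)
    efficiency = duration_h * 60.0 / tib_min

    lat_min = df["latency_min"].to_numpy(dtype=float)
    c1 = df["quality"].to_numpy(dtype=int)
    c2 = _band_leq(
        _band_leq(lat_min, table["latency_minutes_bands"]) + df["freq_latency"].to_numpy(int),
        table["latency_sum_bands"],
    )
    db = np.asarray(table["duration_hours_bands"], dtype=float)  # [7, 6, 5]
    c3 = np.full(len(df), 3, dtype=int)
    c3[duration_h >= db[2]] = 2
    c3[duration_h >= db[1]] = 1
    c3[duration_h > db[0]] = 0
    c4 = _band_geq(efficiency, table["efficiency_bands"])
    c5 = _band_leq(
        df[_DISTURB_ITEMS].to_numpy(int).sum(axis=1), table["disturbance_sum_bands"]
    )
    c6 = df["medication"].to_numpy(dtype=int)
    c7 = _band_leq(
        df["sleepiness"].to_numpy(int) + df["enthusiasm"].to_numpy(int),
        table["dysfunction_sum_bands"],
    )
    comps = np.column_stack([c1, c2, c3, c4, c5, c6, c7])
    if comps.min() < 0 or comps.max() > 3:
        raise DataError("PSQI components out of 0-3 range; check item coding")

    out = pd.DataFrame({"subject_id": df["subject_id"].to_numpy()})
    for i in range(7):
        out[f"psqi_c{i + 1}"] = comps[:, i]
    out["psqi_total"] = comps.sum(axis=1)
    out["psqi_latency"] = lat_min
    out["psqi_bedtime"] = bed
    out["psqi_getup_time"] = getup
    out["psqi_duration"] = duration_h
    out["psqi_efficiency"] = efficiency
    out["psqi_sleepiness"] = df["sleepiness"].to_numpy(dtype=int)
    return out
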