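"""Minute-binned activity streams -> per-fly sleep traits.

A sleep bout is any maximal run of zero-count minutes lasting at least
``min_bout`` minutes (default 5).  Traits are computed separately for the
12-h light (day) and dark (night) phases; bouts spanning the lights
transition are split at the boundary and each segment counts as one bout
in its phase.  Per-phase totals are computed per 24-h day and averaged
over complete days.  Waking activity is beam crossings per minute awake
over the whole record (per-phase available by flag).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
PHASE_MINUTES = 720
TRAITS = [
    "night_sleep", "day_sleep", "night_bout_n", "day_bout_n",
    "night_avg_bout_len", "day_avg_bout_len", "waking_activity",
]


@dataclass
class ActivityStream:
    """One fly's minute-binned beam-crossing counts plus design labels."""

    fly_id: str
    line: str
    sex: str
    block: str
    replicate: str
    counts: np.ndarray
    channel: int = 0
    monitor: str = "M001"
    start_minute_of_day: int = 480
    lights_on_minute: int = 480

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size % MINUTES_PER_DAY != 0:
            raise ValueError("stream length must be a multiple of 1440 minutes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_days(self) -> int:
        return self.counts.size // MINUTES_PER_DAY


@dataclass
class SleepSummary:
    fly_id: str
    line: str
    sex: str
    block: str
    replicate: str
    night_sleep: float
    day_sleep: float
    night_bout_n: float
    day_bout_n: float
    night_avg_bout_len: float
    day_avg_bout_len: float
    waking_activity: float
    n_days_used: int
    dead: bool
    waking_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "fly_id": self.fly_id, "line": self.line, "sex": self.sex,
            "block": self.block, "replicate": self.replicate,
            "night_sleep": self.night_sleep, "day_sleep": self.day_sleep,
            "night_bout_n": self.night_bout_n, "day_bout_n": self.day_bout_n,
            "night_avg_bout_len": self.night_avg_bout_len,
            "day_avg_bout_len": self.day_avg_bout_len,
            "waking_activity": self.waking_activity,
            "n_days_used": self.n_days_used, "dead": self.dead,
            "waking_undefined": self.waking_undefined,
        }


def call_sleep_bouts(counts, min_bout: int = 5):
    """Maximal zero-count runs of length >= min_bout as (start, length) pairs."""
    counts = np.asarray(counts)
    if counts.size == 0:
        return []
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    asleep = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    edges = np.diff(asleep)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    keep = lengths >= min_bout
    return list(zip(starts[keep].tolist(), lengths[keep].tolist()))


def sleep_mask(counts, min_bout: int = 5) -> np.ndarray:
    """Boolean mask of minutes covered by qualifying sleep bouts."""
    mask = np.zeros(len(counts), dtype=bool)
    for start, length in call_sleep_bouts(counts, min_bout):
        mask[start:start + length] = True
    return mask


def detect_dead(stream: ActivityStream, window: int = 1440) -> bool:
    """True iff the final ``window`` minutes contain zero counts."""
    tail = stream.counts[-window:] if window > 0 else stream.counts[:0]
    return bool(np.all(tail == 0))


def _phase_of(aligned_minute: int) -> np.ndarray:
    return (aligned_minute % MINUTES_PER_DAY) < PHASE_MINUTES


def summarize_fly(stream: ActivityStream, min_bout: int = 5,
                  dead_window: int = 1440,
                  per_phase_waking: bool = False):
    """Compute the seven sleep traits for one fly.

    Minutes are re-aligned so each analysis day starts at lights-on; a
    minute is "day" if it falls in the first 720 aligned minutes of its
    day.  Only complete aligned days enter the per-phase averages.
    """
    counts = stream.counts
    offset = (stream.start_minute_of_day - stream.lights_on_minute) % MINUTES_PER_DAY
    aligned = np.arange(counts.size) + offset
    day_idx = aligned // MINUTES_PER_DAY
    is_day = (aligned % MINUTES_PER_DAY) < PHASE_MINUTES

    mask = sleep_mask(counts, min_bout)
    dead = detect_dead(stream, dead_window)

    # complete days only
    complete = np.flatnonzero(np.bincount(day_idx) == MINUTES_PER_DAY)
    n_days = complete.size
    use = np.isin(day_idx, complete)

    totals = {"day": {"sleep": 0, "bouts": 0}, "night": {"sleep": 0, "bouts": 0}}
    for d in complete:
        in_day = day_idx == d
        for phase, sel in (("day", in_day & is_day), ("night", in_day & ~is_day)):
            m = mask[sel]
            totals[phase]["sleep"] += int(m.sum())
            # maximal runs inside the phase window; boundary segments
            # inherit bout status (no re-application of the 5-min rule)
            padded = np.concatenate(([0], m.astype(np.int8), [0]))
            totals[phase]["bouts"] += int(np.sum(np.diff(padded) == 1))

    def _avg(phase):
        sleep = totals[phase]["sleep"]
        bouts = totals[phase]["bouts"]
        if n_days == 0:
            return np.nan, np.nan, np.nan
        return (sleep / n_days, bouts / n_days,
                (sleep / bouts) if bouts > 0 else 0.0)

    night_sleep, night_bout_n, night_avg = _avg("night")
    day_sleep, day_bout_n, day_avg = _avg("day")

    awake = (~mask) & use
    total_awake = int(awake.sum())
    waking_undefined = total_awake == 0
    if per_phase_waking:
        day_awake = awake & is_day
        wa = (counts[day_awake].sum() / day_awake.sum()
              if day_awake.sum() else np.nan)
    else:
        wa = counts[awake].sum() / total_awake if total_awake else np.nan

    return SleepSummary(
        fly_id=stream.fly_id, line=stream.line, sex=stream.sex,
        block=stream.block, replicate=stream.replicate,
        night_sleep=night_sleep, day_sleep=day_sleep,
        night_bout_n=night_bout_n, day_bout_n=day_bout_n,
        night_avg_bout_len=night_avg, day_avg_bout_len=day_avg,
        waking_activity=wa, n_days_used=n_days, dead=dead,
        waking_undefined=waking_undefined,
    )


def summarize_streams(streams, min_bout: int = 5, dead_window: int = 1440,
                      drop_dead: bool = True) -> pd.DataFrame:
    """Per-fly phenotype table from a collection of streams.

    Dead flies (terminal inactivity >= dead_window) are excluded from the
    returned table when drop_dead is set, mirroring the exclusion of flies
    that did not survive the recording period.
    """
    rows = [summarize_fly(s, min_bout=min_bout, dead_window=dead_window).as_dict()
            for s in streams]
    df = pd.DataFrame(rows)
    if drop_dead and len(df):
        n_dead = int(df["dead"].sum())
        if n_dead:
            logger.info("excluding %d dead flies from phenotype table", n_dead)
        df = df[~df["dead"]].reset_index(drop=True)
    return df


def compute_cve(values) -> float:
    """Coefficient of environmental variation: (sample SD / mean) * 100.

    Undefined (NaN) when fewer than two values or the mean is not positive.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return np.nan
    mean = v.mean()
    if mean <= 0:
        return np.nan
    return float(v.std(ddof=1) / mean * 100.0)


def cve_table(phenotypes: pd.DataFrame, traits=None) -> pd.DataFrame:
    """CV_E of each trait per line/sex/replicate (block carried along).

    Cells with n < 2 or non-positive mean yield NaN and are logged.
    """
    traits = list(traits) if traits is not None else [
        t for t in TRAITS if t in phenotypes.columns]
    keys = ["block", "line", "sex", "replicate"]
    records = []
    for key, grp in phenotypes.groupby(keys, observed=True):
        rec = dict(zip(keys, key))
        for t in traits:
            vals = grp[t].dropna()
            cv = compute_cve(vals)
            if not np.isfinite(cv):
                logger.debug("CV_E undefined for %s trait %s (n=%d, mean=%s)",
                             key, t, len(vals),
                             vals.mean() if len(vals) else "NA")
            rec[t] = cv
        records.append(rec)
    return pd.DataFrame(records)


def line_sex_means(phenotypes: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Mean of each trait per line x sex (the GWA unit of observation)."""
    traits = list(traits) if traits is not None else [
        t for t in TRAITS if t in phenotypes.columns]
    out = (phenotypes.groupby(["line", "sex"], observed=True)[traits]
           .mean().reset_index())
    return out


def reconstruct_stream(summary: SleepSummary, lights_on: int = 480,
                       wake_count: int = 1) -> ActivityStream:
    """Build a one-day idealized stream matching a summary's architecture.

    Exact only when bout numbers and lengths are integral and bouts fit in
    their phase with one waking minute between them; used by the
    idempotence property test.
    """
    counts = np.full(MINUTES_PER_DAY, wake_count, dtype=np.int64)

    def _place(start, n_bouts, avg_len):
        n_bouts = int(round(n_bouts))
        avg_len = int(round(avg_len)) if n_bouts else 0
        pos = start + 1
        for _ in range(n_bouts):
            counts[pos:pos + avg_len] = 0
            pos += avg_len + 1

    _place(0, summary.day_bout_n, summary.day_avg_bout_len)
    _place(PHASE_MINUTES, summary.night_bout_n, summary.night_avg_bout_len)
    return ActivityStream(
        fly_id=summary.fly_id, line=summary.line, sex=summary.sex,
        block=summary.block, replicate=summary.replicate, counts=counts,
        start_minute_of_day=lights_on, lights_on_minute=lights_on,
    )


# ---------------------------------------------------------------------------
# DAM-dialect monitor text

_DAM_META_COLS = 10  # index, date, time, status, then six spare columns


def write_dam_files(streams, directory, channels_per_monitor: int = 32) -> Path:
    """Write streams as tab-separated DAM-dialect monitor files.

    Each monitor file holds one row per minute: a reading index, date,
    time, a status column, six spare columns, then one count column per
    channel.  A ``manifest.tsv`` maps monitor/channel to fly metadata.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    monitors: dict = {}
    manifest = []
    for s in streams:
        monitors.setdefault(s.monitor, []).append(s)
        manifest.append({
            "monitor": s.monitor, "channel": s.channel, "fly_id": s.fly_id,
            "line": s.line, "sex": s.sex, "block": s.block,
            "replicate": s.replicate,
            "start_minute_of_day": s.start_minute_of_day,
            "lights_on_minute": s.lights_on_minute,
        })
    for monitor, flies in monitors.items():
        n_min = flies[0].counts.size
        mat = np.zeros((n_min, channels_per_monitor), dtype=np.int64)
        for s in flies:
            if s.counts.size != n_min:
                raise ValueError("streams on one monitor must share length")
            mat[:, s.channel] = s.counts
        start = flies[0].start_minute_of_day
        with open(directory / f"{monitor}.txt", "w") as fh:
            for i in range(n_min):
                minute = (start + i) % MINUTES_PER_DAY
                day = (start + i) // MINUTES_PER_DAY + 1
                meta = [str(i + 1), f"{day:d} Jan 13",
                        f"{minute // 60:02d}:{minute % 60:02d}:00", "1"]
                meta += ["0"] * (_DAM_META_COLS - len(meta))
                fh.write("\t".join(meta + [str(c) for c in mat[i]]) + "\n")
    pd.DataFrame(manifest).to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return directory


def read_dam_dir(directory, count_col_start: int = _DAM_META_COLS):
    """Read DAM-dialect monitor files written by :func:`write_dam_files`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    streams = []
    cache: dict = {}
    for _, row in manifest.iterrows():
        if row.monitor not in cache:
            raw = pd.read_csv(directory / f"{row.monitor}.txt", sep="\t",
                              header=None)
            cache[row.monitor] = raw.iloc[:, count_col_start:].to_numpy(np.int64)
        counts = cache[row.monitor][:, int(row.channel)]
        streams.append(ActivityStream(
            fly_id=row.fly_id, line=row.line, sex=row.sex,
            block=str(row.block), replicate=str(row.replicate),
            counts=counts, channel=int(row.channel), monitor=row.monitor,
            start_minute_of_day=int(row.start_minute_of_day),
            lights_on_minute=int(row.lights_on_minute),
        ))
    return streams
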