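"""GPS track preprocessing: cleaning, regularization to a fixed interval, and
conversion to step series with turn angles and biological seasons.

Conventions follow standard step-selection workflows: fixes are subsampled (not
interpolated) to the target interval; gaps outside tolerance split the track
into bursts; turn angles are never computed across burst boundaries; each step
takes its season from the month of its end fix (spring = April-June, the
kidding season; summer = July-September; autumn = October-December, the rut;
winter = January-March).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "SEASON_MONTHS",
    "season_of_month",
    "read_fixes",
    "clean_track",
    "regularize",
    "build_steps",
    "daily_net_displacement",
    "EmptyTrackError",
]

log = logging.getLogger(__name__)

SEASON_MONTHS = {
    "spring": (4, 5, 6),
    "summer": (7, 8, 9),
    "autumn": (10, 11, 12),
    "winter": (1, 2, 3),
}
_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}


class EmptyTrackError(ValueError):
    """Cleaning or regularization left fewer than two usable fixes."""


def season_of_month(month: int | np.ndarray) -> str | np.ndarray:
    """Biological season for a calendar month (1-12)."""
    if np.isscalar(month):
        return _MONTH_TO_SEASON[int(month)]
    return np.vectorize(_MONTH_TO_SEASON.get)(month)


def read_fixes(path) -> pd.DataFrame:
    """Read a fix table (animal_id, timestamp, x, y[, altitude]); ISO timestamps.

    Coordinates must be projected metres; tables that look geographic
    (every |x| <= 180 and |y| <= 90) are rejected.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if len(df) and (df["x"].abs() <= 180).all() and (df["y"].abs() <= 90).all():
        raise ValueError(
            "coordinates look geographic (lon/lat); project to metres before use"
        )
    return df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def write_fixes(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def _neighbour_speeds_kmh(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
    dist_km = np.hypot(np.diff(x), np.diff(y)) / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt_h > 0, dist_km / dt_h, np.inf)
    prev = np.concatenate([[0.0], v])  # speed from the previous fix
    nxt = np.concatenate([v, [0.0]])  # speed to the next fix
    return prev, nxt


def clean_track(
    fixes: pd.DataFrame,
    n_initial_drop: int = 5,
    speed_threshold_kmh: float = 10.0,
) -> pd.DataFrame:
    """Drop the first ``n_initial_drop`` fixes and iteratively remove relocation
    errors: fixes whose straight-line speed to BOTH neighbours exceeds the
    threshold (an isolated spike, not a genuine fast transit). Endpoints are
    never flagged (they have a single neighbour).
    """
    if n_initial_drop < 0:
        raise ValueError("n_initial_drop must be >= 0")
    df = fixes.sort_values("timestamp").iloc[n_initial_drop:].reset_index(drop=True)
    while len(df) >= 3 and np.isfinite(speed_threshold_kmh):
        prev, nxt = _neighbour_speeds_kmh(
            df["timestamp"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy()
        )
        bad = (prev > speed_threshold_kmh) & (nxt > speed_threshold_kmh)
        bad[0] = bad[-1] = False
        if not bad.any():
            break
        df = df.loc[~bad].reset_index(drop=True)
    if len(df) < 2:
        raise EmptyTrackError("fewer than 2 fixes remain after cleaning")
    return df


def regularize(
    track: pd.DataFrame, interval_h: float = 4.0, tolerance_min: float = 30.0
) -> pd.DataFrame:
    """Greedy-forward subsampling to ``interval_h`` +- ``tolerance_min``.

    Keeps the first fix; from each kept fix takes the next fix whose gap falls
    within tolerance. A gap that cannot be met within tolerance starts a new
    burst at the next available fix. Adds a ``burst`` column.
    """
    if interval_h <= 0:
        raise ValueError("interval must be positive")
    df = track.sort_values("timestamp").reset_index(drop=True)
    t = df["timestamp"].to_numpy()
    target = np.timedelta64(int(interval_h * 3600), "s")
    tol = np.timedelta64(int(tolerance_min * 60), "s")

    keep: list[int] = [0]
    burst_ids: list[int] = [0]
    burst = 0
    i = 0
    while True:
        gaps = t[i + 1:] - t[i]
        in_tol = np.nonzero(np.abs(gaps - target) <= tol)[0]
        if in_tol.size:
            i = i + 1 + int(in_tol[0])
        else:
            beyond = np.nonzero(gaps > target + tol)[0]
            if beyond.size == 0:
                break
            i = i + 1 + int(beyond[0])
            burst += 1
        keep.append(i)
        burst_ids.append(burst)
    out = df.iloc[keep].reset_index(drop=True)
    out["burst"] = burst_ids
    return out


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(np.isclose(w, -np.pi), np.pi, w)


def build_steps(track: pd.DataFrame) -> pd.DataFrame:
    """One step per consecutive fix pair within a burst.

    Columns: animal_id, burst, t_start, t_end, x1, y1, x2, y2, length, heading,
    turn_angle (NaN for the first step of a burst), cos_ta, season (from the
    end fix's month). Zero-length steps keep the previous step's heading so the
    following turn angle stays defined.
    """
    df = track.sort_values("timestamp").reset_index(drop=True)
    if "burst" not in df.columns:
        df = df.assign(burst=0)
    parts = []
    for (animal, burst), g in df.groupby(["animal_id", "burst"], sort=True):
        if len(g) < 2:
            continue
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        t = g["timestamp"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        length = np.hypot(dx, dy)
        heading = np.arctan2(dy, dx)
        # carry heading through zero-length steps
        for k in range(len(heading)):
            if length[k] == 0:
                heading[k] = heading[k - 1] if k > 0 else np.nan
        turn = np.full_like(length, np.nan)
        if len(length) > 1:
            turn[1:] = _wrap_angle(heading[1:] - heading[:-1])
        end_times = pd.DatetimeIndex(t[1:])
        parts.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "burst": burst,
                    "t_start": t[:-1],
                    "t_end": t[1:],
                    "x1": x[:-1],
                    "y1": y[:-1],
                    "x2": x[1:],
                    "y2": y[1:],
                    "length": length,
                    "heading": heading,
                    "turn_angle": turn,
                    "cos_ta": np.cos(turn),
                    "season": season_of_month(end_times.month.to_numpy()),
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "animal_id", "burst", "t_start", "t_end", "x1", "y1", "x2", "y2",
                "length", "heading", "turn_angle", "cos_ta", "season",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def daily_net_displacement(track: pd.DataFrame) -> pd.DataFrame:
    """Per calendar day (UTC by default), the straight-line distance between the
    day's first and last fix, in metres. Days with fewer than 2 fixes are
    skipped with a log notice.
    """
    df = track.sort_values("timestamp").reset_index(drop=True)
    day = pd.to_datetime(df["timestamp"]).dt.normalize()
    rows = []
    for d, g in df.groupby(day):
        if len(g) < 2:
            log.info("daily_net_displacement: skipping %s (<2 fixes)", d.date())
            continue
        rows.append(
            {
                "date": d.date(),
                "displacement": float(
                    np.hypot(
                        g["x"].iloc[-1] - g["x"].iloc[0], g["y"].iloc[-1] - g["y"].iloc[0]
                    )
                ),
            }
        )
    if not rows:
        raise ValueError("no calendar day has >= 2 fixes")
    return pd.DataFrame(rows)
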