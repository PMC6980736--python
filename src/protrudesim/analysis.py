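"""Post-processing of migration runs: velocities, mean-squared
displacement, protrusion statistics and replicate-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "migration_velocities",
    "msd_curve",
    "msd_slope",
    "protrusion_stats",
    "ProtrusionSummary",
    "compare_groups",
    "summarize_replicates",
]


def _resample(traj: pd.DataFrame, interval: float) -> np.ndarray:
    """Positions at regular time intervals (linear interpolation)."""
    t = traj["t"].to_numpy()
    ts = np.arange(t[0], t[-1] + 1e-9, interval)
    x = np.interp(ts, t, traj["x_cm"].to_numpy())
    y = np.interp(ts, t, traj["y_cm"].to_numpy())
    return np.column_stack([x, y])


def migration_velocities(traj: pd.DataFrame, T: float | None = None,
                         resample: float = 60.0):
    """Absolute and along-path migration velocities in um/hr.

    v_abs is the net displacement of the centre of mass over the window
    divided by its duration; v_path is the total path length (sampled at
    ``resample`` seconds to suppress discretisation jitter) divided by
    the duration.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t = traj["t"].to_numpy()
    if T is None:
        T = t[-1] - t[0]
    if T > t[-1] - t[0] + 1e-9:
        raise ValueError("requested window exceeds trajectory span")
    sub = traj[t <= t[0] + T + 1e-9]
    pos = np.column_stack([sub["x_cm"], sub["y_cm"]])
    v_abs = np.linalg.norm(pos[-1] - pos[0]) / T * 3600.0
    rs = _resample(sub, resample)
    path = np.linalg.norm(np.diff(rs, axis=0), axis=1).sum()
    v_path = path / T * 3600.0
    return v_abs, v_path


def msd_curve(traj: pd.DataFrame, resample: float = 60.0):
    """Sliding-window mean squared displacement over all start times.

    Returns (lags s, msd um^2) for every multiple of the resampling
    interval up to half the track duration.
    """
    pos = _resample(traj, resample)
    nmax = len(pos) // 2
    lags = np.arange(1, max(nmax, 2)) * resample
    msd = np.empty(len(lags))
    for k in range(1, len(lags) + 1):
        d = pos[k:] - pos[:-k]
        msd[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return lags, msd


def msd_slope(traj: pd.DataFrame, tau_range=(600.0, 7200.0),
              resample: float = 60.0):
    """Log-log slope alpha of the MSD over the given lag range
    (alpha = 1 for a random walk, 2 for ballistic motion)."""
    lags, msd = msd_curve(traj, resample)
    sel = (lags >= tau_range[0]) & (lags <= tau_range[1]) & (msd > 0)
    if sel.sum() < 2:
        sel = msd > 0
    if sel.sum() < 2:
        return (lags, msd), np.nan
    alpha = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)[0]
    return (lags, msd), float(alpha)


@dataclass
class ProtrusionSummary:
    n_prot_total: int
    lifetimes: np.ndarray          # contracting-phase duration, s
    lengths: np.ndarray            # tip displacement over growth, um
    f_adh_rel: np.ndarray          # relative force at disassembly
    f_mat: np.ndarray              # per-protrusion final maturation


def protrusion_stats(events: pd.DataFrame, T: float | None = None,
                     F_am: float = 0.6) -> ProtrusionSummary:
    """Per-run protrusion statistics from the event log.

    The protrusion count is the number of initiation events; lifetimes
    run from the end of maturation to disassembly (growth and maturation
    excluded); lengths are tip displacements from initiation to adhesion
    formation; f_adh_rel is the adhesion force at disassembly divided by
    the protrusion's contractile strength f_mat * F_am.
    """
    ev = events if T is None else events[events["time"] <= T + 1e-9]
    inits = ev[ev["type"] == "init"]
    n_tot = len(inits)
    lifetimes, lengths, fadh, fmats = [], [], [], []
    for pid, grp in ev.groupby("protrusion_id"):
        types = dict(zip(grp["type"], grp["time"]))
        init_row = grp[grp["type"] == "init"]
        adh_row = grp[grp["type"] == "adhesion"]
        if len(init_row) and len(adh_row):
            d = (adh_row[["tip_x", "tip_y"]].to_numpy()[0]
                 - init_row[["tip_x", "tip_y"]].to_numpy()[0])
            lengths.append(float(np.linalg.norm(d)))
        if "mat_done" in types:
            done_row = grp[grp["type"] == "mat_done"]
            fmats.append(float(done_row["f_mat"].iloc[0]))
            dis = grp[grp["type"].isin(["disassemble", "rupture"])]
            if len(dis):
                lifetimes.append(float(dis["time"].iloc[0]) - types["mat_done"])
                f = float(dis["adhesion_force"].iloc[0])
                fm = float(dis["f_mat"].iloc[0])
                fadh.append(f / (fm * F_am))
    orphan = ev[~ev["type"].isin(
        ["init", "adhesion", "mat_step", "mat_done", "disassemble",
         "rupture", "abort", "finish"])]
    if len(orphan):
        raise ValueError(f"event log contains unknown events: "
                         f"{sorted(set(orphan['type']))}")
    return ProtrusionSummary(
        n_prot_total=n_tot,
        lifetimes=np.asarray(lifetimes),
        lengths=np.asarray([v for v in lengths if np.isfinite(v)]),
        f_adh_rel=np.asarray(fadh),
        f_mat=np.asarray(fmats))


def compare_groups(a, b):
    """Unpaired two-sample Student's t-test (pooled variance) with the
    study's significance stars: * p<0.05, ** p<0.01, *** p<0.005."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0, ""
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if p < 0.005:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        stars = ""
    return float(t), float(p), stars


def summarize_replicates(results, F_am: float = 0.6,
                         tau_range=(600.0, 7200.0)) -> pd.DataFrame:
    """One row per replicate: migration velocities, protrusion counts,
    mean lifetime/length and the MSD slope."""
    rows = []
    for i, res in enumerate(results):
        traj, ev = res["trajectory"], res["events"]
        v_abs, v_path = migration_velocities(traj)
        _, alpha = msd_slope(traj, tau_range)
        ps = protrusion_stats(ev, F_am=F_am)
        rows.append({
            "replicate": i,
            "v_abs": v_abs, "v_path": v_path,
            "n_prot": ps.n_prot_total,
            "mean_lifetime": ps.lifetimes.mean() if len(ps.lifetimes) else np.nan,
            "mean_length": ps.lengths.mean() if len(ps.lengths) else np.nan,
            "alpha": alpha,
        })
    return pd.DataFrame(rows)
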