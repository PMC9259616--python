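"""Track-derived statistics of syncytial nuclear dynamics.

Conventions
-----------
* **Local density** of a nucleus is the number of *other* nuclei within a
  closed 150-um-radius ball ("density units").  A 2D variant (discs in a
  projection plane, for epifluorescence-like data) is available via
  ``projection="xy"`` and is never mixed with 3D values.
* **Speed** is the instantaneous frame-to-frame displacement magnitude
  divided by the frame interval, assigned to the later frame.
* **Phase windows** follow the post-division timing of the two motility
  states: Phase A (fast, cloud present) sampled 3-13.5 min after division,
  Phase B (slow, cloud absent) sampled 33-39 min after division.
* **Correlation** between two movement vectors is cosine similarity.
* The speed-density law is ``y = y0 * exp(-x / x0)``; ``x0`` is the
  "density scale" (the density change producing an e-fold speed change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .errors import FitError
from .geometry import EmbryoDomain
from .tracks import POSITION_COLUMNS, TrackTable, time_since_division

DEFAULT_DENSITY_RADIUS_UM = 150.0
#: density-bin edges: low < 11, 11 <= medium < 29, high >= 29
DENSITY_BIN_EDGES = (11, 29)


@dataclass(frozen=True)
class PhaseWindows:
    """Post-division sampling windows (minutes) for the two motility phases."""

    phaseA: tuple[float, float] = (3.0, 13.5)
    phaseB: tuple[float, float] = (33.0, 39.0)
    phaseA_duration: tuple[float, float] = (20.0, 28.0)
    phaseB_duration: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if not (self.phaseA[0] < self.phaseA[1] <= self.phaseB[0] < self.phaseB[1]):
            raise ValueError("phase windows must be increasing and non-overlapping")


@dataclass(frozen=True)
class DensityScaleFit:
    """Result of the exponential speed-density fit."""

    y0: float
    x0: float
    ci90: tuple[float, float]
    n_points: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "y0": self.y0,
            "x0": self.x0,
            "ci90": list(self.ci90),
            "n_points": self.n_points,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# density & speed
# ---------------------------------------------------------------------------


def local_density(
    positions: np.ndarray,
    radius_um: float = DEFAULT_DENSITY_RADIUS_UM,
    projection: str | None = None,
) -> np.ndarray:
    """Count of other nuclei within a closed ball (or disc) of ``radius_um``."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if projection == "xy":
        pts = pts[:, :2]
    elif projection is not None:
        raise ValueError(f"projection must be None or 'xy', got {projection!r}")
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, radius_um, return_length=True)
    return counts - 1  # exclude the focal nucleus


def density_bin(counts: np.ndarray) -> np.ndarray:
    """Bin density counts into 'low' / 'medium' / 'high'."""
    lo, hi = DENSITY_BIN_EDGES
    return np.where(np.asarray(counts) < lo, "low", np.where(np.asarray(counts) < hi, "medium", "high"))


def nucleus_speed(table: TrackTable, projection: str | None = None) -> pd.DataFrame:
    """Instantaneous speed per record (um/min); NaN on each nucleus's first frame."""
    df = table.df
    pos = df[POSITION_COLUMNS].to_numpy()
    if projection == "xy":
        pos = pos[:, :2]
    elif projection is not None:
        raise ValueError(f"projection must be None or 'xy', got {projection!r}")
    d = np.diff(pos, axis=0, prepend=pos[:1])
    step = np.linalg.norm(d, axis=1)
    same = df["nucleus_id"].to_numpy()
    first = np.ones(len(df), dtype=bool)
    first[1:] = same[1:] != same[:-1]
    dt = df["t_min"].diff().to_numpy()
    speed = np.where(first, np.nan, step / np.where(first, np.nan, dt))
    return pd.DataFrame({"nucleus_id": df["nucleus_id"], "frame": df["frame"], "speed_um_min": speed})


def per_record_metrics(
    table: TrackTable,
    radius_um: float = DEFAULT_DENSITY_RADIUS_UM,
    windows: PhaseWindows = PhaseWindows(),
    projection: str | None = None,
) -> pd.DataFrame:
    """Tidy per-(nucleus, frame) table: position, speed, density, time since division, phase."""
    df = table.df
    out = df[["nucleus_id", "frame", "t_min", *POSITION_COLUMNS]].copy()
    out["speed_um_min"] = nucleus_speed(table, projection=projection)["speed_um_min"].to_numpy()
    tsd = time_since_division(table)
    out["t_since_division_min"] = tsd["t_since_division_min"].to_numpy()
    out["censored"] = tsd["censored"].to_numpy()
    dens = np.empty(len(df), dtype=np.int64)
    for _, idx in df.groupby("frame").indices.items():
        dens[idx] = local_density(df.iloc[idx][POSITION_COLUMNS].to_numpy(), radius_um, projection)
    out["density"] = dens
    out["density_bin"] = density_bin(dens)
    out["phase"] = assign_phase(out["t_since_division_min"].to_numpy(), windows)
    return out


# ---------------------------------------------------------------------------
# proliferation timing
# ---------------------------------------------------------------------------


def count_change_series(
    table: TrackTable, smooth_window_frames: int = 5, method: str = "mean"
) -> pd.Series:
    """Smoothed percent change in total nucleus count per frame.

    ``method`` is ``"mean"`` (default: preserves narrow division pulses —
    a rolling median erases a synchronous single-frame pulse entirely) or
    ``"median"`` (robust to outliers for long, dense series).
    """
    counts = table.counts_per_frame().sort_index()
    if len(counts) < 2:
        raise ValueError("need at least 2 frames")
    pct = 100.0 * counts.diff() / counts.shift(1)
    pct = pct.iloc[1:]
    roll = pct.rolling(smooth_window_frames, center=True, min_periods=1)
    return roll.median() if method == "median" else roll.mean()


def detect_division_peaks(
    series: pd.Series,
    frame_interval_min: float,
    prominence_frac: float = 0.25,
    min_separation_min: float = 20.0,
) -> dict:
    """Peaks of the percent-change trace and the intervals between them.

    Peaks are local maxima with prominence at least ``prominence_frac`` of
    the series maximum, separated by at least ``min_separation_min``.
    """
    y = series.to_numpy(dtype=float)
    y = np.nan_to_num(y, nan=0.0)
    top = y.max()
    if top <= 0:
        return {"peak_times_min": np.array([]), "intervals_min": np.array([])}
    distance = max(1, int(round(min_separation_min / frame_interval_min)))
    idx, _ = signal.find_peaks(y, prominence=prominence_frac * top, distance=distance)
    times = series.index.to_numpy()[idx] * frame_interval_min
    intervals = np.diff(times) if len(times) >= 2 else np.array([])
    return {"peak_times_min": times, "intervals_min": intervals}


def _generation(table: TrackTable) -> pd.Series:
    """Depth of each nucleus in its lineage tree (roots = 0)."""
    parents = table.df.groupby("nucleus_id")["parent_id"].first()
    gen = {}

    def depth(nid):
        if nid in gen:
            return gen[nid]
        p = parents[nid]
        g = 0 if pd.isna(p) else depth(int(p)) + 1
        gen[nid] = g
        return g

    for nid in parents.index:
        depth(nid)
    return pd.Series(gen).sort_index()


def cycle_lengths(table: TrackTable) -> pd.DataFrame:
    """Birth-to-division interval per internal, uncensored nucleus.

    Root nuclei (birth unobserved) and leaves (division unobserved) are
    excluded.  ``cycle_number`` is the lineage depth (first fully observed
    cycle = 1 for the daughters of a root).
    """
    df = table.df
    parents = df.groupby("nucleus_id")["parent_id"].first()
    first_t = df.groupby("nucleus_id")["t_min"].min()
    has_children = set(parents.dropna().astype(np.int64).to_numpy().tolist())
    gen = _generation(table)
    rows = []
    kids = parents.dropna().astype(np.int64)
    div_t = {}  # parent -> daughters' first frame time
    for d, p in kids.items():
        div_t[p] = first_t[d]
    for nid in sorted(has_children):
        if pd.isna(parents[nid]):
            continue  # censored root
        rows.append((nid, float(div_t[nid] - first_t[nid]), int(gen[nid])))
    return pd.DataFrame(rows, columns=["nucleus_id", "cycle_length_min", "cycle_number"])


def local_proliferation_time(
    table: TrackTable,
    t0_min: float,
    radius_um: float = DEFAULT_DENSITY_RADIUS_UM,
    increase_frac: float = 0.25,
    projection: str | None = None,
) -> pd.DataFrame:
    """Minutes until the neighborhood count of each nucleus alive at ``t0``
    rises by ``increase_frac`` (ceiling on the integer target).

    The neighborhood follows the nucleus's own moving position.  NaN marks
    nuclei whose record ends before the target is reached.
    """
    df = table.df
    dt = table.frame_interval_min
    frame_times = df.groupby("frame")["t_min"].first()
    hits = frame_times.index[np.isclose(frame_times.to_numpy(), t0_min)]
    if len(hits) == 0:
        raise ValueError(f"t0_min={t0_min} is not a recorded frame time")
    f0 = int(hits[0])
    cols = slice(0, 2) if projection == "xy" else slice(0, 3)
    by_frame = {f: sub.set_index("nucleus_id")[POSITION_COLUMNS] for f, sub in df.groupby("frame")}
    focal = by_frame[f0].index.to_numpy()
    base = by_frame[f0].to_numpy()[:, cols]
    tree0 = cKDTree(by_frame[f0].to_numpy()[:, cols])
    counts0 = tree0.query_ball_point(base, radius_um, return_length=True) - 1
    target = np.ceil((1.0 + increase_frac) * counts0).astype(int)
    result = {int(n): np.nan for n in focal}
    pending = {int(n): target[i] for i, n in enumerate(focal)}
    reached_now = [int(n) for i, n in enumerate(focal) if counts0[i] >= target[i]]
    for n in reached_now:
        result[n] = 0.0
        del pending[n]
    for f in sorted(k for k in by_frame if k > f0):
        if not pending:
            break
        frame_pos = by_frame[f]
        alive = [n for n in list(pending) if n in frame_pos.index]
        for n in list(pending):
            if n not in frame_pos.index:
                del pending[n]  # record ended before the target was reached
        if not alive:
            continue
        pts = frame_pos.to_numpy()[:, cols]
        tree = cKDTree(pts)
        pos = frame_pos.loc[alive].to_numpy()[:, cols]
        counts = tree.query_ball_point(pos, radius_um, return_length=True) - 1
        for n, c in zip(alive, counts):
            if c >= pending[n]:
                result[n] = (f - f0) * dt
                del pending[n]
    return pd.DataFrame(
        {"nucleus_id": list(result), "prolif_time_min": [result[n] for n in result]}
    ).sort_values("nucleus_id", ignore_index=True)


def density_cycle_concordance(densities: np.ndarray, prolif_times: np.ndarray) -> float:
    """Percent of unordered pairs where the denser nucleus proliferates slower.

    Pairs tied in either variable, or with a missing time, are excluded.
    Returns NaN when no valid pairs remain.
    """
    d = np.asarray(densities, dtype=float)
    t = np.asarray(prolif_times, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(t)
    d, t = d[ok], t[ok]
    if len(d) < 2:
        return float("nan")
    dd = d[:, None] - d[None, :]
    tt = t[:, None] - t[None, :]
    iu = np.triu_indices(len(d), k=1)
    dd, tt = dd[iu], tt[iu]
    valid = (dd != 0) & (tt != 0)
    if not valid.any():
        return float("nan")
    concordant = (dd[valid] * tt[valid]) > 0
    return 100.0 * concordant.mean()


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------


def voronoi_centroids(positions: np.ndarray, domain: EmbryoDomain) -> np.ndarray:
    """Centroid of each nucleus's domain-bounded Voronoi cell.

    Every interior voxel is assigned to its nearest nucleus; the centroid is
    the mean of a nucleus's assigned voxel centers (NaN if it owns none).
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    vox = domain.interior_points_um
    tree = cKDTree(pts)
    _, owner = tree.query(vox)
    sums = np.zeros((len(pts), 3))
    np.add.at(sums, owner, vox)
    n = np.bincount(owner, minlength=len(pts)).astype(float)
    with np.errstate(invalid="ignore"):
        return sums / n[:, None]


def space_seeking_score(table: TrackTable, domain: EmbryoDomain, frame: int) -> pd.DataFrame:
    """Cosine between each nucleus's one-step displacement and the vector to
    its bounded-Voronoi-cell centroid.

    NaN marks nuclei without a next-frame record (e.g. they divided) or with
    a degenerate (<1e-6 um) displacement or target vector.  A lone nucleus
    owns the whole domain as its cell (at the center of a symmetric domain
    its target vector vanishes and the score is the NaN sentinel).
    """
    now = table.positions_at(frame)
    nxt = table.positions_at(frame + 1)
    if len(now) < 1:
        raise ValueError("space-seeking score requires at least one nucleus at the frame")
    if len(nxt) == 0:
        raise ValueError(f"frame {frame + 1} has no records")
    pos = now[POSITION_COLUMNS].to_numpy()
    cent = voronoi_centroids(pos, domain)
    target = cent - pos
    scores = np.full(len(now), np.nan)
    common = now.index.intersection(nxt.index)
    loc = {n: i for i, n in enumerate(now.index)}
    for n in common:
        i = loc[n]
        disp = nxt.loc[n, POSITION_COLUMNS].to_numpy(dtype=float) - pos[i]
        nd, nt = np.linalg.norm(disp), np.linalg.norm(target[i])
        if nd >= 1e-6 and nt >= 1e-6:
            scores[i] = float(np.dot(disp, target[i]) / (nd * nt))
    return pd.DataFrame({"nucleus_id": now.index.to_numpy(), "score": scores})


def pairwise_movement_correlation(
    table: TrackTable,
    frame: int,
    exclude_sisters: bool = True,
    sister_window_frames: int = 5,
) -> pd.DataFrame:
    """Cosine similarity of one-step displacement vectors for all pairs.

    Sister pairs (same parent, within ``sister_window_frames`` of their
    shared birth) are excluded when ``exclude_sisters`` — immediately after
    a division the daughters' movements are anti-correlated by construction.
    """
    now = table.positions_at(frame)
    nxt = table.positions_at(frame + 1)
    common = now.index.intersection(nxt.index)
    if len(common) < 2:
        return pd.DataFrame(columns=["id_a", "id_b", "separation_um", "correlation"])
    pos = now.loc[common, POSITION_COLUMNS].to_numpy()
    disp = nxt.loc[common, POSITION_COLUMNS].to_numpy() - pos
    norms = np.linalg.norm(disp, axis=1)
    parents = table.df.groupby("nucleus_id")["parent_id"].first()
    births = table.df.groupby("nucleus_id")["frame"].min()
    ids = common.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if exclude_sisters:
                pa, pb = parents[a], parents[b]
                if (
                    not pd.isna(pa)
                    and not pd.isna(pb)
                    and pa == pb
                    and frame < births[a] + sister_window_frames
                ):
                    continue
            if norms[i] < 1e-9 or norms[j] < 1e-9:
                continue
            corr = float(np.dot(disp[i], disp[j]) / (norms[i] * norms[j]))
            sep = float(np.linalg.norm(pos[i] - pos[j]))
            rows.append((a, b, sep, corr))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "separation_um", "correlation"])


def correlation_distance_r2(pairs: pd.DataFrame) -> float:
    """R^2 of the linear dependence of pairwise correlation on separation."""
    if len(pairs) < 3:
        return float("nan")
    if np.std(pairs["correlation"].to_numpy()) < 1e-12:
        return 0.0  # constant correlations: separation explains nothing
    res = stats.linregress(pairs["separation_um"], pairs["correlation"])
    return float(res.rvalue**2)


# ---------------------------------------------------------------------------
# phases & the density-scale fit
# ---------------------------------------------------------------------------


def assign_phase(
    time_since_division_min: np.ndarray, windows: PhaseWindows = PhaseWindows()
) -> np.ndarray:
    """'A' in the Phase A window, 'B' in the Phase B window, else 'outside'."""
    t = np.asarray(time_since_division_min, dtype=float)
    if np.any(t[~np.isnan(t)] < 0):
        raise ValueError("time since division must be non-negative")
    a_lo, a_hi = windows.phaseA
    b_lo, b_hi = windows.phaseB
    out = np.full(t.shape, "outside", dtype=object)
    out[(t >= a_lo) & (t <= a_hi)] = "A"
    out[(t >= b_lo) & (t <= b_hi)] = "B"
    return out


def _expdecay(x, y0, x0):
    return y0 * np.exp(-x / x0)


def fit_density_scale(
    speeds: np.ndarray,
    densities: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> DensityScaleFit:
    """Nonlinear least-squares fit of ``y = y0 * exp(-x/x0)`` with a seeded
    case-resampling percentile bootstrap 90% CI for ``x0``."""
    y = np.asarray(speeds, dtype=float)
    x = np.asarray(densities, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(x)
    y, x = y[ok], x[ok]
    if len(y) < 10:
        raise FitError(f"need >= 10 points, got {len(y)}")
    if np.any(y < 0):
        raise FitError("speeds must be non-negative")
    if np.ptp(x) == 0:
        raise FitError("all densities equal: x0 is unidentifiable")

    def fit_once(xx, yy):
        p0 = (max(yy.mean(), 1e-6), max(np.ptp(xx), 1.0))
        popt, _ = curve_fit(
            _expdecay, xx, yy, p0=p0, bounds=([1e-9, 1e-6], [np.inf, 1e12]), maxfev=10000
        )
        return popt

    try:
        y0_hat, x0_hat = fit_once(x, y)
    except Exception as e:  # noqa: BLE001 - re-raise with diagnostics
        raise FitError(f"exponential fit did not converge: {e}") from e

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), len(y))
        if np.ptp(x[idx]) == 0:
            continue
        try:
            boots.append(fit_once(x[idx], y[idx])[1])
        except Exception:  # noqa: BLE001 - failed resample, skip
            continue
    if len(boots) < max(10, n_boot // 2):
        raise FitError(f"bootstrap unstable: only {len(boots)}/{n_boot} resamples converged")
    lo, hi = np.percentile(boots, [5.0, 95.0])
    return DensityScaleFit(
        y0=float(y0_hat), x0=float(x0_hat), ci90=(float(lo), float(hi)), n_points=len(y), seed=seed
    )


def space_seeking_phase_medians(
    table: TrackTable,
    domain: EmbryoDomain,
    periplasm_um: float = 75.0,
    min_interior_frac: float = 0.5,
    frame_stride: int = 6,
    windows: PhaseWindows = PhaseWindows(),
) -> dict:
    """Median space-seeking score of interior nuclei by cycle phase.

    Scores are pooled over every ``frame_stride``-th frame of the axial
    expansion epoch — frames where at least ``min_interior_frac`` of nuclei
    are still interior (deeper than ``periplasm_um`` from the shell).  Once
    the blastoderm has formed, the few remaining "interior" nuclei sit at
    the rim of the vacated yolk and no longer constitute the cohort this
    statistic describes.
    """
    df = table.df
    shell_d = domain.shell_distance_at(df[POSITION_COLUMNS].to_numpy())
    interior_frac = pd.Series(shell_d > periplasm_um).groupby(df["frame"]).mean()
    usable = interior_frac.index[interior_frac >= min_interior_frac].to_numpy()
    frames = [int(f) for f in usable[::frame_stride] if f + 1 in set(table.frames)]
    if not frames:
        raise ValueError("no frames satisfy the interior-fraction requirement")
    rec = per_record_metrics(table, windows=windows)
    rows = []
    for f in frames:
        s = space_seeking_score(table, domain, f)
        s["frame"] = f
        rows.append(s)
    ss = pd.concat(rows).merge(rec, on=["nucleus_id", "frame"])
    ss["interior"] = domain.shell_distance_at(ss[POSITION_COLUMNS].to_numpy()) > periplasm_um
    out = {"frames": frames}
    for phase in ("A", "B"):
        sub = ss[(ss["phase"] == phase) & ss["interior"] & ss["score"].notna()]
        out[phase] = {"median": float(sub["score"].median()), "n": int(len(sub))}
    return out


# ---------------------------------------------------------------------------
# cross-run staging helper
# ---------------------------------------------------------------------------


def stage_match_frame(table: TrackTable, total_count: int) -> int:
    """First frame at which the total nucleus count reaches ``total_count``."""
    counts = table.counts_per_frame().sort_index()
    hit = counts.index[counts >= total_count]
    if len(hit) == 0:
        raise ValueError(f"run never reaches {total_count} nuclei (max {counts.max()})")
    return int(hit[0])
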