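"""Seeded fixture generators with analytically known ground truth.

These produce valid :class:`~blastosim.tracks.TrackTable` objects (and raw
point/sample sets) whose statistics are known by construction, so every
metric can be tested against an exact or enumerable oracle.  They are
deliberately independent of the geometry module so metric tests run fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracks import DEFAULT_FRAME_INTERVAL_MIN, TrackTable


def make_lattice_config(spacing_um: float, extent_um: float) -> np.ndarray:
    """Cubic lattice points in ``[0, extent]^3``; neighbor counts follow from shell enumeration."""
    axis = np.arange(0.0, extent_um + 1e-9, spacing_um)
    g = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def make_ballistic_tracks(
    n: int,
    speed_um_min: float,
    frames: int,
    seed: int,
    directions: np.ndarray | None = None,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    box_um: float = 400.0,
) -> TrackTable:
    """Constant-velocity, non-dividing tracks (all roots).

    Instantaneous speed equals ``speed_um_min`` exactly at every recorded
    step; pairwise movement correlations equal the cosines between rows of
    ``directions``.
    """
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, box_um, size=(n, 3))
    if directions is None:
        directions = rng.standard_normal((n, 3))
    directions = np.asarray(directions, dtype=float)
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    rows = []
    for i in range(n):
        for f in range(frames):
            t = f * frame_interval_min
            p = starts[i] + speed_um_min * t * directions[i]
            rows.append((i, None, f, t, *p))
    df = pd.DataFrame(rows, columns=["nucleus_id", "parent_id", "frame", "t_min", "x_um", "y_um", "z_um"])
    return TrackTable(df, frame_interval_min=frame_interval_min)


def make_scripted_lineage(
    cycle_means_min,
    seed: int,
    noise_sd_min: float = 0.0,
    n_roots: int = 1,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    daughter_offset_um: float = 20.0,
    root_spacing_um: float = 600.0,
    tail_frames: int = 3,
) -> TrackTable:
    """Binary lineage with programmed per-generation cycle lengths.

    ``cycle_means_min[g]`` is the mean cycle length of generation ``g``
    (generation 0 = the roots, whose cycles are censored in downstream
    statistics because their birth is unobserved by convention).  Division
    times snap to the frame grid: the realized cycle of a nucleus is
    ``round(T / dt) * dt``.  Generation ``len(cycle_means_min)`` nuclei are
    leaves recorded for ``tail_frames`` frames.

    Nuclei are stationary between divisions; daughters are displaced by
    ``daughter_offset_um`` in a random direction, so speeds are zero except
    at birth.
    """
    cycle_means_min = list(cycle_means_min)
    if not cycle_means_min:
        raise ValueError("cycle_means_min must be non-empty")
    rng = np.random.default_rng(seed)
    dt = frame_interval_min
    rows = []
    leaves = []  # (id, parent, birth_frame, pos); emitted after the global end is known
    next_id = [0]

    def emit(nucleus_id, parent_id, first_frame, last_frame, pos):
        for f in range(first_frame, last_frame + 1):
            rows.append((nucleus_id, parent_id, f, f * dt, *pos))

    def grow(parent_id, birth_frame, pos, gen):
        nid = next_id[0]
        next_id[0] += 1
        if gen < len(cycle_means_min):
            mean = cycle_means_min[gen]
            T = mean if noise_sd_min == 0 else rng.normal(mean, noise_sd_min)
            n_frames = max(2, int(round(T / dt)))
            emit(nid, parent_id, birth_frame, birth_frame + n_frames - 1, pos)
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            for sign in (+1.0, -1.0):
                grow(nid, birth_frame + n_frames, pos + sign * daughter_offset_um * d, gen + 1)
        else:
            leaves.append((nid, parent_id, birth_frame, pos))

    for r in range(n_roots):
        grow(None, 0, np.array([r * root_spacing_um, 0.0, 0.0]), 0)
    # all leaves persist to a shared final frame so the total count never dips
    end_frame = max(b for _, _, b, _ in leaves) + tail_frames - 1
    for nid, parent_id, birth_frame, pos in leaves:
        emit(nid, parent_id, birth_frame, end_frame, pos)
    df = pd.DataFrame(rows, columns=["nucleus_id", "parent_id", "frame", "t_min", "x_um", "y_um", "z_um"])
    return TrackTable(df, frame_interval_min=dt)


def make_expdecay_dataset(
    y0: float,
    x0: float,
    noise_sd: float,
    n: int,
    seed: int,
    density_range: tuple[float, float] = (0.0, 60.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(speeds, densities) drawn from y = y0*exp(-x/x0) + N(0, noise_sd), truncated at 0."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(*density_range, size=n)
    y = y0 * np.exp(-x / x0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return np.clip(y, 0.0, None), x
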