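"""Asymmetric pulling-cloud simulator of syncytial blastoderm formation.

Each nucleus carries a *cloud origin* — a body-fixed point on its surface
abstracting the microtubule-organizing center.  During the fast
post-division state (Phase A) a *cloud* (abstracting the astral microtubule
array) grows geodesically from the origin through the cytoplasm at speed
``r_max / tau_grow``, up to a 150-um maximum radius.  Growth is occluded by
the eggshell, by every nucleus body, and by the other clouds (first-arrival
partition).  Uniformly distributed motors tug the origin toward every cloud
voxel with weight 1/R^2 (R = geodesic distance voxel-to-origin), so a cloud
shaped like a rod of length L pulls with force proportional to L, and open
space — where the cloud could grow large — wins the tug of war.  In the
overdamped limit velocity is proportional to force, plus a small constant
bias toward the eggshell (the periplasm bias).  During the slow pre-division
state (Phase B) the cloud is absent and only the bias acts.

Cycle lengths are drawn from a lognormal law whose mean rises linearly with
local density, so crowded regions divide more slowly; Phase A lasts a
clamped fraction of the cycle.  At division the two daughters inherit
antipodal cloud origins along a uniformly random axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry import EmbryoDomain, ShapeSpec, build_domain, geodesic_distances
from .tracks import TrackTable

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleModel:
    """Density-dependent mitotic cycle length.

    Mean cycle length is linear in local density, ``T(rho) = T0 + slope*rho``,
    with lognormal noise.  The default line is anchored to two observed
    points of cricket development: ~49 min cycles at the four-nucleus stage
    (local density ~4) and ~87 min at the high-density regime (density 29),
    giving slope = 38/25 = 1.52 min per density unit and
    T0 = 49 - 4*slope = 42.92 min.

    The noise has a constant coefficient of variation: ``noise_sd_min`` is
    the standard deviation *at the reference mean* ``noise_ref_mean_min``
    (defaults 11 min at 87 min, the reported fourth-cycle dispersion), so
    early short cycles are proportionally tighter — which is what makes the
    early division pulses sharp while synchronicity degrades later.
    """

    T0_min: float = 42.92
    slope_min_per_density: float = 1.52
    noise_sd_min: float = 11.0
    noise_ref_mean_min: float = 87.0
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if self.T0_min <= 0:
            raise ValidationError(f"cycle.T0_min must be positive, got {self.T0_min}")
        if self.slope_min_per_density < 0:
            raise ValidationError("cycle.slope_min_per_density must be non-negative")
        if self.noise_sd_min < 0:
            raise ValidationError("cycle.noise_sd_min must be non-negative")
        if self.noise_ref_mean_min <= 0:
            raise ValidationError("cycle.noise_ref_mean_min must be positive")
        if self.distribution != "lognormal":
            raise ValidationError(f"cycle.distribution must be 'lognormal', got {self.distribution!r}")

    def mean_at(self, density: float) -> float:
        return self.T0_min + self.slope_min_per_density * density

    def sd_at(self, density: float) -> float:
        """Constant-CV noise: SD scales with the mean."""
        return self.noise_sd_min / self.noise_ref_mean_min * self.mean_at(density)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a simulation run.

    ``mu`` (mobility, um/min per force unit) may be left ``None`` to be set
    by :func:`calibrate_mobility` so that the fastest Phase A movements
    match ``target_max_speed_um_min``.
    """

    shape: ShapeSpec
    seed: int
    voxel_um: float = 10.0
    dt_min: float = 1.5
    mu: float | None = None
    bias_speed_um_min: float = 0.4
    target_max_speed_um_min: float = 4.0
    cycle: CycleModel = field(default_factory=CycleModel)
    phaseA_frac: float = 0.6
    phaseA_bounds_min: tuple[float, float] = (20.0, 28.0)
    tau_grow_min: float = 5.0
    r_max_um: float = 150.0
    nucleus_radius_um: float = 10.0
    weighting: str = "volume"
    force_sign: float = 1.0
    n_start: int = 4
    start_position_frac: float | None = None
    start_spread_um: float = 40.0
    t_end_min: float | None = None
    n_end: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is mandatory and must be an integer")
        for name in ("dt_min", "tau_grow_min", "r_max_um", "nucleus_radius_um", "voxel_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.bias_speed_um_min < 0:
            raise ValidationError("bias_speed_um_min must be non-negative")
        if self.weighting not in ("volume", "surface"):
            raise ValidationError(f"weighting must be volume|surface, got {self.weighting!r}")
        if self.force_sign not in (1.0, -1.0):
            raise ValidationError("force_sign must be +1 or -1")
        if self.n_start < 1:
            raise ValidationError("n_start must be >= 1")
        if self.t_end_min is None and self.n_end is None:
            raise ValidationError("one of t_end_min or n_end is required")
        if not 0 < self.phaseA_frac <= 1:
            raise ValidationError("phaseA_frac must be in (0, 1]")
        lo, hi = self.phaseA_bounds_min
        if not 0 < lo <= hi:
            raise ValidationError("phaseA_bounds_min must satisfy 0 < lo <= hi")


@dataclass
class NucleusState:
    """Simulator agent."""

    id: int
    position: np.ndarray
    radius_um: float
    phase: str  # "A" or "B"
    phase_clock_min: float
    cycle_length_min: float
    phaseA_duration_min: float
    cloud_origin: np.ndarray  # unit vector, nucleus center -> origin point on the surface
    parent_id: int | None
    rng: np.random.Generator = field(repr=False, default=None)


@dataclass
class CloudField:
    """Per-step partition of the cytoplasm into pulling clouds."""

    label: np.ndarray  # grid -> index into nucleus_ids, -1 unlabeled
    R_um: np.ndarray  # geodesic distance to the owning cloud's origin
    r_max_um: float
    nucleus_ids: list[int]
    origin_points_um: np.ndarray  # (k, 3)
    voxel_um: float


def _nucleus_rng(seed: int, nucleus_id: int) -> np.random.Generator:
    """Deterministic per-nucleus stream: divisions don't perturb unrelated draws."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(nucleus_id,)))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# cycle scheduling
# ---------------------------------------------------------------------------


def sample_cycle_length(
    local_density: float, config: SimConfig, rng: np.random.Generator
) -> float:
    """Lognormal cycle length with density-dependent mean (minutes)."""
    m = config.cycle.mean_at(local_density)
    sd = config.cycle.sd_at(local_density)
    floor = config.phaseA_bounds_min[0] + 2 * config.dt_min
    if sd == 0:
        return max(m, floor)
    sigma2 = np.log1p((sd / m) ** 2)
    mu_ln = np.log(m) - sigma2 / 2.0
    return max(float(rng.lognormal(mu_ln, np.sqrt(sigma2))), floor)


def sample_phaseA_duration(cycle_length_min: float, config: SimConfig) -> float:
    """Phase A lasts a clamped fraction of the cycle (default 0.6T in [20, 28] min)."""
    lo, hi = config.phaseA_bounds_min
    return float(np.clip(config.phaseA_frac * cycle_length_min, lo, hi))


# ---------------------------------------------------------------------------
# clouds & forces
# ---------------------------------------------------------------------------


def _blocked_mask(domain: EmbryoDomain, positions: np.ndarray, radius_um: float) -> np.ndarray:
    """Voxels whose center lies within ``radius_um`` of any nucleus center."""
    blocked = np.zeros(domain.grid_shape, dtype=bool)
    if len(positions) == 0:
        return blocked
    r_vox = int(np.ceil(radius_um / domain.voxel_um)) + 1
    shape = np.array(domain.grid_shape)
    for p in np.atleast_2d(positions):
        c = np.rint(domain.to_index(p)[0]).astype(int)
        lo = np.maximum(c - r_vox, 0)
        hi = np.minimum(c + r_vox + 1, shape)
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij")
        centers = domain.to_physical(np.stack([ii, jj, kk], axis=-1))
        d2 = np.sum((centers - p) ** 2, axis=-1)
        sub = blocked[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub |= d2 <= radius_um**2
        blocked[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return blocked


def _project_source(domain: EmbryoDomain, point: np.ndarray, blocked: np.ndarray) -> tuple[np.ndarray, bool]:
    """Nearest interior, non-blocked voxel center to a desired origin point."""
    ok_mask = domain.inside_mask & ~blocked
    c = np.rint(domain.to_index(point)[0]).astype(int)
    c = np.clip(c, 0, np.array(domain.grid_shape) - 1)
    if ok_mask[tuple(c)]:
        return domain.to_physical(c), False
    shape = np.array(domain.grid_shape)
    for r in range(1, max(domain.grid_shape)):
        lo = np.maximum(c - r, 0)
        hi = np.minimum(c + r + 1, shape)
        sub = ok_mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        if sub.any():
            cand = np.argwhere(sub) + lo
            centers = domain.to_physical(cand)
            best = cand[np.argmin(np.sum((centers - point) ** 2, axis=1))]
            return domain.to_physical(best), True
    raise ValidationError("no interior voxel available for a cloud origin")


def grow_clouds(
    domain: EmbryoDomain,
    nuclei: list[NucleusState],
    elapsedA_min: dict[int, float],
    config: SimConfig,
    events: list | None = None,
) -> CloudField:
    """Grow the pulling clouds of all Phase A nuclei with mutual occlusion.

    Fronts advance at ``r_max/tau_grow`` um/min from each cloud origin,
    blocked by the shell and by every nucleus body; clouds that entered
    Phase A earlier are proportionally larger (first-arrival labeling with
    per-source head starts).
    """
    phaseA = [n for n in nuclei if n.phase == "A"]
    positions = np.array([n.position for n in nuclei]) if nuclei else np.empty((0, 3))
    blocked = _blocked_mask(domain, positions, config.nucleus_radius_um)
    label = np.full(domain.grid_shape, -1, dtype=np.int64)
    R = np.full(domain.grid_shape, np.inf)
    if not phaseA:
        return CloudField(label, R, config.r_max_um, [], np.empty((0, 3)), domain.voxel_um)

    v_grow = config.r_max_um / config.tau_grow_min
    origins, radii, delays = [], [], []
    e_max = max(min(elapsedA_min[n.id], config.tau_grow_min) for n in phaseA)
    e_max = max(e_max, 1e-6)
    for n in phaseA:
        desired = n.position + n.radius_um * n.cloud_origin
        src, projected = _project_source(domain, desired, blocked)
        if projected and events is not None:
            events.append({"type": "origin_projected", "nucleus_id": n.id})
        origins.append(src)
        e = float(np.clip(elapsedA_min[n.id], 1e-6, config.tau_grow_min))
        radii.append(v_grow * e)
        delays.append(v_grow * (e_max - e))
    origins = np.array(origins)
    dist, lab = geodesic_distances(
        domain,
        origins,
        blocked=blocked,
        r_max_um=config.r_max_um,
        source_delays_um=delays if any(d > 0 for d in delays) else None,
    )
    # enforce each cloud's current radius
    radii = np.array(radii)
    labeled = lab >= 0
    over = labeled & (dist > radii[np.clip(lab, 0, None)])
    lab[over] = -1
    dist[over] = np.inf
    return CloudField(
        lab, dist, config.r_max_um, [n.id for n in phaseA], origins, domain.voxel_um
    )


def _cloud_boundary(field: CloudField, domain: EmbryoDomain) -> np.ndarray:
    """Voxels on the 6-connected boundary of their own cloud."""
    lab = field.label
    boundary = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(lab, shift, axis=axis)
            # rolled-in edge voxels are compared against themselves; edge voxels
            # of the grid are exterior anyway (the domain is padded)
            boundary |= (lab >= 0) & (rolled != lab)
    return boundary


def net_pull_force(
    voxel_centers_um: np.ndarray,
    R_um: np.ndarray,
    origin_um: np.ndarray,
    voxel_um: float,
    weighting: str = "volume",
    surface_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Net tug of a set of cloud voxels on an origin point.

    Each voxel pulls along the unit vector origin->voxel with magnitude
    ``w / R^2`` where ``w`` is the voxel volume (``weighting="volume"``) or
    the voxel face area for boundary voxels only (``weighting="surface"``).
    Voxels with ``R`` below one voxel are excluded (singularity guard).
    """
    pts = np.atleast_2d(voxel_centers_um)
    R = np.asarray(R_um, dtype=float)
    if len(pts) == 0:
        return np.zeros(3)
    keep = R >= voxel_um
    if weighting == "surface":
        if surface_mask is None:
            raise ValidationError("surface weighting requires surface_mask")
        keep = keep & surface_mask
        w = voxel_um**2
    else:
        w = voxel_um**3
    pts, R = pts[keep], R[keep]
    if len(pts) == 0:
        return np.zeros(3)
    vec = pts - origin_um
    norm = np.linalg.norm(vec, axis=1)
    ok = norm > 1e-9
    u = vec[ok] / norm[ok, None]
    return (u * (w / R[ok] ** 2)[:, None]).sum(axis=0)


def cloud_forces(field: CloudField, domain: EmbryoDomain, config: SimConfig) -> dict[int, np.ndarray]:
    """Net pulling force per Phase A nucleus from its cloud."""
    forces = {nid: np.zeros(3) for nid in field.nucleus_ids}
    if not field.nucleus_ids:
        return forces
    mask = field.label >= 0
    if not mask.any():
        return forces
    idx = np.argwhere(mask)
    centers = domain.to_physical(idx)
    owner = field.label[mask]
    R = field.R_um[mask]
    surface = _cloud_boundary(field, domain)[mask] if config.weighting == "surface" else None
    for k, nid in enumerate(field.nucleus_ids):
        sel = owner == k
        forces[nid] = net_pull_force(
            centers[sel],
            R[sel],
            field.origin_points_um[k],
            domain.voxel_um,
            weighting=config.weighting,
            surface_mask=None if surface is None else surface[sel],
        )
    return forces


# ---------------------------------------------------------------------------
# stepping, division, the run loop
# ---------------------------------------------------------------------------


def _clamp_inside(
    domain: EmbryoDomain, p: np.ndarray, radius_um: float, fallback: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Project a point to stay at least one nucleus radius inside the shell."""
    q = p.copy()
    for _ in range(8):
        d = float(domain.shell_distance_at(q)[0])
        if d >= radius_um and domain.contains(q)[0]:
            return q, not np.allclose(q, p)
        u = domain.inward_direction(q)[0]
        if np.linalg.norm(u) < 1e-9:
            break
        q = q + (radius_um - d + 0.25 * domain.voxel_um) * u
    return fallback.copy(), True


def step(
    nuclei: list[NucleusState],
    forces: dict[int, np.ndarray],
    config: SimConfig,
    domain: EmbryoDomain,
    mu: float,
    events: list | None = None,
) -> None:
    """Advance positions by one overdamped time step (in place).

    velocity = mu * force + bias, the bias pointing toward the nearest
    eggshell point.  Positions are clamped to remain one nucleus radius
    inside the shell; clamping is logged, never raised.
    """
    if not nuclei:
        return
    positions = np.array([n.position for n in nuclei])
    bias = config.bias_speed_um_min * domain.outward_direction(positions)
    for i, n in enumerate(nuclei):
        F = forces.get(n.id, np.zeros(3))
        vel = mu * config.force_sign * F + bias[i]
        new_p = n.position + vel * config.dt_min
        new_p, clamped = _clamp_inside(domain, new_p, n.radius_um, n.position)
        if clamped and events is not None:
            events.append({"type": "clamp", "nucleus_id": n.id})
        n.position = new_p


def divide(
    parent: NucleusState, config: SimConfig, local_density: float, next_id: int
) -> tuple[NucleusState, NucleusState]:
    """Split a nucleus into two daughters with antipodal cloud origins."""
    d = _random_unit(parent.rng)
    daughters = []
    for sign in (+1.0, -1.0):
        nid = next_id if sign > 0 else next_id + 1
        rng = _nucleus_rng(config.seed, nid)
        T = sample_cycle_length(local_density, config, rng)
        daughters.append(
            NucleusState(
                id=nid,
                position=parent.position + sign * parent.radius_um * d,
                radius_um=parent.radius_um,
                phase="A",
                phase_clock_min=0.0,
                cycle_length_min=T,
                phaseA_duration_min=sample_phaseA_duration(T, config),
                cloud_origin=sign * d,
                parent_id=parent.id,
                rng=rng,
            )
        )
    return daughters[0], daughters[1]


def _local_density_at(positions: np.ndarray, query: np.ndarray, radius_um: float) -> np.ndarray:
    """Count of nuclei (excluding self-coincident points) within radius of each query."""
    if len(positions) == 0:
        return np.zeros(len(np.atleast_2d(query)))
    tree = cKDTree(np.atleast_2d(positions))
    n = tree.query_ball_point(np.atleast_2d(query), radius_um, return_length=True)
    return n - 1  # each query is itself a nucleus position


def _init_nuclei(config: SimConfig, domain: EmbryoDomain) -> list[NucleusState]:
    frac = (
        config.start_position_frac
        if config.start_position_frac is not None
        else config.shape.first_division_frac
    )
    center = np.array([frac * config.shape.length_um, 0.0, 0.0])
    center, _ = _clamp_inside(domain, center, config.nucleus_radius_um, center)
    placement_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xB1A57,))
    )
    nuclei = []
    positions = []
    for nid in range(config.n_start):
        p = center + config.start_spread_um * (placement_rng.random(3) * 2 - 1)
        p, _ = _clamp_inside(domain, p, config.nucleus_radius_um, center)
        positions.append(p)
    dens = _local_density_at(np.array(positions), np.array(positions), config.r_max_um)
    for nid in range(config.n_start):
        rng = _nucleus_rng(config.seed, nid)
        T = sample_cycle_length(float(dens[nid]), config, rng)
        nuclei.append(
            NucleusState(
                id=nid,
                position=positions[nid],
                radius_um=config.nucleus_radius_um,
                phase="A",
                phase_clock_min=0.0,
                cycle_length_min=T,
                phaseA_duration_min=sample_phaseA_duration(T, config),
                cloud_origin=_random_unit(rng),
                parent_id=None,
                rng=rng,
            )
        )
    return nuclei


def calibrate_mobility(
    config: SimConfig,
    domain: EmbryoDomain | None = None,
    pilot_t_min: float = 40.0,
    tol: float = 0.02,
    max_iter: int = 20,
) -> float:
    """Bisect the mobility so the 99th-percentile Phase A pilot speed matches
    ``target_max_speed_um_min`` within ``tol`` (relative).

    Deterministic given the config seed.  Raises :class:`ValidationError`
    with diagnostics if a bracket cannot be established.
    """
    if domain is None:
        domain = build_domain(config.shape, config.voxel_um)
    pilot_cfg = dataclasses.replace(config, t_end_min=pilot_t_min, n_end=None)
    target = config.target_max_speed_um_min

    def p99(mu: float) -> float:
        _, diag = _simulate(pilot_cfg, mu, domain)
        sp = diag["phaseA_speeds"]
        if len(sp) == 0:
            raise ValidationError("pilot run produced no Phase A movements")
        return float(np.percentile(sp, 99))

    mu = 1.0
    f = p99(mu)
    # establish a bracket [lo, hi] with f(lo) < target < f(hi)
    grow = 0
    while f < target and grow < max_iter:
        mu *= 2 ** max(1, int(np.log2(max(target / max(f, 1e-9), 2.0))))
        f = p99(mu)
        grow += 1
    if f < target:
        raise ValidationError(
            f"calibration could not bracket the target: p99={f:.3g} < target={target} at mu={mu:.3g}"
        )
    hi, f_hi = mu, f
    lo = 0.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        f_mid = p99(mid)
        if abs(f_mid - target) / target <= tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _simulate(
    config: SimConfig,
    mu: float,
    domain: EmbryoDomain,
    force_provider=None,
) -> tuple[TrackTable, dict]:
    """Shared frame loop for the pulling/pushing/repulsion models."""
    nuclei = _init_nuclei(config, domain)
    rows = []
    events: list[dict] = []
    phaseA_speeds: list[float] = []
    f = 0
    while True:
        t = f * config.dt_min
        for n in sorted(nuclei, key=lambda n: n.id):
            rows.append((n.id, n.parent_id, f, t, *n.position))
        count = len(nuclei)
        if config.n_end is not None and count >= config.n_end:
            break
        if config.t_end_min is not None and t >= config.t_end_min:
            break

        if force_provider is None:
            elapsedA = {n.id: n.phase_clock_min for n in nuclei if n.phase == "A"}
            fld = grow_clouds(domain, nuclei, elapsedA, config, events)
            forces = cloud_forces(fld, domain, config)
        else:
            forces = force_provider(nuclei, domain, config)

        prev = {n.id: n.position.copy() for n in nuclei}
        was_A = {n.id for n in nuclei if n.phase == "A"}
        step(nuclei, forces, config, domain, mu, events)
        for n in nuclei:
            if n.id in was_A:
                phaseA_speeds.append(
                    float(np.linalg.norm(n.position - prev[n.id]) / config.dt_min)
                )

        # clocks, phase transitions, divisions
        to_divide = []
        for n in nuclei:
            n.phase_clock_min += config.dt_min
            if n.phase == "A" and n.phase_clock_min >= n.phaseA_duration_min:
                n.phase = "B"
            if n.phase_clock_min >= n.cycle_length_min:
                to_divide.append(n)
        if to_divide:
            positions = np.array([m.position for m in nuclei])
            next_id = max(m.id for m in nuclei) + 1
            for n in sorted(to_divide, key=lambda m: m.id):
                rho = float(_local_density_at(positions, n.position, config.r_max_um)[0])
                d1, d2 = divide(n, config, rho, next_id)
                for dgt in (d1, d2):
                    dgt.position, _ = _clamp_inside(
                        domain, dgt.position, dgt.radius_um, n.position
                    )
                next_id += 2
                nuclei.remove(n)
                nuclei.extend([d1, d2])
                events.append(
                    {
                        "type": "division",
                        "t_min": t + config.dt_min,
                        "parent_id": n.id,
                        "daughter_ids": [d1.id, d2.id],
                    }
                )
        f += 1

    df = pd.DataFrame(
        rows, columns=["nucleus_id", "parent_id", "frame", "t_min", "x_um", "y_um", "z_um"]
    )
    table = TrackTable(df, frame_interval_min=config.dt_min)
    table.meta = {"events": events, "mu": mu, "model": "pulling" if force_provider is None else "custom"}
    return table, {"phaseA_speeds": np.array(phaseA_speeds), "events": events}


def run_simulation(config: SimConfig, domain: EmbryoDomain | None = None) -> TrackTable:
    """Run the pulling-cloud model and return the nuclear track table.

    Builds the voxel domain (reusable via ``domain``), calibrates the
    mobility if ``config.mu`` is None, then iterates
    grow -> force -> step -> schedule -> divide until ``t_end``/``n_end``.
    Fully reproducible given the config seed.
    """
    if domain is None:
        domain = build_domain(config.shape, config.voxel_um)
    mu = config.mu if config.mu is not None else calibrate_mobility(config, domain)
    table, _ = _simulate(config, mu, domain)
    return table
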