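"""Rejected comparator models, run under the same stepping harness.

Two alternatives to the asymmetric pulling clouds:

* **Mutual repulsion** — soft pairwise repulsion among nuclei (exponential
  decay by default, power-law optional).  Because repulsion grows with
  crowding, an isolated nucleus moves at its *slowest* (bias only) — the
  inverse of the empirically observed speed-density relationship, which is
  the substance of the negative result.
* **Asymmetric pushing** — the pulling-cloud force with its sign reversed:
  nuclei are pushed away from their cloud origin's cloud, so they move
  *away* from nearby open space.

Both emit the same track tables as the pulling model, so every metric
applies unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry import EmbryoDomain, build_domain
from .pulling import NucleusState, SimConfig, _simulate, calibrate_mobility
from .tracks import TrackTable


@dataclass(frozen=True)
class RepulsionConfig:
    """Pairwise repulsion parameters wrapped around a shared :class:`SimConfig`.

    The kernel is ``w(r) = exp(-r/lambda)`` (``form="exponential"``) or
    ``w(r) = r**-exponent`` (``form="power"``), truncated at ``cutoff_um``.
    """

    sim: SimConfig
    strength: float = 1.0
    lambda_um: float = 50.0
    form: str = "exponential"
    exponent: float = 2.0
    cutoff_um: float = 150.0

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValidationError(f"strength must be positive, got {self.strength}")
        if self.lambda_um <= 0:
            raise ValidationError(f"lambda_um must be positive, got {self.lambda_um}")
        if self.form not in ("exponential", "power"):
            raise ValidationError(f"form must be exponential|power, got {self.form!r}")
        if self.exponent <= 0:
            raise ValidationError(f"exponent must be positive, got {self.exponent}")
        if self.cutoff_um < self.lambda_um:
            raise ValidationError("cutoff_um must be >= lambda_um")


def repulsion_force(
    positions: np.ndarray,
    config: RepulsionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pairwise equal-and-opposite repulsive forces (one row per nucleus).

    Coincident nuclei are separated by a random 0.1-um jitter before the
    kernel is evaluated.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
    n = len(pts)
    F = np.zeros((n, 3))
    if n < 2:
        return F
    tree = cKDTree(pts)
    pairs = tree.query_pairs(config.cutoff_um, output_type="ndarray")
    if len(pairs) == 0:
        return F
    i, j = pairs[:, 0], pairs[:, 1]
    vec = pts[i] - pts[j]
    r = np.linalg.norm(vec, axis=1)
    coincident = r < 1e-9
    if coincident.any():
        if rng is None:
            rng = np.random.default_rng(0)
        jit = rng.standard_normal((coincident.sum(), 3))
        jit = 0.1 * jit / np.linalg.norm(jit, axis=1, keepdims=True)
        vec[coincident] = jit
        r[coincident] = 0.1
    u = vec / r[:, None]
    if config.form == "exponential":
        w = np.exp(-r / config.lambda_um)
    else:
        w = r ** (-config.exponent)
    fpair = config.strength * w[:, None] * u  # force on i, away from j
    np.add.at(F, i, fpair)
    np.add.at(F, j, -fpair)
    return F


def run_repulsion(config: RepulsionConfig, domain: EmbryoDomain | None = None) -> TrackTable:
    """Run the mutual-repulsion comparator.

    The repulsive force is active during Phase A (mirroring the pulling
    model's cloud-present state); the periplasm bias acts in both phases.
    The mobility defaults to 1 unless set on the wrapped SimConfig.
    """
    sim = config.sim
    if domain is None:
        domain = build_domain(sim.shape, sim.voxel_um)

    def provider(nuclei: list[NucleusState], dom, cfg) -> dict[int, np.ndarray]:
        pts = np.array([n.position for n in nuclei])
        F = repulsion_force(pts, config)
        return {n.id: F[k] if n.phase == "A" else np.zeros(3) for k, n in enumerate(nuclei)}

    mu = sim.mu if sim.mu is not None else 1.0
    table, _ = _simulate(sim, mu, domain, force_provider=provider)
    table.meta["model"] = "repulsion"
    return table


def run_pushing(config: SimConfig, domain: EmbryoDomain | None = None) -> TrackTable:
    """Run the asymmetric pushing comparator (pulling clouds, sign reversed)."""
    cfg = dataclasses.replace(config, force_sign=-1.0)
    if domain is None:
        domain = build_domain(cfg.shape, cfg.voxel_um)
    mu = cfg.mu
    if mu is None:
        # calibrate the magnitude on the pulling force, then flip the sign
        mu = calibrate_mobility(dataclasses.replace(cfg, force_sign=1.0), domain)
    table, _ = _simulate(dataclasses.replace(cfg, mu=mu), mu, domain)
    table.meta["model"] = "pushing"
    return table
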