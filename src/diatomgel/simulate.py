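"""Synthetic-data generators for the gel-entrapment analysis pipeline.

Every downstream stage (indentation fitting, particle-tracking strain maps,
single-cell event statistics, colony statistics) can be exercised on data
from this module with known ground truth:

* load-and-hold indentation force curves: Hertz loading at constant rate plus
  a double-exponential relaxation hold, with additive Gaussian force noise;
* fluorescent tracer-bead image stacks advected by an incompressible
  expanding-sphere displacement field around a growing inclusion (the
  closed-form stand-in for the deformation a dividing cell imposes on the
  gel), rendered at the confocal geometry of 512 x 512 px over 500 um;
* single-cell division-event tables with concentration-dependent transition
  times, expansions and viabilities;
* colony time series from a stochastic birth process with carrying capacity
  and a constant death hazard.

All draws come from one seeded :class:`numpy.random.Generator` per call;
sub-streams are derived from ``SimConfig.seed`` with fixed offsets, so a
fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .growth import (
    GrowthParams,
    colony_capacity_mean,
    colony_capacity_sigma,
    colony_death_hazard,
    division_time,
    expansion_fraction,
    packing_exponent,
    transition_viability,
)
from .indentation import IndentationCurve, hertz_force

__all__ = [
    "SimConfig",
    "CavityField",
    "cavity_displacement",
    "gen_indentation_curve",
    "gen_bead_stack",
    "gen_cell_events",
    "gen_colony_series",
]

# fixed sub-stream offsets, one per generator
_STREAM_INDENT = 1
_STREAM_BEADS = 2
_STREAM_CELLS = 3
_STREAM_COLONIES = 4


@dataclass
class SimConfig:
    """Shared simulation settings.

    px_size defaults to the confocal calibration of 500 um across 512 px;
    noise_sd_force is relative to the peak force of the generated curve.
    """

    seed: int = 0
    noise_sd_force: float = 0.01
    bead_density: float = 0.008  # beads per um^2 of frame area
    px_size: float = 500.0 / 512.0  # um per pixel
    frame_interval: float = 3.0  # minutes between frames

    def __post_init__(self):
        if self.noise_sd_force < 0:
            raise ValueError("noise_sd_force must be >= 0")
        if self.px_size <= 0:
            raise ValueError("px_size must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _linear_ramp(frac: float) -> float:
    return min(max(frac, 0.0), 1.0)


@dataclass
class CavityField:
    """Incompressible expanding-sphere displacement field.

    An inclusion of initial radius ``a0`` expands to ``a1``; conserving gel
    volume, a material point at radius r moves to ``(r^3 + a^3 - a0^3)^(1/3)``
    once the inclusion has reached radius ``a``.  ``ramp`` maps the elapsed
    fraction of the schedule in [0, 1] to the completed fraction of the
    expansion (default: linear).
    """

    a0: float
    a1: float
    center: tuple[float, float] = (250.0, 250.0)  # um
    ramp: Callable[[float], float] = field(default=_linear_ramp)

    def __post_init__(self):
        if not (self.a1 >= self.a0 > 0):
            raise ValueError("need a1 >= a0 > 0")

    def radius_at(self, frac: float) -> float:
        """Inclusion radius at elapsed fraction ``frac`` of the schedule."""
        return self.a0 + (self.a1 - self.a0) * self.ramp(frac)

    def displace(self, points: np.ndarray, a_now: float) -> np.ndarray:
        """Advect material points (n, 2) um by the field at inclusion radius
        ``a_now``; returns the displaced positions."""
        rel = points - np.asarray(self.center)
        r = np.hypot(rel[:, 0], rel[:, 1])
        u = cavity_displacement(r, self.a0, a_now)
        with np.errstate(invalid="ignore"):
            unit = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-300)[:, None], 0.0)
        return points + u[:, None] * unit


def cavity_displacement(r, a0: float, a1: float):
    """Radial displacement u_r (um) of a gel point at radius r when an
    incompressible spherical inclusion expands from a0 to a1.

    u_r = (r^3 + a1^3 - a0^3)^(1/3) - r; the boundary point moves with the
    inclusion wall and u_r decays as (a/r)^2 far away.
    """
    if not (a1 >= a0 > 0):
        raise ValueError("need a1 >= a0 > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < a0 * (1 - 1e-12)):
        raise ValueError("point inside the initial inclusion (r < a0)")
    out = np.cbrt(r**3 + a1**3 - a0**3) - r
    return float(out) if out.ndim == 0 else out


def gen_indentation_curve(
    E0_star: float,
    Einf_star: float,
    tau1: float = 99.0,
    tau2: float = 1644.0,
    R: float = 1.565,
    rate: float = 0.01,
    d_max: float = 1.0,
    hold: float = 3600.0,
    cfg: SimConfig | None = None,
    dt_load: float = 0.5,
    dt_hold: float = 1.0,
    amp_split: float = 0.5,
) -> IndentationCurve:
    """Synthesize a load-and-hold indentation test.

    The ramp loads at constant ``rate`` following Hertz's law with modulus
    ``E0_star``; the hold relaxes as a double exponential whose residual force
    corresponds to ``Einf_star`` via Hertz at ``d_max``.  ``amp_split`` is the
    fraction of the relaxing amplitude assigned to the fast exponential
    (default 0.5, keeping both exponentials identifiable).  Gaussian noise of
    sd = ``cfg.noise_sd_force`` x peak force is added to every sample.

    Default relaxation times mirror measured agar-gel values (~99 s, ~1644 s);
    default geometry is a 3.13 mm-diameter sphere, 0.01 mm/s ramp to 1 mm,
    3600 s hold.
    """
    cfg = cfg or SimConfig()
    if not (E0_star >= Einf_star > 0):
        raise ValueError("need E0_star >= Einf_star > 0")
    if not (tau2 > tau1 > 0):
        raise ValueError("need tau2 > tau1 > 0")
    if d_max <= 0 or hold < 0 or rate <= 0:
        raise ValueError("d_max and rate must be > 0, hold >= 0")

    t_ramp = d_max / rate
    t_load = np.arange(0.0, t_ramp, dt_load)
    d_load = rate * t_load
    F_load = hertz_force(d_load, E0_star, R)

    t_hold = np.arange(0.0, hold + dt_hold / 2, dt_hold)
    F_peak = hertz_force(d_max, E0_star, R)
    F_inf = hertz_force(d_max, Einf_star, R)
    amp = F_peak - F_inf
    F1, F2 = amp_split * amp, (1.0 - amp_split) * amp
    F_hold = F_inf + F1 * np.exp(-t_hold / tau1) + F2 * np.exp(-t_hold / tau2)

    t = np.concatenate([t_load, t_ramp + t_hold])
    d = np.concatenate([d_load, np.full_like(t_hold, d_max)])
    F = np.concatenate([F_load, F_hold])
    if cfg.noise_sd_force > 0:
        F = F + cfg.rng(_STREAM_INDENT).normal(0.0, cfg.noise_sd_force * F_peak, F.size)
    return IndentationCurve(t=t, d=d, F=F, R=R, rate=rate, d_max=d_max)


# -- bead stacks -------------------------------------------------------------

def _seed_beads(rng, n_beads, extent_um, center, a0, min_sep_um, margin_um=1.0,
                max_tries=400):
    """Uniform bead positions outside the inclusion with a minimum spacing.

    Sequential rejection sampling against a cell list (bin size = the minimum
    separation), so each candidate checks only its 3x3 neighbourhood.
    """
    cell = max(min_sep_um, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    placed = np.empty((n_beads, 2))
    count = 0
    for _ in range(max_tries):
        if count >= n_beads:
            break
        cand = rng.uniform([0.0, 0.0], extent_um, size=(2 * (n_beads - count) + 16, 2))
        r = np.hypot(cand[:, 0] - center[0], cand[:, 1] - center[1])
        cand = cand[r >= a0 + margin_um]
        for p in cand:
            if count >= n_beads:
                break
            cx, cy = int(p[0] // cell), int(p[1] // cell)
            ok = True
            for nx in (cx - 1, cx, cx + 1):
                for ny in (cy - 1, cy, cy + 1):
                    for i in grid.get((nx, ny), ()):
                        if np.hypot(*(placed[i] - p)) < min_sep_um:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                placed[count] = p
                grid.setdefault((cx, cy), []).append(count)
                count += 1
    if count < n_beads:
        raise RuntimeError(
            f"could only place {count}/{n_beads} beads at min separation "
            f"{min_sep_um} um; lower the density or the separation")
    return placed


def _render_spots(shape, pos_px, sigma_px, amplitude):
    """Additively render Gaussian spots (x, y) px into a float image."""
    img = np.zeros(shape, dtype=float)
    h, w = shape
    half = int(math.ceil(4 * sigma_px))
    for x, y in pos_px:
        c0, r0 = int(round(x)), int(round(y))
        rows = np.arange(max(r0 - half, 0), min(r0 + half + 1, h))
        cols = np.arange(max(c0 - half, 0), min(c0 + half + 1, w))
        if rows.size == 0 or cols.size == 0:
            continue
        gy = np.exp(-((rows - y) ** 2) / (2 * sigma_px**2))
        gx = np.exp(-((cols - x) ** 2) / (2 * sigma_px**2))
        img[np.ix_(rows, cols)] += amplitude * gy[:, None] * gx[None, :]
    return img


def gen_bead_stack(
    fieldspec: CavityField,
    cfg: SimConfig | None = None,
    n_frames: int = 20,
    image_shape: tuple[int, int] = (512, 512),
    n_beads: int | None = None,
    min_sep_px: float = 6.0,
    spot_sigma_px: float = 1.2,
    amplitude: float = 8000.0,
    background: float = 100.0,
    read_noise: float = 0.0,
):
    """Render a tracer-bead stack advected by an expanding-inclusion field.

    Beads are seeded uniformly outside the inclusion, advected by
    :func:`cavity_displacement` at each frame's inclusion radius (linear
    ramp a0 -> a1 by default), and rendered as 2D Gaussian spots
    (sd 1.2 px) into a 16-bit stack with optional Gaussian read noise.

    Returns ``(stack, truth)`` where ``stack`` is uint16 of shape
    (n_frames, H, W) and ``truth`` is the exact ground-truth trajectory table
    with columns ``track_id, frame, x_um, y_um`` (image convention: x along
    columns, y along rows, origin at the top-left pixel centre).
    """
    cfg = cfg or SimConfig()
    h, w = image_shape
    extent = (w * cfg.px_size, h * cfg.px_size)
    if n_beads is None:
        n_beads = int(round(cfg.bead_density * extent[0] * extent[1]))
    if n_beads <= 0:
        raise ValueError("n_beads must be >= 1 (empty stack requested)")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = cfg.rng(_STREAM_BEADS)
    pos0 = _seed_beads(rng, n_beads, extent, fieldspec.center, fieldspec.a0,
                       min_sep_um=min_sep_px * cfg.px_size)

    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    rows = []
    for k in range(n_frames):
        frac = k / (n_frames - 1) if n_frames > 1 else 1.0
        pos = fieldspec.displace(pos0, fieldspec.radius_at(frac))
        img = background + _render_spots((h, w), pos / cfg.px_size, spot_sigma_px,
                                         amplitude)
        if read_noise > 0:
            img = img + rng.normal(0.0, read_noise, img.shape)
        stack[k] = np.clip(img, 0, 65535).astype(np.uint16)
        rows.append(pd.DataFrame({
            "track_id": np.arange(n_beads),
            "frame": k,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
        }))
    truth = pd.concat(rows, ignore_index=True)
    return stack, truth


# -- single-cell division events ---------------------------------------------

def _lognormal_about(rng, mean, sigma, size):
    """Lognormal draws with the requested arithmetic mean and shape sigma."""
    if sigma == 0:
        return np.full(size, mean)
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size)


def gen_cell_events(
    params: GrowthParams | None = None,
    phi: float = 1.0,
    n_cells: int = 50,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate single entrapped cells through the three division transitions.

    Per cell: an initial size ``l0`` uniform on the configured range; Bernoulli
    survival of each transition with the conditional probabilities implied by
    the cumulative viability law; transition durations lognormal about
    ``division_time(phi)`` times the per-transition multiplier; a relative
    expansion drawn about ``expansion_fraction(phi)`` for cells completing the
    first transition.

    Returns a table with columns ``cell_id, l0_um, reached_p1, reached_mit,
    reached_p2, t_p1_h, t_mit_h, t_p2_h, dl_rel`` (times cumulative from
    entrapment, NaN where a transition was not reached).
    """
    params = params or GrowthParams()
    cfg = cfg or SimConfig()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    rng = cfg.rng(_STREAM_CELLS)

    l0 = rng.uniform(*params.l0_range, n_cells)
    v = np.array(transition_viability(phi, None, params))
    # conditional pass probabilities from the cumulative fractions
    cond = np.ones(3)
    cond[0] = v[0]
    cond[1] = v[1] / v[0] if v[0] > 0 else 0.0
    cond[2] = v[2] / v[1] if v[1] > 0 else 0.0

    t_mean = division_time(phi, params)
    reached = np.zeros((n_cells, 3), dtype=bool)
    times = np.full((n_cells, 3), np.nan)
    alive = np.ones(n_cells, dtype=bool)
    clock = np.zeros(n_cells)
    for k in range(3):
        passed = alive & (rng.uniform(size=n_cells) < cond[k])
        if math.isfinite(t_mean):
            dur = _lognormal_about(rng, t_mean * params.transition_time_multipliers[k],
                                   params.division_time_sigma, n_cells)
            clock = clock + dur
            times[passed, k] = clock[passed]
        reached[:, k] = passed
        alive = passed

    dl = np.full(n_cells, np.nan)
    done1 = reached[:, 0]
    if done1.any():
        draw = rng.normal(expansion_fraction(phi, params), params.expansion_sd,
                          n_cells)
        dl[done1] = np.clip(draw[done1], 0.0, None)

    return pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "l0_um": l0,
        "reached_p1": reached[:, 0],
        "reached_mit": reached[:, 1],
        "reached_p2": reached[:, 2],
        "t_p1_h": times[:, 0],
        "t_mit_h": times[:, 1],
        "t_p2_h": times[:, 2],
        "dl_rel": dl,
    })


# -- colony time series -------------------------------------------------------

def gen_colony_series(
    params: GrowthParams | None = None,
    phi: float = 0.5,
    n_colonies: int = 60,
    t_grid: np.ndarray | list[float] = (0, 3, 7, 14, 21),
    cfg: SimConfig | None = None,
    capacity_cap: int = 500,
) -> pd.DataFrame:
    """Simulate colony growth records on a day grid.

    Each colony starts from one cell at day 0 and grows as a stochastic birth
    (Yule) process with exponential per-cell division intervals of mean
    ``division_time(phi)``, saturating at a carrying capacity drawn lognormal
    about the calibrated mean.  A constant per-colony death hazard kills whole
    colonies (all fluorescence lost, size frozen); while alive, the number of
    viable cells is binomial with the calibrated per-cell viability,
    conditioned on at least one viable cell (the aliveness criterion).  Colony
    size follows the packing rule ``l/l0 = n_cells**p(phi)``.

    Returns a long table: ``colony_id, phi, day, n_cells, n_viable, alive,
    l_um, l0_um``.
    """
    params = params or GrowthParams()
    cfg = cfg or SimConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 1 or np.any(np.diff(t_grid) <= 0) or t_grid[0] != 0:
        raise ValueError("t_grid must be increasing and start at day 0")
    rng = cfg.rng(_STREAM_COLONIES)

    l0 = rng.uniform(*params.l0_range, n_colonies)
    sigma = colony_capacity_sigma(phi, params)
    cap = _lognormal_about(rng, colony_capacity_mean(phi, params), sigma, n_colonies)
    cap = np.clip(np.round(cap), 1, capacity_cap).astype(int)

    lam = colony_death_hazard(phi, params)
    death = rng.exponential(1.0 / lam, n_colonies) if lam > 0 else np.full(n_colonies, np.inf)

    t_div_days = division_time(phi, params) / 24.0
    kmax = int(cap.max())
    if math.isfinite(t_div_days) and kmax > 1:
        # Yule process: waiting time from n to n+1 cells ~ Exp(mean t_div / n)
        waits = rng.exponential(t_div_days, size=(n_colonies, kmax - 1))
        waits /= np.arange(1, kmax)[None, :]
        birth_times = np.cumsum(waits, axis=1)
        # mask divisions beyond each colony's capacity
        birth_times[np.arange(1, kmax)[None, :] >= cap[:, None]] = np.inf
    else:
        birth_times = np.full((n_colonies, max(kmax - 1, 1)), np.inf)

    p_viab = params.viable_cell_p
    rows = []
    for day in t_grid:
        alive = death > day
        t_eff = np.minimum(day, death)  # growth freezes at colony death
        n_cells = 1 + (birth_times <= t_eff[:, None]).sum(axis=1)
        # binomial viable count, conditioned >= 1 while the colony is alive
        n_viable = rng.binomial(n_cells, p_viab)
        redo = alive & (n_viable == 0)
        while redo.any():
            n_viable[redo] = rng.binomial(n_cells[redo], p_viab)
            redo = alive & (n_viable == 0)
        n_viable[~alive] = 0
        ratio = n_cells.astype(float) ** packing_exponent(phi, params)
        rows.append(pd.DataFrame({
            "colony_id": np.arange(n_colonies),
            "phi": phi,
            "day": day,
            "n_cells": n_cells,
            "n_viable": n_viable,
            "alive": alive,
            "l_um": l0 * ratio,
            "l0_um": l0,
        }))
    return pd.concat(rows, ignore_index=True)
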