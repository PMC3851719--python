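"""Overdamped Langevin pulling simulator with exact work bookkeeping.

Each replica follows Euler–Maruyama dynamics on the toy landscape while a
harmonic restraint of stiffness k is dragged at constant velocity:

    x  <-  x - βD ∇[U(x) + V(x, λ)] dt + sqrt(2 D dt) η,   η ~ N(0, 1)

Mechanical work is accumulated by the potential-difference convention: each
time the restraint center advances from λ_t to λ_{t+1} the increment
``V(x_t, λ_{t+1}) - V(x_t, λ_t)`` is added *before* the particle relaxes.
With this convention the discrete-time Jarzynski identity applies to the
simulated process up to integrator discretization error.

Initial positions are independent draws from the λ0-restrained Boltzmann
density (rejection sampling under the stiff trap), mimicking starting points
extracted from a long restrained equilibration.  Replica i of an ensemble
uses seed ``base_seed + i``; a (landscape, protocol, seed) triple fully
determines every emitted number.

The inner loop is JIT-compiled with numba when available and falls back to
the identical pure-Python code path otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kt
from .errors import IntegrationError, ShapeError
from .landscape import GaussianWell, RectWell, ToyLandscape
from .protocol import PullingProtocol

__all__ = ["WorkTrajectory", "WorkEnsemble", "simulate_trajectory", "simulate_ensemble"]

_GAUSS, _RECT = 0, 1


def _encode_wells(landscape: ToyLandscape) -> tuple[np.ndarray, np.ndarray]:
    types = np.empty(len(landscape.wells), dtype=np.int64)
    params = np.zeros((len(landscape.wells), 4))
    for i, w in enumerate(landscape.wells):
        if isinstance(w, GaussianWell):
            types[i] = _GAUSS
            params[i, :3] = (w.center, w.depth, w.width)
        elif isinstance(w, RectWell):
            types[i] = _RECT
            a, b = w.edges
            params[i] = (a, b, w.depth, w.softness)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown well type {type(w)!r}")
    return types, params


def _integrate_py(x0, lam0, v, dt, n_steps, k, beta, diff, noise,
                  well_types, well_params, frame_steps):
    """Sequential EM integration; returns (x_frames, w_frames, bad_step)."""
    sqrt2ddt = np.sqrt(2.0 * diff * dt)
    bdt = beta * diff * dt
    n_frames = frame_steps.shape[0]
    x_frames = np.empty(n_frames)
    w_frames = np.empty(n_frames)
    x = x0
    w = 0.0
    fi = 0
    if frame_steps[0] == 0:
        x_frames[0] = x
        w_frames[0] = 0.0
        fi = 1
    for j in range(n_steps):
        lam_cur = lam0 + v * j * dt
        lam_new = lam0 + v * (j + 1) * dt
        # work for advancing the restraint at frozen x
        w += 0.5 * k * ((x - lam_new) ** 2 - (x - lam_cur) ** 2)
        # total force at (x, lam_new)
        g = k * (x - lam_new)
        for m in range(well_types.shape[0]):
            if well_types[m] == 0:
                c = well_params[m, 0]
                d = well_params[m, 1]
                wd = well_params[m, 2]
                z = (x - c) / wd
                g += d * (x - c) / (wd * wd) * np.exp(-0.5 * z * z)
            else:
                a = well_params[m, 0]
                b = well_params[m, 1]
                d = well_params[m, 2]
                s = well_params[m, 3]
                ca = np.cosh((x - a) / s)
                cb = np.cosh((x - b) / s)
                g += -0.5 * d / s * (1.0 / (ca * ca) - 1.0 / (cb * cb))
        x = x - bdt * g + sqrt2ddt * noise[j]
        if not np.isfinite(x):
            return x_frames, w_frames, j + 1
        if fi < n_frames and j + 1 == frame_steps[fi]:
            x_frames[fi] = x
            w_frames[fi] = w
            fi += 1
    return x_frames, w_frames, -1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _integrate = njit(cache=True, fastmath=False)(_integrate_py)
except ImportError:  # pragma: no cover
    _integrate = _integrate_py


@dataclass(frozen=True)
class WorkTrajectory:
    """Single pulling replica on a recorded frame grid.

    All series share one length; ``work[0] == 0`` and ``lam`` follows the
    protocol schedule exactly.
    """

    time: np.ndarray       # ps
    position: np.ndarray   # nm
    lam: np.ndarray        # nm, restraint center
    work: np.ndarray | None    # kJ/mol accumulated; None when not recorded
    nhb: np.ndarray | None     # discrete H-bond count; None when not recorded
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("position", "lam", "work", "nhb"):
            s = getattr(self, name)
            if s is not None and len(s) != n:
                raise ShapeError(f"series {name!r} has length {len(s)}, expected {n}")
        if self.work is not None and n and self.work[0] != 0.0:
            raise ShapeError("accumulated work must start at exactly 0")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class WorkEnsemble:
    """N independent replicas on an identical time grid and λ schedule."""

    trajectories: tuple[WorkTrajectory, ...]
    landscape: ToyLandscape | None = None
    protocol: PullingProtocol | None = None
    base_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        if not self.trajectories:
            raise ShapeError("ensemble must contain at least one trajectory")
        t0 = self.trajectories[0]
        for i, tr in enumerate(self.trajectories[1:], start=1):
            if len(tr) != len(t0) or not np.allclose(tr.time, t0.time):
                raise ShapeError(f"replica {i} is not on the shared time grid")
            if not np.allclose(tr.lam, t0.lam):
                raise ShapeError(f"replica {i} has a different λ schedule")

    @property
    def n_replicas(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return len(self.trajectories[0])

    @property
    def time(self) -> np.ndarray:
        return self.trajectories[0].time

    @property
    def lam(self) -> np.ndarray:
        return self.trajectories[0].lam

    def position_matrix(self) -> np.ndarray:
        """(N, T) matrix of steered-CV positions."""
        return np.stack([tr.position for tr in self.trajectories])

    def work_matrix(self) -> np.ndarray:
        """(N, T) matrix of accumulated work; raises if any replica lacks it."""
        cols = []
        for i, tr in enumerate(self.trajectories):
            if tr.work is None:
                raise ShapeError(f"replica {i} has no recorded work series")
            cols.append(tr.work)
        return np.stack(cols)

    def nhb_matrix(self) -> np.ndarray:
        cols = []
        for i, tr in enumerate(self.trajectories):
            if tr.nhb is None:
                raise ShapeError(f"replica {i} has no recorded H-bond counts")
            cols.append(tr.nhb)
        return np.stack(cols)


def _sample_initial(landscape: ToyLandscape, protocol: PullingProtocol,
                    rng: np.random.Generator) -> float:
    """Rejection-sample x0 from the λ0-restrained Boltzmann density."""
    kbt = protocol.kbt
    beta = 1.0 / kbt
    sigma = np.sqrt(kbt / protocol.spring_constant)
    lam0 = protocol.lambda_start
    grid = np.linspace(lam0 - 8 * sigma, lam0 + 8 * sigma, 513)
    u_floor = float(np.min(landscape.energy(grid)))
    for _ in range(10_000):
        xs = rng.normal(lam0, sigma, size=256)
        acc = rng.random(256) < np.exp(-beta * (landscape.energy(xs) - u_floor))
        hits = np.nonzero(acc)[0]
        if hits.size:
            return float(xs[hits[0]])
    raise IntegrationError("initial-condition rejection sampling did not accept")


def simulate_trajectory(landscape: ToyLandscape, protocol: PullingProtocol,
                        seed: int) -> WorkTrajectory:
    """Run one pulling replica; fully determined by (landscape, protocol, seed)."""
    rng = np.random.default_rng(seed)
    x0 = _sample_initial(landscape, protocol, rng)
    noise = rng.standard_normal(protocol.n_steps)
    types, params = _encode_wells(landscape)
    frame_steps = protocol.frame_steps()
    x_frames, w_frames, bad = _integrate(
        x0, protocol.lambda_start, protocol.velocity, protocol.dt,
        protocol.n_steps, protocol.spring_constant, 1.0 / protocol.kbt,
        protocol.diffusion, noise, types, params, frame_steps,
    )
    if bad >= 0:
        raise IntegrationError(
            f"non-finite position at integration step {bad} (seed {seed}); "
            f"reduce dt or soften the landscape"
        )
    lam = protocol.lambda_at_step(frame_steps)
    return WorkTrajectory(
        time=frame_steps * protocol.dt,
        position=x_frames,
        lam=np.asarray(lam, dtype=float),
        work=w_frames,
        nhb=landscape.hbond_count(x_frames),
        seed=seed,
    )


def simulate_ensemble(landscape: ToyLandscape, protocol: PullingProtocol,
                      n_replicas: int, base_seed: int) -> WorkEnsemble:
    """Simulate ``n_replicas`` independent replicas; replica i uses seed base+i."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    trajectories = []
    for i in range(n_replicas):
        try:
            trajectories.append(simulate_trajectory(landscape, protocol, base_seed + i))
        except IntegrationError as exc:
            raise IntegrationError(f"replica {i}: {exc}") from exc
    return WorkEnsemble(
        trajectories=tuple(trajectories),
        landscape=landscape,
        protocol=protocol,
        base_seed=base_seed,
    )
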