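"""Constant-velocity pulling protocols for the moving harmonic restraint.

Default numbers follow the steering protocol of the system this package
emulates: a stiff spring of 3.9e4 (kJ/mol)/nm² dragged from 0 to 0.35 nm at
0.175 nm/ns over 2 ns at 300 K.  The diffusion coefficient and time step are
numerical choices of the overdamped integrator (see docs/methods.md) and are
set so that the dimensionless step βDk·dt stays well below one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kt

__all__ = ["PullingProtocol", "replica_count"]


@dataclass(frozen=True)
class PullingProtocol:
    """Moving-restraint schedule λ(t) = λ0 + v·t with a harmonic spring.

    Parameters
    ----------
    spring_constant:
        k in (kJ/mol)/nm²; restraint energy V(x, λ) = k/2 (x - λ)².
    lambda_start, lambda_end:
        Restraint endpoints in nm.
    velocity:
        Pulling speed in nm/ps (0.175 nm/ns = 1.75e-4 nm/ps).
    dt:
        Integrator time step in ps.
    temperature:
        Bath temperature in K.
    diffusion:
        Diffusion coefficient D in nm²/ps of the overdamped dynamics.
    n_steps:
        Number of integration steps.  Derived from the schedule when omitted;
        must be given explicitly for a stationary restraint (velocity 0).
    save_stride:
        Every ``save_stride``-th step is recorded as an analysis frame (the
        initial state is always frame 0).
    """

    spring_constant: float = 3.9e4
    lambda_start: float = 0.0
    lambda_end: float = 0.35
    velocity: float = 1.75e-4
    dt: float = 5e-3
    temperature: float = 300.0
    diffusion: float = 6e-4
    n_steps: int | None = None
    save_stride: int = 2000

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if self.dt <= 0 or self.temperature <= 0 or self.diffusion <= 0:
            raise ValueError("dt, temperature and diffusion must be positive")
        if self.lambda_end < self.lambda_start:
            raise ValueError("lambda_end must be >= lambda_start")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.n_steps is None:
            if self.velocity == 0:
                raise ValueError("n_steps must be given when velocity is 0")
            n = round((self.lambda_end - self.lambda_start) / (self.velocity * self.dt))
            object.__setattr__(self, "n_steps", int(n))
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def duration(self) -> float:
        """Total pulling time in ps."""
        return self.n_steps * self.dt

    @property
    def kbt(self) -> float:
        return kt(self.temperature)

    def lambda_at_step(self, step) -> np.ndarray | float:
        """Restraint center after ``step`` integration steps."""
        return self.lambda_start + self.velocity * np.asarray(step) * self.dt

    def lambda_schedule(self) -> np.ndarray:
        """Restraint centers at every integration step (length n_steps + 1)."""
        return self.lambda_at_step(np.arange(self.n_steps + 1))

    def frame_steps(self) -> np.ndarray:
        """Integration-step indices of the recorded analysis frames."""
        steps = np.arange(0, self.n_steps + 1, self.save_stride)
        if steps[-1] != self.n_steps:
            steps = np.append(steps, self.n_steps)
        return steps

    def restraint_energy(self, x, lam):
        """V(x, λ) = k/2 (x - λ)² in kJ/mol."""
        d = np.asarray(x, dtype=float) - np.asarray(lam, dtype=float)
        return 0.5 * self.spring_constant * d * d


def replica_count(run_ps: float = 8192.0, spacing_ps: float = 16.0) -> int:
    """Number of pulling replicas from equidistant starting-point extraction.

    Starting configurations are taken one every ``spacing_ps`` from an
    equilibrated restrained run of length ``run_ps``; the default 8192-ps run
    sampled every 16 ps yields the 512 independent replicas of the reference
    protocol.
    """
    n = run_ps / spacing_ps
    if abs(n - round(n)) > 1e-9:
        raise ValueError("run length must be an integer multiple of the spacing")
    return int(round(n))
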