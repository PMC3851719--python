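"""One-dimensional toy free-energy landscapes with a discrete hydrogen-bond count.

A :class:`ToyLandscape` is a sum of attractive wells on a 1-D "separation-like"
coordinate (nm), standing in for the energy surface governing the rupture of a
terminal base pair.  Two increasing thresholds map the coordinate to a discrete
hydrogen-bond count n in {2, 1, 0}; frames with n >= 1 belong to the *bound*
ensemble and frames with n = 0 to the *unbound* one.

Two well shapes are supported:

* :class:`GaussianWell` — ``U(x) = -depth * exp(-(x-center)^2 / (2 width^2))``
* :class:`RectWell` — a smoothed rectangular well built from two tanh edges,
  ``U(x) = -depth/2 * [tanh((x-a)/s) - tanh((x-b)/s)]`` with
  ``a = center - half_width``, ``b = center + half_width`` and edge-softness
  ``s``.  As ``s -> 0`` this approaches a square well of depth ``depth``.

The module also provides the exact quadrature oracle for the bound/unbound
free-energy difference and a depth-calibration routine that tunes the bound
well until the oracle hits a prescribed target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
from scipy import integrate, optimize

from .constants import kt
from .errors import CalibrationError, DegeneratePartitionError, DomainError

__all__ = [
    "GaussianWell",
    "RectWell",
    "ToyLandscape",
    "potential_energy",
    "hbond_count",
    "quadrature_delta_f",
    "calibrate_depth",
]


@dataclass(frozen=True)
class GaussianWell:
    """Attractive Gaussian well: center (nm), depth (kJ/mol, > 0), width (nm)."""

    center: float
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("Gaussian well width must be positive")

    def energy(self, x):
        z = (np.asarray(x, dtype=float) - self.center) / self.width
        return -self.depth * np.exp(-0.5 * z * z)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.center) / self.width
        return self.depth * (x - self.center) / self.width**2 * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class RectWell:
    """Smoothed rectangular well: center, depth (kJ/mol), half-width, edge softness (nm)."""

    center: float
    depth: float
    half_width: float
    softness: float

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.softness <= 0:
            raise ValueError("RectWell half_width and softness must be positive")

    @property
    def edges(self) -> tuple[float, float]:
        return (self.center - self.half_width, self.center + self.half_width)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.edges
        return -0.5 * self.depth * (
            np.tanh((x - a) / self.softness) - np.tanh((x - b) / self.softness)
        )

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.edges
        sa = 1.0 / np.cosh((x - a) / self.softness) ** 2
        sb = 1.0 / np.cosh((x - b) / self.softness) ** 2
        return -0.5 * self.depth / self.softness * (sa - sb)


Well = Union[GaussianWell, RectWell]


@dataclass(frozen=True)
class ToyLandscape:
    """Sum-of-wells potential with hydrogen-bond-count thresholds.

    Parameters
    ----------
    wells:
        Any mix of :class:`GaussianWell` / :class:`RectWell`; an empty tuple is
        a flat (free-particle) landscape.
    hbond_thresholds:
        Two strictly increasing positions ``(x_21, x_10)``: the count is 2
        below ``x_21``, 1 in ``[x_21, x_10)`` and 0 at or above ``x_10``.
    bounds:
        Domain over which the potential is considered defined; quadrature
        integrates over it and :func:`potential_energy` rejects positions
        outside it.
    """

    wells: tuple[Well, ...] = ()
    hbond_thresholds: tuple[float, float] = (0.12, 0.25)
    bounds: tuple[float, float] = (-0.06, 0.41)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        lo, hi = self.bounds
        t21, t10 = self.hbond_thresholds
        if not lo < hi:
            raise ValueError("domain bounds must satisfy lo < hi")
        if not t21 < t10:
            raise ValueError("hbond thresholds must be strictly increasing")
        if not (lo < t21 and t10 < hi):
            raise ValueError("hbond thresholds must lie strictly inside the domain")

    # --- energetics -----------------------------------------------------

    def energy(self, x):
        """Potential U(x) in kJ/mol; defined for any real x (smooth extension)."""
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for w in self.wells:
            u = u + w.energy(x)
        return u

    def gradient(self, x):
        """dU/dx in (kJ/mol)/nm."""
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for w in self.wells:
            g = g + w.gradient(x)
        return g

    def hbond_count(self, x):
        """Discrete hydrogen-bond count in {2, 1, 0} as a step function of x."""
        x = np.asarray(x)
        t21, t10 = self.hbond_thresholds
        return np.where(x < t21, 2, np.where(x < t10, 1, 0))

    def with_bound_depth(self, depth: float) -> "ToyLandscape":
        """Copy of the landscape with the bound well's depth replaced."""
        i = self._bound_well_index()
        wells = list(self.wells)
        wells[i] = replace(wells[i], depth=depth)
        return replace(self, wells=tuple(wells))

    def _bound_well_index(self) -> int:
        t10 = self.hbond_thresholds[1]
        idx = [i for i, w in enumerate(self.wells) if w.center < t10]
        if len(idx) != 1:
            raise CalibrationError(
                f"landscape must have exactly one well centered in the bound "
                f"region (found {len(idx)})"
            )
        return idx[0]


def potential_energy(landscape: ToyLandscape, x) -> np.ndarray | float:
    """Potential energy U(x) in kJ/mol; x must lie within the domain bounds."""
    xa = np.asarray(x, dtype=float)
    lo, hi = landscape.bounds
    if np.any(xa < lo) or np.any(xa > hi):
        raise DomainError(f"position outside landscape domain [{lo}, {hi}]")
    u = landscape.energy(xa)
    return float(u) if np.isscalar(x) else u


def hbond_count(landscape: ToyLandscape, x):
    """Hydrogen-bond count n(x) in {2, 1, 0} (total function of position)."""
    n = landscape.hbond_count(x)
    return int(n) if np.isscalar(x) else n


def _partition_integral(landscape: ToyLandscape, beta: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.0
    # break at well edges to help the adaptive quadrature across stiff walls
    pts = []
    for w in landscape.wells:
        if isinstance(w, RectWell):
            pts.extend(w.edges)
        else:
            pts.extend([w.center - w.width, w.center, w.center + w.width])
    pts = sorted(p for p in pts if lo < p < hi)
    val, _ = integrate.quad(
        lambda x: np.exp(-beta * landscape.energy(x)),
        lo, hi, points=pts or None, limit=400,
    )
    return val


def quadrature_delta_f(
    landscape: ToyLandscape, temperature: float, direction: str = "breaking"
) -> float:
    """Exact bound/unbound free-energy difference by numerical quadrature.

    ``breaking`` returns ``F(unbound) - F(bound) = -kT ln(Z_u / Z_b)`` where
    the bound region is the part of the domain with hydrogen-bond count >= 1
    (below the 1->0 threshold) and the unbound region the remainder;
    ``formation`` is the negative.
    """
    if direction not in ("breaking", "formation"):
        raise ValueError(f"unknown direction {direction!r}")
    kbt = kt(temperature)
    beta = 1.0 / kbt
    lo, hi = landscape.bounds
    t10 = landscape.hbond_thresholds[1]
    z_bound = _partition_integral(landscape, beta, lo, t10)
    z_unbound = _partition_integral(landscape, beta, t10, hi)
    if z_bound <= 0 or z_unbound <= 0 or not np.isfinite(z_bound + z_unbound):
        raise DegeneratePartitionError("vanishing partition integral")
    df = -kbt * np.log(z_unbound / z_bound)
    return df if direction == "breaking" else -df


def calibrate_depth(
    landscape_template: ToyLandscape,
    target_delta_f: float,
    temperature: float,
    depth_range: tuple[float, float] = (0.05, 60.0),
    tol: float = 1e-3,
) -> ToyLandscape:
    """Tune the bound well's depth until the breaking ΔF matches a target.

    The breaking free energy is monotonically increasing in the bound-well
    depth (a deeper bound basin makes breaking more costly), so a bracketing
    root search on the depth converges to the unique solution.  The returned
    landscape satisfies ``quadrature_delta_f(..., "breaking")`` within ``tol``
    kJ/mol of ``target_delta_f``.
    """

    def f(depth: float) -> float:
        ls = landscape_template.with_bound_depth(depth)
        return quadrature_delta_f(ls, temperature, "breaking") - target_delta_f

    d0 = landscape_template.wells[landscape_template._bound_well_index()].depth
    if abs(f(d0)) <= tol:
        return landscape_template
    lo, hi = depth_range
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"target {target_delta_f} kJ/mol not bracketed by bound-well depths "
            f"in [{lo}, {hi}] (ΔF range [{flo + target_delta_f:.3f}, "
            f"{fhi + target_delta_f:.3f}])"
        )
    depth = optimize.brentq(f, lo, hi, xtol=1e-7, rtol=1e-12)
    result = landscape_template.with_bound_depth(float(depth))
    resid = quadrature_delta_f(result, temperature, "breaking") - target_delta_f
    if abs(resid) > tol:
        raise CalibrationError(f"calibration residual {resid:.2e} exceeds {tol}")
    return result
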