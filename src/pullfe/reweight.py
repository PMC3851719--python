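"""Free energies from nonequilibrium work ensembles.

Implements the forward-pulling estimators used throughout the package:

* **Jarzynski profile** — the free energy along the pulling schedule,
  ``F(t) = -kT ln < exp(-βW_t) >``, evaluated with log-sum-exp so that βW
  spanning ±1e4 neither overflows nor collapses to zero weight.

* **Frame weights** — the Jarzynski/WHAM combination: every recorded frame
  (i, t) of every replica receives an unbiased statistical weight

      w_{i,t} ∝ exp(-β[W_{i,t} - f_t]) / Σ_{t'} N exp(-β[V(q_{i,t}, λ_{t'}) - f_{t'}])

  with ``V(q, λ) = k/2 (q - λ)²`` the restraint bias and ``f_t`` the
  Jarzynski free energy of time slice t.  The ``exp(+βf_t)`` numerator
  factor normalizes each slice's exponentially weighted samples before the
  WHAM pooling; by the nonequilibrium identity
  ``<δ(x - x_t) exp(-βW_t)> = exp(-β[U(x) + V_t(x)]) / Z_0`` the pooled
  estimator is then unbiased for the equilibrium density (dropping the
  factor, i.e. pooling un-normalized slices, systematically distorts the
  recovered landscape).  The pooled weights reconstruct
  the *unbiased* equilibrium ensemble, so free-energy profiles can be
  projected onto any a-posteriori chosen collective variable — in
  particular the discrete hydrogen-bond count that defines the bound and
  unbound states.

* **State ΔF / ΔΔF** — the bound/unbound free-energy difference from the
  weight shares of each state, and the apo-minus-holo double difference
  that quantifies ligand-induced stabilization (negative values mean the
  ligand stabilizes the paired state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .errors import (
    ConventionError,
    DegeneratePartitionError,
    PullfeError,
    ShapeError,
)
from .simulate import WorkEnsemble

__all__ = [
    "FreeEnergyProfile",
    "FrameWeights",
    "StatePartition",
    "DeltaFResult",
    "OutlierDominationWarning",
    "accumulate_work",
    "jarzynski_profile",
    "mean_work_profile",
    "frame_weights",
    "project_free_energy",
    "state_delta_f",
    "delta_delta_f",
    "weight_concentration",
]


class OutlierDominationWarning(UserWarning):
    """A single trajectory carries most of the statistical weight."""


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energy (kJ/mol) over a grid; comparisons are shift-invariant.

    ``convention`` records the anchoring: "endpoint" (F = 0 at the first
    grid point) for schedule profiles, "minimum" (min F = 0) for projected
    profiles.  Bins no sample reached are NaN, never interpolated.
    """

    grid: np.ndarray
    values: np.ndarray
    convention: str = "endpoint"
    grid_label: str = "time"
    single_support: bool = False

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ShapeError("grid and values must have equal length")


@dataclass(frozen=True)
class StatePartition:
    """Total map from the H-bond count to {bound, unbound}.

    A frame is *bound* when its count is at least ``bound_min_count``
    (default 1: one or two hydrogen bonds) and *unbound* otherwise.
    """

    bound_min_count: int = 1

    def is_bound(self, nhb) -> np.ndarray:
        return np.asarray(nhb) >= self.bound_min_count


@dataclass(frozen=True)
class FrameWeights:
    """Normalized unbiased frame weights plus per-slice free energies.

    ``log_weights`` has shape (N, T) over replicas x recorded frames and
    sums (in linear space) to one; ``slice_free_energy`` is the Jarzynski
    profile f_t used in the WHAM denominator, endpoint-anchored (f_0 = 0).
    """

    log_weights: np.ndarray
    slice_free_energy: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        if self.log_weights.ndim != 2:
            raise ShapeError("log_weights must be (n_replicas, n_frames)")
        if self.log_weights.shape[1] != len(self.slice_free_energy):
            raise ShapeError("slice_free_energy length must match frame count")

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @property
    def n_replicas(self) -> int:
        return self.log_weights.shape[0]

    def trajectory_weights(self) -> np.ndarray:
        """Per-trajectory aggregated weight (sums to one across replicas)."""
        return np.exp(logsumexp(self.log_weights, axis=1))


@dataclass(frozen=True)
class DeltaFResult:
    """A bound/unbound free-energy difference with provenance.

    ``direction`` is "breaking" (F_unbound - F_bound) or "formation" (its
    exact negative).  ``se`` stays None until a bootstrap attaches it.
    """

    value: float
    direction: str
    temperature: float
    n_replicas: int
    se: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def negated(self) -> "DeltaFResult":
        other = "formation" if self.direction == "breaking" else "breaking"
        return DeltaFResult(
            value=-self.value, direction=other, temperature=self.temperature,
            n_replicas=self.n_replicas, se=self.se, diagnostics=dict(self.diagnostics),
        )


# ---------------------------------------------------------------------------


def accumulate_work(positions, lambda_schedule, spring_constant: float) -> np.ndarray:
    """Accumulated work from recorded series by the potential-difference rule.

    ``W_t = W_{t-1} + V(x_{t-1}, λ_t) - V(x_{t-1}, λ_{t-1})`` with W_0 = 0;
    matches the simulator's convention on the recorded grid, and recomputes
    the work column for external COLVAR files that lack one.
    """
    x = np.asarray(positions, dtype=float)
    lam = np.asarray(lambda_schedule, dtype=float)
    if x.shape != lam.shape or x.ndim != 1:
        raise ShapeError("positions and lambda_schedule must be equal-length 1-D")
    if spring_constant <= 0:
        raise ValueError("spring_constant must be positive")
    d_new = x[:-1] - lam[1:]
    d_old = x[:-1] - lam[:-1]
    inc = 0.5 * spring_constant * (d_new * d_new - d_old * d_old)
    return np.concatenate([[0.0], np.cumsum(inc)])


def _work_matrix(ensemble: WorkEnsemble) -> np.ndarray:
    """Recorded works, recomputed from positions when a replica lacks them."""
    if all(tr.work is not None for tr in ensemble.trajectories):
        return ensemble.work_matrix()
    if ensemble.protocol is None:
        raise ShapeError("work missing and no protocol available to recompute it")
    k = ensemble.protocol.spring_constant
    return np.stack([
        tr.work if tr.work is not None else accumulate_work(tr.position, tr.lam, k)
        for tr in ensemble.trajectories
    ])


def _check_finite_work(w: np.ndarray) -> None:
    bad = np.nonzero(~np.isfinite(w).all(axis=1))[0]
    if bad.size:
        raise PullfeError(f"non-finite work in replica {bad[0]}")


def _jarzynski_values(work: np.ndarray, beta: float) -> np.ndarray:
    n = work.shape[0]
    return -(logsumexp(-beta * work, axis=0) - np.log(n)) / beta


def jarzynski_profile(ensemble: WorkEnsemble, temperature: float) -> FreeEnergyProfile:
    """Endpoint-anchored free-energy profile F(t) = -kT ln <exp(-βW_t)>."""
    work = _work_matrix(ensemble)
    _check_finite_work(work)
    beta = 1.0 / kt(temperature)
    return FreeEnergyProfile(
        grid=ensemble.time.copy(),
        values=_jarzynski_values(work, beta),
        convention="endpoint",
        grid_label="time",
    )


def mean_work_profile(ensemble: WorkEnsemble) -> FreeEnergyProfile:
    """Ensemble-mean accumulated work over the schedule (upper bounds F(t))."""
    work = _work_matrix(ensemble)
    return FreeEnergyProfile(
        grid=ensemble.time.copy(),
        values=work.mean(axis=0),
        convention="endpoint",
        grid_label="time",
    )


def _log_bias(positions: np.ndarray, lam: np.ndarray, spring_constant: float,
              beta: float) -> np.ndarray:
    """-βV(q_{i,t}, λ_{t'}) with shape (N, T, T'), computed lazily per call."""
    d = positions[:, :, None] - lam[None, None, :]
    return -beta * 0.5 * spring_constant * d * d


def _log_weights_from(work: np.ndarray, neg_beta_bias: np.ndarray,
                      beta_f_denom: np.ndarray, beta_f_num: np.ndarray,
                      beta: float) -> np.ndarray:
    """Normalized log-weights given works, -βV matrix and per-slice βf.

    ``beta_f_num`` is βf_t on the full frame grid (numerator slice
    normalization); ``beta_f_denom`` is βf_{t'} on the (possibly strided)
    denominator slices.
    """
    n = work.shape[0]
    log_denom = logsumexp(neg_beta_bias + beta_f_denom[None, None, :], axis=2) + np.log(n)
    log_r = -beta * work + beta_f_num[None, :] - log_denom
    return log_r - logsumexp(log_r)


def frame_weights(ensemble: WorkEnsemble, spring_constant: float | None = None,
                  temperature: float | None = None, stride: int = 1) -> FrameWeights:
    """Unbiased frame weights by the Jarzynski + WHAM combination.

    The per-slice free energies f_t come directly from the Jarzynski
    estimate (no self-consistent iteration); the denominator pools all
    recorded slices, optionally decimated by ``stride`` for speed (a
    constant factor that cancels in the normalization).  All exponentials
    are evaluated in log space.
    """
    if spring_constant is None:
        if ensemble.protocol is None:
            raise ValueError("spring_constant required when ensemble has no protocol")
        spring_constant = ensemble.protocol.spring_constant
    if temperature is None:
        if ensemble.protocol is None:
            raise ValueError("temperature required when ensemble has no protocol")
        temperature = ensemble.protocol.temperature
    if stride < 1:
        raise ValueError("stride must be >= 1")
    work = _work_matrix(ensemble)
    _check_finite_work(work)
    beta = 1.0 / kt(temperature)
    f = _jarzynski_values(work, beta)
    pos = ensemble.position_matrix()
    sl = slice(None, None, stride)
    neg_beta_bias = _log_bias(pos, ensemble.lam[sl], spring_constant, beta)
    log_w = _log_weights_from(work, neg_beta_bias, beta * f[sl], beta * f, beta)
    if not np.isfinite(logsumexp(log_w)):
        raise DegeneratePartitionError("all frames have vanishing weight")
    return FrameWeights(log_weights=log_w, slice_free_energy=f, temperature=temperature)


def project_free_energy(weights: FrameWeights, cv_values, binning) -> FreeEnergyProfile:
    """Project the unbiased ensemble onto an a-posteriori chosen CV.

    ``binning`` is either an array of monotone bin edges (continuous CV) or
    the string ``"discrete"`` (integer-valued CV, one bin per observed
    value).  Returns a minimum-anchored profile; empty bins are NaN.
    """
    cv = np.asarray(cv_values)
    if cv.shape != weights.log_weights.shape:
        raise ShapeError("cv_values must match the (n_replicas, n_frames) frame grid")
    kbt = kt(weights.temperature)
    flat_cv = cv.ravel()
    flat_lw = weights.log_weights.ravel()
    if isinstance(binning, str) and binning == "discrete":
        centers = np.unique(flat_cv)
        idx = np.searchsorted(centers, flat_cv)
        n_bins = len(centers)
        label = "cv (discrete)"
    else:
        edges = np.asarray(binning, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be a 1-D increasing array of length >= 2")
        idx = np.digitize(flat_cv, edges) - 1
        n_bins = len(edges) - 1
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = (idx >= 0) & (idx < n_bins)
        idx, flat_lw = idx[keep], flat_lw[keep]
        label = "cv"
    log_mass = np.full(n_bins, -np.inf)
    for b in range(n_bins):
        sel = flat_lw[idx == b]
        if sel.size:
            log_mass[b] = logsumexp(sel)
    values = np.where(np.isfinite(log_mass), -kbt * log_mass, np.nan)
    occupied = np.isfinite(values)
    if not occupied.any():
        raise DegeneratePartitionError("no frame falls inside the binning")
    values = values - np.nanmin(values)
    return FreeEnergyProfile(
        grid=np.asarray(centers, dtype=float), values=values,
        convention="minimum", grid_label=label,
        single_support=int(occupied.sum()) == 1,
    )


def state_delta_f(weights: FrameWeights, nhb, partition: StatePartition | None = None,
                  direction: str = "breaking") -> DeltaFResult:
    """Bound/unbound ΔF from the pooled unbiased weights.

    ``breaking`` is ``-kT ln(Σ_unbound w / Σ_bound w)``; ``formation`` its
    exact negative.  Kish effective sample size and the largest single
    trajectory's weight share are attached as diagnostics.
    """
    if direction not in ("breaking", "formation"):
        raise ValueError(f"unknown direction {direction!r}")
    partition = partition or StatePartition()
    nhb = np.asarray(nhb)
    if nhb.shape != weights.log_weights.shape:
        raise ShapeError("nhb must match the (n_replicas, n_frames) frame grid")
    bound = partition.is_bound(nhb)
    lw = weights.log_weights
    if not bound.any():
        raise DegeneratePartitionError("bound state is empty")
    if bound.all():
        raise DegeneratePartitionError("unbound state is empty")
    log_b = logsumexp(lw[bound])
    log_u = logsumexp(lw[~bound])
    if not (np.isfinite(log_b) and np.isfinite(log_u)):
        empty = "bound" if not np.isfinite(log_b) else "unbound"
        raise DegeneratePartitionError(f"{empty} state carries zero weight")
    kbt = kt(weights.temperature)
    df = -kbt * (log_u - log_b)
    diag = weight_concentration(weights, warn=False)
    res = DeltaFResult(
        value=float(df), direction="breaking", temperature=weights.temperature,
        n_replicas=weights.n_replicas, diagnostics=diag,
    )
    return res if direction == "breaking" else res.negated()


def delta_delta_f(result_apo: DeltaFResult, result_holo: DeltaFResult) -> DeltaFResult:
    """ΔΔF = ΔF(apo) - ΔF(holo); negative values mean ligand stabilization.

    Both inputs must share the direction convention and temperature; the
    standard error (when both carry one) combines in quadrature.
    """
    if result_apo.direction != result_holo.direction:
        raise ConventionError(
            f"direction mismatch: {result_apo.direction!r} vs {result_holo.direction!r}"
        )
    if abs(result_apo.temperature - result_holo.temperature) > 1e-9:
        raise ConventionError("temperature mismatch between ΔF results")
    se = None
    if result_apo.se is not None and result_holo.se is not None:
        se = float(np.hypot(result_apo.se, result_holo.se))
    return DeltaFResult(
        value=float(result_apo.value - result_holo.value),
        direction=result_apo.direction,
        temperature=result_apo.temperature,
        n_replicas=min(result_apo.n_replicas, result_holo.n_replicas),
        se=se,
        diagnostics={"apo": dict(result_apo.diagnostics),
                     "holo": dict(result_holo.diagnostics)},
    )


def weight_concentration(weights: FrameWeights, warn: bool = True) -> dict:
    """Domination diagnostics over per-trajectory aggregated weights.

    Returns the Kish effective sample size ``(Σw)²/Σw²`` and the largest
    single-trajectory share of the total weight; emits
    :class:`OutlierDominationWarning` when one trajectory holds more than
    half the weight — the qualitative signature of a few low-work
    realizations dominating an exponential average.
    """
    tw = weights.trajectory_weights()
    ess = float(tw.sum() ** 2 / np.sum(tw**2))
    max_frac = float(tw.max() / tw.sum())
    if warn and max_frac > 0.5:
        warnings.warn(
            f"one trajectory holds {max_frac:.1%} of the total weight "
            f"(ESS = {ess:.1f} of {len(tw)})",
            OutlierDominationWarning,
            stacklevel=2,
        )
    return {"ess": ess, "max_traj_fraction": max_frac}
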