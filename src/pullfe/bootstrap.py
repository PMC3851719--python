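"""Trajectory-level bootstrap errors for ΔF estimates, plus convergence flags.

Frames within a pulling replica are strongly correlated, so the resampling
unit is the whole trajectory: each of the B resamples draws N replicas with
replacement, re-runs the complete weighting pipeline (Jarzynski slice free
energies -> WHAM frame weights -> state ΔF) and the standard error is the
standard deviation of the resample distribution.  The point estimate is
always the full-sample value; resampling never alters it.

Resamples whose partition loses a state are recorded as failed and dropped;
more than 20% failures raises rather than reporting a misleading error bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .errors import DiagnosticsError
from .reweight import (
    DeltaFResult,
    StatePartition,
    _jarzynski_values,
    _log_bias,
    _log_weights_from,
    _work_matrix,
    frame_weights,
    state_delta_f,
)
from .simulate import WorkEnsemble

__all__ = ["BootstrapConfig", "bootstrap_delta_f", "convergence_report"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Nonparametric trajectory bootstrap: B resamples from a fixed seed."""

    n_resamples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")


def bootstrap_delta_f(
    ensemble: WorkEnsemble,
    config: BootstrapConfig | None = None,
    partition: StatePartition | None = None,
    direction: str = "breaking",
    spring_constant: float | None = None,
    temperature: float | None = None,
    stride: int = 1,
) -> DeltaFResult:
    """Bound/unbound ΔF with a trajectory-bootstrap standard error.

    Returns the full-sample :class:`DeltaFResult` with ``se`` attached and
    the resample distribution, failure count and B in its diagnostics.
    """
    if ensemble.n_replicas < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    config = config or BootstrapConfig()
    partition = partition or StatePartition()
    if spring_constant is None:
        spring_constant = ensemble.protocol.spring_constant
    if temperature is None:
        temperature = ensemble.protocol.temperature
    beta = 1.0 / kt(temperature)

    weights = frame_weights(ensemble, spring_constant, temperature, stride=stride)
    nhb = ensemble.nhb_matrix()
    point = state_delta_f(weights, nhb, partition, direction)

    work = _work_matrix(ensemble)
    sl = slice(None, None, stride)
    neg_beta_bias = _log_bias(ensemble.position_matrix(), ensemble.lam[sl],
                              spring_constant, beta)
    # the bias matrix is fixed across resamples: precompute exp(M - rowmax)
    # once so each resample's WHAM denominator is a single mat-vec product
    row_max = neg_beta_bias.max(axis=2)
    exp_bias = np.exp(neg_beta_bias - row_max[:, :, None])
    bound = partition.is_bound(nhb)
    sign = 1.0 if direction == "breaking" else -1.0
    kbt = kt(temperature)
    n = ensemble.n_replicas

    rng = np.random.default_rng(config.seed)
    values = []
    n_failed = 0
    for _ in range(config.n_resamples):
        idx = rng.integers(0, n, size=n)
        w_b = work[idx]
        f_b = _jarzynski_values(w_b, beta)
        bf = beta * f_b[sl]
        bf0 = bf.max()  # keep exp(bf - bf0) in range
        log_denom = (row_max[idx] + bf0
                     + np.log(exp_bias[idx] @ np.exp(bf - bf0)) + np.log(n))
        log_r = -beta * w_b + beta * f_b[None, :] - log_denom
        log_w = log_r - logsumexp(log_r)
        bound_b = bound[idx]
        if not bound_b.any() or bound_b.all():
            n_failed += 1
            continue
        log_bound = logsumexp(log_w[bound_b])
        log_unbound = logsumexp(log_w[~bound_b])
        if not (np.isfinite(log_bound) and np.isfinite(log_unbound)):
            n_failed += 1
            continue
        values.append(sign * -kbt * (log_unbound - log_bound))
    if n_failed > 0.2 * config.n_resamples:
        raise DiagnosticsError(
            f"{n_failed}/{config.n_resamples} bootstrap resamples lost a state; "
            f"the partition is too fragile for a standard error"
        )
    values = np.asarray(values)
    se = float(np.std(values, ddof=1))
    diag = dict(point.diagnostics)
    diag.update({
        "n_resamples": config.n_resamples,
        "n_failed": n_failed,
        "bootstrap_distribution": values,
    })
    return DeltaFResult(
        value=point.value, direction=point.direction, temperature=point.temperature,
        n_replicas=point.n_replicas, se=se, diagnostics=diag,
    )


def convergence_report(result: DeltaFResult, temperature: float | None = None) -> dict:
    """Convergence flags for a ΔF estimate with bootstrap error.

    Converged iff the standard error is below the thermal energy kT, the
    effective sample size is at least 10 and no single trajectory holds more
    than half the weight; the report lists each criterion's value and flag.
    """
    temperature = temperature if temperature is not None else result.temperature
    kbt = kt(temperature)
    se = result.se
    ess = result.diagnostics.get("ess")
    max_frac = result.diagnostics.get("max_traj_fraction")
    se_ok = se is not None and se <= kbt
    ess_ok = ess is not None and ess >= 10
    outlier_ok = max_frac is not None and max_frac <= 0.5
    lines = [
        f"standard error: {se if se is not None else float('nan'):.3f} kJ/mol "
        f"(threshold kT = {kbt:.3f}) -> {'ok' if se_ok else 'FAIL'}",
        f"effective sample size: {ess if ess is not None else float('nan'):.1f} "
        f"(threshold 10) -> {'ok' if ess_ok else 'FAIL'}",
        f"max trajectory weight share: "
        f"{max_frac if max_frac is not None else float('nan'):.3f} "
        f"(threshold 0.5) -> {'ok' if outlier_ok else 'FAIL'}",
    ]
    return {
        "converged": bool(se_ok and ess_ok and outlier_ok),
        "se_below_kt": bool(se_ok),
        "ess_sufficient": bool(ess_ok),
        "outlier_dominated": bool(not outlier_ok),
        "text": "\n".join(lines),
    }
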