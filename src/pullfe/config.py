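"""TOML run configuration for the two-system pulling experiment.

A config file has sections ``[landscape.apo]`` / ``[landscape.holo]`` (well
list, thresholds, bounds and an optional ``target_delta_f`` the bound well
is calibrated to), ``[protocol]``, ``[analysis]``, ``[bootstrap]``,
``[seeds]`` and ``[run]``.  All seeds are explicit — no wall-clock seeding.
The packaged ``default_config.toml`` encodes the reference experiment: an
apo-like system calibrated to a breaking ΔF of -2.5 kJ/mol and a holo-like
system calibrated to +1.9 kJ/mol, 512 replicas each.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .bootstrap import BootstrapConfig
from .landscape import GaussianWell, RectWell, ToyLandscape
from .protocol import PullingProtocol

__all__ = ["SystemSpec", "RunConfig", "load_config", "default_config_text"]


@dataclass(frozen=True)
class SystemSpec:
    """One system's landscape template plus an optional calibration target."""

    name: str
    landscape: ToyLandscape
    target_delta_f: float | None = None


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible two-system experiment needs."""

    systems: dict[str, SystemSpec]
    protocol: PullingProtocol
    bootstrap: BootstrapConfig
    seeds: dict[str, int]
    n_replicas: int = 512
    stride: int = 1
    bound_min_count: int = 1
    position_bins: int = 60

    def __post_init__(self) -> None:
        for name in self.systems:
            if name not in self.seeds:
                raise ValueError(f"no seed configured for system {name!r}")


def _well_from_dict(d: dict):
    shape = d.get("shape", "rect")
    if shape == "rect":
        return RectWell(center=d["center"], depth=d["depth"],
                        half_width=d["half_width"], softness=d["softness"])
    if shape == "gaussian":
        return GaussianWell(center=d["center"], depth=d["depth"], width=d["width"])
    raise ValueError(f"unknown well shape {shape!r}")


def _landscape_from_dict(d: dict) -> ToyLandscape:
    return ToyLandscape(
        wells=tuple(_well_from_dict(w) for w in d.get("wells", [])),
        hbond_thresholds=tuple(d.get("hbond_thresholds", (0.12, 0.25))),
        bounds=tuple(d.get("bounds", (-0.06, 0.41))),
    )


def load_config(path=None) -> RunConfig:
    """Load a TOML config; with no path, the packaged default experiment."""
    if path is None:
        raw = tomllib.loads(default_config_text())
    else:
        with Path(path).open("rb") as fh:
            raw = tomllib.load(fh)
    systems = {}
    for name, sec in raw["landscape"].items():
        systems[name] = SystemSpec(
            name=name,
            landscape=_landscape_from_dict(sec),
            target_delta_f=sec.get("target_delta_f"),
        )
    prot = raw.get("protocol", {})
    protocol = PullingProtocol(**prot)
    bs = raw.get("bootstrap", {})
    bootstrap = BootstrapConfig(n_resamples=bs.get("n_resamples", 200),
                                seed=bs.get("seed", 0))
    ana = raw.get("analysis", {})
    run = raw.get("run", {})
    return RunConfig(
        systems=systems,
        protocol=protocol,
        bootstrap=bootstrap,
        seeds={k: int(v) for k, v in raw.get("seeds", {}).items()},
        n_replicas=int(run.get("n_replicas", 512)),
        stride=int(ana.get("stride", 1)),
        bound_min_count=int(ana.get("bound_min_count", 1)),
        position_bins=int(ana.get("position_bins", 60)),
    )


def default_config_text() -> str:
    """Text of the packaged default experiment configuration."""
    return (resources.files("pullfe.data") / "default_config.toml").read_text()
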