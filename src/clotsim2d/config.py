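"""Scenario configuration: geometry, flow, kinetics, numerics, output.

A :class:`ScenarioConfig` fully determines one run and round-trips
through YAML.  Stock full-scale scenarios reproduce the published
3 geometries x 3 wall shear rates; the ``mini-*`` fixtures are
down-scaled scenarios (smaller channel and plug, identical local
physics) that run in minutes on one CPU and exercise every code path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from clotsim2d.geometry import PlugConfig, Grid2D, STOCK_GAPS
from clotsim2d.params import FluidParams, KineticParams

__all__ = ["ScenarioConfig", "make_fixture", "FIXTURE_NAMES"]


@dataclass
class ScenarioConfig:
    """All settings for one simulation run."""

    # geometry
    channel_length: float = 216.0  # um
    channel_height: float = 72.0  # um
    h: float = 0.25  # um
    plug: PlugConfig | None = field(default_factory=PlugConfig)
    se_strip_length: float = 50.0  # um, centred under the plug

    # flow
    shear_rate: float = 1000.0  # 1/s
    flow_mode: str = "stokes"

    # kinetics overrides applied on top of the stock parameter set
    kinetics: dict = field(default_factory=dict)
    fluid: dict = field(default_factory=dict)

    # numerics
    dt: float = 0.02  # s
    t_end: float = 60.0  # s
    n_surface_substeps: int = 4
    output_interval: float = 1.0  # s, cadence of series recording
    snapshot_interval: float = 0.0  # s, VTK cadence (0 = final state only)

    # probes: label -> (x, y) um; empty = default plug midline probes
    probes: dict = field(default_factory=dict)

    output_dir: str = "runs/scenario"
    name: str = "scenario"

    # ------------------------------------------------------------------

    def grid(self) -> Grid2D:
        return Grid2D(length=self.channel_length, height=self.channel_height, h=self.h)

    def fluid_params(self) -> FluidParams:
        return FluidParams(shear_rate=self.shear_rate, **self.fluid)

    def kinetic_params(self) -> KineticParams:
        return KineticParams(**self.kinetics)

    def se_strip(self) -> tuple[float, float]:
        cx = self.plug.center_x if self.plug is not None else self.channel_length / 2
        return (cx - self.se_strip_length / 2, cx + self.se_strip_length / 2)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        plug = d.get("plug")
        if plug is not None and not isinstance(plug, PlugConfig):
            d["plug"] = PlugConfig(**plug)
        if "probes" in d and d["probes"]:
            d["probes"] = {k: tuple(v) for k, v in d["probes"].items()}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = self.to_dict()
        if d.get("probes"):
            d["probes"] = {k: list(v) for k, v in d["probes"].items()}
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stock_scenario(density: str, shear_rate: float) -> ScenarioConfig:
    """A full-scale published scenario (long-running)."""
    if density not in STOCK_GAPS:
        raise ValueError(f"unknown density {density!r}; options {sorted(STOCK_GAPS)}")
    gap = STOCK_GAPS[density]
    h = 0.25 if gap >= 0.5 else 0.05
    return ScenarioConfig(
        plug=PlugConfig(gap=gap, center_x=108.0),
        shear_rate=shear_rate,
        h=h,
        t_end=120.0,
        name=f"{density}-shear{int(shear_rate)}",
        output_dir=f"runs/{density}-shear{int(shear_rate)}",
    )


#: Interplatelet gaps of the down-scaled fixture plugs, um.  The mini
#: channel keeps the published platelet diameter and wall clearance but
#: shrinks the channel and plug; gaps are chosen so the default mini
#: grid (h = 0.25 um) resolves every gap with >= 2 cells while
#: preserving a 4x contrast in local surface-to-volume and a monotone
#: dense < medium < loose intraplug velocity ordering, the regime of
#: the full-scale configurations.
MINI_GAPS = {"mini-dense": 0.5, "mini-medium": 1.0, "mini-loose": 2.0}

FIXTURE_NAMES = sorted(MINI_GAPS) + ["batch-fibrin", "empty-channel"]


def make_fixture(name: str) -> ScenarioConfig:
    """Named desk-scale scenario configurations.

    mini-dense / mini-medium / mini-loose
        36 x 70 um channel with a half-elliptical plug (a = 14 um,
        b = 11 um) of full-size platelets at decreasing packing density.
    batch-fibrin
        zero-dimensional (single-cell, no-flow) configuration driving
        the fibrin module with a prescribed thrombin input.
    empty-channel
        no platelets; the Poiseuille verification case.
    """
    if name in MINI_GAPS:
        return ScenarioConfig(
            channel_length=70.0,
            channel_height=36.0,
            h=0.25,
            plug=PlugConfig(
                gap=MINI_GAPS[name], half_width=14.0, height=11.0, center_x=30.0
            ),
            se_strip_length=28.0,
            shear_rate=1000.0,
            dt=0.02,
            t_end=60.0,
            name=name,
            output_dir=f"runs/{name}",
        )
    if name == "batch-fibrin":
        return ScenarioConfig(
            channel_length=1.0,
            channel_height=1.0,
            h=1.0,
            plug=None,
            shear_rate=0.0,
            dt=0.001,
            t_end=30.0,
            name=name,
            output_dir="runs/batch-fibrin",
        )
    if name == "empty-channel":
        return ScenarioConfig(
            channel_length=36.0,
            channel_height=72.0,
            h=0.5,
            plug=None,
            shear_rate=1000.0,
            dt=0.02,
            t_end=0.0,
            name=name,
            output_dir="runs/empty-channel",
        )
    raise ValueError(f"unknown fixture {name!r}; options: {FIXTURE_NAMES}")
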