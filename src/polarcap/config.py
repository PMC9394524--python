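"""Run configuration: YAML-backed settings for the end-to-end analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError
from .nucleinator import NucleinatorParams
from .scenes import SceneConfig


@dataclass
class SimulationSpec:
    """What to simulate when the run starts from synthetic scenes."""

    n_cells: int = 10
    offset_um: float = 1.0  # constant planted offset; use offset_range for uniform
    offset_range: tuple[float, float] | None = None
    scene: SceneConfig = field(default_factory=SceneConfig)

    @property
    def offset_sampler(self):
        if self.offset_range is not None:
            lo, hi = self.offset_range
            return ("uniform", float(lo), float(hi))
        return float(self.offset_um)


@dataclass
class RunConfig:
    """All knobs of one analysis run.

    Defaults mirror the standard analysis settings: 5-px line width, nuclear
    masking at 1 SD / 25 px / 1-px dilation, averaging from frame 9 onward,
    0.1 µm registration grid, alpha 0.05, 10,000 bootstrap resamplings.
    """

    outdir: str = "polarcap_out"
    seed: int = 0
    pixel_size_um: float = 0.18
    line_width_px: int = 5
    start_frame: int = 9
    grid_spacing_um: float = 0.1
    alpha: float = 0.05
    n_boot: int = 10000
    mask_nuclei: bool = True
    nucleinator: NucleinatorParams = field(default_factory=NucleinatorParams)
    simulation: SimulationSpec | None = field(default_factory=SimulationSpec)
    # alternatively: pre-rendered inputs (per-cell TIFFs, see io module)
    input_dir: str | None = None

    def validate(self) -> None:
        if self.line_width_px < 1 or self.line_width_px % 2 == 0:
            raise InvalidConfigError("line_width_px must be odd and >= 1")
        if self.pixel_size_um <= 0 or self.grid_spacing_um <= 0:
            raise InvalidConfigError("pixel size and grid spacing must be positive")
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.n_boot < 1 or self.start_frame < 0:
            raise InvalidConfigError("n_boot >= 1 and start_frame >= 0 required")
        if self.simulation is None and self.input_dir is None:
            raise InvalidConfigError("either a simulation spec or an input_dir is required")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise InvalidConfigError(f"input_dir does not exist: {self.input_dir}")

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "nucleinator" in d and isinstance(d["nucleinator"], dict):
            d["nucleinator"] = NucleinatorParams(**d["nucleinator"])
        if d.get("simulation") is not None and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if isinstance(sim.get("scene"), dict):
                scene = dict(sim["scene"])
                for key in ("image_size", "cell_center", "nucleus_center"):
                    if isinstance(scene.get(key), list):
                        scene[key] = tuple(scene[key])
                sim["scene"] = SceneConfig(**scene)
            if isinstance(sim.get("offset_range"), list):
                sim["offset_range"] = tuple(sim["offset_range"])
            d["simulation"] = SimulationSpec(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidConfigError("config YAML must map keys to values")
        try:
            cfg = cls.from_dict(data)
        except TypeError as exc:
            raise InvalidConfigError(f"bad config field: {exc}") from exc
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
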