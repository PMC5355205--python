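"""Run configuration for end-to-end pipeline runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class LandscapeConfig:
    # demo default: ~1,020 ha enclosure (matching the study's ~970 ha scale)
    # at 20 m cells to keep the demo quick; analyses at full 10 m resolution
    # configure rows/cols/cell_size explicitly
    rows: int = 160
    cols: int = 160
    cell_size: float = 20.0
    relief_amplitude: float = 50.0
    base_elevation: float = 380.0
    correlation_length: float = 150.0
    shrub_fraction: float = 0.02
    burn_intervals: list[int] = field(default_factory=lambda: [1, 2, 4, 20])


@dataclass
class WeatherConfig:
    years: list[int] = field(default_factory=lambda: [2011, 2012])
    mean_annual_precip_mm: float = 835.0
    growing_season_fraction: float = 0.75
    mean_temp_c: float = 12.8
    drought_years: list[int] = field(default_factory=lambda: [2012])
    drought_precip_factor: float = 0.6
    drought_temp_offset_c: float = 2.0


@dataclass
class ForageConfig:
    trees: int = 1000
    node_size: int = 5
    n_protein_plots: int = 300
    n_biomass_plots: int = 600
    protein_noise_sd: float = 0.5
    height_noise_cm: float = 1.0
    train_frac: float = 0.33
    validation_repeats: int = 10
    # year -> (slope, intercept) of the disk calibration used to invert
    # heights; the 2011 season reuses the 2013 calibration
    calibrations: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {2011: (3.78, 6.18), 2012: (2.40, 3.70), 2013: (3.78, 6.18)}
    )


@dataclass
class IndividualYear:
    id: str
    year: int
    n_steps: int = 500
    lactating: bool = False


@dataclass
class MovementConfig:
    theta_m: float = 546.0
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "elevation": 0.05,
            "slope": -0.1,
            "cos_aspect": -0.2,
            "protein": 0.4,
            "biomass": -0.005,
            "protein_x_biomass": 0.0,
        }
    )
    individuals: list[IndividualYear] = field(
        default_factory=lambda: [
            IndividualYear("W601", 2011, 500, True),
            IndividualYear("W602", 2011, 500, False),
            IndividualYear("W603", 2011, 500, True),
            IndividualYear("W601", 2012, 500, False),
            IndividualYear("W602", 2012, 500, True),
            IndividualYear("W603", 2012, 500, False),
        ]
    )


@dataclass
class FittingConfig:
    n_controls: int = 100
    radius_rule: float = 3.0


@dataclass
class RunConfig:
    seed: int
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    forage: ForageConfig = field(default_factory=ForageConfig)
    movement: MovementConfig = field(default_factory=MovementConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    analyze: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d or d["seed"] is None:
            raise ValueError("config must provide a seed")
        forage = dict(d.get("forage", {}))
        if "calibrations" in forage:
            forage["calibrations"] = {
                int(k): tuple(v) for k, v in forage["calibrations"].items()
            }
        movement = dict(d.get("movement", {}))
        if "individuals" in movement:
            movement["individuals"] = [
                iy if isinstance(iy, IndividualYear) else IndividualYear(**iy)
                for iy in movement["individuals"]
            ]
        return cls(
            seed=int(d["seed"]),
            landscape=LandscapeConfig(**d.get("landscape", {})),
            weather=WeatherConfig(**d.get("weather", {})),
            forage=ForageConfig(**forage),
            movement=MovementConfig(**movement),
            fitting=FittingConfig(**d.get("fitting", {})),
            analyze=bool(d.get("analyze", True)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0) -> RunConfig:
    """The demo configuration: 6 individual-years (3 animals × 2 seasons,
    one a drought year) of 500 steps each on a ~1,020-ha enclosure."""
    return RunConfig(seed=seed)
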