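"""Configuration objects for synthetic-study generation and pipeline runs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Molar gas constant, J K^-1 mol^-1.
R_GAS = 8.3144

#: Response labels used throughout the package.
RESPONSE_PV = "PV"
RESPONSE_TBARS = "TBARS"


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth kinetic parameters for one process/response pair.

    ``order`` is ``"zero"`` (linear accumulation, ``k0`` in response
    units per day) or ``"first"`` (exponential growth, ``k0`` in day^-1).
    ``Ea`` is the activation energy in J mol^-1 and ``y0`` the initial
    response value.
    """

    order: str
    Ea: float
    k0: float
    y0: float

    def __post_init__(self) -> None:
        if self.order not in ("zero", "first"):
            raise ValueError(f"kinetic order must be 'zero' or 'first', got {self.order!r}")
        if self.y0 <= 0:
            raise ValueError("y0 must be positive")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.Ea < 0:
            raise ValueError("Ea must be non-negative")


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    Amplitude responds linearly to the latent oxidation state:
    ``amp = base_amplitude + pv_coeff * PV + tbars_coeff * TBARS``.
    """

    center: float
    width_sigma: float = 15.0
    base_amplitude: float = 0.2
    pv_coeff: float = 0.0
    tbars_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("band width_sigma must be positive")


def default_kinetics() -> dict[str, dict[str, KineticTruth]]:
    """Per-process, per-response kinetic ground truth.

    Values chosen so that simulated PV stays within roughly 0.7-3.2
    meq/kg and TBARS within 7-27 nmol/g over 20 days at 30-50 degC.
    """
    return {
        "DP": {
            RESPONSE_PV: KineticTruth(order="first", Ea=52_000.0, k0=1.885e7, y0=0.73),
            RESPONSE_TBARS: KineticTruth(order="zero", Ea=55_000.0, k0=7.4e8, y0=7.5),
        },
        "HP": {
            RESPONSE_PV: KineticTruth(order="first", Ea=48_000.0, k0=3.49e6, y0=0.93),
            RESPONSE_TBARS: KineticTruth(order="zero", Ea=50_000.0, k0=1.09e8, y0=7.0),
        },
    }


def default_bands() -> list[Band]:
    """Twelve stylized mid-IR bands on the 401-4000 cm^-1 grid.

    The bands at 2854 and 1745 cm^-1 carry the primary-oxidation (PV)
    signal; 3010 and 1745 cm^-1 carry the secondary-oxidation (TBARS)
    signal.
    """
    return [
        Band(center=3313.0, base_amplitude=0.40),
        Band(center=3010.0, base_amplitude=0.15, tbars_coeff=0.003),
        Band(center=2925.0, base_amplitude=0.30),
        Band(center=2854.0, base_amplitude=0.30, pv_coeff=0.06),
        Band(center=1745.0, base_amplitude=0.35, pv_coeff=0.04, tbars_coeff=0.004),
        Band(center=1645.0, base_amplitude=0.30),
        Band(center=1458.0, base_amplitude=0.20),
        Band(center=1377.0, base_amplitude=0.18),
        Band(center=1248.0, base_amplitude=0.15),
        Band(center=1157.0, base_amplitude=0.22),
        Band(center=1049.0, base_amplitude=0.28),
        Band(center=715.0, base_amplitude=0.12),
    ]


@dataclass
class SyntheticConfig:
    """Full description of a simulated storage study.

    The default design mirrors a 2-process x 3-temperature x 4-stored-
    timepoint layout with two unpackaged day-0 controls (one per
    process), 26 distinct samples, 3 replicates each -> 78 spectra.
    """

    seed: int = 0
    processes: list[str] = field(default_factory=lambda: ["DP", "HP"])
    temperatures_C: list[float] = field(default_factory=lambda: [30.0, 40.0, 50.0])
    days: list[float] = field(default_factory=lambda: [0.0, 5.0, 10.0, 15.0, 20.0])
    replicates: int = 3
    kinetics: dict[str, dict[str, KineticTruth]] = field(default_factory=default_kinetics)
    noise_sd: float = 0.05
    band_table: list[Band] = field(default_factory=default_bands)
    scatter_sd: float = 0.05
    baseline_slope_sd: float = 5e-6
    spectral_noise_sd: float = 0.002
    n_channels: int = 1869
    wn_min: float = 401.0
    wn_max: float = 4000.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if self.n_channels < 2:
            raise ValueError("n_channels must be at least 2")
        for name, seq in (("temperatures_C", self.temperatures_C), ("days", self.days)):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if any(d < 0 for d in self.days):
            raise ValueError("days must be non-negative")
        for name in ("noise_sd", "scatter_sd", "baseline_slope_sd", "spectral_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wn_min >= self.wn_max:
            raise ValueError("wn_min must be below wn_max")
        for band in self.band_table:
            if not (self.wn_min <= band.center <= self.wn_max):
                raise ValueError(
                    f"band center {band.center} outside grid [{self.wn_min}, {self.wn_max}]"
                )

    @property
    def responses(self) -> list[str]:
        labels: list[str] = []
        for per_process in self.kinetics.values():
            for resp in per_process:
                if resp not in labels:
                    labels.append(resp)
        return labels

    def to_dict(self) -> dict[str, Any]:
        return _as_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SyntheticConfig":
        data = dict(data)
        if "kinetics" in data:
            data["kinetics"] = {
                process: {resp: KineticTruth(**entry) for resp, entry in per.items()}
                for process, per in data["kinetics"].items()
            }
        if "band_table" in data:
            data["band_table"] = [Band(**b) for b in data["band_table"]]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _as_plain(obj: Any) -> Any:
    """Recursively convert to YAML/JSON-friendly plain containers."""
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj
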