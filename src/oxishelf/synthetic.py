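"""Synthetic storage-study generator.

Produces oxidation trajectories from configured zero/first-order kinetics
with Arrhenius temperature dependence, plus FTIR-like spectra whose band
amplitudes depend linearly on the latent PV/TBARS state of each sample.
Spectra are corrupted by multiplicative scatter, linear baseline drift
and additive channel noise — exactly the artefacts SNV and derivative
preprocessing are meant to remove.

Everything is deterministic given ``config.seed``: every random stream is
derived from the seed plus a stable label, so regeneration is bit-for-bit
reproducible and individual pieces can be regenerated in isolation.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import R_GAS, Band, KineticTruth, SyntheticConfig
from .dataset import SpectralDataset
from .kinetics import OxidationSeries, celsius_to_kelvin


def _rng(seed: int, *tokens: object) -> np.random.Generator:
    """Independent generator keyed by (seed, label path)."""
    entropy = [int(seed) & 0xFFFFFFFF] + [
        zlib.crc32(str(t).encode("utf8")) for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def kinetic_mean(truth: KineticTruth, temperature_C: float, t_days: np.ndarray) -> np.ndarray:
    """Noise-free trajectory at the Arrhenius rate k(T)."""
    t_days = np.asarray(t_days, dtype=float)
    k = truth.k0 * math.exp(-truth.Ea / (R_GAS * celsius_to_kelvin(temperature_C)))
    if truth.order == "zero":
        return truth.y0 + k * t_days
    return truth.y0 * np.exp(k * t_days)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    oxidation: list[OxidationSeries]
    spectra: SpectralDataset
    truth: pd.DataFrame  # sample_id, process, temperature_C, day, replicate, PV, TBARS


def _kinetics_entry(config: SyntheticConfig, process: str, response: str) -> KineticTruth:
    try:
        return config.kinetics[process][response]
    except KeyError:
        raise KeyError(
            f"no kinetic ground truth configured for process {process!r}, "
            f"response {response!r}"
        ) from None


def generate_oxidation_series(
    config: SyntheticConfig,
    process: str,
    response: str,
    temperature_C: float,
    day0_values: np.ndarray | None = None,
) -> OxidationSeries:
    """Replicate-resolved trajectory for one design cell.

    ``day0_values`` (length ``config.replicates``) overrides the day-0
    replicate draws so that shared unpackaged controls can be injected
    across temperatures by :func:`make_study`.
    """
    if temperature_C not in config.temperatures_C:
        raise ValueError(f"temperature {temperature_C} not in study design")
    truth = _kinetics_entry(config, process, response)
    days = np.asarray(config.days, dtype=float)
    mean = kinetic_mean(truth, temperature_C, days)
    rng = _rng(config.seed, "oxidation", process, response, f"{temperature_C:.6g}")
    noise = rng.normal(0.0, config.noise_sd, size=(days.size, config.replicates))
    values = mean[:, None] + noise
    if day0_values is not None:
        day0_values = np.asarray(day0_values, dtype=float)
        if day0_values.shape != (config.replicates,):
            raise ValueError("day0_values must have one entry per replicate")
        values[days == 0.0, :] = day0_values
    reps = np.arange(1, config.replicates + 1)
    return OxidationSeries(
        response=response,
        process=process,
        temperature_K=celsius_to_kelvin(temperature_C),
        times_days=np.repeat(days, config.replicates),
        values=values.ravel(),
        replicate=np.tile(reps, days.size),
    )


def _band_amplitude(band: Band, pv: float, tbars: float) -> float:
    amp = band.base_amplitude + band.pv_coeff * pv + band.tbars_coeff * tbars
    if amp < 0:
        warnings.warn(
            f"band at {band.center} cm^-1 produced negative amplitude {amp:.4g}; "
            "clipped to 0",
            stacklevel=3,
        )
        amp = 0.0
    return amp


def generate_spectra(config: SyntheticConfig, latent_states: pd.DataFrame) -> SpectralDataset:
    """Spectra for a table of per-sample latent (PV, TBARS) states.

    ``latent_states`` needs columns ``sample_id, process, temperature_C,
    day, replicate, PV, TBARS``.  Each spectrum is

        scatter * (sum of Gaussian bands + linear baseline) + noise

    with scatter lognormal, baseline slope Gaussian, and i.i.d. channel
    noise, all drawn from streams keyed by the sample id.
    """
    required = {"sample_id", "process", "temperature_C", "day", "replicate", "PV", "TBARS"}
    missing = required - set(latent_states.columns)
    if missing:
        raise ValueError(f"latent_states missing columns {sorted(missing)}")
    wn = np.linspace(config.wn_min, config.wn_max, config.n_channels)
    matrix = np.empty((len(latent_states), config.n_channels))
    for i, row in enumerate(latent_states.itertuples(index=False)):
        clean = np.zeros_like(wn)
        for band in config.band_table:
            amp = _band_amplitude(band, row.PV, row.TBARS)
            clean += amp * np.exp(-((wn - band.center) ** 2) / (2.0 * band.width_sigma**2))
        rng = _rng(config.seed, "spectrum", row.sample_id)
        slope = rng.normal(0.0, config.baseline_slope_sd)
        scatter = math.exp(rng.normal(0.0, config.scatter_sd))
        baseline = slope * (wn - wn.mean())
        noise = rng.normal(0.0, config.spectral_noise_sd, size=wn.size)
        matrix[i] = scatter * (clean + baseline) + noise
    metadata = latent_states[
        ["sample_id", "process", "temperature_C", "day", "replicate"]
    ].reset_index(drop=True)
    return SpectralDataset(wavenumbers=wn, absorbance=matrix, metadata=metadata)


def make_study(config: SyntheticConfig) -> SyntheticStudy:
    """Full synthetic study: oxidation series plus matching spectra.

    Day-0 samples are unpackaged controls shared across temperatures
    (one distinct sample per process), so the default design counts
    |processes| * |temperatures| * |days>0| + |processes| distinct
    samples, each measured in ``replicates`` replicates.
    """
    responses = config.responses
    reps = np.arange(1, config.replicates + 1)

    # Shared day-0 control draws, one per (process, response).
    control_values: dict[tuple[str, str], np.ndarray] = {}
    for process in config.processes:
        for response in responses:
            truth = _kinetics_entry(config, process, response)
            rng = _rng(config.seed, "control", process, response)
            control_values[(process, response)] = truth.y0 + rng.normal(
                0.0, config.noise_sd, size=config.replicates
            )

    series: list[OxidationSeries] = []
    cell_values: dict[tuple[str, str, float], np.ndarray] = {}
    for process in config.processes:
        for temperature in config.temperatures_C:
            for response in responses:
                s = generate_oxidation_series(
                    config,
                    process,
                    response,
                    temperature,
                    day0_values=control_values[(process, response)],
                )
                series.append(s)
                cell_values[(process, response, temperature)] = s.values.reshape(
                    len(config.days), config.replicates
                )

    rows = []
    for process in config.processes:
        for r_i, rep in enumerate(reps):
            rows.append(
                {
                    "sample_id": f"{process}-ctrl-d0-r{rep}",
                    "process": process,
                    "temperature_C": float("nan"),
                    "day": 0.0,
                    "replicate": int(rep),
                    "PV": float(control_values[(process, "PV")][r_i])
                    if "PV" in responses
                    else float("nan"),
                    "TBARS": float(control_values[(process, "TBARS")][r_i])
                    if "TBARS" in responses
                    else float("nan"),
                }
            )
        for temperature in config.temperatures_C:
            for d_i, day in enumerate(config.days):
                if day == 0.0:
                    continue
                for r_i, rep in enumerate(reps):
                    row = {
                        "sample_id": f"{process}-T{temperature:g}-d{day:g}-r{rep}",
                        "process": process,
                        "temperature_C": float(temperature),
                        "day": float(day),
                        "replicate": int(rep),
                    }
                    for response in ("PV", "TBARS"):
                        row[response] = (
                            float(cell_values[(process, response, temperature)][d_i, r_i])
                            if response in responses
                            else float("nan")
                        )
                    rows.append(row)
    truth = pd.DataFrame(rows)
    spectra = generate_spectra(config, truth)
    return SyntheticStudy(config=config, oxidation=series, spectra=spectra, truth=truth)


def oxidation_table(study: SyntheticStudy) -> pd.DataFrame:
    """Long table ``process,response,temperature_C,day,replicate,value``."""
    frames = []
    for s in study.oxidation:
        frames.append(
            pd.DataFrame(
                {
                    "process": s.process,
                    "response": s.response,
                    "temperature_C": round(s.temperature_C, 6),
                    "day": s.times_days,
                    "replicate": s.replicate,
                    "value": s.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
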