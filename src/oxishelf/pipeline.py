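"""End-to-end orchestration: simulate (or load) -> kinetics -> preprocess
-> PLS/PCA -> report files.

All tables are computed in memory first and written in one pass at the
end, so a validation failure part-way through leaves no partial output
directory behind.  The manifest records the seed, a hash of the resolved
configuration and the preprocessing log, which is enough to reproduce
every output file bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (
    auto_predict,
    loocv,
    pca,
    pls_fit,
    select_bands,
    vip_scores,
)
from .config import SyntheticConfig, _as_plain
from .dataset import SpectralDataset, read_spectra_csv, write_spectra_csv
from .kinetics import OxidationSeries, celsius_to_kelvin, shelf_life_table
from .preprocess import DEFAULT_RECIPE, preprocess
from .synthetic import SyntheticStudy, make_study, oxidation_table


@dataclass
class InputPaths:
    """File-based inputs: spectra + metadata sidecar, an oxidation table,
    and a per-sample response table (``sample_id, PV, TBARS``)."""

    spectra: str
    metadata: str
    oxidation: str
    sample_responses: str
    dialect: str = "wide"


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    responses: list[str] = field(default_factory=lambda: ["PV", "TBARS"])
    endpoints: dict[str, float] = field(default_factory=lambda: {"PV": 2.0, "TBARS": 10.0})
    recipe: list[str] = field(default_factory=lambda: list(DEFAULT_RECIPE))
    n_lv: int = 10
    vip_threshold: float = 1.0
    pca_augmented: bool = True
    out_dir: str = "oxishelf_out"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("provide exactly one of a synthetic config or input paths")
        missing = [r for r in self.responses if r not in self.endpoints]
        if missing:
            raise ValueError(f"no endpoint configured for response(s) {missing}")

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "synthetic" in data and data["synthetic"] is not None:
            data["synthetic"] = SyntheticConfig.from_dict(data["synthetic"])
        if "inputs" in data and data["inputs"] is not None:
            data["inputs"] = InputPaths(**data["inputs"])
        cfg = cls(**data)
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
            if cfg.synthetic is not None:
                cfg = dataclasses.replace(
                    cfg, synthetic=dataclasses.replace(cfg.synthetic, seed=seed)
                )
        if out_dir is not None:
            cfg = dataclasses.replace(cfg, out_dir=out_dir)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        data = {
            "seed": self.seed,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "inputs": dataclasses.asdict(self.inputs) if self.inputs else None,
            "responses": list(self.responses),
            "endpoints": dict(self.endpoints),
            "recipe": list(self.recipe),
            "n_lv": self.n_lv,
            "vip_threshold": self.vip_threshold,
            "pca_augmented": self.pca_augmented,
            "out_dir": self.out_dir,
        }
        return _as_plain(data)

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("out_dir")  # output location must not change the run identity
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf8")
        ).hexdigest()


def read_oxidation_csv(path: str | Path) -> list[OxidationSeries]:
    """Parse ``process,response,temperature_C,day,replicate,value`` rows
    into one series per process x response x temperature."""
    frame = pd.read_csv(path)
    required = {"process", "response", "temperature_C", "day", "replicate", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"oxidation CSV missing columns {sorted(missing)}")
    series = []
    for (process, response, temp), grp in frame.groupby(
        ["process", "response", "temperature_C"], sort=True
    ):
        series.append(
            OxidationSeries(
                response=str(response),
                process=str(process),
                temperature_K=celsius_to_kelvin(float(temp)),
                times_days=grp["day"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                replicate=grp["replicate"].to_numpy(int),
            )
        )
    return series


def _load_stage(config: RunConfig) -> tuple[list[OxidationSeries], SpectralDataset, pd.DataFrame]:
    """Returns (oxidation series, spectra, per-sample response table)."""
    if config.synthetic is not None:
        study: SyntheticStudy = make_study(config.synthetic)
        return study.oxidation, study.spectra, study.truth
    assert config.inputs is not None
    series = read_oxidation_csv(config.inputs.oxidation)
    spectra = read_spectra_csv(
        config.inputs.spectra, config.inputs.metadata, dialect=config.inputs.dialect
    )
    responses = pd.read_csv(config.inputs.sample_responses)
    responses["sample_id"] = responses["sample_id"].astype(str)
    missing = set(spectra.sample_ids) - set(responses["sample_id"])
    if missing:
        raise ValueError(f"sample response table missing sample(s): {sorted(missing)}")
    responses = responses.set_index("sample_id").loc[spectra.sample_ids].reset_index()
    return series, spectra, responses


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write all report files.

    Returns a dict with the in-memory tables plus the manifest.
    """
    series, spectra, sample_responses = _load_stage(config)

    # --- kinetics / shelf life -------------------------------------------
    shelf = shelf_life_table(series, config.endpoints)

    # --- preprocessing ----------------------------------------------------
    processed = preprocess(spectra, config.recipe)
    processing_label = " + ".join(config.recipe) if config.recipe else "raw"
    X = processed.absorbance

    # --- PLS per response -------------------------------------------------
    pls_rows = []
    vip_frames = []
    band_rows = []
    obs_pred_frames = []
    for response in config.responses:
        y = sample_responses[response].to_numpy(float)
        cv = loocv(X, y, config.n_lv)
        auto = auto_predict(X, y, config.n_lv)
        model = pls_fit(X, y, config.n_lv)
        vip = vip_scores(model, threshold=config.vip_threshold)
        intervals = select_bands(vip, processed.wavenumbers)
        pls_rows.append(
            {
                "response": response,
                "n": y.size,
                "processing": processing_label,
                "LVs": config.n_lv,
                "RMSECV": cv.rmse,
                "R2_cv": cv.r_squared,
                "RPD_cv": cv.rpd,
                "RMSE_auto": auto.rmse,
                "R2_auto": auto.r_squared,
                "RPD_auto": auto.rpd,
            }
        )
        vip_frames.append(
            pd.DataFrame(
                {
                    "response": response,
                    "wavenumber_cm1": processed.wavenumbers,
                    "vip": vip.scores,
                }
            )
        )
        for low, high in intervals:
            band_rows.append(
                {"response": response, "low_cm1": low, "high_cm1": high}
            )
        obs_pred_frames.append(
            pd.DataFrame(
                {
                    "response": response,
                    "sample_id": processed.sample_ids,
                    "observed": y,
                    "predicted_loocv": cv.predictions,
                    "predicted_auto": auto.predictions,
                }
            )
        )
    pls_summary = pd.DataFrame(pls_rows)
    vip_table = pd.concat(vip_frames, ignore_index=True)
    band_table = pd.DataFrame(band_rows, columns=["response", "low_cm1", "high_cm1"])
    obs_pred = pd.concat(obs_pred_frames, ignore_index=True)

    # --- PCA --------------------------------------------------------------
    if config.pca_augmented:
        extra = sample_responses[config.responses].to_numpy(float)
        pca_matrix = np.hstack([X, extra])
    else:
        pca_matrix = X
    n_comp = min(10, pca_matrix.shape[0] - 1, pca_matrix.shape[1])
    pca_result = pca(pca_matrix, n_comp)
    pca_scores = pd.DataFrame(
        pca_result.scores, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    pca_scores.insert(0, "sample_id", processed.sample_ids)
    pca_explained = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(n_comp)],
            "explained_variance_pct": pca_result.explained_variance_pct,
        }
    )

    manifest = {
        "package": "oxishelf",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "preprocessing_log": processed.preprocessing_log,
        "n_samples": int(X.shape[0]),
        "n_channels": int(X.shape[1]),
    }

    # --- write everything (only after all stages succeeded) ---------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shelf.to_csv(out / "shelf_life.csv", index=False)
    pls_summary.to_csv(out / "pls_summary.csv", index=False)
    vip_table.to_csv(out / "vip_scores.csv", index=False)
    band_table.to_csv(out / "vip_bands.csv", index=False)
    obs_pred.to_csv(out / "observed_predicted.csv", index=False)
    pca_scores.to_csv(out / "pca_scores.csv", index=False)
    pca_explained.to_csv(out / "pca_explained.csv", index=False)
    if config.synthetic is not None:
        oxidation_table_df = oxidation_table(
            SyntheticStudy(config.synthetic, series, spectra, sample_responses)
        )
        oxidation_table_df.to_csv(out / "oxidation.csv", index=False)
        write_spectra_csv(
            spectra,
            out / "spectra.csv",
            out / "spectra_metadata.csv",
            dialect="wide",
        )
        sample_responses.to_csv(out / "sample_responses.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "shelf_life": shelf,
        "pls_summary": pls_summary,
        "vip_scores": vip_table,
        "vip_bands": band_table,
        "observed_predicted": obs_pred,
        "pca_scores": pca_scores,
        "pca_explained": pca_explained,
        "manifest": manifest,
    }
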