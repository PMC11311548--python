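"""Spectral dataset container and its CSV dialects.

Spectra travel as a samples x channels absorbance matrix on a strictly
ascending wavenumber grid, with a per-sample metadata table keyed by
``sample_id`` and an ordered log of applied preprocessing transforms.

Two on-disk dialects are supported:

* wide  — first column ``wavenumber_cm1``, one column per sample id;
* long  — columns ``sample_id, wavenumber_cm1, absorbance``.

Metadata lives in a sidecar CSV (``sample_id, process, temperature_C,
day, replicate``); the preprocessing log in a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "process", "temperature_C", "day", "replicate"]


@dataclass
class SpectralDataset:
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    metadata: pd.DataFrame
    preprocessing_log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} channels but the grid "
                f"has {self.wavenumbers.size}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if "sample_id" not in self.metadata.columns:
            raise ValueError("metadata must contain a sample_id column")
        if len(self.metadata) != self.absorbance.shape[0]:
            raise ValueError(
                f"metadata has {len(self.metadata)} rows for "
                f"{self.absorbance.shape[0]} spectra"
            )
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def sample_ids(self) -> list[str]:
        return self.metadata["sample_id"].astype(str).tolist()

    def with_absorbance(
        self, absorbance: np.ndarray, log_entry: dict[str, Any] | None = None
    ) -> "SpectralDataset":
        """New dataset with replaced matrix and optionally extended log."""
        log = [dict(e) for e in self.preprocessing_log]
        if log_entry is not None:
            log.append(log_entry)
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=np.asarray(absorbance, dtype=float).copy(),
            metadata=self.metadata.copy(),
            preprocessing_log=log,
        )


def to_wide_frame(dataset: SpectralDataset) -> pd.DataFrame:
    frame = pd.DataFrame(
        dataset.absorbance.T, columns=dataset.sample_ids
    )
    frame.insert(0, "wavenumber_cm1", dataset.wavenumbers)
    return frame


def to_long_frame(dataset: SpectralDataset) -> pd.DataFrame:
    ids = np.repeat(dataset.sample_ids, dataset.n_channels)
    wns = np.tile(dataset.wavenumbers, dataset.n_samples)
    return pd.DataFrame(
        {
            "sample_id": ids,
            "wavenumber_cm1": wns,
            "absorbance": dataset.absorbance.ravel(),
        }
    )


def write_spectra_csv(
    dataset: SpectralDataset,
    spectra_path: str | Path,
    metadata_path: str | Path | None = None,
    dialect: str = "wide",
    log_path: str | Path | None = None,
) -> None:
    spectra_path = Path(spectra_path)
    if dialect == "wide":
        to_wide_frame(dataset).to_csv(spectra_path, index=False)
    elif dialect == "long":
        to_long_frame(dataset).to_csv(spectra_path, index=False)
    else:
        raise ValueError(f"unknown spectra dialect {dialect!r}")
    if metadata_path is not None:
        dataset.metadata.to_csv(metadata_path, index=False)
    if log_path is not None:
        Path(log_path).write_text(json.dumps(dataset.preprocessing_log, indent=2))


def read_spectra_csv(
    spectra_path: str | Path,
    metadata_path: str | Path,
    dialect: str = "wide",
) -> SpectralDataset:
    """Load a spectra CSV plus metadata sidecar.

    Descending input grids are reversed to ascending (with a log note).
    Every spectrum column/sample id must have a metadata row.
    """
    metadata = pd.read_csv(metadata_path)
    if "sample_id" not in metadata.columns:
        raise ValueError("metadata sidecar must contain a sample_id column")
    metadata["sample_id"] = metadata["sample_id"].astype(str)

    if dialect == "wide":
        frame = pd.read_csv(spectra_path)
        if "wavenumber_cm1" != frame.columns[0]:
            raise ValueError("wide spectra CSV must start with a wavenumber_cm1 column")
        wavenumbers = frame["wavenumber_cm1"].to_numpy(dtype=float)
        sample_ids = [str(c) for c in frame.columns[1:]]
        matrix = frame.iloc[:, 1:].to_numpy(dtype=float).T
    elif dialect == "long":
        frame = pd.read_csv(spectra_path)
        required = {"sample_id", "wavenumber_cm1", "absorbance"}
        if not required.issubset(frame.columns):
            raise ValueError(f"long spectra CSV must contain columns {sorted(required)}")
        frame["sample_id"] = frame["sample_id"].astype(str)
        pivot = frame.pivot(index="sample_id", columns="wavenumber_cm1", values="absorbance")
        if pivot.isna().any().any():
            raise ValueError("ragged channel counts: some samples miss wavenumbers")
        # preserve first-appearance sample order from the file
        order = frame["sample_id"].drop_duplicates().tolist()
        pivot = pivot.loc[order]
        wavenumbers = pivot.columns.to_numpy(dtype=float)
        sample_ids = [str(i) for i in pivot.index]
        matrix = pivot.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown spectra dialect {dialect!r}")

    log: list[dict[str, Any]] = []
    if wavenumbers.size >= 2 and wavenumbers[0] > wavenumbers[-1]:
        logger.info("input wavenumber grid is descending; reversing to ascending")
        wavenumbers = wavenumbers[::-1]
        matrix = matrix[:, ::-1]
        log.append({"transform": "reverse_grid", "reason": "descending input grid"})

    known = set(metadata["sample_id"])
    missing = [sid for sid in sample_ids if sid not in known]
    if missing:
        raise ValueError(f"samples missing from metadata sidecar: {missing}")
    meta = (
        metadata.set_index("sample_id").loc[sample_ids].reset_index()
    )
    return SpectralDataset(
        wavenumbers=wavenumbers,
        absorbance=matrix,
        metadata=meta,
        preprocessing_log=log,
    )
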