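"""Wet-lab assay arithmetic: moisture content, peroxide value, and
TBARS-derived malondialdehyde."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

#: Molar mass of malondialdehyde, g/mol.
MDA_MOLAR_MASS = 72.07


@dataclass(frozen=True)
class TitrationReading:
    """Iodometric titration volumes plus the oil mass titrated."""

    titre_sample_mL: float
    titre_blank_mL: float
    oil_mass_g: float

    def __post_init__(self) -> None:
        if self.oil_mass_g <= 0:
            raise ValueError("oil_mass_g must be positive")
        if self.titre_sample_mL < 0 or self.titre_blank_mL < 0:
            raise ValueError("titre volumes must be non-negative")


@dataclass(frozen=True)
class TbarsReading:
    """Two-wavelength absorbance reading for the MDA-TBA adduct.

    532 nm carries the signal, 600 nm the turbidity baseline; the default
    extinction coefficient is 155 mM^-1 cm^-1 at 1 cm path.
    """

    a532: float
    a600: float
    extract_volume_mL: float
    sample_mass_g: float
    epsilon_mM_cm: float = 155.0
    path_cm: float = 1.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("epsilon_mM_cm", "path_cm", "extract_volume_mL", "sample_mass_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def moisture_percent(weight_loss_g: float, sample_weight_g: float) -> float:
    """Moisture on a wet basis: 100 * loss / sample weight."""
    if sample_weight_g <= 0:
        raise ValueError("sample_weight_g must be positive")
    if weight_loss_g < 0 or weight_loss_g > sample_weight_g:
        raise ValueError("weight loss must lie in [0, sample weight]")
    # min() guards the one-ulp overshoot when loss == sample weight
    return min(100.0 * weight_loss_g / sample_weight_g, 100.0)


def peroxide_value(reading: TitrationReading) -> float:
    """Peroxide value in meq peroxide per kg oil.

    PV = 2 * (sample titre - blank titre) / oil mass.  A blank exceeding
    the sample signals assay failure; the negative value is returned
    as-is with a warning rather than clipped.
    """
    pv = 2.0 * (reading.titre_sample_mL - reading.titre_blank_mL) / reading.oil_mass_g
    if pv < 0:
        warnings.warn(
            "blank titre exceeds sample titre: negative peroxide value "
            f"({pv:.4g} meq/kg) suggests assay failure",
            stacklevel=2,
        )
    return pv


def tbars_mda(reading: TbarsReading) -> float:
    """Malondialdehyde content in nmol per g sample.

    The baseline-corrected absorbance (A532 - A600) converts to a molar
    concentration via Beer-Lambert (mM = nmol/uL), then to an amount via
    the extract volume and back to a per-gram basis.
    """
    if reading.a532 < reading.a600:
        warnings.warn(
            f"A532 ({reading.a532}) below A600 ({reading.a600}): "
            "negative MDA returned",
            stacklevel=2,
        )
    conc_mM = (reading.a532 - reading.a600) / (reading.epsilon_mM_cm * reading.path_cm)
    return (
        conc_mM
        * reading.extract_volume_mL
        * 1000.0
        * reading.dilution_factor
        / reading.sample_mass_g
    )


def tbars_nmol_g_to_mg_kg(nmol_per_g: float) -> float:
    """Convert MDA from nmol/g to mg/kg (x 72.07 g/mol / 1000)."""
    return nmol_per_g * MDA_MOLAR_MASS / 1000.0


def derive_pv_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Append ``pv_meq_kg`` to a table with columns
    ``titre_sample_mL, titre_blank_mL, oil_mass_g``."""
    out = frame.copy()
    out["pv_meq_kg"] = [
        peroxide_value(
            TitrationReading(row.titre_sample_mL, row.titre_blank_mL, row.oil_mass_g)
        )
        for row in frame.itertuples(index=False)
    ]
    return out


def derive_tbars_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Append ``tbars_nmol_g`` to a table with columns
    ``a532, a600, extract_volume_mL, sample_mass_g`` (optional
    ``epsilon_mM_cm, path_cm, dilution_factor``)."""
    out = frame.copy()
    optional = ("epsilon_mM_cm", "path_cm", "dilution_factor")
    values = []
    for row in frame.to_dict(orient="records"):
        kwargs = {
            "a532": row["a532"],
            "a600": row["a600"],
            "extract_volume_mL": row["extract_volume_mL"],
            "sample_mass_g": row["sample_mass_g"],
        }
        for name in optional:
            if name in row and pd.notna(row[name]):
                kwargs[name] = row[name]
        values.append(tbars_mda(TbarsReading(**kwargs)))
    out["tbars_nmol_g"] = values
    return out
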