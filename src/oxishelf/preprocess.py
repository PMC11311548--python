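"""Spectral pretreatments applied before multivariate modelling.

Two transforms are provided: standard normal variate (per-spectrum
centering/scaling, removing multiplicative scatter and additive offsets)
and a Savitzky-Golay first derivative taken with respect to the physical
wavenumber axis (units: absorbance per cm^-1).  ``preprocess`` chains
registered transforms in order; the default recipe is SNV then the
first derivative.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset


def snv(dataset: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: each spectrum to mean 0, sample sd 1.

    Uses the n-1 denominator.  A constant spectrum has no scale to
    normalise and raises, naming the offending sample.
    """
    A = dataset.absorbance
    sd = A.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        sid = dataset.sample_ids[int(flat[0])]
        raise ValueError(f"SNV undefined for constant spectrum (sample {sid!r})")
    out = (A - A.mean(axis=1, keepdims=True)) / sd[:, None]
    return dataset.with_absorbance(out, {"transform": "snv"})


def first_derivative(
    dataset: SpectralDataset, window: int = 11, polyorder: int = 2
) -> SpectralDataset:
    """Savitzky-Golay first derivative along the wavenumber axis.

    Requires an (approximately) uniform grid; the derivative is scaled by
    the physical channel spacing so values carry real units.  Edges are
    handled by evaluating the polynomial fitted to the truncated window.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > dataset.n_channels:
        raise ValueError("window exceeds channel count")
    spacing = np.diff(dataset.wavenumbers)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError("first_derivative requires a uniform wavenumber grid")
    out = savgol_filter(
        dataset.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=1,
        delta=float(spacing.mean()),
        axis=1,
        mode="interp",
    )
    return dataset.with_absorbance(
        out, {"transform": "deriv1", "window": window, "polyorder": polyorder}
    )


TRANSFORMS: dict[str, Callable[..., SpectralDataset]] = {
    "snv": snv,
    "deriv1": first_derivative,
    "first_derivative": first_derivative,
}

DEFAULT_RECIPE: list[str] = ["snv", "deriv1"]


def preprocess(
    dataset: SpectralDataset,
    recipe: Sequence[str | tuple[str, dict]] | None = None,
) -> SpectralDataset:
    """Apply an ordered recipe of named transforms.

    Each step is a transform name or a ``(name, kwargs)`` pair.  Note the
    order matters: SNV-then-derivative and derivative-then-SNV are
    different pipelines.  An empty recipe returns the dataset unchanged.
    """
    if recipe is None:
        recipe = DEFAULT_RECIPE
    out = dataset
    for step in recipe:
        if isinstance(step, str):
            name, kwargs = step, {}
        else:
            name, kwargs = step
        if name not in TRANSFORMS:
            raise KeyError(
                f"unknown transform {name!r}; registered: {sorted(TRANSFORMS)}"
            )
        out = TRANSFORMS[name](out, **kwargs)
    return out
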