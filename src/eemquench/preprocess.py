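"""EEM correction chain: inner-filter effect, scatter removal, median filter.

Order of application in :func:`preprocess_pipeline` is IFE correction,
then Rayleigh/Raman scatter masking + interpolation, then a 2-D median
filter. Scatter band half-widths and the water Raman shift are declared
defaults, exposed through :class:`PreprocessConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter

from eemquench.core import EEM, AbsorbanceSpectrum, SamplePair
from eemquench.errors import ValidationError

__all__ = [
    "ScatterWidths",
    "PreprocessConfig",
    "ife_correct",
    "remove_scatter",
    "median_filter_eem",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class ScatterWidths:
    """Half-widths (nm) of the masked scatter bands."""

    rayleigh1_nm: float = 15.0
    rayleigh2_nm: float = 15.0
    raman_nm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.rayleigh1_nm, self.rayleigh2_nm, self.raman_nm) < 0:
            raise ValidationError("scatter band widths must be >= 0")


@dataclass(frozen=True)
class PreprocessConfig:
    ife_enabled: bool = True
    ife_pathlength_cm: float = 1.0
    scatter_enabled: bool = True
    scatter_widths: ScatterWidths = field(default_factory=ScatterWidths)
    raman_shift_cm1: float = 3400.0
    median_enabled: bool = True
    median_kernel: int = 3


def ife_correct(
    eem: EEM, absorbance: AbsorbanceSpectrum, pathlength_cm: float = 1.0
) -> EEM:
    """Absorbance-based (ABA) inner-filter-effect correction.

    Each cell is multiplied by ``10 ** ((A(ex) + A(em)) / 2 * pathlength)``,
    so the correction factor is >= 1 whenever absorbance is nonnegative.
    """
    if pathlength_cm <= 0:
        raise ValidationError("pathlength must be positive (cm)")
    a_ex = absorbance.at(eem.grid.excitation)
    a_em = absorbance.at(eem.grid.emission)
    factor = 10.0 ** (
        (a_ex[:, None] + a_em[None, :]) / 2.0 * pathlength_cm
    )
    return EEM(eem.grid, eem.intensity * factor, eem.mask.copy())


def ife_attenuate(
    eem: EEM, absorbance: AbsorbanceSpectrum, pathlength_cm: float = 1.0
) -> EEM:
    """Forward model of the inner-filter effect (inverse of ife_correct)."""
    a_ex = absorbance.at(eem.grid.excitation)
    a_em = absorbance.at(eem.grid.emission)
    factor = 10.0 ** (-(a_ex[:, None] + a_em[None, :]) / 2.0 * pathlength_cm)
    return EEM(eem.grid, eem.intensity * factor, eem.mask.copy())


def scatter_band_mask(
    eem: EEM,
    widths: ScatterWidths = ScatterWidths(),
    raman_shift_cm1: float = 3400.0,
) -> np.ndarray:
    """Boolean mask of cells inside the scatter bands.

    Bands: first-order Rayleigh (em = ex), second-order Rayleigh
    (em = 2*ex), and the solvent Raman line
    em = 1 / (1/ex - shift * 1e-7) with wavelengths in nm.
    """
    ex = eem.grid.excitation[:, None]
    em = eem.grid.emission[None, :]
    mask = np.abs(em - ex) <= widths.rayleigh1_nm
    mask |= np.abs(em - 2.0 * ex) <= widths.rayleigh2_nm
    raman_center = 1.0 / (1.0 / ex - raman_shift_cm1 * 1e-7)
    mask |= np.abs(em - raman_center) <= widths.raman_nm
    return mask


def _interp_rows(intensity: np.ndarray, mask: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """Fill masked cells by linear interpolation along emission, per row."""
    out = intensity.copy()
    for i in range(intensity.shape[0]):
        bad = mask[i]
        if not bad.any():
            continue
        good = ~bad
        if not good.any():
            out[i] = 0.0
            continue
        out[i, bad] = np.interp(
            emission[bad], emission[good], intensity[i, good]
        )
    return out


def remove_scatter(
    eem: EEM,
    widths: ScatterWidths = ScatterWidths(),
    raman_shift_cm1: float = 3400.0,
) -> EEM:
    """Mask Rayleigh/Raman scatter bands and fill by interpolation.

    Interpolation is 1-D along the emission axis within each excitation
    row; rows that are entirely inside a band are zero-filled with a
    warning. Pre-existing masked cells are filled the same way, so the
    output has no masked cells.
    """
    band = scatter_band_mask(eem, widths, raman_shift_cm1)
    fill = band | eem.mask
    dead_rows = fill.all(axis=1)
    if dead_rows.any():
        warnings.warn(
            f"{int(dead_rows.sum())} excitation row(s) fully masked by "
            "scatter bands; zero-filled",
            stacklevel=2,
        )
    filled = _interp_rows(np.where(eem.mask, 0.0, eem.intensity), fill, eem.grid.emission)
    return EEM(eem.grid, filled)


def median_filter_eem(eem: EEM, kernel: int = 3) -> EEM:
    """2-D moving median with edge replication; ``kernel=1`` is identity."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError("median kernel must be an odd integer >= 1")
    if kernel == 1:
        return eem.copy()
    if eem.mask.any():
        raise ValidationError(
            "median filter requires a fully interpolated EEM (run scatter "
            "removal first)"
        )
    out = median_filter(eem.intensity, size=kernel, mode="nearest")
    return EEM(eem.grid, out)


def _preprocess_eem(
    eem: EEM, absorbance: AbsorbanceSpectrum | None, cfg: PreprocessConfig
) -> EEM:
    if cfg.ife_enabled:
        if absorbance is None:
            raise ValidationError(
                "IFE correction enabled but the sample carries no absorbance "
                "spectrum"
            )
        eem = ife_correct(eem, absorbance, cfg.ife_pathlength_cm)
    if cfg.scatter_enabled:
        eem = remove_scatter(eem, cfg.scatter_widths, cfg.raman_shift_cm1)
    if cfg.median_enabled:
        eem = median_filter_eem(eem, cfg.median_kernel)
    return eem


def preprocess_pipeline(pair: SamplePair, config: PreprocessConfig | None = None) -> SamplePair:
    """Apply the correction chain to both EEMs of a pair, in order."""
    cfg = config or PreprocessConfig()
    return replace(
        pair,
        original=_preprocess_eem(pair.original, pair.absorbance, cfg),
        quenched=_preprocess_eem(pair.quenched, pair.absorbance, cfg),
    )
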