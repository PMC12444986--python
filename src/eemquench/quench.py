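"""Quenching math: Stern-Volmer models and the apparent F0/F indicator.

The apparent F0/F of a PARAFAC component is the ratio of its Fmax in the
original sample to its Fmax after dosing an extrinsic quencher. For a
pure compound in the ideal regime this equals the Stern-Volmer ratio
1 + K[Q]; for a mixture of compounds sharing one spectral signature it is
the intensity-weighted harmonic-mean aggregate implemented in
:func:`mixture_f0f_oracle`.

The two-quencher model adds an intrinsic (static, already-present)
quencher. With ``alpha = 0`` the two quenchers act independently and the
intrinsic quencher cancels out of the apparent ratio; with ``alpha > 0``
the intrinsic quencher shields the fluorophore and attenuates the
extrinsic constant as K_e' = K_e / (1 + alpha * Q_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from eemquench.core import EEMDataset, SamplePair
from eemquench.errors import UndefinedRatioError, ValidationError
from eemquench.parafac import ParafacModel, project_eem

__all__ = [
    "CompoundQuenchModel",
    "QuenchScenario",
    "FmaxRecord",
    "stern_volmer_ratio",
    "apparent_f0f",
    "mixture_f0f_oracle",
    "dataset_f0f",
    "peak_picked_f0f",
]


@dataclass(frozen=True)
class CompoundQuenchModel:
    """Quenching constants of one fluorescent compound.

    K_e: Stern-Volmer constant for the extrinsic quencher (L/g).
    K_s: static binding constant for the intrinsic quencher (L/mg).
    alpha: shielding coefficient (L/mg); alpha = 0 recovers the fully
    multiplicative (independent-quenchers) regime.
    """

    K_e: float = 0.0
    K_s: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K_e, self.K_s, self.alpha) < 0:
            raise ValidationError("quenching constants must be >= 0")


@dataclass(frozen=True)
class QuenchScenario:
    """Extrinsic (Q_e, g/L) and intrinsic (Q_i, mg/L) quencher doses."""

    Q_e: float = 0.0
    Q_i: float = 0.0

    def __post_init__(self) -> None:
        if self.Q_e < 0 or self.Q_i < 0:
            raise ValidationError("quencher concentrations must be >= 0")


@dataclass(frozen=True)
class FmaxRecord:
    """Paired Fmax of one component in one sample, before/after dosing."""

    sample_id: str
    component: int
    fmax_original: float
    fmax_quenched: float

    def __post_init__(self) -> None:
        if self.fmax_original < 0:
            raise ValidationError("fmax_original must be >= 0")


def stern_volmer_ratio(
    model: CompoundQuenchModel, scenario: QuenchScenario
) -> dict[str, float]:
    """Attenuation factors of a compound's pristine fluorescence.

    pre_dose_factor = F_0,true / F_0,obs = 1 + K_s * Q_i (intrinsic only);
    post_dose_factor = (1 + K_s * Q_i) * (1 + K_e' * Q_e) with
    K_e' = K_e / (1 + alpha * Q_i). Observed fluorescence = pristine
    divided by the factor.
    """
    pre = 1.0 + model.K_s * scenario.Q_i
    k_eff = model.K_e / (1.0 + model.alpha * scenario.Q_i)
    post = pre * (1.0 + k_eff * scenario.Q_e)
    return {"pre_dose_factor": pre, "post_dose_factor": post}


def apparent_f0f(record: FmaxRecord) -> float:
    """Apparent F0/F = Fmax_original / Fmax_quenched for one component."""
    if record.fmax_quenched <= 0:
        raise UndefinedRatioError(
            f"sample {record.sample_id!r} component {record.component}: "
            f"quenched Fmax is {record.fmax_quenched} (ratio undefined)"
        )
    return record.fmax_original / record.fmax_quenched


def mixture_f0f_oracle(
    contributions: Sequence[tuple[float, float]],
) -> float:
    """Closed-form apparent F0/F of same-spectrum compounds.

    ``contributions`` lists (F0_i, factor_i) per compound, where F0_i is
    the compound's un-dosed intensity and factor_i >= 1 its individual
    quench factor. The aggregate is the intensity-weighted harmonic mean:
    sum(F0_i) / sum(F0_i / factor_i).
    """
    if not contributions:
        raise ValidationError("empty mixture")
    f0 = np.array([c[0] for c in contributions], dtype=float)
    fac = np.array([c[1] for c in contributions], dtype=float)
    if np.any(f0 < 0):
        raise ValidationError("intensities must be >= 0")
    if np.any(fac < 1):
        raise ValidationError("quench factors must be >= 1")
    total = f0.sum()
    if total <= 0:
        raise ValidationError("total intensity must be positive")
    return float(total / np.sum(f0 / fac))


def dataset_f0f(
    model: ParafacModel, dataset: EEMDataset, *, project: bool = False
) -> pd.DataFrame:
    """Tidy table of paired Fmax and apparent F0/F, sample x component.

    By default Fmax values are read from the fitted model's scores, pairing
    each sample's ``/orig`` and ``/quench`` entries by id; with
    ``project=True`` both EEMs are instead projected onto the fixed
    components (for samples not in the training fit).

    Undefined ratios (quenched Fmax <= 0) yield NaN in ``apparent_f0f``
    and ``ratio_defined=False`` — rows are reported, never dropped.
    """
    id_to_row = {eid: i for i, eid in enumerate(model.eem_ids)}
    rows = []
    for pair in dataset:
        if project:
            fo, _ = project_eem(model, pair.original)
            fq, _ = project_eem(model, pair.quenched)
            fmax_o = fo * model.ex_loadings.max(axis=0) * model.em_loadings.max(axis=0)
            fmax_q = fq * model.ex_loadings.max(axis=0) * model.em_loadings.max(axis=0)
        else:
            ko, kq = pair.sample_id + "/orig", pair.sample_id + "/quench"
            if ko not in id_to_row or kq not in id_to_row:
                raise ValidationError(
                    f"sample {pair.sample_id!r} is not paired in the model "
                    "(missing /orig or /quench entry); use project=True for "
                    "out-of-model samples"
                )
            fmax_o = model.scores[id_to_row[ko]]
            fmax_q = model.scores[id_to_row[kq]]
        for r in range(model.R):
            defined = fmax_q[r] > 0
            rows.append(
                {
                    "sample_id": pair.sample_id,
                    "component": r,
                    "fmax_original": fmax_o[r],
                    "fmax_quenched": fmax_q[r],
                    "apparent_f0f": fmax_o[r] / fmax_q[r] if defined else np.nan,
                    "ratio_defined": bool(defined),
                }
            )
    return pd.DataFrame(rows)


def peak_picked_f0f(
    pair: SamplePair,
    ex_window: tuple[float, float],
    em_window: tuple[float, float],
) -> float:
    """F0/F from mean raw intensity in a wavelength window (no PARAFAC)."""
    grid = pair.grid
    ex_sel = (grid.excitation >= ex_window[0]) & (grid.excitation <= ex_window[1])
    em_sel = (grid.emission >= em_window[0]) & (grid.emission <= em_window[1])
    if not ex_sel.any() or not em_sel.any():
        raise ValidationError(
            f"window ex={ex_window}, em={em_window} contains no grid points"
        )
    num = np.nanmean(pair.original.intensity[np.ix_(ex_sel, em_sel)])
    den = np.nanmean(pair.quenched.intensity[np.ix_(ex_sel, em_sel)])
    if not den > 0:
        raise UndefinedRatioError(
            f"sample {pair.sample_id!r}: quenched window mean is {den}"
        )
    return float(num / den)
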