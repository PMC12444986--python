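"""Training + testing workflow for real-time EEM monitoring.

Training fits a PARAFAC model on historical paired EEMs, calibrates a
linear Fmax -> target relationship on the component best correlated with
the target, and freezes per-component apparent-F0/F reference ranges
(min/max of the z-trimmed training values, |z| > 3 removed once).
Prediction projects a new pair onto the fixed components, predicts the
targets, and flags the sample when any monitored quantity falls outside
its reference range. Bulk fluorescence indices (HIX, BIX, AQY) and
reconstruction errors are computed as comparison indicators under the
same range protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from eemquench.core import EEM, EEMDataset, SamplePair
from eemquench.errors import ValidationError
from eemquench.parafac import ParafacModel, fit_parafac_hals, project_eem
from eemquench.quench import dataset_f0f

__all__ = [
    "CalibrationModel",
    "ReferenceRange",
    "IndexSet",
    "MonitorVerdict",
    "MonitorBundle",
    "train_monitor",
    "predict_sample",
    "compute_indices",
    "relative_error",
    "outlier_rate",
]


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line predicting one target from one component's original Fmax."""

    target_name: str
    component: int
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n_train: int

    def predict(self, fmax: float) -> float:
        return self.slope * fmax + self.intercept


@dataclass(frozen=True)
class ReferenceRange:
    """Historical interval for one monitored quantity after z-trimming."""

    lower: float
    upper: float
    n_used: int
    n_trimmed: int
    component: int | None = None
    indicator: str | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("reference range has lower > upper")

    def contains(self, value: float) -> bool:
        return bool(np.isfinite(value) and self.lower <= value <= self.upper)


@dataclass(frozen=True)
class IndexSet:
    """Bulk fluorescence indicators for one sample.

    Wavelength windows follow common literature definitions (HIX as an
    emission-sum ratio, BIX as a two-point emission ratio, AQY as
    integrated emission over absorbance); the excitation columns actually
    used are recorded in ``ex_used`` since the measured excitation axis
    may not contain the nominal wavelengths. AQY entries are None without
    an absorbance spectrum; reconstruction errors are None without a model.
    """

    hix: float | None = None
    bix: float | None = None
    aqy_254: float | None = None
    aqy_320: float | None = None
    reconstruction_error: float | None = None
    relative_reconstruction_error: float | None = None
    ex_used: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {}
        for name in (
            "hix",
            "bix",
            "aqy_254",
            "aqy_320",
            "reconstruction_error",
            "relative_reconstruction_error",
        ):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


@dataclass
class MonitorVerdict:
    """Predictions, apparent F0/F, and outlier flags for one new sample."""

    sample_id: str
    predictions: dict[str, float]
    apparent_f0f: dict[int, float]
    f0f_outlier_flags: dict[int, bool]
    index_outlier_flags: dict[str, bool]
    indices: IndexSet | None = None

    @property
    def any_f0f_outlier(self) -> bool:
        return any(self.f0f_outlier_flags.values())


@dataclass
class MonitorBundle:
    """Everything :func:`predict_sample` needs, produced by training."""

    model: ParafacModel
    calibrations: dict[str, CalibrationModel]
    f0f_ranges: dict[int, ReferenceRange]
    index_ranges: dict[str, ReferenceRange]
    z_max: float = 3.0
    range_mode: str = "minmax"


def _z_trim(values: np.ndarray, z_max: float) -> tuple[np.ndarray, int]:
    """Single-pass removal of |z| > z_max under sample mean/SD (ddof 1)."""
    v = values[np.isfinite(values)]
    if v.size < 2:
        return v, 0
    sd = v.std(ddof=1)
    if sd == 0:
        return v, 0
    z = np.abs(v - v.mean()) / sd
    keep = z <= z_max
    return v[keep], int((~keep).sum())


def _build_range(
    values: np.ndarray,
    z_max: float,
    mode: str,
    *,
    component: int | None = None,
    indicator: str | None = None,
) -> ReferenceRange | None:
    trimmed, n_trim = _z_trim(np.asarray(values, dtype=float), z_max)
    if trimmed.size == 0:
        return None
    if mode == "minmax":
        lo, hi = float(trimmed.min()), float(trimmed.max())
    elif mode == "percentile":
        lo, hi = (float(q) for q in np.percentile(trimmed, [2.5, 97.5]))
    else:
        raise ValidationError(f"unknown range mode {mode!r}")
    return ReferenceRange(
        lower=lo,
        upper=hi,
        n_used=int(trimmed.size),
        n_trimmed=n_trim,
        component=component,
        indicator=indicator,
    )


def _ex_column(grid, nominal: float) -> tuple[int, float]:
    idx = int(np.argmin(np.abs(grid.excitation - nominal)))
    return idx, float(grid.excitation[idx])


def _em_slice(grid, lo: float, hi: float, index_name: str) -> np.ndarray:
    sel = (grid.emission >= lo) & (grid.emission <= hi)
    if not sel.any():
        raise ValidationError(
            f"{index_name}: emission window [{lo}, {hi}] nm is off-grid"
        )
    return sel


def compute_indices(
    pair: SamplePair,
    model: ParafacModel | None = None,
    *,
    hix_ex: float = 254.0,
    bix_ex: float = 310.0,
    aqy_wavelengths: Sequence[float] = (254.0, 320.0),
) -> IndexSet:
    """Bulk indices of the pair's original EEM.

    HIX = sum(em 435-480) / sum(em 300-345) at the excitation column
    nearest ``hix_ex``; BIX = I(em 380) / I(em 430) at the column nearest
    ``bix_ex``; AQY_l = integrated emission at the column nearest l over
    absorbance at l. Reconstruction error = Frobenius norm of the
    projection residual of the original EEM.
    """
    eem = pair.original
    grid = eem.grid
    intensity = eem.filled(0.0)
    ex_used: dict[str, float] = {}

    hix_i, hix_wl = _ex_column(grid, hix_ex)
    ex_used["hix"] = hix_wl
    num = intensity[hix_i, _em_slice(grid, 435.0, 480.0, "hix")].sum()
    den = intensity[hix_i, _em_slice(grid, 300.0, 345.0, "hix")].sum()
    hix = float(num / den) if den > 0 else (0.0 if num == 0 else float("inf"))

    bix_i, bix_wl = _ex_column(grid, bix_ex)
    ex_used["bix"] = bix_wl
    em380 = int(np.argmin(np.abs(grid.emission - 380.0)))
    em430 = int(np.argmin(np.abs(grid.emission - 430.0)))
    den_b = intensity[bix_i, em430]
    bix = float(intensity[bix_i, em380] / den_b) if den_b > 0 else None

    aqy: dict[float, float | None] = {}
    for wl in aqy_wavelengths:
        if pair.absorbance is None:
            aqy[wl] = None
            continue
        col, used = _ex_column(grid, wl)
        ex_used[f"aqy_{int(wl)}"] = used
        try:
            a = float(pair.absorbance.at(wl))
        except Exception:
            a = float(pair.absorbance.at(used))
        aqy[wl] = float(intensity[col].sum() / a) if a > 0 else None

    rec_err = rel_rec_err = None
    if model is not None:
        scores, resid = project_eem(model, eem)
        rec_err = float(resid)
        norm = float(np.linalg.norm(intensity))
        rel_rec_err = rec_err / norm if norm > 0 else 0.0

    return IndexSet(
        hix=hix,
        bix=bix,
        aqy_254=aqy.get(254.0),
        aqy_320=aqy.get(320.0),
        reconstruction_error=rec_err,
        relative_reconstruction_error=rel_rec_err,
        ex_used=ex_used,
    )


def _calibrate(
    fmax: np.ndarray, target: np.ndarray, target_name: str, component_override: int | None
) -> CalibrationModel:
    if np.all(target == target[0]):
        raise ValidationError(
            f"target {target_name!r} is constant; correlation undefined"
        )
    R = fmax.shape[1]
    if component_override is not None:
        comp = component_override
    else:
        rs = np.zeros(R)
        for r in range(R):
            if np.std(fmax[:, r]) > 0:
                rs[r] = stats.pearsonr(fmax[:, r], target)[0]
        comp = int(np.argmax(np.abs(rs)))  # argmax takes the lowest index on ties
    res = stats.linregress(fmax[:, comp], target)
    return CalibrationModel(
        target_name=target_name,
        component=comp,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        n_train=int(target.size),
    )


def train_monitor(
    train: EEMDataset,
    target_names: str | Sequence[str],
    R: int,
    *,
    z_max: float = 3.0,
    range_mode: str = "minmax",
    component_override: int | None = None,
    seed: int | None = None,
    fit_opts: dict | None = None,
    compute_index_ranges: bool = True,
) -> MonitorBundle:
    """Fit the monitoring bundle on historical paired EEMs.

    For each target, the component maximizing |Pearson r| between original
    Fmax and the target is calibrated by OLS (overridable). Reference
    ranges for per-component apparent F0/F and for each bulk index use
    min/max (or percentiles) of the z-trimmed training values.
    """
    if isinstance(target_names, str):
        target_names = [target_names]
    if len(train) < max(3, R):
        raise ValidationError("too few training pairs")
    opts = dict(fit_opts or {})
    model = fit_parafac_hals(train, R, seed=seed, **opts)
    table = dataset_f0f(model, train)

    fmax_o = (
        table.pivot(index="sample_id", columns="component", values="fmax_original")
        .loc[train.sample_ids]
        .to_numpy()
    )
    calibrations: dict[str, CalibrationModel] = {}
    for tname in target_names:
        missing = [p.sample_id for p in train if not p.targets or tname not in p.targets]
        if missing:
            raise ValidationError(
                f"target {tname!r} missing for samples {missing[:5]}"
            )
        target = np.array([p.targets[tname] for p in train], dtype=float)
        calibrations[tname] = _calibrate(fmax_o, target, tname, component_override)

    f0f_ranges: dict[int, ReferenceRange] = {}
    for r in range(model.R):
        vals = table.loc[
            (table["component"] == r) & table["ratio_defined"], "apparent_f0f"
        ].to_numpy()
        rng_ = _build_range(vals, z_max, range_mode, component=r)
        if rng_ is not None:
            f0f_ranges[r] = rng_

    index_ranges: dict[str, ReferenceRange] = {}
    if compute_index_ranges:
        per_sample = [compute_indices(p, model) for p in train]
        names = set()
        for s in per_sample:
            names |= set(s.as_dict())
        for name in sorted(names):
            vals = np.array(
                [s.as_dict().get(name, np.nan) for s in per_sample], dtype=float
            )
            rng_ = _build_range(vals, z_max, range_mode, indicator=name)
            if rng_ is not None:
                index_ranges[name] = rng_

    return MonitorBundle(
        model=model,
        calibrations=calibrations,
        f0f_ranges=f0f_ranges,
        index_ranges=index_ranges,
        z_max=z_max,
        range_mode=range_mode,
    )


def predict_sample(bundle: MonitorBundle, pair: SamplePair) -> MonitorVerdict:
    """Project a new pair, predict targets, and flag reference-range outliers.

    Predictions are never suppressed for flagged samples; flags are
    advisory. An undefined apparent F0/F (non-positive quenched Fmax) is
    itself flagged as an outlier.
    """
    model = bundle.model
    so, _ = project_eem(model, pair.original)
    sq, _ = project_eem(model, pair.quenched)
    predictions = {
        t: cal.predict(so[cal.component]) for t, cal in bundle.calibrations.items()
    }
    apparent: dict[int, float] = {}
    f0f_flags: dict[int, bool] = {}
    for r, ref in bundle.f0f_ranges.items():
        if sq[r] > 0:
            val = float(so[r] / sq[r])
            apparent[r] = val
            f0f_flags[r] = not ref.contains(val)
        else:
            apparent[r] = float("nan")
            f0f_flags[r] = True
    indices = compute_indices(pair, model)
    idx_vals = indices.as_dict()
    index_flags = {
        name: not ref.contains(idx_vals.get(name, float("nan")))
        for name, ref in bundle.index_ranges.items()
    }
    return MonitorVerdict(
        sample_id=pair.sample_id,
        predictions=predictions,
        apparent_f0f=apparent,
        f0f_outlier_flags=f0f_flags,
        index_outlier_flags=index_flags,
        indices=indices,
    )


def relative_error(predicted: float, actual: float) -> float:
    """|predicted - actual| / |actual| (scale-invariant)."""
    if actual == 0:
        raise ValidationError("relative error undefined for actual == 0")
    return abs(predicted - actual) / abs(actual)


def outlier_rate(
    verdicts: Sequence[MonitorVerdict],
    flag_selector: int | str | Callable[[MonitorVerdict], bool] = "any",
) -> float:
    """Fraction of verdicts flagged by the selected indicator.

    ``flag_selector``: a component index (per-component F0/F flag), an
    indicator name, ``"any"`` (any F0/F component), or a callable.
    """
    if not verdicts:
        raise ValidationError("no verdicts supplied")
    if callable(flag_selector):
        fn = flag_selector
    elif flag_selector == "any":
        fn = lambda v: v.any_f0f_outlier
    elif isinstance(flag_selector, int):
        fn = lambda v: v.f0f_outlier_flags.get(flag_selector, False)
    else:
        fn = lambda v: v.index_outlier_flags.get(flag_selector, False)
    return float(np.mean([bool(fn(v)) for v in verdicts]))
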