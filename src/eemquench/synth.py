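"""Physics-based synthetic EEM generator.

Fluorescent compounds have Gaussian excitation/emission profiles; a
sample's pristine signal is the concentration-weighted sum of compound
patterns. Quenching divides each compound's contribution by its
Stern-Volmer factor (intrinsic quencher before dosing, intrinsic +
extrinsic after dosing), so noiseless stacks are exactly low-rank and
every downstream module has a closed-form oracle.

Two stock compounds ("bacteria-like", weakly quenched; "protein-like",
strongly quenched and shielded by the intrinsic quencher) share one
spectral shape, mirroring mixtures of distinct compounds on a common
fluorophore. Their quenching constants are declared simulator defaults,
not measured values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from eemquench.core import EEM, EEMDataset, SamplePair, WavelengthGrid
from eemquench.errors import ValidationError
from eemquench.quench import CompoundQuenchModel, QuenchScenario, stern_volmer_ratio

__all__ = [
    "CompoundSpec",
    "ScenarioConfig",
    "DriftSpec",
    "instrument_grid",
    "coarse_grid",
    "bacteria_like",
    "protein_like",
    "humic_like",
    "generate_eem",
    "generate_pair",
    "mixture_series",
    "monitoring_scenario",
]


@dataclass(frozen=True)
class CompoundSpec:
    """Ground-truth spectral and quenching description of one compound."""

    name: str
    ex_center: float
    ex_sigma: float
    em_center: float
    em_sigma: float
    brightness: float = 100.0
    conc_unit: str = "mg/L"
    quench: CompoundQuenchModel = field(default_factory=CompoundQuenchModel)
    absorptivity: float = 0.0

    def __post_init__(self) -> None:
        if self.ex_sigma <= 0 or self.em_sigma <= 0:
            raise ValidationError(f"{self.name}: sigmas must be > 0")
        if self.em_center <= self.ex_center:
            raise ValidationError(
                f"{self.name}: emission center must exceed excitation center "
                "(Stokes shift)"
            )
        if self.brightness < 0:
            raise ValidationError(f"{self.name}: brightness must be >= 0")

    def pattern(self, grid: WavelengthGrid) -> np.ndarray:
        """Unit-peak excitation (x) emission Gaussian pattern on a grid."""
        gx = np.exp(-0.5 * ((grid.excitation - self.ex_center) / self.ex_sigma) ** 2)
        gm = np.exp(-0.5 * ((grid.emission - self.em_center) / self.em_sigma) ** 2)
        return np.outer(gx, gm)


def instrument_grid() -> WavelengthGrid:
    """The measurement grid: excitation 274-400 nm step 2, emission
    309.6-500.4 nm step 1.19."""
    return WavelengthGrid(
        np.arange(274.0, 400.0 + 1e-9, 2.0),
        np.arange(309.6, 500.4 + 1e-9, 1.19),
    )


def coarse_grid(ex_step: float = 6.0, em_step: float = 4.76) -> WavelengthGrid:
    """Decimated grid covering the same range — keeps tests fast."""
    return WavelengthGrid(
        np.arange(274.0, 400.0 + 1e-9, ex_step),
        np.arange(309.6, 500.4 + 1e-9, em_step),
    )


# ---------------------------------------------------------------------------
# Stock compounds (tryptophan-like shared shape; declared defaults)
# ---------------------------------------------------------------------------

def bacteria_like(**overrides) -> CompoundSpec:
    """Weakly quenched compound (cellular protection motif)."""
    spec = CompoundSpec(
        name="bacteria_like",
        ex_center=280.0,
        ex_sigma=12.0,
        em_center=340.0,
        em_sigma=22.0,
        brightness=100.0,
        conc_unit="Mcells/mL",
        quench=CompoundQuenchModel(K_e=0.08, K_s=0.03, alpha=0.0),
    )
    return replace(spec, **overrides)


def protein_like(**overrides) -> CompoundSpec:
    """Strongly quenched free-protein compound, shielded by the intrinsic
    quencher (alpha > 0)."""
    spec = CompoundSpec(
        name="protein_like",
        ex_center=280.0,
        ex_sigma=12.0,
        em_center=340.0,
        em_sigma=22.0,
        brightness=100.0,
        conc_unit="mg/L",
        quench=CompoundQuenchModel(K_e=0.4, K_s=0.12, alpha=0.08),
    )
    return replace(spec, **overrides)


def humic_like(**overrides) -> CompoundSpec:
    """Broad red-shifted compound standing in for humic material."""
    spec = CompoundSpec(
        name="humic_like",
        ex_center=330.0,
        ex_sigma=25.0,
        em_center=440.0,
        em_sigma=35.0,
        brightness=40.0,
        conc_unit="mg/L",
        quench=CompoundQuenchModel(K_e=0.05, K_s=0.0, alpha=0.0),
    )
    return replace(spec, **overrides)


# ---------------------------------------------------------------------------
# EEM generation
# ---------------------------------------------------------------------------

def _scatter_signal(grid: WavelengthGrid, amplitude: float) -> np.ndarray:
    """Narrow Rayleigh (1st/2nd order) and Raman ridges for preprocess tests."""
    ex = grid.excitation[:, None]
    em = grid.emission[None, :]
    sig = amplitude * np.exp(-0.5 * ((em - ex) / 3.0) ** 2)
    sig += 0.5 * amplitude * np.exp(-0.5 * ((em - 2.0 * ex) / 3.0) ** 2)
    raman = 1.0 / (1.0 / ex - 3400.0 * 1e-7)
    sig += 0.2 * amplitude * np.exp(-0.5 * ((em - raman) / 1.5) ** 2)
    return sig


def generate_eem(
    compounds: Sequence[CompoundSpec],
    concs: Sequence[float],
    scenario: QuenchScenario,
    grid: WavelengthGrid,
    *,
    dosed: bool = False,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    include_scatter: bool = False,
) -> tuple[EEM, EEM]:
    """Generate one EEM and its noiseless quencher-free ("pristine") twin.

    The observed signal divides each compound's pristine contribution by
    its pre-dose factor (``dosed=False``; intrinsic quencher only) or its
    post-dose factor (``dosed=True``). Noise is additive Gaussian with
    sigma = ``noise_sigma`` x the noiseless peak intensity.
    """
    if len(compounds) != len(concs):
        raise ValidationError("compounds and concentrations differ in length")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    pristine = np.zeros(grid.shape)
    observed = np.zeros(grid.shape)
    key = "post_dose_factor" if dosed else "pre_dose_factor"
    for spec, conc in zip(compounds, concs):
        if conc < 0:
            raise ValidationError(f"{spec.name}: concentration must be >= 0")
        contrib = conc * spec.brightness * spec.pattern(grid)
        pristine += contrib
        observed += contrib / stern_volmer_ratio(spec.quench, scenario)[key]
    if include_scatter:
        peak = observed.max() if observed.max() > 0 else 1.0
        observed = observed + _scatter_signal(grid, 2.0 * peak)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        observed = observed + rng.normal(
            0.0, noise_sigma * max(pristine.max(), 1e-30), size=grid.shape
        )
    return EEM(grid, observed), EEM(grid, pristine)


def generate_pair(
    compounds: Sequence[CompoundSpec],
    concs: Sequence[float],
    Q_e: float,
    Q_i: float = 0.0,
    *,
    grid: WavelengthGrid | None = None,
    sample_id: str = "sample",
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    include_scatter: bool = False,
    targets: Mapping[str, float] | None = None,
    labels: Mapping[str, str] | None = None,
) -> SamplePair:
    """One original/quenched measurement pair.

    The original EEM sees only the intrinsic quencher; the quenched EEM
    sees the extrinsic dose ``Q_e`` on top. Noise draws are independent
    between the two measurements but flow from one rng stream.
    """
    if grid is None:
        grid = instrument_grid()
    scenario = QuenchScenario(Q_e=Q_e, Q_i=Q_i)
    original, _ = generate_eem(
        compounds, concs, scenario, grid,
        dosed=False, noise_sigma=noise_sigma, rng=rng,
        include_scatter=include_scatter,
    )
    quenched, _ = generate_eem(
        compounds, concs, scenario, grid,
        dosed=True, noise_sigma=noise_sigma, rng=rng,
        include_scatter=include_scatter,
    )
    return SamplePair(
        sample_id=sample_id,
        original=original,
        quenched=quenched,
        quencher_conc=Q_e,
        targets=dict(targets) if targets else None,
        labels=dict(labels) if labels else None,
    )


def mixture_series(
    compound_a: CompoundSpec | None = None,
    compound_b: CompoundSpec | None = None,
    *,
    baseline_a: float = 1.0,
    baseline_b: float = 1.0,
    ratios: Sequence[tuple[float, float]] = ((0, 1), (1, 3), (1, 1), (3, 1), (1, 0)),
    Q_e_levels: Sequence[float] = (0.0, 1.25, 2.5, 3.75, 5.0),
    Q_i_levels: Sequence[float] = (0.0,),
    grid: WavelengthGrid | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> EEMDataset:
    """Full-factorial two-compound mixing design.

    Samples mix the two baseline solutions at volume ratios a:b, so the
    compound concentrations are baseline * a/(a+b) and baseline * b/(a+b).
    Defaults replay the model-compound design: ratios 0:1 .. 1:0 and
    extrinsic doses 0-5 g/L.
    """
    if not ratios:
        raise ValidationError("ratios must be nonempty")
    ca = compound_a if compound_a is not None else bacteria_like()
    cb = compound_b if compound_b is not None else protein_like()
    if grid is None:
        grid = coarse_grid()
    rng = np.random.default_rng(seed)
    pairs = []
    for ri, (a, b) in enumerate(ratios):
        if a < 0 or b < 0 or a + b == 0:
            raise ValidationError(f"invalid mixing ratio {a}:{b}")
        conc_a = baseline_a * a / (a + b)
        conc_b = baseline_b * b / (a + b)
        for qi_idx, q_i in enumerate(Q_i_levels):
            for qe_idx, q_e in enumerate(Q_e_levels):
                pairs.append(
                    generate_pair(
                        [ca, cb],
                        [conc_a, conc_b],
                        Q_e=q_e,
                        Q_i=q_i,
                        grid=grid,
                        sample_id=f"r{ri}_qi{qi_idx}_qe{qe_idx}",
                        noise_sigma=noise_sigma,
                        rng=rng,
                        labels={
                            "ratio": f"{a}:{b}",
                            "Q_e": f"{q_e}",
                            "Q_i": f"{q_i}",
                        },
                    )
                )
    return EEMDataset(pairs, provenance="synthetic mixture series")


@dataclass(frozen=True)
class DriftSpec:
    """Test-phase distribution shift for :func:`monitoring_scenario`.

    share_shift moves the within-group share of the strongly quenched
    compound (added to the baseline share, clipped to [0, 1]); q_i_shift
    adds intrinsic quencher; anomaly_frac is the fraction of test samples
    receiving the shift (those pairs get label ``anomaly="1"``).
    """

    share_shift: float = 0.0
    q_i_shift: float = 0.0
    anomaly_frac: float = 1.0


#: spectral groups for the monitoring scenario; each holds a weakly and a
#: strongly quenched compound on one shared shape
def _monitoring_groups() -> list[tuple[CompoundSpec, CompoundSpec]]:
    g1_weak = bacteria_like()
    g1_strong = protein_like()
    g2_weak = bacteria_like(
        name="g2_weak", ex_center=305.0, em_center=380.0,
        quench=CompoundQuenchModel(K_e=0.12, K_s=0.02, alpha=0.0),
    )
    g2_strong = protein_like(
        name="g2_strong", ex_center=305.0, em_center=380.0,
        quench=CompoundQuenchModel(K_e=0.5, K_s=0.1, alpha=0.06),
    )
    g3_weak = humic_like(name="g3_weak")
    g3_strong = humic_like(
        name="g3_strong",
        quench=CompoundQuenchModel(K_e=0.3, K_s=0.0, alpha=0.0),
    )
    return [(g1_weak, g1_strong), (g2_weak, g2_strong), (g3_weak, g3_strong)]


def monitoring_scenario(
    n_train: int,
    n_test: int,
    drift: DriftSpec | Mapping | None = None,
    seed: int | None = None,
    *,
    grid: WavelengthGrid | None = None,
    Q_e: float = 2.5,
    noise_sigma: float = 0.01,
    base_shares: Sequence[float] = (0.3, 0.4, 0.5),
    tcc_per_unit: float = 1e5,
    doc_per_unit: float = 1.0,
) -> tuple[EEMDataset, EEMDataset]:
    """Train/test datasets for the real-time monitoring workflow.

    Three spectrally distinct fluorophore groups, each a two-compound
    mixture. TCC is proportional to the bacteria-like compound's
    concentration; DOC to the summed organic concentration. The test set
    optionally drifts per ``drift``; drifted pairs carry
    ``labels["anomaly"] == "1"``.
    """
    if n_train < 4 or n_test < 4:
        raise ValidationError("n_train and n_test must each be >= 4")
    if drift is None:
        drift = DriftSpec()
    elif isinstance(drift, Mapping):
        drift = DriftSpec(**drift)
    if grid is None:
        grid = coarse_grid()
    rng = np.random.default_rng(seed)
    groups = _monitoring_groups()

    def _make(n: int, phase: str, drifted_mask: np.ndarray) -> EEMDataset:
        pairs = []
        for i in range(n):
            is_anom = bool(drifted_mask[i])
            compounds: list[CompoundSpec] = []
            concs: list[float] = []
            tcc = 0.0
            doc = 0.0
            for (weak, strong), base_share in zip(groups, base_shares):
                total = float(rng.lognormal(mean=0.0, sigma=0.15))
                share = base_share + rng.normal(0.0, 0.05)
                if is_anom:
                    share += drift.share_shift
                share = float(np.clip(share, 0.0, 1.0))
                c_strong = total * share
                c_weak = total * (1.0 - share)
                compounds += [weak, strong]
                concs += [c_weak, c_strong]
                if weak.name == "bacteria_like":
                    tcc += tcc_per_unit * c_weak
                doc += doc_per_unit * (c_weak + c_strong)
            q_i = float(abs(rng.normal(1.0, 0.2)))
            if is_anom:
                q_i += drift.q_i_shift
            pairs.append(
                generate_pair(
                    compounds,
                    concs,
                    Q_e=Q_e,
                    Q_i=q_i,
                    grid=grid,
                    sample_id=f"{phase}{i:03d}",
                    noise_sigma=noise_sigma,
                    rng=rng,
                    targets={"tcc": tcc, "doc": doc},
                    labels={"anomaly": "1" if is_anom else "0"},
                )
            )
        return EEMDataset(pairs, provenance=f"synthetic monitoring ({phase})")

    train = _make(n_train, "train", np.zeros(n_train, dtype=bool))
    n_anom = int(round(drift.anomaly_frac * n_test))
    has_drift = drift.share_shift != 0.0 or drift.q_i_shift != 0.0
    test_mask = np.zeros(n_test, dtype=bool)
    if has_drift and n_anom > 0:
        anom_idx = rng.choice(n_test, size=min(n_anom, n_test), replace=False)
        test_mask[anom_idx] = True
    test = _make(n_test, "test", test_mask)
    return train, test


@dataclass
class ScenarioConfig:
    """Serializable scenario description consumed by the CLI.

    ``kind`` selects the generator: ``"mixture_series"`` or
    ``"monitoring"``; ``params`` passes keyword arguments through (grid
    objects are built from ``grid_ex_step`` / ``grid_em_step`` keys).
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(kind=raw["kind"], params=raw.get("params", {}), seed=raw.get("seed"))

    def build(self):
        params = dict(self.params)
        ex_step = params.pop("grid_ex_step", None)
        em_step = params.pop("grid_em_step", None)
        if ex_step is not None or em_step is not None:
            params["grid"] = coarse_grid(
                ex_step if ex_step is not None else 6.0,
                em_step if em_step is not None else 4.76,
            )
        if self.kind == "mixture_series":
            ratios = params.pop("ratios", None)
            if ratios is not None:
                params["ratios"] = [tuple(r) for r in ratios]
            return mixture_series(seed=self.seed, **params)
        if self.kind == "monitoring":
            return monitoring_scenario(seed=self.seed, **params)
        raise ValidationError(f"unknown scenario kind {self.kind!r}")
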