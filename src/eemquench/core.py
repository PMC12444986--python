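"""Domain types and file I/O for excitation-emission matrices.

The on-disk dialect for an EEM is a wide CSV: the first row holds emission
wavelengths (nm), the first column holds excitation wavelengths (nm), and
the body holds fluorescence intensities. Axes are stored strictly ascending
in memory regardless of file order; masked (removed/invalid) cells are
serialized as ``nan`` tokens.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from eemquench.errors import FormatError, GridError, ValidationError

#: absolute tolerance (nm) when comparing wavelength axes for equality
GRID_ATOL = 1e-6


def _as_axis(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"{name} axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} axis contains non-finite values")
    if np.any(arr <= 0):
        raise ValidationError(f"{name} wavelengths must be positive")
    if np.any(np.diff(arr) <= 0):
        raise ValidationError(f"{name} axis must be strictly increasing")
    return arr


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing excitation and emission wavelength axes (nm)."""

    excitation: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "excitation", _as_axis(self.excitation, "excitation"))
        object.__setattr__(self, "emission", _as_axis(self.emission, "emission"))

    @property
    def shape(self) -> tuple[int, int]:
        return self.excitation.size, self.emission.size

    def isclose(self, other: "WavelengthGrid", atol: float = GRID_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.excitation, other.excitation, atol=atol, rtol=0)
            and np.allclose(self.emission, other.emission, atol=atol, rtol=0)
        )


@dataclass
class EEM:
    """One excitation x emission intensity grid with its wavelength axes.

    ``mask`` marks removed/invalid cells (True = masked). Masked cells are
    carried as NaN in ``intensity`` as well, so numerical code can treat
    NaN as the single source of truth.
    """

    grid: WavelengthGrid
    intensity: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        nan_mask = ~np.isfinite(self.intensity)
        if self.mask is None:
            self.mask = nan_mask
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | nan_mask
            if self.mask.shape != self.intensity.shape:
                raise ValidationError("mask shape does not match intensity shape")
        self.intensity = np.where(self.mask, np.nan, self.intensity)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "EEM":
        return EEM(self.grid, self.intensity.copy(), self.mask.copy())

    def filled(self, value: float = 0.0) -> np.ndarray:
        """Intensity array with masked cells replaced by ``value``."""
        return np.where(self.mask, value, self.intensity)


@dataclass
class AbsorbanceSpectrum:
    """Absorbance (dimensionless, per cm pathlength) over wavelength (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = _as_axis(self.wavelengths, "absorbance wavelength")
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != self.wavelengths.shape:
            raise ValidationError("absorbance and wavelength lengths differ")
        if np.any(~np.isfinite(self.absorbance)) or np.any(self.absorbance < 0):
            raise ValidationError("absorbance must be finite and >= 0")

    def at(self, wavelength) -> np.ndarray:
        """Linear interpolation; raises GridError outside the measured range."""
        wl = np.asarray(wavelength, dtype=float)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(wl < lo - GRID_ATOL) or np.any(wl > hi + GRID_ATOL):
            raise GridError(
                f"absorbance spectrum covers [{lo}, {hi}] nm but "
                f"[{wl.min()}, {wl.max()}] nm was requested"
            )
        return np.interp(wl, self.wavelengths, self.absorbance)


@dataclass
class SamplePair:
    """Original + quenched EEM of one physical sample and the quencher dose.

    ``quencher_conc`` is the extrinsic quencher concentration (g/L) dosed
    before the second measurement. ``targets`` optionally carries reference
    values (e.g. TCC in cells/mL, DOC in mg/L) for calibration.
    """

    sample_id: str
    original: EEM
    quenched: EEM
    quencher_conc: float
    absorbance: AbsorbanceSpectrum | None = None
    targets: Mapping[str, float] | None = None
    labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.quencher_conc < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: quencher_conc must be >= 0"
            )
        if not self.original.grid.isclose(self.quenched.grid):
            raise ValidationError(
                f"sample {self.sample_id!r}: original and quenched EEMs "
                "are on different grids (regrid first)"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return self.original.grid


@dataclass
class EEMDataset:
    """An ordered collection of sample pairs sharing one wavelength grid."""

    pairs: list[SamplePair]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.pairs]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate sample_ids: {sorted(dupes)}")
        if self.pairs:
            g = self.pairs[0].grid
            for p in self.pairs[1:]:
                if not p.grid.isclose(g):
                    raise ValidationError(
                        f"sample {p.sample_id!r} is on a different grid"
                    )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i: int) -> SamplePair:
        return self.pairs[i]

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.pairs]

    @property
    def grid(self) -> WavelengthGrid:
        if not self.pairs:
            raise ValidationError("empty dataset has no grid")
        return self.pairs[0].grid

    def eems(self, which: str = "both") -> tuple[list[EEM], list[str]]:
        """Flatten to a list of EEMs with ids.

        ``which`` is ``"both"`` (original then quenched per pair),
        ``"original"`` or ``"quenched"``. Ids carry ``/orig`` and
        ``/quench`` suffixes in ``"both"`` mode.
        """
        eems: list[EEM] = []
        ids: list[str] = []
        for p in self.pairs:
            if which in ("both", "original"):
                eems.append(p.original)
                ids.append(p.sample_id + "/orig" if which == "both" else p.sample_id)
            if which in ("both", "quenched"):
                eems.append(p.quenched)
                ids.append(p.sample_id + "/quench" if which == "both" else p.sample_id)
        return eems, ids

    def subset(self, sample_ids: Sequence[str]) -> "EEMDataset":
        wanted = set(sample_ids)
        return EEMDataset(
            [p for p in self.pairs if p.sample_id in wanted],
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_eem(path: str | os.PathLike) -> EEM:
    """Read a wide-CSV EEM (rows = excitation, columns = emission).

    Axes are sorted ascending, reordering the intensity body to match.
    ``nan`` tokens in the body become masked cells; any other non-numeric
    cell is a parse error reporting its coordinates.
    """
    try:
        df = pd.read_csv(path, index_col=0, header=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse EEM CSV: {exc}") from exc
    try:
        em = np.asarray([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(
            f"{path}: header row must be numeric emission wavelengths ({exc})"
        ) from exc
    try:
        ex = np.asarray([float(i) for i in df.index])
    except ValueError as exc:
        raise FormatError(
            f"{path}: first column must be numeric excitation wavelengths ({exc})"
        ) from exc
    body = df.to_numpy()
    if body.dtype == object:
        for (i, j), v in np.ndenumerate(body):
            try:
                float(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {v!r} at excitation row "
                    f"{ex[i]} nm, emission column {em[j]} nm"
                ) from None
        body = body.astype(float)
    ex_order = np.argsort(ex)
    em_order = np.argsort(em)
    grid = WavelengthGrid(ex[ex_order], em[em_order])
    return EEM(grid, body[np.ix_(ex_order, em_order)].astype(float))


def write_eem(eem: EEM, path: str | os.PathLike) -> None:
    """Write the wide-CSV dialect of :func:`read_eem`; masked cells → ``nan``."""
    df = pd.DataFrame(
        eem.intensity,
        index=eem.grid.excitation,
        columns=eem.grid.emission,
    )
    df.index.name = "ex_nm"
    df.to_csv(path, float_format="%.12g", na_rep="nan")


def read_absorbance(path: str | os.PathLike) -> AbsorbanceSpectrum:
    """Read a two-column CSV (wavelength_nm, absorbance)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (wavelength, absorbance)")
    return AbsorbanceSpectrum(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    )


def write_absorbance(spec: AbsorbanceSpectrum, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "absorbance": spec.absorbance}
    ).to_csv(path, index=False, float_format="%.12g")


#: manifest columns that are not target indicators or labels
_MANIFEST_CORE = {
    "sample_id",
    "eem_original",
    "eem_quenched",
    "quencher_conc",
    "absorbance",
}
_TARGET_COLUMNS = {"tcc", "doc"}


def read_manifest(path: str | os.PathLike) -> EEMDataset:
    """Load a sample manifest CSV and all EEMs it references.

    Required columns: ``sample_id``, ``eem_original``, ``eem_quenched``,
    ``quencher_conc``. Optional: ``absorbance`` (path), ``tcc``, ``doc``
    (numeric targets), any other column is kept as a label. Paths are
    resolved relative to the manifest location. All EEMs are regridded to
    the intersection grid.
    """
    base = os.path.dirname(os.fspath(path))
    df = pd.read_csv(path)
    missing = {"sample_id", "eem_original", "eem_quenched", "quencher_conc"} - set(
        df.columns
    )
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    label_cols = [
        c for c in df.columns if c not in _MANIFEST_CORE and c not in _TARGET_COLUMNS
    ]

    def _resolve(rel: str) -> str:
        return rel if os.path.isabs(rel) else os.path.join(base, rel)

    pairs: list[SamplePair] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        sid = str(rec["sample_id"])
        for key in ("eem_original", "eem_quenched"):
            p = _resolve(str(rec[key]))
            if not os.path.exists(p):
                raise FormatError(
                    f"{path} row {row_no} (sample {sid!r}): {key} file "
                    f"not found: {p}"
                )
        original = read_eem(_resolve(str(rec["eem_original"])))
        quenched = read_eem(_resolve(str(rec["eem_quenched"])))
        absorbance = None
        if "absorbance" in rec and isinstance(rec["absorbance"], str):
            ap = _resolve(rec["absorbance"])
            if not os.path.exists(ap):
                raise FormatError(
                    f"{path} row {row_no} (sample {sid!r}): absorbance "
                    f"file not found: {ap}"
                )
            absorbance = read_absorbance(ap)
        targets = {
            t: float(rec[t])
            for t in _TARGET_COLUMNS
            if t in rec and pd.notna(rec[t])
        }
        labels = {
            c: str(rec[c]) for c in label_cols if pd.notna(rec[c])
        }
        pairs.append(
            SamplePair(
                sample_id=sid,
                original=original,
                quenched=quenched,
                quencher_conc=float(rec["quencher_conc"]),
                absorbance=absorbance,
                targets=targets or None,
                labels=labels or None,
            )
        )
    if not pairs:
        raise FormatError(f"{path}: manifest contains no samples")
    target_grid = common_grid([p.grid for p in pairs] + [p.quenched.grid for p in pairs])
    for p in pairs:
        if not p.grid.isclose(target_grid):
            p.original = regrid(p.original, target_grid)
            p.quenched = regrid(p.quenched, target_grid)
            p.__post_init__()
    return EEMDataset(pairs, provenance=f"manifest:{os.fspath(path)}")


def write_dataset(dataset: EEMDataset, directory: str | os.PathLike) -> str:
    """Write a dataset as manifest.csv + per-sample EEM CSVs.

    Returns the manifest path; the layout round-trips through
    :func:`read_manifest`.
    """
    d = os.fspath(directory)
    os.makedirs(d, exist_ok=True)
    rows = []
    for p in dataset:
        orig_rel = f"{p.sample_id}_original.csv"
        quen_rel = f"{p.sample_id}_quenched.csv"
        write_eem(p.original, os.path.join(d, orig_rel))
        write_eem(p.quenched, os.path.join(d, quen_rel))
        row: dict = {
            "sample_id": p.sample_id,
            "eem_original": orig_rel,
            "eem_quenched": quen_rel,
            "quencher_conc": p.quencher_conc,
        }
        if p.absorbance is not None:
            abs_rel = f"{p.sample_id}_absorbance.csv"
            write_absorbance(p.absorbance, os.path.join(d, abs_rel))
            row["absorbance"] = abs_rel
        for t, v in (p.targets or {}).items():
            row[t] = v
        for k, v in (p.labels or {}).items():
            row[k] = v
        rows.append(row)
    manifest = os.path.join(d, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def common_grid(grids: Sequence[WavelengthGrid]) -> WavelengthGrid:
    """Intersection grid: the first grid's axes clipped to the shared range."""
    if not grids:
        raise ValidationError("no grids supplied")
    ex_lo = max(g.excitation[0] for g in grids)
    ex_hi = min(g.excitation[-1] for g in grids)
    em_lo = max(g.emission[0] for g in grids)
    em_hi = min(g.emission[-1] for g in grids)
    if ex_lo > ex_hi or em_lo > em_hi:
        raise GridError("grids have no overlapping wavelength range")
    ref = grids[0]
    ex = ref.excitation[(ref.excitation >= ex_lo - GRID_ATOL) & (ref.excitation <= ex_hi + GRID_ATOL)]
    em = ref.emission[(ref.emission >= em_lo - GRID_ATOL) & (ref.emission <= em_hi + GRID_ATOL)]
    return WavelengthGrid(ex, em)


def regrid(eem: EEM, target: WavelengthGrid) -> EEM:
    """Bilinear interpolation of an EEM onto ``target``; masks propagate.

    Raises :class:`GridError` if the target extends beyond the source axes.
    """
    src = eem.grid
    if src.isclose(target):
        return eem.copy()
    if (
        target.excitation[0] < src.excitation[0] - GRID_ATOL
        or target.excitation[-1] > src.excitation[-1] + GRID_ATOL
        or target.emission[0] < src.emission[0] - GRID_ATOL
        or target.emission[-1] > src.emission[-1] + GRID_ATOL
    ):
        raise GridError("target grid requires extrapolation beyond source range")
    interp = RegularGridInterpolator(
        (src.excitation, src.emission),
        eem.intensity,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    exg, emg = np.meshgrid(target.excitation, target.emission, indexing="ij")
    pts = np.column_stack([exg.ravel(), emg.ravel()])
    # clip round-off just outside the source box back onto it
    pts[:, 0] = np.clip(pts[:, 0], src.excitation[0], src.excitation[-1])
    pts[:, 1] = np.clip(pts[:, 1], src.emission[0], src.emission[-1])
    values = interp(pts).reshape(target.shape)
    return EEM(target, values)
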