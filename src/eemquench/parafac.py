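"""Nonnegative trilinear PARAFAC for EEM stacks.

The solver is hierarchical alternating least squares (HALS) on the 3-way
tensor (samples x excitation x emission) with nonnegativity on all modes.
Excitation/emission loadings are normalized to unit maximum with the scale
absorbed into the sample scores, so a score is directly the component's
Fmax contribution in that EEM.

Also provided: projection of fixed components onto new EEMs by nonnegative
least squares, split-half similarity for component-number selection,
Tucker congruence, and congruence-based component matching.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from eemquench.core import EEM, EEMDataset, WavelengthGrid
from eemquench.errors import GridError, NumericError, ValidationError

__all__ = [
    "ParafacModel",
    "SplitHalfResult",
    "fit_parafac_hals",
    "compute_fmax",
    "project_eem",
    "split_half_similarity",
    "select_n_components",
    "tucker_congruence",
    "match_components",
]

_EPS = np.finfo(float).eps


@dataclass
class ParafacModel:
    """Nonnegative CP decomposition of a stack of EEMs.

    ``ex_loadings`` (n_ex x R) and ``em_loadings`` (n_em x R) are
    column-normalized to unit maximum; ``scores`` (n_eems x R) carry the
    scale, so ``scores[i, r]`` equals component r's Fmax in EEM i.
    """

    ex_loadings: np.ndarray
    em_loadings: np.ndarray
    scores: np.ndarray
    grid: WavelengthGrid
    eem_ids: list[str]
    rel_error: float = np.nan
    n_iter: int = 0
    error_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("ex_loadings", "em_loadings", "scores"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"{name} must be 2-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{name} must be finite and nonnegative")
            setattr(self, name, arr)
        if not (
            self.ex_loadings.shape[1]
            == self.em_loadings.shape[1]
            == self.scores.shape[1]
        ):
            raise ValidationError("component counts differ across factor matrices")

    @property
    def R(self) -> int:
        return self.scores.shape[1]

    @property
    def n_eems(self) -> int:
        return self.scores.shape[0]

    def component_matrix(self, r: int) -> np.ndarray:
        """Unit-scale spatial pattern of component r (n_ex x n_em)."""
        return np.outer(self.ex_loadings[:, r], self.em_loadings[:, r])

    def reconstruct(self, i: int) -> np.ndarray:
        """Model reconstruction of EEM i."""
        return np.einsum(
            "r,jr,kr->jk", self.scores[i], self.ex_loadings, self.em_loadings
        )

    def save(self, directory: str | os.PathLike) -> None:
        """Serialize to a directory of plain CSV/JSON files."""
        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        d = os.fspath(directory)
        pd.DataFrame(
            self.ex_loadings, index=self.grid.excitation
        ).to_csv(os.path.join(d, "ex_loadings.csv"))
        pd.DataFrame(
            self.em_loadings, index=self.grid.emission
        ).to_csv(os.path.join(d, "em_loadings.csv"))
        pd.DataFrame(self.scores, index=self.eem_ids).to_csv(
            os.path.join(d, "scores.csv")
        )
        with open(os.path.join(d, "meta.json"), "w") as fh:
            json.dump(
                {
                    "R": self.R,
                    "rel_error": float(self.rel_error),
                    "n_iter": self.n_iter,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "ParafacModel":
        import pandas as pd

        d = os.fspath(directory)
        exl = pd.read_csv(os.path.join(d, "ex_loadings.csv"), index_col=0)
        eml = pd.read_csv(os.path.join(d, "em_loadings.csv"), index_col=0)
        sc = pd.read_csv(os.path.join(d, "scores.csv"), index_col=0)
        with open(os.path.join(d, "meta.json")) as fh:
            meta = json.load(fh)
        grid = WavelengthGrid(
            exl.index.to_numpy(float), eml.index.to_numpy(float)
        )
        return cls(
            ex_loadings=exl.to_numpy(float),
            em_loadings=eml.to_numpy(float),
            scores=sc.to_numpy(float),
            grid=grid,
            eem_ids=[str(i) for i in sc.index],
            rel_error=meta.get("rel_error", np.nan),
            n_iter=meta.get("n_iter", 0),
        )


def _stack(eems: list[EEM]) -> tuple[np.ndarray, WavelengthGrid]:
    if not eems:
        raise ValidationError("no EEMs supplied")
    grid = eems[0].grid
    for e in eems[1:]:
        if not e.grid.isclose(grid):
            raise ValidationError("all EEMs must share one wavelength grid")
    X = np.stack([e.filled(0.0) for e in eems])
    if not np.all(np.isfinite(X)):
        raise NumericError("EEM stack contains non-finite values")
    return X, grid


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # rows indexed (i of a, j of b) with j fastest, matching row-major reshape
    return (a[:, None, :] * b[None, :, :]).reshape(-1, a.shape[1])


def _hals_update(F: np.ndarray, M: np.ndarray, G: np.ndarray, rng) -> None:
    """One HALS sweep over the columns of factor matrix F, in place."""
    for r in range(F.shape[1]):
        denom = G[r, r]
        if denom < _EPS:
            denom = _EPS
        col = F[:, r] + (M[:, r] - F @ G[:, r]) / denom
        np.maximum(col, 0.0, out=col)
        if not col.any():
            # dead component: reseed tiny to keep the solver alive
            col = rng.uniform(0.0, 1.0, size=col.shape) * 1e-12
        F[:, r] = col


def _fit_single(
    X: np.ndarray,
    R: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, list[float]]:
    n_i, n_j, n_k = X.shape
    A = rng.uniform(0.1, 1.0, size=(n_i, R))
    B = rng.uniform(0.1, 1.0, size=(n_j, R))
    C = rng.uniform(0.1, 1.0, size=(n_k, R))
    X0 = X.reshape(n_i, n_j * n_k)
    X1 = np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(n_j, n_i * n_k)
    X2 = np.ascontiguousarray(X.transpose(2, 0, 1)).reshape(n_k, n_i * n_j)
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        return A * 0, B, C, 0.0, 0, [0.0]
    prev_err = np.inf
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        _hals_update(A, X0 @ _khatri_rao(B, C), (B.T @ B) * (C.T @ C), rng)
        _hals_update(B, X1 @ _khatri_rao(A, C), (A.T @ A) * (C.T @ C), rng)
        _hals_update(C, X2 @ _khatri_rao(A, B), (A.T @ A) * (B.T @ B), rng)
        rec_sq = (
            norm_x**2
            - 2.0 * np.sum((X2 @ _khatri_rao(A, B)) * C)
            + np.sum(((A.T @ A) * (B.T @ B)) * (C.T @ C))
        )
        err = np.sqrt(max(rec_sq, 0.0)) / norm_x
        trace.append(err)
        if not np.isfinite(err):
            raise NumericError("HALS diverged (non-finite reconstruction error)")
        if abs(prev_err - err) < tol:
            break
        prev_err = err
    return A, B, C, trace[-1], it, trace


def _normalize_unit_max(
    A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-max loadings with scale pushed into scores; components sorted
    by descending total score for a deterministic output order."""
    b_max = B.max(axis=0)
    c_max = C.max(axis=0)
    b_max[b_max < _EPS] = 1.0
    c_max[c_max < _EPS] = 1.0
    B = B / b_max
    C = C / c_max
    A = A * b_max * c_max
    order = np.argsort(-A.sum(axis=0), kind="stable")
    return A[:, order], B[:, order], C[:, order]


def fit_parafac_hals(
    eems: list[EEM] | EEMDataset,
    R: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 5,
    seed: int | None = None,
    eem_ids: list[str] | None = None,
) -> ParafacModel:
    """Fit a nonnegative R-component PARAFAC model by HALS.

    The best of ``n_restarts`` random initializations (by final relative
    reconstruction error) is returned. Deterministic for a given seed.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    if isinstance(eems, EEMDataset):
        eem_list, ids = eems.eems("both")
    else:
        eem_list = list(eems)
        ids = eem_ids if eem_ids is not None else [str(i) for i in range(len(eem_list))]
    X, grid = _stack(eem_list)
    master = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(0, 2**63))
        A, B, C, err, n_iter, trace = _fit_single(X, R, rng, max_iter, tol)
        if best is None or err < best[3]:
            best = (A, B, C, err, n_iter, trace)
    A, B, C, err, n_iter, trace = best
    A, B, C = _normalize_unit_max(A, B, C)
    return ParafacModel(
        ex_loadings=B,
        em_loadings=C,
        scores=A,
        grid=grid,
        eem_ids=ids,
        rel_error=err,
        n_iter=n_iter,
        error_trace=np.asarray(trace),
    )


def compute_fmax(model: ParafacModel, eem_index: int) -> np.ndarray:
    """Per-component Fmax of one modeled EEM.

    Fmax_r = score_r * max(ex_loading_r) * max(em_loading_r); with the
    unit-max normalization used here this equals the score itself, but the
    product form keeps the value invariant to the normalization convention.
    """
    return (
        model.scores[eem_index]
        * model.ex_loadings.max(axis=0)
        * model.em_loadings.max(axis=0)
    )


def project_eem(model: ParafacModel, eem: EEM) -> tuple[np.ndarray, float]:
    """Nonnegative least-squares fit of fixed components to a new EEM.

    Returns the per-component scores (Fmax under unit-max loadings) and
    the residual Frobenius norm.
    """
    if not eem.grid.isclose(model.grid):
        raise GridError("EEM grid does not match the model grid")
    D = np.column_stack(
        [model.component_matrix(r).ravel() for r in range(model.R)]
    )
    scores, resid = nnls(D, eem.filled(0.0).ravel())
    return scores, resid


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient: a.b / (|a| |b|)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("congruence undefined for zero vectors")
    return float(a @ b / (na * nb))


def _congruence_matrix(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(fa, axis=0)
    nb = np.linalg.norm(fb, axis=0)
    na[na == 0] = _EPS
    nb[nb == 0] = _EPS
    return (fa.T @ fb) / np.outer(na, nb)


def match_components(model_a: ParafacModel, model_b: ParafacModel) -> np.ndarray:
    """Permutation p with p[i] = b's component matched to a's component i.

    Solved exactly as an optimal assignment maximizing summed excitation +
    emission congruence; ties resolve deterministically to lowest index.
    """
    if model_a.R != model_b.R:
        raise ValidationError("models have different component counts")
    sim = _congruence_matrix(
        model_a.ex_loadings, model_b.ex_loadings
    ) + _congruence_matrix(model_a.em_loadings, model_b.em_loadings)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(model_a.R, dtype=int)
    perm[rows] = cols
    return perm


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SplitHalfResult:
    """Average split-half loading similarity at one candidate R."""

    R: int
    mean_similarity: float
    per_split: list[dict] = field(default_factory=list)
    N: int = 0


def split_half_similarity(
    dataset: EEMDataset,
    R: int,
    N: int = 100,
    seed: int | None = None,
    *,
    fit_opts: dict | None = None,
) -> SplitHalfResult:
    """Mean Pearson similarity of loadings across N random halvings.

    Each halving keeps a pair's original and quenched EEMs in the same
    half. Both halves are fitted at R, components are matched by
    congruence, and the Pearson correlations of matched excitation and
    emission loadings are averaged over components and splits.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    if len(dataset) < 4:
        raise ValidationError("split-half needs at least 4 sample pairs")
    half = len(dataset) // 2
    if 2 * half < 2 * R:
        raise ValidationError(
            f"halves of {half} pairs are too small to fit R={R} components"
        )
    opts = dict(max_iter=300, tol=1e-7, n_restarts=2)
    if fit_opts:
        opts.update(fit_opts)
    rng = np.random.default_rng(seed)
    per_split: list[dict] = []
    sims: list[float] = []
    for _ in range(N):
        order = rng.permutation(len(dataset))
        ids = dataset.sample_ids
        ids_a = [ids[i] for i in order[:half]]
        ids_b = [ids[i] for i in order[half : 2 * half]]
        seeds = rng.integers(0, 2**63, size=2)
        ma = fit_parafac_hals(dataset.subset(ids_a), R, seed=int(seeds[0]), **opts)
        mb = fit_parafac_hals(dataset.subset(ids_b), R, seed=int(seeds[1]), **opts)
        perm = match_components(ma, mb)
        sim_ex = np.array(
            [
                _pearson(ma.ex_loadings[:, r], mb.ex_loadings[:, perm[r]])
                for r in range(R)
            ]
        )
        sim_em = np.array(
            [
                _pearson(ma.em_loadings[:, r], mb.em_loadings[:, perm[r]])
                for r in range(R)
            ]
        )
        per_split.append({"sim_ex": sim_ex, "sim_em": sim_em})
        sims.append(float(np.mean((sim_ex + sim_em) / 2.0)))
    return SplitHalfResult(
        R=R, mean_similarity=float(np.mean(sims)), per_split=per_split, N=N
    )


def select_n_components(
    dataset: EEMDataset,
    R_range: list[int],
    N: int = 100,
    seed: int | None = None,
    threshold: float = 0.95,
    *,
    fit_opts: dict | None = None,
) -> tuple[int, list[SplitHalfResult]]:
    """Largest R whose mean split-half similarity passes ``threshold``.

    Returns the recommendation and the full curve. If no R passes, the
    argmax is returned with a warning.
    """
    if not R_range:
        raise ValidationError("R_range must be nonempty")
    rng = np.random.default_rng(seed)
    curve = [
        split_half_similarity(
            dataset, R, N, seed=int(rng.integers(0, 2**63)), fit_opts=fit_opts
        )
        for R in sorted(R_range)
    ]
    passing = [res.R for res in curve if res.mean_similarity >= threshold]
    if passing:
        return max(passing), curve
    best = max(curve, key=lambda res: res.mean_similarity)
    warnings.warn(
        f"no candidate R reached split-half similarity {threshold}; "
        f"returning argmax R={best.R} "
        f"(similarity {best.mean_similarity:.3f})",
        stacklevel=2,
    )
    return best.R, curve
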