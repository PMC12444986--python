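"""F0/F-driven K-PARAFACs clustering.

Partitions sample pairs so that clusters are homogeneous in apparent
F0/F, with a separate PARAFAC model fitted per cluster. The alternation
is k-means-like: (per-cluster PARAFAC fit) -> (project every pair under
every cluster model, components matched to a global reference model) ->
(reassign each pair to the cluster whose centroid F0/F vector is
nearest). Pairs move atomically — original and quenched EEMs are always
co-clustered. Iterations that would increase the objective are rejected,
so the recorded trace is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from eemquench.core import EEMDataset
from eemquench.errors import ValidationError
from eemquench.parafac import (
    ParafacModel,
    fit_parafac_hals,
    match_components,
    project_eem,
)

__all__ = ["ClusteringResult", "f0f_kparafacs", "cluster_summary"]

#: presence floor relative to the pair's largest Fmax; components absent
#: from both measurements contribute a neutral ratio of 1
_PRESENCE_FRAC = 1e-6
_RATIO_CAP = 1e3


def _safe_f0f(fmax_o: np.ndarray, fmax_q: np.ndarray) -> np.ndarray:
    scale = max(fmax_o.max(), fmax_q.max(), 1e-30)
    floor = _PRESENCE_FRAC * scale
    out = np.ones_like(fmax_o)
    present = (fmax_o > floor) | (fmax_q > floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fmax_o / np.maximum(fmax_q, floor)
    out[present] = np.clip(ratio[present], 0.0, _RATIO_CAP)
    return out


def _pair_f0f_under_model(model: ParafacModel, pair, perm: np.ndarray) -> np.ndarray:
    so, _ = project_eem(model, pair.original)
    sq, _ = project_eem(model, pair.quenched)
    return _safe_f0f(so, sq)[perm]


@dataclass
class ClusteringResult:
    """Labels, per-cluster models, and the accepted objective trace."""

    labels: dict[str, int]
    models: list[ParafacModel]
    objective_trace: list[float] = field(default_factory=list)
    f0f_centroids: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = False
    global_model: ParafacModel | None = None


def _enforce_min_size(
    labels: np.ndarray, dist: np.ndarray, K: int, min_size: int, ids: list[str]
) -> np.ndarray:
    """Top up clusters below min_size from the largest cluster.

    Moves the surplus samples closest (by assignment distance to the
    starving cluster) out of the largest cluster; deterministic by
    distance then sample id.
    """
    labels = labels.copy()
    for k in range(K):
        while np.sum(labels == k) < min_size:
            sizes = np.bincount(labels, minlength=K)
            donor = int(np.argmax(sizes))
            if donor == k or sizes[donor] <= min_size:
                raise ValidationError(
                    f"cannot satisfy min_size={min_size} with K={len(sizes)} "
                    f"clusters over {labels.size} pairs"
                )
            candidates = np.flatnonzero(labels == donor)
            order = sorted(candidates, key=lambda i: (dist[i, k], ids[i]))
            labels[order[0]] = k
    return labels


def f0f_kparafacs(
    dataset: EEMDataset,
    K: int,
    R: int,
    *,
    max_iter: int = 20,
    min_size: int = 2,
    seed: int | None = None,
    fit_opts: dict | None = None,
) -> ClusteringResult:
    """Cluster sample pairs by apparent F0/F with per-cluster PARAFAC models.

    Initialization: a global PARAFAC fit at R provides each pair's
    apparent-F0/F vector, which is k-means clustered into K groups. The
    alternation then refits a PARAFAC per cluster and reassigns pairs by
    squared distance between their F0/F vector under each cluster's model
    and that cluster's centroid. Deterministic for a given seed.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if len(dataset) < K * min_size:
        raise ValidationError(
            f"dataset of {len(dataset)} pairs cannot hold {K} clusters of "
            f"min_size {min_size}"
        )
    opts = dict(max_iter=300, tol=1e-7, n_restarts=2)
    if fit_opts:
        opts.update(fit_opts)
    rng = np.random.default_rng(seed)
    ids = dataset.sample_ids
    n = len(dataset)

    global_model = fit_parafac_hals(dataset, R, seed=int(rng.integers(0, 2**63)), **opts)
    identity = np.arange(R)
    init_f0f = np.stack(
        [_pair_f0f_under_model(global_model, p, identity) for p in dataset]
    )
    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=10, random_state=int(rng.integers(0, 2**31)))
        labels = km.fit_predict(init_f0f)
        labels = _enforce_min_size(
            labels, km.transform(init_f0f) ** 2, K, min_size, ids
        )

    trace: list[float] = []
    models: list[ParafacModel] = []
    centroids = np.zeros((K, R))
    best_obj = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        models = []
        perms = []
        for k in range(K):
            members = [ids[i] for i in np.flatnonzero(labels == k)]
            mk = fit_parafac_hals(
                dataset.subset(members), R, seed=int(rng.integers(0, 2**63)), **opts
            )
            models.append(mk)
            perms.append(match_components(global_model, mk))
        # F0/F of every pair under every cluster model, global component order
        f0f = np.stack(
            [
                [_pair_f0f_under_model(models[k], p, perms[k]) for k in range(K)]
                for p in dataset
            ]
        )  # (n, K, R)
        centroids = np.stack(
            [f0f[labels == k, k].mean(axis=0) for k in range(K)]
        )
        dist = ((f0f - centroids[None, :, :]) ** 2).sum(axis=2)  # (n, K)
        new_labels = dist.argmin(axis=1)
        new_labels = _enforce_min_size(new_labels, dist, K, min_size, ids)
        obj = float(dist[np.arange(n), new_labels].sum())
        if obj > best_obj + 1e-12:
            # refusing a worsening step keeps the trace non-increasing
            converged = True
            break
        best_obj = obj
        trace.append(obj)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    return ClusteringResult(
        labels={ids[i]: int(labels[i]) for i in range(n)},
        models=models,
        objective_trace=trace,
        f0f_centroids=centroids,
        n_iter=it,
        converged=converged,
        global_model=global_model,
    )


def cluster_summary(result: ClusteringResult, dataset: EEMDataset) -> pd.DataFrame:
    """Per-cluster, per-component apparent F0/F and target-to-Fmax ratios.

    Ratio columns (``<target>_per_fmax``: target concentration divided by
    the component's original-sample Fmax) appear only for targets present
    in the dataset.
    """
    ids = dataset.sample_ids
    K = len(result.models)
    identity_perms = [
        match_components(result.global_model, m) if result.global_model else
        np.arange(m.R)
        for m in result.models
    ]
    target_names = sorted(
        {t for p in dataset for t in (p.targets or {})}
    )
    rows = []
    for k in range(K):
        model = result.models[k]
        perm = identity_perms[k]
        members = [p for p in dataset if result.labels[p.sample_id] == k]
        f0f = np.stack([_pair_f0f_under_model(model, p, perm) for p in members])
        fmax_o = np.stack(
            [project_eem(model, p.original)[0][perm] for p in members]
        )
        for r in range(model.R):
            row = {
                "cluster": k,
                "component": r,
                "n": len(members),
                "f0f_mean": float(f0f[:, r].mean()),
                "f0f_std": float(f0f[:, r].std(ddof=1)) if len(members) > 1 else 0.0,
            }
            for t in target_names:
                vals = [
                    p.targets[t] / fmax_o[i, r]
                    for i, p in enumerate(members)
                    if p.targets and t in p.targets and fmax_o[i, r] > 0
                ]
                if vals:
                    row[f"{t}_per_fmax_mean"] = float(np.mean(vals))
                    row[f"{t}_per_fmax_std"] = (
                        float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                    )
            rows.append(row)
    return pd.DataFrame(rows)
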