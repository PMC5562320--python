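"""EM clustering with a diagonal-covariance Gaussian mixture.

The clusterer alternates an E-step (posterior responsibilities under the
current parameters) and an M-step (weighted maximum-likelihood update of
mixing weights, per-component means and per-dimension variances) until the
total log-likelihood improves by less than ``tol``.  The component count is
chosen automatically by cross-validated held-out log-likelihood, emulating
clustering toolkits that grow k while the CV score improves.

Candidate compounds falling in the same mixture component as the approved
drugs are retained (:func:`cocluster_select`), and the whole
encode -> select k -> fit -> co-cluster loop can be iterated
(:func:`iterative_refine`) until the candidate set stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from chemscreen.features import FEATURE_NAMES, encode_cohort
from chemscreen.index import NeighborIndex, ScreenInputs

_LOG_2PI = np.log(2.0 * np.pi)


class CoClusterError(RuntimeError):
    """Drugs split across clusters under policy 'all'."""

    def __init__(self, partition: dict[Hashable, int]):
        self.partition = partition
        super().__init__(f"approved drugs split across clusters: {partition}")


@dataclass
class GMMModel:
    """Fitted diagonal-covariance Gaussian mixture."""

    k: int
    weights: np.ndarray            # (k,)
    means: np.ndarray              # (k, d)
    variances: np.ndarray          # (k, d), floored
    loglik_trace: list[float] = field(default_factory=list)
    seed: int = 0
    converged: bool = False
    n_iter: int = 0

    def _log_prob(self, X: np.ndarray) -> np.ndarray:
        """Weighted component log-densities, shape (n, k)."""
        n, d = X.shape
        out = np.empty((n, self.k))
        for j in range(self.k):
            diff2 = (X - self.means[j]) ** 2 / self.variances[j]
            out[:, j] = -0.5 * (d * _LOG_2PI + np.log(self.variances[j]).sum()
                                + diff2.sum(axis=1))
        return out + np.log(self.weights)

    def log_likelihood(self, X: np.ndarray) -> float:
        """Total log-likelihood of ``X`` under the mixture."""
        return float(logsumexp(self._log_prob(np.asarray(X, float)), axis=1).sum())

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_prob(np.asarray(X, float))
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax breaks ties toward the lower cluster index
        return np.argmax(self.responsibilities(X), axis=1)


@dataclass
class ClusterAssignment:
    """Hard labels plus the posterior matrix they were derived from."""

    labels: dict[Hashable, int]
    responsibilities: np.ndarray
    row_order: list[Hashable]


def _init_params(
    X: np.ndarray, k: int, rng: np.random.Generator, floor: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Farthest-point seeding followed by 10 k-means iterations."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [((X - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        centers.append(X[int(np.argmax(d2))])
    centers_arr = np.array(centers)

    labels = np.zeros(n, dtype=int)
    for _ in range(10):
        d2 = ((X[:, None, :] - centers_arr[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centers_arr[j] = members.mean(axis=0)
            else:
                # re-seed an empty cluster on the point farthest from its center
                far = int(np.argmax(d2.min(axis=1)))
                centers_arr[j] = X[far]

    weights = np.full(k, 1.0 / k)
    variances = np.empty_like(centers_arr)
    for j in range(k):
        members = X[labels == j]
        v = members.var(axis=0) if len(members) > 1 else np.zeros(X.shape[1])
        variances[j] = np.maximum(v, floor)
    counts = np.bincount(labels, minlength=k).astype(float)
    if counts.sum() > 0:
        weights = np.maximum(counts, 1.0) / np.maximum(counts, 1.0).sum()
    return weights, centers_arr, variances


def em_fit(
    data: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    variance_floor: float = 1e-6,
) -> GMMModel:
    """Fit a k-component diagonal Gaussian mixture by EM.

    ``variance_floor`` is a fraction of each dimension's overall data
    variance used as a lower bound on component variances, keeping
    degenerate (e.g. all-identical) inputs well-posed.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} data rows")

    floor = np.maximum(variance_floor * X.var(axis=0), 1e-12)
    rng = np.random.default_rng(seed)
    weights, means, variances = _init_params(X, k, rng, floor)

    model = GMMModel(k=k, weights=weights, means=means, variances=variances, seed=seed)
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        lp = model._log_prob(X)
        row_ll = logsumexp(lp, axis=1)
        ll = float(row_ll.sum())
        model.loglik_trace.append(ll)
        resp = np.exp(lp - row_ll[:, None])

        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        model.weights = nk / nk.sum()
        model.means = (resp.T @ X) / nk[:, None]
        ex2 = (resp.T @ (X**2)) / nk[:, None]
        model.variances = np.maximum(ex2 - model.means**2, floor)

        model.n_iter = it
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            model.converged = True
            break
        prev_ll = ll
    return model


def select_k(
    data: np.ndarray | pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    k_max: int = 10,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> int:
    """Automatic component count by cross-validated log-likelihood.

    Starting at k=1, k grows while the mean held-out per-datum
    log-likelihood over the folds strictly improves; the last improving k
    is returned (capped at ``k_max``).
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"{n} rows cannot be split into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_idx = np.array_split(order, folds)
    min_train = min(n - len(f) for f in fold_idx)

    best_k, best_score = 1, -np.inf
    for k in range(1, min(k_max, min_train) + 1):
        held = 0.0
        for f in fold_idx:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            model = em_fit(X[mask], k, seed=seed, tol=tol, max_iter=max_iter)
            held += model.log_likelihood(X[f])
        score = held / n
        if score > best_score:
            best_k, best_score = k, score
        else:
            break
    return best_k


def assign(model: GMMModel, cohort: pd.DataFrame) -> ClusterAssignment:
    """Hard cluster assignment of an :func:`encode_cohort` frame."""
    X = cohort[list(FEATURE_NAMES)].to_numpy(float)
    resp = model.responsibilities(X)
    labels = {row: int(c) for row, c in zip(cohort.index, resp.argmax(axis=1))}
    return ClusterAssignment(labels=labels, responsibilities=resp,
                             row_order=list(cohort.index))


def cocluster_select(
    assignment: ClusterAssignment,
    drug_labels: Iterable[Hashable],
    policy: Literal["all", "plurality"] = "plurality",
) -> set[Hashable]:
    """Candidates sharing a mixture component with the approved drugs.

    Policy "all" demands every drug in one cluster and raises
    :class:`CoClusterError` otherwise; "plurality" uses the cluster holding
    the most drugs (ties toward the lower cluster index).
    """
    drug_labels = set(drug_labels)
    missing = drug_labels - set(assignment.labels)
    if missing:
        raise ValueError(f"assignment does not cover drugs: {sorted(missing)}")
    drug_clusters = {d: assignment.labels[d] for d in drug_labels}
    clusters = set(drug_clusters.values())
    if policy == "all":
        if len(clusters) != 1:
            raise CoClusterError(drug_clusters)
        target = clusters.pop()
    else:
        counts: dict[int, int] = {}
        for c in drug_clusters.values():
            counts[c] = counts.get(c, 0) + 1
        target = min(c for c in counts if counts[c] == max(counts.values()))
    return {
        row
        for row, c in assignment.labels.items()
        if c == target and row not in drug_labels
    }


def iterative_refine(
    candidates: Iterable[int],
    drugs: Iterable[int],
    inputs: ScreenInputs,
    index: NeighborIndex,
    rounds: int = 2,
    folds: int = 10,
    k_max: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    policy: Literal["all", "plurality"] = "plurality",
) -> tuple[set[int], list[dict]]:
    """Repeat encode -> select_k -> em_fit -> cocluster_select.

    Stops when the candidate set stops shrinking, becomes empty, or
    ``rounds`` is reached.  The fold count is clamped to the cohort size so
    late rounds with few survivors remain runnable.  Returns the surviving
    candidate set and a per-round audit.
    """
    survivors = sorted(set(candidates))
    drugs = sorted(set(drugs))
    audit: list[dict] = []
    for r in range(rounds):
        if not survivors:
            break
        cohort = encode_cohort(survivors, drugs, inputs, index)
        X = cohort[list(FEATURE_NAMES)].to_numpy(float)
        eff_folds = min(folds, len(cohort))
        k = select_k(X, folds=eff_folds, seed=seed + r, k_max=k_max,
                     tol=tol, max_iter=max_iter)
        model = em_fit(X, k, seed=seed + r, tol=tol, max_iter=max_iter)
        assignment = assign(model, cohort)
        selected = cocluster_select(assignment, drugs, policy=policy)
        new = sorted(int(c) for c in selected)
        sizes = np.bincount(
            np.array([assignment.labels[row] for row in assignment.row_order]),
            minlength=k,
        )
        audit.append(
            {
                "round": r + 1,
                "k": k,
                "cluster_sizes": sizes.tolist(),
                "candidates_in": len(survivors),
                "survivors": len(new),
            }
        )
        if new == survivors:
            break
        survivors = new
    return set(survivors), audit
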