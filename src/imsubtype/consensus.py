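"""Resampling consensus clustering with PAM and prognosis-ordered labels.

The discovery cohort's selected signature scores are clustered many times
on random 80% subsamples with k-medoids (PAM, Euclidean distance). For
every k the consensus matrix M_k(i, j) is the fraction of co-sampled runs
in which samples i and j landed in the same cluster. The empirical CDF of
the upper-triangle consensus values, its exact area A(k), and the relative
area increase Delta(k) summarize how stable each k is; the final partition
for the chosen k comes from average-linkage hierarchical clustering of the
dissimilarity 1 - M_k. Labels are then renamed IS1..ISK so that IS1 has
the poorest prognosis (lowest restricted-mean DFS) and ISK the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import SurvivalTable
from .scoring import SignatureScoreMatrix

__all__ = [
    "ConsensusResult",
    "SubtypeAssignment",
    "ConsensusClusterer",
    "pam_cluster",
    "consensus_run",
    "final_labels",
    "order_by_prognosis",
]


# ---------------------------------------------------------------------------
# PAM (k-medoids): deterministic BUILD + SWAP on a precomputed distance matrix
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dmin = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate h: sum of max(dmin - d(., h), 0)
        gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        dmin = np.minimum(dmin, D[:, h])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        Dm = D[:, medoids]                      # n x k
        part = np.argpartition(Dm, 1, axis=1)[:, :2]
        row = np.arange(n)
        two = np.stack([Dm[row, part[:, 0]], Dm[row, part[:, 1]]], axis=1)
        swap_ord = two[:, 0] > two[:, 1]
        part[swap_ord] = part[swap_ord][:, ::-1]
        two[swap_ord] = two[swap_ord][:, ::-1]
        nearest_idx, d1, d2 = part[:, 0], two[:, 0], two[:, 1]
        cost = d1.sum()
        best_cost = cost
        best_swap = None
        for mi in range(len(medoids)):
            # distance to nearest medoid if medoid mi were removed
            dref = np.where(nearest_idx == mi, d2, d1)
            cand = np.minimum(D, dref[:, None]).sum(axis=0)  # cost per new h
            cand[medoids] = np.inf
            h = int(np.argmin(cand))
            if cand[h] < best_cost - 1e-12:
                best_cost = cand[h]
                best_swap = (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    return medoids


def _pam_labels(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    return np.argmin(D[:, medoids], axis=1)


def _pam_from_dist(D: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    medoids = _pam_build(D, k)
    medoids = _pam_swap(D, medoids)
    return _pam_labels(D, medoids), medoids


def pam_cluster(points: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    """k-medoids clustering (BUILD then SWAP) with Euclidean distance.

    Deterministic given the input order: all ties break toward the lowest
    index, so ``seed`` is accepted for interface stability but unused.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot place {k} medoids among {n} points")
    D = cdist(pts, pts)
    labels, _ = _pam_from_dist(D, k)
    return labels


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    sample_ids: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]   # (x grid, CDF values)
    area: dict[int, float]                          # A(k)
    delta: dict[int, float]                         # Delta(k)
    n_resamples: int
    frac: float
    seed: int | None
    never_cosampled_pairs: int = 0

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_range,
             "area": [self.area[k] for k in self.k_range],
             "delta": [self.delta[k] for k in self.k_range]}
        )

    def suggest_k(self) -> int:
        """Delta-area heuristic: the k >= 3 with the largest relative area
        increase. Delta(2) = A(2) lives on a different scale and is not
        comparable; the choice of k remains a user decision informed by the
        full A/Delta table and CDF curves."""
        ks = [k for k in self.k_range if k >= 3]
        if not ks:
            return self.k_range[0]
        return max(ks, key=lambda k: self.delta[k])


@dataclass
class SubtypeAssignment:
    labels: pd.Series          # sample id -> label string
    k: int
    ordering_basis: dict[str, float] | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, lab in self.labels.items():
            out.setdefault(lab, []).append(sid)
        return out


def _ecdf_area(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of consensus entries and its exact step integral.

    The area is sum_i (x_{i+1} - x_i) * F(x_i) over the sorted breakpoints
    extended to [0, 1]; for a perfect 0/1 consensus matrix this equals the
    fraction of zero pairs.
    """
    xs = np.unique(np.concatenate([[0.0], values, [1.0]]))
    F = np.searchsorted(np.sort(values), xs, side="right") / values.size
    area = float(np.sum(np.diff(xs) * F[:-1]))
    return xs, F, area


class ConsensusClusterer(ClusterMixin, BaseEstimator):
    """Consensus clustering estimator over samples x features scores.

    Parameters
    ----------
    k_range : sequence of int, default 2..10
        Cluster numbers to evaluate.
    n_resamples : int, default 500
        Number of random subsamples.
    frac : float, default 0.8
        Item-resampling fraction (subsampling without replacement).
    k : int or None
        If set, ``fit`` also computes ``labels_`` for this k.
    random_state : int or None
        Seed for the subsampling stream.
    """

    def __init__(self, k_range=tuple(range(2, 11)), n_resamples: int = 500,
                 frac: float = 0.8, k: int | None = None,
                 random_state: int | None = None):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.frac = frac
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, SignatureScoreMatrix):
            frame = X.scores.T          # samples x features
        elif isinstance(X, pd.DataFrame):
            frame = X
        else:
            frame = pd.DataFrame(np.asarray(X, dtype=float))
        pts = frame.to_numpy(dtype=float)
        n = pts.shape[0]
        ks = sorted(int(k) for k in self.k_range)
        if n < 10:
            raise ValueError("consensus clustering needs at least 10 samples")
        if not (0.0 < self.frac <= 1.0):
            raise ValueError("frac must be in (0, 1]")
        m = int(np.ceil(self.frac * n))
        if max(ks) >= m:
            raise ValueError(
                f"largest k ({max(ks)}) must be smaller than the subsample "
                f"size ({m})"
            )
        rng = np.random.default_rng(self.random_state)
        counts = {k: np.zeros((n, n)) for k in ks}
        cosampled = np.zeros((n, n))
        for _ in range(self.n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = pts[idx]
            D = cdist(sub, sub)
            cosampled[np.ix_(idx, idx)] += 1.0
            for k in ks:
                labels, _ = _pam_from_dist(D, k)
                Z = np.zeros((m, k))
                Z[np.arange(m), labels] = 1.0
                counts[k][np.ix_(idx, idx)] += Z @ Z.T
        iu = np.triu_indices(n, 1)
        never = int((cosampled[iu] == 0).sum())
        if never:
            warnings.warn(
                f"{never} sample pair(s) were never co-sampled; their "
                f"consensus entries are set to 0",
                stacklevel=2,
            )
        consensus, cdf, area, delta = {}, {}, {}, {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for k in ks:
                M = np.where(cosampled > 0, counts[k] / np.maximum(cosampled, 1), 0.0)
                M = (M + M.T) / 2.0
                np.fill_diagonal(M, 1.0)
                consensus[k] = M
                xs, F, a = _ecdf_area(M[iu])
                cdf[k] = (xs, F)
                area[k] = a
        for i, k in enumerate(ks):
            if i == 0:
                delta[k] = area[k]
            else:
                prev = ks[i - 1]
                delta[k] = ((area[k] - area[prev]) / area[prev]
                            if area[prev] > 0 else np.inf)
        self.result_ = ConsensusResult(
            sample_ids=[str(s) for s in frame.index],
            k_range=ks,
            consensus=consensus,
            cdf=cdf,
            area=area,
            delta=delta,
            n_resamples=self.n_resamples,
            frac=self.frac,
            seed=self.random_state,
            never_cosampled_pairs=never,
        )
        if self.k is not None:
            assign = final_labels(self.result_, self.k)
            self.labels_ = assign.labels.to_numpy()
            self.assignment_ = assign
        return self

    def suggest_k(self) -> int:
        return self.result_.suggest_k()


def consensus_run(scores, k_range=tuple(range(2, 11)), n_resamples: int = 500,
                  frac: float = 0.8, seed: int | None = None) -> ConsensusResult:
    """Functional wrapper over :class:`ConsensusClusterer`."""
    est = ConsensusClusterer(k_range=k_range, n_resamples=n_resamples,
                             frac=frac, random_state=seed)
    est.fit(scores)
    return est.result_


def final_labels(result: ConsensusResult, k: int) -> SubtypeAssignment:
    """Cut the average-linkage tree of 1 - M_k into k groups."""
    if k not in result.consensus:
        raise ValueError(f"k={k} was not evaluated (k_range={result.k_range})")
    M = result.consensus[k]
    d = 1.0 - M
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    uniq = np.unique(raw)
    if len(uniq) < k:
        raise ValueError(
            f"consensus matrix supports only {len(uniq)} group(s) at k={k}; "
            f"the requested k is unstable"
        )
    # contiguous labels in order of first appearance
    remap = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([f"C{remap[lab]}" for lab in raw],
                       index=result.sample_ids, name="subtype")
    return SubtypeAssignment(labels=labels, k=k)


def _rmst(time: np.ndarray, event: np.ndarray, tau: float) -> float:
    """Restricted mean survival time from the Kaplan-Meier curve."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    kmf = KaplanMeierFitter().fit(time, event)
    return float(restricted_mean_survival_time(kmf, t=tau))


def order_by_prognosis(assign: SubtypeAssignment,
                       surv: SurvivalTable) -> SubtypeAssignment:
    """Relabel clusters IS1..ISK by increasing restricted-mean DFS.

    IS1 gets the poorest prognosis (lowest RMST at the horizon of the
    largest observed time), ISK the best. Ties keep the original label
    order, with a warning.
    """
    common = assign.labels.index.intersection(surv.data.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between assignment and survival")
    labels = assign.labels.loc[common]
    tau = float(surv.data.loc[common, "time_days"].max())
    original = list(dict.fromkeys(assign.labels))
    basis: dict[str, float] = {}
    for lab in original:
        members = labels.index[labels == lab]
        if len(members) == 0:
            raise ValueError(f"cluster {lab!r} has no samples with survival data")
        t = surv.data.loc[members, "time_days"].to_numpy()
        e = surv.data.loc[members, "event"].to_numpy()
        if e.sum() == 0:
            warnings.warn(f"cluster {lab!r} has zero events; its RMST equals "
                          f"the horizon", stacklevel=2)
        basis[lab] = _rmst(t, e, tau)
    if len(set(basis.values())) < len(basis):
        warnings.warn("tied prognosis between clusters; ties broken by "
                      "original label order", stacklevel=2)
    ordered = sorted(original, key=lambda lab: (basis[lab], original.index(lab)))
    rename = {lab: f"IS{i + 1}" for i, lab in enumerate(ordered)}
    new_labels = assign.labels.map(rename)
    new_labels.name = "subtype"
    return SubtypeAssignment(
        labels=new_labels,
        k=assign.k,
        ordering_basis={rename[lab]: basis[lab] for lab in original},
    )
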