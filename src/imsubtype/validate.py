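"""Cross-cohort reproducibility of subtypes.

Discovery-cohort subtypes are summarized by their centroids (per-label mean
signature-score vectors). A validation cohort scored on the same signatures
is either projected directly onto those centroids (each sample takes the
label of the centroid with the highest Pearson correlation) or clustered
independently and matched to the discovery centroids by correlation. The
in-group proportion (IGP) — the fraction of a group's samples whose nearest
neighbor belongs to the same group — quantifies how well the projected
groups cohere in the validation cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .consensus import SubtypeAssignment
from .scoring import SignatureScoreMatrix

__all__ = [
    "CentroidSet",
    "IGPReport",
    "NearestCentroidProjector",
    "subtype_centroids",
    "project_nearest_centroid",
    "igp",
    "centroid_correlation",
]


@dataclass
class CentroidSet:
    """Label -> mean score vector; ``centroids`` is labels x features."""

    centroids: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.centroids.columns)


@dataclass
class IGPReport:
    per_label: dict[str, float]
    metric: str
    n_per_label: dict[str, int]
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.per_label),
             "igp": list(self.per_label.values()),
             "n": [self.n_per_label[lab] for lab in self.per_label]}
        )


def _score_frame(scores) -> pd.DataFrame:
    """Accept a SignatureScoreMatrix or a signatures x samples DataFrame."""
    if isinstance(scores, SignatureScoreMatrix):
        return scores.scores
    return scores


def subtype_centroids(scores, assign: SubtypeAssignment) -> CentroidSet:
    """Per-label arithmetic mean of the samples' score vectors."""
    frame = _score_frame(scores)
    rows = {}
    for lab, members in assign.groups().items():
        cols = [m for m in members if m in frame.columns]
        if not cols:
            raise ValueError(f"label {lab!r} has no scored samples")
        rows[lab] = frame[cols].mean(axis=1)
    return CentroidSet(centroids=pd.DataFrame(rows).T)


class NearestCentroidProjector(ClassifierMixin, BaseEstimator):
    """Assign validation samples to the best-correlated discovery centroid.

    ``fit`` stores centroids from a discovery score matrix and its subtype
    assignment; ``predict`` labels each validation sample with the centroid
    of maximal Pearson correlation. At least ``min_feature_overlap`` of the
    centroid features must be present in the validation scores. Samples
    with zero-variance score vectors (correlation undefined) fall back to
    minimal Euclidean distance and are flagged.
    """

    def __init__(self, min_feature_overlap: float = 0.8):
        self.min_feature_overlap = min_feature_overlap

    def fit(self, scores, assign: SubtypeAssignment):
        self.centroids_ = subtype_centroids(scores, assign)
        return self

    def predict(self, scores_val) -> SubtypeAssignment:
        frame = _score_frame(scores_val)
        cents = self.centroids_.centroids
        shared = [f for f in cents.columns if f in frame.index]
        if len(shared) < self.min_feature_overlap * cents.shape[1]:
            raise ValueError(
                f"only {len(shared)}/{cents.shape[1]} centroid features are "
                f"present in the validation scores (need "
                f">= {self.min_feature_overlap:.0%})"
            )
        C = cents[shared].to_numpy(dtype=float)       # labels x features
        V = frame.loc[shared].to_numpy(dtype=float).T  # samples x features
        labels = list(cents.index)
        out = []
        self.euclidean_fallback_ = []
        Cc = C - C.mean(axis=1, keepdims=True)
        Cn = np.linalg.norm(Cc, axis=1)
        for i, sid in enumerate(frame.columns):
            v = V[i]
            vc = v - v.mean()
            vn = np.linalg.norm(vc)
            if vn == 0:
                d = np.linalg.norm(C - v, axis=1)
                j = int(np.argmin(d))
                self.euclidean_fallback_.append(str(sid))
                out.append(labels[j])
                continue
            r = (Cc @ vc) / (Cn * vn)
            best = r.max()
            ties = np.flatnonzero(np.isclose(r, best, rtol=0, atol=1e-12))
            if len(ties) > 1:
                warnings.warn(
                    f"sample {sid!r}: correlation tie between centroids "
                    f"{[labels[t] for t in ties]}; first label kept",
                    stacklevel=2,
                )
            out.append(labels[int(ties[0])])
        if self.euclidean_fallback_:
            warnings.warn(
                f"{len(self.euclidean_fallback_)} zero-variance sample(s) "
                f"assigned by Euclidean distance",
                stacklevel=2,
            )
        labels_series = pd.Series(out, index=[str(s) for s in frame.columns],
                                  name="subtype")
        return SubtypeAssignment(labels=labels_series, k=len(labels))


def project_nearest_centroid(scores_val, centroids: CentroidSet,
                             min_feature_overlap: float = 0.8) -> SubtypeAssignment:
    """Functional wrapper over :class:`NearestCentroidProjector.predict`."""
    proj = NearestCentroidProjector(min_feature_overlap=min_feature_overlap)
    proj.centroids_ = centroids
    return proj.predict(scores_val)


def _distance_matrix(V: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(V, V)
    if metric == "pearson":
        Vc = V - V.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Vc, axis=1)
        if (norms == 0).any():
            # constant vectors: define r = 0 against everything
            norms = np.where(norms == 0, 1.0, norms)
        R = (Vc @ Vc.T) / np.outer(norms, norms)
        return 1.0 - R
    raise ValueError(f"unknown metric {metric!r}")


def igp(scores_val, assign_val: SubtypeAssignment,
        metric: str = "pearson") -> IGPReport:
    """In-group proportion per label.

    IGP(g) = fraction of samples in g whose nearest neighbor (self
    excluded, ties to the lowest sample index) is also in g. Singleton
    labels get IGP = 0 with a flag.
    """
    frame = _score_frame(scores_val)
    samples = [s for s in frame.columns if s in assign_val.labels.index]
    if len(samples) < 2:
        raise ValueError("IGP needs at least two assigned samples")
    V = frame[samples].to_numpy(dtype=float).T
    D = _distance_matrix(V, metric)
    np.fill_diagonal(D, np.inf)
    nn = np.argmin(D, axis=1)        # ties -> lowest index
    labels = assign_val.labels.loc[samples].to_numpy()
    report: dict[str, float] = {}
    n_per: dict[str, int] = {}
    flags: list[str] = []
    for lab in dict.fromkeys(labels):
        members = np.flatnonzero(labels == lab)
        n_per[str(lab)] = len(members)
        if len(members) == 1:
            report[str(lab)] = 0.0
            flags.append(f"singleton label {lab!r}")
            continue
        same = labels[nn[members]] == lab
        report[str(lab)] = float(same.mean())
    finite = D[np.isfinite(D)]
    if finite.size and np.isclose(finite.min(), finite.max()):
        flags.append("degenerate configuration: all pairwise distances equal")
        warnings.warn("IGP computed on a degenerate configuration "
                      "(all distances tied)", stacklevel=2)
    return IGPReport(per_label=report, metric=metric, n_per_label=n_per,
                     flags=flags)


def centroid_correlation(c_a: CentroidSet, c_b: CentroidSet):
    """Pearson correlation matrix between two cohorts' centroids + matching.

    Returns ``(corr, matching)`` where ``corr`` is a labels_a x labels_b
    DataFrame and ``matching`` a list of (label_a, label_b, r) chosen
    greedily by descending correlation without replacement.
    """
    shared = [f for f in c_a.feature_ids if f in set(c_b.feature_ids)]
    if len(shared) < 2:
        raise ValueError("centroid correlation needs at least 2 shared features")
    A = c_a.centroids[shared].to_numpy(dtype=float)
    B = c_b.centroids[shared].to_numpy(dtype=float)
    for name, mat, cs in (("first", A, c_a), ("second", B, c_b)):
        sd = mat.std(axis=1)
        if (sd == 0).any():
            lab = cs.labels[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"constant centroid {lab!r} in {name} cohort")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    R = (Ac @ Bc.T) / np.outer(np.linalg.norm(Ac, axis=1),
                               np.linalg.norm(Bc, axis=1))
    corr = pd.DataFrame(R, index=c_a.labels, columns=c_b.labels)
    pairs = sorted(
        ((corr.loc[a, b], a, b) for a in c_a.labels for b in c_b.labels),
        key=lambda t: -t[0],
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    matching: list[tuple[str, str, float]] = []
    for r, a, b in pairs:
        if a in used_a or b in used_b:
            continue
        matching.append((a, b, float(r)))
        used_a.add(a)
        used_b.add(b)
    return corr, matching
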