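"""Single-sample gene-set enrichment (ssGSEA) and derived per-sample scores.

The enrichment score for a gene set G in one sample is a rank-weighted
running-sum statistic. Genes are ranked by expression (highest expression
gets rank N, ties receive the average rank) and walked in decreasing
expression order. At position i the in-set fraction is

    P_in(i)  = sum_{g in G, pos(g) <= i} rank_g^alpha / sum_{g in G} rank_g^alpha

and the out-of-set fraction is

    P_out(i) = #{g not in G, pos(g) <= i} / (N - |G|).

The enrichment score is ES = sum_i (P_in(i) - P_out(i)). Because the walk
depends only on ranks, ES is invariant under any strictly monotone
transform of a sample's expression values. With ``normalize=True`` every
score in the matrix is divided by the global range (max ES - min ES), the
convention for putting scores from different gene sets on one scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, GeneSetCollection, Scale, read_gene_sets

__all__ = [
    "SignatureScoreMatrix",
    "SSGSEAScorer",
    "ssgsea_scores",
    "cytolytic_activity",
    "estimate_scores",
    "named_signature_scores",
    "available_collections",
    "load_bundled_collection",
]

DEFAULT_ALPHA = 0.25


@dataclass
class SignatureScoreMatrix:
    """Signatures x samples enrichment scores.

    ``missing`` lists gene sets that could not be scored (fewer than two
    member genes present in the expression matrix).
    """

    scores: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    normalized: bool = False
    missing: list[str] = field(default_factory=list)

    @property
    def signature_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _es_single(ranks_ordered: np.ndarray, member_ordered: np.ndarray,
               alpha: float) -> float:
    """Running-sum enrichment score for one sample / one set.

    ``ranks_ordered`` and ``member_ordered`` are aligned to the decreasing-
    expression gene order.
    """
    n = ranks_ordered.size
    n_in = int(member_ordered.sum())
    w = np.where(member_ordered, ranks_ordered, 0.0) ** alpha
    w[~member_ordered] = 0.0
    denom_in = w.sum()
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~member_ordered) / (n - n_in)
    return float(np.sum(p_in - p_out))


class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping an expression matrix to signature scores.

    Parameters
    ----------
    gene_sets : GeneSetCollection
        Signatures to score.
    alpha : float, default 0.25
        Rank-weighting exponent of the running sum.
    normalize : bool, default False
        Divide all scores by the global (matrix-wide) score range.
    """

    def __init__(self, gene_sets: GeneSetCollection | None = None,
                 alpha: float = DEFAULT_ALPHA, normalize: bool = False):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X: ExpressionMatrix, y=None):
        if self.gene_sets is None or len(self.gene_sets) == 0:
            raise ValueError("gene_sets must be a non-empty GeneSetCollection")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if X.scale is not Scale.LOG2_TPM1:
            raise ValueError("ssGSEA expects expression on the log2(TPM+1) scale")
        gene_index = {g: i for i, g in enumerate(X.gene_ids)}
        members: dict[str, np.ndarray] = {}
        missing: list[str] = []
        n = X.n_genes
        for name in self.gene_sets.names:
            idx = [gene_index[g] for g in self.gene_sets[name] if g in gene_index]
            dropped = len(self.gene_sets[name]) - len(idx)
            if dropped:
                warnings.warn(
                    f"signature {name!r}: {dropped} gene(s) absent from the "
                    f"expression matrix were dropped",
                    stacklevel=2,
                )
            if len(idx) < 2:
                missing.append(name)
                continue
            if len(idx) == n:
                raise ValueError(
                    f"signature {name!r} covers every gene in the matrix; "
                    f"the out-of-set walk is undefined"
                )
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            members[name] = mask
        if missing:
            warnings.warn(
                f"signatures with fewer than 2 matching genes were not scored: "
                f"{missing}",
                stacklevel=2,
            )
        if not members:
            raise ValueError("no signature has at least 2 genes in the matrix")
        self.member_masks_ = members
        self.missing_ = missing
        self.n_features_in_ = n
        return self

    def transform(self, X: ExpressionMatrix) -> SignatureScoreMatrix:
        if not hasattr(self, "member_masks_"):
            self.fit(X)
        values = X.values
        n_genes, n_samples = values.shape
        names = list(self.member_masks_)
        out = np.empty((len(names), n_samples))
        for j in range(n_samples):
            col = values[:, j]
            ranks = rankdata(col)  # highest expression -> rank N, ties averaged
            order = np.argsort(-col, kind="stable")
            r_ord = ranks[order]
            for s, name in enumerate(names):
                m_ord = self.member_masks_[name][order]
                out[s, j] = _es_single(r_ord, m_ord, self.alpha)
        if self.normalize:
            rng = out.max() - out.min()
            if rng > 0:
                out = out / rng
        scores = pd.DataFrame(out, index=names, columns=X.sample_ids)
        return SignatureScoreMatrix(
            scores=scores,
            alpha=self.alpha,
            normalized=self.normalize,
            missing=list(self.missing_),
        )

    def fit_transform(self, X: ExpressionMatrix, y=None, **kwargs):
        return self.fit(X).transform(X)


def ssgsea_scores(X: ExpressionMatrix, sets: GeneSetCollection,
                  alpha: float = DEFAULT_ALPHA,
                  normalize: bool = False) -> SignatureScoreMatrix:
    """Functional wrapper over :class:`SSGSEAScorer`."""
    return SSGSEAScorer(gene_sets=sets, alpha=alpha,
                        normalize=normalize).fit_transform(X)


def cytolytic_activity(X: ExpressionMatrix, geometric: bool = False) -> pd.Series:
    """Per-sample cytolytic activity: the average of GZMA and PRF1 expression.

    The default is the arithmetic mean of the two log2(TPM+1) values. With
    ``geometric=True`` the geometric mean of the TPM values (+0.01 offset,
    the convention of the original cytolytic-activity literature) is
    returned instead.
    """
    if X.scale is not Scale.LOG2_TPM1:
        raise ValueError("cytolytic activity expects log2(TPM+1) expression")
    for gene in ("GZMA", "PRF1"):
        if gene not in X.data.index:
            raise ValueError(f"{gene} not found in the expression matrix")
    a = X.data.loc["GZMA"]
    b = X.data.loc["PRF1"]
    if geometric:
        tpm_a = np.power(2.0, a) - 1.0
        tpm_b = np.power(2.0, b) - 1.0
        cyt = np.sqrt((tpm_a + 0.01) * (tpm_b + 0.01))
    else:
        cyt = (a + b) / 2.0
    cyt.name = "CYT"
    return cyt


def estimate_scores(X: ExpressionMatrix, stromal_set: list[str],
                    immune_set: list[str],
                    alpha: float = DEFAULT_ALPHA) -> dict[str, pd.Series]:
    """Stromal / immune / combined microenvironment scores.

    StromalScore and ImmuneScore are the unnormalized enrichment scores of
    the two sets; ESTIMATEScore is their per-sample sum (a purity proxy:
    higher combined score means lower tumor cellularity).
    """
    coll = GeneSetCollection(sets={"__stromal__": list(stromal_set),
                                   "__immune__": list(immune_set)})
    mat = ssgsea_scores(X, coll, alpha=alpha, normalize=False)
    if mat.missing:
        raise ValueError(
            f"stromal/immune set(s) could not be scored: {mat.missing}"
        )
    stromal = mat.scores.loc["__stromal__"].rename("StromalScore")
    immune = mat.scores.loc["__immune__"].rename("ImmuneScore")
    combined = (stromal + immune).rename("ESTIMATEScore")
    return {"StromalScore": stromal, "ImmuneScore": immune,
            "ESTIMATEScore": combined}


# Bundled collections. The member lists are SYNTHETIC surrogate marker
# lists assembled for testing the scoring machinery; users substitute the
# full published signature lists for real analyses.
_BUNDLED = {
    "metagenes7": "metagenes7.synthetic.gmt",
    "immunecells28": "immunecells28.synthetic.gmt",
    "angiogenesis": "angiogenesis.synthetic.gmt",
    "ifng": "ifng.synthetic.gmt",
    "estimate": "estimate.synthetic.gmt",
}


def available_collections() -> list[str]:
    return sorted(_BUNDLED)


def load_bundled_collection(name: str) -> GeneSetCollection:
    """Load one of the bundled synthetic surrogate GMT collections."""
    if name not in _BUNDLED:
        raise ValueError(
            f"unknown collection {name!r}; available: {available_collections()}"
        )
    ref = resources.files("imsubtype").joinpath("data", _BUNDLED[name])
    with resources.as_file(ref) as path:
        return read_gene_sets(path)


def named_signature_scores(X: ExpressionMatrix, collection_name: str,
                           alpha: float = DEFAULT_ALPHA,
                           normalize: bool = False) -> SignatureScoreMatrix:
    """Score a bundled named collection (metagenes7, immunecells28, ...)."""
    coll = load_bundled_collection(collection_name)
    return ssgsea_scores(X, coll, alpha=alpha, normalize=normalize)
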