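"""Weighted co-expression network analysis: modules, eigengenes, hub genes.

The network is built from pairwise Pearson correlations raised to a soft
threshold power (unsigned by default: a_ij = |cor|^beta). The topological
overlap TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
l_ij = sum_{u != i,j} a_iu a_uj and connectivity k_i = sum_{j != i} a_ij,
downweights links not supported by shared neighbors. Modules come from
average-linkage clustering of 1 - TOM with a simplified dynamic cut
(static height cut at a deep-split-dependent quantile of the merge
heights, capped at 99% of the dendrogram height, then small-branch rescue
by module membership kME). Each module is summarized by its eigengene
(first principal component of the standardized member expression, sign
fixed so member genes correlate positively on average); modules whose
eigengenes are closer than the merge height are fused. Hub genes are
module members with kME above a threshold and a univariate Cox DFS
p-value below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import median_abs_deviation, pearsonr
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, SurvivalTable
from .screen import cox_univariate

__all__ = [
    "CoexpressionNetwork",
    "ModuleSet",
    "CoexpressionModules",
    "mad_filter",
    "build_network",
    "detect_modules",
    "module_trait_correlation",
    "hub_genes",
]

# Familiar color names assigned by decreasing module size; "grey" is
# reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    signed: bool = False


@dataclass
class ModuleSet:
    assignments: pd.Series            # gene -> module color ("grey" = none)
    eigengenes: pd.DataFrame          # modules x samples, unit-norm rows
    merge_height: float
    min_size: int
    deep_split: int

    @property
    def module_names(self) -> list[str]:
        return list(self.eigengenes.index)

    def members(self, module: str) -> list[str]:
        return list(self.assignments.index[self.assignments == module])

    def sizes(self) -> dict[str, int]:
        return {m: len(self.members(m)) for m in self.module_names}


def _expr_frame(X) -> pd.DataFrame:
    return X.data if isinstance(X, ExpressionMatrix) else X


def mad_filter(X, top_prop: float = 0.5):
    """Keep the genes in the top ``top_prop`` fraction by MAD.

    Genes whose median absolute deviation falls below the (1 - top_prop)
    quantile, or is exactly zero (constant genes), are removed; with
    ``top_prop=1`` the matrix passes through unchanged.
    """
    frame = _expr_frame(X)
    if frame.shape[1] < 2:
        raise ValueError("MAD filter needs at least two samples")
    mads = median_abs_deviation(frame.to_numpy(dtype=float), axis=1)
    if (mads == 0).all():
        raise ValueError("all genes are constant; nothing to rank by MAD")
    if top_prop >= 1.0:
        return X
    thresh = np.quantile(mads, 1.0 - top_prop)
    keep = (mads >= thresh) & (mads > 0)
    out = frame.loc[keep]
    if isinstance(X, ExpressionMatrix):
        return ExpressionMatrix(out.copy(), scale=X.scale)
    return out


def build_network(X, beta: float = 10.0, signed: bool = False) -> CoexpressionNetwork:
    """Adjacency and topological-overlap matrices from expression."""
    frame = _expr_frame(X)
    if frame.shape[0] < 3:
        raise ValueError("network needs at least 3 genes")
    if frame.shape[1] < 4:
        raise ValueError("network needs at least 4 samples")
    vals = frame.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        gene = frame.index[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance gene {gene!r}")
    corr = np.corrcoef(vals)
    if signed:
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    tom = _tom_from_adjacency(a)
    return CoexpressionNetwork(gene_ids=list(frame.index), beta=beta,
                               adjacency=a, tom=tom, signed=signed)


def _tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1."""
    k = a.sum(axis=1) - 1.0
    # l_ij over u != i, j equals (a @ a)_ij - 2 a_ij given unit diagonal
    num = a @ a - a          # = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(frame: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """First principal component across samples of standardized member rows."""
    M = frame.loc[genes].to_numpy(dtype=float)
    M = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    e = vt[0]
    ec = e - e.mean()
    if (M @ ec).mean() < 0:       # sign: member genes correlate positively
        e = -e
    return e / np.linalg.norm(e)


def _kme(frame: pd.DataFrame, genes, eigengene: np.ndarray) -> np.ndarray:
    M = frame.loc[list(genes)].to_numpy(dtype=float)
    Mc = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Mc, axis=1)
    norms = np.where(norms == 0, np.inf, norms)
    ec = eigengene - eigengene.mean()
    en = np.linalg.norm(ec)
    return (Mc @ ec) / (norms * en)


class CoexpressionModules(BaseEstimator):
    """Estimator detecting co-expression modules from an expression matrix.

    Parameters follow the conventional defaults of weighted co-expression
    analysis: soft power ``beta=10``, ``min_size=60``, ``deep_split=4``,
    eigengene ``merge_height=0.25``. ``reassign_kme`` is the minimum module
    membership for rescuing genes from sub-threshold branches.
    """

    def __init__(self, beta: float = 10.0, signed: bool = False,
                 min_size: int = 60, deep_split: int = 4,
                 merge_height: float = 0.25, reassign_kme: float = 0.5):
        self.beta = beta
        self.signed = signed
        self.min_size = min_size
        self.deep_split = deep_split
        self.merge_height = merge_height
        self.reassign_kme = reassign_kme

    def fit(self, X, y=None):
        frame = _expr_frame(X)
        net = build_network(frame, beta=self.beta, signed=self.signed)
        self.network_ = net
        self.modules_ = detect_modules(
            net, frame, min_size=self.min_size, deep_split=self.deep_split,
            merge_height=self.merge_height, reassign_kme=self.reassign_kme,
        )
        return self


def detect_modules(net: CoexpressionNetwork, X, min_size: int = 60,
                   deep_split: int = 4, merge_height: float = 0.25,
                   reassign_kme: float = 0.5) -> ModuleSet:
    """Cut the 1 - TOM dendrogram into modules and merge close eigengenes."""
    frame = _expr_frame(X)
    frame = frame.loc[net.gene_ids]
    d = 1.0 - net.tom
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    q = 0.99 - 0.01 * deep_split
    cut = min(float(np.quantile(heights, q)), 0.99 * float(heights.max()))
    raw = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    seed_ids = [int(c) for c in sizes.index if sizes[c] >= min_size]
    genes = pd.Index(net.gene_ids)
    if not seed_ids:
        warnings.warn(f"no branch reaches min_size={min_size}; all genes "
                      f"unassigned", stacklevel=2)
        assignments = pd.Series("grey", index=genes, name="module")
        eigengenes = pd.DataFrame(columns=frame.columns)
        return ModuleSet(assignments=assignments, eigengenes=eigengenes,
                         merge_height=merge_height, min_size=min_size,
                         deep_split=deep_split)
    membership: dict[int, list[str]] = {
        c: list(genes[raw == c]) for c in seed_ids
    }
    eig = {c: _eigengene(frame, g) for c, g in membership.items()}
    # rescue genes from sub-threshold branches by best kME
    small = genes[~np.isin(raw, seed_ids)]
    if len(small):
        ids = list(membership)
        K = np.stack([_kme(frame, small, eig[c]) for c in ids], axis=1)
        best = np.argmax(K, axis=1)
        for g, j, row in zip(small, best, K):
            if row[j] >= reassign_kme:
                membership[ids[j]].append(g)
        eig = {c: _eigengene(frame, g) for c, g in membership.items()}
    # iterative eigengene merging
    while len(membership) > 1:
        ids = list(membership)
        E = np.stack([eig[c] for c in ids])
        Ec = E - E.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Ec, axis=1)
        R = (Ec @ Ec.T) / np.outer(norms, norms)
        np.fill_diagonal(R, -np.inf)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if 1.0 - R[i, j] >= merge_height:
            break
        a, b = ids[i], ids[j]
        membership[a] = membership[a] + membership[b]
        del membership[b]
        eig[a] = _eigengene(frame, membership[a])
        del eig[b]
    # name modules by size rank
    ordered = sorted(membership, key=lambda c: (-len(membership[c]), c))
    names = {}
    for rank, c in enumerate(ordered):
        names[c] = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                    else f"module{rank + 1}")
    assignments = pd.Series("grey", index=genes, name="module")
    for c, gs in membership.items():
        assignments.loc[gs] = names[c]
    eigengenes = pd.DataFrame(
        {names[c]: eig[c] for c in ordered}, index=frame.columns
    ).T
    return ModuleSet(assignments=assignments, eigengenes=eigengenes,
                     merge_height=merge_height, min_size=min_size,
                     deep_split=deep_split)


def module_trait_correlation(modules: ModuleSet, traits) -> pd.DataFrame:
    """Pearson correlation (+ two-sided p) of eigengenes with traits.

    ``traits`` is a samples x traits DataFrame or a single Series; a
    categorical subtype assignment should be passed as 0/1 indicator
    columns (e.g. ``pd.get_dummies(assign.labels)``).
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = traits.astype(float)
    samples = modules.eigengenes.columns.intersection(traits.index)
    if len(samples) < 3:
        raise ValueError("need at least 3 overlapping samples")
    rows = []
    for mod in modules.module_names:
        e = modules.eigengenes.loc[mod, samples].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits.loc[samples, trait].to_numpy(dtype=float)
            if t.std() == 0:
                raise ValueError(f"constant trait {trait!r}")
            r, p = pearsonr(e, t)
            rows.append({"module": mod, "trait": trait, "r": float(r),
                         "p": float(p)})
    return pd.DataFrame(rows)


def hub_genes(X, modules: ModuleSet, module_id: str, surv: SurvivalTable,
              kme_thresh: float = 0.85, p_thresh: float = 0.05) -> pd.DataFrame:
    """Module members with kME > ``kme_thresh`` and Cox DFS p < ``p_thresh``.

    Returns one row per module gene with its kME, univariate Cox p-value
    on the gene's expression, and the selection flag (both thresholds are
    strict).
    """
    frame = _expr_frame(X)
    members = modules.members(module_id)
    if not members:
        raise ValueError(f"module {module_id!r} is empty or unknown")
    eig = modules.eigengenes.loc[module_id].to_numpy(dtype=float)
    sub = frame.loc[members, modules.eigengenes.columns]
    kmes = _kme(sub, members, eig)
    rows = []
    for gene, kme_val in zip(members, kmes):
        cox_p = np.nan
        try:
            res = cox_univariate(frame.loc[gene], surv)
            cox_p = res.p_value
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"hub-gene Cox fit failed for {gene!r}: {exc}",
                          stacklevel=2)
        selected = bool(kme_val > kme_thresh and cox_p == cox_p
                        and cox_p < p_thresh)
        rows.append({"module": module_id, "gene": gene, "kME": float(kme_val),
                     "cox_p": float(cox_p) if cox_p == cox_p else np.nan,
                     "selected": selected})
    return pd.DataFrame(rows)
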