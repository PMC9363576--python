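"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each statistic from its definition
(explicit loops, grid searches, exhaustive enumeration) so they stay
independent of the vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import imsubtype as ims
from imsubtype.io import filter_expressed_genes, log_transform


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def ssgsea_walk_oracle(expr: pd.Series, set_genes, alpha: float) -> float:
    """Direct O(N * |walk|) double-loop evaluation of the running sum."""
    genes = list(expr.index)
    values = expr.to_numpy(dtype=float)
    ranks = rankdata(values)
    order = np.argsort(-values, kind="stable")
    member = [genes[i] in set(set_genes) for i in order]
    r_ord = ranks[order]
    n = len(genes)
    n_in = sum(member)
    denom = sum(r_ord[i] ** alpha for i in range(n) if member[i])
    es = 0.0
    for i in range(n):
        p_in = sum(r_ord[j] ** alpha for j in range(i + 1) if member[j]) / denom
        p_out = sum(1 for j in range(i + 1) if not member[j]) / (n - n_in)
        es += p_in - p_out
    return es


def breslow_partial_loglik(beta: float, x, time, event) -> float:
    """Hand-coded Breslow partial log-likelihood (explicit risk sets)."""
    ll = 0.0
    n = len(x)
    for i in range(n):
        if event[i]:
            denom = sum(np.exp(beta * x[j]) for j in range(n)
                        if time[j] >= time[i])
            ll += beta * x[i] - np.log(denom)
    return ll


def cox_grid_oracle(x, time, event, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Grid-search maximizer of the Breslow partial likelihood."""
    betas = np.arange(lo, hi + step / 2, step)
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    E = np.exp(np.outer(betas, x))           # n_beta x n
    ll = np.zeros_like(betas)
    for i in range(len(x)):
        if event[i]:
            mask = time >= time[i]
            ll += betas * x[i] - np.log(E[:, mask].sum(axis=1))
    return float(betas[np.argmax(ll)])


def igp_bruteforce(vectors: np.ndarray, labels, metric: str) -> dict:
    """All-pairs nearest-neighbor enumeration."""
    n = len(labels)
    out: dict[str, list[bool]] = {}
    for i in range(n):
        best_j, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            if metric == "euclidean":
                d = float(np.linalg.norm(vectors[i] - vectors[j]))
            else:
                a = vectors[i] - vectors[i].mean()
                b = vectors[j] - vectors[j].mean()
                d = 1.0 - float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
            if d < best_d - 1e-15:
                best_d, best_j = d, j
        out.setdefault(str(labels[i]), []).append(labels[best_j] == labels[i])
    return {lab: (float(np.mean(v)) if len(v) > 1 else 0.0)
            for lab, v in out.items()}


def tom_tripleloop_oracle(a: np.ndarray) -> np.ndarray:
    """Direct triple-loop evaluation of the topological overlap."""
    p = a.shape[0]
    k = a.sum(axis=1) - 1.0
    tom = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(p) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort():
    cfg = ims.SimulationConfig(n_genes=600, n_samples=120, seed=7)
    return ims.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    logged = log_transform(filter_expressed_genes(small_cohort.expression))
    return ims.ssgsea_scores(logged, small_cohort.signature_sets,
                             normalize=True)


def random_expression(rng, n_genes: int, n_samples: int,
                      scale=ims.Scale.LOG2_TPM1) -> ims.ExpressionMatrix:
    vals = rng.uniform(0.0, 12.0, size=(n_genes, n_samples))
    return ims.ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{j}" for j in range(n_samples)]),
        scale=scale,
    )
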