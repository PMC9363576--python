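"""Subtype-level downstream statistics.

Kaplan-Meier curves with the K-group log-rank test, tumor mutational
burden, the per-gene mutation-frequency chi-square screen, nonparametric
expression comparisons (Kruskal-Wallis across subtypes, pairwise Wilcoxon
rank-sum), and categorical associations (Fisher's exact for 2x2 tables,
chi-square otherwise, with a seeded Monte-Carlo option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import SubtypeAssignment
from .io import ExpressionMatrix, MutationTable, NONSILENT_CLASSES, SurvivalTable
from .scoring import SignatureScoreMatrix

__all__ = [
    "KMResult",
    "GroupComparisonResult",
    "MutationScreenRow",
    "CategoricalAssociation",
    "km_logrank",
    "tmb",
    "mutation_frequency_test",
    "compare_across_subtypes",
    "categorical_association",
]


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]   # label -> (time, at_risk, survival)
    statistic: float
    p_value: float
    df: int


@dataclass
class GroupComparisonResult:
    feature_id: str
    kruskal_wallis_p: float
    kruskal_wallis_stat: float
    pairwise: dict[tuple[str, str], float]
    adjusted: bool = False


@dataclass
class MutationScreenRow:
    gene: str
    mutated: dict[str, int]
    totals: dict[str, int]
    chi_square_p: float
    chi_square_stat: float
    passes_min_count: bool


@dataclass
class CategoricalAssociation:
    table: pd.DataFrame
    method: str
    statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)


def km_logrank(surv: SurvivalTable, assign: SubtypeAssignment,
               min_days: float = 30.0) -> KMResult:
    """Product-limit curves per subtype and the K-group log-rank test.

    Samples observed for fewer than ``min_days`` days are excluded before
    estimation, matching the cohort screen.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    common = assign.labels.index.intersection(surv.data.index)
    sub = surv.data.loc[common]
    sub = sub[sub["time_days"] >= min_days]
    labels = assign.labels.loc[sub.index]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least two subtypes")
    res = multivariate_logrank_test(sub["time_days"], labels, sub["event"])
    curves: dict[str, pd.DataFrame] = {}
    for lab in uniq:
        members = labels.index[labels == lab]
        kmf = KaplanMeierFitter().fit(sub.loc[members, "time_days"],
                                      sub.loc[members, "event"])
        tbl = kmf.event_table
        curves[str(lab)] = pd.DataFrame(
            {"time": kmf.survival_function_.index,
             "at_risk": tbl["at_risk"].reindex(
                 kmf.survival_function_.index).to_numpy(),
             "survival": kmf.survival_function_.iloc[:, 0].to_numpy()}
        ).reset_index(drop=True)
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=float(res.p_value), df=len(uniq) - 1)


def tmb(muts: MutationTable, samples: list[str],
        nonsilent_classes=NONSILENT_CLASSES,
        denominator_mb: float | None = None) -> pd.Series:
    """Tumor mutational burden: nonsilent record count per sample.

    Samples absent from the mutation table get 0 (flagged with a warning).
    With ``denominator_mb`` the count becomes mutations per megabase.
    """
    nonsilent = muts.data[muts.data["variant_class"].isin(set(nonsilent_classes))]
    counts = nonsilent.groupby("sample_id").size()
    out = pd.Series(0.0, index=list(samples), name="TMB")
    present = out.index.intersection(counts.index)
    out.loc[present] = counts.loc[present].astype(float)
    absent = [s for s in samples if s not in set(muts.data["sample_id"])]
    if absent:
        warnings.warn(
            f"{len(absent)} sample(s) absent from the mutation table get "
            f"TMB 0: {absent[:5]}{'...' if len(absent) > 5 else ''}",
            stacklevel=2,
        )
    if denominator_mb is not None:
        out = out / float(denominator_mb)
        out.name = "TMB_per_Mb"
    return out


def mutation_frequency_test(muts: MutationTable, assign: SubtypeAssignment,
                            min_count: int = 3) -> list[MutationScreenRow]:
    """Chi-square screen of per-gene mutation frequency across subtypes.

    A gene enters the test when it is mutated in strictly more than
    ``min_count`` samples of at least one subtype; the test is a chi-square
    on the 2 x K mutated/not-mutated table without continuity correction.
    Genes failing the count filter are reported with ``passes_min_count``
    False and no p-value.
    """
    groups = assign.groups()
    if len(groups) < 2:
        raise ValueError("mutation screen needs at least two subtypes")
    totals = {lab: len(m) for lab, m in groups.items()}
    if min(totals.values()) == 0:
        raise ValueError("subtype with zero samples")
    sample_to_label = assign.labels
    muts_in = muts.data[muts.data["sample_id"].isin(sample_to_label.index)]
    rows: list[MutationScreenRow] = []
    labels = list(groups)
    mutated_by_gene = (
        muts_in.drop_duplicates(["gene", "sample_id"])
        .assign(label=lambda d: sample_to_label.loc[d["sample_id"]].to_numpy())
        .groupby(["gene", "label"], sort=False)
        .size()
    )
    for gene in mutated_by_gene.index.get_level_values(0).unique():
        counts = {lab: int(mutated_by_gene.get((gene, lab), 0)) for lab in labels}
        passes = any(c > min_count for c in counts.values())
        if passes:
            table = np.array(
                [[counts[lab] for lab in labels],
                 [totals[lab] - counts[lab] for lab in labels]]
            )
            if (table.sum(axis=1) == 0).any():
                stat, p = np.nan, np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            stat, p = np.nan, np.nan
        rows.append(MutationScreenRow(
            gene=str(gene), mutated=counts, totals=dict(totals),
            chi_square_p=float(p) if p == p else np.nan,
            chi_square_stat=float(stat) if stat == stat else np.nan,
            passes_min_count=passes,
        ))
    return rows


def _feature_values(values, feature: str) -> pd.Series | None:
    if isinstance(values, ExpressionMatrix):
        frame = values.data
    elif isinstance(values, SignatureScoreMatrix):
        frame = values.scores
    else:
        frame = values
    if feature not in frame.index:
        return None
    return frame.loc[feature]


def compare_across_subtypes(values, features: list[str],
                            assign: SubtypeAssignment,
                            adjust: str = "none") -> list[GroupComparisonResult]:
    """Kruskal-Wallis across subtypes plus pairwise Wilcoxon rank-sum tests.

    ``adjust="BH"`` applies Benjamini-Hochberg to the Kruskal-Wallis
    p-values across the requested feature list.
    """
    groups = assign.groups()
    labels = list(groups)
    if any(len(m) < 2 for m in groups.values()):
        raise ValueError("each subtype needs at least two samples")
    results: list[GroupComparisonResult] = []
    for feature in features:
        row = _feature_values(values, feature)
        if row is None:
            warnings.warn(f"feature {feature!r} absent; skipped", stacklevel=2)
            continue
        by_label = {lab: row.loc[[s for s in m if s in row.index]].to_numpy()
                    for lab, m in groups.items()}
        try:
            stat, p = stats.kruskal(*by_label.values())
        except ValueError:       # all values identical
            stat, p = 0.0, 1.0
        if not np.isfinite(p):   # degenerate (zero-variance) input
            stat, p = 0.0, 1.0
        pairwise: dict[tuple[str, str], float] = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                xa, xb = by_label[a], by_label[b]
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    pairwise[(a, b)] = 1.0
                else:
                    pairwise[(a, b)] = float(
                        stats.mannwhitneyu(xa, xb,
                                           alternative="two-sided").pvalue
                    )
        results.append(GroupComparisonResult(
            feature_id=str(feature), kruskal_wallis_p=float(p),
            kruskal_wallis_stat=float(stat), pairwise=pairwise,
        ))
    if adjust == "BH" and results:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.kruskal_wallis_p for r in results],
                            method="fdr_bh")[1]
        for r, p in zip(results, adj):
            r.kruskal_wallis_p = float(p)
            r.adjusted = True
    return results


def categorical_association(factor, assign: SubtypeAssignment,
                            monte_carlo: bool = False,
                            n_permutations: int = 10_000,
                            seed: int | None = None) -> CategoricalAssociation:
    """Association between a categorical factor and the subtype labels.

    2x2 tables use Fisher's exact test; larger tables use the chi-square
    test (no continuity correction) or, with ``monte_carlo=True``, a seeded
    permutation estimate of the exact p-value using the chi-square
    statistic.
    """
    factor = pd.Series(factor)
    common = factor.index.intersection(assign.labels.index)
    factor = factor.loc[common].dropna()
    labels = assign.labels.loc[factor.index]
    flags: list[str] = []
    table = pd.crosstab(factor, labels)
    empty_rows = table.index[(table.sum(axis=1) == 0)]
    if len(empty_rows):
        flags.append(f"dropped empty categories: {list(empty_rows)}")
        warnings.warn(flags[-1], stacklevel=2)
        table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        warnings.warn("degenerate table (constant factor or single subtype); "
                      "p = 1", stacklevel=2)
        return CategoricalAssociation(table=table, method="degenerate",
                                      statistic=0.0, p_value=1.0,
                                      flags=flags + ["degenerate table"])
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table.to_numpy())
        return CategoricalAssociation(table=table, method="fisher_exact",
                                      statistic=np.nan, p_value=float(p),
                                      flags=flags)
    obs_stat, p, _, _ = stats.chi2_contingency(table.to_numpy(),
                                               correction=False)
    if not monte_carlo:
        return CategoricalAssociation(table=table, method="chi_square",
                                      statistic=float(obs_stat),
                                      p_value=float(p), flags=flags)
    rng = np.random.default_rng(seed)
    lab_arr = labels.to_numpy()
    fac_arr = factor.to_numpy()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab_arr)
        t = pd.crosstab(pd.Series(fac_arr), pd.Series(perm)).to_numpy()
        stat, _, _, _ = stats.chi2_contingency(t, correction=False)
        if stat >= obs_stat - 1e-12:
            count += 1
    p_mc = (count + 1) / (n_permutations + 1)
    return CategoricalAssociation(table=table, method="chi_square_monte_carlo",
                                  statistic=float(obs_stat),
                                  p_value=float(p_mc), flags=flags)
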