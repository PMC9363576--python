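"""Univariate Cox screening of signature scores against disease-free survival.

Each signature score is tested one at a time against DFS with a univariate
Cox proportional-hazards model. The partial likelihood uses Breslow tie
handling and is maximized by Newton-Raphson starting from beta = 0; the
reported p-value is the two-sided Wald test. Scores are standardized to
unit variance before fitting so coefficients are comparable across
signatures (the reported beta is per standard deviation of the score).

A cohort screen drops samples observed for fewer than ``min_days`` days,
fits every signature, and selects those with p below the threshold without
multiplicity adjustment; features selected in at least ``min_cohorts``
cohorts survive the cross-cohort overlap filter and become the clustering
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .io import SurvivalTable
from .scoring import SignatureScoreMatrix

__all__ = [
    "CoxResult",
    "ScreenReport",
    "CoxSignatureScreen",
    "cox_univariate",
    "screen_cohort",
    "overlap_filter",
]


@dataclass
class CoxResult:
    feature_id: str
    beta: float
    hr: float
    se: float
    z: float
    p_value: float
    n_used: int
    n_events: int
    standardized: bool = True


@dataclass
class ScreenReport:
    cohort_id: str
    results: list[CoxResult] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": r.feature_id,
                "beta": r.beta,
                "HR": r.hr,
                "se": r.se,
                "z": r.z,
                "p": r.p_value,
                "n": r.n_used,
                "events": r.n_events,
                "selected": r.feature_id in self.selected,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _breslow_loglik_terms(beta: float | np.ndarray, x: np.ndarray,
                          time: np.ndarray, event: np.ndarray):
    """Breslow partial log-likelihood pieces on time-sorted data.

    Returns (loglik, score, information) at scalar ``beta``. Samples must be
    sorted by ascending time; tied event times share the full risk set.
    """
    eta = beta * x
    # numeric guard: center the linear predictor
    c = eta.max()
    e = np.exp(eta - c)
    # suffix cumulative sums; risk set of sample i = all j with t_j >= t_i,
    # shared across ties via searchsorted on the left
    s0 = np.cumsum(e[::-1])[::-1]
    s1 = np.cumsum((x * e)[::-1])[::-1]
    s2 = np.cumsum((x * x * e)[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")
    r0 = s0[first]
    r1 = s1[first]
    r2 = s2[first]
    ev = event.astype(bool)
    ll = float(np.sum(eta[ev] - (np.log(r0[ev]) + c)))
    m1 = r1[ev] / r0[ev]
    score = float(np.sum(x[ev] - m1))
    info = float(np.sum(r2[ev] / r0[ev] - m1 * m1))
    return ll, score, info


def _cox_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 100, tol: float = 1e-9):
    """Newton-Raphson maximization of the Breslow partial likelihood."""
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    beta = 0.0
    ll, score, info = _breslow_loglik_terms(beta, x, time, event)
    for _ in range(max_iter):
        if info <= 0:
            raise RuntimeError("Cox fit failed: non-positive information")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _breslow_loglik_terms(new_beta, x, time, event)
        # step halving if the likelihood decreased
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _breslow_loglik_terms(
                new_beta, x, time, event)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(step) < tol and abs(score) < 1e-6:
            se = 1.0 / np.sqrt(info)
            return beta, se, ll
    raise RuntimeError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(beta={beta:.4g}, score={score:.4g}); the covariate may be "
        f"monotone in survival (infinite MLE)"
    )


def cox_univariate(scores: pd.Series, surv: SurvivalTable,
                   standardize: bool = True) -> CoxResult:
    """Univariate Cox regression of DFS on one per-sample score.

    Samples are intersected by id. Requires at least two events and a
    covariate with nonzero variance.
    """
    common = scores.index.intersection(surv.data.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between scores and survival")
    x = scores.loc[common].to_numpy(dtype=float)
    if np.isnan(x).any():
        keep = ~np.isnan(x)
        common = common[keep]
        x = x[keep]
    time = surv.data.loc[common, "time_days"].to_numpy(dtype=float)
    event = surv.data.loc[common, "event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(
            f"need at least 2 events, got {n_events} "
            f"(feature {scores.name!r})"
        )
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero-variance covariate {scores.name!r}")
    if standardize:
        x = (x - x.mean()) / sd
    beta, se, _ = _cox_newton(x, time, event)
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    return CoxResult(
        feature_id=str(scores.name),
        beta=float(beta),
        hr=float(np.exp(beta)),
        se=float(se),
        z=float(z),
        p_value=float(p),
        n_used=int(len(x)),
        n_events=n_events,
        standardized=standardize,
    )


class CoxSignatureScreen(BaseEstimator):
    """Per-cohort univariate Cox screen over a signature-score matrix.

    Parameters
    ----------
    p_thresh : float, default 0.05
        Selection threshold on the unadjusted Wald p-value.
    min_days : float, default 30
        Samples observed for fewer days are excluded before fitting.
    adjust : {"none", "BH"}, default "none"
        Optional Benjamini-Hochberg correction before thresholding.
    """

    def __init__(self, p_thresh: float = 0.05, min_days: float = 30.0,
                 adjust: str = "none", standardize: bool = True):
        self.p_thresh = p_thresh
        self.min_days = min_days
        self.adjust = adjust
        self.standardize = standardize

    def fit(self, scores, surv: SurvivalTable, cohort_id: str = "cohort"):
        frame = scores.scores if isinstance(scores, SignatureScoreMatrix) else scores
        keep = surv.data.index[surv.data["time_days"] >= self.min_days]
        common = frame.columns.intersection(keep)
        if len(common) == 0:
            raise ValueError(
                f"no overlapping samples between scores and survival for "
                f"cohort {cohort_id!r} after the {self.min_days}-day exclusion"
            )
        surv_used = surv.subset(common)
        results: list[CoxResult] = []
        failed: list[str] = []
        for feature in frame.index:
            row = frame.loc[feature, common]
            try:
                results.append(cox_univariate(row.rename(feature), surv_used,
                                              standardize=self.standardize))
            except (ValueError, RuntimeError) as exc:
                failed.append(f"{feature}: {exc}")
        if failed:
            warnings.warn(
                f"cohort {cohort_id!r}: {len(failed)} feature(s) could not be "
                f"fitted and were skipped: {failed[:3]}",
                stacklevel=2,
            )
        pvals = np.array([r.p_value for r in results])
        if self.adjust == "BH" and len(pvals):
            from statsmodels.stats.multitest import multipletests

            pvals = multipletests(pvals, method="fdr_bh")[1]
        selected = [r.feature_id for r, p in zip(results, pvals)
                    if p < self.p_thresh]
        self.report_ = ScreenReport(cohort_id=cohort_id, results=results,
                                    selected=selected)
        self.selected_ = selected
        return self


def screen_cohort(scores, surv: SurvivalTable, p_thresh: float = 0.05,
                  min_days: float = 30.0, cohort_id: str = "cohort",
                  adjust: str = "none") -> ScreenReport:
    """Functional wrapper over :class:`CoxSignatureScreen`."""
    est = CoxSignatureScreen(p_thresh=p_thresh, min_days=min_days,
                             adjust=adjust)
    est.fit(scores, surv, cohort_id=cohort_id)
    return est.report_


def overlap_filter(reports: list[ScreenReport], min_cohorts: int = 2) -> list[str]:
    """Features selected in at least ``min_cohorts`` cohort screens.

    Output is ordered by descending selection count, then feature name.
    """
    if len(reports) < 2:
        raise ValueError("overlap filter needs at least two cohort reports")
    counts: dict[str, int] = {}
    for rep in reports:
        for feat in set(rep.selected):
            counts[feat] = counts.get(feat, 0) + 1
    chosen = [f for f, c in counts.items() if c >= min_cohorts]
    if not chosen:
        warnings.warn("no feature overlaps across cohorts", stacklevel=2)
    return sorted(chosen, key=lambda f: (-counts[f], f))
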