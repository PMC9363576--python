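"""Synthetic multi-cohort data with planted immune-subtype structure.

A cohort has K latent subtypes. Disjoint signature gene sets receive a
mean log2 shift in their "up" subtype on top of a gene-specific baseline
(log2 means uniform on [2, 8], Gaussian noise), so single-sample
enrichment scores separate the subtypes. Disease-free survival is
exponential with a subtype-specific log hazard ratio and independent
exponential censoring tuned to a target censoring fraction; mutation
counts are Poisson with subtype-specific means. Expression is emitted on
the TPM scale (2^log2 - 1, floored at 0) so the pipeline's own expression
filter and log transform are exercised.

Structure (gene means, signature membership, up-subtype patterns) is
derived from ``SimulationConfig.seed`` alone, so a second cohort drawn
with a different sampling seed shares the same subtype centroids — the
discovery/validation cohort pair of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    Scale,
    SurvivalTable,
    write_expression,
    write_gene_sets,
    write_mutations,
    write_survival,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_pair",
    "simulate_block_expression",
    "write_cohort",
]

LOG_HR_DEFAULT = (float(np.log(2.5)), float(np.log(1.35)), 0.0)
PREVALENCES_DEFAULT = (0.4, 0.2, 0.4)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate a mid-sized discovery cohort: 2,000 genes, 150
    samples, three subtypes at prevalences 0.4/0.2/0.4 separated by a
    1.0 log2 mean shift on six disjoint 25-gene signatures over
    unit-variance noise; exponential DFS with per-subtype hazard ratios
    2.5 / 1.35 / 1 (worst, intermediate, best; baseline rate 1/2000 per
    day), 10% censoring; and subtype-dependent nonsilent mutation burdens
    of 5/10/20 with a 30% silent admixture. ``subtype_prevalences=None``
    means uniform prevalences for any K.
    """

    n_genes: int = 2000
    n_samples: int = 150
    K: int = 3
    n_signatures: int = 6
    genes_per_signature: int = 25
    effect_size: float = 1.0
    noise_sd: float = 1.0
    subtype_prevalences: tuple[float, ...] | None = PREVALENCES_DEFAULT
    hazard_scale: float = 1.0 / 2000.0
    subtype_log_hr: tuple[float, ...] = LOG_HR_DEFAULT
    censor_rate: float = 0.1
    tmb_means: tuple[float, ...] = (5.0, 10.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.n_signatures < self.K:
            raise ValueError("need at least one signature per subtype")
        if self.n_genes < self.n_signatures * self.genes_per_signature:
            raise ValueError("n_genes too small for the signature layout")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.subtype_prevalences == PREVALENCES_DEFAULT and self.K != 3:
            self.subtype_prevalences = None   # study default only fits K=3
        if self.subtype_prevalences is None:
            self.subtype_prevalences = tuple([1.0 / self.K] * self.K)
        if len(self.subtype_prevalences) != self.K:
            raise ValueError("one prevalence per subtype required")
        if abs(sum(self.subtype_prevalences) - 1.0) > 1e-8:
            raise ValueError("prevalences must sum to 1")
        if len(self.subtype_log_hr) != self.K:
            raise ValueError("one log hazard ratio per subtype required")
        if len(self.tmb_means) != self.K:
            raise ValueError("one TMB mean per subtype required")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    survival: SurvivalTable
    mutations: MutationTable
    truth: pd.Series                   # sample -> planted subtype index
    signature_sets: GeneSetCollection
    config: SimulationConfig = field(repr=False, default=None)


def _structure(cfg: SimulationConfig):
    """Gene means, signature membership and up-subtype patterns from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    mu = rng.uniform(2.0, 8.0, size=cfg.n_genes)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sig_sets = {}
    shift = np.zeros((cfg.n_signatures, cfg.K))
    for s in range(cfg.n_signatures):
        lo = s * cfg.genes_per_signature
        sig_sets[f"SIG{s + 1:02d}"] = list(range(lo, lo + cfg.genes_per_signature))
        shift[s, s % cfg.K] = cfg.effect_size
    return mu, gene_ids, sig_sets, shift


def _censor_rate_to_rate(cfg: SimulationConfig, event_rates: np.ndarray) -> float:
    """Censoring rate lambda_c with E[P(censored)] = censor_rate.

    For exponential event rate l and censoring rate c the censoring
    probability is c / (c + l); solve the prevalence-weighted mean.
    """
    if cfg.censor_rate == 0.0:
        return 0.0
    p = np.asarray(cfg.subtype_prevalences)

    def f(c):
        return float(np.sum(p * c / (c + event_rates)) - cfg.censor_rate)

    hi = event_rates.max()
    while f(hi) < 0:
        hi *= 10.0
    return brentq(f, 1e-12 * event_rates.min(), hi)


def simulate_cohort(cfg: SimulationConfig,
                    sampling_seed: int | None = None) -> SyntheticCohort:
    """Draw one cohort; ``sampling_seed`` defaults to ``cfg.seed``.

    The structural quantities (gene means, signatures, shift patterns)
    always come from ``cfg.seed``, so cohorts drawn with different
    sampling seeds share centroids.
    """
    mu, gene_ids, sig_sets, shift = _structure(cfg)
    seed = cfg.seed if sampling_seed is None else sampling_seed
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    sample_ids = [f"S{seed}_{i:04d}" for i in range(n)]
    z = rng.choice(cfg.K, size=n, p=cfg.subtype_prevalences)
    log2x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    for s, genes in enumerate(sig_sets.values()):
        up = shift[s].argmax()
        bump = shift[s, up]
        if bump > 0:
            cols = np.flatnonzero(z == up)
            log2x[np.ix_(genes, cols)] += bump
    tpm = np.maximum(np.power(2.0, log2x) - 1.0, 0.0)
    expression = ExpressionMatrix(
        pd.DataFrame(tpm, index=gene_ids, columns=sample_ids), scale=Scale.TPM
    )

    log_hr = np.asarray(cfg.subtype_log_hr)
    event_rates_by_subtype = cfg.hazard_scale * np.exp(log_hr)
    lam = event_rates_by_subtype[z]
    t_event = rng.exponential(1.0 / lam)
    c_rate = _censor_rate_to_rate(cfg, event_rates_by_subtype)
    if c_rate > 0:
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = SurvivalTable(pd.DataFrame(
        {"time_days": time, "event": event},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    tmb_means = np.asarray(cfg.tmb_means)
    records = []
    classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del"]
    for i, sid in enumerate(sample_ids):
        n_nonsilent = rng.poisson(tmb_means[z[i]])
        n_silent = rng.poisson(0.3 * tmb_means[z[i]])
        genes_hit = rng.choice(cfg.n_genes, size=n_nonsilent + n_silent,
                               replace=True)
        for j, g in enumerate(genes_hit):
            cls = ("Silent" if j >= n_nonsilent
                   else classes[rng.integers(len(classes))])
            records.append((sid, gene_ids[g], cls))
    mutations = MutationTable(pd.DataFrame(
        records, columns=["sample_id", "gene", "variant_class"]
    ))

    truth = pd.Series(z, index=sample_ids, name="subtype_truth")
    collection = GeneSetCollection(
        sets={name: [gene_ids[i] for i in idx]
              for name, idx in sig_sets.items()},
        provenance={name: "planted synthetic signature" for name in sig_sets},
    )
    return SyntheticCohort(expression=expression, survival=survival,
                           mutations=mutations, truth=truth,
                           signature_sets=collection, config=cfg)


def simulate_pair(cfg: SimulationConfig, seed_a: int,
                  seed_b: int) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Discovery/validation cohort pair sharing planted structure."""
    return (simulate_cohort(cfg, sampling_seed=seed_a),
            simulate_cohort(cfg, sampling_seed=seed_b))


def simulate_block_expression(n_blocks: int = 2, block_size: int = 80,
                              n_noise: int = 40, n_samples: int = 100,
                              within_cor: float = 0.8,
                              seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Expression with planted correlated gene blocks for module recovery.

    Block genes share a latent sample factor: x_g = sqrt(rho) * f_b +
    sqrt(1 - rho) * noise, giving within-block correlation ``within_cor``
    and zero between blocks. Returns (genes x samples frame, gene -> block
    truth with -1 for noise genes).
    """
    rng = np.random.default_rng(seed)
    rho = within_cor
    rows = []
    truth = []
    ids = []
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        for g in range(block_size):
            rows.append(np.sqrt(rho) * f +
                        np.sqrt(1 - rho) * rng.normal(size=n_samples))
            truth.append(b)
            ids.append(f"B{b + 1}_{g:03d}")
    for g in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        truth.append(-1)
        ids.append(f"N_{g:03d}")
    frame = pd.DataFrame(np.asarray(rows), index=ids,
                         columns=[f"S{i:03d}" for i in range(n_samples)])
    return frame, pd.Series(truth, index=ids, name="block")


def write_cohort(cohort: SyntheticCohort, outdir, prefix: str = "cohort") -> dict:
    """Write the cohort's standard TSV/GMT files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / f"{prefix}_expression.tsv",
        "survival": outdir / f"{prefix}_survival.tsv",
        "mutations": outdir / f"{prefix}_mutations.tsv",
        "gene_sets": outdir / f"{prefix}_signatures.gmt",
        "truth": outdir / f"{prefix}_truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_survival(cohort.survival, paths["survival"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_gene_sets(cohort.signature_sets, paths["gene_sets"])
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t",
                                   index_label="sample_id")
    return paths
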