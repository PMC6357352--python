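"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants a shared low-dimensional latent state z per sample that
drives both expression and drug response, sparse binary mutations with a few
response-driving genes, and a large corpus plus a small cohort drawn from the
SAME loadings and effects — the transferability the pre-training stage
exploits. Per sample i:

* z_i ~ N(stratum shift, I_k);
* expression e_gi = max(0, a_g . z_i + mu_g + eps_e), with mu_g offset so the
  bulk of entries is positive (log2(TPM+1)-like support);
* mutations m_ji ~ Bernoulli(p1) for driver genes, Bernoulli(p0) otherwise;
* response ic_di = beta_d + s_u * (u_d . z_i) + sum_j gamma_dj m_ji + eps_r,
  with a configurable fraction of entries masked missing at random.

``generate_null_cohort`` zeroes the latent response loadings and the driver
effects, giving responses independent of both omics layers for type-I-error
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort geometry, effect sizes and noise levels.

    Defaults are sized for desk-scale runs: small enough for minute-scale
    training, large enough that the transfer benefit is detectable.
    """

    latent_dim: int = 8
    n_expr_genes: int = 300
    n_mut_genes: int = 200
    n_drugs: int = 30
    n_corpus: int = 2000
    n_cohort: int = 300
    n_drivers: int = 4
    driver_effect: float = 1.0  # gamma, log-IC50 units
    background_mutation_rate: float = 0.05  # p0
    driver_mutation_rate: float = 0.30  # p1
    loading_scale: float = 1.0
    latent_response_scale: float = 1.0  # s_u
    expression_noise_sd: float = 0.5
    response_noise_sd: float = 0.5
    missing_fraction: float = 0.10
    n_strata: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.latent_dim, self.n_expr_genes, self.n_mut_genes, self.n_drugs,
            self.n_corpus, self.n_cohort, self.n_strata,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts must be positive")
        for p in (self.background_mutation_rate, self.driver_mutation_rate):
            if not 0 < p < 1:
                raise ValidationError("mutation probabilities must be in (0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must be in [0, 1)")
        if self.n_drivers > self.n_mut_genes:
            raise ValidationError("more drivers than mutation genes")
        if self.n_drivers < 0:
            raise ValidationError("n_drivers must be >= 0")


@dataclass
class SyntheticTruth:
    """The planted generative state shared by corpus and cohort."""

    expr_loadings: np.ndarray = field(repr=False)  # G_e x k
    expr_offsets: np.ndarray = field(repr=False)  # G_e
    response_loadings: np.ndarray = field(repr=False)  # D x k (already scaled)
    response_baseline: np.ndarray = field(repr=False)  # D
    driver_effects: list[tuple[str, str, float]] = field(default_factory=list)
    stratum_shifts: np.ndarray = field(default=None, repr=False)  # n_strata x k
    gene_ids_expr: list[str] = field(default_factory=list)
    gene_ids_mut: list[str] = field(default_factory=list)
    drug_ids: list[str] = field(default_factory=list)

    @property
    def driver_genes(self) -> list[str]:
        return sorted({g for g, _, _ in self.driver_effects})


@dataclass
class Cohort:
    """One generated cohort plus the truth that produced it."""

    mutation: pd.DataFrame
    expression: pd.DataFrame
    response: pd.DataFrame  # NaN marks masked entries
    annotation: pd.DataFrame
    truth: SyntheticTruth

    def as_tuple(self):
        return (self.mutation, self.expression, self.response, self.annotation, self.truth)


@dataclass
class Study:
    """A corpus (pre-training) and a cohort (supervised) from shared truth."""

    corpus_mutation: pd.DataFrame
    corpus_expression: pd.DataFrame
    corpus_annotation: pd.DataFrame
    cohort: Cohort


def _make_truth(cfg: SyntheticConfig, rng: np.random.Generator) -> SyntheticTruth:
    k = cfg.latent_dim
    A = cfg.loading_scale * rng.standard_normal((cfg.n_expr_genes, k)) / np.sqrt(k)
    row_norm = np.sqrt((A**2).sum(axis=1))
    sigma_tot = np.sqrt(row_norm**2 + cfg.expression_noise_sd**2)
    # offset keeps >= 95% of pre-rectification values positive (2 sd + margin)
    mu = 2.0 * sigma_tot + rng.uniform(0.0, 2.0, size=cfg.n_expr_genes)
    U = cfg.latent_response_scale * rng.standard_normal((cfg.n_drugs, k)) / np.sqrt(k)
    beta = rng.normal(0.0, 1.0, size=cfg.n_drugs)

    gene_ids_mut = [f"mg{j:04d}" for j in range(cfg.n_mut_genes)]
    gene_ids_expr = [f"eg{j:04d}" for j in range(cfg.n_expr_genes)]
    drug_ids = [f"drug{d:03d}" for d in range(cfg.n_drugs)]
    driver_idx = rng.choice(cfg.n_mut_genes, size=cfg.n_drivers, replace=False)
    target_idx = rng.choice(cfg.n_drugs, size=cfg.n_drivers, replace=cfg.n_drivers > cfg.n_drugs)
    driver_effects = [
        (gene_ids_mut[g], drug_ids[d], float(cfg.driver_effect))
        for g, d in zip(driver_idx, target_idx)
    ]
    shifts = rng.normal(0.0, 0.5, size=(cfg.n_strata, k))
    return SyntheticTruth(
        expr_loadings=A,
        expr_offsets=mu,
        response_loadings=U,
        response_baseline=beta,
        driver_effects=driver_effects,
        stratum_shifts=shifts,
        gene_ids_expr=gene_ids_expr,
        gene_ids_mut=gene_ids_mut,
        drug_ids=drug_ids,
    )


def _sample_omics(
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    n: int,
    rng: np.random.Generator,
    prefix: str,
):
    sample_ids = [f"{prefix}{i:05d}" for i in range(n)]
    stratum_idx = rng.integers(cfg.n_strata, size=n)
    z = truth.stratum_shifts[stratum_idx] + rng.standard_normal((n, cfg.latent_dim))

    expr = (
        truth.expr_loadings @ z.T
        + truth.expr_offsets[:, None]
        + cfg.expression_noise_sd * rng.standard_normal((cfg.n_expr_genes, n))
    )
    expr = np.maximum(expr, 0.0)

    probs = np.full(cfg.n_mut_genes, cfg.background_mutation_rate)
    gene_pos = {g: j for j, g in enumerate(truth.gene_ids_mut)}
    for g in truth.driver_genes:
        probs[gene_pos[g]] = cfg.driver_mutation_rate
    mut = (rng.random((cfg.n_mut_genes, n)) < probs[:, None]).astype(np.int8)

    annotation = pd.DataFrame(
        {"stratum": [f"stratum{s}" for s in stratum_idx]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    M = pd.DataFrame(mut, index=truth.gene_ids_mut, columns=sample_ids)
    E = pd.DataFrame(expr, index=truth.gene_ids_expr, columns=sample_ids)
    return M, E, annotation, z


def _sample_response(
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    M: pd.DataFrame,
    z: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = M.shape[1]
    ic = (
        truth.response_baseline[:, None]
        + truth.response_loadings @ z.T
        + cfg.response_noise_sd * rng.standard_normal((cfg.n_drugs, n))
    )
    gene_pos = {g: j for j, g in enumerate(truth.gene_ids_mut)}
    drug_pos = {d: j for j, d in enumerate(truth.drug_ids)}
    mut = M.to_numpy()
    for gene, drug, gamma in truth.driver_effects:
        ic[drug_pos[drug]] += gamma * mut[gene_pos[gene]]
    if cfg.missing_fraction > 0:
        mask = rng.random(ic.shape) < cfg.missing_fraction
        for d in np.flatnonzero(mask.all(axis=1)):  # keep every drug observable
            mask[d, rng.integers(n)] = False
        ic = np.where(mask, np.nan, ic)
    return pd.DataFrame(ic, index=truth.drug_ids, columns=M.columns)


def generate_study(cfg: SyntheticConfig) -> Study:
    """Generate a corpus and a cohort from shared loadings and effects.

    Deterministic given ``cfg.seed``; the cohort is bit-identical to the one
    :func:`generate_cohort` returns for the same config.
    """
    ss = np.random.SeedSequence(cfg.seed)
    truth_rng, corpus_rng, cohort_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = _make_truth(cfg, truth_rng)
    cM, cE, cAnn, _ = _sample_omics(cfg, truth, cfg.n_corpus, corpus_rng, prefix="t")
    M, E, ann, z = _sample_omics(cfg, truth, cfg.n_cohort, cohort_rng, prefix="c")
    IC = _sample_response(cfg, truth, M, z, cohort_rng)
    return Study(
        corpus_mutation=cM,
        corpus_expression=cE,
        corpus_annotation=cAnn,
        cohort=Cohort(mutation=M, expression=E, response=IC, annotation=ann, truth=truth),
    )


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate one cohort (mutation, expression, response, annotation, truth)."""
    ss = np.random.SeedSequence(cfg.seed)
    truth_rng, _, cohort_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = _make_truth(cfg, truth_rng)
    M, E, ann, z = _sample_omics(cfg, truth, cfg.n_cohort, cohort_rng, prefix="c")
    IC = _sample_response(cfg, truth, M, z, cohort_rng)
    return Cohort(mutation=M, expression=E, response=IC, annotation=ann, truth=truth)


def generate_null_cohort(cfg: SyntheticConfig) -> Cohort:
    """Cohort with all driver effects and latent response loadings zeroed.

    Responses are then independent of mutations and expression; used for
    type-I-error calibration of the association scan.
    """
    null_cfg = replace(cfg, driver_effect=0.0, latent_response_scale=0.0)
    return generate_cohort(null_cfg)
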