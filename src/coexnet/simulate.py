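"""Synthetic tumor cohorts with planted ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, so the full analysis runs end-to-end with no downloads:

* expression follows a nested factor model: genes in a parent module
  share a parent latent factor, genes in a child module additionally
  share a child factor, plus iid Gaussian noise on the log2 scale.
  Loadings are solved in closed form from the target within-block
  correlations (r = explained variance fraction of the shared factors),
  so realized mean within-parent and within-child Pearson correlations
  hit their targets;
* survival times are exponential with hazard h0 * exp(beta * z), where
  z is the standardized latent factor of a designated driver module;
  censoring is independent exponential with its rate solved numerically
  to hit the target censoring fraction;
* a designated driver gene carries nonsynonymous mutations in a random
  sample fraction, and carriers receive a planted log2 shift on a set
  of target genes;
* cis methylation probes are logistic squashes of Gaussians
  anticorrelated with their gene's expression — Spearman correlation is
  invariant to the monotone squash, so the planted rank correlation
  survives (the latent Pearson correlation is set via
  r = 2 sin(pi * rho_s / 6));
* per-gene batch shifts are added and recorded in the covariate table.

Everything is drawn from a single seeded generator; the truth manifest
maps every planted structure to its gene/sample ids and parameters and
is sufficient to score every recovery experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalTable, ValidationError
from .preprocess import CovariateTable
from .signatures import MethylationMatrix, MutationMatrix


@dataclass
class ModuleSpec:
    parent_size: int
    child_sizes: tuple[int, ...]
    r_parent: float
    r_child: float

    def __post_init__(self) -> None:
        if sum(self.child_sizes) > self.parent_size:
            raise ValidationError("child sizes must sum to <= parent size")
        if not (0 < self.r_parent < 1 and 0 < self.r_child < 1):
            raise ValidationError("correlation targets must lie in (0, 1)")
        if self.r_child <= self.r_parent:
            raise ValidationError("child correlation must exceed parent correlation")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort (desk-scale defaults)."""

    n_genes: int = 800
    n_samples: int = 250
    modules: tuple[ModuleSpec, ...] = tuple(
        ModuleSpec(80, (40, 40), 0.35, 0.65) for _ in range(4))
    driver_module: str = "P1.C1"      # survival driver (module id in the truth)
    cox_beta: float = 1.0
    baseline_hazard: float = 0.002    # events per day
    censoring_rate: float = 0.3
    mutated_fraction: float = 0.3
    n_mutation_targets: int = 40
    mutation_log2_effect: float = 1.0
    n_cis_probes: int = 30
    cis_rho: float = -0.7             # Spearman target, methylation vs expression
    n_null_probes: int = 50
    n_batches: int = 2
    batch_shift_sd: float = 0.3
    noise_sd: float = 1.0
    base_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.parent_size for m in self.modules) > self.n_genes:
            raise ValidationError("module genes exceed n_genes")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if not 0 < self.mutated_fraction < 1:
            raise ValidationError("mutated_fraction must lie in (0, 1)")
        if not -1 < self.cis_rho < 1 or self.cis_rho == 0:
            raise ValidationError("cis_rho must be nonzero in (-1, 1)")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix          # raw RPKM-like scale
    survival: SurvivalTable
    mutations: MutationMatrix
    methylation: MethylationMatrix
    covariates: CovariateTable
    truth: dict = field(default_factory=dict)

    @property
    def logged(self) -> np.ndarray:
        return np.log2(self.expression.values + 1.0)


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate one cohort; byte-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]

    assignment, loadings, gene_scale = _plan_modules(cfg)
    logged, factors = _draw_expression(cfg, assignment, loadings, gene_scale, rng)

    # mutation driver and planted shift (applied on the log2 scale)
    module_genes = {g for gs in assignment.values() for g in gs}
    background = [g for g in genes if g not in module_genes]
    driver_gene = background[0]
    candidates = background[1:]
    target_genes = sorted(
        np.asarray(candidates, dtype=object)[
            rng.choice(len(candidates), size=cfg.n_mutation_targets, replace=False)])
    carriers = np.zeros(cfg.n_samples, dtype=int)
    carriers[rng.choice(cfg.n_samples, size=max(3, int(round(
        cfg.mutated_fraction * cfg.n_samples))), replace=False)] = 1
    gidx = {g: i for i, g in enumerate(genes)}
    for g in target_genes:
        logged[gidx[g], carriers == 1] += cfg.mutation_log2_effect

    # batch shifts, recorded in covariates
    batch = rng.integers(cfg.n_batches, size=cfg.n_samples)
    shifts = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, cfg.n_batches))
    logged = logged + shifts[:, batch]
    age = np.round(rng.normal(60.0, 10.0, size=cfg.n_samples), 1)

    # survival driven by the driver module's latent factor
    z = factors[cfg.driver_module]
    z = (z - z.mean()) / z.std()
    hazard = cfg.baseline_hazard * np.exp(cfg.cox_beta * z)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_rate = _solve_censor_rate(hazard, 1.0 - cfg.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=cfg.n_samples)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(cfg.n_samples, dtype=int)
    time = np.maximum(time, 1e-3)

    # methylation: cis probes anticorrelated with module genes, plus null probes
    module_gene_list = sorted(module_genes)
    cis_genes = sorted(np.asarray(module_gene_list, dtype=object)[
        rng.choice(len(module_gene_list), size=cfg.n_cis_probes, replace=False)])
    r_latent = 2.0 * np.sin(np.pi * abs(cfg.cis_rho) / 6.0) * np.sign(cfg.cis_rho)
    probes, annotation, beta_rows = [], {}, []
    for i, g in enumerate(cis_genes):
        pid = f"Pr{i:03d}"
        gz = logged[gidx[g]]
        gz = (gz - gz.mean()) / gz.std()
        latent = r_latent * gz + np.sqrt(1 - r_latent ** 2) * rng.standard_normal(cfg.n_samples)
        probes.append(pid)
        annotation[pid] = g
        beta_rows.append(1.0 / (1.0 + np.exp(-latent)))
    for i in range(cfg.n_null_probes):
        pid = f"Pr{cfg.n_cis_probes + i:03d}"
        probes.append(pid)
        beta_rows.append(1.0 / (1.0 + np.exp(-rng.standard_normal(cfg.n_samples))))

    raw = np.maximum(np.exp2(logged) - 1.0, 0.0)
    mut_values = carriers[None, :]
    truth = {
        "config": _config_dict(cfg),
        "modules": {mid: sorted(gs) for mid, gs in assignment.items()},
        "loadings": {mid: list(map(float, lam)) for mid, lam in loadings.items()},
        "gene_scale": gene_scale,
        "driver_module": cfg.driver_module,
        "cox_beta": cfg.cox_beta,
        "mutation": {"driver_gene": driver_gene,
                     "carriers": [s for s, c in zip(samples, carriers) if c],
                     "targets": list(target_genes),
                     "log2_effect": cfg.mutation_log2_effect},
        "methylation": {"cis": {p: {"gene": g, "rho": cfg.cis_rho}
                                for p, g in annotation.items()}},
        "batch": {"labels": [int(b) for b in batch]},
    }
    return SyntheticCohort(
        expression=ExpressionMatrix(genes, samples, raw, "raw"),
        survival=SurvivalTable(samples, time, event),
        mutations=MutationMatrix([driver_gene], samples, mut_values),
        methylation=MethylationMatrix(probes, samples, np.array(beta_rows), annotation),
        covariates=CovariateTable(samples, pd.DataFrame(
            {"batch": pd.Series(batch).map(lambda b: f"B{b}"), "age": age})),
        truth=truth,
    )


def simulate_replicate_cohort(base: SyntheticCohort, n_samples: int, seed: int,
                              reshuffle_loadings: bool = False) -> SyntheticCohort:
    """An independent cohort from the same generative parameters.

    Fresh samples, factors and noise with the same gene-to-module
    assignment and loadings, so module structure is preserved; with
    ``reshuffle_loadings`` the gene-to-module assignment is randomly
    permuted over all genes, destroying the planted structure (a
    negative control).
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be positive")
    if "config" not in base.truth:
        raise ValidationError("base cohort lacks a truth manifest")
    cfg = _config_from_dict(base.truth["config"])
    cfg = SimConfig(**{**cfg.__dict__, "n_samples": n_samples, "seed": seed,
                       "modules": cfg.modules})
    rng = np.random.default_rng(seed)
    assignment = {mid: list(gs) for mid, gs in base.truth["modules"].items()}
    gene_scale = dict(base.truth["gene_scale"])
    if reshuffle_loadings:
        genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
        perm = rng.permutation(cfg.n_genes)
        remap = {genes[i]: genes[perm[i]] for i in range(cfg.n_genes)}
        assignment = {mid: [remap[g] for g in gs] for mid, gs in assignment.items()}
        gene_scale = {remap[g]: u for g, u in gene_scale.items()}
    loadings = {mid: tuple(lam) for mid, lam in base.truth["loadings"].items()}
    logged, _ = _draw_expression(cfg, assignment, loadings, gene_scale, rng)
    samples = [f"R{j:03d}" for j in range(n_samples)]
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    raw = np.maximum(np.exp2(logged) - 1.0, 0.0)
    truth = dict(base.truth)
    truth["modules"] = {mid: sorted(gs) for mid, gs in assignment.items()}
    truth["replicate_of_seed"] = base.truth["config"]["seed"]
    dummy_surv = SurvivalTable(samples, np.ones(n_samples), np.ones(n_samples, int))
    return SyntheticCohort(
        expression=ExpressionMatrix(genes, samples, raw, "raw"),
        survival=dummy_surv,
        mutations=MutationMatrix(["none"], samples, np.zeros((1, n_samples), int)),
        methylation=MethylationMatrix([], samples, np.empty((0, n_samples)), {}),
        covariates=CovariateTable(samples, pd.DataFrame({"age": np.full(n_samples, 60.0)})),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write all component tables plus truth.json into a directory."""
    from pathlib import Path

    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_expression_matrix(cohort.expression, out / "expression.tsv")
    cio.write_survival_table(cohort.survival, out / "clinical.tsv")
    cio.write_table(pd.DataFrame(cohort.mutations.values,
                                 index=cohort.mutations.gene_ids,
                                 columns=cohort.mutations.sample_ids)
                    .reset_index(names="gene_id"), out / "mutations.tsv")
    meth = pd.DataFrame(cohort.methylation.values, index=cohort.methylation.probe_ids,
                        columns=cohort.methylation.sample_ids).reset_index(names="probe_id")
    cio.write_table(meth, out / "methylation.tsv")
    ann = pd.DataFrame(sorted(cohort.methylation.annotation.items()),
                       columns=["probe_id", "gene_id"])
    cio.write_table(ann, out / "probe_annotation.tsv")
    cov = cohort.covariates.covariates.copy()
    cov.insert(0, "sample_id", cohort.covariates.sample_ids)
    cio.write_table(cov, out / "covariates.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------


def _plan_modules(cfg: SimConfig):
    """Assign genes to parent/child modules and solve factor loadings.

    With total variance T = sigma^2 / (1 - r_child), the parent loading
    lambda_p = sqrt(r_parent * T) and the child loading
    lambda_c = sqrt((r_child - r_parent) * T) give within-child
    correlation r_child and within-parent (cross-child) correlation
    r_parent. Each module gene additionally carries a fixed loading
    multiplier (uniform 0.8-1.2, part of the gene's identity, so it is
    shared by replicate cohorts): genes with larger multipliers become
    the module's highly connected hub genes, giving the heterogeneous
    intramodular connectivity that preservation statistics compare.
    """
    assignment: dict[str, list[str]] = {}
    loadings: dict[str, tuple[float, float]] = {}
    cursor = 0
    for pi, spec in enumerate(cfg.modules, start=1):
        sigma2 = cfg.noise_sd ** 2
        total = sigma2 / (1.0 - spec.r_child)
        lam_p = float(np.sqrt(spec.r_parent * total))
        lam_c = float(np.sqrt((spec.r_child - spec.r_parent) * total))
        pid = f"P{pi}"
        parent_genes = [f"G{i:04d}" for i in range(cursor, cursor + spec.parent_size)]
        assignment[pid] = parent_genes
        loadings[pid] = (lam_p, lam_c)
        offset = 0
        for ci, size in enumerate(spec.child_sizes, start=1):
            assignment[f"{pid}.C{ci}"] = parent_genes[offset:offset + size]
            loadings[f"{pid}.C{ci}"] = (lam_p, lam_c)
            offset += size
        cursor += spec.parent_size
    scale_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    module_genes = sorted({g for gs in assignment.values() for g in gs})
    gene_scale = {g: float(scale_rng.uniform(0.8, 1.2)) for g in module_genes}
    return assignment, loadings, gene_scale


def _draw_expression(cfg: SimConfig, assignment, loadings, gene_scale, rng):
    """Draw the logged expression matrix and latent factors."""
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gidx = {g: i for i, g in enumerate(genes)}
    sigma2 = cfg.noise_sd ** 2
    r_child_default = max((m.r_child for m in cfg.modules), default=0.5)
    total_sd = float(np.sqrt(sigma2 / (1.0 - r_child_default)))
    logged = cfg.base_mean + total_sd * rng.standard_normal((cfg.n_genes, cfg.n_samples))

    factors: dict[str, np.ndarray] = {}
    parents = [mid for mid in assignment if "." not in mid]
    for pid in parents:
        factors[pid] = rng.standard_normal(cfg.n_samples)
    children = [mid for mid in assignment if "." in mid]
    for mid in children:
        factors[mid] = rng.standard_normal(cfg.n_samples)

    covered: set[str] = set()
    for mid in children:
        pid = mid.split(".")[0]
        lam_p, lam_c = loadings[mid]
        noise_sd = cfg.noise_sd
        for g in assignment[mid]:
            i = gidx[g]
            u = gene_scale.get(g, 1.0)
            logged[i] = (cfg.base_mean + u * lam_p * factors[pid]
                         + u * lam_c * factors[mid]
                         + noise_sd * rng.standard_normal(cfg.n_samples))
            covered.add(g)
    # parent genes outside any child share only the parent factor
    for pid in parents:
        lam_p, lam_c = loadings[pid]
        resid = float(np.sqrt(lam_c ** 2 + cfg.noise_sd ** 2))
        for g in assignment[pid]:
            if g in covered:
                continue
            i = gidx[g]
            logged[i] = (cfg.base_mean + gene_scale.get(g, 1.0) * lam_p * factors[pid]
                         + resid * rng.standard_normal(cfg.n_samples))
    return logged, factors


def _solve_censor_rate(hazard: np.ndarray, target_event_rate: float) -> float:
    """Censoring rate c with mean_i h_i / (h_i + c) = target event rate."""
    lo, hi = 1e-12, float(hazard.max()) * 1e6

    def event_rate(c: float) -> float:
        return float(np.mean(hazard / (hazard + c)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if event_rate(mid) > target_event_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _config_dict(cfg: SimConfig) -> dict:
    d = dict(cfg.__dict__)
    d["modules"] = [[m.parent_size, list(m.child_sizes), m.r_parent, m.r_child]
                    for m in cfg.modules]
    return d


def _config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["modules"] = tuple(ModuleSpec(ps, tuple(cs), rp, rc)
                         for ps, cs, rp, rc in d["modules"])
    return SimConfig(**d)
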