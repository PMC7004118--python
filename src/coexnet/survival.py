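"""Module eigen-genes and survival-based module prioritization.

A module's eigen-gene is the per-sample score vector of the first
principal component of its standardized gene-expression block, with the
sign fixed so that the eigen-gene correlates nonnegatively with the
module's mean expression profile.

Each module is tested for survival association two ways: a univariate
Cox proportional-hazards fit of the eigen-gene (Newton-Raphson on the
partial likelihood with Efron tie handling, Wald p), and a logrank test
after splitting patients at the median eigen-gene value (ties at the
median go to the low group). The module prognostic score is

    MS_m = sum_t -log10(p_t)

over the configured family of tests; modules are ranked by MS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ModuleHierarchy, SurvivalTable, ValidationError

logger = logging.getLogger("coexnet")


@dataclass
class EigenGene:
    module_id: str
    sample_ids: list[str]
    values: np.ndarray
    explained_variance_ratio: float
    sign_convention: str = "positive correlation with module mean profile"


@dataclass
class SurvivalTestResult:
    module_id: str
    test_id: str
    statistic: float
    p_value: float
    hazard_ratio: float | None
    n_samples: int
    n_events: int
    flagged: bool = False
    note: str = ""


@dataclass
class ModuleScore:
    module_id: str
    ms: float
    p_values: dict[str, float] = field(default_factory=dict)


def compute_eigengene(x: ExpressionMatrix, module_genes, module_id: str = "") -> EigenGene:
    """First right singular vector of the standardized gene x sample block."""
    sub = x.subset_genes(sorted(module_genes))
    if sub.n_genes < 3:
        raise ValidationError(
            f"module {module_id or '<anon>'}: fewer than 3 module genes in matrix")
    v = sub.values
    sd = v.std(axis=1)
    keep = sd > 1e-12
    if keep.sum() < 3:
        raise ValidationError(f"module {module_id}: fewer than 3 non-constant genes")
    z = (v[keep] - v[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    evr = float(s[0] ** 2 / (s ** 2).sum())
    return EigenGene(module_id, list(sub.sample_ids), scores, evr)


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, Efron ties)


def cox_univariate(z: np.ndarray | EigenGene, s: SurvivalTable,
                   module_id: str = "", test_id: str = "cox",
                   tol: float = 1e-8, max_iter: int = 50) -> SurvivalTestResult:
    """Univariate Cox PH by Newton-Raphson with Efron tie handling.

    Reports beta (as ``statistic``), HR = exp(beta) and the two-sided
    Wald p. On monotone likelihood (perfect separation) the result is
    flagged and the p-value falls back to the likelihood-ratio test.
    """
    cov, surv = _align(z, s)
    if surv.n_events < 2:
        raise ValidationError("Cox fit requires >= 2 events")
    if cov.std() <= 1e-12:
        raise ValidationError("zero-variance covariate in Cox fit")
    scale = cov.std()
    zz = (cov - cov.mean()) / scale  # standardized internally for stable Newton steps

    order = np.argsort(-surv.time, kind="stable")
    t_sorted = surv.time[order]
    z_sorted = zz[order]
    e_sorted = surv.event[order].astype(bool)

    # group boundaries of tied times (descending), and per-event Efron fractions
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    ends = np.r_[starts[1:], len(t_sorted)]
    d_per_group = np.add.reduceat(e_sorted.astype(int), starts)
    ev_groups = np.flatnonzero(d_per_group > 0)
    group_of_event, frac = [], []
    for g in ev_groups:
        d = d_per_group[g]
        group_of_event += [g] * d
        frac += [l / d for l in range(d)]
    group_of_event = np.asarray(group_of_event)
    frac = np.asarray(frac)
    sum_z_events = float(z_sorted[e_sorted].sum())

    def loglik_grad_hess(beta: float):
        ebz = np.exp(beta * z_sorted)
        c0 = np.cumsum(ebz)
        c1 = np.cumsum(z_sorted * ebz)
        c2 = np.cumsum(z_sorted ** 2 * ebz)
        S0 = c0[ends - 1]
        S1 = c1[ends - 1]
        S2 = c2[ends - 1]
        ev = e_sorted.astype(float)
        s0 = np.add.reduceat(ev * ebz, starts)
        s1 = np.add.reduceat(ev * z_sorted * ebz, starts)
        s2 = np.add.reduceat(ev * z_sorted ** 2 * ebz, starts)
        D = S0[group_of_event] - frac * s0[group_of_event]
        R1 = (S1[group_of_event] - frac * s1[group_of_event]) / D
        R2 = (S2[group_of_event] - frac * s2[group_of_event]) / D
        ll = beta * sum_z_events - float(np.log(D).sum())
        grad = sum_z_events - float(R1.sum())
        hess = -float((R2 - R1 ** 2).sum())
        return ll, grad, hess

    beta = 0.0
    ll, grad, hess = loglik_grad_hess(beta)
    ll0 = ll
    converged = False
    for _ in range(max_iter):
        if hess >= -1e-300:
            break
        step = -grad / hess
        step = float(np.clip(step, -2.0, 2.0))
        new_beta = beta + step
        new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
            halvings += 1
        if abs(new_beta - beta) < tol:
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            converged = True
            break
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess

    flagged = (not converged) or abs(beta) > 12.0
    beta_raw = beta / scale
    if not flagged and hess < 0:
        se = math.sqrt(-1.0 / hess) / scale
        wald = beta_raw / se
        p = 2.0 * stats.norm.sf(abs(wald))
        note = ""
    else:
        lr = max(0.0, 2.0 * (ll - ll0))
        p = float(stats.chi2.sf(lr, df=1))
        note = "monotone likelihood or non-convergence; likelihood-ratio p reported"
        logger.warning("Cox fit for %s: %s", module_id or test_id, note)
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return SurvivalTestResult(module_id, test_id, float(beta_raw), p,
                              float(np.exp(np.clip(beta_raw, -700, 700))),
                              len(surv), surv.n_events, flagged, note)


# ---------------------------------------------------------------------------
# logrank on the median split of the eigen-gene


def logrank_median_split(z: np.ndarray | EigenGene, s: SurvivalTable,
                         module_id: str = "", test_id: str = "logrank") -> SurvivalTestResult:
    """Two-group logrank chi-square after a median split of the covariate.

    Samples exactly at the median are assigned to the low group.
    """
    cov, surv = _align(z, s)
    median = np.median(cov)
    high = cov > median
    if high.all() or (~high).all():
        raise ValidationError("median split produced an empty group")
    stat, p = logrank_test(surv.time, surv.event, high.astype(int))
    return SurvivalTestResult(module_id, test_id, float(stat), float(p), None,
                              len(surv), surv.n_events)


def logrank_test(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Standard two-group logrank chi-square (1 df) and p-value."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    if event.sum() == 0:
        raise ValidationError("logrank test requires at least one event")
    o1 = e1 = var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# module score and ranking


def module_score(p_values, module_id: str = "") -> ModuleScore:
    """MS = sum over tests of -log10(p)."""
    if isinstance(p_values, dict):
        items = dict(p_values)
    else:
        items = {f"t{i}": p for i, p in enumerate(p_values)}
    for tid, p in items.items():
        if not 0 < p <= 1:
            raise ValidationError(f"p-value {p} for test {tid!r} outside (0, 1]")
    ms = float(sum(-math.log10(p) for p in items.values()))
    return ModuleScore(module_id, ms, items)


def rank_modules(h: ModuleHierarchy, x: ExpressionMatrix, surv: SurvivalTable,
                 strata_spec: list[dict] | None = None,
                 tests: tuple[str, ...] = ("cox", "logrank"),
                 alpha: float | None = None,
                 min_events: int = 2) -> pd.DataFrame:
    """Score every non-root module by MS and rank.

    ``strata_spec`` lists patient strata, each a dict with ``name`` and
    optionally ``column``/``value`` selecting rows of the survival
    table's strata columns; default is the whole cohort. Each stratum
    contributes one Cox and/or one logrank p per module. Strata with
    fewer than ``min_events`` events are skipped with a log entry.
    Output is sorted by MS descending, ties by module size descending
    then module id.
    """
    if strata_spec is None:
        strata_spec = [{"name": "all"}]
    pool = h.non_root(alpha)
    rows = []
    for m in pool:
        present = m.genes & set(x.gene_ids)
        if len(present) < 3:
            logger.info("module %s skipped: <3 genes in expression matrix", m.module_id)
            continue
        eg = compute_eigengene(x, present, m.module_id)
        pvals: dict[str, float] = {}
        for spec in strata_spec:
            sub_surv = _select_stratum(surv, spec)
            shared = [sid for sid in eg.sample_ids if sid in set(sub_surv.sample_ids)]
            if len(shared) < 3:
                continue
            sub_surv = sub_surv.subset(shared)
            cov = np.array([eg.values[eg.sample_ids.index(sid)] for sid in shared])
            if sub_surv.n_events < min_events:
                logger.info("module %s stratum %s skipped: <%d events",
                            m.module_id, spec["name"], min_events)
                continue
            for test in tests:
                tid = f"{spec['name']}:{test}"
                try:
                    if test == "cox":
                        res = cox_univariate(cov, sub_surv, m.module_id, tid)
                    elif test == "logrank":
                        res = logrank_median_split(cov, sub_surv, m.module_id, tid)
                    else:
                        raise ValidationError(f"unknown test {test!r}")
                except ValidationError as exc:
                    logger.info("module %s test %s skipped: %s", m.module_id, tid, exc)
                    continue
                pvals[tid] = res.p_value
        score = module_score(pvals, m.module_id) if pvals else ModuleScore(m.module_id, 0.0, {})
        rows.append({
            "module_id": m.module_id,
            "alpha": m.alpha,
            "size": m.size,
            "MS": score.ms,
            "n_tests": len(score.p_values),
            "p_values": ";".join(f"{k}={v:.6g}" for k, v in sorted(score.p_values.items())),
        })
    df = pd.DataFrame(rows, columns=["module_id", "alpha", "size", "MS", "n_tests", "p_values"])
    if len(df):
        df = df.sort_values(["MS", "size", "module_id"],
                            ascending=[False, False, True], kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df["rank"] = []
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------


def _align(z, s: SurvivalTable) -> tuple[np.ndarray, SurvivalTable]:
    """Align a covariate (array over s's samples, or EigenGene) with s."""
    if isinstance(z, EigenGene):
        shared = [sid for sid in z.sample_ids if sid in set(s.sample_ids)]
        if not shared:
            raise ValidationError("no shared samples between eigen-gene and survival table")
        cov = np.array([z.values[z.sample_ids.index(sid)] for sid in shared])
        return cov, s.subset(shared)
    cov = np.asarray(z, dtype=float)
    if len(cov) != len(s):
        raise ValidationError("covariate length does not match survival table")
    return cov, s


def _select_stratum(surv: SurvivalTable, spec: dict) -> SurvivalTable:
    if "column" not in spec or spec.get("column") is None:
        return surv
    if surv.strata is None or spec["column"] not in surv.strata.columns:
        raise ValidationError(f"stratum column {spec['column']!r} not in survival table")
    mask = (surv.strata[spec["column"]] == spec["value"]).to_numpy()
    keep = [sid for sid, m in zip(surv.sample_ids, mask) if m]
    return surv.subset(keep)
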