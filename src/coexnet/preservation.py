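"""Cross-cohort module preservation and module overlap.

A module discovered in a reference cohort is preserved in a test cohort
when its coexpression structure recurs there. Two statistics are
computed per module:

* density: mean absolute pairwise correlation among the module's genes
  in the test cohort;
* connectivity: Spearman correlation between the genes' intramodular
  connectivities (row sums of absolute within-module correlation) in the
  reference vs the test cohort.

Both are z-scored against ``n_perm`` random gene sets of the same size
drawn from the genes shared by the two cohorts; the summary statistic is
the mean of the two z-scores (the median of two values). A permutation
p-value with pseudo-count accompanies the z-scores, and a module is
called preserved when z_summary >= z_cut and perm_p < p_cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ModuleHierarchy, ValidationError

logger = logging.getLogger("coexnet")


@dataclass
class PreservationResult:
    module_id: str
    z_density: float
    z_connectivity: float
    z_summary: float
    perm_p: float
    preserved: bool
    n_perm: int
    n_genes_tested: int
    flagged: bool = False


def preservation_stats(h: ModuleHierarchy, ref: ExpressionMatrix, test: ExpressionMatrix,
                       n_perm: int = 100, seed: int = 0, z_cut: float = 2.0,
                       p_cut: float = 0.05, alpha: float | None = None,
                       min_genes: int = 5) -> pd.DataFrame:
    """Preservation z-statistics for every non-root module of ``h``.

    Modules with < ``min_genes`` genes in the test cohort are skipped;
    modules with < 50% of their genes shared are flagged.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    shared = sorted(set(ref.gene_ids) & set(test.gene_ids))
    if len(shared) < min_genes:
        raise ValidationError("cohorts share too few genes")
    ref_s = ref.subset_genes(shared)
    test_s = test.subset_genes(shared)
    ref_z = _standardize(ref_s.values)
    test_z = _standardize(test_s.values)
    gene_pos = {g: i for i, g in enumerate(ref_s.gene_ids)}
    rng = np.random.default_rng(seed)

    rows = []
    for m in h.non_root(alpha):
        genes = sorted(m.genes & set(gene_pos))
        if len(genes) < min_genes:
            logger.info("module %s skipped in preservation: %d shared genes",
                        m.module_id, len(genes))
            continue
        flagged = len(genes) < 0.5 * m.size
        idx = np.array([gene_pos[g] for g in genes])
        obs_d, obs_c = _module_stats(idx, ref_z, test_z)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            ridx = rng.choice(len(gene_pos), size=len(idx), replace=False)
            null_d[b], null_c[b] = _module_stats(ridx, ref_z, test_z)
        zd = _zscore(obs_d, null_d)
        zc = _zscore(obs_c, null_c)
        z_summary = 0.5 * (zd + zc)
        null_summary = 0.5 * (_zvec(null_d) + _zvec(null_c))
        perm_p = (1.0 + np.sum(null_summary >= z_summary)) / (n_perm + 1.0)
        preserved = bool(z_summary >= z_cut and perm_p < p_cut)
        rows.append(PreservationResult(m.module_id, zd, zc, z_summary, perm_p,
                                       preserved, n_perm, len(genes), flagged))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df


def module_overlap(genes, b_modules: ModuleHierarchy, alpha: float | None = None,
                   query_id: str = "query") -> pd.DataFrame:
    """Best Jaccard-matched module of ``b_modules`` for a query gene set.

    Overlap percentage is |a intersect b| / |a| * 100, relative to the
    query module's size. Returns a single-row table; use repeatedly for
    a full best-match table.
    """
    a = frozenset(genes)
    if not a or len(b_modules.non_root(alpha)) == 0:
        raise ValidationError("module_overlap requires nonempty inputs")
    best = None
    for m in b_modules.non_root(alpha):
        inter = len(a & m.genes)
        union = len(a | m.genes)
        jacc = inter / union if union else 0.0
        key = (jacc, inter, m.module_id)
        if best is None or key > (best[0], best[1], best[2]):
            best = (jacc, inter, m.module_id, m.size)
    jacc, inter, mid, msize = best
    return pd.DataFrame([{
        "query": query_id,
        "best_match": mid,
        "jaccard": jacc,
        "overlap_pct": 100.0 * inter / len(a),
        "query_size": len(a),
        "match_size": msize,
    }])


def overlap_table(a_modules: ModuleHierarchy, b_modules: ModuleHierarchy,
                  alpha: float | None = None) -> pd.DataFrame:
    """Best-match overlap of every non-root module of a vs the modules of b."""
    frames = [module_overlap(m.genes, b_modules, alpha, m.module_id)
              for m in a_modules.non_root(alpha)]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=1, keepdims=True)
    return (v - v.mean(axis=1, keepdims=True)) / np.maximum(sd, 1e-12)


def _module_stats(idx: np.ndarray, ref_z: np.ndarray, test_z: np.ndarray) -> tuple[float, float]:
    n = ref_z.shape[1]
    m = test_z.shape[1]
    ct = test_z[idx] @ test_z[idx].T / m
    np.clip(ct, -1, 1, out=ct)
    iu = np.triu_indices(len(idx), k=1)
    density = float(np.abs(ct[iu]).mean())
    cr = ref_z[idx] @ ref_z[idx].T / n
    np.clip(cr, -1, 1, out=cr)
    conn_ref = np.abs(cr).sum(axis=1) - 1.0
    conn_test = np.abs(ct).sum(axis=1) - 1.0
    rho = stats.spearmanr(conn_ref, conn_test).statistic
    if np.isnan(rho):
        rho = 0.0
    return density, float(rho)


def _zscore(obs: float, null: np.ndarray) -> float:
    sd = null.std()
    if sd <= 1e-12:
        return 0.0
    return float((obs - null.mean()) / sd)


def _zvec(null: np.ndarray) -> np.ndarray:
    sd = null.std()
    if sd <= 1e-12:
        return np.zeros_like(null)
    return (null - null.mean()) / sd
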