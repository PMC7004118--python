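"""Fisher's-exact gene-set enrichment of signatures and pathways in modules.

All tests are one-sided over-representation tests: the p-value is the
hypergeometric upper tail P(X >= k) for drawing n target genes from a
background of N containing K query genes. Fold enrichment is the
observed overlap over its expectation under independence,
FE = k / (K * n / N). Both Bonferroni and Benjamini-Hochberg corrected
p-values are always reported across the full family of tested pairs.

The default background universe is the set of network genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSignature, ModuleHierarchy, ValidationError
from .modules import extract_neighborhood
from .network import PlanarNetwork
from .signatures import SignaturePair

logger = logging.getLogger("coexnet")


@dataclass
class EnrichmentResult:
    query: str
    target: str
    k: int          # overlap
    K: int          # query size within background
    n: int          # target size within background
    N: int          # background size
    fold_enrichment: float
    p_raw: float
    p_bonferroni: float = np.nan
    q_bh: float = np.nan
    flagged: bool = False

    def as_dict(self) -> dict:
        return {
            "query": self.query, "target": self.target,
            "k": self.k, "K": self.K, "n": self.n, "N": self.N,
            "fold_enrichment": self.fold_enrichment, "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni, "q_bh": self.q_bh,
            "flagged": self.flagged,
        }


def fisher_enrichment(query: GeneSignature, target, background,
                      target_id: str = "target") -> EnrichmentResult:
    """One-sided hypergeometric over-representation test of query in target."""
    background = frozenset(background)
    if len(background) < 10:
        raise ValidationError("background must contain >= 10 genes")
    q = query.genes & background
    t = frozenset(target) & background
    N, K, n = len(background), len(q), len(t)
    k = len(q & t)
    if K == 0 or n == 0:
        return EnrichmentResult(query.name, target_id, k, K, n, N, 0.0, 1.0, flagged=True)
    fe = k / (K * n / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(query.name, target_id, k, K, n, N, float(fe), p)


def enrich_modules(h: ModuleHierarchy, signatures: list[GeneSignature], background,
                   correction: str = "bh", alpha: float | None = None) -> pd.DataFrame:
    """Test every module x signature pair; correct across the full family.

    ``correction`` chooses which corrected p-value drives the
    ``significant`` flag (threshold 0.05); Bonferroni and BH values are
    both reported regardless.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValidationError("correction must be 'bonferroni' or 'bh'")
    background = frozenset(background)
    results = []
    for m in h.non_root(alpha):
        for sig in signatures:
            results.append(fisher_enrichment(sig, m.genes, background, m.module_id))
    return _finish_table(results, correction)


def annotate_modules(h: ModuleHierarchy, pathway_gmt: list[GeneSignature], background,
                     correction: str = "bh", alpha: float | None = None) -> pd.DataFrame:
    """Annotate modules by enrichment of a pathway collection (GMT)."""
    return enrich_modules(h, pathway_gmt, background, correction, alpha)


def project_perturbation(net: PlanarNetwork, gene: str, k: int, sig: SignaturePair,
                         background=None) -> pd.DataFrame:
    """Project a perturbation signature onto a gene's k-layer neighborhood.

    The neighborhood excludes the perturbed gene itself; the up and down
    signatures are each tested against it within the network background.
    Neighborhoods smaller than 5 genes yield flagged low-power results.
    """
    if background is None:
        background = set(net.graph.nodes)
    neighborhood = extract_neighborhood(net, gene, k) - {gene}
    low_power = len(neighborhood) < 5
    if low_power:
        logger.warning("neighborhood of %s at k=%d has only %d genes",
                       gene, k, len(neighborhood))
    results = []
    for part in (sig.up, sig.down):
        res = fisher_enrichment(part, neighborhood, background,
                                target_id=f"{gene}_k{k}_neighborhood")
        if low_power:
            res.flagged = True
        results.append(res)
    return _finish_table(results, "bh")


def _finish_table(results: list[EnrichmentResult], correction: str) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=["query", "target", "k", "K", "n", "N",
                                     "fold_enrichment", "p_raw", "p_bonferroni",
                                     "q_bh", "flagged", "significant"])
    p = np.array([r.p_raw for r in results])
    p_bonf = np.minimum(p * len(p), 1.0)
    _, q_bh, _, _ = multipletests(p, method="fdr_bh")
    rows = []
    for r, pb, qb in zip(results, p_bonf, q_bh):
        r.p_bonferroni = float(pb)
        r.q_bh = float(qb)
        d = r.as_dict()
        d["significant"] = bool((pb if correction == "bonferroni" else qb) < 0.05
                                and not r.flagged)
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.sort_values(["p_raw", "query", "target"], kind="stable").reset_index(drop=True)
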