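"""Gene-set over-representation: one-tailed Fisher exact and its EASE variant.

For a query list of n genes drawn from a background of N genes, a gene set
with K background members and k overlapping query genes is scored with the
hypergeometric upper tail P(X >= k).  The EASE score is the same tail after
removing one gene from the overlap (P(X >= k-1) at k-1), a deliberately
conservative penalty on small overlaps: a singleton overlap can never be
significant.  Computation is exact and log-space stable via
``scipy.stats.hypergeom``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import false_discovery_control, hypergeom

from .types import GeneSetCollection


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_genes: list[str]
    k: int  # overlap size
    n: int  # query size within background
    K: int  # set size within background
    N: int  # background size
    p_fisher: float
    p_ease: float
    significant: bool
    q_value: float | None = None  # only when FDR correction is requested


def _check_counts(k, n, K, N) -> None:
    # k below the support floor max(0, n+K-N) is allowed: the tail is then 1
    k, n, K, N = (
        np.atleast_1d(a).ravel()
        for a in np.broadcast_arrays(*(np.asarray(x) for x in (k, n, K, N)))
    )
    ok = (0 <= k) & (k <= n) & (n <= N) & (k <= K) & (K <= N)
    if not ok.all():
        i = int(np.argmin(ok))
        raise ValueError(
            f"inconsistent counts: k={k[i]}, n={n[i]}, K={K[i]}, N={N[i]}"
        )


def fisher_one_tailed(k, n, K, N):
    """Exact one-tailed (enrichment) Fisher p-value: P(X >= k), X ~ Hypergeom(N, K, n).

    Accepts scalars or broadcastable integer arrays; returns a float for
    scalar input, an ndarray otherwise.
    """
    _check_counts(k, n, K, N)
    k_a, n_a, K_a, N_a = np.broadcast_arrays(*(np.asarray(x) for x in (k, n, K, N)))
    p = hypergeom.sf(k_a - 1, N_a, K_a, n_a)
    p = np.where(k_a <= 0, 1.0, np.clip(p, 5e-324, 1.0))
    if np.asarray(k).ndim == 0:
        return float(p)
    return p


def ease_score(k, n, K, N):
    """DAVID's modified Fisher exact: the one-tailed p after discounting one overlap gene."""
    _check_counts(k, n, K, N)
    k_shift = np.maximum(np.asarray(k) - 1, 0)
    if np.asarray(k).ndim == 0:
        k_shift = int(k_shift)
    return fisher_one_tailed(k_shift, n, K, N)


def enrich(
    query_genes,
    gene_sets: GeneSetCollection,
    background,
    alpha: float = 0.05,
    statistic: str = "ease",
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Score every gene set overlapping the query; sort ascending by the chosen statistic.

    Query and gene sets are intersected with the background first; sets with
    no overlap are omitted.  Significance is called at ``alpha`` on the EASE
    score by default (``statistic="fisher"`` switches to the plain tail);
    with ``fdr=True`` the threshold applies to Benjamini-Hochberg q-values.
    """
    if statistic not in ("ease", "fisher"):
        raise ValueError(f"unknown enrichment statistic {statistic!r}")
    background = frozenset(g.upper() for g in background)
    if not background:
        raise ValueError("empty background universe")
    query = frozenset(g.upper() for g in query_genes) & background
    N, n = len(background), len(query)

    results = []
    for gs in gene_sets:
        members = gs.genes & background
        overlap = sorted(query & members)
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                overlap_genes=overlap,
                k=k,
                n=n,
                K=K,
                N=N,
                p_fisher=fisher_one_tailed(k, n, K, N),
                p_ease=ease_score(k, n, K, N),
                significant=False,
            )
        )

    stat = (lambda r: r.p_ease) if statistic == "ease" else (lambda r: r.p_fisher)
    results.sort(key=lambda r: (stat(r), r.set_name))
    if results and fdr:
        qs = false_discovery_control([stat(r) for r in results], method="bh")
        for r, q in zip(results, qs):
            r.q_value = float(q)
            r.significant = q < alpha
    else:
        for r in results:
            r.significant = stat(r) < alpha
    return results


def results_table(results: list[EnrichmentResult]):
    """Rows mirroring a pathway table: set name, p-values, overlap genes."""
    return [
        {
            "set_name": r.set_name,
            "p_ease": r.p_ease,
            "p_fisher": r.p_fisher,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "significant": r.significant,
            "genes": ",".join(r.overlap_genes),
        }
        for r in results
    ]
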