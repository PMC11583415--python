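"""Gene-set over-representation and enriched-term clustering.

Enrichment of a query gene list against a flat gene-set collection is the
upper-tail hypergeometric test with Benjamini-Hochberg correction across
terms.  Because enriched terms are often near-duplicates of one another,
terms are then grouped: pairwise Jaccard similarity of their gene sets,
hierarchical clustering (complete linkage) on distance 1 - J, and the
number of clusters selected by the gap statistic — within-cluster
dispersion of the observed clustering compared against randomised
reference collections, the chosen k being the smallest whose gap is within
one reference standard error of the next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSetCollection:
    """Flat term -> gene-set mapping (term names optional)."""

    terms: Mapping[str, frozenset]
    names: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_dict(cls, d: Mapping[str, set]) -> "GeneSetCollection":
        return cls({t: frozenset(g) for t, g in d.items()})


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, genes...)."""
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if term in terms:
            raise ValueError(f"duplicate term {term!r} in GMT")
        terms[term] = frozenset(genes)
        names[term] = desc
    return GeneSetCollection(terms, names)


def ora_hypergeometric(
    query: set,
    collection: GeneSetCollection,
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Term gene sets are intersected with the universe; for overlap k, term
    size K, query size n, universe size N, ``p_hyper = P(X >= k)`` under
    Hypergeom(N, K, n), and ``q_bh`` is the Benjamini-Hochberg adjusted
    value across all terms.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query:
        raise ValueError("query must be non-empty")
    query = set(query)
    if not query <= set(universe):
        extra = sorted(query - set(universe))[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in collection.terms.items():
        term_genes = genes & universe
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "overlap_k", "term_size_K", "query_size_n", "universe_N", "p_hyper"],
    )
    out["q_bh"] = multipletests(out["p_hyper"], method="fdr_bh")[1] if len(out) else []
    return out


def _jaccard_from_membership(M: np.ndarray) -> np.ndarray:
    """Jaccard matrix from a binary term x gene membership matrix."""
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(J, 1.0)
    return J


def jaccard_matrix(collection: GeneSetCollection) -> pd.DataFrame:
    """Symmetric Jaccard similarity |A&B| / |A|B| between all term pairs."""
    terms = list(collection.terms)
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    universe = sorted(set().union(*collection.terms.values()))
    col = {g: i for i, g in enumerate(universe)}
    M = np.zeros((len(terms), len(universe)))
    for i, t in enumerate(terms):
        for g in collection.terms[t]:
            M[i, col[g]] = 1.0
    return pd.DataFrame(_jaccard_from_membership(M), index=terms, columns=terms)


def _within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum over clusters of (1/(2 n_r)) * sum of pairwise distances
    within the cluster (Tibshirani's dispersion on a given metric)."""
    W = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            W += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return W


def _cut_tree(D: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(D, checks=False), method="complete")
    return fcluster(Z, t=k, criterion="maxclust")


def _dispersion_curve(D: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """W_k for each k, cutting one complete-linkage tree per matrix."""
    Z = linkage(squareform(D, checks=False), method="complete")
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = np.ones(D.shape[0], int) if k == 1 else fcluster(Z, t=k, criterion="maxclust")
        out[i] = _within_dispersion(D, labels)
    return out


def _shuffled_reference(rng: np.random.Generator, D: np.ndarray) -> np.ndarray:
    """Default reference: symmetric shuffle of the off-diagonal distances."""
    m = D.shape[0]
    cond = squareform(D, checks=False)
    rng.shuffle(cond)
    return squareform(cond)


def gap_statistic_k(
    distance: np.ndarray | pd.DataFrame,
    k_max: int = 15,
    n_boot: int = 1000,
    seed: int = 0,
    reference: Callable[[np.random.Generator], np.ndarray] | None = None,
    eps: float = 1e-12,
    rule: str = "firstSEmax",
) -> tuple[int, pd.DataFrame]:
    """Select the number of clusters by the gap statistic.

    For k = 1..k_max the observed distance matrix is cut by complete-linkage
    hierarchical clustering and the within-cluster dispersion ``W_k``
    recorded; ``Gap(k)`` is the mean over ``n_boot`` reference datasets of
    ``log W_k(ref) - log W_k(obs)``, with se carrying the sqrt(1 + 1/B)
    simulation-error factor.  ``rule`` picks ``k_opt`` from the curve:

    * ``'firstSEmax'`` (default) — smallest k whose gap is within one se of
      the global maximum, robust to the local dip the curve shows when a
      cut is forced to merge two well-separated groups;
    * ``'tibshirani'`` — smallest k with ``Gap(k) >= Gap(k+1) - se(k+1)``
      (the original sequential rule).

    ``reference`` generates a reference distance matrix per bootstrap draw
    from the provided RNG; the default shuffles the observed off-diagonal
    distances.  :func:`cluster_terms` passes a generator that redraws the
    gene sets themselves.  Deterministic given ``seed``.
    """
    D = np.asarray(distance, dtype=float)
    m = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be square")
    if not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance must be symmetric with zero diagonal")
    if m == 1:
        warnings.warn("single item; k_opt = 1")
        return 1, pd.DataFrame({"k": [1], "gap": [0.0], "se": [0.0]})
    if k_max >= m:
        warnings.warn(f"k_max {k_max} >= number of items {m}; capped at {m - 1}")
        k_max = max(1, m - 1)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)

    log_w_obs = np.log(np.maximum(_dispersion_curve(D, ks), eps))
    ref_fn = reference if reference is not None else (lambda r: _shuffled_reference(r, D))
    log_w_ref = np.empty((n_boot, len(ks)))
    for b in range(n_boot):
        log_w_ref[b] = np.log(np.maximum(_dispersion_curve(ref_fn(rng), ks), eps))

    gap = log_w_ref.mean(axis=0) - log_w_obs
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_boot)
    if rule == "firstSEmax":
        imax = int(np.argmax(gap))
        k_opt = int(ks[np.flatnonzero(gap >= gap[imax] - se[imax])[0]])
    elif rule == "tibshirani":
        k_opt = int(ks[-1])
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                k_opt = int(ks[i])
                break
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    curve = pd.DataFrame({"k": ks, "gap": gap, "se": se})
    return k_opt, curve


def _geneset_reference_factory(collection: GeneSetCollection):
    """Reference generator drawing random gene sets from the collection's
    own gene universe, preserving each term's set size."""
    sizes = [len(g) for g in collection.terms.values()]
    n_universe = len(set().union(*collection.terms.values()))

    def make(rng: np.random.Generator) -> np.ndarray:
        M = np.zeros((len(sizes), n_universe))
        for i, s in enumerate(sizes):
            M[i, rng.choice(n_universe, size=s, replace=False)] = 1.0
        return 1.0 - _jaccard_from_membership(M)

    return make


def cluster_terms(
    collection: GeneSetCollection,
    k_max: int = 15,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[int, pd.DataFrame, pd.DataFrame]:
    """Cluster a term collection by gene-set similarity.

    Complete-linkage hierarchical clustering on distance 1 - Jaccard, the
    tree cut at the gap-statistic optimum (reference datasets preserve
    each term's set size, drawing genes at random from the collection's
    universe).  Returns (k_opt, assignments, gap_curve); assignments has
    columns term_id, cluster, k_opt.
    """
    J = jaccard_matrix(collection)
    D = 1.0 - J.to_numpy()
    np.fill_diagonal(D, 0.0)
    k_opt, curve = gap_statistic_k(
        D,
        k_max=k_max,
        n_boot=n_boot,
        seed=seed,
        reference=_geneset_reference_factory(collection),
    )
    labels = np.ones(len(J), int) if k_opt == 1 else _cut_tree(D, k_opt)
    assignments = pd.DataFrame(
        {"term_id": J.index, "cluster": labels, "k_opt": k_opt}
    )
    return k_opt, assignments, curve
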