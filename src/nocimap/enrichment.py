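"""Gene-set enrichment of an upregulated gene list.

For each term of a gene-set library, a one-sided Fisher exact test on the
2x2 query x term table over the background universe, Benjamini-Hochberg
adjustment across the library, a Monte-Carlo rank z-score (deviation of the
term's observed p-value rank from its rank distribution under random
queries of the same size), and the combined score c = -ln(p_adj) * z.
Enriched terms score positive under this sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetLibrary",
    "read_gmt",
    "term_enrichment",
    "rank_zscore",
    "combined_score",
    "enrich",
]

logger = logging.getLogger(__name__)

P_ADJ_FLOOR = 1e-300


@dataclass
class GeneSetLibrary:
    """Term -> gene-set mapping over a background universe.

    Term genes outside the universe are dropped (logged); empty terms are
    removed. If no universe is given it defaults to the union of all term
    genes.
    """

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        clean = {}
        for name, genes in self.terms.items():
            inside = set(genes) & self.universe
            dropped = len(genes) - len(inside)
            if dropped:
                logger.info("term %s: dropped %d genes outside universe", name, dropped)
            if inside:
                clean[name] = inside
            else:
                logger.info("term %s empty after harmonization; removed", name)
        self.terms = clean

    def with_universe(self, universe: set[str]) -> "GeneSetLibrary":
        return GeneSetLibrary({t: set(g) for t, g in self.terms.items()}, set(universe))


def read_gmt(path) -> GeneSetLibrary:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms[parts[0]] = {g for g in parts[2:] if g}
    return GeneSetLibrary(terms)


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """OR of the 2x2 table with Haldane 0.5 correction when any cell is 0."""
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def term_enrichment(query: set[str], library: GeneSetLibrary) -> pd.DataFrame:
    """Per-term overlap, odds ratio, one-sided Fisher p and BH-adjusted p.

    Query genes outside the universe are dropped with a log line.
    """
    if not library.universe:
        raise ValueError("empty background universe")
    q = set(query) & library.universe
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("query: dropped %d genes outside universe", dropped)
    if not q:
        raise ValueError("empty query after harmonization")

    N = len(library.universe)
    n = len(q)
    rows = []
    for term, genes in library.terms.items():
        K = len(genes)
        overlap = q & genes
        k = len(overlap)
        table = [[k, K - k], [n - k, N - K - n + k]]
        _, p = fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "odds_ratio": _odds_ratio(k, K, n, N),
                "pvalue": float(p),
                "overlap_genes": ";".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows).set_index("term", drop=False)
    out.index.name = None
    out["p_adj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out


def rank_zscore(
    observed: pd.DataFrame,
    library: GeneSetLibrary,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """z-score of each term's observed p-value rank vs random queries.

    Random query sets of the observed size are drawn uniformly from the
    universe; terms are ranked by p ascending in each draw. z = (mean
    permuted rank - observed rank) / sd(permuted rank), so terms ranked
    earlier than expected get z > 0. With a single term z is undefined
    and reported as 0 with a warning.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    terms = list(observed["term"])
    if len(terms) < 2:
        import warnings

        warnings.warn("library has one term: rank z undefined, reporting 0", stacklevel=2)
        return pd.Series(0.0, index=observed.index)

    rng = np.random.default_rng(seed)
    universe = sorted(library.universe)
    n = int(observed["n"].iloc[0])
    term_genes = [library.terms[t] for t in terms]

    obs_rank = observed["pvalue"].rank(method="average").to_numpy()
    ranks = np.empty((n_permutations, len(terms)))
    for b in range(n_permutations):
        draw = set(rng.choice(len(universe), size=n, replace=False))
        qset = {universe[i] for i in draw}
        ks = np.array([len(qset & genes) for genes in term_genes])
        Ks = np.array([len(genes) for genes in term_genes])
        # one-sided Fisher p == hypergeometric upper tail
        ps = hypergeom.sf(ks - 1, len(universe), Ks, n)
        ranks[b] = pd.Series(ps).rank(method="average").to_numpy()

    mean_r = ranks.mean(axis=0)
    sd_r = np.maximum(ranks.std(axis=0, ddof=1), 1e-6)
    z = (mean_r - obs_rank) / sd_r
    return pd.Series(z, index=observed.index)


def combined_score(p_adj, z):
    """c = -ln(p_adj) * z; p_adj floored at 1e-300. Scalar or vectorized."""
    p = np.maximum(np.asarray(p_adj, dtype=float), P_ADJ_FLOOR)
    c = -np.log(p) * np.asarray(z, dtype=float)
    return float(c) if np.isscalar(p_adj) or np.ndim(p_adj) == 0 else c


def enrich(
    query: set[str],
    library: GeneSetLibrary,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full enrichment table: Fisher p, BH, rank z and combined score."""
    out = term_enrichment(query, library)
    out["z"] = rank_zscore(out, library, n_permutations=n_permutations, seed=seed)
    out["combined_score"] = combined_score(out["p_adj"].to_numpy(), out["z"].to_numpy())
    cols = [
        "term", "k", "K", "n", "N", "odds_ratio", "pvalue", "p_adj", "z",
        "combined_score", "overlap_genes",
    ]
    return out[cols].sort_values("combined_score", ascending=False)
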