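"""Negative-binomial differential expression for bulk count matrices.

Implements the classic count-based DE chain for a two-group comparison:
low-count filtering on CPM, TMM (trimmed mean of M-values) normalization
factors, conditional-likelihood estimation of a common and tagwise NB
dispersion, an exact NB test conditioned on per-gene totals, and
Benjamini-Hochberg FDR control.

The in-memory substrate is a :class:`CountMatrix`: a genes x samples
``pandas.DataFrame`` of non-negative integers plus a group label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "DispersionEstimate",
    "filter_low_counts",
    "tmm_factors",
    "estimate_dispersion",
    "nb_exact_test",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a group label per sample."""

    counts: pd.DataFrame  # genes in rows, samples in columns
    groups: pd.Series  # indexed by sample id

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self.groups = pd.Series(self.groups).reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        lib = self.library_sizes().to_numpy(dtype=float)
        return self.counts / lib * 1e6

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.groups)


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors; geometric mean is 1 by construction."""

    factors: pd.Series
    ref_sample: str

    def effective_library_sizes(self, counts: CountMatrix) -> pd.Series:
        return counts.library_sizes() * self.factors


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    prior_df: float = 10.0


def filter_low_counts(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples_per_group: int = 2
) -> CountMatrix:
    """Drop genes not reaching ``min_cpm`` CPM in at least
    ``min_samples_per_group`` samples of at least one group.

    A gene expressed in only one sample per group is removed under the
    defaults. Gene order is preserved.
    """
    cpm = counts.cpm()
    keep = np.zeros(len(counts.gene_ids), dtype=bool)
    for g in counts.groups.unique():
        cols = counts.groups.index[counts.groups == g]
        n_ok = (cpm[cols] >= min_cpm).sum(axis=1)
        keep |= (n_ok >= min_samples_per_group).to_numpy()
    if not keep.any():
        import warnings

        warnings.warn("low-count filter removed every gene", stacklevel=2)
    return counts.subset_genes(counts.gene_ids[keep])


def _choose_reference(counts: CountMatrix) -> str:
    # sample whose upper-quartile CPM (over nonzero genes) is closest to the mean
    cpm = counts.cpm().to_numpy()
    uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0 for col in cpm.T])
    return str(counts.sample_ids[np.argmin(np.abs(uq - uq.mean()))])


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample versus the reference, genes expressed in both are
    doubly trimmed (``trim_m`` on each tail of the log-ratios M, ``trim_a``
    on each tail of the log-abundances A); the factor is 2**(weighted mean
    of the surviving M-values) with inverse asymptotic-variance weights,
    rescaled so the factors have geometric mean 1.
    """
    lib = counts.library_sizes()
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    if len(counts.sample_ids) < 2:
        raise ValueError("TMM needs at least two samples")
    if ref_sample is None:
        ref_sample = _choose_reference(counts)

    mat = counts.counts.to_numpy(dtype=float)
    libv = lib.to_numpy(dtype=float)
    r_idx = list(counts.sample_ids).index(ref_sample)
    ref = mat[:, r_idx]
    n_ref = libv[r_idx]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == r_idx:
            continue
        obs = mat[:, j]
        n_obs = libv[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            continue
        p_obs = obs[ok] / n_obs
        p_ref = ref[ok] / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic binomial variance of M
        w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
        if np.allclose(m, m[0], atol=1e-10):
            # degenerate: every surviving ratio identical, nothing to trim
            log_factors[j] = float(m[0])
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            keep = np.ones_like(m, dtype=bool)
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0**log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.sample_ids), ref_sample=ref_sample
    )


# ---------------------------------------------------------------------------
# dispersion estimation on library-size-equalized pseudocounts


def _pseudocounts(counts: CountMatrix, factors: NormalizationFactors) -> np.ndarray:
    """Rescale every sample to the geometric-mean effective library size."""
    eff = factors.effective_library_sizes(counts).to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(eff)))
    return counts.counts.to_numpy(dtype=float) * (common / eff)


def _cond_loglik(pseudo: np.ndarray, group_cols: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-gene NB conditional log-likelihood given per-group totals.

    For n iid NB(r, p) observations the sum is NB(n*r, p) and the
    conditional likelihood of the split given the total is free of p:
    sum_i lgamma(z_i + r) - n*lgamma(r) + lgamma(n*r) - lgamma(z + n*r)
    (plus multinomial terms constant in phi, omitted).
    """
    r = 1.0 / max(phi, 1e-10)
    ll = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        z = pseudo[:, cols]
        n = len(cols)
        if n < 2:
            continue
        tot = z.sum(axis=1)
        ll += (
            gammaln(z + r).sum(axis=1)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(tot + n * r)
            # multinomial coefficient, constant in phi but keeps ll a proper
            # log-pmf so per-gene curves are comparable across phi
            + gammaln(tot + 1)
            - gammaln(z + 1).sum(axis=1)
        )
    return ll


def estimate_dispersion(
    counts: CountMatrix,
    factors: NormalizationFactors,
    prior_df: float = 10.0,
) -> DispersionEstimate:
    """Common and tagwise NB dispersion by conditional maximum likelihood.

    The common dispersion maximizes the summed per-gene conditional
    log-likelihood on library-size-equalized pseudocounts (log-spaced grid
    then bounded Brent refinement). Tagwise values maximize the per-gene
    likelihood plus ``prior_df / residual_df`` gene-equivalents of the
    average likelihood curve, shrinking each gene toward the common value.
    """
    groups = counts.groups
    group_cols = []
    cols_arr = np.arange(len(counts.sample_ids))
    for g in groups.unique():
        cols = cols_arr[(groups == g).to_numpy()]
        if len(cols) >= 2:
            group_cols.append(cols)
    if not group_cols:
        raise ValueError("no group with >= 2 samples: common dispersion undefined")

    pseudo = _pseudocounts(counts, factors)
    n_genes = pseudo.shape[0]
    grid = np.concatenate([[1e-8], np.logspace(-4, 1, 40)])
    mean_ll = np.array([_cond_loglik(pseudo, group_cols, p).mean() for p in grid])
    i = int(np.argmax(mean_ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]

    def neg_mean(phi: float) -> float:
        return -_cond_loglik(pseudo, group_cols, phi).mean()

    res = minimize_scalar(neg_mean, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    common = float(res.x)
    if common <= 2e-8:
        common = 0.0

    # tagwise: weighted likelihood, per-gene curve + shared average curve,
    # maximized on a fine log grid with parabolic refinement
    df_res = sum(len(c) - 1 for c in group_cols)
    weight = prior_df / max(df_res, 1)
    if weight > 1e3:
        # shrinkage dominated by the shared curve: tagwise == common
        tagwise = np.full(n_genes, common)
    else:
        fine = np.unique(np.concatenate([np.logspace(-4, 1, 160), [max(common, 1e-8)]]))
        ll_grid = np.stack([_cond_loglik(pseudo, group_cols, p) for p in fine], axis=1)
        obj = ll_grid + weight * ll_grid.mean(axis=0)[None, :]
        idx = np.argmax(obj, axis=1)
        tagwise = fine[idx].astype(float)
        # parabolic refinement in log-phi using the three bracketing grid points
        inner = (idx > 0) & (idx < len(fine) - 1)
        li = np.log(fine)
        for g in np.flatnonzero(inner):
            k = idx[g]
            x0, x1, x2 = li[k - 1 : k + 2]
            y0, y1, y2 = obj[g, k - 1 : k + 2]
            den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
            if abs(den) > 1e-12:
                xv = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / den
                if x0 <= xv <= x2:
                    tagwise[g] = float(np.exp(xv))
    tagwise[tagwise <= 2e-8] = 0.0
    return DispersionEstimate(
        common=common,
        tagwise=pd.Series(tagwise, index=counts.gene_ids),
        prior_df=prior_df,
    )


# ---------------------------------------------------------------------------
# exact test


def _nb_log_coef(k: np.ndarray, size: float) -> np.ndarray:
    """log Gamma(k+size) - log Gamma(size) - log k! (NB combinatorial part)."""
    return gammaln(k + size) - gammaln(size) - gammaln(k + 1)


def _exact_pvalue(total: int, k_obs: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p: sum P(outcomes) with P <= P(observed).

    Conditional on the total, the group-A sum is distributed as the ratio
    of NB combinatorial coefficients (binomial when phi = 0).
    """
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi <= 0:
        logp = (
            gammaln(total + 1)
            - gammaln(k + 1)
            - gammaln(total - k + 1)
            + k * np.log(n_a / (n_a + n_b))
            + (total - k) * np.log(n_b / (n_a + n_b))
        )
    else:
        r = 1.0 / phi
        logp = _nb_log_coef(k, n_a * r) + _nb_log_coef(total - k, n_b * r)
        logp -= _nb_log_coef(np.array([float(total)]), (n_a + n_b) * r)[0]
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(p[p <= p[k_obs] * (1 + 1e-12)].sum())


def nb_exact_test(
    counts: CountMatrix,
    factors: NormalizationFactors,
    disp: DispersionEstimate,
    group_a: str,
    group_b: str,
    prior_count: float = 0.125,
    use_tagwise: bool = True,
) -> pd.DataFrame:
    """Exact NB test of group A vs group B for every gene.

    Returns a DataFrame with columns gene_id, log2fc (A over B), mean_cpm,
    pvalue, fdr, direction. log2 fold changes use ``prior_count`` added to
    each group's average pseudocount to avoid infinities.
    """
    groups = counts.groups
    cols_a = np.flatnonzero((groups == group_a).to_numpy())
    cols_b = np.flatnonzero((groups == group_b).to_numpy())
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")

    pseudo = _pseudocounts(counts, factors)
    phi = disp.tagwise.to_numpy() if use_tagwise else np.full(pseudo.shape[0], disp.common)

    sum_a = pseudo[:, cols_a].sum(axis=1)
    sum_b = pseudo[:, cols_b].sum(axis=1)
    # round each group sum separately so swapping the groups is an exact
    # mirror of the conditional distribution
    k_obs = np.rint(sum_a).astype(np.int64)
    totals = k_obs + np.rint(sum_b).astype(np.int64)

    pvals = np.ones(pseudo.shape[0])
    for g in range(pseudo.shape[0]):
        pvals[g] = _exact_pvalue(int(totals[g]), int(k_obs[g]), len(cols_a), len(cols_b), float(phi[g]))

    mean_a = sum_a / len(cols_a)
    mean_b = sum_b / len(cols_b)
    log2fc = np.log2(mean_a + prior_count) - np.log2(mean_b + prior_count)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    cpm = counts.cpm().mean(axis=1).to_numpy()
    out = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2fc": log2fc,
            "mean_cpm": cpm,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    ).set_index("gene_id", drop=False)
    out.index.name = None
    return out
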