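"""Negative-binomial Wald differential expression engine.

A transparent, self-contained engine in the mould of count-based DE tools:

* expression filtering (>= ``min_count`` in >= ``min_samples`` samples),
* median-of-ratios size factors,
* gene-wise method-of-moments dispersion within design cells (no
  empirical-Bayes shrinkage),
* per-gene NB log-link GLMs (treatment + source-colony design) fitted by
  iteratively reweighted least squares with fixed dispersion, Wald z tests of
  each treatment-vs-control contrast,
* Benjamini-Hochberg FDR adjustment,
* a shifted-log variance-stabilising transform and sample PCA.

Deliberate simplifications relative to shrinkage-based packages: gene-wise
MoM dispersion, no LFC shrinkage, no independent filtering, no outlier
refitting.  The goal is a calibrated Wald engine whose behaviour is fully
auditable, not bit-compatibility with any particular tool.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTROL, DESettings

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "wald_z", "pvalue", "fdr", "significant"]

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def filter_low_counts(counts: pd.DataFrame, settings: DESettings = DESettings()) -> pd.DataFrame:
    """Retain genes with at least ``min_count`` in at least ``min_samples`` samples."""
    keep = (counts >= settings.min_count).sum(axis=1) >= settings.min_samples
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return counts.loc[keep]


def _lower_median(values: np.ndarray) -> float:
    """Median as an order statistic; for even lengths take the lower of the pair."""
    v = np.sort(values)
    return float(v[(len(v) - 1) // 2])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample, the (lower) median over reference genes of
    ``count / geometric mean across samples``.  Reference genes are those with
    strictly positive counts in every sample (nonzero geometric mean); if no
    such gene exists, geometric means are computed over positive entries only.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns, name="size_factor")
    all_positive = (x > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if all_positive.any():
        ref = all_positive
        loggeo = logx[ref].mean(axis=1)
    else:
        warnings.warn(
            "no gene has all-positive counts; falling back to geometric means "
            "over positive entries",
            stacklevel=2,
        )
        ref = (x > 0).any(axis=1)
        if not ref.any():
            raise ValueError(
                "size factors are undefined: every gene is all-zero; "
                "filter the matrix or check the input"
            )
        loggeo = np.array(
            [row[row > -np.inf].mean() for row in logx[ref]]
        )
    ratios = logx[ref] - loggeo[:, None]
    factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        col = ratios[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no positive reference gene; "
                "cannot compute its size factor"
            )
        factors[j] = np.exp(_lower_median(col))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _residual_mom_alpha(
    Y: np.ndarray, mu: np.ndarray, resid_df: float, settings: DESettings
) -> np.ndarray:
    """Method-of-moments dispersion from residuals around fitted means.

    Since ``E[(y - mu)^2] = mu + alpha mu^2`` per observation,
    ``alpha = sum((y - mu)^2 - mu) / mu^2 / df`` with the residual degrees of
    freedom accounting for the fitted mean parameters.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = ((Y - mu) ** 2 - mu) / mu**2
    alpha = np.nansum(np.where(mu > 0, contrib, np.nan), axis=1) / max(resid_df, 1.0)
    return np.clip(alpha, settings.dispersion_floor, settings.dispersion_cap)


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.DataFrame,
    settings: DESettings = DESettings(),
    include_colony: bool = True,
) -> pd.Series:
    """Gene-wise method-of-moments NB dispersion around full-design means.

    A GLM with the full design (treatment and, when requested and present,
    source colony) is fitted per gene and the dispersion is the
    method-of-moments estimate from the squared residuals about the fitted
    means, ``alpha = mean[((y - mu)^2 - mu) / mu^2]`` over the residual
    degrees of freedom, clamped to ``[dispersion_floor, dispersion_cap]``.
    Using model residuals (rather than raw within-group variances) means
    that variance explained by modelled covariates — notably the colony
    blocking factor — does not inflate the dispersion.  Deterministic; no
    shrinkage across genes.

    The fit is iterated once: Poisson-like start, dispersion estimate,
    refit, re-estimate.
    """
    if include_colony and "colony" not in design.columns:
        include_colony = False
    X, _ = _design_matrix(design, include_colony=include_colony)
    Y = counts.to_numpy(dtype=float)
    offset = np.log(factors.to_numpy())
    alpha = _estimate_dispersion_for_design(Y, X, offset, settings)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _estimate_dispersion_for_design(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, settings: DESettings
) -> np.ndarray:
    resid_df = Y.shape[1] - X.shape[1]
    start = np.full(Y.shape[0], settings.dispersion_floor)
    beta, _, _ = _fit_nb_glm(Y, X, offset, start, settings)
    mu = np.exp(np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP))
    alpha = _residual_mom_alpha(Y, mu, resid_df, settings)
    beta, _, _ = _fit_nb_glm(Y, X, offset, alpha, settings)
    mu = np.exp(np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP))
    return _residual_mom_alpha(Y, mu, resid_df, settings)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design_matrix(
    meta: pd.DataFrame, include_colony: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment dummies (control reference) + colony dummies."""
    treatments = [t for t in pd.unique(meta["treatment"]) if t != CONTROL]
    names = ["intercept"] + [f"treatment[{t}]" for t in treatments]
    cols = [np.ones(len(meta))]
    for t in treatments:
        cols.append((meta["treatment"] == t).to_numpy(dtype=float))
    if include_colony:
        colonies = sorted(pd.unique(meta["colony"]))
        for c in colonies[1:]:
            names.append(f"colony[{c}]")
            cols.append((meta["colony"] == c).to_numpy(dtype=float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )
    return X, names


# ---------------------------------------------------------------------------
# IRLS fit
# ---------------------------------------------------------------------------

def _fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    settings: DESettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for NB log-link GLMs sharing a design matrix.

    Parameters: ``Y`` genes x samples, ``X`` samples x p, ``offset`` log size
    factors, ``alpha`` per-gene dispersion.  Returns (beta, covariance
    diagonal, converged flag) per gene.
    """
    G, n = Y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    eta0 = np.log(Y + 0.5) - offset[None, :]
    beta = eta0 @ pinv.T
    converged = np.zeros(G, dtype=bool)
    A = np.empty((G, p, p))
    ridge = 1e-10 * np.eye(p)
    for _ in range(settings.max_irls_iter):
        eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        Wz = W * z
        A = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True) + ridge
        b = Wz @ X
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        bad = ~np.isfinite(new_beta).all(axis=1)
        if bad.any():
            new_beta[bad] = beta[bad]
        step = np.abs(new_beta - beta).max(axis=1)
        converged |= np.isfinite(step) & (step < settings.irls_tol) & ~bad
        beta = new_beta
        if converged.all():
            break
    # covariance from the Fisher information at the final iterate
    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True) + ridge
    cov = np.linalg.inv(A)
    var = np.einsum("gpp->gp", cov)
    return beta, var, converged


def fit_contrasts(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    settings: DESettings = DESettings(),
    contrasts: list[str] | None = None,
    include_colony: bool = True,
    factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit the NB GLM once and return a Wald DE table per requested contrast.

    ``counts`` is assumed expression-filtered; size factors and dispersions
    are computed here unless supplied.  Each table has the stable columns
    ``gene_id, base_mean, log2fc, se, wald_z, pvalue, fdr, significant``;
    genes whose IRLS fit did not converge carry missing statistics and are
    excluded from the BH adjustment.
    """
    settings.validate()
    meta = meta.set_index("sample_id").loc[counts.columns].reset_index()
    if factors is None:
        factors = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(
            counts, factors, meta, settings, include_colony=include_colony
        )
    if contrasts is None:
        contrasts = [t for t in pd.unique(meta["treatment"]) if t != CONTROL]
    for contrast in contrasts:
        if contrast not in set(meta["treatment"]):
            raise ValueError(f"contrast {contrast!r} not present in the sample table")

    X, names = _design_matrix(meta, include_colony=include_colony)
    Y = counts.to_numpy(dtype=float)
    offset = np.log(factors.to_numpy())
    beta, var, converged = _fit_nb_glm(Y, X, offset, dispersion.to_numpy(), settings)

    # Wald reference: Student t with the residual df of the design
    # (n - p, the df behind the gene-wise dispersion estimate).  With
    # unshrunk gene-wise dispersions a plain normal reference has slightly
    # inflated extreme tails; the t reference restores null uniformity.
    wald_df = float(len(meta) - X.shape[1])
    if wald_df < 1:
        wald_df = np.inf

    base_mean = (Y / factors.to_numpy()[None, :]).mean(axis=1)
    log2 = np.log(2.0)
    results: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        j = names.index(f"treatment[{contrast}]")
        b = beta[:, j]
        se_nat = np.sqrt(np.maximum(var[:, j], 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = b / se_nat
        pvalue = 2.0 * stats.t.sf(np.abs(z), wald_df)
        pvalue = np.where(converged & np.isfinite(z), pvalue, np.nan)
        fdr = bh_adjust(pvalue)
        table = pd.DataFrame(
            {
                "gene_id": counts.index,
                "base_mean": base_mean,
                "log2fc": b / log2,
                "se": se_nat / log2,
                "wald_z": z,
                "pvalue": pvalue,
                "fdr": fdr,
                "significant": fdr < settings.fdr_alpha,
            }
        ).set_index("gene_id", drop=False)
        table.index.name = None
        results[contrast] = table
    return results


def nb_wald(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    settings: DESettings = DESettings(),
    contrast: str = "",
    include_colony: bool = True,
) -> pd.DataFrame:
    """Wald DE table for a single treatment-vs-control contrast."""
    if not contrast:
        raise ValueError("a contrast (treatment label) is required")
    return fit_contrasts(
        counts, meta, settings, contrasts=[contrast], include_colony=include_colony
    )[contrast]


def de_pipeline(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    settings: DESettings = DESettings(),
    contrasts: list[str] | None = None,
    include_colony: bool = True,
) -> dict[str, pd.DataFrame]:
    """Filter + normalise + dispersion + Wald tests, one table per contrast."""
    filtered = filter_low_counts(counts, settings)
    return fit_contrasts(
        filtered, meta, settings, contrasts=contrasts, include_colony=include_colony
    )


def significant_genes(de_table: pd.DataFrame) -> list[str]:
    return de_table.loc[de_table["significant"], "gene_id"].to_list()


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotone enforcement.

    Missing values propagate and are excluded from the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    ps = p[valid]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[valid] = adj
    return out


# ---------------------------------------------------------------------------
# VST and PCA
# ---------------------------------------------------------------------------

def vst_transform(
    counts: pd.DataFrame,
    factors: pd.Series,
    settings: DESettings = DESettings(),
) -> pd.DataFrame:
    """Shifted-log variance-stabilising transform, log2(count/factor + pc)."""
    f = factors.to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / f[None, :] + settings.vst_pseudocount),
        index=counts.index,
        columns=counts.columns,
    )


def pca(transformed: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA of a genes x samples matrix via SVD after gene centring.

    Returns sample coordinates for every component and the variance fraction
    per component (summing to one when total variance is positive; all zero
    for a degenerate matrix).
    """
    if transformed.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    M = transformed.to_numpy(dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    U, S, _ = np.linalg.svd(M.T, full_matrices=False)
    coords = U * S
    total = float((S**2).sum())
    varfrac = S**2 / total if total > 0 else np.zeros_like(S)
    coord_df = pd.DataFrame(
        coords,
        index=transformed.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coord_df, varfrac
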