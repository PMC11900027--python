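"""Scheme-contrast statistics.

Quantifies how acute and chronic exposure differ beyond gene lists: the
amplitude of the most extreme expression changes (top-k Welch test), the
proportion of large (>= fourfold) changes, direction-of-change goodness of
fit, replicate-variance inflation on the VST scale, a generic Fisher/
hypergeometric gene-set enrichment, and two-sample KS / skewness utilities
used by the resampling diagnostics.

The replicate-variance contrast replaces a gamma GLMM with gene as a random
effect by an exactly paired per-gene log-SD difference: differencing the
acute and chronic log SDs eliminates the gene effect, and the scheme-by-DE-
status interaction becomes the difference in mean log-SD-difference between
DE and non-DE genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass(frozen=True)
class AmplitudeContrast:
    """Welch comparison of top-k |log2FC| amplitudes between two DE tables."""

    k: int
    mean_abs_lfc_a: float
    mean_abs_lfc_b: float
    ratio: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ProportionTest:
    """2x2 chi-square comparison of >= fourfold-change proportions."""

    threshold_log2: float
    table: tuple[tuple[int, int], tuple[int, int]]
    proportion_a: float
    proportion_b: float
    chi2: float
    p: float
    corrected: bool


@dataclass
class VarianceContrast:
    """Acute-vs-chronic replicate-SD contrast on the VST scale.

    ``coefficient`` is the mean log(SD_acute / SD_chronic) among DE genes
    minus that among non-DE genes (natural-log scale, so exp(coefficient) is
    the DE-specific SD inflation factor).
    """

    coefficient: float
    t: float
    df: float
    p: float
    n_de: int
    n_non_de: int
    n_excluded: int
    log_sd_diff: pd.Series


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite degrees of freedom, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate: no within-sample variability
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), float("nan"), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi2_2x2(table, corrected: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (optional Yates correction), 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: a row or column sums to zero")
    res = stats.chi2_contingency(t, correction=corrected)
    return float(res.statistic), float(res.pvalue)


def chi2_gof(observed, expected_proportions) -> tuple[float, float]:
    """Chi-square goodness of fit of counts against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions must align")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("expected proportions must sum to 1")
    if (props <= 0).any():
        raise ValueError("expected proportions must be positive")
    res = stats.chisquare(obs, f_exp=props * obs.sum())
    return float(res.statistic), float(res.pvalue)


def proportion_large_changes(
    de_a: pd.DataFrame, de_b: pd.DataFrame, threshold_log2: float = 2.0, corrected: bool = False
) -> ProportionTest:
    """Compare the share of significant genes with |log2FC| >= threshold."""
    cells = []
    props = []
    for de in (de_a, de_b):
        sig = de.loc[de["significant"]]
        if sig.empty:
            raise ValueError("a DE table has no significant genes")
        large = int((sig["log2fc"].abs() >= threshold_log2).sum())
        cells.append((large, len(sig) - large))
        props.append(large / len(sig))
    table = (cells[0], cells[1])
    if any(cells[0][j] + cells[1][j] == 0 for j in (0, 1)):
        # every gene falls in the same category in both tables (e.g. a zero
        # threshold makes all changes "large"): no association to test
        chi2, p = 0.0, 1.0
    else:
        chi2, p = chi2_2x2(table, corrected=corrected)
    return ProportionTest(
        threshold_log2=threshold_log2,
        table=table,
        proportion_a=props[0],
        proportion_b=props[1],
        chi2=chi2,
        p=p,
        corrected=corrected,
    )


def top_k_amplitude(
    de_a: pd.DataFrame, de_b: pd.DataFrame, k: int = 20, order_by: str = "lfc"
) -> AmplitudeContrast:
    """Welch test on the |log2FC| of the k most extreme significant genes.

    ``order_by='lfc'`` ranks by |log2FC| (default); ``order_by='fdr'`` ranks
    by adjusted p-value.
    """
    if k < 2:
        raise ValueError("k must be >= 2: Welch degrees of freedom need n >= 2 per side")
    if order_by not in ("lfc", "fdr"):
        raise ValueError("order_by must be 'lfc' or 'fdr'")
    tops = []
    for de in (de_a, de_b):
        sig = de.loc[de["significant"]].copy()
        if len(sig) < k:
            raise ValueError(
                f"only {len(sig)} significant genes; choose k <= that (got k={k})"
            )
        if order_by == "lfc":
            sig = sig.reindex(sig["log2fc"].abs().sort_values(ascending=False).index)
        else:
            sig = sig.sort_values("fdr", kind="stable")
        tops.append(sig["log2fc"].abs().to_numpy()[:k])
    t, df, p = welch_t(tops[0], tops[1])
    mean_a, mean_b = float(tops[0].mean()), float(tops[1].mean())
    return AmplitudeContrast(
        k=k,
        mean_abs_lfc_a=mean_a,
        mean_abs_lfc_b=mean_b,
        ratio=mean_a / mean_b,
        t=t,
        df=df,
        p=p,
    )


def variance_contrast(
    vst_matrix: pd.DataFrame, meta: pd.DataFrame, de_flags: pd.Series
) -> VarianceContrast:
    """Replicate-SD inflation of acute vs chronic samples, by DE status.

    The replicate SD of a gene is measured within each treatment group (so
    between-treatment expression differences do not contaminate it) and
    summarised per scheme as the mean log SD over that scheme's treatments.
    Genes with a zero SD in any treatment group are excluded (counted in
    ``n_excluded``).  The coefficient contrasts the mean paired log-SD
    difference (acute minus chronic) of DE genes against non-DE genes, with
    a Welch t between the two groups of differences; any replicate-number
    bias of log SD cancels in this difference of differences.
    """
    meta = meta.set_index("sample_id").loc[vst_matrix.columns]

    def scheme_log_sd(scheme: str) -> tuple[pd.Series, pd.Series]:
        logs = []
        for _, group in meta.loc[meta["scheme"] == scheme].groupby("treatment"):
            if len(group) < 2:
                raise ValueError("need at least two replicates per treatment group")
            sd = vst_matrix[group.index].std(axis=1, ddof=1)
            with np.errstate(divide="ignore"):
                logs.append(np.log(sd))
        if not logs:
            raise ValueError(f"no {scheme} samples present")
        stacked = pd.concat(logs, axis=1)
        return stacked.mean(axis=1), np.isfinite(stacked).all(axis=1)

    log_sd_a, ok_a = scheme_log_sd("acute")
    log_sd_c, ok_c = scheme_log_sd("chronic")
    ok = ok_a & ok_c
    n_excluded = int((~ok).sum())
    diff = log_sd_a[ok] - log_sd_c[ok]
    flags = de_flags.reindex(diff.index).astype(bool)
    d_de = diff[flags].to_numpy()
    d_null = diff[~flags].to_numpy()
    if len(d_de) < 2 or len(d_null) < 2:
        raise ValueError("need at least two DE and two non-DE genes")
    t, df, p = welch_t(d_de, d_null)
    return VarianceContrast(
        coefficient=float(d_de.mean() - d_null.mean()),
        t=t,
        df=df,
        p=p,
        n_de=len(d_de),
        n_non_de=len(d_null),
        n_excluded=n_excluded,
        log_sd_diff=diff,
    )


def fisher_enrichment(
    de_set, annotation: dict[str, set], pool
) -> pd.DataFrame:
    """One-sided hypergeometric (Fisher) enrichment of annotation terms.

    For each term, tests whether the DE set contains more term genes than
    expected under uniform sampling from the pool; BH adjustment across
    terms.  Terms with no gene in the pool are skipped with a warning column.
    """
    pool = set(pool)
    de = set(de_set) & pool
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & pool
        if not term_genes:
            continue
        k = len(term_genes & de)
        K = len(term_genes)
        n = len(de)
        N = len(pool)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, K - k
        c, d = n - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        rows.append({"term": term, "overlap": k, "term_size": K, "odds_ratio": odds, "p": p})
    result = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "odds_ratio", "p"])
    if not result.empty:
        result["fdr"] = bh_adjust(result["p"].to_numpy())
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov sup-distance with asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs at least one observation")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def skewness(x) -> float:
    """Standardised third central moment (bias-uncorrected)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("skewness needs at least three observations")
    if np.var(x) == 0:
        raise ValueError("skewness is undefined for a zero-variance sample")
    return float(stats.skew(x, bias=True))
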