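"""Robust normalization, nonparametric metric screening and PCA.

Every metric column is scaled by the robust Z-score

    z_i = (x_i - x_m) / NIQR,        NIQR = 0.7414 * IQR,

with x_m the column median and IQR the interquartile range from linearly
interpolated (type-7) quantiles; the 0.7414 factor makes NIQR a consistent
estimate of the standard deviation under normality while resisting
outliers.  Metrics are screened by a Kruskal-Wallis omnibus test over the
three experience groups, with pairwise Mann-Whitney comparisons reported
only for metrics whose omnibus test is significant, and the retained,
normalized metrics are summarized by PCA with loadings scaled as
eigenvector * sqrt(eigenvalue).

The rank tests are implemented here (with explicit exact-enumeration and
tie-correction policies) rather than delegated, so the test suite can
cross-check them against an independent implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

NIQR_FACTOR = 0.7414


# ---------------------------------------------------------------------------
# robust Z-score (Eq.-style median/NIQR normalization)


@dataclass
class NormalizationParams:
    """Per-metric median, IQR, NIQR and degenerate-scale flags."""

    table: pd.DataFrame  # columns: median, iqr, niqr, degenerate

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        out = values.copy().astype(float)
        for col in out.columns:
            row = self.table.loc[col]
            if row["degenerate"]:
                out[col] = 0.0
            else:
                out[col] = (out[col] - row["median"]) / row["niqr"]
        return out


def robust_z_normalize(
    values: pd.DataFrame,
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Columnwise robust Z-score; IQR-zero columns map to zeros and are flagged."""
    if values.shape[1] == 0 or values.shape[0] == 0:
        raise ValueError("empty feature table")
    rows = {}
    for col in values.columns:
        x = values[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError(f"column {col!r} has no finite values")
        q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear, type-7
        iqr = q75 - q25
        rows[col] = {
            "median": q50,
            "iqr": iqr,
            "niqr": NIQR_FACTOR * iqr,
            "degenerate": bool(iqr == 0.0),
        }
    params = NormalizationParams(pd.DataFrame.from_dict(rows, orient="index"))
    return params.transform(values), params


# ---------------------------------------------------------------------------
# rank tests


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square limit.

    All-identical pooled data yields (0.0, 1.0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    n_total = values.size
    ranks = rankdata(values)
    h = (
        12.0 / (n_total * (n_total + 1))
        * sum(np.sum(ranks[groups == g]) ** 2 / (groups == g).sum() for g in levels)
        - 3.0 * (n_total + 1)
    )
    correction = 1.0 - _tie_term(values) / (n_total**3 - n_total)
    if correction == 0.0:  # every value identical
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    return float(h), float(chi2.sf(h, df=len(samples) - 1))


def _u_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of the Mann-Whitney U statistic (no ties).

    counts[u] = number of the C(n1+n2, n1) rank arrangements giving U = u;
    built by the standard Gaussian-binomial recurrence.
    """
    max_u = n1 * n2
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # multiply the generating function by (1 - x^(n2+k)) / (1 - x^k) stepwise
    for k in range(1, n1 + 1):
        new = np.zeros_like(counts)
        # divide by (1 - x^k): prefix recurrence on the cumulative series
        for u in range(max_u + 1):
            new[u] = counts[u] + (new[u - k] if u >= k else 0.0)
        # multiply by (1 - x^(n2+k))
        for u in range(max_u, -1, -1):
            if u >= n2 + k:
                new[u] -= new[u - (n2 + k)]
        counts = new
    return counts


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U reported for the first sample.

    Exact p by enumeration of the null U distribution when n1*n2 <= 400 and
    the pooled data has no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(np.sum(ranks[:n1]))
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u1 = n1 * n2 - u1  # rank-sum gives U for 'b>a'; flip to count a>b pairs
    has_ties = np.unique(pooled).size < pooled.size

    if n1 * n2 <= 400 and not has_ties:
        counts = _u_count_distribution(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        p_le = counts[: u_int + 1].sum() / total
        p_ge = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u1), float(p)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if sigma_sq <= 0:
        return float(u1), 1.0
    # continuity correction of 0.5 toward the mean
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(sigma_sq)
    return float(u1), float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass
class WilcoxonResult:
    statistic: float
    p: float
    n_nonzero: int
    degenerate: bool = False


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the statistic is min(W+, W-).  Exact p by
    enumeration of the 2^n sign patterns for <= 25 nonzero pairs (tied
    |differences| handled by conditioning on the observed mean ranks), else
    the normal approximation with continuity and tie corrections.  All-zero
    differences give p = 1 with a degeneracy flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p=1.0, n_nonzero=0, degenerate=True)
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    stat = min(w_plus, w_minus)
    has_ties = np.unique(absd).size < n

    if n <= 25:
        # DP over sign patterns; mean ranks are multiples of 1/2, so doubled
        # ranks are integers and the rank-sum distribution stays exact
        ranks2 = np.rint(2.0 * ranks).astype(int)
        max_w = int(ranks2.sum())
        counts = np.zeros(max_w + 1)
        counts[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: max_w + 1 - r]
            counts = counts + shifted
        total = counts.sum()
        w_int = int(round(2.0 * w_plus))
        p_le = counts[: w_int + 1].sum() / total
        p_ge = counts[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=stat, p=float(p), n_nonzero=n)

    mu = n * (n + 1) / 4.0
    tie = _tie_term(absd)
    sigma_sq = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    if sigma_sq <= 0:
        return WilcoxonResult(statistic=stat, p=1.0, n_nonzero=n, degenerate=True)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(sigma_sq)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=stat, p=p, n_nonzero=n)


def friedman_test(accuracy_matrix) -> tuple[float, float]:
    """Friedman chi-square over an (n_blocks, k_treatments) matrix.

    Within-block mean ranks for ties; the statistic
    chi2_F = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)
    is divided by the tie-correction factor; p from chi-square, df = k-1.
    """
    x = np.asarray(accuracy_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    n, k = x.shape
    ranks = np.apply_along_axis(rankdata, 1, x)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(rj**2)) - 3.0 * n * (k + 1)
    tie_sum = sum(_tie_term(row) for row in x)
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0.0:  # every block entirely tied
        return 0.0, 1.0
    stat /= correction
    stat = max(stat, 0.0)
    return float(stat), float(chi2.sf(stat, df=k - 1))


# ---------------------------------------------------------------------------
# screening


@dataclass
class GroupComparisonResult:
    """Per-metric omnibus and pairwise test results."""

    table: pd.DataFrame  # index metric; columns H, p, retained, pairwise p's

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


PAIRS = (("expert", "intermediate"), ("expert", "novice"), ("intermediate", "novice"))


def screen_metrics(
    values: pd.DataFrame,
    labels3: pd.Series,
    alpha: float = 0.05,
    holm: bool = False,
) -> GroupComparisonResult:
    """Retain metrics whose Kruskal-Wallis omnibus p is below alpha.

    Pairwise Mann-Whitney results are computed only for retained metrics.
    Trials with a missing value are dropped per metric (listwise within the
    metric's test).
    """
    rows = {}
    for col in values.columns:
        x = values[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        h, p = kruskal_wallis(x[ok], labels3.to_numpy()[ok])
        rows[col] = {"H": h, "p": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    pvals = table["p"].to_numpy()
    effective = holm_adjust(pvals) if holm else pvals
    table["p_adjusted"] = effective
    table["retained"] = effective < alpha
    for g1, g2 in PAIRS:
        table[f"p_{g1}_vs_{g2}"] = np.nan
    for col in table.index[table["retained"]]:
        x = values[col].to_numpy(dtype=float)
        lab = labels3.to_numpy()
        ok = np.isfinite(x)
        for g1, g2 in PAIRS:
            _, p = mann_whitney(x[ok & (lab == g1)], x[ok & (lab == g2)])
            table.loc[col, f"p_{g1}_vs_{g2}"] = p
    return GroupComparisonResult(table=table)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Loadings (eigenvector * sqrt(eigenvalue)), scores and variance shares."""

    loadings: pd.DataFrame           # metrics x components
    scores: pd.DataFrame             # trials x components
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray


def pca_fit(normalized: pd.DataFrame) -> PCAResult:
    """PCA of the sample covariance of robust-z features.

    The data is centered but *not* re-standardized to unit variance (the
    single normalization is the robust Z-score), so loadings can exceed 1
    in magnitude for heavy-tailed metrics.  Component signs are fixed so
    each component's largest-magnitude loading is positive; zero-variance
    components sort last.
    """
    if normalized.shape[1] < 2 or normalized.shape[0] < 3:
        raise ValueError("need >= 2 metrics and >= 3 trials")
    x = normalized.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(eigval)
    scores = centered @ eigvec
    total = eigval.sum()
    evr = eigval / total if total > 0 else np.zeros_like(eigval)
    comp_names = [f"PC{j + 1}" for j in range(eigval.size)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=normalized.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=normalized.index, columns=comp_names),
        explained_variance_ratio=evr,
        eigenvalues=eigval,
    )
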