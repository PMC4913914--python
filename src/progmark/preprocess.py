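"""Sample QC, gene pre-filtering and empirical-Bayes covariate adjustment.

The preprocessing stages mirror a standard blood-microarray workflow:
degraded samples are dropped on RNA Integrity Number (RIN), multivariate
outlier samples are flagged on the first principal components, the least
variable genes are removed, and hybridization-batch plus age/gender
effects are removed with a parametric empirical-Bayes (ComBat-style)
adjustment that leaves the biological group signal in place.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["filter_by_rin", "variance_prefilter", "pca_outliers", "eb_adjust"]


def filter_by_rin(
    sheet: pd.DataFrame, min_rin: float = 6.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose RIN falls below ``min_rin``.

    Removal is strict (``rin < min_rin``); a sample at exactly the
    threshold is retained.  Sample order is preserved.

    Returns the filtered sheet and the removed sample ids.
    """
    if len(sheet) == 0:
        return sheet.copy(), []
    rin = pd.to_numeric(sheet["rin"], errors="coerce")
    if rin.isna().any():
        bad = sheet.loc[rin.isna(), "sample_id"].tolist()
        raise ValueError(f"missing RIN for samples: {bad}")
    keep = rin >= min_rin
    removed = sheet.loc[~keep, "sample_id"].tolist()
    return sheet.loc[keep].reset_index(drop=True), removed


def variance_prefilter(
    matrix: pd.DataFrame, drop_fraction: float = 0.15
) -> tuple[pd.DataFrame, int]:
    """Remove the least-variable ("non-variant") genes.

    The ``k = ceil(drop_fraction * n_genes)`` genes with the lowest sample
    variance are removed; this rounding is what maps a 20,014-gene matrix
    to 17,011 retained genes at the default 15%.  Variance ties are broken
    by gene id (lexicographic), making the removed set deterministic.  The
    retained matrix preserves the input gene order.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    if matrix.shape[1] < 2:
        raise ValueError("variance_prefilter needs at least 2 samples")
    k = int(np.ceil(drop_fraction * matrix.shape[0]))
    if k == 0:
        return matrix.copy(), 0
    variances = matrix.var(axis=1, ddof=1)
    order = pd.DataFrame(
        {"var": variances, "gene": variances.index}
    ).sort_values(["var", "gene"], kind="mergesort")
    dropped = set(order.index[:k])
    keep_mask = ~matrix.index.isin(dropped)
    return matrix.loc[keep_mask], k


def pca_outliers(
    matrix: pd.DataFrame, n_components: int = 2, k_sd: float = 3.0
) -> list[str]:
    """Flag outlier samples on the first principal components.

    Genes are centered, samples are scored on the first ``n_components``
    PCs, and a sample is flagged when its score on any retained component
    lies more than ``k_sd`` robust SDs (median +/- k * 1.4826 * MAD) from
    that component's median.  Deterministic given the input.
    """
    n_samples = matrix.shape[1]
    if n_samples < 4:
        raise ValueError("pca_outliers needs at least 4 samples")
    if n_components >= n_samples:
        raise ValueError(
            f"n_components={n_components} must be < n_samples={n_samples}"
        )
    X = matrix.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    flagged: set[str] = set()
    for j in range(n_components):
        s = scores[:, j]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            continue
        idx = np.nonzero(np.abs(s - med) > k_sd * robust_sd)[0]
        flagged.update(matrix.columns[i] for i in idx)
    return [c for c in matrix.columns if c in flagged]


def _design(sheet: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + covariate columns (numeric as-is, categorical dummy-coded)."""
    cols = [np.ones(len(sheet))]
    for cov in covariates:
        col = sheet[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _it_sol(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB estimates of per-gene batch location/scale for one batch.

    Standard parametric empirical-Bayes scheme: batch means are shrunk
    toward a Normal prior, batch variances toward an Inverse-Gamma prior,
    iterating the two conditional posterior modes to convergence.
    """
    n = np.sum(~np.isnan(z_batch), axis=1)
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        ssq = np.nansum((z_batch - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * ssq + b_prior) / (0.5 * n + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-30)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-30)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def eb_adjust(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    batch_key: str = "batch",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Remove batch and covariate effects by parametric empirical Bayes.

    The scheme is the ComBat one: (1) fit per-gene means plus fixed
    covariate terms and batch indicators by least squares and standardize
    the data gene-wise; (2) estimate per-batch, per-gene location and
    scale on the standardized data and shrink them toward Normal /
    Inverse-Gamma priors whose hyperparameters are estimated across genes
    (method of moments); (3) subtract the shrunken batch effects, rescale,
    and back-transform to the original scale with the covariate estimates
    restored.  The biological group label is deliberately NOT part of the
    design, so the slow-vs-rapid signal passes through.

    Parameters
    ----------
    matrix : genes x samples log2 expression.
    sheet : sample metadata aligned to ``matrix`` columns via ``sample_id``.
    batch_key : column of ``sheet`` holding the batch factor.
    covariates : fixed-effect columns to protect and restore
        (default ``["age", "gender"]``).
    """
    if covariates is None:
        covariates = ["age", "gender"]
    sheet = sheet.set_index("sample_id").loc[list(matrix.columns)]
    batches = sheet[batch_key].astype(str)
    levels = sorted(batches.unique())
    counts = batches.value_counts()
    singletons = [b for b in levels if counts[b] < 2]
    if singletons:
        raise ValueError(
            f"batches {singletons} have fewer than 2 samples; "
            "merge them with a neighbouring batch before adjustment"
        )
    if len(levels) < 2:
        return matrix.copy()
    if "group" in sheet.columns:
        for b in levels:
            if sheet.loc[batches == b, "group"].nunique() == 1:
                warnings.warn(
                    f"batch {b!r} contains a single biological group; "
                    "batch and group are confounded for it",
                    UserWarning,
                    stacklevel=2,
                )

    Y = matrix.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samples = Y.shape
    batch_idx = [np.nonzero((batches == b).to_numpy())[0] for b in levels]
    n_per_batch = np.array([len(ix) for ix in batch_idx], dtype=float)

    # Design: batch indicators (no intercept) followed by fixed covariates.
    B = np.zeros((n_samples, len(levels)))
    for j, ix in enumerate(batch_idx):
        B[ix, j] = 1.0
    C = _design(sheet.reset_index(), covariates)[:, 1:]  # drop intercept
    X = np.hstack([B, C]) if C.shape[1] else B

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p_design, genes)
    batch_effects = beta[: len(levels), :]           # per-batch gene means
    grand_mean = (n_per_batch / n_samples) @ batch_effects  # (genes,)
    cov_part = (C @ beta[len(levels):, :]).T if C.shape[1] else 0.0

    stand_mean = grand_mean[:, None] + cov_part
    resid = Y - (X @ beta).T
    var_pooled = np.mean(resid**2, axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    Z_adj = Z.copy()
    for j, ix in enumerate(batch_idx):
        zb = Z[:, ix]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        # Inverse-Gamma hyperparameters by method of moments.
        m, v = delta_hat.mean(), delta_hat.var(ddof=1)
        v = max(v, 1e-12)
        a_prior = (2 * v + m**2) / v
        b_prior = (m * v + m**3) / v
        gamma_star, delta_star = _it_sol(
            zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior
        )
        Z_adj[:, ix] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    Y_adj = Z_adj * sd + stand_mean
    return pd.DataFrame(Y_adj, index=matrix.index, columns=matrix.columns)
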