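"""Two-group differential expression by three procedures and consensus.

Each gene is tested for a slow-vs-rapid expression difference three ways:

* a one-way F test (ANOVA; with two groups this is the squared pooled t),
* a bootstrap achieved-significance-level t-test — both groups are
  centered to the grand mean to enforce the null, stratified resamples are
  drawn with replacement, and the Welch t is recomputed on each,
* a permutation t-test on relabelled samples, enumerated exhaustively when
  the number of distinct label assignments is small enough and Monte-Carlo
  otherwise.

Genes significant under all three at their configured thresholds form the
consensus signature.  Monte-Carlo p-values use the +1 smoothing
``p = (1 + #{|t*| >= |t_obs|}) / (B + 1)``, which keeps them strictly
positive and type-I calibrated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t",
    "anova_f",
    "bootstrap_ttest",
    "permutation_ttest",
    "consensus",
    "de_table",
    "Thresholds",
]

logger = logging.getLogger(__name__)

#: exhaustive permutation mode engages when C(n, n_A) is at most this
EXHAUSTIVE_LIMIT = 20_000

#: chunk of resampling iterations processed at once (memory / speed balance)
_CHUNK = 256


@dataclass(frozen=True)
class Thresholds:
    """Per-test significance thresholds for consensus calling."""

    anova: float = 0.05
    boot: float = 0.005
    perm: float = 0.05


def _welch_from_moments(
    mx: np.ndarray, vx: np.ndarray, nx: int, my: np.ndarray, vy: np.ndarray, ny: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and Welch-Satterthwaite df from group moments."""
    sex, sey = vx / nx, vy / ny
    se2 = sex + sey
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (sex**2 / (nx - 1) + sey**2 / (ny - 1))
    return t, df


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t-test between two samples.

    Returns ``(t, df, p)`` with a two-sided p from the t distribution.
    Degenerate rows follow the documented conventions: both groups constant
    with equal means gives ``p = 1`` (t = 0); both constant with unequal
    means gives ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(len(x) + len(y) - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        logger.info("welch_t: zero variance in both groups with unequal means")
        return math.copysign(math.inf, x.mean() - y.mean()), df, 0.0
    t, df = _welch_from_moments(x.mean(), vx, len(x), y.mean(), vy, len(y))
    p = 2.0 * stats.t.sf(abs(float(t)), float(df))
    return float(t), float(df), min(p, 1.0)


def _split(matrix: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups)
    if not groups.index.equals(pd.RangeIndex(len(groups))):
        groups = groups.reindex(matrix.columns)
    labels = pd.unique(groups.to_numpy())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    g = groups.to_numpy()
    X = matrix.to_numpy(dtype=float)
    return X[:, g == labels[0]], X[:, g == labels[1]]


def _welch_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t, df = _welch_from_moments(
        X.mean(axis=1), X.var(axis=1, ddof=1), X.shape[1],
        Y.mean(axis=1), Y.var(axis=1, ddof=1), Y.shape[1],
    )
    # degenerate rows: both groups constant
    both_const = (X.var(axis=1, ddof=1) == 0) & (Y.var(axis=1, ddof=1) == 0)
    if both_const.any():
        eq = both_const & (X.mean(axis=1) == Y.mean(axis=1))
        t = np.where(eq, 0.0, t)
        df = np.where(both_const, X.shape[1] + Y.shape[1] - 2, df)
        t = np.where(both_const & ~eq,
                     np.sign(X.mean(axis=1) - Y.mean(axis=1)) * np.inf, t)
    return t, df


def anova_f(matrix: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """One-way ANOVA F-test per gene.

    With exactly two groups the F statistic is the square of the
    pooled-variance t and the p-values coincide.  Constant rows get
    ``p = 1`` by convention.
    """
    groups = pd.Series(groups)
    if not groups.index.equals(pd.RangeIndex(len(groups))):
        groups = groups.reindex(matrix.columns)
    labels = pd.unique(groups.to_numpy())
    if len(labels) < 2:
        raise ValueError("anova_f needs at least two groups")
    X = matrix.to_numpy(dtype=float)
    g = groups.to_numpy()
    parts = [X[:, g == lab] for lab in labels]
    if any(part.shape[1] < 2 for part in parts):
        raise ValueError("each group needs at least 2 samples")
    n = X.shape[1]
    k = len(parts)
    grand = X.mean(axis=1)
    ss_between = sum(
        part.shape[1] * (part.mean(axis=1) - grand) ** 2 for part in parts
    )
    ss_within = sum(
        ((part - part.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for part in parts
    )
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(F, df1, df2)
    constant = (ss_between + ss_within) == 0
    if constant.any():
        logger.info("anova_f: %d constant gene rows given p = 1", constant.sum())
        p = np.where(constant, 1.0, p)
    # zero within-variance but real between-variance: p -> 0
    p = np.where(np.isnan(p) & ~constant, 0.0, p)
    return pd.Series(p, index=matrix.index, name="p_anova")


def bootstrap_ttest(
    matrix: pd.DataFrame,
    groups: pd.Series,
    B: int = 1000,
    seed: int | None = 0,
) -> pd.Series:
    """Bootstrap achieved-significance level per gene.

    The null is enforced by centering each group's values to the grand
    mean; ``B`` stratified with-replacement resamples are drawn, the Welch
    t recomputed on each, and ``p = (1 + #{|t*| >= |t_obs|}) / (B + 1)``.
    Identical seeds give identical output.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    X, Y = _split(matrix, groups)
    t_obs, _ = _welch_rows(X, Y)
    t_obs = np.abs(np.nan_to_num(t_obs, nan=0.0))
    grand = matrix.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True) + grand
    Yc = Y - Y.mean(axis=1, keepdims=True) + grand
    rng = np.random.default_rng(seed)
    exceed = np.zeros(matrix.shape[0], dtype=np.int64)
    nx, ny = X.shape[1], Y.shape[1]
    for start in range(0, B, _CHUNK):
        b = min(_CHUNK, B - start)
        ix = rng.integers(0, nx, size=(b, nx))
        iy = rng.integers(0, ny, size=(b, ny))
        Xb = Xc[:, ix]  # genes x b x nx
        Yb = Yc[:, iy]
        t_star, _ = _welch_from_moments(
            Xb.mean(axis=2), Xb.var(axis=2, ddof=1), nx,
            Yb.mean(axis=2), Yb.var(axis=2, ddof=1), ny,
        )
        t_star = np.abs(np.nan_to_num(t_star, nan=0.0))
        exceed += (t_star >= t_obs[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (B + 1.0)
    return pd.Series(p, index=matrix.index, name="p_boot")


def _perm_pvalues(
    X: np.ndarray, assignment_rows: np.ndarray, n_a: int, t_obs: np.ndarray,
    smoothing: bool,
) -> np.ndarray:
    """Count |t*| >= |t_obs| over the given label assignments (rows of
    column indices for group A; the complement forms group B)."""
    n_genes, n = X.shape
    exceed = np.zeros(n_genes, dtype=np.int64)
    all_cols = np.arange(n)
    for start in range(0, len(assignment_rows), _CHUNK):
        chunk = assignment_rows[start:start + _CHUNK]
        b = len(chunk)
        mask = np.zeros((b, n), dtype=bool)
        mask[np.arange(b)[:, None], chunk] = True
        comp = np.where(~mask)[1].reshape(b, n - n_a)
        Xa = X[:, chunk]            # genes x b x n_a
        Xb = X[:, comp]
        t_star, _ = _welch_from_moments(
            Xa.mean(axis=2), Xa.var(axis=2, ddof=1), n_a,
            Xb.mean(axis=2), Xb.var(axis=2, ddof=1), n - n_a,
        )
        t_star = np.abs(np.nan_to_num(t_star, nan=0.0))
        exceed += (t_star >= t_obs[:, None]).sum(axis=1)
        del mask, comp, Xa, Xb
    C = len(assignment_rows)
    if smoothing:
        return (1.0 + exceed) / (C + 1.0)
    return exceed / C


def permutation_ttest(
    matrix: pd.DataFrame,
    groups: pd.Series,
    B: int = 10_000,
    seed: int | None = 0,
    exhaustive: bool | None = None,
) -> pd.Series:
    """Permutation t-test per gene (two-sided).

    Group labels are reassigned and the Welch t recomputed.  When the
    number of distinct assignments ``C(n, n_A)`` is at most 20,000 (or
    ``exhaustive=True``), ALL assignments are enumerated and
    ``p = #{|t*| >= |t_obs|} / C`` is exact (the identity assignment makes
    it strictly positive).  Otherwise ``B`` random relabellings are drawn
    and the +1-smoothed Monte-Carlo estimate is returned.
    """
    X, Y = _split(matrix, groups)
    n_a, n_b = X.shape[1], Y.shape[1]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b
    t_obs, _ = _welch_rows(X, Y)
    t_obs = np.abs(np.nan_to_num(t_obs, nan=0.0))
    pooled = np.hstack([X, Y])
    n_assign = math.comb(n, n_a)
    if exhaustive is None:
        exhaustive = n_assign <= EXHAUSTIVE_LIMIT
    if exhaustive:
        rows = np.array(list(combinations(range(n), n_a)), dtype=np.intp)
        p = _perm_pvalues(pooled, rows, n_a, t_obs, smoothing=False)
        # observed assignment always attains |t_obs|, so p >= 1/C
        p = np.maximum(p, 1.0 / n_assign)
    else:
        if B < 100:
            raise ValueError(f"B must be >= 100 in Monte-Carlo mode, got {B}")
        rng = np.random.default_rng(seed)
        rows = np.empty((B, n_a), dtype=np.intp)
        for i in range(B):
            rows[i] = rng.choice(n, size=n_a, replace=False)
        p = _perm_pvalues(pooled, rows, n_a, t_obs, smoothing=True)
    return pd.Series(p, index=matrix.index, name="p_perm")


@dataclass
class ConsensusResult:
    """Per-test significant gene lists and their intersection."""

    anova: list[str]
    boot: list[str]
    perm: list[str]
    intersection: list[str] = field(default_factory=list)


def consensus(
    results: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> ConsensusResult:
    """Call the consensus signature from a per-gene result table.

    ``results`` must hold columns ``p_anova``, ``p_boot`` and ``p_perm``.
    Genes at or below each test's threshold form that test's list; the
    consensus is the intersection (its size is bounded by the smallest
    per-test list).  Output order follows the table's gene order.
    """
    for col in ("p_anova", "p_boot", "p_perm"):
        if col not in results.columns:
            raise ValueError(f"results lacks column {col!r}")
    sig = {
        "anova": results.index[results["p_anova"] <= thresholds.anova],
        "boot": results.index[results["p_boot"] <= thresholds.boot],
        "perm": results.index[results["p_perm"] <= thresholds.perm],
    }
    inter = results.index[
        (results["p_anova"] <= thresholds.anova)
        & (results["p_boot"] <= thresholds.boot)
        & (results["p_perm"] <= thresholds.perm)
    ]
    return ConsensusResult(
        anova=list(sig["anova"]),
        boot=list(sig["boot"]),
        perm=list(sig["perm"]),
        intersection=list(inter),
    )


def de_table(
    matrix: pd.DataFrame,
    groups: pd.Series,
    B_boot: int = 1000,
    B_perm: int = 10_000,
    seed: int | None = 0,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Full per-gene differential-expression table (all three tests).

    Columns: group means, ``log2_fc`` (rapid minus slow when groups are
    labelled so, otherwise second-level minus first), Welch ``t_stat``,
    the three p-values, per-test flags and the ``consensus`` flag.
    """
    groups = pd.Series(groups)
    if not groups.index.equals(pd.RangeIndex(len(groups))):
        groups = groups.reindex(matrix.columns)
    labels = list(pd.unique(groups.to_numpy()))
    if set(labels) == {"slow", "rapid"}:
        labels = ["slow", "rapid"]
    g = groups.to_numpy()
    X = matrix.to_numpy(dtype=float)
    A = X[:, g == labels[0]]
    Bm = X[:, g == labels[1]]
    t, _ = _welch_rows(A, Bm)
    out = pd.DataFrame(
        {
            f"mean_{labels[0]}": A.mean(axis=1),
            f"mean_{labels[1]}": Bm.mean(axis=1),
            "log2_fc": Bm.mean(axis=1) - A.mean(axis=1),
            "t_stat": t,
        },
        index=matrix.index,
    )
    out["p_anova"] = anova_f(matrix, groups)
    out["p_boot"] = bootstrap_ttest(matrix, groups, B=B_boot, seed=seed)
    out["p_perm"] = permutation_ttest(
        matrix, groups, B=B_perm, seed=None if seed is None else seed + 1
    )
    out["sig_anova"] = out["p_anova"] <= thresholds.anova
    out["sig_boot"] = out["p_boot"] <= thresholds.boot
    out["sig_perm"] = out["p_perm"] <= thresholds.perm
    out["consensus"] = out["sig_anova"] & out["sig_boot"] & out["sig_perm"]
    return out
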