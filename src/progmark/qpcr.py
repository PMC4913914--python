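"""Relative qPCR quantification by the comparative Ct (ddCt) method.

Replicate Ct values are collapsed per sample x gene (flagging noisy
triplicates), normalized against a housekeeping gene (dCt = Ct_target -
Ct_housekeeping, which cancels per-sample loading differences), and group
fold changes computed as 2^-ddCt with ddCt = mean dCt(rapid) - mean
dCt(slow).  A fold change above 1 means up-regulation in the rapid group.
Group differences of dCt are tested with Welch's t at the patient level
(replicates are collapsed first).  Amplification efficiency is assumed to
be 2 (perfect doubling per cycle), as validated assays confirm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import welch_t

__all__ = ["collapse_replicates", "delta_ct", "fold_change",
           "group_ttest_dct", "qpcr_pipeline"]


def collapse_replicates(table: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Average replicate Ct values per sample x gene.

    Returns a frame with columns ``mean_ct``, ``sd_ct``, ``n_rep`` and
    ``flag``: ``"high_sd"`` when the replicate SD exceeds ``max_sd``
    cycles, ``"n=1"`` for single replicates, empty otherwise.
    """
    if len(table) == 0:
        raise ValueError("empty Ct table")
    grouped = table.groupby(["sample_id", "gene_id"])["ct"]
    out = grouped.agg(mean_ct="mean", sd_ct=lambda s: s.std(ddof=1), n_rep="size")
    out = out.reset_index()
    flags = np.where(out["n_rep"] == 1, "n=1", "")
    flags = np.where(out["sd_ct"].fillna(0.0) > max_sd, "high_sd", flags)
    out["flag"] = flags
    return out


def delta_ct(mean_ct: pd.DataFrame, housekeeping: str) -> pd.DataFrame:
    """Normalize mean Ct against the housekeeping gene, per sample.

    dCt = Ct_target - Ct_housekeeping; the housekeeping gene's own dCt is
    0 by construction.  Adding a constant to every Ct of a sample (a
    loading difference) leaves dCt unchanged.
    """
    hk = mean_ct.loc[mean_ct["gene_id"] == housekeeping]
    hk_by_sample = hk.set_index("sample_id")["mean_ct"]
    samples = mean_ct["sample_id"].unique()
    missing = [s for s in samples if s not in hk_by_sample.index]
    if missing:
        raise ValueError(
            f"housekeeping gene {housekeeping!r} missing for samples: {missing}"
        )
    out = mean_ct.copy()
    out["delta_ct"] = out["mean_ct"] - out["sample_id"].map(hk_by_sample)
    return out


def fold_change(dct: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene ddCt and fold change between rapid and slow groups.

    ddCt = mean dCt(rapid) - mean dCt(slow); fold = 2^-ddCt.  Requires
    both groups for every gene.
    """
    group_of = pd.Series(groups)
    d = dct.copy()
    d["group"] = d["sample_id"].map(group_of)
    if d["group"].isna().any():
        missing = d.loc[d["group"].isna(), "sample_id"].unique().tolist()
        raise ValueError(f"no group for samples: {missing}")
    rows = []
    for gene, sub in d.groupby("gene_id", sort=False):
        means = sub.groupby("group")["delta_ct"].mean()
        if "slow" not in means or "rapid" not in means:
            raise ValueError(f"gene {gene!r} lacks one of the groups")
        ddct = means["rapid"] - means["slow"]
        rows.append((gene, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(rows, columns=["gene_id", "ddct", "fold"]).set_index(
        "gene_id"
    )


def group_ttest_dct(dct: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Welch t-test of dCt between groups, per gene (two-sided)."""
    group_of = pd.Series(groups)
    d = dct.copy()
    d["group"] = d["sample_id"].map(group_of)
    rows = []
    for gene, sub in d.groupby("gene_id", sort=False):
        x = sub.loc[sub["group"] == "slow", "delta_ct"].to_numpy()
        y = sub.loc[sub["group"] == "rapid", "delta_ct"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 samples per group")
        t, _, p = welch_t(x, y)
        rows.append((gene, t, p))
    return pd.DataFrame(rows, columns=["gene_id", "t", "p"]).set_index("gene_id")


def qpcr_pipeline(
    table: pd.DataFrame,
    groups: pd.Series,
    housekeeping: str = "RPLP0",
    max_sd: float = 0.5,
) -> pd.DataFrame:
    """Replicate collapse -> dCt -> fold change -> group t-test.

    Returns one row per target gene (the housekeeping gene is dropped)
    with ``ddct``, ``fold``, ``t`` and ``p``.
    """
    collapsed = collapse_replicates(table, max_sd=max_sd)
    dct = delta_ct(collapsed, housekeeping)
    dct = dct.loc[dct["gene_id"] != housekeeping]
    folds = fold_change(dct, groups)
    tests = group_ttest_dct(dct, groups)
    return folds.join(tests)
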