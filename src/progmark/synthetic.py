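"""Synthetic cohorts with known ground truth.

Generates log2 expression matrices, sample sheets and qPCR Ct tables with
the statistical structure the downstream analysis assumes: a two-group
(slow / rapid progression) blood cohort with group effects on a minority of
genes, hybridization-batch shifts, linear age and additive gender effects,
Gaussian per-gene noise on the log2 scale, a few degraded (low-RIN) samples
and a few multivariate outlier samples.

The defaults mirror the study design this pipeline targets: 33 slow + 34
rapid samples on a 20,014-gene matrix, 3 low-RIN samples and 2 outliers.
Every run carries a :class:`Truth` record naming the differentially
expressed genes, their injected log2 effects, and the planted outlier and
low-RIN samples, so that recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "Truth", "simulate_cohort", "simulate_ct_table"]

#: fraction of genes shifted in a planted outlier sample.  Outliers are
#: global additive shifts on a minority of genes so that they separate on
#: the first principal components without dominating every gene.
OUTLIER_GENE_FRACTION = 0.30


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated two-group expression cohort.

    All effect and noise scales are in log2 expression units.  The default
    shape is the 67-sample / 20,014-gene design of the target study, with
    200 true differentially expressed genes (``frac_de * n_genes`` must be
    an integer count).
    """

    n_slow: int = 33
    n_rapid: int = 34
    n_genes: int = 20014
    frac_de: float = 200 / 20014
    effect_size: float = 1.0          # group mean shift for DE genes (log2)
    effect_size_sd: float = 0.0       # per-gene spread of the shift
    noise_sd: float = 0.5             # per-gene Gaussian noise (log2)
    n_batches: int = 3
    batch_shift_sd: float = 0.3       # SD of per-gene, per-batch shifts
    age_mean: float = 68.0            # years; cohort is elderly PD patients
    age_sd: float = 8.5
    age_effect_sd: float = 0.005      # log2 units per year, per gene
    gender_effect_sd: float = 0.1     # additive male-vs-female shift, per gene
    n_low_rin: int = 3                # samples with degraded RNA (RIN < 6)
    n_outliers: int = 2
    outlier_shift: float = 6.0        # additive shift on 30% of genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError(f"n_genes must be >= 10, got {self.n_genes}")
        for name in ("n_slow", "n_rapid", "n_batches", "n_low_rin", "n_outliers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("effect_size_sd", "noise_sd", "batch_shift_sd", "age_sd",
                     "age_effect_sd", "gender_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError(f"frac_de must be in [0, 1], got {self.frac_de}")
        n_de = self.frac_de * self.n_genes
        if abs(n_de - round(n_de)) > 1e-6:
            raise ValueError(
                f"frac_de * n_genes = {n_de!r} is not an integer count of DE genes"
            )
        if self.n_low_rin + self.n_outliers > self.n_slow + self.n_rapid:
            raise ValueError("n_low_rin + n_outliers exceeds the cohort size")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))

    @property
    def n_samples(self) -> int:
        return self.n_slow + self.n_rapid


@dataclass(frozen=True)
class Truth:
    """Ground truth emitted alongside a simulated cohort."""

    de_gene_ids: frozenset[str]
    effects: pd.Series = field(repr=False)     # per-gene true log2 group shift
    outlier_sample_ids: frozenset[str]
    low_rin_sample_ids: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        """Per-gene truth table (gene_id, is_de, effect)."""
        return pd.DataFrame(
            {
                "is_de": self.effects.index.isin(self.de_gene_ids).astype(int),
                "effect": self.effects,
            }
        ).rename_axis("gene_id")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n_slow: int, n_rapid: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n_slow + 1)] + [
        f"R{i:03d}" for i in range(1, n_rapid + 1)
    ]


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, Truth]:
    """Simulate a two-group expression cohort.

    The expression value of gene g in sample i is

        mu_g + beta_g * 1[rapid] + gamma_{g, batch(i)}
             + a_g * (age_i - mean age) + s_g * 1[male] + eps_{gi}

    with ``eps ~ Normal(0, noise_sd^2)``, ``beta_g = 0`` for non-DE genes,
    and an additional ``outlier_shift`` added to 30% of genes for each
    planted outlier sample.  RIN values are drawn >= 6.5 except for the
    designated low-RIN samples, which fall below 6.

    A single :class:`numpy.random.Generator` seeded from ``config.seed``
    drives all sampling in a fixed order, so identical configs produce
    bit-identical output.

    Returns
    -------
    (matrix, sheet, truth)
        ``matrix`` is a genes x samples :class:`pandas.DataFrame` of log2
        expression; ``sheet`` a per-sample metadata frame (group, age,
        gender, batch, rin); ``truth`` the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_genes
    genes = _gene_ids(p)
    samples = _sample_ids(config.n_slow, config.n_rapid)
    is_rapid = np.array([0] * config.n_slow + [1] * config.n_rapid)

    # Sampling order is fixed: baselines, DE effects, covariate coefficients,
    # sample covariates, batch shifts, noise, outlier/low-RIN designations, RIN.
    mu = rng.uniform(4.0, 12.0, size=p)
    de_idx = rng.choice(p, size=config.n_de, replace=False)
    beta = np.zeros(p)
    if config.n_de:
        signs = rng.choice([-1.0, 1.0], size=config.n_de)
        magnitudes = config.effect_size + config.effect_size_sd * rng.standard_normal(
            config.n_de
        )
        beta[de_idx] = signs * magnitudes

    age_coef = config.age_effect_sd * rng.standard_normal(p)
    gender_coef = config.gender_effect_sd * rng.standard_normal(p)

    ages = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n), 40.0, 90.0
    )
    is_male = rng.integers(0, 2, size=n)
    batches = rng.integers(0, config.n_batches, size=n)
    gamma = config.batch_shift_sd * rng.standard_normal((p, config.n_batches))

    values = (
        mu[:, None]
        + beta[:, None] * is_rapid[None, :]
        + gamma[:, batches]
        + age_coef[:, None] * (ages - ages.mean())[None, :]
        + gender_coef[:, None] * is_male[None, :]
        + config.noise_sd * rng.standard_normal((p, n))
    )

    special = rng.choice(n, size=config.n_outliers + config.n_low_rin, replace=False)
    outlier_pos = special[: config.n_outliers]
    low_rin_pos = special[config.n_outliers:]
    n_shifted = int(round(OUTLIER_GENE_FRACTION * p))
    for pos in outlier_pos:
        shifted = rng.choice(p, size=n_shifted, replace=False)
        values[shifted, pos] += config.outlier_shift

    rin = rng.uniform(6.5, 9.5, size=n)
    rin[low_rin_pos] = rng.uniform(4.0, 5.9, size=len(low_rin_pos))

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "group": np.where(is_rapid == 1, "rapid", "slow"),
            "age": np.round(ages, 1),
            "gender": np.where(is_male == 1, "male", "female"),
            "batch": [f"B{b + 1}" for b in batches],
            "rin": np.round(rin, 2),
        }
    )
    truth = Truth(
        de_gene_ids=frozenset(genes[i] for i in de_idx),
        effects=pd.Series(beta, index=matrix.index, name="effect"),
        outlier_sample_ids=frozenset(samples[i] for i in outlier_pos),
        low_rin_sample_ids=frozenset(samples[i] for i in low_rin_pos),
    )
    return matrix, sheet, truth


def simulate_ct_table(
    genes: list[str],
    n_slow: int,
    n_rapid: int,
    true_fold_changes: dict[str, float],
    ct_sd: float = 0.2,
    housekeeping: str = "RPLP0",
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replicate-level qPCR Ct table.

    Each sample x gene combination yields ``n_replicates`` Ct values (the
    assays this emulates load samples in triplicate).  Relative to the slow
    group, target genes in the rapid group have their Ct shifted by
    ``-log2(fold)``, so a ddCt analysis of the table recovers
    ``true_fold_changes`` exactly when ``ct_sd = 0``.  The housekeeping
    gene must be present with fold change 1.

    Returns the long-format Ct table (sample_id, gene_id, replicate, ct)
    and a sample -> group sheet.
    """
    if ct_sd < 0:
        raise ValueError(f"ct_sd must be >= 0, got {ct_sd}")
    if housekeeping not in genes:
        raise ValueError(f"housekeeping gene {housekeeping!r} must be in genes")
    hk_fold = true_fold_changes.get(housekeeping, 1.0)
    if abs(hk_fold - 1.0) > 1e-12:
        raise ValueError("housekeeping gene must have fold change 1")
    missing = [g for g in genes if g != housekeeping and g not in true_fold_changes]
    if missing:
        raise ValueError(f"no fold change given for genes: {missing}")

    rng = np.random.default_rng(seed)
    samples = _sample_ids(n_slow, n_rapid)
    groups = ["slow"] * n_slow + ["rapid"] * n_rapid

    # Housekeeping amplifies early; targets later, with per-gene baselines.
    base = {housekeeping: 18.0}
    for g in genes:
        if g != housekeeping:
            base[g] = rng.uniform(22.0, 30.0)
    # Per-sample loading offset: cancels in dCt, exercises the control logic.
    loading = rng.normal(0.0, 0.5, size=len(samples))

    rows = []
    for si, (sample, grp) in enumerate(zip(samples, groups)):
        for gene in genes:
            ct = base[gene] + loading[si]
            if grp == "rapid" and gene != housekeeping:
                ct -= np.log2(true_fold_changes[gene])
            reps = ct + ct_sd * rng.standard_normal(n_replicates)
            for r, value in enumerate(reps, start=1):
                rows.append((sample, gene, r, float(value)))
    table = pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"])
    sheet = pd.DataFrame({"sample_id": samples, "group": groups})
    return table, sheet
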