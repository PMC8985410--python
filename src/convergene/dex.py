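"""Differential expression between AD and control samples.

A gene is called differentially expressed (DEG) when |logFC| > 0.1 and the
Benjamini-Hochberg adjusted p-value (FDR) is below 0.05, both strict.
logFC is the difference of group means on the log2 scale (AD minus
control).  The per-gene test is Welch's unequal-variance t-test on the
log2 values.

For cohorts with a strong control excess (the blood cohort here has 194
controls against 40 cases), :func:`resampled_degs` balances the design by
repeatedly subsampling the controls, re-running the full DEG call each
time, and keeping genes flagged in at least ``frequency_threshold`` of
the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import ExpressionStudy

LOGFC_THRESHOLD = 0.1
FDR_THRESHOLD = 0.05


def _group_masks(study: ExpressionStudy) -> tuple[np.ndarray, np.ndarray]:
    pheno = study.phenotype.to_numpy()
    control, case = pheno == 0, pheno == 1
    if control.sum() == 0 or case.sum() == 0:
        raise ValueError("both phenotype classes must be present")
    return control, case


def compute_logfc(study: ExpressionStudy) -> pd.Series:
    """Per-gene log2 fold change: mean over AD samples minus mean over controls."""
    control, case = _group_masks(study)
    values = study.values.to_numpy()
    logfc = values[:, case].mean(axis=1) - values[:, control].mean(axis=1)
    return pd.Series(logfc, index=study.values.index, name="logFC")


def de_test(study: ExpressionStudy, pooled_variance: bool = False) -> pd.Series:
    """Two-sided two-sample t-test per gene on log2 expression.

    Welch's unequal-variance form by default; ``pooled_variance=True``
    selects the classical pooled t.  Genes with zero variance in both
    groups and equal means get p = 1 by convention (no evidence either
    way); zero variance with unequal means gives p = 0.
    """
    control, case = _group_masks(study)
    if control.sum() < 2 or case.sum() < 2:
        raise ValueError("need at least 2 samples per class")
    values = study.values.to_numpy()
    a, b = values[:, case], values[:, control]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=pooled_variance)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate & equal_means, 1.0, p)
        p = np.where(degenerate & ~equal_means, 0.0, p)
    return pd.Series(p, index=study.values.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(logfc, fdr) -> pd.DataFrame:
    """Apply the strict DEG thresholds |logFC| > 0.1 and FDR < 0.05."""
    logfc = pd.Series(logfc) if not isinstance(logfc, pd.Series) else logfc
    if len(logfc) != len(fdr):
        raise ValueError("logfc and fdr must be aligned")
    fdr = np.asarray(fdr, dtype=float)
    table = pd.DataFrame(
        {
            "logFC": logfc.to_numpy(),
            "fdr": fdr,
            "is_deg": (np.abs(logfc.to_numpy()) > LOGFC_THRESHOLD)
            & (fdr < FDR_THRESHOLD),
        },
        index=logfc.index,
    )
    return table


def deg_table(study: ExpressionStudy, pooled_variance: bool = False) -> pd.DataFrame:
    """Full DEG call for one study: logFC, p, BH-FDR and the DEG flag."""
    logfc = compute_logfc(study)
    p = de_test(study, pooled_variance=pooled_variance)
    fdr = bh_adjust(p.to_numpy())
    table = call_degs(logfc, fdr)
    table.insert(1, "p_value", p.to_numpy())
    return table


@dataclass
class ResamplingResult:
    """Outcome of the control-subsampling DEG call."""

    frequency: pd.Series  # gene -> number of repeats flagged
    n_repeats: int
    subsample_size: int
    frequency_threshold: int
    seed: int

    @property
    def selected(self) -> pd.Series:
        return (self.frequency >= self.frequency_threshold).rename("selected")


def resampled_degs(
    study: ExpressionStudy,
    n_subsample: int = 40,
    n_repeats: int = 10,
    frequency_threshold: int = 3,
    seed: int = 0,
) -> ResamplingResult:
    """Repeated control-subsampled DEG calls with a frequency filter.

    In each of ``n_repeats`` rounds, ``n_subsample`` controls are drawn
    without replacement, all case samples are kept, and the full DEG call
    (logFC, Welch t, BH) is re-run.  A gene is selected when it is a DEG in
    at least ``frequency_threshold`` rounds.  Per-round seeds are derived
    from ``seed`` by fixed offsets.
    """
    pheno = study.phenotype
    controls = pheno.index[pheno == 0]
    cases = pheno.index[pheno == 1]
    if len(controls) < n_subsample:
        raise ValueError(
            f"need at least {n_subsample} controls, have {len(controls)}"
        )
    freq = np.zeros(len(study.values.index), dtype=int)
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + rep)
        chosen = rng.choice(controls, size=n_subsample, replace=False)
        cols = list(chosen) + list(cases)
        sub = ExpressionStudy(
            values=study.values[cols],
            phenotype=pheno[cols],
            dataset_name=study.dataset_name,
        )
        freq += deg_table(sub)["is_deg"].to_numpy()
    return ResamplingResult(
        frequency=pd.Series(freq, index=study.values.index, name="frequency"),
        n_repeats=n_repeats,
        subsample_size=n_subsample,
        frequency_threshold=frequency_threshold,
        seed=seed,
    )
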