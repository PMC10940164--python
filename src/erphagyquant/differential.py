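"""Per-protein differential abundance: WT-centred log2 values, Student's
t-tests and Benjamini-Hochberg adjustment.

Protein reporter intensities are log2-transformed and centred on the mean of
the reference (WT) replicates, so the reference mean of every protein is
exactly zero and downstream fold changes read directly as log2FC versus WT.
Group comparisons use the pooled-variance two-sided Student's t-test by
default (Welch available), and p-values are adjusted per comparison across all
quantified proteins with the Benjamini-Hochberg step-up procedure.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .errors import DesignError
from .quant import ProteinQuant, validate_design

logger = logging.getLogger(__name__)

_MIN_P = float(np.nextafter(0.0, 1.0))


class ReferenceLog2Centerer(BaseEstimator, TransformerMixin):
    """Log2-transform and centre on the reference-genotype replicate mean.

    value(p, s) = log2 I(p, s) - mean over reference replicates of log2 I(p, .)

    Centring subtracts the reference mean on the log scale (geometric-mean
    centring), so the reference-replicate mean of every row is exactly 0.
    Nonpositive intensities become NaN (unquantified); proteins with no
    quantified reference replicate are excluded with a log entry and listed in
    ``excluded_``.
    """

    def __init__(self, reference_genotype: str = "WT"):
        self.reference_genotype = reference_genotype

    def fit(self, X: ProteinQuant, y=None):
        design = validate_design(X.design)
        ref_channels = [c for c in X.samples
                        if design.loc[c, "genotype"] == self.reference_genotype]
        if not ref_channels:
            raise DesignError(
                f"no channels for reference genotype {self.reference_genotype!r}")
        self.reference_channels_ = ref_channels
        return self

    def transform(self, X: ProteinQuant) -> pd.DataFrame:
        self.fit(X)
        with np.errstate(divide="ignore"):
            log2 = np.log2(X.intensities.where(X.intensities > 0))
        ref_mean = log2[self.reference_channels_].mean(axis=1, skipna=True)
        keep = ref_mean.notna()
        self.excluded_ = X.intensities.index[~keep].tolist()
        if self.excluded_:
            logger.info("centering: excluded %d proteins with no reference "
                        "quantification: %s", len(self.excluded_), self.excluded_[:10])
        centred = log2.loc[keep].sub(ref_mean.loc[keep], axis=0)
        centred.attrs["reference_genotype"] = self.reference_genotype
        centred.attrs["excluded"] = self.excluded_
        return centred


def log2_transform_and_center(pq: ProteinQuant,
                              reference_genotype: str = "WT") -> pd.DataFrame:
    """WT-centred log2 matrix; excluded proteins in ``result.attrs['excluded']``."""
    return ReferenceLog2Centerer(reference_genotype).transform(pq)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def t_test_per_protein(centred: pd.DataFrame, design: pd.DataFrame, mutant: str,
                       reference: str = "WT", equal_var: bool = True,
                       require_full: bool = True) -> pd.DataFrame:
    """Two-sided Student's t-test of mutant vs reference per protein.

    log2fc = mean(mutant) - mean(reference) on the centred log2 matrix. The
    pooled-variance test is the default; ``equal_var=False`` gives Welch.
    Proteins with insufficient replicates (fewer than 2 usable per group, or
    any missing value when ``require_full``) are flagged ``insufficient_n``
    and keep NaN statistics rather than being dropped. A zero pooled variance
    gives p = 1 for equal means, else the smallest positive float, flagged
    ``degenerate_variance``. BH adjustment is applied across the tested
    proteins of this comparison.
    """
    design = validate_design(design.loc[centred.columns])
    a_cols = design.index[design["genotype"] == mutant]
    b_cols = design.index[design["genotype"] == reference]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DesignError(
            f"need >= 2 replicates per group; {mutant}: {len(a_cols)}, "
            f"{reference}: {len(b_cols)}")
    A = centred[a_cols].to_numpy(dtype=float)
    B = centred[b_cols].to_numpy(dtype=float)
    na = np.isfinite(A).sum(axis=1)
    nb = np.isfinite(B).sum(axis=1)
    if require_full:
        usable = (na == len(a_cols)) & (nb == len(b_cols))
    else:
        usable = (na >= 2) & (nb >= 2)

    log2fc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    pvals = np.full(len(centred), np.nan)
    flags = np.where(usable, "", "insufficient_n").astype(object)

    if usable.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(A[usable], B[usable], axis=1,
                                  equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance: p is 1 for equal means, else the smallest
        # representable positive p, with a degeneracy flag either way
        va = np.nanvar(A[usable], axis=1, ddof=1)
        vb = np.nanvar(B[usable], axis=1, ddof=1)
        degen = (va == 0) & (vb == 0)
        if degen.any():
            eq = np.isclose(np.nanmean(A[usable], axis=1),
                            np.nanmean(B[usable], axis=1))
            p[degen & eq] = 1.0
            p[degen & ~eq] = _MIN_P
            sub = flags[usable]
            sub[degen] = "degenerate_variance"
            flags[usable] = sub
        pvals[usable] = p

    padj = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        padj[ok] = bh_adjust(pvals[ok])

    out = pd.DataFrame({
        "protein_id": centred.index,
        "comparison": f"{mutant}_vs_{reference}",
        "log2fc": np.where(usable | ~require_full, log2fc, np.nan),
        "p_value": pvals,
        "p_adjusted": padj,
        "n_reference": nb,
        "n_mutant": na,
        "flags": flags,
    }).set_index("protein_id")
    out.attrs["method"] = "student_t_pooled" if equal_var else "welch_t"
    return out
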