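"""Sequential-knockout (allelic-series) linear model.

For an ordered genotype series ``WT, DKO, TKO, QKO, PKO`` each sample is coded
with cumulative 0/1 indicators ``x_k`` = 1 iff the sample's genotype contains
the k-th sequential deletion, giving the staircase design

    WT  -> (0,0,0,0)    DKO -> (1,0,0,0)    TKO -> (1,1,0,0)
    QKO -> (1,1,1,0)    PKO -> (1,1,1,1)

and a per-protein model ``y = b0 + X beta + eps`` on WT-centred log2
intensities. Centring on the WT replicate mean drives the fitted intercept
``b0`` to zero (isobaric reporter intensities carry no absolute-abundance
meaning), but the intercept column is retained in the solve: dropping it
would credit the step-1 coefficient with the certainty of a noiseless WT
baseline and overcount residual degrees of freedom, inflating the step-1
false-positive rate. Each ``beta_k`` is the mean log2 fold change contributed
by the k-th deletion step: the OLS solution equals the successive difference
of adjacent genotype means (``beta_1`` = mean DKO - mean WT, ...), so e.g.
``beta_3`` is the average fold change from the triple to the quadruple
knockout. Inference uses the t distribution with ``n - k - 1`` residual
degrees of freedom; p-values are Benjamini-Hochberg adjusted per step across
proteins, significant at adjusted p < 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .differential import bh_adjust
from .errors import DesignError
from .quant import validate_design

DEFAULT_SERIES = ("WT", "DKO", "TKO", "QKO", "PKO")

#: p reported for a zero-residual fit whose estimate is nonzero.
_MIN_P = float(np.nextafter(0.0, 1.0))


def step_labels(series) -> list[str]:
    s = tuple(series)
    return [f"{a}->{b}" for a, b in zip(s[:-1], s[1:])]


@dataclass
class AllelicDesign:
    """Cumulative-indicator design aligned to a sample set.

    ``X`` is samples x steps (the staircase, no intercept column); WT rows are
    all-zero. The fit augments it with an intercept internally.
    """

    X: pd.DataFrame
    series: tuple[str, ...]

    @property
    def steps(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_steps(self) -> int:
        return self.X.shape[1]

    def augmented(self) -> np.ndarray:
        """Design matrix with the leading intercept column."""
        X = self.X.to_numpy()
        return np.hstack([np.ones((X.shape[0], 1)), X])


def build_design(design: pd.DataFrame, series=DEFAULT_SERIES) -> AllelicDesign:
    """Build the staircase indicator matrix from a plex design table.

    Every sample genotype must belong to ``series``; samples of genotypes
    outside the series (e.g. extra plex controls) must be excluded by the
    caller first. Raises :class:`DesignError` if a mutant genotype is entirely
    absent (the matrix would be rank-deficient).
    """
    series = tuple(series)
    validate_design(design)
    rank = {g: i for i, g in enumerate(series)}
    unknown = sorted(set(design["genotype"]) - set(series))
    if unknown:
        raise DesignError(f"genotype(s) not in series {series}: {unknown}")
    labels = step_labels(series)
    geno_rank = design["genotype"].map(rank).to_numpy()
    X = (geno_rank[:, None] >= np.arange(1, len(series))[None, :]).astype(float)
    Xdf = pd.DataFrame(X, index=design.index, columns=labels)
    present = set(design["genotype"])
    missing = [g for g in series if g not in present]
    if missing:
        raise DesignError(
            f"rank-deficient allelic design: no samples for genotype(s) {missing}")
    return AllelicDesign(X=Xdf, series=series)


def fit_protein(y: np.ndarray, design: AllelicDesign) -> dict:
    """OLS of one protein's centred log2 values on the staircase design.

    The solve includes the intercept column (zero on properly centred data);
    reported coefficients, standard errors and two-sided t p-values cover the
    step coefficients only, with ``n - n_steps - 1`` residual degrees of
    freedom. Samples with non-finite ``y`` are dropped; if too few usable
    samples remain (or the reduced design loses rank) the protein is flagged
    ``rank_deficient`` with NaN estimates. With no residual degrees of freedom
    the betas are still returned, flagged ``no_inference``. A zero-residual fit
    is flagged ``degenerate_variance``: p = 1 where beta = 0, else the smallest
    positive float.
    """
    y = np.asarray(y, dtype=float)
    Xa = design.augmented()
    k = design.n_steps
    mask = np.isfinite(y)
    n = int(mask.sum())
    out = {
        "beta": np.full(k, np.nan), "se": np.full(k, np.nan),
        "p": np.full(k, np.nan), "intercept": np.nan,
        "df_residual": n - k - 1, "n_used": n, "flag": "",
    }
    Xm, ym = Xa[mask], y[mask]
    if n < k + 1 or np.linalg.matrix_rank(Xm) < k + 1:
        out["flag"] = "rank_deficient"
        return out
    coef, _, _, _ = np.linalg.lstsq(Xm, ym, rcond=None)
    resid = ym - Xm @ coef
    rss = float(resid @ resid)
    dof = n - k - 1
    out["intercept"] = coef[0]
    out["beta"] = coef[1:]
    if dof <= 0:
        out["flag"] = "no_inference"
        return out
    s2 = rss / dof
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    if s2 <= np.finfo(float).tiny * max(1.0, float(ym @ ym)):
        out["flag"] = "degenerate_variance"
        out["se"] = np.zeros(k)
        out["p"] = np.where(out["beta"] == 0.0, 1.0, _MIN_P)
        return out
    se = np.sqrt(s2 * np.diag(xtx_inv))[1:]
    t = out["beta"] / se
    out["se"] = se
    out["p"] = 2.0 * stats.t.sf(np.abs(t), dof)
    return out


class AllelicSeriesModel(BaseEstimator):
    """Per-protein allelic-series fit across a WT-centred log2 matrix.

    Parameters
    ----------
    series:
        Ordered genotype labels, first entry the reference the matrix was
        centred on.
    alpha:
        Adjusted-p significance threshold (default 0.05).
    bh_scope:
        ``"per_step"`` adjusts p-values separately for each coefficient across
        proteins (default); ``"pooled"`` adjusts all coefficients together.

    Fitted attributes
    -----------------
    design_ : AllelicDesign
    beta_, se_, pvalues_, padj_ : DataFrame, proteins x steps
    significant_ : boolean DataFrame at adjusted p < alpha
    df_residual_, n_used_ : Series per protein
    flags_ : Series of fit flags ('' when clean)
    results_ : flat per-protein table (beta1.., se1.., p1.., padj1.., flags)
    """

    def __init__(self, series=DEFAULT_SERIES, alpha: float = 0.05,
                 bh_scope: str = "per_step"):
        self.series = series
        self.alpha = alpha
        self.bh_scope = bh_scope

    def fit(self, centred: pd.DataFrame, design: pd.DataFrame):
        """Fit every protein of a centred log2 matrix (proteins x samples)."""
        if self.bh_scope not in ("per_step", "pooled"):
            raise ValueError("bh_scope must be 'per_step' or 'pooled'")
        if len(centred) < 1:
            raise ValueError("no proteins to fit")
        design = design.loc[centred.columns]
        ad = build_design(design, self.series)
        k = ad.n_steps
        Y = centred.to_numpy(dtype=float)
        nprot = Y.shape[0]
        beta = np.empty((nprot, k))
        se = np.empty((nprot, k))
        pv = np.empty((nprot, k))
        dfres = np.empty(nprot, dtype=int)
        nused = np.empty(nprot, dtype=int)
        flags = np.empty(nprot, dtype=object)

        finite = np.isfinite(Y)
        complete = finite.all(axis=1)
        if complete.any():
            rows = self._fit_complete(Y[complete], ad)
            beta[complete], se[complete], pv[complete] = rows["beta"], rows["se"], rows["p"]
            dfres[complete] = rows["df_residual"]
            nused[complete] = Y.shape[1]
            flags[complete] = rows["flag"]
        for i in np.flatnonzero(~complete):
            r = fit_protein(Y[i], ad)
            beta[i], se[i], pv[i] = r["beta"], r["se"], r["p"]
            dfres[i], nused[i], flags[i] = r["df_residual"], r["n_used"], r["flag"]

        idx, cols = centred.index, ad.steps
        self.design_ = ad
        self.beta_ = pd.DataFrame(beta, index=idx, columns=cols)
        self.se_ = pd.DataFrame(se, index=idx, columns=cols)
        self.pvalues_ = pd.DataFrame(pv, index=idx, columns=cols)
        self.padj_ = self._adjust(self.pvalues_)
        self.significant_ = self.padj_ < self.alpha
        self.df_residual_ = pd.Series(dfres, index=idx, name="df_residual")
        self.n_used_ = pd.Series(nused, index=idx, name="n_used")
        self.flags_ = pd.Series(flags, index=idx, name="flags").fillna("")
        self.results_ = self._flat_results()
        return self

    def _fit_complete(self, Y: np.ndarray, ad: AllelicDesign) -> dict:
        """Vectorized OLS for proteins with no missing samples (shared design)."""
        Xa = ad.augmented()
        n = Xa.shape[0]
        k = ad.n_steps
        xtx_inv = np.linalg.inv(Xa.T @ Xa)
        coef = Y @ (xtx_inv @ Xa.T).T
        resid = Y - coef @ Xa.T
        rss = np.einsum("ij,ij->i", resid, resid)
        beta = coef[:, 1:]
        dof = n - k - 1
        flag = np.full(Y.shape[0], "", dtype=object)
        if dof <= 0:
            return {"beta": beta, "se": np.full_like(beta, np.nan),
                    "p": np.full_like(beta, np.nan), "df_residual": dof,
                    "flag": np.full(Y.shape[0], "no_inference", dtype=object)}
        s2 = rss / dof
        degen = s2 <= np.finfo(float).tiny * np.maximum(
            1.0, np.einsum("ij,ij->i", Y, Y))
        se = np.sqrt(s2[:, None] * np.diag(xtx_inv)[None, 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        if degen.any():
            flag[degen] = "degenerate_variance"
            se[degen] = 0.0
            p[degen] = np.where(beta[degen] == 0.0, 1.0, _MIN_P)
        return {"beta": beta, "se": se, "p": p, "df_residual": dof, "flag": flag}

    def _adjust(self, pvals: pd.DataFrame) -> pd.DataFrame:
        padj = pd.DataFrame(np.nan, index=pvals.index, columns=pvals.columns)
        if self.bh_scope == "pooled":
            flat = pvals.to_numpy().ravel()
            ok = np.isfinite(flat)
            adj = flat.copy()
            if ok.any():
                adj[ok] = bh_adjust(flat[ok])
            padj.loc[:, :] = adj.reshape(pvals.shape)
            return padj
        for col in pvals.columns:
            p = pvals[col].to_numpy()
            ok = np.isfinite(p)
            if ok.any():
                padj.loc[ok, col] = bh_adjust(p[ok])
        return padj

    def _flat_results(self) -> pd.DataFrame:
        out = {"protein_id": self.beta_.index}
        for j, _ in enumerate(self.beta_.columns, start=1):
            col = self.beta_.columns[j - 1]
            out[f"beta{j}"] = self.beta_[col].to_numpy()
            out[f"se{j}"] = self.se_[col].to_numpy()
            out[f"p{j}"] = self.pvalues_[col].to_numpy()
            out[f"padj{j}"] = self.padj_[col].to_numpy()
        out["df_residual"] = self.df_residual_.to_numpy()
        out["flags"] = self.flags_.to_numpy()
        df = pd.DataFrame(out).set_index("protein_id")
        df.attrs["steps"] = list(self.beta_.columns)
        return df


def fit_all(centred: pd.DataFrame, design: pd.DataFrame, series=DEFAULT_SERIES,
            alpha: float = 0.05, bh_scope: str = "per_step") -> AllelicSeriesModel:
    """Fit the allelic-series model to every protein; returns the fitted model."""
    return AllelicSeriesModel(series=series, alpha=alpha, bh_scope=bh_scope).fit(
        centred, design)


def summarize_beta(model: AllelicSeriesModel, annotation: pd.DataFrame,
                   by: str = "er_class") -> pd.DataFrame:
    """Mean beta per step within each annotation group, with group counts.

    ``annotation`` is indexed by protein id; fitted proteins without annotation
    are summarized under the group label ``"unannotated"`` so that counts
    conserve (annotated + unannotated = fitted).
    """
    if by not in annotation.columns:
        raise KeyError(f"annotation lacks column {by!r}")
    groups = annotation[by].reindex(model.beta_.index).fillna("unannotated")
    if (groups != "unannotated").sum() == 0:
        raise ValueError("annotation covers no fitted protein")
    summary = model.beta_.groupby(groups).mean()
    summary["n_proteins"] = model.beta_.groupby(groups).size()
    summary.index.name = by
    return summary


def rank_top(model_or_beta, step, n_top: int = 25, n_bottom: int = 5) -> pd.DataFrame:
    """Top accumulated and bottom depleted proteins ranked on one step's beta.

    Descending order; ties broken by accession. Significance asterisks mark
    adjusted p < 0.05 when the input is a fitted model.
    """
    if isinstance(model_or_beta, AllelicSeriesModel):
        beta = model_or_beta.beta_[step]
        sig = model_or_beta.significant_[step]
    else:
        beta = model_or_beta[step]
        sig = pd.Series(False, index=beta.index)
    if len(beta) < n_top + n_bottom:
        raise ValueError(
            f"need at least {n_top + n_bottom} proteins, have {len(beta)}")
    order = pd.DataFrame({"beta": beta, "significant": sig})
    order = order.sort_values(["beta", "protein_id"]
                              if order.index.name == "protein_id" else "beta",
                              ascending=False, kind="mergesort")
    # mergesort is stable; pre-sort by accession so ties resolve lexicographically
    order = order.sort_index(kind="mergesort").sort_values(
        "beta", ascending=False, kind="mergesort")
    top = order.head(n_top).copy()
    top["rank_class"] = "top"
    bottom = order.tail(n_bottom).copy()
    bottom["rank_class"] = "bottom"
    ranked = pd.concat([top, bottom])
    ranked["marker"] = np.where(ranked["significant"], "*", "")
    ranked["step"] = step
    return ranked
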