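"""Compartment annotations and distribution-level statistics.

Annotation tables classify proteins by organelle and ER compartment
(ER-associated, ER-membrane, ER-lumen), flag curvature-related and receptor
proteins, and encode transmembrane-segment counts as ``_n`` name suffixes
(``VAPA_1`` means VAPA with one TM segment).

The randomized-selection null asks whether a compartment's distribution of
per-protein values (betas or log2FCs) differs from chance: for each of 100
iterations a random protein set of the same size is drawn from the quantified
background and compared with a two-sided two-sample Kolmogorov-Smirnov test.
Compartment-level shifts of beta away from zero use a one-sided Wilcoxon
signed-rank test with Bonferroni correction, and genotype-vs-genotype
compartment comparisons use paired two-sided Wilcoxon tests.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ER_CLASSES

_TM_SUFFIX = re.compile(r"^(?P<base>.+)_(?P<tm>\d+)$")


def parse_annotations(source) -> pd.DataFrame:
    """Read an annotation table; strips ``_n`` TM suffixes into ``tm_count``.

    ``source`` is a delimited-file path or an equivalent DataFrame with a
    ``name`` column plus any of ``organelle``, ``er_class``, ``is_curvature``,
    ``is_receptor``. Names without a numeric suffix get ``tm_count`` 0.
    Duplicate protein ids (after suffix stripping) raise an error listing them.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    if "name" not in df.columns:
        raise ValueError("annotation table needs a 'name' column")

    ids, tms = [], []
    for name in df["name"].astype(str):
        m = _TM_SUFFIX.match(name)
        if m:
            ids.append(m.group("base"))
            tms.append(int(m.group("tm")))
        else:
            ids.append(name)
            tms.append(0)
    df["protein_id"] = ids
    df["tm_count"] = tms

    dup = df["protein_id"][df["protein_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate protein ids in annotation table: {dup}")

    df["organelle"] = df.get("organelle", pd.Series("unknown", index=df.index))
    df["er_class"] = df.get("er_class", pd.Series("none", index=df.index)).fillna("none")
    bad = sorted(set(df["er_class"]) - set(ER_CLASSES))
    if bad:
        raise ValueError(f"unknown er_class value(s): {bad}")
    inconsistent = (df["er_class"] != "none") & (df["organelle"] != "ER")
    if inconsistent.any():
        raise ValueError(
            "er_class set for non-ER organelle: "
            f"{df.loc[inconsistent, 'protein_id'].tolist()}")
    for col in ("is_curvature", "is_receptor"):
        df[col] = df.get(col, pd.Series(False, index=df.index)).astype(bool)
    return df.set_index("protein_id")[
        ["organelle", "er_class", "is_curvature", "is_receptor", "tm_count"]]


@dataclass
class NullTestResult:
    """Outcome of the randomized-selection KS null for one protein group.

    ``p_values`` holds the per-iteration two-sided KS p-values; ``median_p``
    and ``frac_significant`` summarize them, and ``pooled_p`` is a single KS
    test of the group against all randomized draws pooled together (both
    aggregations are reported because either reading is defensible).
    """

    group: str
    n_group: int
    n_background: int
    iterations: int
    p_values: np.ndarray = field(repr=False)
    statistics: np.ndarray = field(repr=False)
    median_p: float
    frac_significant: float
    pooled_p: float
    alpha: float = 0.05


def randomized_null_ks(values: pd.Series, group_ids, iterations: int = 100,
                       seed: int | None = None, alpha: float = 0.05,
                       group_label: str = "group",
                       ks_method: str = "auto") -> NullTestResult:
    """Compare a group's value distribution to random same-size selections.

    ``values`` maps every quantified (background) protein to its statistic;
    ``group_ids`` selects the group (must be quantified, size >= 2, and no
    larger than the background). Each iteration draws ``|group|`` proteins
    uniformly without replacement from the full background (group members may
    be redrawn) and applies a two-sided two-sample KS test.
    """
    values = values.dropna()
    group_ids = [g for g in group_ids]
    missing = sorted(set(group_ids) - set(values.index))
    if missing:
        raise ValueError(f"group proteins absent from background: {missing[:10]}")
    group_vals = values.loc[group_ids].to_numpy(dtype=float)
    background = values.to_numpy(dtype=float)
    n_group = len(group_vals)
    if n_group < 2:
        raise ValueError("group must contain at least 2 proteins")
    if n_group > len(background):
        raise ValueError("group larger than the quantified background")

    rng = np.random.default_rng(seed)
    pvals = np.empty(iterations)
    ds = np.empty(iterations)
    draws = np.empty((iterations, n_group))
    for i in range(iterations):
        draw = rng.choice(background, size=n_group, replace=False)
        draws[i] = draw
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # exact-method tie fallback
            res = stats.ks_2samp(group_vals, draw, alternative="two-sided",
                                 method=ks_method)
        pvals[i], ds[i] = res.pvalue, res.statistic
    pooled = stats.ks_2samp(group_vals, draws.ravel(),
                            alternative="two-sided").pvalue
    return NullTestResult(
        group=group_label, n_group=n_group, n_background=len(background),
        iterations=iterations, p_values=pvals, statistics=ds,
        median_p=float(np.median(pvals)),
        frac_significant=float(np.mean(pvals < alpha)),
        pooled_p=float(pooled), alpha=alpha)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    p_adjusted: float
    n_used: int
    degenerate: bool = False
    method: str = ""


def _signed_rank_method(diffs: np.ndarray) -> str:
    # exact distribution for n <= 25 without tied magnitudes, else normal
    # approximation with continuity correction (signed-rank convention)
    if len(diffs) <= 25 and len(np.unique(np.abs(diffs))) == len(diffs):
        return "exact"
    return "approx"


def wilcoxon_beta_vs_zero(values, alternative: str = "greater",
                          n_comparisons: int = 1) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank of beta values against zero.

    Zeros are dropped (signed-rank convention); with everything zero the test
    is degenerate and p = 1. The Bonferroni-adjusted p is
    ``min(1, p * n_comparisons)``.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    nz = v[v != 0]
    if len(nz) == 0:
        return WilcoxonResult(np.nan, 1.0, 1.0, 0, degenerate=True,
                              method="degenerate")
    method = _signed_rank_method(nz)
    res = stats.wilcoxon(nz, alternative=alternative, method=method,
                         correction=(method == "approx"))
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), p_adj,
                          len(nz), method=method)


def paired_wilcoxon_genotypes(values_a: pd.Series,
                              values_b: pd.Series) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank between two genotypes.

    Values are paired by protein id; proteins missing in either series are
    dropped. All-zero differences give a degenerate p = 1.
    """
    common = values_a.index.intersection(values_b.index)
    diffs = (values_a.loc[common] - values_b.loc[common]).to_numpy(dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    nz = diffs[diffs != 0]
    if len(nz) < 2:
        if len(nz) == 0:
            return WilcoxonResult(np.nan, 1.0, 1.0, 0, degenerate=True,
                                  method="degenerate")
        raise ValueError("need at least 2 non-tied pairs")
    method = _signed_rank_method(nz)
    res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return WilcoxonResult(float(res.statistic), float(res.pvalue),
                          float(res.pvalue), len(nz), method=method)
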