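"""PSM-level quality filtering, channel sum-normalization and protein rollup.

A PSM (peptide-spectrum match) table is a :class:`pandas.DataFrame` with the
columns ``protein_id``, ``peptide``, one reporter-intensity column per TMT
channel, ``summed_snr`` (reporter signal-to-noise summed across the plex) and
``isolation_purity`` (fraction of the MS1 isolation window attributable to the
precursor). Quality filtering keeps PSMs with summed SNR strictly above 200
and isolation purity strictly above 0.5; channel totals are then sum-normalized
to the median channel total across the plex, and protein intensities are the
sums of their constituent normalized PSM intensities (a weighted-average
quantification, since high-signal PSMs dominate the sum).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DesignError

logger = logging.getLogger(__name__)

#: Non-channel columns of a PSM table.
PSM_META_COLUMNS = ("protein_id", "peptide", "summed_snr", "isolation_purity")


def channel_columns(psms: pd.DataFrame) -> list[str]:
    """Reporter-intensity columns of a PSM table (everything non-meta)."""
    return [c for c in psms.columns if c not in PSM_META_COLUMNS]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a plex design table (index: channel; columns incl. genotype, replicate)."""
    if design.index.has_duplicates:
        dups = design.index[design.index.duplicated()].unique().tolist()
        raise DesignError(f"duplicate channel labels in design: {dups}")
    for col in ("genotype", "replicate"):
        if col not in design.columns:
            raise DesignError(f"plex design lacks required column {col!r}")
    if design[["genotype", "replicate"]].isna().any().any():
        raise DesignError("every channel must be annotated with genotype and replicate")
    return design


@dataclass
class ProteinQuant:
    """Protein x sample intensity matrix plus the plex design.

    Attributes
    ----------
    intensities:
        Linear-scale intensity matrix, proteins (index) x channels (columns).
    design:
        Plex design indexed by channel with ``genotype``, ``replicate`` and
        ``condition`` columns.
    provenance:
        Filter/normalization parameters applied upstream.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_design(self.design)
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate protein ids in intensity matrix")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample labels in intensity matrix")
        missing = [c for c in self.intensities.columns if c not in self.design.index]
        if missing:
            raise DesignError(f"channels missing from design: {missing}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities in protein matrix")

    @property
    def proteins(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def channels_for(self, genotype: str) -> list[str]:
        """Channel labels belonging to one genotype, in design order."""
        sel = self.design.index[self.design["genotype"] == genotype]
        return [c for c in sel if c in self.intensities.columns]


class PsmQcFilter(BaseEstimator, TransformerMixin):
    """Keep PSMs with summed SNR > ``min_snr`` and purity > ``min_purity``.

    Both inequalities are strict, so a PSM at exactly the threshold is removed.
    Input order is preserved. Fitted attributes: ``n_removed_``, ``n_kept_``.
    """

    def __init__(self, min_snr: float = 200.0, min_purity: float = 0.5):
        self.min_snr = min_snr
        self.min_purity = min_purity

    def fit(self, X: pd.DataFrame, y=None):
        if self.min_snr < 0 or self.min_purity < 0:
            raise ValueError("QC thresholds must be >= 0")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        mask = (X["summed_snr"] > self.min_snr) & (X["isolation_purity"] > self.min_purity)
        kept = X.loc[mask]
        self.n_removed_ = int((~mask).sum())
        self.n_kept_ = int(mask.sum())
        if self.n_kept_ == 0:
            warnings.warn("all PSMs removed by QC filtering", stacklevel=2)
        out = kept.copy()
        out.attrs["qc_filter"] = {
            "min_snr": self.min_snr,
            "min_purity": self.min_purity,
            "n_removed": self.n_removed_,
        }
        return out


class ChannelSumNormalizer(BaseEstimator, TransformerMixin):
    """Sum-normalize channel totals to the median channel total.

    The per-channel factor is ``median(totals) / total_c``; after applying it,
    every channel total equals the median of the original totals (midpoint of
    the two central totals for an even plex size). Applying the transform to
    its own output is the identity. Fitted attribute: ``factors_``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        cols = channel_columns(X)
        if len(X) == 0:
            raise ValueError("cannot normalize an empty PSM table")
        totals = X[cols].sum(axis=0)
        zero = totals.index[totals == 0].tolist()
        if zero:
            raise ValueError(f"channel(s) with zero total intensity: {zero}")
        self.totals_ = totals
        self.factors_ = totals.median() / totals
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = channel_columns(X)
        out = X.copy()
        out[cols] = X[cols] * self.factors_[cols]
        out.attrs["normalization"] = {"factors": self.factors_.to_dict()}
        return out


class ProteinRollup(BaseEstimator, TransformerMixin):
    """Sum PSM channel intensities per protein (expects filtered+normalized input).

    Proteins are ordered by accession; a protein with no PSMs is simply absent
    (never a zero row). With ``allowed_proteins`` set, PSMs mapping elsewhere
    are dropped with a log entry.
    """

    def __init__(self, allowed_proteins: Sequence[str] | None = None):
        self.allowed_proteins = allowed_proteins

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        psms = X
        if self.allowed_proteins is not None:
            allowed = set(self.allowed_proteins)
            drop = ~psms["protein_id"].isin(allowed)
            if drop.any():
                dropped = psms.loc[drop, "protein_id"].unique().tolist()
                logger.info("rollup: dropping %d PSMs from %d proteins outside allow-list: %s",
                            int(drop.sum()), len(dropped), dropped[:10])
            psms = psms.loc[~drop]
        cols = channel_columns(psms)
        mat = psms.groupby("protein_id", sort=True)[cols].sum()
        mat.index.name = "protein_id"
        return mat


def filter_psms(psms: pd.DataFrame, min_snr: float = 200.0,
                min_purity: float = 0.5) -> pd.DataFrame:
    """QC-filter a PSM table; removal count is in ``result.attrs['qc_filter']``."""
    return PsmQcFilter(min_snr=min_snr, min_purity=min_purity).transform(psms)


def normalize_channels(psms: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Sum-normalize channels to the median total; returns (table, factors)."""
    norm = ChannelSumNormalizer().fit(psms)
    return norm.transform(psms), norm.factors_


def rollup_proteins(psms: pd.DataFrame, design: pd.DataFrame,
                    allowed_proteins: Sequence[str] | None = None,
                    provenance: dict | None = None) -> ProteinQuant:
    """Roll filtered, normalized PSMs up to a :class:`ProteinQuant`."""
    mat = ProteinRollup(allowed_proteins=allowed_proteins).transform(psms)
    prov = dict(provenance or {})
    prov.setdefault("qc_filter", psms.attrs.get("qc_filter"))
    prov.setdefault("normalization", psms.attrs.get("normalization"))
    return ProteinQuant(intensities=mat, design=validate_design(design), provenance=prov)


def quantify(psms: pd.DataFrame, design: pd.DataFrame, min_snr: float = 200.0,
             min_purity: float = 0.5) -> ProteinQuant:
    """Full PSM -> protein pipeline: QC filter, sum-normalize, roll up."""
    filtered = filter_psms(psms, min_snr=min_snr, min_purity=min_purity)
    normalized, factors = normalize_channels(filtered)
    return rollup_proteins(
        normalized, design,
        provenance={"qc_filter": filtered.attrs["qc_filter"],
                    "normalization": {"factors": factors.to_dict()}})
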