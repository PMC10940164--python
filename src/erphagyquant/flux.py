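"""Ratiometric Keima flux quantification from gated flow-cytometry events.

Keima shifts its excitation maximum in acidic lysosomes, so the ratio of the
561-nm-excited (acidic) to the 445-nm-excited (neutral) population signal
reports autophagic flux. The per-condition ratio divides the mean of the
acidic channel by the mean of the neutral channel (means of channels, not the
mean of per-event ratios), and flux is expressed relative to a matched
bafilomycin-A1 (BAFA) control in which lysosomal acidification is blocked —
the BAFA sample itself therefore normalizes to exactly 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError


@dataclass
class FluxResult:
    condition: str
    raw_ratio: float
    normalized_ratio: float
    n_events: int
    bafa_condition: str


def keima_ratio(events: pd.DataFrame, condition: str | None = None,
                statistic: str = "arithmetic") -> float:
    """Acidic/neutral population ratio: mean(561 nm) / mean(445 nm).

    ``statistic="geometric"`` uses geometric channel means instead (a common
    alternative in cytometry workflows). Restricting to ``condition`` selects
    that condition's events; otherwise all events are pooled.
    """
    ev = events if condition is None else events[events["condition"] == condition]
    if len(ev) == 0:
        raise ValueError(f"no events for condition {condition!r}")
    acidic = ev["acidic_561"].to_numpy(dtype=float)
    neutral = ev["neutral_445"].to_numpy(dtype=float)
    if (acidic < 0).any() or (neutral < 0).any():
        raise ValueError("negative channel intensities")
    if statistic == "arithmetic":
        denom = neutral.mean()
        if denom <= 0:
            raise ValueError("mean neutral (445 nm) intensity is zero")
        return float(acidic.mean() / denom)
    if statistic == "geometric":
        if (acidic <= 0).any() or (neutral <= 0).any():
            raise ValueError("geometric mean requires strictly positive intensities")
        return float(np.exp(np.log(acidic).mean() - np.log(neutral).mean()))
    raise ValueError("statistic must be 'arithmetic' or 'geometric'")


def normalize_to_bafa(raw_ratio: float, bafa_ratio: float) -> float:
    """Express a raw Keima ratio relative to the matched BAFA control."""
    if bafa_ratio <= 0:
        raise ValueError("BAFA reference ratio must be > 0")
    return raw_ratio / bafa_ratio


def compute_flux(events: pd.DataFrame, pairings: pd.DataFrame,
                 statistic: str = "arithmetic") -> pd.DataFrame:
    """Per-condition raw and BAFA-normalized Keima ratios.

    ``pairings`` maps each analyzed ``condition`` to its matched
    ``bafa_condition`` (explicit pairing, never inferred). A missing BAFA
    condition in the event table raises a :class:`DesignError` naming it.
    """
    for col in ("condition", "bafa_condition"):
        if col not in pairings.columns:
            raise DesignError(f"pairings table needs a {col!r} column")
    present = set(events["condition"])
    rows = []
    for _, pair in pairings.iterrows():
        cond, bafa = pair["condition"], pair["bafa_condition"]
        if bafa not in present:
            raise DesignError(f"matched BAFA condition {bafa!r} has no events")
        raw = keima_ratio(events, cond, statistic=statistic)
        bafa_raw = keima_ratio(events, bafa, statistic=statistic)
        rows.append(FluxResult(
            condition=cond, raw_ratio=raw,
            normalized_ratio=normalize_to_bafa(raw, bafa_raw),
            n_events=int((events["condition"] == cond).sum()),
            bafa_condition=bafa))
    return pd.DataFrame([r.__dict__ for r in rows])
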