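"""Readers and writers for the pipeline's delimited-text formats.

All tables are plain TSV (flow events CSV): PSM tables carry ``protein_id``,
``peptide``, one ``channel_*`` column per reporter channel, ``summed_snr`` and
``isolation_purity``; plex designs map channels to genotype/replicate/
condition; intensity and centred matrices are proteins x channels.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .quant import ProteinQuant, validate_design


def write_psms(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psms(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t", index_col="channel"))


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_protein_quant(pq: ProteinQuant, matrix_path, design_path=None) -> None:
    write_matrix(pq.intensities, matrix_path)
    if design_path is not None:
        write_design(pq.design, design_path)


def read_protein_quant(matrix_path, design_path) -> ProteinQuant:
    return ProteinQuant(intensities=read_matrix(matrix_path),
                        design=read_design(design_path))


def write_flow_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_flow_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
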