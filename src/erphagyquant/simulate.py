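"""Synthetic allelic-series TMT data with known ground truth.

Generates, from a single :class:`~erphagyquant.config.SimConfig`, everything
the downstream pipeline consumes: a truth table of per-protein baselines and
true per-step log2 effects (including receptor-deletion signatures), a
protein x channel intensity matrix following the staircase model with Gaussian
log2 replicate noise, a PSM-level table whose lognormal peptide shares roll
back up to the protein matrix exactly, a compartment annotation table, and
ratiometric flow-cytometry event tables for Keima flux.

Randomness is drawn from named child streams of the root seed
(``default_rng([seed, k])`` with k = 0 truth, 1 matrix, 2 PSM shares, 3 QC
attributes), so each artefact is reproducible independently of the others.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .allelic import build_design
from .config import ER_CLASSES, SimConfig
from .errors import ConfigError, DesignError
from .quant import ProteinQuant

_QC_STREAM = 3  # child-stream key for PSM QC draws; tests recompute from it


def _beta_columns(config: SimConfig) -> list[str]:
    return [f"beta_{lbl}" for lbl in config.step_labels]


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw per-protein ground truth: baseline, true betas, compartment.

    Effects are sparse: at each deletion step a protein carries a nonzero
    effect with probability ``effect_sparsity`` (multiplied by
    ``enrichment_factor`` for ER-membrane proteins at the first step and
    ER-lumen proteins at the last, mirroring membrane-first / lumen-late
    remodelling); nonzero magnitudes are |N(0, effect_scale)| with a positive
    sign bias in the enriched cells. Receptor proteins named in
    ``receptor_deletions`` override this with a single large negative step
    effect (default -2.5 log2 units) at their deletion step and zero after,
    and record the genotypes in which they are deleted.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, k = config.n_proteins, config.n_steps
    receptors = list(config.receptor_deletions)
    n_rec = len(receptors)

    ids = [name for name, _ in receptors]
    ids += [f"SYNP{i:05d}" for i in range(n - n_rec)]

    compartment = rng.choice(ER_CLASSES, size=n, p=config.compartment_fractions)
    organelle = np.where(
        compartment != "none", "ER",
        rng.choice(["Golgi", "mitochondria", "cytosol", "nucleus"], size=n))
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    prob = np.full((n, k), config.effect_sparsity)
    pos_bias = np.full((n, k), 0.5)
    if k >= 1:
        enriched_first = compartment == "ER-membrane"
        enriched_last = compartment == "ER-lumen"
        prob[enriched_first, 0] = min(1.0, config.effect_sparsity * config.enrichment_factor)
        prob[enriched_last, k - 1] = min(1.0, config.effect_sparsity * config.enrichment_factor)
        pos_bias[enriched_first, 0] = config.enriched_positive_bias
        pos_bias[enriched_last, k - 1] = config.enriched_positive_bias

    nonzero = rng.random((n, k)) < prob
    magnitude = np.abs(rng.normal(0.0, config.effect_scale, size=(n, k)))
    sign = np.where(rng.random((n, k)) < pos_bias, 1.0, -1.0)
    beta = np.where(nonzero, sign * magnitude, 0.0)

    deleted_in = np.full(n, "", dtype=object)
    for i, (name, step) in enumerate(receptors):
        beta[i, :] = 0.0
        beta[i, step - 1] = config.receptor_effect
        compartment[i] = "ER-membrane"
        organelle[i] = "ER"
        deleted_in[i] = ";".join(config.genotype_series[step:])

    tm = np.zeros(n, dtype=int)
    membrane = compartment == "ER-membrane"
    tm[membrane] = rng.integers(1, 9, size=int(membrane.sum()))

    truth = pd.DataFrame({"protein_id": ids,
                          "baseline_log2": baseline,
                          "compartment": compartment,
                          "organelle": organelle,
                          "is_receptor": [i < n_rec for i in range(n)],
                          "deleted_in": deleted_in,
                          "tm_count": tm})
    for j, col in enumerate(_beta_columns(config)):
        truth[col] = beta[:, j]
    truth.attrs["step_labels"] = config.step_labels
    return truth.set_index("protein_id")


def truth_beta(truth: pd.DataFrame) -> pd.DataFrame:
    """True per-step effect matrix (proteins x steps) from a truth table."""
    cols = [c for c in truth.columns if c.startswith("beta_")]
    out = truth[cols].copy()
    out.columns = [c[len("beta_"):] for c in cols]
    return out


def make_plex_design(config: SimConfig) -> pd.DataFrame:
    """Channel -> (genotype, replicate, condition) table for one plex."""
    genos = list(config.genotype_series) + list(config.extra_genotypes)
    rows = []
    ch = 1
    for g in genos:
        for r in range(1, config.replicates_per_genotype + 1):
            rows.append({"channel": f"channel_{ch:03d}", "genotype": g,
                         "replicate": r, "condition": config.condition})
            ch += 1
    return pd.DataFrame(rows).set_index("channel")


def simulate_protein_matrix(truth: pd.DataFrame, config: SimConfig) -> ProteinQuant:
    """Linear-scale protein x channel matrix under the staircase model.

    log2 I(p, s) = baseline(p) + sum_k beta_true(p, k) x_k(genotype(s)) + eps,
    eps ~ N(0, noise_sigma^2). Extra (non-series) genotypes receive baseline
    plus noise only.
    """
    rng = np.random.default_rng([config.seed, 1])
    design = make_plex_design(config)
    series_mask = design["genotype"].isin(config.genotype_series)
    if not series_mask.any():
        raise DesignError("no samples from the genotype series in the design")
    ad = build_design(design.loc[series_mask], config.genotype_series)
    beta = truth_beta(truth).to_numpy()

    n, s = len(truth), len(design)
    log2 = np.tile(truth["baseline_log2"].to_numpy()[:, None], (1, s)).astype(float)
    log2[:, series_mask.to_numpy()] += beta @ ad.X.to_numpy().T
    log2 += rng.normal(0.0, config.noise_sigma, size=(n, s))

    intensities = pd.DataFrame(np.exp2(log2), index=truth.index,
                               columns=design.index)
    return ProteinQuant(intensities=intensities, design=design,
                        provenance={"simulated": True, "seed": config.seed,
                                    "noise_sigma": config.noise_sigma})


def simulate_psm_table(pq: ProteinQuant, config: SimConfig) -> pd.DataFrame:
    """Split protein intensities into PSMs with QC attributes.

    Each protein gets ``1 + Poisson(peptides_per_protein - 1)`` PSMs whose
    lognormal shares are identical across channels, so summing a protein's
    PSMs reproduces its channel intensities exactly. QC attributes come from
    the dedicated child stream ``default_rng([seed, 3])`` in a fixed draw
    order (SNR-failure mask over all PSMs, then purity-failure mask, then the
    attribute values, then the perturbation factors): failing PSMs get
    summed_snr <= 200 or isolation_purity <= 0.5 and their intensities are
    perturbed per channel by U(qc_perturb_range), so QC filtering measurably
    changes the rollup.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_pep = 1 + rng.poisson(config.peptides_per_protein - 1.0, size=len(pq.proteins))
    total_psms = int(n_pep.sum())

    shares = rng.lognormal(0.0, 1.0, size=total_psms)
    pos = 0
    mat = pq.intensities.to_numpy()
    channels = list(pq.samples)
    intens = np.empty((total_psms, len(channels)))
    prot_ids = np.empty(total_psms, dtype=object)
    peptides = np.empty(total_psms, dtype=object)
    for i, pid in enumerate(pq.proteins):
        m = n_pep[i]
        sh = shares[pos:pos + m]
        sh = sh / sh.sum()
        intens[pos:pos + m] = np.outer(sh, mat[i])
        prot_ids[pos:pos + m] = pid
        peptides[pos:pos + m] = [f"{pid}.pep{j + 1}" for j in range(m)]
        pos += m

    qc = np.random.default_rng([config.seed, _QC_STREAM])
    fail_snr = qc.random(total_psms) < config.frac_fail_snr
    fail_pur = qc.random(total_psms) < config.frac_fail_purity
    snr = np.where(fail_snr, qc.uniform(20.0, 200.0, total_psms),
                   qc.uniform(201.0, 5000.0, total_psms))
    purity = np.where(fail_pur, qc.uniform(0.05, 0.5, total_psms),
                      qc.uniform(0.501, 1.0, total_psms))
    failed = fail_snr | fail_pur
    if failed.any():
        lo, hi = config.qc_perturb_range
        perturb = qc.uniform(lo, hi, size=(int(failed.sum()), len(channels)))
        intens[failed] *= perturb

    psms = pd.DataFrame(intens, columns=channels)
    psms.insert(0, "protein_id", prot_ids)
    psms.insert(1, "peptide", peptides)
    psms["summed_snr"] = snr
    psms["isolation_purity"] = purity
    return psms


def simulate_experiment(config: SimConfig) -> dict:
    """Truth, protein matrix, plex design and PSM table in one call."""
    truth = generate_truth(config)
    pq = simulate_protein_matrix(truth, config)
    psms = simulate_psm_table(pq, config)
    return {"truth": truth, "protein_quant": pq, "psms": psms,
            "design": pq.design}


def truth_to_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Annotation table (Supplementary-Table-style) for the simulated proteome.

    TM-segment counts are encoded as ``_n`` name suffixes, as in curated ER
    annotation tables.
    """
    name = [f"{pid}_{tm}" if tm > 0 else pid
            for pid, tm in zip(truth.index, truth["tm_count"])]
    return pd.DataFrame({
        "name": name,
        "organelle": truth["organelle"].to_numpy(),
        "er_class": truth["compartment"].to_numpy(),
        "is_curvature": (truth["tm_count"] >= 2).to_numpy(),
        "is_receptor": truth["is_receptor"].to_numpy(),
    })


def simulate_flow_events(true_ratio: float, n_events: int, bafa: bool = False,
                         seed: int = 0, *, bafa_baseline_ratio: float = 0.25,
                         sigma: float = 0.4, neutral_mean: float = 1000.0,
                         condition: str | None = None) -> pd.DataFrame:
    """Gated flow-cytometry events with a known acidic/neutral population ratio.

    Per-event neutral (445 nm) intensities are lognormal with mean
    ``neutral_mean``; acidic (561 nm) intensities are the neutral intensity
    times the effective ratio times independent mean-one lognormal noise, so
    mean(acidic)/mean(neutral) converges to the effective ratio. ``bafa=True``
    models bafilomycin-blocked lysosomal acidification: the effective ratio is
    forced to ``bafa_baseline_ratio`` regardless of ``true_ratio``.
    """
    if true_ratio <= 0:
        raise ConfigError("true_ratio must be > 0")
    if n_events < 1:
        raise ConfigError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    eff = bafa_baseline_ratio if bafa else true_ratio
    neutral = neutral_mean * rng.lognormal(-sigma ** 2 / 2, sigma, n_events)
    noise = rng.lognormal(-sigma ** 2 / 2, sigma, n_events)
    acidic = eff * neutral * noise
    if condition is None:
        condition = ("BAFA" if bafa else f"ratio{true_ratio:g}")
    return pd.DataFrame({"event_id": np.arange(1, n_events + 1),
                         "acidic_561": acidic,
                         "neutral_445": neutral,
                         "condition": condition})
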