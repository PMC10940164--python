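"""Simulation configuration for the synthetic allelic-series TMT experiment.

The simulator emulates an isobaric-labelling (TMT) proteomics experiment on an
ordered knockout series (WT, DKO, TKO, QKO, PKO by default): per-protein log2
abundances follow the cumulative-indicator staircase model, replicate noise is
Gaussian on the log2 scale, and each protein's channel intensities are split
across peptide-spectrum matches (PSMs) with lognormal shares so that protein
rollup is exact. A configurable fraction of PSMs fail the summed-SNR and
isolation-purity quality filters, and failing PSMs carry multiplicatively
perturbed intensities so that filtering is consequential downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

DEFAULT_SERIES = ("WT", "DKO", "TKO", "QKO", "PKO")

#: Receptor gene deleted at each sequential step of the default series.
#: Step 1 (WT->DKO) removes two paralogues at once, mirroring a double knockout.
DEFAULT_RECEPTOR_DELETIONS = (
    ("FAM134A", 1),
    ("FAM134C", 1),
    ("FAM134B", 2),
    ("TEX264", 3),
    ("CCPG1", 4),
)

ER_CLASSES = ("ER-associated", "ER-membrane", "ER-lumen", "none")


@dataclass
class SimConfig:
    """Parameters of the synthetic allelic-series experiment.

    Parameters
    ----------
    n_proteins:
        Number of simulated proteins (receptor proteins included in the count).
    genotype_series:
        Ordered genotype labels; position k in the series adds the k-th
        sequential deletion.
    replicates_per_genotype:
        Biological replicates per genotype (one TMT channel each). At least 2,
        since t-tests and residual variance need within-group spread.
    peptides_per_protein:
        Mean PSM count per protein; each protein receives
        ``1 + Poisson(peptides_per_protein - 1)`` PSMs.
    noise_sigma:
        Standard deviation of the Gaussian replicate noise on the log2 scale.
    effect_sparsity:
        Baseline fraction of proteins carrying a nonzero true effect at each
        deletion step.
    effect_scale:
        Scale (log2 units) of nonzero effects: magnitudes are |N(0, scale)|.
    frac_fail_snr, frac_fail_purity:
        Fractions of PSMs drawn to fail the summed-SNR (<= 200) and
        isolation-purity (<= 0.5) quality filters.
    seed:
        Root seed; identical seed and config give byte-identical outputs.
    compartment_fractions:
        Probabilities of (ER-associated, ER-membrane, ER-lumen, none).
    enrichment_factor:
        Multiplier on ``effect_sparsity`` for ER-membrane proteins at the first
        step and ER-lumen proteins at the last step.
    enriched_positive_bias:
        Probability that an enriched compartment/step effect is positive
        (accumulation upon receptor loss); unenriched effects are sign-balanced.
    receptor_deletions:
        ``(protein_name, step)`` pairs: each named protein is knocked out at
        that 1-based step and carries ``receptor_effect`` there, zero after.
    receptor_effect:
        Log2 step effect of a receptor at its deletion step (large negative to
        keep log2 intensities finite rather than literally zero).
    qc_perturb_range:
        ``(low, high)`` of the uniform multiplicative per-channel perturbation
        applied to QC-failing PSMs.
    baseline_log2_mean, baseline_log2_sd:
        Lognormal abundance structure of protein baselines (log2 scale).
    condition:
        Condition label stamped on every channel of the plex design.
    """

    n_proteins: int = 1000
    genotype_series: tuple[str, ...] = DEFAULT_SERIES
    replicates_per_genotype: int = 3
    peptides_per_protein: float = 3.0
    noise_sigma: float = 0.25
    effect_sparsity: float = 0.1
    effect_scale: float = 0.5
    frac_fail_snr: float = 0.05
    frac_fail_purity: float = 0.05
    seed: int = 0
    compartment_fractions: tuple[float, float, float, float] = (0.10, 0.20, 0.15, 0.55)
    enrichment_factor: float = 3.0
    enriched_positive_bias: float = 0.8
    receptor_deletions: tuple[tuple[str, int], ...] = DEFAULT_RECEPTOR_DELETIONS
    receptor_effect: float = -2.5
    qc_perturb_range: tuple[float, float] = (0.1, 10.0)
    baseline_log2_mean: float = 16.0
    baseline_log2_sd: float = 1.5
    condition: str = "day12"
    extra_genotypes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.genotype_series = tuple(self.genotype_series)
        self.receptor_deletions = tuple(tuple(r) for r in self.receptor_deletions)
        self.extra_genotypes = tuple(self.extra_genotypes)
        self.validate()

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if len(self.genotype_series) < 2:
            raise ConfigError("genotype_series needs at least 2 genotypes")
        if len(set(self.genotype_series)) != len(self.genotype_series):
            raise ConfigError("genotype_series labels must be unique")
        if self.replicates_per_genotype < 2:
            raise ConfigError("replicates_per_genotype must be >= 2")
        if self.peptides_per_protein < 1:
            raise ConfigError("peptides_per_protein must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        for name in ("effect_sparsity", "frac_fail_snr", "frac_fail_purity",
                     "enriched_positive_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be >= 0")
        fr = self.compartment_fractions
        if len(fr) != 4 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigError("compartment_fractions must be 4 nonnegative values summing to 1")
        if self.enrichment_factor < 0:
            raise ConfigError("enrichment_factor must be >= 0")
        n_steps = len(self.genotype_series) - 1
        for name, step in self.receptor_deletions:
            if not 1 <= step <= n_steps:
                raise ConfigError(
                    f"receptor_deletions: step {step} for {name} outside 1..{n_steps}")
        lo, hi = self.qc_perturb_range
        if not 0 < lo <= hi:
            raise ConfigError("qc_perturb_range must satisfy 0 < low <= high")
        if len(self.receptor_deletions) > self.n_proteins:
            raise ConfigError("more receptor_deletions than n_proteins")

    @property
    def n_steps(self) -> int:
        return len(self.genotype_series) - 1

    @property
    def step_labels(self) -> list[str]:
        s = self.genotype_series
        return [f"{a}->{b}" for a, b in zip(s[:-1], s[1:])]
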