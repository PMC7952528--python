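"""Simulation configuration.

The defaults define the study conditions under which the recovery and
calibration analyses are run: a desk-scale duplicated genome (300 ancestral
genes on 5 chromosomes, 40% single-copy reversion), mildly asymmetric
post-duplication divergence with both copies under purifying selection
(omega 0.1 vs 0.2), an 8-tissue expression atlas, and a 12-vs-12 two-sex
liver count matrix in which 20% of genes carry a mean |log2 FC| of 1.5 with
a 70% female-direction bias.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class SimConfig:
    # genome / duplication
    n_genes: int = 300
    n_chromosomes: int = 5
    loss_prob: float = 0.4
    mean_protein_len: int = 200  # codons

    # sequence divergence (accepted substitutions per nucleotide site,
    # ancestor -> copy; the outgroup lineage evolves at the conserved rate)
    divergence_rate_conserved: float = 0.02
    divergence_rate_diverged: float = 0.05
    omega_conserved: float = 0.10
    omega_diverged: float = 0.20

    # annotation
    frac_immune: float = 0.3
    domain_loss_prob: float = 0.1

    # expression atlas
    n_tissues: int = 8
    n_archetypes: int = 6
    frac_divergent_profiles: float = 0.2
    frac_silent: float = 0.05

    # two-sex count matrix
    n_samples_per_sex: int = 12
    frac_sex_biased: float = 0.2
    bias_direction_prob: float = 0.7  # toward the designated sex (female)
    lfc_mean: float = 1.5
    nb_dispersion: float = 0.1

    seed: int = 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = {
            "loss_prob": self.loss_prob,
            "frac_immune": self.frac_immune,
            "domain_loss_prob": self.domain_loss_prob,
            "frac_divergent_profiles": self.frac_divergent_profiles,
            "frac_silent": self.frac_silent,
            "frac_sex_biased": self.frac_sex_biased,
            "bias_direction_prob": self.bias_direction_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "mean_protein_len": self.mean_protein_len,
            "n_tissues": self.n_tissues,
            "n_archetypes": self.n_archetypes,
            "n_samples_per_sex": self.n_samples_per_sex,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name in ("divergence_rate_conserved", "divergence_rate_diverged",
                     "omega_conserved", "omega_diverged", "lfc_mean", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "SimConfig":
        data = asdict(self)
        data.update(kwargs)
        return SimConfig(**data)
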