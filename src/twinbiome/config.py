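"""Configuration for the synthetic twin-cohort generator.

The generator emulates an adult twin-registry cohort: monozygotic (MZ) and
dizygotic (DZ) twin pairs plus unrelated singletons, tag-SNP genotypes at the
ABO, FUT2 (secretor) and LCT loci, a background SNP panel for ancestry, and a
16S OTU count table whose log-abundances carry family-shared and additive
genetic components (MZ sharing > DZ sharing > unrelated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal


# ABO tag SNPs in the order used by the haplotype lookup table, followed by
# the FUT2 secretor SNP and the LCT-region SNP.
ABO_TAG_SNPS = ("rs651007", "rs8176746", "rs8176704")
SECRETOR_SNP = "rs601338"
LCT_SNP = "rs1446585"


@dataclass(frozen=True)
class EffectSpec:
    """A phenotype effect injected into one taxon's latent log-abundance.

    ``size`` is expressed in units of the residual latent SD
    (``SimConfig.residual_sd``); samples whose ``phenotype`` value equals
    ``level`` receive a shift of ``size * residual_sd`` on the latent scale.
    """

    taxon: int
    phenotype: Literal["abo", "secretor"]
    level: str
    size: float


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the scale and demographics of a large adult twin
    registry: ~750 twin families plus singletons (1503 individuals), 91%
    female, age ~ Normal(61, 10). Allele frequencies are set so that the
    expected ABO phenotype mix under Hardy-Weinberg matches a UK cohort
    (O ~ 48%, A ~ 40%, B ~ 9%, AB ~ 3%).
    """

    # cohort structure
    n_mz_pairs: int = 315
    n_dz_pairs: int = 314
    n_unrelated: int = 245

    # demographics / technical covariates
    male_fraction: float = 0.09
    age_mean: float = 61.0
    age_sd: float = 10.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.5
    n_shipment_batches: int = 4
    n_technicians: int = 3
    mean_depth: float = 20000.0
    depth_dispersion: float = 8.0  # negative-binomial shape; larger = tighter

    # phenotyping of the cohort (serology vs genotype inference)
    typed_fraction: float = 0.59       # fraction with serotyped ABO available
    typing_error_rate: float = 0.02    # serology/genotype discordance rate
    secretor_unknown_fraction: float = 0.034

    # genetics
    abo_allele_freqs: dict[str, float] = field(
        default_factory=lambda: {"A1": 0.18, "A2": 0.065, "B": 0.065, "O": 0.69}
    )
    nonsecretor_allele_freq: float = 0.52  # rs601338 A allele
    lct_allele_freq: float = 0.74          # rs1446585 effect allele
    n_background_snps: int = 500
    # two-subpopulation ancestry structure; 0 disables it
    subpop2_fraction: float = 0.0
    subpop_divergence: float = 0.1  # SD of logit-scale allele-frequency drift

    # microbiome generative model (latent log-abundance components)
    n_otus: int = 200
    baseline_sd: float = 2.0
    family_sd: float = 0.3
    additive_sd: float = 0.5
    residual_sd: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.1, "sex": 0.1, "depth": 0.1, "batch": 0.1}
    )
    effect_spec: list[EffectSpec] = field(default_factory=list)
    # fraction of OTUs left unassigned at the genus rank
    unassigned_genus_fraction: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return 2 * self.n_mz_pairs + 2 * self.n_dz_pairs + self.n_unrelated

    def validate(self) -> None:
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_unrelated) < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_samples == 0:
            raise ValueError("cohort has zero samples")
        total = sum(self.abo_allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"abo_allele_freqs must sum to 1 (got {total!r})"
            )
        for name, f in self.abo_allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency of {name} outside [0, 1]")
        for name in ("nonsecretor_allele_freq", "lct_allele_freq",
                     "male_fraction", "typed_fraction", "typing_error_rate",
                     "secretor_unknown_fraction", "subpop2_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("baseline_sd", "family_sd", "additive_sd", "residual_sd",
                     "age_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for spec in self.effect_spec:
            if not 0 <= spec.taxon < self.n_otus:
                raise ValueError(
                    f"effect_spec taxon {spec.taxon} outside [0, {self.n_otus})"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        """Write the configuration as JSON."""
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "SimConfig":
        import json
        from pathlib import Path

        raw = json.loads(Path(path).read_text())
        raw["effect_spec"] = [EffectSpec(**e)
                              for e in raw.get("effect_spec", [])]
        return cls(**raw)
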