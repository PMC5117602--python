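"""Shared demo-cohort settings for the numbered analysis scripts.

The demo cohort is a scaled-down twin registry (700 individuals, 120 OTUs)
so the full script sequence runs in a few minutes; every step uses the same
library code that the tests validate at cohort scale.
"""

from pathlib import Path

from twinbiome.config import EffectSpec, SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 20160926
RAREFACTION_DEPTH = 3000

DEMO_CONFIG = SimConfig(
    n_mz_pairs=150,
    n_dz_pairs=150,
    n_unrelated=100,
    n_otus=120,
    n_background_snps=150,
    mean_depth=6000,
    additive_sd=1.0,
    # one secretor-associated OTU so the association stages have a known
    # positive control; taxon 74 (OTU_00089) is common (~90% prevalence)
    # but not dominant under this seed, so the compositional spillover of
    # the injected shift onto other taxa stays small
    effect_spec=[EffectSpec(taxon=74, phenotype="secretor", level="NS",
                            size=0.8)],
    seed=SEED,
)
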