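"""Small published inputs used by the comparative analyses.

These are literature-compiled constants (life-history stage timings, the
cross-mammal compilation of male mutation bias vs paternal age, and external
human regression coefficients), shipped as data so the comparative operations
run without network access.
"""

from __future__ import annotations

import pandas as pd

#: Cross-mammal pedigree estimates of the male-to-female mutation ratio
#: (alpha) with the study's mean paternal age at conception (years).  One row
#: per study; ``duplicate_species`` marks the second study of an
#: already-represented species, excluded from the alpha-vs-age regression.
MAMMAL_ALPHA = pd.DataFrame(
    [
        ("baboon", 10.27, 4.50, False),
        ("human", 34.29, 4.00, False),
        ("human_deCODE", 31.63, 4.05, True),
        ("chimpanzee", 19.27, 4.37, False),
        ("chimpanzee_single_trio", 24.0, 3.08, True),
        ("gorilla", 13.5, 2.00, False),
        ("orangutan", 31.0, 4.13, False),
        ("macaque", 7.5, 3.21, False),
        ("owl_monkey", 5.55, 2.09, False),
        ("mouse", 0.44, 2.76, False),
        ("cattle", 5.0, 2.53, False),
    ],
    columns=["species", "mean_paternal_age", "alpha", "duplicate_species"],
)

#: Haploid autosomal genome sizes (bp) of the two reference assemblies.
HAPLOID_GENOME_BP = {"human": 2_881_033_286, "baboon": 2_581_196_250}

#: Orthologous accessible territory shared by the two species (bp).
ORTHOLOGOUS_BP = 1_631_476_416

#: Callable genome (bp) of the external 3-generation human study whose
#: regression coefficients are rescaled by H/R before comparison.  Stored as
#: published; overridable wherever it is consumed.
EXTERNAL_CALLABLE_R_BP = 2_682_890

#: External human identity-link Poisson coefficients after H/R genome
#: rescaling: paternal slope (DNMs/yr) and the alpha they imply at typical
#: reproductive ages.
EXTERNAL_HUMAN_PATERNAL_SLOPE = 1.35
EXTERNAL_HUMAN_ALPHA = 4.106

#: Typical life-history timings (years unless noted).
LIFE_HISTORY = {
    "human": dict(
        G_m=32.0,
        G_f=28.2,
        gestation=0.767,  # 280 days
        puberty_m=13.0,
        ssc_cycle_days=16.0,
    ),
    "baboon": dict(
        G_m=10.7,
        G_f=10.2,
        gestation=0.468,  # ~171 days (Papio)
        puberty_m=5.41,
        ssc_cycle_days=11.0,
    ),
}

#: Germline cell-division counts by developmental stage (shared across
#: mammals for stages 1-3 absent species-specific data): zygote to sex
#: differentiation, sex differentiation to birth (male/female), and the
#: spermatogenesis tail after the last spermatogonial stem-cell division.
CELL_DIVISION_STAGES = dict(
    stage1=16,
    stage2_male=21,
    stage2_female=15,
    stage3_male=0,
    spermatogenesis_tail=4,
)
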