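import numpy as np
import pandas as pd
import pytest

from pathburden.pathway_db import GeneSet
from pathburden.synthetic_data import (
    CONTAMINANT_RULES,
    GeneModel,
    SimulationConfig,
    generate_cohort,
)
from pathburden.variant_model import ANNOTATION_MAF_COLUMNS, CohortTable

RECORD_DEFAULTS = {
    "chrom": "1", "pos": 1, "ref": "A", "alt": "C",
    "site_qual": 100.0, "mapping_quality": 60.0,
    "gene": "G1", "region": "exonic", "consequence": "nonsynonymous SNV",
    "maf_1000g_all": np.nan, "maf_esp6500": np.nan,
    "maf_gnomad_all": np.nan, "maf_gnomad_eas": np.nan,
    "sift_call": "deleterious", "polyphen_call": "deleterious",
    "mutationtaster_call": "deleterious", "cadd_phred": 30.0,
    "dbscsnv_splice_relevant": pd.NA, "in_repeat_region": False,
    "indel_length": 0, "splice_distance_bp": np.nan,
}


def make_cohort(
    rows,
    n_cases: int = 1,
    n_controls: int = 1,
    genotypes=None,
    depths=None,
) -> CohortTable:
    """Build a joined cohort table from per-record field overrides.

    Default genotypes: every sample het; default depths: 50 everywhere.
    """
    n_samples = n_cases + n_controls
    records = pd.DataFrame(
        [{**RECORD_DEFAULTS, "pos": i + 1, **row} for i, row in enumerate(rows)]
    )
    samples = pd.DataFrame({
        "sample_id": [f"case_{i}" for i in range(n_cases)]
        + [f"ctrl_{i}" for i in range(n_controls)],
        "group": ["case"] * n_cases + ["control"] * n_controls,
    })
    gt = (np.asarray(genotypes, dtype=np.int8) if genotypes is not None
          else np.ones((len(rows), n_samples), dtype=np.int8))
    dp = (np.asarray(depths, dtype=np.int32) if depths is not None
          else np.full((len(rows), n_samples), 50, dtype=np.int32))
    return CohortTable(samples=samples, records=records,
                       genotypes=gt, depths=dp)


@pytest.fixture(scope="session")
def toy_config() -> SimulationConfig:
    """A small cohort with planted structure and contaminants for every rule."""
    return SimulationConfig(
        n_cases=30,
        n_controls=20,
        genes=(
            GeneModel("GENEA", case_carrier_prob=0.5, control_carrier_prob=0.1),
            GeneModel("GENEB", case_carrier_prob=1.0, control_carrier_prob=0.0),
            GeneModel("GENEC", case_carrier_prob=0.2, control_carrier_prob=0.2),
        ),
        background_gene_count=20,
        background_carrier_prob=0.05,
        pathways=(GeneSet("P1", "toy pathway", frozenset({"GENEA", "GENEB"})),),
        contaminants_per_rule=tuple((r, 4) for r in CONTAMINANT_RULES),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_sim(toy_config):
    return generate_cohort(toy_config)


@pytest.fixture()
def toy_cohort(toy_sim) -> CohortTable:
    return toy_sim.to_cohort_table()
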