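import numpy as np
import pandas as pd
import pytest

from fibromark.preprocess import MethylationCohort
from fibromark.simdata import MethCohortConfig, simulate_methylation_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest clean-ish cohort with planted effects, shared across tests."""
    cfg = MethCohortConfig(
        seed=11,
        n_probes=2000,
        n_loci=400,
        planted_loci=(("GENE00003", -0.8, 2),),
        planted_baselines={"GENE00003": 0.55},
    )
    return simulate_methylation_cohort(cfg)


@pytest.fixture()
def tiny_cohort():
    """A hand-built 6-probe x 4-sample cohort for exact filter checks."""
    probes = pd.Index([f"cg{i:08d}" for i in range(6)], name="probe_id")
    samples = pd.Index([f"S{i}" for i in range(4)], name="sample_id")
    rng = np.random.default_rng(5)
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, (6, 4)), index=probes, columns=samples)
    detection_p = pd.DataFrame(np.zeros((6, 4)), index=probes, columns=samples)
    bead_count = pd.DataFrame(np.full((6, 4), 10), index=probes, columns=samples)
    annotation = pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": np.arange(1, 7) * 100,
            "strand": "+",
            "design_type": ["I", "II", "I", "II", "I", "II"],
            "gene_symbols": ["GA", "GA", "GB", "", "GC", "GC"],
            "region_relation": "body",
            "cgi_relation": "island",
            "snp_associated": [False, False, True, False, False, False],
        },
        index=probes,
    )
    sheet = pd.DataFrame(
        {
            "fibrosis": [1, 1, 0, 0],
            "age": [55.0, 60.0, 50.0, 65.0],
            "smoker_ever": [0, 1, 0, 1],
            "chemotherapy": [1, 0, 0, 1],
        },
        index=samples,
    )
    return MethylationCohort(
        beta=beta,
        detection_p=detection_p,
        bead_count=bead_count,
        annotation=annotation,
        samples=sheet,
    )
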