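import pandas as pd
import pytest

import pam50kit as pk
from pam50kit.normalization import RnaSeqNormConfig
from pam50kit.synthetic_data import generate_reference_medians


@pytest.fixture(scope="session")
def centroids():
    return pk.generate_centroids(seed=11)


@pytest.fixture(scope="session")
def pam_config():
    return pk.Pam50Config.default()


@pytest.fixture(scope="session")
def paired_pipeline():
    """Run simulate -> normalize -> classify on both platforms.

    Returns (cohort, matrix_ns, matrix_rs, calls_ns, calls_rs).
    """

    def run(cfg: pk.SimulationConfig):
        cohort = pk.simulate_cohort(cfg)
        matrix_ns = pk.run_nanostring_pipeline(
            cohort.probe_counts, cohort.housekeepers
        )
        calls_ns = pk.classify_cohort(matrix_ns, cohort.centroids)
        ref = generate_reference_medians(cohort.centroids)
        matrix_rs = pk.run_rnaseq_pipeline(
            cohort.rnaseq_raw, RnaSeqNormConfig(reference_medians=ref)
        )
        calls_rs = pk.classify_cohort(matrix_rs, cohort.centroids)
        return cohort, matrix_ns, matrix_rs, calls_ns, calls_rs

    return run


@pytest.fixture
def small_probe_table():
    ann = pd.DataFrame(
        {
            "gene_symbol": ["ESR1", "ERBB2", "ACTB", "NEGA", "NEGB"],
            "probe_class": [
                "endogenous", "endogenous", "housekeeping", "negative",
                "negative",
            ],
        },
        index=pd.Index(
            ["p_ESR1", "p_ERBB2", "p_ACTB", "p_NEGA", "p_NEGB"],
            name="probe_name",
        ),
    )
    counts = pd.DataFrame(
        {
            "s1": [100.0, 40.0, 80.0, 10.0, 14.0],
            "s2": [220.0, 55.0, 160.0, 9.0, 9.0],
        },
        index=ann.index,
    )
    return pk.ProbeCountTable(annotations=ann, counts=counts)


def make_call(sample_id, corrs, **kw):
    """Construct a Pam50Call from a subtype->correlation mapping."""
    order = sorted(pk.SUBTYPES, key=lambda s: -corrs[s])
    defaults = dict(
        centroid_correlations=dict(corrs),
        call=order[0],
        second_call=order[1],
        confidence=1.0,
        ambiguous=False,
        proliferation_score=0.0,
        ror_s=50.0,
        ror_s_group="med",
        ror_ps=50.0,
        ror_ps_group="med",
    )
    defaults.update(kw)
    return pk.Pam50Call(sample_id=sample_id, **defaults)
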