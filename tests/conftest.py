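import warnings

import pytest

from psdremodel import pipeline, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(
        n_proteins=300, frac_ddp=0.2, frac_dip=0.2, frac_stage_specific=0.05, seed=7
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A compact synthetic study shared across tests (read-only)."""
    table, truth = synthetic.simulate_quant_table(small_config)
    courses = synthetic.simulate_transcriptomes(small_config, truth)
    asd = synthetic.simulate_asd_table(
        truth, small_config.asd_anticorrelation_rho,
        small_config.seed + synthetic.SEED_ASD,
    )
    halflife = synthetic.simulate_halflife_table(small_config, truth)
    sets = synthetic.simulate_reference_genesets(small_config, truth)
    return {
        "config": small_config,
        "table": table,
        "truth": truth,
        "courses": courses,
        "asd": asd,
        "halflife": halflife,
        "sets": sets,
    }


@pytest.fixture(scope="session")
def default_summary(tmp_path_factory):
    """Full pipeline run at the default study conditions (n=2000)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = pipeline.PipelineConfig(seed=1, outdir=str(outdir))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = pipeline.run_pipeline(config)
    return summary, outdir
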