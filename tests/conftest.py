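import pytest

from triomr.pipeline import PipelineConfig, bundled_scenario_path, run_pipeline
from triomr.synthetic_cohort import (RegionSpec, simulate_haplotype_panel,
                                     simulate_trios)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the bundled demo scenario, shared read-only."""
    cfg = PipelineConfig.from_yaml(bundled_scenario_path())
    out = tmp_path_factory.mktemp("demo_run")
    run_pipeline(cfg, seed=7, out_dir=out)
    return out


@pytest.fixture
def small_region():
    return RegionSpec(
        region_id="R1", chrom="2",
        positions=(100, 200, 300, 400, 500),
        maf=(0.3, 0.2, 0.4, 0.25, 0.35),
        ld_r=0.5,
    )


@pytest.fixture
def small_panel(small_region):
    return simulate_haplotype_panel(small_region, n_founders=500, seed=11)


@pytest.fixture
def small_trios(small_panel):
    return simulate_trios(small_panel, n_trios=400, seed=11)
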