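import pytest
from hypothesis import settings as _hyp_settings

from dupmeth.pipeline import RunConfig, run_pipeline

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
from dupmeth.simulate import ScenarioConfig, scenario_headline


def small_scenario_config(seed: int = 3) -> ScenarioConfig:
    """A scaled-down headline scenario for fast integration tests."""
    return ScenarioConfig(
        seed=seed,
        n_pairs=30,
        n_trios=3,
        n_consistent_pairs=8,
        n_codons=150,
        spike_sites=500,
        depth_mean=15.0,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = scenario_headline(small_scenario_config(), str(outdir))
    return paths


def run_config_for(paths, outdir) -> RunConfig:
    return RunConfig(
        proteins=paths["proteins"],
        cds=paths["cds"],
        hits=paths["hits"],
        annotation=paths["annotation"],
        chrom_sizes=paths["chrom_sizes"],
        expression=paths["expression"],
        outgroup=paths["outgroup"],
        domains=paths["domains"],
        promoters=paths["promoters"],
        methylomes=paths["methylomes"],
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    cfg = run_config_for(small_bundle, outdir)
    results = run_pipeline(cfg)
    return cfg, results
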