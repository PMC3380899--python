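import pytest

from aggquant import pipeline, simulate


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One default-condition synthetic experiment shared across tests."""
    root = tmp_path_factory.mktemp("defaultsim")
    config = simulate.SimulationConfig(seed=1234)
    proteins = simulate.generate_proteome(config, str(root / "proteome.fasta"))
    paths = simulate.simulate_experiment(config, proteins, str(root))
    paths["fasta"] = str(root / "proteome.fasta")
    return config, proteins, paths


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run over the shared synthetic experiment."""
    config, proteins, paths = default_sim
    outdir = tmp_path_factory.mktemp("defaultrun")
    pc = pipeline.PipelineConfig(
        outdir=str(outdir),
        fasta=paths["fasta"],
        features=paths["features"],
        psm=paths["psm"],
        targeted_scans=paths["targeted"],
        traces=paths["traces"],
        seed=config.seed,
    )
    bundle = pipeline.run_pipeline(pc)
    return pc, bundle
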