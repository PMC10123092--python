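import pytest

from riboselect.synthetic import (
    SimConfig,
    simulate_footprints,
    simulate_rna_counts,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-condition simulated dataset shared across tests."""
    cfg = SimConfig(n_transcripts=60, seed=11)
    transcripts, truth = simulate_transcriptome(cfg)
    libs = {cond: simulate_footprints(transcripts, truth, cond, cfg)
            for cond in ("control", "knockdown")}
    rna = {cond: simulate_rna_counts(transcripts, cond, cfg)
           for cond in ("control", "knockdown")}
    return cfg, transcripts, truth, libs, rna
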