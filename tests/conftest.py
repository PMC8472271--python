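import pytest

from mirddr import pipeline, simdata


class DefaultSim:
    """One fully simulated + analysed experiment, shared across tests."""

    def __init__(self, seed: int = 1):
        self.config = simdata.default_config(seed=seed)
        self.refs, self.truth = simdata.build_references(self.config)
        self.libs = simdata.simulate_libraries(self.config, self.refs, self.truth)
        self.result = pipeline.run_stages(
            self.refs, self.libs.reads_ck, self.libs.reads_tr
        )


@pytest.fixture(scope="session")
def default_sim() -> DefaultSim:
    return DefaultSim(seed=1)
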