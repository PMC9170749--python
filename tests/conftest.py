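import numpy as np
import pytest

from mirforge import discovery, profiling, synthetic

# One moderate simulated study shared by several test modules: 2 stages x 2
# replicates, 10 planted hairpins, modest depth so the whole suite stays fast.
SMALL_CFG = synthetic.SimulationConfig(
    genome_len=60_000,
    n_hairpins=10,
    stages=[("egg", 2), ("adult", 2)],
    pirna_fraction_by_stage={"egg": 0.40, "adult": 0.25},
    read_depth=120_000,
    seed=7,
    contaminant_count=2,
)


@pytest.fixture(scope="session")
def small_sim():
    genome, truth, contaminants = synthetic.plant_genome(SMALL_CFG)
    libraries, manifest = synthetic.simulate_reads(genome, truth, SMALL_CFG,
                                                   contaminants)
    return {"cfg": SMALL_CFG, "genome": genome, "truth": truth,
            "contaminants": contaminants, "libraries": libraries,
            "manifest": manifest}


@pytest.fixture(scope="session")
def small_collapsed(small_sim):
    collapsed = {lib: profiling.collapse_reads(reads, lib)
                 for lib, reads in small_sim["libraries"].items()}
    lib_sizes = {lib: sum(r.count for r in col) for lib, col in collapsed.items()}
    return collapsed, lib_sizes


@pytest.fixture(scope="session")
def small_discovery(small_sim, small_collapsed):
    collapsed, lib_sizes = small_collapsed
    filtered = {lib: profiling.length_filter(col) for lib, col in collapsed.items()}
    records = discovery.discover(
        filtered, small_sim["genome"], discovery.DiscoveryParams(),
        contaminant_db={c.name: c.sequence for c in small_sim["contaminants"]},
        lib_sizes=lib_sizes)
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(42)
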