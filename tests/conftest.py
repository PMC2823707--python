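import numpy as np
import pytest

from hybtherm import hybmodel, nn_thermo, synth


@pytest.fixture(scope="session")
def dna_params():
    return nn_thermo.load_parameter_set("DNA/DNA")


@pytest.fixture(scope="session")
def rna_params():
    return nn_thermo.load_parameter_set("RNA/RNA")


@pytest.fixture(scope="session")
def hybrid_params():
    return nn_thermo.load_parameter_set("RNA/DNA")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_benchmark():
    """Shared synthetic cDNA-style benchmark: ~270 probes with profiles.

    All targets expressed so every probe carries energy-driven signal.
    """
    cfg = synth.cdna_preset(seed=11, n_targets=30, target_length=(150, 300),
                            frac_expressed=1.0)
    targets = synth.random_targets(cfg)
    tdict = {r.id: str(r.seq) for r in targets}
    probes = synth.tile_probes(targets, cfg)
    pmap = hybmodel.map_probes(probes, tdict)
    profiles = hybmodel.profile_probes(
        probes, tdict, target_chemistry="DNA", pmap=pmap
    )
    return {
        "config": cfg,
        "targets": tdict,
        "probes": probes,
        "pmap": pmap,
        "profiles": profiles,
    }
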