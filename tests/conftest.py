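import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_system():
    """Small fitted membrane system with protein wall and waters."""
    import memtraj as mt

    spec = mt.SyntheticSpec(seed=11, n_frames=40)
    spec.bilayer.lipids_per_leaflet = 60
    frames, roles, truth = mt.make_membrane_system(spec)
    return spec, frames, roles, truth


def membrane_refs(frames, roles):
    import memtraj as mt

    phos = mt.selection_from_roles(roles, "phosphate")
    gly = mt.selection_from_roles(roles, "glycerol")
    lipid = mt.BeadSelection(
        np.concatenate([phos.indices, gly.indices]), phos.labels + gly.labels, "other"
    )
    leaflets = mt.assign_leaflets(frames, phos)
    refs = mt.membrane_centers(frames, gly, lipid, leaflets)
    return phos, gly, lipid, refs
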