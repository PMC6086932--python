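import numpy as np
import pytest

from endonano import synthetic_data as sd


@pytest.fixture
def ring_spec():
    return sd.StructureSpec(
        shape="ring", center=(500.0, 500.0), r_out=70.0, dr=30.0, n_molecules=150
    )


@pytest.fixture
def ring_table(ring_spec):
    """A grouped-quality localization table of a single ring site."""
    positions = sd.sample_structure(ring_spec, seed=11)
    manifest = sd.GroundTruthManifest([ring_spec], [positions])
    model = sd.EmissionModel(mean_blinks=2.0, precision_mean=15.0, precision_sd=3.0)
    return sd.emit_localizations(manifest, model, n_frames=2000, seed=12, fov_nm=(1000, 1000))


def radial_distances(positions, center):
    pos = np.asarray(positions, float)
    return np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1])
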