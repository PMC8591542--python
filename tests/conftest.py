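import warnings

import numpy as np
import pytest

from ermorph.synth import cortical_spec, mid_spec, render_cortical_field, render_mid_field

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="skimage")


@pytest.fixture(scope="session")
def mid_field():
    """One default mid-section field (band coverage 0.9, 2 gaps per cell)."""
    return render_mid_field(mid_spec(seed=42))


@pytest.fixture(scope="session")
def cortical_field():
    """One cortical field with tubules, sheets and one cluster patch."""
    return render_cortical_field(
        cortical_spec(
            seed=42,
            n_slices=1,
            target_tubule_fraction=0.18,
            target_sheet_fraction=0.2,
            target_cluster_fraction=0.05,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_cortical(seed, **kw):
    """A fast-to-render cortical spec for bulk property tests."""
    defaults = dict(
        image_size=(128, 128),
        n_cells=2,
        cell_radius_range=(14.0, 20.0),
        n_slices=1,
        target_tubule_fraction=0.15,
        target_sheet_fraction=0.15,
    )
    defaults.update(kw)
    return cortical_spec(seed=seed, **defaults)
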