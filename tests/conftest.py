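import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from hydromelt.melting_diagram import MeltingDiagram
from hydromelt.units_scales import CELSIUS_OFFSET


def md_from_tfn(t_fn, n, n_err=None, sample_id="test"):
    """Build a MeltingDiagram directly from T_fn and n arrays."""
    t_fn = np.asarray(t_fn, dtype=float)
    return MeltingDiagram(
        temperature=t_fn * CELSIUS_OFFSET,
        t_fn=t_fn,
        n=np.asarray(n, dtype=float),
        n_err=None if n_err is None else np.asarray(n_err, dtype=float),
        sample_id=sample_id,
    )


@pytest.fixture
def ubq_spec_dict():
    return {
        "protein_name": "UBQ",
        "concentration_mg_ml": 50.0,
        "molecular_weight_da": 8565.0,
        "residue_count": 76,
    }
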