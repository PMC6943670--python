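import numpy as np
import pytest

from fieldqsar.structures import CompoundStructure


@pytest.fixture
def make_structure():
    """Factory for bare geometric structures without going through RDKit."""

    def _make(
        coords,
        charges=None,
        radii=None,
        compound_id="M",
        skeleton=None,
        hydrophobic=None,
        donor=None,
        acceptor=None,
    ):
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = coords.shape[0]
        return CompoundStructure(
            compound_id=compound_id,
            elements=["C"] * n,
            coords=coords,
            partial_charges=np.zeros(n) if charges is None else np.asarray(charges, float),
            vdw_radii=np.full(n, 1.7) if radii is None else np.asarray(radii, float),
            hydrophobic=np.zeros(n) if hydrophobic is None else np.asarray(hydrophobic, float),
            is_donor=np.zeros(n, bool) if donor is None else np.asarray(donor, bool),
            is_acceptor=np.zeros(n, bool) if acceptor is None else np.asarray(acceptor, bool),
            skeleton_atom_indices=() if skeleton is None else tuple(skeleton),
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
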