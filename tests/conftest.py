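import numpy as np
import pytest

from ktgo.fixtures import BundleSpec, HelixSpec, make_ideal_helix, make_three_helix_bundle
from ktgo.go_builder import build_go_model
from ktgo.simulate import minimize


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(HelixSpec(12))


@pytest.fixture(scope="session")
def extended8():
    return make_ideal_helix(HelixSpec(8, phi=180.0, psi=180.0))


@pytest.fixture(scope="session")
def bundle():
    return make_three_helix_bundle(BundleSpec())


@pytest.fixture(scope="session")
def bundle_model(bundle):
    return build_go_model(bundle)


@pytest.fixture(scope="session")
def minimized_bundle(bundle_model):
    coords, history = minimize(bundle_model)
    return coords, history


def brute_force_contacts(cg, cutoff=4.5, min_separation=3):
    """Independent O(n^2) double loop over SC bead pairs (the oracle)."""
    out = []
    sc = [i for i, b in enumerate(cg.beads) if b.site_type == "SC"]
    for a in range(len(sc)):
        for b_ in range(a + 1, len(sc)):
            i, j = sc[a], sc[b_]
            ri = cg.beads[i].residue_index
            rj = cg.beads[j].residue_index
            delta = cg.beads[i].position - cg.beads[j].position
            d = float(np.sqrt(np.sum(delta * delta)))
            if abs(ri - rj) >= min_separation and d <= cutoff:
                out.append((i, j, d))
    return sorted(out)


def assert_contact_lists_equal(found, oracle):
    """Pair indices must match exactly; distances to high precision."""
    assert [(i, j) for i, j, _ in found] == [(i, j) for i, j, _ in oracle]
    np.testing.assert_allclose([d for *_ij, d in found],
                               [d for *_ij, d in oracle], rtol=0, atol=1e-12)
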