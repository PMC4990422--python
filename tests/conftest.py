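import numpy as np
import pytest

from thermonet import ParameterSet, default_model, load_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def params(model):
    return model.default_parameters()


def _square_doc(K1=1e-6, K2=3e-4, K3=1e-4, K4=None, free=False):
    """Complete two-ligand square: P binds R and T with a coupling feature.

    K4 (T-bound P binding R) is always derived: K4 = K1*K3/K2 by energy
    conservation around the square.
    """
    return {
        "components": [
            {"id": "P", "kind": "protein", "binds_atp": True},
            {"id": "R", "kind": "rna"},
            {"id": "T", "kind": "nucleotide"},
        ],
        "species": [
            {"proteins": {"P": 1}, "rna": False, "atp_sites": {"P": False}, "features": []},
            {"proteins": {"P": 1}, "rna": True, "atp_sites": {"P": False}, "features": ["KR"]},
            {"proteins": {"P": 1}, "rna": False, "atp_sites": {"P": True}, "features": ["KT"]},
            {"proteins": {"P": 1}, "rna": True, "atp_sites": {"P": True}, "features": ["KR", "KT", "KRT"]},
        ],
        "reactions": [
            {"id": "r1", "reactant": "P", "ligand": "R", "product": "P-R", "group": "KR"},
            {"id": "r2", "reactant": "P", "ligand": "T@P", "product": "P-TP", "group": "KT"},
            {"id": "r3", "reactant": "P-R", "ligand": "T@P", "product": "P-R-TP", "group": "KRT"},
            {"id": "r4", "reactant": "P-TP", "ligand": "R", "product": "P-R-TP", "group": "KRT"},
        ],
        "groups": [
            {"id": "KR", "representative": "r1", "K_half": None if free else K1},
            {"id": "KT", "representative": "r2", "K_half": None if free else K2},
            {"id": "KRT", "representative": "r3", "K_half": None if free else K3},
        ],
    }


@pytest.fixture
def square_doc():
    return _square_doc()


@pytest.fixture
def toy_square():
    return load_model(_square_doc())


@pytest.fixture
def square_params():
    return ParameterSet({"KR": 1e-6, "KT": 3e-4, "KRT": 1e-4}, {})


@pytest.fixture
def toy_binary():
    """Single binding step P + R <=> P-R."""
    return load_model({
        "components": [
            {"id": "P", "kind": "protein"},
            {"id": "R", "kind": "rna"},
        ],
        "species": [
            {"proteins": {"P": 1}, "rna": False, "features": []},
            {"proteins": {"P": 1}, "rna": True, "features": ["KR"]},
        ],
        "reactions": [
            {"id": "r1", "reactant": "P", "ligand": "R", "product": "P-R", "group": "KR"},
        ],
        "groups": [{"id": "KR", "representative": "r1", "K_half": 1e-7}],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(0)
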