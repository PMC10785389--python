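import numpy as np
import pytest

from mdcapnet.pipeline import DataBundle
from mdcapnet.simulate import SyntheticSpec, generate_bundle
from mdcapnet.types import AssociationMatrix, MirnaProfileSet


@pytest.fixture(scope="session")
def small_bundle() -> DataBundle:
    """Compact strong-signal bundle shared by integration tests."""
    spec = SyntheticSpec(n_mirnas=30, n_diseases=20, n_groups=3, signal=0.9, seed=11)
    profiles, dag, md, noncausal = generate_bundle(spec)
    return DataBundle(profiles, dag, md, noncausal)


@pytest.fixture
def tiny_profiles() -> MirnaProfileSet:
    return MirnaProfileSet(
        mirna_ids=["m1", "m2", "m3"],
        precursor_seq={"m1": "ACGUACGUAC", "m2": "ACGUACGUAC", "m3": "UUUUGGGGCC"},
        mature_seq={"m1": "ACGUACG", "m2": "ACGAACG", "m3": "GGGGCCC"},
        seed_seq={"m1": "CGUACG", "m2": "CGAACG", "m3": "GGGCCC"},
        tf_profile={"m1": np.array([1, 0, 1.0]), "m2": np.array([1, 0, 0.0]),
                    "m3": np.array([0, 1, 1.0])},
        target_profile={"m1": np.array([1, 1, 0.0]), "m2": np.array([1, 0, 0.0]),
                        "m3": np.array([0, 0, 1.0])},
        expression_profile={"m1": np.array([1.0, 2.0]), "m2": np.array([1.0, 2.0]),
                            "m3": np.array([5.0, 0.5])},
        pathway_profile={"m1": np.array([2.0, 0.0, 1.0]), "m2": np.array([2.0, 0.0, 0.9]),
                         "m3": np.array([0.0, 3.0, 0.0])},
    )


@pytest.fixture
def tiny_md() -> AssociationMatrix:
    values = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
    return AssociationMatrix(values, ["m1", "m2", "m3"], ["d1", "d2"])
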