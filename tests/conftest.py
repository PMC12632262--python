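import numpy as np
import pytest

from psrkit import (
    AlignedDomainSet,
    LandmarkMap,
    build_landmark_map,
    chey_reference,
)


@pytest.fixture(scope="session")
def chey():
    """(reference_id, sequence, landmark residue numbers) for E. coli CheY."""
    return chey_reference()


@pytest.fixture(scope="session")
def chey_alignment(chey):
    """Tiny 3-row alignment containing the ungapped CheY reference row."""
    ref_id, seq, _ = chey
    variant = "A" + seq[1:]          # point change, same length
    gapped = seq[:50] + "-" * 4 + seq[54:]  # 4 residues dropped to gaps
    return AlignedDomainSet(
        "toy",
        ((ref_id, seq), ("var1", variant), ("var2", gapped)),
    )


@pytest.fixture(scope="session")
def chey_map(chey, chey_alignment):
    ref_id, _, landmarks = chey
    return build_landmark_map(chey_alignment, ref_id, landmarks)


@pytest.fixture
def toy_map():
    """Gapless 20-column identity map with landmarks in order."""
    return LandmarkMap.identity(
        {"DD1": 2, "DD2": 3, "D": 8, "T": 13, "K": 17}, 20
    )


def make_alignment(rows, label="toy"):
    return AlignedDomainSet(
        label, tuple((f"s{i}", r) for i, r in enumerate(rows))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
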