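import numpy as np
import pytest

from oligoms.chem import MonomerRegistry, Oligo, parse_sequence

CODES = ["A", "C", "G", "T", "mC", "lA", "lT", "eG", "eC"]


@pytest.fixture(scope="session")
def registry() -> MonomerRegistry:
    return MonomerRegistry.default()


def make_random_oligo(rng: np.random.Generator, n: int | None = None) -> Oligo:
    """Random modified oligo with a mixed PS/PO backbone."""
    if n is None:
        n = int(rng.integers(3, 9))
    codes = [CODES[i] for i in rng.integers(0, len(CODES), n)]
    links = ["*" if rng.random() < 0.7 else "." for _ in range(n - 1)]
    text = codes[0] + "".join(l + c for l, c in zip(links, codes[1:]))
    return parse_sequence(text)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def oligo16() -> Oligo:
    # 16-mer gapmer-style: cEt wings, DNA core, full PS backbone
    return parse_sequence(
        "eG*eC*eT*A*T*G*C*T*A*G*C*T*A*eG*eC*eT"
    )
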