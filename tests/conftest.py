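import random

import pytest

from covafold.energy_model import default_parameters
from covafold.guide import GuideStructure
from covafold.msa_io import is_canonical, pairs_cross


@pytest.fixture(scope="session")
def params():
    return default_parameters()


def random_sequence(rng: random.Random, n: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_guide(
    rng: random.Random,
    seq: str,
    max_pairs: int = 3,
    x_rate: float = 0.1,
) -> GuideStructure:
    """A random feasible guide: a few non-crossing canonical pairs plus
    forced-unpaired marks on other positions."""
    n = len(seq)
    pairs: set[tuple[int, int]] = set()
    used: set[int] = set()
    for _ in range(max_pairs * 3):
        if len(pairs) >= max_pairs:
            break
        i, j = rng.randrange(n), rng.randrange(n)
        if i > j:
            i, j = j, i
        if (
            j - i > 3
            and is_canonical(seq[i], seq[j])
            and not ({i, j} & used)
            and all(not pairs_cross((i, j), p) for p in pairs)
        ):
            pairs.add((i, j))
            used.update((i, j))
    unpaired = frozenset(
        k for k in range(n) if k not in used and rng.random() < x_rate
    )
    return GuideStructure(length=n, pairs=frozenset(pairs), unpaired=unpaired)
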