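import logging

import numpy as np
import pytest

from mirloop import HairpinSpec, generate_cohort

# the folder warns about multi-branch structures on purpose; keep test
# output readable
logging.getLogger("mirloop").setLevel(logging.ERROR)


def g_biased_probs(p_g: float) -> dict[str, float]:
    rest = (1.0 - p_g) / 3.0
    return {"A": rest, "C": rest, "G": p_g, "U": rest}


PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Independent folding oracle: plain recursion over all nested structures."""

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        score = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                inner = best(i + 1, k - 1) if k - 1 > i else 0
                rest = best(k + 1, j) if k + 1 <= j else 0
                score = max(score, 1 + inner + rest)
        return score

    return best(0, len(seq) - 1)


def assert_valid_structure(seq: str, structure, min_loop: int = 3) -> None:
    """Check the nested-structure invariants: involution, pair set, loop size."""
    pairs = structure.pairs
    assert len(structure.dotbracket) == len(seq)
    for i, j in enumerate(pairs):
        if j is None:
            assert structure.dotbracket[i] == "."
            continue
        assert pairs[j] == i
        if j > i:
            assert (seq[i], seq[j]) in PAIRABLE
            assert j - i - 1 >= min_loop


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def biased_cohort():
    """One seeded cohort with the headline programmed +24.4% loop-G enrichment."""
    return generate_cohort(
        HairpinSpec(loop_base_probs=g_biased_probs(0.3110)),
        HairpinSpec(),
        n_targets=20,
        n_universe=200,
        seed=7,
    )
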