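"""k-word nucleotide composition of sequence sets (EMBOSS compseq semantics).

Words of size k are counted at every offset (step 1, overlapping) within
each sequence and never across record boundaries. A set's profile pools the
raw counts over all sequences, so longer sequences carry proportionally more
weight — the behaviour of compseq on a multi-FASTA and the convention used
throughout this package. Per-sequence averaging (each sequence weighted
equally regardless of length) is available as a sensitivity analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_BASES = "ACGU"


def all_words(k: int) -> list[str]:
    """All k-words over {A,C,G,U} in lexicographic order."""
    return ["".join(p) for p in itertools.product(sorted(_BASES), repeat=k)]


def count_words(sequence: str, k: int) -> dict[str, int]:
    """Count all overlapping k-words of one sequence (empty map if too short)."""
    if k < 1:
        raise ValueError(f"word size must be >= 1, got {k}")
    counts: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        word = sequence[i : i + k]
        counts[word] = counts.get(word, 0) + 1
    return counts


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled k-word counts and fractions for a named sequence set."""

    k: int
    counts: Mapping[str, int]
    total_words: int
    fractions: Mapping[str, float]
    n_sequences: int
    set_label: str = ""

    def sorted_words(self) -> list[str]:
        return sorted(self.counts)


def pool_profiles(
    sequences: Iterable[str],
    k: int,
    label: str = "",
    average: bool = False,
) -> CompositionProfile:
    """Pool k-word composition over a sequence set.

    Sequences shorter than ``k`` contribute no words (a warning reports how
    many were skipped, mirroring compseq); if every sequence is too short a
    ``ValueError("empty profile")`` is raised. With ``average=True`` the
    profile is the unweighted mean of per-sequence fraction vectors instead
    of the pooled (length-weighted) counts.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty profile: no sequences given")
    counts: dict[str, int] = {}
    per_seq_fractions: list[dict[str, float]] = []
    n_contributing = 0
    for seq in seqs:
        c = count_words(seq, k)
        if not c:
            continue
        n_contributing += 1
        for w, n in c.items():
            counts[w] = counts.get(w, 0) + n
        if average:
            tot = sum(c.values())
            per_seq_fractions.append({w: n / tot for w, n in c.items()})
    if n_contributing == 0:
        raise ValueError(f"empty profile: all {len(seqs)} sequences shorter than k={k}")
    if n_contributing < len(seqs):
        logger.warning(
            "%d/%d sequences shorter than k=%d skipped", len(seqs) - n_contributing, len(seqs), k
        )
    total = sum(counts.values())
    if average:
        fractions = {
            w: sum(f.get(w, 0.0) for f in per_seq_fractions) / len(per_seq_fractions)
            for w in counts
        }
    else:
        fractions = {w: n / total for w, n in counts.items()}
    return CompositionProfile(
        k=k,
        counts=dict(sorted(counts.items())),
        total_words=total,
        fractions=dict(sorted(fractions.items())),
        n_sequences=len(seqs),
        set_label=label,
    )


def word_fraction(profile: CompositionProfile, word: str) -> float:
    """Fraction of a single word in a profile (0 if never observed)."""
    if len(word) != profile.k:
        raise ValueError(
            f"word {word!r} has length {len(word)}, profile has k={profile.k}"
        )
    return profile.fractions.get(word, 0.0)
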