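"""Synthetic hairpins and expression matrices with programmed ground truth.

Hairpins are built as a perfectly complementary stem (optionally softened
with G·U wobble pairs) around an apical loop whose bases are drawn i.i.d.
from a specified composition — uniform for the control universe, a G-biased
distribution for a "target" cohort. The drawn loop bases are rearranged
(a composition-preserving permutation, see :func:`_arrange_loop`) just
enough that a maximum-base-pairing fold keeps the designed stem and closing
pair; stray complementarity *within* the loop is left alone, since
terminal-loop delineation treats short buried helices as loop content. The
realised loop multiset — and hence all pooled composition truth — is
exactly the i.i.d. draw, and the near-free ordering keeps dinucleotide
(e.g. GG) frequencies at their i.i.d. expectations.

Expression matrices emulate two independent two-condition experiments that
share a differentially expressed gene set whose direction agrees between
experiments with a programmed probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .seqio import MiRNASet, PrecursorRecord

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_CAN_PAIR = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


@dataclass(frozen=True)
class HairpinSpec:
    """Design parameters of one synthetic hairpin cohort.

    stem_len
        Base pairs in the designed stem (default 22, a typical pre-miRNA
        stem length in miRBase).
    loop_len
        Unpaired apical loop length in nt (default 8, within the observed
        3-20 nt range of precursor terminal loops).
    loop_base_probs
        i.i.d. per-base composition of the loop (default uniform).
    gu_fraction
        Probability that a stem pair whose 5' base is G or U is converted
        to a G·U wobble by mutating its 3' partner (default 0.1).
    motif_spike
        Optional ``(motif, probability)``: overwrite a random loop window
        with the motif at the given per-hairpin probability.
    """

    stem_len: int = 22
    loop_len: int = 8
    loop_base_probs: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
    )
    gu_fraction: float = 0.1
    motif_spike: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.stem_len < 4:
            raise ValueError("stem_len must be >= 4")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        total = sum(self.loop_base_probs.get(b, 0.0) for b in "ACGU")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"loop base probabilities sum to {total}, not 1")
        if not 0 <= self.gu_fraction <= 1:
            raise ValueError("gu_fraction must be a probability")
        if self.motif_spike is not None:
            motif, prob = self.motif_spike
            if len(motif) > self.loop_len:
                raise ValueError(
                    f"motif {motif!r} longer than loop ({self.loop_len} nt)"
                )
            if not 0 <= prob <= 1:
                raise ValueError("motif spike probability must be in [0, 1]")

    def prob_vector(self) -> np.ndarray:
        return np.array([self.loop_base_probs.get(b, 0.0) for b in "ACGU"])


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded alongside generated data."""

    loop_intervals: Mapping[str, tuple[int, int]] | None = None
    target_loop_g_prob: float | None = None
    control_loop_g_prob: float | None = None
    programmed_enrichment_pct: float | None = None
    de_genes: tuple[str, ...] | None = None
    directions_a: Mapping[str, str] | None = None
    directions_b: Mapping[str, str] | None = None
    programmed_concordance_pct: float | None = None


def _arrange_loop(
    bases: list[str],
    flank5: str,
    flank3: str,
    rng: np.random.Generator,
    min_loop: int = 3,
) -> list[str] | None:
    """Find an ordering of the loop multiset with no foldable internal pair.

    Constraints (0-based loop positions, loop length L, min_loop m), chosen
    as the minimal set under which a maximum-pairing fold with
    outermost-first tie-breaking keeps the designed closing pair and stem:

    * the two loop ends may not pair each other — otherwise the stem helix
      would extend into the loop;
    * the 5' closing base may not pair loop positions [m, L-m-2] and the 3'
      closing base may not pair loop positions [m+1, L-m-1] — the only
      configuration in which a nested pair of new pairs outscores (rather
      than ties) the designed closing pair.

    Other intra-loop pairings are allowed: they only create short incidental
    helices inside the loop, which terminal-loop delineation treats as loop
    content. Backtracking with the candidate order randomised at each step,
    so the returned arrangement is a random valid one; ``None`` if the
    multiset admits no valid arrangement (essentially never at L >= 4).
    """
    length = len(bases)
    placed: list[str] = []

    def ok(base: str, pos: int) -> bool:
        if min_loop <= pos <= length - min_loop - 2 and (flank5, base) in _CAN_PAIR:
            return False
        if min_loop + 1 <= pos <= length - min_loop - 1 and (base, flank3) in _CAN_PAIR:
            return False
        if pos == length - 1 and placed and (placed[0], base) in _CAN_PAIR:
            return False
        return True

    def solve(remaining: list[str]) -> bool:
        pos = len(placed)
        if pos == length:
            return True
        order = list(dict.fromkeys(remaining))
        rng.shuffle(order)
        for base in order:
            if not ok(base, pos):
                continue
            placed.append(base)
            rest = remaining.copy()
            rest.remove(base)
            if solve(rest):
                return True
            placed.pop()
        return False

    return placed.copy() if solve(bases) else None


def _loop_ok(loop: list[str], flank5: str, flank3: str, min_loop: int = 3) -> bool:
    length = len(loop)
    for j in range(min_loop, length - min_loop - 1):
        if (flank5, loop[j]) in _CAN_PAIR:
            return False
    for k in range(min_loop + 1, length - min_loop):
        if (loop[k], flank3) in _CAN_PAIR:
            return False
    return (loop[0], loop[-1]) not in _CAN_PAIR


def _draw_loop(
    spec: HairpinSpec, flank5: str, flank3: str, rng: np.random.Generator
) -> list[str]:
    drawn = [str(b) for b in rng.choice(_BASES, size=spec.loop_len, p=spec.prob_vector())]
    # composition-preserving rearrangement: rejection over random
    # permutations keeps the accepted ordering uniform among valid ones, so
    # multiplicative order biases cancel in target/control ratios; the rare
    # multiset that defeats rejection goes through exhaustive backtracking,
    # and a genuinely infeasible one is emitted as drawn
    if _loop_ok(drawn, flank5, flank3):
        return drawn
    for _ in range(200):
        perm = [drawn[i] for i in rng.permutation(spec.loop_len)]
        if _loop_ok(perm, flank5, flank3):
            return perm
    arranged = _arrange_loop(sorted(drawn), flank5, flank3, rng)
    return arranged if arranged is not None else drawn


def generate_hairpin(
    spec: HairpinSpec,
    seed: int | np.random.Generator = 0,
    name: str = "syn-mir-1",
) -> tuple[PrecursorRecord, tuple[int, int]]:
    """Generate one hairpin and its true terminal-loop interval.

    Layout: 5' stem arm (uniform bases) + loop + reverse-complement 3' arm,
    with wobble substitutions applied to the 3' partner of sampled pairs.
    The truth interval is ``[stem_len, stem_len + loop_len)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    five = [str(b) for b in rng.choice(_BASES, size=spec.stem_len)]
    three = [_COMPLEMENT[b] for b in five[::-1]]
    for t in range(spec.stem_len):
        if rng.random() < spec.gu_fraction:
            if five[t] == "G":
                three[spec.stem_len - 1 - t] = "U"
            elif five[t] == "U":
                three[spec.stem_len - 1 - t] = "G"
    loop = _draw_loop(spec, five[-1], three[0], rng)
    if spec.motif_spike is not None:
        motif, prob = spec.motif_spike
        if rng.random() < prob:
            offset = int(rng.integers(0, spec.loop_len - len(motif) + 1))
            loop[offset : offset + len(motif)] = list(motif)
    sequence = "".join(five) + "".join(loop) + "".join(three)
    record = PrecursorRecord(id=name, sequence=sequence, species="other")
    return record, (spec.stem_len, spec.stem_len + spec.loop_len)


def generate_cohort(
    target_spec: HairpinSpec,
    control_spec: HairpinSpec,
    n_targets: int = 20,
    n_universe: int = 200,
    seed: int = 0,
) -> tuple[MiRNASet, MiRNASet, dict[str, PrecursorRecord], SyntheticTruth]:
    """Generate a target cohort embedded in a control universe.

    The universe holds ``n_universe`` precursors of which the first
    ``n_targets`` are the target set (drawn with ``target_spec``) and the
    rest are controls (``control_spec``) — mirroring a registry in which
    control draws must exclude the targets, hence the precondition
    ``n_universe >= 50 + n_targets``.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_universe < 50 + n_targets:
        raise ValueError(
            f"n_universe={n_universe} too small: need >= 50 + n_targets ({50 + n_targets})"
        )
    rng = np.random.default_rng(seed)
    precursors: dict[str, PrecursorRecord] = {}
    intervals: dict[str, tuple[int, int]] = {}
    target_ids: list[str] = []
    universe_ids: list[str] = []
    for i in range(n_universe):
        is_target = i < n_targets
        spec = target_spec if is_target else control_spec
        ident = f"syn-mir-{'t' if is_target else 'c'}{i:04d}"
        record, interval = generate_hairpin(spec, rng, name=ident)
        precursors[ident] = record
        intervals[ident] = interval
        universe_ids.append(ident)
        if is_target:
            target_ids.append(ident)
    p_t = target_spec.loop_base_probs.get("G", 0.0)
    p_c = control_spec.loop_base_probs.get("G", 0.0)
    programmed = 100.0 * (p_t / p_c - 1.0) if p_c > 0 else float("nan")
    truth = SyntheticTruth(
        loop_intervals=intervals,
        target_loop_g_prob=p_t,
        control_loop_g_prob=p_c,
        programmed_enrichment_pct=programmed,
    )
    targets = MiRNASet(label="target", members=tuple(target_ids))
    universe = MiRNASet(label="universe", members=tuple(universe_ids))
    return targets, universe, precursors, truth


def true_loop_sequences(
    precursors: Mapping[str, PrecursorRecord],
    truth: SyntheticTruth,
) -> dict[str, str]:
    """Loop sequences sliced at the generator's true intervals."""
    assert truth.loop_intervals is not None
    return {
        pid: precursors[pid].sequence[s:e]
        for pid, (s, e) in truth.loop_intervals.items()
    }


def generate_expression(
    n_genes: int = 2000,
    n_de: int = 200,
    effect: float = 2.0,
    sigma: float = 0.5,
    n_per_group: int = 5,
    concordance_target: float = 0.82,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Two independent two-condition matrices sharing a DE gene set.

    In matrix A each DE gene is shifted by ±``effect`` (random direction) in
    the treated group; matrix B keeps A's direction with probability
    ``concordance_target`` and flips it otherwise. Noise is i.i.d.
    normal(0, sigma) on the (log-scale) values; the default sigma of 0.5
    is typical replicate-level noise for normalized arrays, at which a
    shift of 2 is reliably detectable with five samples per group.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if not 0 <= concordance_target <= 1:
        raise ValueError("concordance_target must be a probability")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    dirs_a = rng.choice([-1.0, 1.0], size=n_de)
    keep = rng.random(n_de) < concordance_target
    dirs_b = np.where(keep, dirs_a, -dirs_a)

    def build(dirs: np.ndarray, tag: str) -> ExpressionMatrix:
        samples = [f"{tag}_ctl_{i}" for i in range(n_per_group)] + [
            f"{tag}_trt_{i}" for i in range(n_per_group)
        ]
        values = rng.normal(0.0, sigma, size=(n_genes, 2 * n_per_group))
        shift = np.zeros(n_genes)
        shift[de_idx] = dirs * effect
        values[:, n_per_group:] += shift[:, None]
        groups = {s: ("control" if "_ctl_" in s else "treated") for s in samples}
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=samples),
            groups=groups,
        )

    mat_a = build(dirs_a, "A")
    mat_b = build(dirs_b, "B")
    de_genes = tuple(genes[i] for i in de_idx)
    truth = SyntheticTruth(
        de_genes=de_genes,
        directions_a={g: ("up" if d > 0 else "down") for g, d in zip(de_genes, dirs_a)},
        directions_b={g: ("up" if d > 0 else "down") for g, d in zip(de_genes, dirs_b)},
        programmed_concordance_pct=100.0 * concordance_target,
    )
    return mat_a, mat_b, truth
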