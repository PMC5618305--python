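"""Exact motif scanning in terminal loops and presence-based enrichment.

The motifs of interest are short regulatory elements bound by RNA-binding
proteins at the precursor apical loop — GGAG (Lin28) and AGGGU (KSRP).
Matching is exact and overlapping. Enrichment is reported both as
occurrence totals and as per-loop presence rates, with a two-sided Fisher
exact test on the 2x2 presence table; presence is the headline metric.
Paralog redundancy can be removed by collapsing each miRNA family to a
single representative before counting.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .seqio import MiRNASet

logger = logging.getLogger(__name__)


def scan_motif(sequence: str, motif: str) -> int:
    """Count overlapping exact occurrences of ``motif`` (0 if longer than sequence)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    n = len(sequence) - len(motif) + 1
    if n <= 0:
        return 0
    return sum(1 for i in range(n) if sequence[i : i + len(motif)] == motif)


_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-")
_PARALOG_SUFFIX = re.compile(r"-\d+$")
_VARIANT_LETTERS = re.compile(r"(?<=\d)[a-z]+$")


def default_family(identifier: str) -> str:
    """Heuristic miRBase family name: strip species prefix, paralog number, variant letter.

    ``dre-let-7a-1`` -> ``let-7``; ``mmu-mir-26a`` -> ``mir-26``;
    ``hsa-mir-107`` -> ``mir-107`` (a trailing number is only removed when
    a digit remains, so gene numbers are preserved).
    """
    name = _SPECIES_PREFIX.sub("", identifier.lower())
    stripped = _PARALOG_SUFFIX.sub("", name)
    if any(ch.isdigit() for ch in stripped):
        name = stripped
    return _VARIANT_LETTERS.sub("", name)


def family_collapse(
    mirna_set: MiRNASet, family_of: Mapping[str, str] | None = None
) -> MiRNASet:
    """Keep one representative (lexicographically smallest id) per family.

    Unmapped ids form singleton families. Without an explicit map the
    miRBase naming heuristic of :func:`default_family` is applied (logged).
    The result is ordered by family name, making the operation idempotent.
    """
    if family_of is None:
        family_of = mirna_set.family_of
    if family_of is None:
        logger.info(
            "no family map for set %r; using miRBase id naming heuristic",
            mirna_set.label,
        )
        family_of = {}
    reps: dict[str, str] = {}
    for member in mirna_set.members:
        fam = family_of.get(member) or default_family(member)
        if fam not in reps or member < reps[fam]:
            reps[fam] = member
    members = tuple(reps[fam] for fam in sorted(reps))
    return MiRNASet(
        label=f"{mirna_set.label}-families",
        members=members,
        family_of=dict(family_of) or None,
    )


@dataclass(frozen=True)
class MotifEnrichment:
    """Presence and occurrence statistics of a motif in target vs control loops."""

    motif: str
    n_target_with: int
    n_target: int
    n_control_with: int
    n_control: int
    occurrences_target: int
    occurrences_control: int
    relative_enrichment_pct: float
    fisher_p: float


def motif_enrichment(
    target_loops: Sequence[str] | Mapping[str, str],
    control_loops: Sequence[str] | Mapping[str, str],
    motif: str,
) -> MotifEnrichment:
    """Compare motif presence between target and control loop collections.

    ``relative_enrichment_pct`` is the presence-rate ratio minus one, x100;
    when no control loop carries the motif it is the infinity sentinel (the
    motif is entirely absent from controls). ``fisher_p`` is the two-sided
    Fisher exact p of the presence 2x2 table.
    """
    t_seqs = list(target_loops.values()) if isinstance(target_loops, Mapping) else list(target_loops)
    c_seqs = list(control_loops.values()) if isinstance(control_loops, Mapping) else list(control_loops)
    if not t_seqs or not c_seqs:
        raise ValueError("both loop collections must be non-empty")
    t_occ = [scan_motif(s, motif) for s in t_seqs]
    c_occ = [scan_motif(s, motif) for s in c_seqs]
    n_t_with = sum(1 for n in t_occ if n > 0)
    n_c_with = sum(1 for n in c_occ if n > 0)
    rate_t = n_t_with / len(t_seqs)
    rate_c = n_c_with / len(c_seqs)
    if rate_c == 0:
        rel = math.inf if rate_t > 0 else math.nan
    else:
        rel = 100.0 * (rate_t - rate_c) / rate_c
    table = [
        [n_t_with, len(t_seqs) - n_t_with],
        [n_c_with, len(c_seqs) - n_c_with],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    return MotifEnrichment(
        motif=motif,
        n_target_with=n_t_with,
        n_target=len(t_seqs),
        n_control_with=n_c_with,
        n_control=len(c_seqs),
        occurrences_target=sum(t_occ),
        occurrences_control=sum(c_occ),
        relative_enrichment_pct=rel,
        fisher_p=float(p),
    )
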