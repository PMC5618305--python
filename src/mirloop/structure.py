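"""Hairpin secondary structure: maximum-base-pairing folding and terminal-loop delineation.

The folding model is maximum base pairing over nested (pseudoknot-free)
structures — a Nussinov-style dynamic program — with a steric minimum
hairpin-loop size and an allowed-pair set of the Watson–Crick pairs plus,
by default, the G·U wobble. This is deliberately not a thermodynamic model:
it is parameter-free and reproducible, and miRNA precursors are strongly
self-complementary, so the maximum-pairing structure is dominated by the
single long hairpin stem. Callers who want thermodynamic structures can
supply dot-bracket strings (e.g. RNAfold output) which always override
internal folding.

The *terminal loop* of a hairpin is the maximal run of unpaired bases whose
two flanking positions pair with each other (the closing pair); the loop
excludes the closing pair itself. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import PrecursorRecord

logger = logging.getLogger(__name__)

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}

WATSON_CRICK = ("AU", "UA", "GC", "CG")
WOBBLE = ("GU", "UG")


def _pair_matrix(allow_gu: bool) -> np.ndarray:
    pairs = WATSON_CRICK + (WOBBLE if allow_gu else ())
    mat = np.zeros((4, 4), dtype=np.bool_)
    for a, b in pairs:
        mat[_ENCODE[a], _ENCODE[b]] = True
    return mat


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - callers validate upstream
        raise ValueError(f"non-RNA symbol {exc.args[0]!r} in sequence") from exc


@njit(cache=False)
def _max_pairing_table(enc, pairmat, min_loop):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    table = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = table[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairmat[enc[i], enc[k]]:
                    left = table[i + 1, k - 1]
                    right = table[k + 1, j] if k + 1 <= j else np.int16(0)
                    score = np.int16(1) + left + right
                    if score > best:
                        best = score
            table[i, j] = best
    return table


def _traceback(enc, table, pairmat, min_loop: int) -> list[int | None]:
    """Deterministic traceback: pair position i with the largest admissible j
    (outermost pairing first), preferring pairing over leaving i unpaired on
    score ties, recursing left-to-right."""
    n = enc.shape[0]
    pairs: list[int | None] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        best = int(table[i, j])
        if best == 0:
            continue
        placed = False
        for k in range(j, i + min_loop, -1):
            if pairmat[enc[i], enc[k]]:
                left = int(table[i + 1, k - 1])
                right = int(table[k + 1, j]) if k + 1 <= j else 0
                if 1 + left + right == best:
                    pairs[i], pairs[k] = k, i
                    stack.append((k + 1, j))
                    stack.append((i + 1, k - 1))
                    placed = True
                    break
        if not placed:
            stack.append((i + 1, j))
    return pairs


def pair_table(dotbracket: str) -> tuple[int | None, ...]:
    """Parse dot-bracket into an involution table: p[i] = j iff (i, j) pair.

    Raises ``ValueError`` on unbalanced brackets or foreign symbols.
    """
    pairs: list[int | None] = [None] * len(dotbracket)
    opened: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            opened.append(i)
        elif ch == ")":
            if not opened:
                raise ValueError(f"unbalanced brackets in {dotbracket!r}")
            j = opened.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure symbol {ch!r}")
    if opened:
        raise ValueError(f"unbalanced brackets in {dotbracket!r}")
    return tuple(pairs)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure for one precursor."""

    precursor_id: str
    dotbracket: str
    pairs: tuple[int | None, ...]

    @classmethod
    def from_dotbracket(cls, precursor_id: str, dotbracket: str) -> "SecondaryStructure":
        return cls(precursor_id, dotbracket, pair_table(dotbracket))

    @property
    def n_pairs(self) -> int:
        return sum(1 for p in self.pairs if p is not None) // 2


@dataclass(frozen=True)
class TerminalLoop:
    """The apical loop interval of a hairpin, 0-based half-open.

    Enclosed by the innermost pair of the stem; may contain incidental
    short-lived pairings that a maximum-pairing fold places inside the loop.
    """

    precursor_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def fold_hairpin(
    record: PrecursorRecord | str,
    min_loop: int = 3,
    allow_gu: bool = True,
) -> SecondaryStructure:
    """Fold a precursor into the maximum-base-pairing nested structure.

    Parameters
    ----------
    record:
        A :class:`PrecursorRecord` or a bare RNA string.
    min_loop:
        Minimum number of unpaired bases a pair must enclose (steric limit).
    allow_gu:
        Admit G·U wobble pairs in addition to Watson–Crick pairs.

    A sequence with no attainable pair (including any sequence shorter than
    ``min_loop + 2``) folds to all dots — not an error; only a sequence of
    fewer than 2 nt raises ``ValueError``.
    """
    if isinstance(record, PrecursorRecord):
        ident, seq = record.id, record.sequence
    else:
        ident, seq = "seq", record
    if len(seq) < 2:
        raise ValueError(f"{ident}: sequence of length {len(seq)} too short to fold")
    enc = _encode(seq)
    pairmat = _pair_matrix(allow_gu)
    table = _max_pairing_table(enc, pairmat, min_loop)
    pairs = _traceback(enc, table, pairmat, min_loop)
    db = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pairs)
    )
    return SecondaryStructure(ident, db, tuple(pairs))


def find_hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Return every hairpin loop as a 0-based half-open interval, ordered by position.

    A hairpin loop is a maximal run of unpaired bases whose immediate flanks
    pair *with each other* (internal loops and bulges do not qualify).
    """
    pairs = structure.pairs
    n = len(pairs)
    loops: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if pairs[i] is None:
            start = i
            while i < n and pairs[i] is None:
                i += 1
            end = i
            if start > 0 and end < n and pairs[start - 1] == end:
                loops.append((start, end))
        else:
            i += 1
    return loops


def stem_depth(structure: SecondaryStructure, loop: tuple[int, int]) -> int:
    """Number of consecutively stacked pairs enclosing a hairpin loop."""
    pairs = structure.pairs
    n = len(pairs)
    a, b = loop[0] - 1, loop[1]
    depth = 0
    while a >= 0 and b < n and pairs[a] == b:
        depth += 1
        a -= 1
        b += 1
    return depth


def _branches(pairs: tuple[int | None, ...], start: int, end: int) -> list[tuple[int, int]]:
    """Outermost pairs directly inside [start, end), left to right."""
    out: list[tuple[int, int]] = []
    i = start
    while i < end:
        j = pairs[i]
        if j is not None and j > i:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def _helix(pairs: tuple[int | None, ...], outer: tuple[int, int]) -> tuple[int, tuple[int, int]]:
    """Depth and innermost pair of the maximal stacked run starting at ``outer``."""
    a, b = outer
    depth = 1
    while a + 1 < b - 1 and pairs[a + 1] == b - 1:
        a, b = a + 1, b - 1
        depth += 1
    return depth, (a, b)


def extract_terminal_loop(
    record: PrecursorRecord,
    structure: SecondaryStructure | None = None,
    policy: str = "longest_stem",
    min_loop: int = 3,
    allow_gu: bool = True,
) -> TerminalLoop:
    """Delineate the terminal (apical) loop of a precursor.

    The stem is followed from the outside in, through bulges and internal
    loops. At a branch point with several substantial helices, policy
    ``"longest_stem"`` descends into the branch whose closing helix stacks
    the most pairs (warning logged); ``"error_on_multi"`` raises instead.
    Descent stops at the innermost pair of the final stem helix; everything
    it encloses is the terminal loop. A short helix (one or two stacked
    pairs) buried under a much longer stem is treated as incidental
    intra-loop pairing — part of the loop, not a continuation of the stem —
    so that the maximum-pairing folder's habit of seizing stray complementary
    positions inside a genuine apical loop does not truncate the loop. An
    unpaired structure raises ``ValueError("no terminal loop")`` — callers
    exclude such records and report the count.
    """
    if policy not in ("longest_stem", "error_on_multi"):
        raise ValueError(f"unknown policy {policy!r}")
    if structure is None:
        structure = fold_hairpin(record, min_loop=min_loop, allow_gu=allow_gu)
    pairs = structure.pairs
    region = (0, len(pairs))
    current_depth = 0
    entered = False
    while True:
        branches = _branches(pairs, region[0], region[1])
        if not branches:
            if not entered:
                raise ValueError(f"{record.id}: no terminal loop")
            break
        info = [_helix(pairs, br) for br in branches]
        if entered:
            # helices of <=2 stacked pairs under a much longer stem are
            # incidental intra-loop pairing, not structure
            structural = [
                (d, inner) for d, inner in info
                if not (d <= 2 and current_depth >= 2 * d + 1)
            ]
        else:
            structural = info
        if not structural:
            break
        if len(structural) > 1:
            if policy == "error_on_multi":
                raise ValueError(
                    f"{record.id}: {len(structural)} hairpin branches (policy error_on_multi)"
                )
            logger.warning(
                "%s: %d hairpin branches; descending the longest closing stem",
                record.id,
                len(structural),
            )
        depth, inner = max(structural, key=lambda di: di[0])
        current_depth = depth
        region = (inner[0] + 1, inner[1])
        entered = True
    start, end = region
    return TerminalLoop(
        precursor_id=record.id,
        start=start,
        end=end,
        sequence=record.sequence[start:end],
    )


def region_sequences(
    precursors: dict[str, PrecursorRecord],
    region: str,
    structures: dict[str, str] | None = None,
    policy: str = "longest_stem",
    min_loop: int = 3,
    allow_gu: bool = True,
) -> tuple[dict[str, str], list[str]]:
    """Map each precursor id to its analysis region sequence.

    ``region`` is ``"terminal_loop"`` (apical loop only) or ``"stem_loop"``
    (the complete precursor). Supplied dot-bracket ``structures`` override
    internal folding per id. Returns ``(sequences, excluded_ids)`` where
    excluded ids are precursors without an extractable terminal loop; the
    count is logged so silent exclusion cannot bias downstream composition.
    """
    if region == "stem_loop":
        return {pid: rec.sequence for pid, rec in precursors.items()}, []
    if region != "terminal_loop":
        raise ValueError(f"unknown region {region!r}")
    out: dict[str, str] = {}
    excluded: list[str] = []
    for pid, rec in precursors.items():
        struct = None
        if structures and pid in structures:
            struct = SecondaryStructure.from_dotbracket(pid, structures[pid])
        try:
            loop = extract_terminal_loop(
                rec, struct, policy=policy, min_loop=min_loop, allow_gu=allow_gu
            )
        except ValueError:
            excluded.append(pid)
            continue
        out[pid] = loop.sequence
    if excluded:
        logger.warning(
            "terminal loop extraction excluded %d/%d records",
            len(excluded),
            len(precursors),
        )
    return out, excluded
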