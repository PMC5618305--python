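"""Readers and writers for precursor FASTA, Vienna dot-bracket, target lists, and reports.

Sequences are held internally in the RNA alphabet {A, C, G, U}; DNA input
(T, lower case) is normalised on read. miRBase-style FASTA headers carry an
accession and description after the identifier token; only the first
whitespace-delimited token is used as the record id.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: species prefixes recognised from miRBase-style ids ("dre-let-7a-1" -> "dre")
KNOWN_SPECIES = ("dre", "mmu", "hsa")


def species_of(identifier: str) -> str:
    """Infer the species code from a miRBase-style id; "other" if unrecognised."""
    prefix = identifier.split("-", 1)[0].lower()
    return prefix if prefix in KNOWN_SPECIES else "other"


@dataclass(frozen=True)
class PrecursorRecord:
    """One pre-miRNA hairpin: an id and its RNA sequence."""

    id: str
    sequence: str
    species: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-nucleotide symbol {sorted(bad)[0]!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MiRNASet:
    """A named, ordered collection of precursor ids (e.g. a target or control set)."""

    label: str
    members: tuple[str, ...]
    family_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m in seen:
                raise ValueError(f"set {self.label!r}: duplicate id {m!r}")
            seen.add(m)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


def normalize_sequence(raw: str) -> str:
    """Upper-case and convert T -> U (DNA input accepted, RNA canonical)."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path) -> dict[str, PrecursorRecord]:
    """Read a (multi-line) FASTA file into an ordered id -> PrecursorRecord map.

    The id is the header token up to the first whitespace. Raises ``ValueError``
    on an empty file, a duplicate id, or a non-nucleotide symbol.
    """
    records: dict[str, PrecursorRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r}")
        records[rec.id] = PrecursorRecord(
            id=rec.id, sequence=seq, species=species_of(rec.id)
        )
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(
    records: Iterable[PrecursorRecord], path: str | Path, width: int = 60
) -> None:
    """Write precursor records as FASTA (fixed line width, RNA alphabet)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _check_balanced(structure: str, context: str) -> None:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"{context}: unbalanced brackets in {structure!r}")
        elif ch != ".":
            raise ValueError(f"{context}: invalid structure symbol {ch!r}")
    if depth != 0:
        raise ValueError(f"{context}: unbalanced brackets in {structure!r}")


def read_dotbracket(path: str | Path) -> dict[str, str]:
    """Read Vienna-style triplets (header / sequence / dot-bracket) into id -> structure.

    The structure line may carry a trailing free-energy annotation after a
    space (RNAfold convention); it is ignored. Structure length must equal
    sequence length and brackets must balance.
    """
    structures: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected FASTA-style header, got {header!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"truncated dot-bracket record for {header!r}")
        ident = header[1:].split()[0]
        seq = lines[i + 1].strip()
        struct = lines[i + 2].strip().split()[0]
        if len(struct) != len(seq):
            raise ValueError(
                f"{ident}: structure length {len(struct)} != sequence length {len(seq)}"
            )
        _check_balanced(struct, ident)
        structures[ident] = struct
        i += 3
    if not structures:
        raise ValueError(f"no records in dot-bracket file {path}")
    return structures


def read_mirna_list(path: str | Path, label: str | None = None) -> MiRNASet:
    """Read a target-list file: one id per line, optional tab-separated family.

    Blank lines and lines starting with ``#`` are skipped; order is preserved;
    a duplicate id raises ``ValueError``.
    """
    members: list[str] = []
    family_of: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ident = parts[0].strip()
        if ident in members:
            raise ValueError(f"duplicate id in list {path}: {ident!r}")
        members.append(ident)
        if len(parts) > 1 and parts[1].strip():
            family_of[ident] = parts[1].strip()
    return MiRNASet(
        label=label or Path(path).stem,
        members=tuple(members),
        family_of=family_of or None,
    )


def _fmt_float(value: float) -> str:
    return f"{value:.6g}"


def _as_rows(result: object) -> list[dict]:
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        row = {}
        for f in dataclasses.fields(result):
            v = getattr(result, f.name)
            if isinstance(v, tuple):
                v = list(v)
            row[f.name] = v
        return [row]
    if isinstance(result, Mapping):
        return [dict(result)]
    if isinstance(result, Sequence) and not isinstance(result, (str, bytes)):
        rows: list[dict] = []
        for item in result:
            rows.extend(_as_rows(item))
        return rows
    raise TypeError(f"cannot serialise result of type {type(result).__name__}")


def _round_json(obj):
    if isinstance(obj, float):
        return float(_fmt_float(obj))
    if isinstance(obj, dict):
        return {k: _round_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_json(v) for v in obj]
    return obj


def write_report(result: object, path: str | Path, format: str = "tsv") -> None:
    """Serialise a result (dataclass, mapping, or sequence thereof) to TSV or JSON.

    Field order follows declaration order; floats are rendered with six
    significant digits, so repeated writes of the same result are
    byte-identical.
    """
    rows = _as_rows(result)
    if format == "tsv":
        header = list(rows[0].keys())
        out_lines = ["\t".join(header)]
        for row in rows:
            cells = []
            for key in header:
                v = row.get(key, "")
                if isinstance(v, float):
                    cells.append(_fmt_float(v))
                elif isinstance(v, (list, tuple)):
                    cells.append(",".join(_fmt_float(x) if isinstance(x, float) else str(x) for x in v))
                else:
                    cells.append(str(v))
            out_lines.append("\t".join(cells))
        Path(path).write_text("\n".join(out_lines) + "\n")
    elif format == "json":
        payload = rows[0] if len(rows) == 1 else rows
        Path(path).write_text(json.dumps(_round_json(payload), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")
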