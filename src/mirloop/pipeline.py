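"""End-to-end composition/motif analysis runs: configuration, execution, reports.

One run folds the precursors (unless dot-bracket structures are supplied),
extracts terminal loops, profiles mono-/di-nucleotide composition of the
target set against resampled controls for both regions, scans the loop
motifs with and without family collapsing, and writes deterministic TSV
tables plus one machine-readable JSON bundle stamped with the seed and a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .composition import all_words
from .enrichment import resampled_enrichment
from .motifs import family_collapse, motif_enrichment
from .seqio import (
    MiRNASet,
    read_dotbracket,
    read_fasta,
    read_mirna_list,
    write_report,
)
from .structure import region_sequences

logger = logging.getLogger(__name__)

REGIONS = ("terminal_loop", "stem_loop")


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    fasta: str
    targets: str
    outdir: str
    dotbracket: str | None = None
    family_map: str | None = None
    regions: tuple[str, ...] = REGIONS
    k_values: tuple[int, ...] = (1, 2)
    motifs: tuple[str, ...] = ("GGAG", "AGGGU")
    n_controls: int = 50
    n_resamples: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regions", "k_values", "motifs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("fasta", "targets", "dotbracket", "family_map"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config {attr}: no such file {value!r}")
        for region in self.regions:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("outdir")
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_composition_analysis(config: RunConfig) -> dict:
    """Run the full composition + motif analysis and write the report bundle.

    Returns the bundle as a dict; writes per-(region, k) enrichment TSVs,
    a motif TSV, and ``bundle.json`` under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    precursors = read_fasta(config.fasta)
    targets = read_mirna_list(config.targets, label="targets")
    unresolved = [m for m in targets.members if m not in precursors]
    if unresolved:
        raise ValueError(
            f"stage targets: {len(unresolved)} target ids not in FASTA "
            f"(first: {unresolved[0]!r})"
        )
    universe = MiRNASet(label="universe", members=tuple(precursors))
    structures = read_dotbracket(config.dotbracket) if config.dotbracket else None
    family_of = (
        read_mirna_list(config.family_map).family_of if config.family_map else None
    )

    bundle: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_targets": len(targets),
        "n_universe": len(universe),
        "excluded": {},
        "enrichment": [],
        "motifs": [],
    }

    region_seqs: dict[str, dict[str, str]] = {}
    for region in config.regions:
        seqs, excluded = region_sequences(precursors, region, structures)
        region_seqs[region] = seqs
        bundle["excluded"][region] = len(excluded)

    for region in config.regions:
        for k in config.k_values:
            rows = []
            for word in all_words(k):
                res = resampled_enrichment(
                    targets,
                    universe,
                    region_seqs[region],
                    word,
                    region=region,
                    n_controls=config.n_controls,
                    n_resamples=config.n_resamples,
                    seed=config.seed,
                )
                rows.append(res)
            write_report(rows, outdir / f"enrichment_{region}_k{k}.tsv", "tsv")
            bundle["enrichment"].extend(dataclasses.asdict(r) for r in rows)

    if "terminal_loop" in region_seqs and config.motifs:
        loops = region_seqs["terminal_loop"]
        target_loops = {m: loops[m] for m in targets.members if m in loops}
        control_loops = {
            m: loops[m] for m in universe.members
            if m not in set(targets.members) and m in loops
        }
        collapsed = family_collapse(targets, family_of)
        collapsed_loops = {m: loops[m] for m in collapsed.members if m in loops}
        motif_rows = []
        for motif in config.motifs:
            full = motif_enrichment(target_loops, control_loops, motif)
            fam = motif_enrichment(collapsed_loops, control_loops, motif)
            motif_rows.append({"collapsed": False, **dataclasses.asdict(full)})
            motif_rows.append({"collapsed": True, **dataclasses.asdict(fam)})
        write_report(motif_rows, outdir / "motif_enrichment.tsv", "tsv")
        bundle["motifs"] = motif_rows

    write_report(bundle, outdir / "bundle.json", "json")
    logger.info(
        "analysis complete: seed=%d hash=%s excluded=%s",
        config.seed,
        bundle["config_hash"],
        bundle["excluded"],
    )
    return bundle
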