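"""Differential expression, FDR control, and cross-dataset direction concordance.

Inputs are normalised gene-level expression matrices (log scale assumed),
one per dataset, with a sample -> condition map. Per-gene differential
expression uses a two-sided Welch t-test (pooled-variance optional) or
one-way ANOVA across more than two groups, with Benjamini-Hochberg FDR.
Two datasets are then compared by the overlap of their significant genes
and, among the common genes, the percentage regulated in the same direction
and the percentage co-upregulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression table with a sample -> condition map."""

    values: pd.DataFrame  # index: gene symbols; columns: sample ids
    groups: Mapping[str, str]
    timepoint: str = "NA"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")

    def group_columns(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix: first column gene symbol, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression matrix {path}")
    return df


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a sample -> condition map (TSV: sample, label[, timepoint])."""
    df = pd.read_csv(path, sep="\t", header=None)
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN entries (undefined tests) stay NaN and do not count toward the
    number of hypotheses. Out-of-range values raise ``ValueError``.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def differential_expression(
    matrix: ExpressionMatrix,
    reference: str,
    treated: str,
    method: str = "ttest",
    equal_var: bool = False,
    extra_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression of ``treated`` vs ``reference``.

    Returns a DataFrame with columns gene, effect (mean treated − mean
    reference), direction (up/down by the sign of the effect), p and
    BH-adjusted fdr. ``method="ttest"`` runs a two-sided Welch t-test
    (``equal_var=True`` for the pooled-variance variant); ``method="anova"``
    runs a one-way ANOVA across reference, treated and any ``extra_groups``
    while the effect/direction still contrast treated vs reference. Genes
    with zero variance in every group get a NaN p (undefined sentinel).
    """
    ref_cols = matrix.group_columns(reference)
    trt_cols = matrix.group_columns(treated)
    for label, cols in ((reference, ref_cols), (treated, trt_cols)):
        if len(cols) < 2:
            raise ValueError(f"group {label!r} has {len(cols)} samples; need >= 2")
    a = matrix.values[trt_cols].to_numpy(float)
    b = matrix.values[ref_cols].to_numpy(float)
    effect = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "ttest":
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        elif method == "anova":
            blocks = [a, b] + [
                matrix.values[matrix.group_columns(g)].to_numpy(float)
                for g in (extra_groups or [])
            ]
            _, p = stats.f_oneway(*blocks, axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
    p = np.asarray(p, dtype=float)
    # identical groups with within-group spread give t == 0 -> p = 1;
    # genes constant everywhere are genuinely undefined and stay NaN
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p[degenerate & (effect == 0)] = np.nan
    n_flagged = int(np.isnan(p).sum())
    if n_flagged:
        logger.warning("%d genes with undefined test statistic flagged", n_flagged)
    return pd.DataFrame(
        {
            "gene": matrix.values.index,
            "effect": effect,
            "direction": np.where(effect > 0, "up", "down"),
            "p": p,
            "fdr": bh_fdr(p),
        }
    ).reset_index(drop=True)


def significant_genes(de: pd.DataFrame, fdr_cut: float = 0.05) -> list[str]:
    """Gene symbols passing the FDR cut (NaN fdr never passes)."""
    mask = de["fdr"].notna() & (de["fdr"] < fdr_cut)
    return de.loc[mask, "gene"].tolist()


def overlap_sets(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Case-insensitive intersection of two gene lists, ordered by symbol."""
    set_b = {g.upper() for g in b}
    common = {g.upper() for g in a} & set_b
    return sorted(common)


@dataclass(frozen=True)
class OverlapConcordance:
    """Direction agreement among genes significant in two datasets."""

    n_common: int
    pct_same_direction: float
    pct_both_up: float
    timepoint: str = "NA"


def _direction_map(de: pd.DataFrame | Mapping[str, str]) -> dict[str, str]:
    if isinstance(de, pd.DataFrame):
        return {g.upper(): d for g, d in zip(de["gene"], de["direction"])}
    return {g.upper(): d for g, d in de.items()}


def direction_concordance(
    de_a: pd.DataFrame | Mapping[str, str],
    de_b: pd.DataFrame | Mapping[str, str],
    common: Sequence[str],
    timepoint: str = "NA",
) -> OverlapConcordance:
    """Percent of common genes with the same direction, and co-upregulated.

    Every common gene must be present in both DE results; an empty common
    list raises ``ValueError``.
    """
    if not common:
        raise ValueError("empty common gene list")
    dirs_a = _direction_map(de_a)
    dirs_b = _direction_map(de_b)
    missing = [g for g in common if g.upper() not in dirs_a or g.upper() not in dirs_b]
    if missing:
        raise ValueError(f"common genes missing from a DE result: {missing[:5]}")
    same = sum(1 for g in common if dirs_a[g.upper()] == dirs_b[g.upper()])
    both_up = sum(
        1 for g in common if dirs_a[g.upper()] == "up" and dirs_b[g.upper()] == "up"
    )
    n = len(common)
    return OverlapConcordance(
        n_common=n,
        pct_same_direction=100.0 * same / n,
        pct_both_up=100.0 * both_up / n,
        timepoint=timepoint,
    )
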