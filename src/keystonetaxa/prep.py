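"""Prevalence filtering, relative abundance, abundance floors, alpha diversity.

Conventions follow standard amplicon practice: a taxon is "detected" in a
sample when its count is > 0; Shannon diversity defaults to log base 2;
Chao1 is the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table_io import CountTable

__all__ = [
    "RelativeAbundanceTable",
    "DiversityResult",
    "prevalence_filter",
    "to_relative_abundance",
    "abundance_floor",
    "alpha_diversity",
    "transform_for_correlation",
]


@dataclass
class RelativeAbundanceTable:
    """Proportions (taxa x samples, columns summing to 1) at a taxonomic level."""

    proportions: pd.DataFrame
    level: str = "genus"

    def __post_init__(self) -> None:
        sums = self.proportions.to_numpy().sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.proportions.columns[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"sample {bad!r} proportions sum to {sums.max():.6g}, not 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class DiversityResult:
    """Per-sample alpha diversity: bias-corrected Chao1 richness, Shannon
    entropy, and the singleton/doubleton counts (F1/F2) behind Chao1."""

    chao1: pd.Series
    shannon: pd.Series
    observed: pd.Series
    F1: pd.Series
    F2: pd.Series

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed,
                "chao1": self.chao1,
                "shannon": self.shannon,
                "F1": self.F1,
                "F2": self.F2,
            }
        )


def prevalence_filter(table: CountTable, min_fraction: float = 0.5) -> CountTable:
    """Keep taxa detected (count > 0) in at least ``min_fraction`` of samples.

    The boundary is inclusive: a taxon detected in exactly half the samples
    survives a 0.5 filter.  Idempotent; the sample set is never changed.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    detected = (table.counts > 0).mean(axis=1)
    keep = detected >= min_fraction
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = table.taxonomy.loc[table.taxonomy.index.intersection(table.counts.index[keep])]
    return CountTable(counts=table.counts.loc[keep], taxonomy=taxonomy)


def to_relative_abundance(table: CountTable, level: str = "ASV") -> RelativeAbundanceTable:
    """Proportions per sample, optionally rolled up to genus or family.

    Aggregation above the table's native unit requires the taxonomy sidecar;
    unannotated taxa are pooled under 'unclassified'.
    """
    counts = table.counts
    if level != "ASV":
        if table.taxonomy is None:
            raise ValueError(f"level={level!r} requires a taxonomy sidecar")
        if level not in table.taxonomy.columns:
            raise ValueError(f"taxonomy has no {level!r} column")
        labels = table.taxonomy[level].reindex(counts.index).fillna("unclassified")
        counts = counts.groupby(labels).sum()
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    return RelativeAbundanceTable(proportions=counts / totals, level=level)


def abundance_floor(rel: RelativeAbundanceTable, floor: float) -> list[str]:
    """Taxa whose across-sample mean proportion is strictly above ``floor``.

    The study's screens used > 0.1% at genus level and > 1.0% at family
    level; the comparison is strict, so a taxon sitting exactly at the floor
    is excluded.
    """
    if not (0 <= floor < 1):
        raise ValueError("floor must be in [0, 1)")
    means = rel.proportions.mean(axis=1)
    return list(means.index[means > floor])


def alpha_diversity(table: CountTable, shannon_base: float = 2.0) -> DiversityResult:
    """Bias-corrected Chao1 and Shannon entropy per sample.

    Chao1 = S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton
    counts; when a sample has no singletons the estimate equals the observed
    richness.  Shannon is computed on proportions with 0*log(0) := 0, in
    ``shannon_base`` (2 by default, the QIIME 2 convention).
    """
    counts = table.counts
    observed = (counts > 0).sum(axis=0)
    f1 = (counts == 1).sum(axis=0)
    f2 = (counts == 2).sum(axis=0)
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))

    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    props = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = props * np.log(props)
    shannon = -plogp.fillna(0.0).sum(axis=0) / np.log(shannon_base)

    return DiversityResult(
        chao1=chao1.astype(float),
        shannon=shannon.astype(float),
        observed=observed.astype(float),
        F1=f1.astype(float),
        F2=f2.astype(float),
    )


def transform_for_correlation(
    rel: RelativeAbundanceTable, method: str = "log", pseudocount: float | None = None
) -> pd.DataFrame:
    """Prepare proportions for Pearson correlation.

    'log': log10(p + pseudocount) with the pseudocount defaulting to half
    the smallest nonzero proportion in the table -- raw proportions would
    let the few most abundant taxa dominate every correlation.
    'zscore': per-taxon standardisation of the proportions.
    Depth changes cancel in proportions, so both transforms are invariant to
    resequencing at a different depth.  Zero-variance taxa are flagged with
    a warning (they carry no correlation signal).
    """
    props = rel.proportions
    if method == "log":
        if pseudocount is None:
            nonzero = props.to_numpy()[props.to_numpy() > 0]
            if nonzero.size == 0:
                raise ValueError("table has no nonzero proportions")
            pseudocount = 0.5 * nonzero.min()
        out = np.log10(props + pseudocount)
    elif method == "zscore":
        sd = props.std(axis=1, ddof=0)
        sd_safe = sd.replace(0, 1.0)
        out = props.sub(props.mean(axis=1), axis=0).div(sd_safe, axis=0)
    else:
        raise ValueError(f"unknown transform {method!r}; use 'log' or 'zscore'")
    var = out.var(axis=1, ddof=0)
    flat = var.index[var == 0].tolist()
    if flat:
        warnings.warn(f"zero-variance taxa after transform: {flat}", stacklevel=2)
    return out
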