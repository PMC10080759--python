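"""Group-difference and trait-correlation screens, FDR control, ordination.

Wilcoxon rank-sum compares taxa between groups (exact when both groups are
small and tie-free, normal approximation with tie and continuity correction
otherwise); Welch's t compares traits; Spearman screens relate abundances to
continuous host traits.  Each screen is one Benjamini-Hochberg family.
Community-level contrasts use Bray-Curtis distance, classical PCoA, and
ANOSIM with seeded label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .prep import RelativeAbundanceTable, abundance_floor
from .table_io import TraitTable

__all__ = [
    "rank_sum_test",
    "welch_t_test",
    "spearman",
    "bh_adjust",
    "differential_screen",
    "trait_screen",
    "cooccurrence_network",
    "bray_curtis",
    "pcoa",
    "PcoaResult",
    "anosim",
    "AnosimResult",
]

_EXACT_LIMIT = 12  # total n at or below which the rank-sum null is enumerated


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the permutation null when n1 + n2 <= 12 and there
    are no ties; otherwise the normal approximation with tie correction and
    continuity correction.  Returns (U statistic for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= _EXACT_LIMIT and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def welch_t_test(x, y) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks, p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _group_split(traits: TraitTable) -> tuple[str, str, np.ndarray, np.ndarray]:
    levels = sorted(traits.group.unique())
    if len(levels) != 2:
        raise ValueError(f"differential screen needs exactly 2 groups, got {levels}")
    a, b = levels
    return a, b, (traits.group == a).to_numpy(), (traits.group == b).to_numpy()


def differential_screen(
    rel: RelativeAbundanceTable, traits: TraitTable, floor: float = 0.001
) -> pd.DataFrame:
    """Per-taxon Wilcoxon rank-sum between the two groups with BH adjustment.

    Only taxa above the mean-abundance floor enter the family.  The
    'enriched_in' column names the group with the larger mean relative
    abundance.  Columns: taxon, statistic, p, q, mean_<A>, mean_<B>,
    enriched_in.
    """
    ga, gb, mask_a, mask_b = _group_split(traits)
    props = rel.proportions[traits.sample_ids]
    keep = abundance_floor(rel, floor)
    rows = []
    for taxon in keep:
        vals = props.loc[taxon].to_numpy()
        stat, p = rank_sum_test(vals[mask_a], vals[mask_b])
        ma, mb = vals[mask_a].mean(), vals[mask_b].mean()
        rows.append(
            {
                "taxon": taxon,
                "statistic": stat,
                "p": p,
                f"mean_{ga}": ma,
                f"mean_{gb}": mb,
                "enriched_in": ga if ma >= mb else gb,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("q", kind="mergesort").reset_index(drop=True)
    return out


def trait_screen(
    rel: RelativeAbundanceTable,
    traits: TraitTable,
    trait_names: list[str] | None = None,
    floor: float = 0.001,
) -> pd.DataFrame:
    """Spearman correlation of each floored taxon with each trait.

    BH adjustment runs within one trait's family.  Missing trait values are
    dropped pairwise, never imputed; a trait needs >= 4 non-missing samples.
    Columns: trait, taxon, rho, p, q, n.
    """
    props = rel.proportions[traits.sample_ids]
    keep = abundance_floor(rel, floor)
    names = trait_names if trait_names is not None else traits.trait_names
    frames = []
    for name in names:
        tv = pd.to_numeric(traits.data[name], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(tv)
        if ok.sum() < 4:
            raise ValueError(f"trait {name!r} has fewer than 4 non-missing values")
        rows = []
        for taxon in keep:
            vals = props.loc[taxon].to_numpy()[ok]
            rho, p = spearman(vals, tv[ok])
            rows.append({"trait": name, "taxon": taxon, "rho": rho, "p": p, "n": int(ok.sum())})
        frame = pd.DataFrame(rows)
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def cooccurrence_network(
    rel: RelativeAbundanceTable, floor: float = 0.001, alpha: float = 0.05
) -> pd.DataFrame:
    """Genus-level Spearman co-occurrence edges at BH-adjusted p < alpha.

    All floored taxon pairs form one BH family; an edge keeps its signed
    rho.  Returns an edge table (source, target, rho, p, q, sign); per-node
    degree is the edge count of that node in the table.
    """
    keep = abundance_floor(rel, floor)
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa above the floor")
    mat = rel.proportions.loc[keep].to_numpy()
    rho, p = sps.spearmanr(mat, axis=1)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu = np.triu_indices(len(keep), k=1)
    edges = pd.DataFrame(
        {
            "source": [keep[i] for i in iu[0]],
            "target": [keep[j] for j in iu[1]],
            "rho": rho[iu],
            "p": p[iu],
        }
    )
    edges["q"] = bh_adjust(edges["p"].to_numpy())
    edges = edges[edges["q"] < alpha].reset_index(drop=True)
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    return edges


def network_degrees(edges: pd.DataFrame) -> pd.Series:
    """Node degree from an edge table."""
    return pd.concat([edges["source"], edges["target"]]).value_counts().rename("degree")


def bray_curtis(rel: RelativeAbundanceTable) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity d = sum|u-v| / sum(u+v)."""
    mat = rel.proportions.to_numpy().T
    dist = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(dist, index=rel.sample_ids, columns=rel.sample_ids)


@dataclass
class PcoaResult:
    """Classical-scaling ordination: coordinates on axes with positive
    eigenvalues; negative eigenvalues are reported but excluded from the
    proportion-explained denominator."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(distance: pd.DataFrame, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinate analysis by double-centring the squared
    distance matrix; axes ordered by decreasing eigenvalue."""
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals[0]) if evals.size else 0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    labels = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    index = distance.index if isinstance(distance, pd.DataFrame) else range(n)
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=index, columns=labels),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    distance: pd.DataFrame, groups, n_perm: int = 999, seed: int | None = None
) -> AnosimResult:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the p-value is (number of permuted R >= observed + 1) /
    (n_perm + 1) under seeded uniform label permutation, so p >= 1/(n_perm+1).
    """
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(
        groups.reindex(distance.index) if isinstance(groups, pd.Series) else groups
    )
    if len(labels) != d.shape[0]:
        raise ValueError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    iu = np.triu_indices(d.shape[0], k=1)
    ranks = sps.rankdata(d[iu])
    within = labels[iu[0]] == labels[iu[1]]
    observed = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AnosimResult(R=float(observed), p=float(p), n_perm=n_perm)
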