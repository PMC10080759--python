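"""Random-matrix-theory threshold selection for co-occurrence networks.

The similarity matrix is |Pearson r| of (log-transformed) abundance
profiles.  For each candidate threshold, entries below the cut are zeroed
and the eigenvalue spectrum of the remaining matrix is examined: a matrix
still dominated by noise correlations shows Gaussian-orthogonal-ensemble
(GOE, Wigner) nearest-neighbour spacing statistics, while a matrix reduced
to independent signal blocks shows Poisson spacing statistics.  The network
threshold is the lowest candidate from which the Poisson hypothesis is no
longer rejected (and stays unrejected for every higher usable candidate) --
the transition point between noise and signal.

Spacings are measured after unfolding: eigenvalues are mapped through a
cubic-smoothing-spline estimate of the cumulative spectral density so that
spacings have unit mean regardless of the spectral shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import LSQUnivariateSpline
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SimilarityMatrix",
    "NNSDResult",
    "ThresholdScan",
    "ThresholdSelectionError",
    "NetworkModel",
    "similarity_matrix",
    "unfold_eigenvalues",
    "spacing_gof",
    "nnsd_from_eigenvalues",
    "nnsd_statistics",
    "select_threshold",
    "build_network",
    "pearson_edge_stats",
]


class ThresholdSelectionError(RuntimeError):
    """No candidate threshold satisfied the Poisson-transition rule."""


@dataclass
class SimilarityMatrix:
    """Symmetric |Pearson r| matrix with unit diagonal.

    ``signed`` keeps the signed correlations for edge attributes; the
    thresholding itself runs on absolute values (positive and negative
    dependence are equally informative for network inference).
    """

    values: pd.DataFrame
    signed: pd.DataFrame | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)


def similarity_matrix(transformed: pd.DataFrame) -> SimilarityMatrix:
    """|Pearson r| of taxa (rows) across samples (columns).

    Zero-variance taxa cannot be correlated and are excluded with a warning.
    Needs >= 4 samples.
    """
    if transformed.shape[1] < 4:
        raise ValueError("need at least 4 samples for correlation")
    var = transformed.var(axis=1, ddof=0)
    flat = var.index[var == 0].tolist()
    if flat:
        warnings.warn(f"excluding zero-variance taxa: {flat}", stacklevel=2)
        transformed = transformed.drop(index=flat)
    r = np.corrcoef(transformed.to_numpy())
    np.fill_diagonal(r, 1.0)
    ids = list(transformed.index)
    return SimilarityMatrix(
        values=pd.DataFrame(np.abs(r), index=ids, columns=ids),
        signed=pd.DataFrame(r, index=ids, columns=ids),
        n_samples=transformed.shape[1],
    )


def unfold_eigenvalues(
    eigenvalues: np.ndarray,
    method: str = "spline",
    n_knots: int | None = None,
    broadening: float | None = None,
) -> np.ndarray:
    """Unit-mean nearest-neighbour spacings of an eigenvalue spectrum.

    'spline': fit a cubic least-squares spline to the empirical cumulative
    spectral count, with interior knots at eigenvalue quantiles (default
    ~20, fewer for small spectra), and map each eigenvalue through it.
    Knot count controls the smoothing scale: enough knots to follow the
    spectral density, too few data points per knot would let the spline
    chase level fluctuations and compress the spacings.
    'gaussian': smooth the cumulative count with a Gaussian kernel in rank
    space instead.  Either way the spacings of the mapped spectrum are
    returned (non-finite and negative artefacts of smoothing are clipped).
    """
    w = np.sort(np.asarray(eigenvalues, dtype=float))
    if w.size < 10:
        raise ValueError("need at least 10 eigenvalues to unfold")
    uniq, counts = np.unique(w, return_counts=True)
    cum = np.cumsum(counts).astype(float) - 0.5
    if method == "spline":
        if uniq.size < 15:
            raise ValueError("spectrum too degenerate to unfold")
        if n_knots is None:
            n_knots = int(np.clip(uniq.size // 12, 4, 20))
        knots = np.quantile(uniq, np.linspace(0, 1, n_knots + 2)[1:-1])
        knots = np.unique(knots)
        knots = knots[(knots > uniq[0]) & (knots < uniq[-1])]
        spline = LSQUnivariateSpline(uniq, cum, knots, k=3)
        mapped = spline(w)
    elif method == "gaussian":
        sigma = broadening if broadening is not None else max(2.0, w.size / 50.0)
        smooth = gaussian_filter1d(cum, sigma=sigma, mode="nearest")
        mapped = np.interp(w, uniq, smooth)
    else:
        raise ValueError(f"unknown unfolding method {method!r}")
    spacings = np.diff(mapped)
    spacings = spacings[np.isfinite(spacings)]
    return np.clip(spacings, 0.0, None)


@dataclass
class NNSDResult:
    """Chi-square goodness of fit of unfolded spacings against the Poisson
    (uncorrelated) and GOE/Wigner (correlated) spacing laws."""

    chi2_poisson: float
    p_poisson: float
    chi2_goe: float
    p_goe: float
    n_spacings: int
    mean_spacing: float


def _bin_expected(cdf, edges: np.ndarray, n: int) -> np.ndarray:
    probs = np.diff([cdf(e) for e in edges])
    tail = 1.0 - cdf(edges[-1])
    return n * np.append(probs, tail)


def _merge_small_bins(obs: np.ndarray, exp: np.ndarray, min_expected: float = 5.0):
    """Pool adjacent bins until every expected count reaches min_expected."""
    merged_o, merged_e = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if merged_e:
            merged_o[-1] += acc_o
            merged_e[-1] += acc_e
        else:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
    return np.array(merged_o), np.array(merged_e)


def spacing_gof(spacings: np.ndarray) -> NNSDResult:
    """Chi-square GOF of a spacing sample against Poisson and Wigner laws.

    Histogram bins of width 0.1 on [0, 3] with the tail pooled; bins whose
    expected count falls below 5 are merged with their neighbour.  Both
    reference laws are fully specified (unit mean), so dof = bins - 1.
    """
    s = np.asarray(spacings, dtype=float)
    n = s.size
    if n < 20:
        raise ValueError("need at least 20 spacings for the GOF test")
    edges = np.arange(0.0, 3.0 + 1e-9, 0.1)
    obs_hist, _ = np.histogram(s, bins=np.append(edges, np.inf))

    poisson_cdf = lambda d: 1.0 - np.exp(-d)
    wigner_cdf = lambda d: 1.0 - np.exp(-np.pi * d**2 / 4.0)

    results = {}
    for name, cdf in (("poisson", poisson_cdf), ("goe", wigner_cdf)):
        exp = _bin_expected(cdf, edges, n)
        o, e = _merge_small_bins(obs_hist.astype(float), exp)
        # renormalise tiny mass lost to merging roundoff
        e = e * o.sum() / e.sum()
        chi2 = float(np.sum((o - e) ** 2 / e))
        dof = max(len(o) - 1, 1)
        results[name] = (chi2, float(sps.chi2.sf(chi2, dof)))
    return NNSDResult(
        chi2_poisson=results["poisson"][0],
        p_poisson=results["poisson"][1],
        chi2_goe=results["goe"][0],
        p_goe=results["goe"][1],
        n_spacings=n,
        mean_spacing=float(s.mean()),
    )


def nnsd_from_eigenvalues(eigenvalues: np.ndarray, method: str = "spline") -> NNSDResult:
    """Unfold a raw spectrum and test its spacing distribution."""
    return spacing_gof(unfold_eigenvalues(eigenvalues, method=method))


def _threshold_matrix(
    values: np.ndarray, threshold: float, min_component: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Zero sub-threshold entries (diagonal kept); drop tiny fragments.

    Components smaller than ``min_component`` (including isolated taxa) are
    excluded from the spectrum: their few surviving correlations concentrate
    just above the threshold, so they contribute quasi-degenerate trivial
    eigenvalues that say nothing about the noise-vs-signal transition.
    Returns (submatrix, boolean keep-mask over the original taxa)."""
    from scipy.sparse.csgraph import connected_components

    m = values.copy()
    off = m < threshold
    np.fill_diagonal(off, False)
    m[off] = 0.0
    adj = (m - np.diag(np.diag(m))) > 0
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    keep = sizes[labels] >= min_component
    return m[np.ix_(keep, keep)], keep


def nnsd_statistics(
    matrix: SimilarityMatrix,
    threshold: float,
    n_min: int = 50,
    method: str = "spline",
) -> NNSDResult:
    """NNSD goodness of fit of the similarity matrix thresholded at
    ``threshold``.  Raises ValueError when fewer than ``n_min`` non-isolated
    taxa remain (the scan marks such points unusable)."""
    sub, kept = _threshold_matrix(matrix.values.to_numpy(), threshold)
    if kept.sum() < n_min:
        raise ValueError(
            f"only {int(kept.sum())} non-isolated taxa at threshold {threshold:.2f} "
            f"(need {n_min})"
        )
    evals = np.linalg.eigvalsh(sub)
    return spacing_gof(unfold_eigenvalues(evals, method=method))


@dataclass
class ThresholdScan:
    """Per-candidate NNSD record plus the selected cut-off."""

    scan: pd.DataFrame  # threshold, n_nodes, chi2/p for both laws, usable
    selected: float

    def to_tsv(self, path) -> None:
        self.scan.to_csv(path, sep="\t", index=False)


def select_threshold(
    matrix: SimilarityMatrix,
    grid: np.ndarray | None = None,
    n_min: int = 50,
    alpha: float = 0.05,
    method: str = "spline",
    stability_fraction: float = 0.75,
) -> ThresholdScan:
    """Scan an ascending threshold grid and pick the GOE-to-Poisson transition.

    The selected threshold is the LOWEST candidate at which the Poisson fit
    is not rejected (p > alpha) and at least ``stability_fraction`` of that
    candidate and every higher usable candidate are likewise not rejected.
    The fraction tolerates the chi-square test's own ~alpha false-rejection
    rate along the scan and the degenerate-clique artefacts that appear just
    before total fragmentation; demanding non-rejection at literally every
    higher candidate would make selection fail on most finite-sample
    matrices.  Candidates with fewer than ``n_min`` non-isolated taxa are
    recorded as unusable.
    """
    if grid is None:
        grid = np.round(np.arange(0.30, 0.95 + 1e-9, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly ascending")

    values = matrix.values.to_numpy()
    rows = []
    for t in grid:
        sub, kept = _threshold_matrix(values, t)
        row = {
            "threshold": t,
            "n_nodes": int(kept.sum()),
            "chi2_poisson": np.nan,
            "p_poisson": np.nan,
            "chi2_goe": np.nan,
            "p_goe": np.nan,
            "usable": False,
        }
        if kept.sum() >= n_min:
            try:
                res = spacing_gof(
                    unfold_eigenvalues(np.linalg.eigvalsh(sub), method=method)
                )
            except ValueError:
                pass
            else:
                row.update(
                    chi2_poisson=res.chi2_poisson,
                    p_poisson=res.p_poisson,
                    chi2_goe=res.chi2_goe,
                    p_goe=res.p_goe,
                    usable=True,
                )
        rows.append(row)
    scan = pd.DataFrame(rows)

    usable = scan[scan["usable"]]
    if usable.empty:
        raise ThresholdSelectionError(
            "no usable scan point: widen the grid, lower n_min, or provide more samples"
        )
    selected = None
    thresholds = usable["threshold"].to_numpy()
    accepted = (usable["p_poisson"] > alpha).to_numpy()
    for i, t in enumerate(thresholds):
        if accepted[i] and accepted[i:].mean() >= stability_fraction:
            selected = float(t)
            break
    if selected is None:
        raise ThresholdSelectionError(
            "Poisson statistics never stabilise across the grid: widen the grid "
            "or provide more samples"
        )
    return ThresholdScan(scan=scan, selected=selected)


def pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r at sample size n via the t transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def pearson_edge_stats(matrix: SimilarityMatrix) -> pd.DataFrame:
    """Signed r and per-edge Pearson p for every taxon pair."""
    if matrix.signed is None or matrix.n_samples is None:
        raise ValueError("similarity matrix lacks signed values / sample size")
    ids = matrix.taxon_ids
    r = matrix.signed.to_numpy()
    p = pearson_p_from_r(r, matrix.n_samples)
    iu = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "source": [ids[i] for i in iu[0]],
            "target": [ids[j] for j in iu[1]],
            "r": r[iu],
            "p": p[iu],
        }
    )


@dataclass
class NetworkModel:
    """Thresholded co-occurrence graph plus (once computed) its module
    partition, modularity, and per-node topology table."""

    graph: nx.Graph
    threshold: float
    dropped_isolated: list[str] = field(default_factory=list)
    module_of: dict[str, int] | None = None
    Q: float | None = None
    topology: pd.DataFrame | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    matrix: SimilarityMatrix,
    threshold: float,
    edge_p_filter: bool = True,
    alpha: float = 0.05,
) -> NetworkModel:
    """Undirected graph with an edge wherever |r| >= threshold (and, unless
    disabled, the per-edge Pearson p < alpha).  Edges carry the signed r;
    isolated taxa are dropped and listed on the model."""
    ids = matrix.taxon_ids
    absr = matrix.values.to_numpy()
    signed = matrix.signed.to_numpy() if matrix.signed is not None else absr
    g = nx.Graph()
    g.add_nodes_from(ids)
    if edge_p_filter:
        if matrix.n_samples is None:
            raise ValueError("edge p filter requires the similarity sample size")
        pmat = pearson_p_from_r(signed, matrix.n_samples)
    iu = np.triu_indices(len(ids), k=1)
    for i, j in zip(*iu):
        if absr[i, j] >= threshold:
            if edge_p_filter and pmat[i, j] >= alpha:
                continue
            r = float(signed[i, j])
            g.add_edge(ids[i], ids[j], r=r, sign="positive" if r >= 0 else "negative")
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    return NetworkModel(graph=g, threshold=float(threshold), dropped_isolated=isolated)
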