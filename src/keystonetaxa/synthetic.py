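"""Synthetic gut-community generator with planted ground truth.

Emulates a post-bioinformatics genus-level count table from a two-group
growth-rate contrast study: ~300 genera, balanced high/low groups, planted
correlation modules, connector taxa bridging several modules, taxa with a
group log-abundance shift, and host traits (growth rate, SCFA, immune
measures) coupled to chosen taxa.

The latent model is a Gaussian copula: per-sample log-abundances are
multivariate normal with a factor-structured correlation matrix (one factor
per planted module plus a global background factor).  Counts are multinomial
draws of the softmax-normalised latent abundances at a fixed sequencing
depth, optionally Dirichlet-multinomial overdispersed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._utils import stage_seed
from .table_io import CountTable, TraitTable

__all__ = [
    "TraitCoupling",
    "SyntheticSpec",
    "GroundTruth",
    "planted_correlation",
    "generate_community",
    "generate_traits",
    "generate_dataset",
    "write_fixture",
]


class TraitCoupling(NamedTuple):
    """One trait's dependence on taxa: trait = sum(w_j * z(latent_j)) + noise."""

    taxa: tuple[int, ...]
    weights: tuple[float, ...]
    noise_sd: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted community.

    ``delta`` is a natural-log shift of latent abundance added to the
    differential taxa in group H; ``latent_sd`` sets the marginal spread of
    log-abundance across animals, so delta/latent_sd is the standardised
    effect size seen by a group screen.
    """

    n_taxa: int = 300
    n_samples_per_group: int = 10
    n_blocks: int = 6
    block_size: int = 20
    rho_within: float = 0.7
    rho_between: float = 0.05
    rho_connector: float = 0.4
    n_connectors: int = 4
    connector_targets: int = 3
    n_differential: int = 10
    delta: float = 1.0
    latent_sd: float = 0.4
    trait_couplings: Mapping[str, TraitCoupling] | None = None
    sequencing_depth: int = 50_000
    base_log_abundance: tuple[float, ...] | None = None
    overdispersion: float | None = None  # Dirichlet concentration scale; None = multinomial
    group_labels: tuple[str, str] = ("H", "L")
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1 or self.n_samples_per_group < 2:
            raise ValueError("need n_taxa >= 1 and n_samples_per_group >= 2")
        if not (0 <= self.rho_between < self.rho_within <= 1):
            raise ValueError(
                "require 0 <= rho_between < rho_within <= 1; shrink rho_between "
                f"(got rho_within={self.rho_within}, rho_between={self.rho_between})"
            )
        if self.n_blocks * self.block_size + self.n_connectors > self.n_taxa:
            raise ValueError("block_size * n_blocks + n_connectors exceeds n_taxa")
        if self.n_connectors > 0 and self.connector_targets < 3:
            raise ValueError("connectors must target at least 3 blocks")
        if self.n_connectors > 0 and self.connector_targets > self.n_blocks:
            raise ValueError("connector_targets exceeds n_blocks")
        if self.n_differential > self.n_taxa:
            raise ValueError("n_differential exceeds n_taxa")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be positive")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        if self.base_log_abundance is not None and len(self.base_log_abundance) != self.n_taxa:
            raise ValueError("base_log_abundance length must equal n_taxa")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    @property
    def taxon_ids(self) -> list[str]:
        width = max(3, len(str(self.n_taxa)))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_taxa)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """Planted structure to score recovery against."""

    block_assignment: dict[str, int | None]
    connector_taxa: set[str]
    connector_targets: dict[str, tuple[int, ...]]
    differential_taxa: dict[str, float]  # taxon -> signed delta (log units, H vs L)
    trait_coupled_taxa: dict[str, set[str]]
    groups: pd.Series | None = None  # sample -> group label

    def to_jsonable(self) -> dict:
        return {
            "block_assignment": {
                t: (int(b) if b is not None else None) for t, b in self.block_assignment.items()
            },
            "connector_taxa": sorted(self.connector_taxa),
            "connector_targets": {t: list(v) for t, v in self.connector_targets.items()},
            "differential_taxa": {t: float(d) for t, d in self.differential_taxa.items()},
            "trait_coupled_taxa": {k: sorted(v) for k, v in self.trait_coupled_taxa.items()},
            "groups": None if self.groups is None else self.groups.to_dict(),
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "GroundTruth":
        groups = obj.get("groups")
        return cls(
            block_assignment={t: b for t, b in obj["block_assignment"].items()},
            connector_taxa=set(obj["connector_taxa"]),
            connector_targets={t: tuple(v) for t, v in obj["connector_targets"].items()},
            differential_taxa=dict(obj["differential_taxa"]),
            trait_coupled_taxa={k: set(v) for k, v in obj["trait_coupled_taxa"].items()},
            groups=None if groups is None else pd.Series(groups, name="group"),
        )


def _factor_loadings(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Loading matrix L (taxa x [global + block factors]) and idiosyncratic
    variances psi such that Sigma = L L' + diag(psi) is the planted
    correlation matrix (unit diagonal, PD by construction)."""
    p, B = spec.n_taxa, spec.n_blocks
    L = np.zeros((p, B + 1))
    L[:, 0] = np.sqrt(spec.rho_between)  # shared background factor

    for b in range(B):
        lo, hi = b * spec.block_size, (b + 1) * spec.block_size
        L[lo:hi, 1 + b] = np.sqrt(spec.rho_within - spec.rho_between)

    # Connectors: loading alpha on each target-block factor gives a planted
    # correlation of rho_connector with every member of the target blocks.
    n_block_taxa = B * spec.block_size
    if spec.n_connectors > 0:
        if spec.rho_connector <= spec.rho_between:
            raise ValueError("rho_connector must exceed rho_between; raise rho_connector")
        alpha = (spec.rho_connector - spec.rho_between) / np.sqrt(
            spec.rho_within - spec.rho_between
        )
        for c in range(spec.n_connectors):
            idx = n_block_taxa + c
            # stride by the target count so connectors claim disjoint block
            # sets while blocks outnumber them (overlap correlates the
            # connectors and encourages module merging downstream)
            targets = [(c * spec.connector_targets + k) % B for k in range(spec.connector_targets)]
            L[idx, [1 + t for t in targets]] = alpha

    psi = 1.0 - np.sum(L**2, axis=1)
    if np.any(psi <= 0):
        raise ValueError(
            "planted correlation matrix is not positive definite: connector or "
            "block loadings exceed unit variance; shrink rho_between or "
            "rho_connector, or reduce connector_targets"
        )
    return L, psi


def planted_correlation(spec: SyntheticSpec) -> np.ndarray:
    """The exact latent correlation matrix implied by the spec."""
    spec.validate()
    L, psi = _factor_loadings(spec)
    sigma = L @ L.T + np.diag(psi)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _connector_target_map(spec: SyntheticSpec) -> dict[str, tuple[int, ...]]:
    ids = spec.taxon_ids
    n_block_taxa = spec.n_blocks * spec.block_size
    out = {}
    for c in range(spec.n_connectors):
        targets = tuple(
            (c * spec.connector_targets + k) % spec.n_blocks
            for k in range(spec.connector_targets)
        )
        out[ids[n_block_taxa + c]] = targets
    return out


def _differential_indices(spec: SyntheticSpec) -> list[int]:
    """Differential taxa are drawn from the background (non-block,
    non-connector) taxa so planted effects stay orthogonal to planted
    correlation structure; fall back to the tail of the taxon list."""
    start = spec.n_blocks * spec.block_size + spec.n_connectors
    free = list(range(start, spec.n_taxa))
    if len(free) >= spec.n_differential:
        return free[: spec.n_differential]
    return list(range(spec.n_taxa - spec.n_differential, spec.n_taxa))


def sample_latent(spec: SyntheticSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the latent sample-by-taxon log-abundance matrix and the truth.

    Group H's differential taxa receive the +/- delta shift here, before
    count sampling, so traits coupled to latent abundances see the same
    group structure the counts do.
    """
    spec.validate()
    L, psi = _factor_loadings(spec)
    rng = np.random.default_rng(stage_seed(spec.seed, "latent"))

    n, p = spec.n_samples, spec.n_taxa
    factors = rng.standard_normal((n, L.shape[1]))
    eps = rng.standard_normal((n, p))
    z = factors @ L.T + eps * np.sqrt(psi)  # MVN(0, Sigma) exactly

    if spec.base_log_abundance is not None:
        base = np.asarray(spec.base_log_abundance, dtype=float)
    else:
        base = rng.normal(0.0, 1.5, size=p)  # ~3 orders of magnitude spread

    y = base + spec.latent_sd * z

    ids = spec.taxon_ids
    diff_idx = _differential_indices(spec)
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(len(diff_idx))])
    h_mask = np.zeros(n, dtype=bool)
    h_mask[: spec.n_samples_per_group] = True
    for k, j in enumerate(diff_idx):
        y[h_mask, j] += signs[k] * spec.delta

    block_assignment: dict[str, int | None] = {t: None for t in ids}
    for b in range(spec.n_blocks):
        for j in range(b * spec.block_size, (b + 1) * spec.block_size):
            block_assignment[ids[j]] = b
    connector_targets = _connector_target_map(spec)
    groups = pd.Series(
        [spec.group_labels[0]] * spec.n_samples_per_group
        + [spec.group_labels[1]] * spec.n_samples_per_group,
        index=spec.sample_ids,
        name="group",
    )
    truth = GroundTruth(
        block_assignment=block_assignment,
        connector_taxa=set(connector_targets),
        connector_targets=connector_targets,
        differential_taxa={
            ids[j]: float(signs[k] * spec.delta) for k, j in enumerate(diff_idx)
        },
        trait_coupled_taxa={},
        groups=groups,
    )
    latent = pd.DataFrame(y, index=spec.sample_ids, columns=ids)
    return latent, truth


def _counts_from_latent(latent: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    rng = np.random.default_rng(stage_seed(spec.seed, "counts"))
    out = np.empty(latent.shape, dtype=np.int64)
    for i, row in enumerate(latent):
        logits = row - row.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        if spec.overdispersion is not None:
            probs = rng.dirichlet(probs * spec.overdispersion)
        out[i] = rng.multinomial(spec.sequencing_depth, probs)
    return out


def _default_taxonomy(spec: SyntheticSpec) -> pd.DataFrame:
    """Synthetic taxonomy sidecar: every 5 genera share a family."""
    ids = spec.taxon_ids
    fam = [f"f{(i // 5) + 1:03d}" for i in range(spec.n_taxa)]
    return pd.DataFrame({"family": fam, "genus": ids}, index=pd.Index(ids, name="taxon"))


def generate_community(
    spec: SyntheticSpec, return_latent: bool = False
) -> tuple[CountTable, GroundTruth] | tuple[CountTable, GroundTruth, pd.DataFrame]:
    """Generate a taxa-by-sample count table plus planted ground truth.

    Column sums equal ``spec.sequencing_depth`` exactly.  Identical spec +
    seed gives byte-identical output.
    """
    latent, truth = sample_latent(spec)
    counts = _counts_from_latent(latent.to_numpy(), spec)
    table = CountTable(
        counts=pd.DataFrame(counts.T, index=spec.taxon_ids, columns=spec.sample_ids),
        taxonomy=_default_taxonomy(spec),
    )
    if return_latent:
        return table, truth, latent
    return table, truth


def default_trait_couplings(spec: SyntheticSpec) -> dict[str, TraitCoupling]:
    """Couplings emulating the study's trait families.

    Growth rate (ADG) follows the planted differential taxa with weights
    matching their shift signs; the SCFA traits follow taxa of the first
    planted module; IgG runs against the H-enriched taxa (the study's serum
    IgG was negatively associated with growth).
    """
    diff_idx = _differential_indices(spec) if spec.n_differential > 0 else []
    signs = tuple(1.0 if k % 2 == 0 else -1.0 for k in range(len(diff_idx)))
    block0 = tuple(range(min(3, spec.block_size))) if spec.n_blocks > 0 else ()
    couplings = {
        "ADG": TraitCoupling(tuple(diff_idx), tuple(0.4 * s for s in signs), 1.0),
        "acetate": TraitCoupling(block0, (0.6,) * len(block0), 0.8),
        "propionate": TraitCoupling(block0, (0.5,) * len(block0), 0.8),
        "butyrate": TraitCoupling(block0[:1], (0.7,) * len(block0[:1]), 0.8),
        "total_scfa": TraitCoupling(block0, (0.7,) * len(block0), 0.6),
        "IgG": TraitCoupling(tuple(diff_idx), tuple(-0.3 * s for s in signs), 1.0),
        "ALB": TraitCoupling(
            tuple(diff_idx[:2]), tuple((0.3, -0.3)[: len(diff_idx[:2])]), 1.0
        ),
    }
    return couplings


def generate_traits(
    latent: pd.DataFrame, truth: GroundTruth, spec: SyntheticSpec
) -> TraitTable:
    """Traits as noisy linear read-outs of standardised latent abundances."""
    couplings = spec.trait_couplings
    if couplings is None:
        couplings = default_trait_couplings(spec)
    rng = np.random.default_rng(stage_seed(spec.seed, "traits"))
    ids = list(latent.columns)
    n = latent.shape[0]
    z = latent.to_numpy()
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    zs = (z - z.mean(axis=0)) / sd

    data = {}
    for name, (taxa, weights, noise_sd) in couplings.items():
        taxa_idx = []
        for t in taxa:
            if isinstance(t, str):
                if t not in latent.columns:
                    raise KeyError(f"trait '{name}' couples to unknown taxon {t!r}")
                taxa_idx.append(latent.columns.get_loc(t))
            else:
                if not (0 <= int(t) < latent.shape[1]):
                    raise KeyError(f"trait '{name}' couples to unknown taxon index {t}")
                taxa_idx.append(int(t))
        w = np.asarray(weights, dtype=float)
        if len(w) != len(taxa_idx):
            raise ValueError(f"trait '{name}': weights and taxa lengths differ")
        value = zs[:, taxa_idx] @ w + rng.normal(0.0, noise_sd, size=n)
        data[name] = value
        truth.trait_coupled_taxa[name] = {ids[j] for j, wt in zip(taxa_idx, w) if wt != 0}

    frame = pd.DataFrame(data, index=latent.index)
    groups = truth.groups
    if groups is None:
        raise ValueError("ground truth carries no group design")
    frame.insert(0, "group", groups.reindex(frame.index))
    return TraitTable(data=frame)


def generate_dataset(spec: SyntheticSpec) -> tuple[CountTable, TraitTable, GroundTruth]:
    """Counts + traits + truth in one seeded call."""
    table, truth, latent = generate_community(spec, return_latent=True)
    traits = generate_traits(latent, truth, spec)
    return table, traits, truth


def write_fixture(
    counts: CountTable,
    traits: TraitTable,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv / traits.tsv / truth.json (+ taxonomy.tsv) to a
    directory, creating it on demand; round-trips through table_io readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "traits": directory / "traits.tsv",
        "truth": directory / "truth.json",
    }
    counts.counts.rename_axis("taxon").to_csv(paths["counts"], sep="\t")
    traits.data.rename_axis("sample").to_csv(paths["traits"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
    if counts.taxonomy is not None:
        paths["taxonomy"] = directory / "taxonomy.tsv"
        counts.taxonomy.rename_axis("taxon").to_csv(paths["taxonomy"], sep="\t")
    return paths
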