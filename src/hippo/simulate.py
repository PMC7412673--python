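"""Synthetic UMI count generation under Poisson, Poisson-mixture, NB and ZINB models.

The mixture generator is the ground-truth engine for the whole test suite:
cells belong to one of K clusters and gene g in a cluster-k cell draws
X ~ Poisson(lambda_kg).  "Heterogeneous" genes carry cluster-specific
rates; all other genes share one rate, so under the homogeneous-Poisson
null every gene is shared.  NB counts are generated through the
Gamma-Poisson construction (cell rate ~ Gamma(r, scale=lambda/r), count ~
Poisson(rate)), which realizes variance = lambda^2/r + lambda; ZINB adds a
structural zero with probability pi0.

The default mixture emulates a low-UMI droplet experiment: 3 cell types of
300 cells each, 2,000 genes, 5% heterogeneous genes with per-cluster rates
log-uniform on [0.5, 8], shared genes log-uniform on [0.05, 2].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .counts import CellLabels, CountMatrix, ValidationError, write_labels, write_mtx

__all__ = [
    "MixtureSpec",
    "default_mixture_spec",
    "homogeneous_poisson_spec",
    "simulate_poisson_mixture",
    "simulate_homogeneous_poisson",
    "simulate_nb",
    "simulate_zinb",
    "write_fixture",
]


@dataclass
class MixtureSpec:
    """Ground truth for a finite-Poisson-mixture count matrix.

    ``rates`` is genes x clusters; ``n_cells_per_cluster`` implies the
    mixing weights pi_k = n_k / C.  Genes outside ``heterogeneous_genes``
    must have identical rates across clusters.
    """

    n_cells_per_cluster: tuple[int, ...]
    rates: np.ndarray
    heterogeneous_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    seed: int = 0

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        self.heterogeneous_genes = np.asarray(self.heterogeneous_genes, dtype=int)
        if np.any(self.rates < 0):
            raise ValidationError("rates must be nonnegative")
        if self.rates.shape[1] != len(self.n_cells_per_cluster):
            raise ValidationError("rates must have one column per cluster")
        if any(n <= 0 for n in self.n_cells_per_cluster):
            raise ValidationError("cluster sizes must be positive")
        shared = np.setdiff1d(np.arange(self.n_genes), self.heterogeneous_genes)
        if shared.size and not np.all(
            self.rates[shared] == self.rates[shared][:, [0]]
        ):
            raise ValidationError("non-heterogeneous genes must share one rate")

    @property
    def n_genes(self) -> int:
        return self.rates.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.rates.shape[1]

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_cluster))

    @property
    def weights(self) -> np.ndarray:
        n = np.asarray(self.n_cells_per_cluster, dtype=float)
        return n / n.sum()


def default_mixture_spec(
    n_clusters: int = 3,
    cells_per_cluster: int = 300,
    n_genes: int = 2000,
    het_fraction: float = 0.05,
    het_rate_range: tuple[float, float] = (0.5, 8.0),
    shared_rate_range: tuple[float, float] = (0.05, 2.0),
    seed: int = 0,
) -> MixtureSpec:
    """Low-UMI droplet-style mixture with a fixed fraction of cluster-specific genes."""
    rng = np.random.default_rng(seed)
    n_het = int(round(het_fraction * n_genes))
    het = rng.choice(n_genes, size=n_het, replace=False)
    shared = np.exp(rng.uniform(*np.log(shared_rate_range), size=n_genes))
    rates = np.tile(shared[:, None], (1, n_clusters))
    rates[het] = np.exp(rng.uniform(*np.log(het_rate_range), size=(n_het, n_clusters)))
    return MixtureSpec((cells_per_cluster,) * n_clusters, rates, np.sort(het), seed)


def homogeneous_poisson_spec(
    n_genes: int = 2000,
    n_cells: int = 1000,
    rate_range: tuple[float, float] = (0.05, 20.0),
    seed: int = 0,
) -> MixtureSpec:
    """Single-cluster null: per-gene rates log-uniform on ``rate_range``."""
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.uniform(*np.log(rate_range), size=(n_genes, 1)))
    return MixtureSpec((n_cells,), rates, seed=seed)


def simulate_poisson_mixture(spec: MixtureSpec) -> tuple[CountMatrix, CellLabels]:
    """Draw the count matrix and ground-truth labels; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    blocks = []
    labels = []
    for k, n_k in enumerate(spec.n_cells_per_cluster):
        lam = np.broadcast_to(spec.rates[:, [k]], (spec.n_genes, n_k))
        blocks.append(rng.poisson(lam))
        labels.extend([k] * n_k)
    x = np.hstack(blocks)
    gene_ids = [f"gene{i}" for i in range(spec.n_genes)]
    cell_ids = [f"cell{i}" for i in range(spec.n_cells)]
    return (
        CountMatrix(sp.csr_matrix(x), gene_ids, cell_ids),
        CellLabels(cell_ids, np.array(labels)),
    )


def simulate_homogeneous_poisson(
    n_genes: int = 2000,
    n_cells: int = 1000,
    rate_range: tuple[float, float] = (0.05, 20.0),
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Null fixture: i.i.d. Poisson counts per gene; returns matrix and true rates."""
    spec = homogeneous_poisson_spec(n_genes, n_cells, rate_range, seed)
    m, _ = simulate_poisson_mixture(spec)
    return m, spec.rates[:, 0]


def simulate_nb(
    n_cells: int, lam: float, r: float, seed: int = 0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """NB(lambda, r) counts via the Gamma-Poisson route.

    Each cell's Poisson rate is Gamma(shape=r, scale=lambda/r), giving
    marginal mean lambda and variance lambda^2/r + lambda.
    """
    if r <= 0:
        raise ValidationError("r must be > 0")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if lam == 0:
        return np.zeros(n_cells, dtype=np.int64)
    cell_rates = rng.gamma(shape=r, scale=lam / r, size=n_cells)
    return rng.poisson(cell_rates)


def simulate_zinb(
    n_cells: int,
    lam: float,
    r: float,
    pi0: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ZINB counts: structural zero with probability pi0, else an NB draw."""
    if not (0 <= pi0 < 1):
        raise ValidationError("pi0 must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    x = simulate_nb(n_cells, lam, r, rng=rng)
    structural = rng.random(n_cells) < pi0
    x[structural] = 0
    return x


def write_fixture(spec: MixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Simulate and write matrix.mtx + genes.tsv + barcodes.tsv + labels.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m, labels = simulate_poisson_mixture(spec)
    paths = {
        "matrix": str(out / "matrix.mtx"),
        "genes": str(out / "genes.tsv"),
        "barcodes": str(out / "barcodes.tsv"),
        "labels": str(out / "labels.tsv"),
    }
    write_mtx(m, paths["matrix"], paths["genes"], paths["barcodes"])
    write_labels(labels, paths["labels"])
    return paths
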