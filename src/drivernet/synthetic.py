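"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the shape of a tumour expression cohort without
claiming distributional realism: driver genes are independent standard
normals, each partner gene is ``rho * driver + sqrt(1 - rho^2) * noise``
so its population correlation with its driver is exactly ``rho``, and
noise genes are independent.  Interaction networks are hub-structured so
the true centrality ranking is known, and survival times are exponential
with a hazard that depends on the expression group of a chosen gene.

All outputs are deterministic functions of ``SimulationConfig.seed``:
each operation draws from its own child stream spawned from the seed, so
regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExpressionMatrix

# child-stream tags, one per operation
_STREAM_EXPRESSION = 1
_STREAM_MISSING = 2
_STREAM_NETWORK = 3
_STREAM_SURVIVAL = 4


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``rho`` is the Pearson correlation between each partner gene and its
    driver; ``hazard_ratio`` multiplies the event hazard of samples whose
    ``hazard_gene`` expression exceeds the cohort median; ``horizon_days``
    is the administrative-censoring horizon (default ten years).
    """

    n_drivers: int = 10
    n_partners_per_driver: int = 2
    n_noise: int = 100
    n_samples: int = 200
    rho: float = 0.8
    missing_fraction: float = 0.0
    n_heavy_missing_genes: int = 0
    hazard_gene: str | None = None
    hazard_ratio: float = 1.0
    horizon_days: int = 3650
    baseline_median_days: float = 3650.0
    expression_scale: str = "latent"  # "latent" (normal) or "positive" (exp)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drivers", "n_partners_per_driver", "n_noise",
                     "n_samples", "n_heavy_missing_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a count >= 0, got {v!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigurationError(f"rho must be in [0, 1), got {self.rho!r}")
        if not (0.0 <= self.missing_fraction <= 1.0):
            raise ConfigurationError(
                f"missing_fraction must be in [0, 1], got {self.missing_fraction!r}")
        if not self.hazard_ratio > 0:
            raise ConfigurationError(
                f"hazard_ratio must be > 0, got {self.hazard_ratio!r}")
        if not self.horizon_days > 0:
            raise ConfigurationError(
                f"horizon_days must be > 0, got {self.horizon_days!r}")
        if self.expression_scale not in ("latent", "positive"):
            raise ConfigurationError(
                f"expression_scale must be 'latent' or 'positive', "
                f"got {self.expression_scale!r}")

    @property
    def n_genes(self) -> int:
        return self.n_drivers * (1 + self.n_partners_per_driver) + self.n_noise

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class SyntheticTruth:
    """Ground-truth labels of a generated cohort."""

    roles: pd.DataFrame  # columns: gene, role, driver (NA for non-partners)
    rho: float
    hazard_gene: str | None = None
    hazard_ratio: float = 1.0

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.roles.loc[self.roles["role"] == role, "gene"])

    @property
    def partner_map(self) -> dict[str, str]:
        part = self.roles[self.roles["role"] == "partner"]
        return dict(zip(part["gene"], part["driver"]))

    def to_tsv(self, path: str | Path) -> None:
        self.roles.to_csv(path, sep="\t", index=False, na_rep="NA")


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a driver/partner/noise expression matrix.

    Drivers are i.i.d. standard normal across samples; partner ``j`` of
    driver ``d`` is ``rho*d + sqrt(1-rho^2)*eps``; noise genes are
    independent.  With ``expression_scale="positive"`` the latent values
    are exponentiated (log-normal, FPKM-like); correlations quoted in the
    truth always refer to the latent scale.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    driver_names = [f"DRV{i:03d}" for i in range(config.n_drivers)]
    drivers = rng.standard_normal((config.n_drivers, n))

    rows, names, roles, parent = [], [], [], []
    for i, name in enumerate(driver_names):
        rows.append(drivers[i])
        names.append(name)
        roles.append("driver")
        parent.append(None)
    scale = math.sqrt(1.0 - config.rho ** 2)
    for i, dname in enumerate(driver_names):
        for j in range(config.n_partners_per_driver):
            rows.append(config.rho * drivers[i] + scale * rng.standard_normal(n))
            names.append(f"PTN{i:03d}_{j:02d}")
            roles.append("partner")
            parent.append(dname)
    for i in range(config.n_noise):
        rows.append(rng.standard_normal(n))
        names.append(f"NSE{i:04d}")
        roles.append("noise")
        parent.append(None)

    grid = np.asarray(rows) if rows else np.empty((0, n))
    if config.expression_scale == "positive":
        grid = np.exp(grid)
    matrix = ExpressionMatrix(pd.DataFrame(grid, index=names, columns=samples))
    truth = SyntheticTruth(
        roles=pd.DataFrame({"gene": names, "role": roles, "driver": parent}),
        rho=config.rho,
        hazard_gene=config.hazard_gene,
        hazard_ratio=config.hazard_ratio,
    )
    return matrix, truth


def inject_missing(
    matrix: ExpressionMatrix,
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> ExpressionMatrix:
    """Mask cells as missing: heavy rows above the 50% rule, the rest uniform.

    Exactly ``n_heavy_missing_genes`` rows get strictly more than half of
    their cells masked (these are what the preprocessing 50% rule must
    drop); remaining cells are masked i.i.d. at ``missing_fraction``.
    Heavy rows are drawn from noise genes first (when ``truth`` is given)
    so that planted structure survives preprocessing.  Any non-heavy row
    that the uniform draw pushes above 50% is thinned back deterministically,
    keeping the heavy-row count exact.
    """
    if matrix.n_genes == 0:
        raise ConfigurationError("matrix must be non-empty")
    if config.n_heavy_missing_genes > matrix.n_genes:
        raise ConfigurationError(
            "n_heavy_missing_genes exceeds the number of genes")
    if config.missing_fraction == 0 and config.n_heavy_missing_genes == 0:
        return ExpressionMatrix(matrix.values.copy())

    rng = config.rng(_STREAM_MISSING)
    values = matrix.values.copy()
    n_genes, n_samples = values.shape

    k = config.n_heavy_missing_genes
    if truth is not None:
        noise_idx = [i for i, g in enumerate(matrix.genes)
                     if g in set(truth.genes_with_role("noise"))]
        other_idx = [i for i in range(n_genes) if i not in set(noise_idx)]
        # permute within each tier so noise genes are consumed first
        pool = np.concatenate([
            np.asarray(noise_idx, dtype=int)[rng.permutation(len(noise_idx))],
            np.asarray(other_idx, dtype=int)[rng.permutation(len(other_idx))],
        ])
    else:
        pool = rng.permutation(n_genes)
    heavy = pool[:k] if k else np.empty(0, dtype=int)
    heavy_set = set(int(i) for i in heavy)

    half = n_samples // 2
    n_heavy_cells = max(half + 1, int(round(0.6 * n_samples)))
    mask = np.zeros((n_genes, n_samples), dtype=bool)
    for i in heavy:
        cols = rng.permutation(n_samples)[:n_heavy_cells]
        mask[i, cols] = True

    if config.missing_fraction > 0:
        uniform = rng.random((n_genes, n_samples)) < config.missing_fraction
        for i in range(n_genes):
            if i in heavy_set:
                continue
            row = uniform[i]
            excess = int(row.sum()) - half
            if excess > 0:  # keep the >50% rows exactly the heavy ones
                on = np.flatnonzero(row)
                row[on[rng.permutation(len(on))[:excess]]] = False
            mask[i] |= row

    arr = values.to_numpy()
    arr[mask] = np.nan
    return ExpressionMatrix(pd.DataFrame(arr, index=values.index,
                                         columns=values.columns))


def simulate_network(
    genes: Sequence[str],
    hub_genes: Sequence[str],
    edges_per_nonhub: int = 2,
    seed: int = 0,
    hub_fraction: float = 0.8,
    score_range: tuple[int, int] = (400, 999),
) -> pd.DataFrame:
    """Hub-structured undirected edge list in STRING-export dialect.

    Each hub is wired to ``hub_fraction`` of all other nodes; every
    non-hub additionally receives ``edges_per_nonhub`` random edges to
    other non-hubs, so hubs dominate every centrality metric by
    construction.  Returns a DataFrame with columns ``protein1``,
    ``protein2``, ``combined_score`` (integers in ``score_range``).
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ConfigurationError("genes contains duplicate symbols")
    hubs = list(hub_genes)
    missing = set(hubs) - set(genes)
    if missing:
        raise ConfigurationError(f"hub_genes not among genes: {sorted(missing)}")
    if not (0.0 < hub_fraction <= 1.0):
        raise ConfigurationError(f"hub_fraction must be in (0, 1], got {hub_fraction!r}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_NETWORK]))
    hub_set = set(hubs)
    nonhubs = [g for g in genes if g not in hub_set]

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    n_targets = max(1, int(round(hub_fraction * (len(genes) - 1))))
    for h in hubs:
        others = [g for g in genes if g != h]
        for idx in rng.permutation(len(others))[:n_targets]:
            add(h, others[idx])
    if len(nonhubs) > 1:
        for g in nonhubs:
            for idx in rng.integers(0, len(nonhubs), size=edges_per_nonhub):
                add(g, nonhubs[idx])

    ordered = sorted(edges)
    lo, hi = score_range
    scores = rng.integers(lo, hi + 1, size=len(ordered))
    return pd.DataFrame({
        "protein1": [u for u, _ in ordered],
        "protein2": [v for _, v in ordered],
        "combined_score": scores,
    })


def simulate_survival(matrix: ExpressionMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival times tied to one gene's expression group.

    Samples whose ``hazard_gene`` expression exceeds the cohort median get
    their event hazard multiplied by ``hazard_ratio``; the baseline group
    has median survival ``baseline_median_days``.  Follow-up is cut at
    ``horizon_days`` (administrative censoring: event flag 0, time =
    horizon).  Returns columns ``sample``, ``time_days``, ``event``.
    """
    rng = config.rng(_STREAM_SURVIVAL)
    samples = matrix.samples
    rate = math.log(2.0) / config.baseline_median_days
    rates = np.full(len(samples), rate)
    if config.hazard_ratio != 1.0 or config.hazard_gene is not None:
        gene = config.hazard_gene
        if gene is None:
            raise ConfigurationError("hazard_gene required when hazard_ratio != 1")
        if gene not in matrix.values.index:
            raise ConfigurationError(f"hazard_gene {gene!r} not in expression matrix")
        expr = matrix.row(gene)
        high = expr > np.nanmedian(expr)
        rates[high] *= config.hazard_ratio
    times = rng.exponential(1.0 / rates)
    event = (times <= config.horizon_days).astype(int)
    times = np.minimum(times, float(config.horizon_days))
    return pd.DataFrame({"sample": samples,
                         "time_days": times,
                         "event": event})


@dataclass
class SyntheticDataset:
    """One fully generated cohort plus its ground truth."""

    config: SimulationConfig
    expression: ExpressionMatrix
    truth: SyntheticTruth
    edges: pd.DataFrame
    survival: pd.DataFrame
    hub_genes: list[str] = field(default_factory=list)


def simulate_dataset(
    config: SimulationConfig,
    hub_genes: Sequence[str] | None = None,
    edges_per_nonhub: int = 2,
) -> SyntheticDataset:
    """Generate expression (with missingness), network and survival together.

    ``hub_genes`` defaults to the first three drivers and first two
    partners, so the planted hubs sit inside the driver-anchored relevant
    set that downstream selection recovers.
    """
    expr, truth = simulate_expression(config)
    expr = inject_missing(expr, config, truth)
    if hub_genes is None:
        drivers = truth.genes_with_role("driver")
        partners = truth.genes_with_role("partner")
        hub_genes = drivers[:3] + partners[:2]
    edges = simulate_network(expr.genes, hub_genes,
                             edges_per_nonhub=edges_per_nonhub, seed=config.seed)
    survival = simulate_survival(expr, config)
    return SyntheticDataset(config, expr, truth, edges, survival, list(hub_genes))


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all artifacts as TSV; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "drivers": outdir / "drivers.txt",
        "edges": outdir / "edges.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.tsv",
        "hubs": outdir / "hubs.txt",
    }
    dataset.expression.to_tsv(paths["expression"])
    drivers = dataset.truth.genes_with_role("driver")
    paths["drivers"].write_text("".join(f"{g}\n" for g in drivers))
    dataset.edges.to_csv(paths["edges"], sep="\t", index=False)
    dataset.survival.to_csv(paths["survival"], sep="\t", index=False)
    dataset.truth.to_tsv(paths["truth"])
    paths["hubs"].write_text("".join(f"{g}\n" for g in dataset.hub_genes))
    return paths
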