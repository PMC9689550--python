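"""Driver-anchored gene selection by Gaussian mutual information.

Under a bivariate Gaussian model the mutual information between two
genes reduces to a ratio of covariance determinants,

    I(X, Y) = 1/2 * ln( C(X) * C(Y) / |C(X, Y)| )        [nats]

with C(X), C(Y) the sample variances and |C(X, Y)| the determinant of
the 2x2 joint covariance matrix.  This equals -1/2 * ln(1 - r^2) for the
sample Pearson correlation r, so MI is a monotone function of |r|: the
estimator ranks candidates by the strength of their (linear) association
with the best-matching driver gene.

Selection proceeds in four steps: preprocess (drop genes over 50%
missing, mean-impute the rest), score every candidate against every
driver keeping the maximum, fit a least-squares polynomial to the
descending MI-vs-rank curve, and cut the ranking where the fitted
derivative first flattens to the threshold alpha (default -5e-4 nats per
rank).  Candidates perfectly collinear with a driver have infinite MI;
they bypass the fit and are always selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .errors import ConfigurationError, DegenerateInputError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = -5e-4
DEFAULT_DEGREE = 3


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw: ExpressionMatrix, max_missing: float = 0.5
               ) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes with > ``max_missing`` missing fraction, mean-impute the rest.

    Returns the cleaned matrix and the list of dropped gene symbols.
    Raises if no gene survives.
    """
    if raw.n_genes == 0:
        raise DegenerateInputError("empty expression matrix")
    frac = raw.missing_fraction()
    dropped = list(frac.index[frac > max_missing])
    kept = raw.values.drop(index=dropped)
    if kept.shape[0] == 0:
        raise DegenerateInputError("no gene survives the missing-value filter")
    row_means = kept.mean(axis=1, skipna=True)
    imputed = kept.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    if dropped:
        logger.info("preprocess: dropped %d gene(s) over %.0f%% missing",
                    len(dropped), 100 * max_missing)
    return ExpressionMatrix(imputed), dropped


# ---------------------------------------------------------------------------
# pairwise Gaussian MI
# ---------------------------------------------------------------------------

def pairwise_mi(x: Sequence[float], y: Sequence[float]) -> float:
    """Gaussian mutual information of two expression rows, in nats.

    Computed as ``0.5 * ln(var(x)*var(y) / det(Cov2x2))`` with unbiased
    (N-1) covariances; symmetric in its arguments and invariant under
    affine maps of either row.  Perfect collinearity (singular joint
    covariance) returns ``+inf``; zero variance raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need at least 3 samples, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DegenerateInputError("missing values: preprocess first")
    cov = np.cov(x, y, ddof=1)
    vx, vy, cxy = cov[0, 0], cov[1, 1], cov[0, 1]
    if vx <= 0.0 or vy <= 0.0:
        raise DegenerateInputError("zero sample variance")
    det = vx * vy - cxy * cxy
    if det <= 0.0:
        return math.inf
    return 0.5 * math.log(vx * vy / det)


@dataclass(frozen=True)
class MIRecord:
    """One candidate gene's best score over the driver set."""

    gene: str
    best_driver: str
    mi: float  # nats; may be +inf for a collinear pair

    @property
    def collinear(self) -> bool:
        return math.isinf(self.mi)


def best_driver_mi(drivers: ExpressionMatrix, candidates: ExpressionMatrix
                   ) -> list[MIRecord]:
    """Score each candidate by its maximum MI over all driver genes.

    Both matrices must be preprocessed and share the same sample
    ordering.  Ties in the argmax are broken by driver-symbol
    lexicographic order; the returned list is sorted by MI descending
    (gene symbol ascending as a deterministic secondary key).
    """
    if drivers.samples != candidates.samples:
        raise ConfigurationError("sample ids of drivers and candidates differ")
    if drivers.n_genes == 0:
        raise ConfigurationError("empty driver matrix")
    driver_rows = [(g, drivers.row(g)) for g in sorted(drivers.genes)]
    records = []
    for gene in candidates.genes:
        y = candidates.row(gene)
        best_name, best_val = None, -math.inf
        for dname, drow in driver_rows:
            val = pairwise_mi(drow, y)
            if val > best_val:  # strict: first (lexicographic) driver wins ties
                best_name, best_val = dname, val
        records.append(MIRecord(gene=gene, best_driver=best_name, mi=best_val))
    return sorted(records, key=lambda r: (-r.mi, r.gene))


# ---------------------------------------------------------------------------
# decay-curve fit and derivative threshold
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Polynomial fit of the descending MI-vs-rank curve."""

    degree: int
    coefficients: np.ndarray  # power basis, ascending order
    r_squared: float
    n_points: int
    alpha: float = DEFAULT_ALPHA
    _poly: Polynomial = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        return self._poly(np.asarray(x, dtype=float))

    def derivative(self, x) -> np.ndarray:
        """Analytic dy/dx of the fitted polynomial at rank index x."""
        return self._poly.deriv()(np.asarray(x, dtype=float))


def fit_decay_curve(mi_values: Sequence[float], degree: int = DEFAULT_DEGREE,
                    alpha: float = DEFAULT_ALPHA) -> DecayFit:
    """Least-squares polynomial over (rank index, MI value).

    ``mi_values`` must be finite and sorted descending (infinite records
    are excluded beforehand; they rank first unconditionally).  The fit
    is performed in a scaled Chebyshev-stable domain internally; reported
    coefficients are in the plain power basis.
    """
    y = np.asarray(list(mi_values), dtype=float)
    if not np.isfinite(y).all():
        raise ConfigurationError("mi_values must be finite; drop +inf records first")
    if y.size < degree + 2:
        raise ConfigurationError(
            f"need at least degree+2 = {degree + 2} points, got {y.size}")
    x = np.arange(y.size, dtype=float)
    poly = Polynomial.fit(x, y, degree)
    resid = y - poly(x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return DecayFit(degree=degree,
                    coefficients=poly.convert().coef,
                    r_squared=min(1.0, r2),
                    n_points=y.size,
                    alpha=alpha,
                    _poly=poly)


def threshold_select(fit: DecayFit, n_values: int, alpha: float | None = None) -> int:
    """Rank cutoff: first index where the fitted derivative rises to >= alpha.

    Ranks strictly before the cutoff are selected.  Returns ``n_values``
    when the curve never flattens to alpha (select all) and 0 when it is
    already flat at rank 0 (select none).
    """
    alpha = fit.alpha if alpha is None else alpha
    if alpha >= 0:
        raise ConfigurationError(f"alpha must be negative, got {alpha!r}")
    if n_values <= 0:
        return 0
    deriv = fit.derivative(np.arange(n_values))
    flat = np.flatnonzero(deriv >= alpha)
    return int(flat[0]) if flat.size else int(n_values)


def relevant_gene_set(drivers: Iterable[str], selected: Iterable[str]) -> list[str]:
    """Union of the driver anchor set and the MI-selected genes, sorted."""
    return sorted(set(drivers) | set(selected))


# ---------------------------------------------------------------------------
# end-to-end selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Everything the selection stage produces."""

    records: list[MIRecord]
    fit: DecayFit
    cutoff: int          # rank cutoff among finite records
    n_collinear: int     # +inf records, always selected
    selected: list[str]  # candidate genes passing the threshold
    drivers: list[str]
    relevant: list[str]  # drivers union selected

    def table(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame({
            "gene": [r.gene for r in self.records],
            "best_driver": [r.best_driver for r in self.records],
            "mi_nats": [r.mi for r in self.records],
            "selected": [r.gene in sel for r in self.records],
        })


def select_relevant_genes(expression: ExpressionMatrix, driver_symbols: Sequence[str],
                          alpha: float = DEFAULT_ALPHA, degree: int = DEFAULT_DEGREE
                          ) -> SelectionResult:
    """Run the full driver-anchored selection on a preprocessed matrix.

    Driver symbols absent from the matrix are ignored (logged); the
    candidate set is every remaining gene.
    """
    present = [g for g in driver_symbols if g in expression.values.index]
    absent = sorted(set(driver_symbols) - set(present))
    if absent:
        logger.warning("selection: %d driver gene(s) absent from the matrix "
                       "(e.g. %s)", len(absent), absent[:5])
    if not present:
        raise ConfigurationError("no driver gene present in the expression matrix")
    candidates = [g for g in expression.genes if g not in set(present)]
    records = best_driver_mi(expression.subset(present),
                             expression.subset(candidates))
    finite = [r for r in records if not r.collinear]
    infinite = [r for r in records if r.collinear]
    fit = fit_decay_curve([r.mi for r in finite], degree=degree, alpha=alpha)
    cutoff = threshold_select(fit, len(finite))
    selected = [r.gene for r in infinite] + [r.gene for r in finite[:cutoff]]
    return SelectionResult(
        records=records,
        fit=fit,
        cutoff=cutoff,
        n_collinear=len(infinite),
        selected=selected,
        drivers=sorted(present),
        relevant=relevant_gene_set(present, selected),
    )
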