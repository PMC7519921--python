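"""Sparse partial least squares with keepX-style per-component selection.

PLS seeks latent components t = Xw maximizing covariance with a response y.
The sparse variant used here retains, per component h, only the keep_x[h]
predictors whose cross-covariance weight |w_j| is largest (hard
thresholding), zeroes the rest, and renormalizes — the "keepX" formulation
where sparsity is specified as a count of variables rather than a penalty.
With a univariate response the weight direction w = X^T y is exact (no inner
iteration is needed); deflation is regression-mode: both X and y are deflated
on each component's score, which makes successive scores orthogonal.

Genotype columns are centered and scaled to unit variance before fitting so
that rare variants are not drowned out by common ones; dosage variance grows
with MAF.  Missing dosages must be imputed first (see
:func:`impute_missing`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplsConfig:
    """Settings for a sparse-PLS fit.

    ``keep_x`` gives the number of variables retained per component (the
    selection strength); ``response_type`` chooses between binary population
    membership (coded -1/+1) and a continuous phenotype.  ``max_iter`` and
    ``tol`` are accepted for interface completeness; the univariate-response
    weight update is closed-form so they are not exercised.
    """

    n_components: int = 2
    keep_x: tuple[int, ...] = (400, 400)
    response_type: str = "binary_population"
    max_iter: int = 100
    tol: float = 1e-9
    scale: bool = True

    def validate(self, p: int) -> None:
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if len(self.keep_x) != self.n_components:
            raise ConfigurationError("len(keep_x) must equal n_components")
        for k in self.keep_x:
            if not (1 <= k <= p):
                raise ConfigurationError(
                    f"keep_x entries must lie in [1, {p}], got {k}"
                )
        if self.response_type not in ("binary_population", "continuous_phenotype"):
            raise ConfigurationError(
                f"unknown response_type: {self.response_type!r}"
            )


@dataclass
class SplsFit:
    """Result of a sparse-PLS fit.

    ``loadings`` is (variants x components) with exactly keep_x[h] nonzeros
    per column, each column unit-norm with its largest-|entry| coordinate
    positive; ``scores`` is (samples x components), each column the deflated
    predictor matrix times its loading.  ``residual_norms`` records the
    Frobenius norm of the deflated X after each component.
    """

    loadings: np.ndarray
    scores: np.ndarray
    variant_ids: list
    config: SplsConfig = field(repr=False, default=None)
    residual_norms: list[float] = field(default_factory=list)
    n_ties: int = 0


def impute_missing(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-variant mean over called samples.

    Fully-missing variants are dropped (count logged).  The returned matrix
    holds float dosages (imputed means are fractional) in the same container
    contract as the input.
    """
    d = gm.dosages.astype(float)
    obs = gm.dosages != MISSING
    called = obs.sum(axis=1)
    keep = called > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("impute_missing: dropped %d fully-missing variants", n_dropped)
    d = d[keep]
    obs = obs[keep]
    means = np.where(obs, d, 0.0).sum(axis=1) / obs.sum(axis=1)
    d = np.where(obs, d, means[:, None])
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.dosages = d  # float matrix; bypasses the int8 coercion deliberately
    out.variants = gm.variants.loc[keep].reset_index(drop=True)
    out.samples = list(gm.samples)
    return out


def encode_response(values: np.ndarray | pd.Series, response_type: str) -> np.ndarray:
    """Map a response to the numeric vector the fit consumes."""
    arr = np.asarray(values)
    if response_type == "binary_population":
        labels = list(dict.fromkeys(arr))
        if len(labels) != 2:
            raise ValidationError(
                f"binary response needs exactly 2 labels, got {len(labels)}"
            )
        return np.where(arr == labels[0], -1.0, 1.0)
    return arr.astype(float)


def fit_spls(
    gm: GenotypeMatrix,
    response: np.ndarray | pd.Series,
    config: SplsConfig,
) -> SplsFit:
    """Fit sparse PLS of a per-sample response on the genotype matrix.

    The predictor matrix is samples x variants (the transpose of the stored
    dosage layout), columns centered and, by default, unit-variance scaled
    (zero-variance columns are left unscaled; they carry no signal).  Per
    component: w = X^T y restricted to its keep_x largest-|w| entries and
    renormalized; t = Xw; X and y deflated on t.  Ties in |w| at the keepX
    boundary are broken by variant index order and counted.
    """
    X = np.asarray(gm.dosages, dtype=float).T  # samples x variants
    n, p = X.shape
    config.validate(p)
    if np.any(gm.dosages == MISSING):
        raise ValidationError("missing dosages present: impute first")
    y = encode_response(response, config.response_type)
    if y.shape[0] != n:
        raise ValidationError("response length != number of samples")
    if np.allclose(y, y[0]):
        raise ValidationError("constant response")

    X = X - X.mean(axis=0)
    if config.scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    y = y - y.mean()

    loadings = np.zeros((p, config.n_components))
    scores = np.zeros((n, config.n_components))
    residual_norms: list[float] = []
    n_ties = 0

    for h in range(config.n_components):
        w = X.T @ y
        k = config.keep_x[h]
        order = np.lexsort((np.arange(p), -np.abs(w)))  # |w| desc, index asc
        kept = order[:k]
        boundary = np.abs(w[order[k - 1]])
        n_ties += int(max(0, (np.abs(w) == boundary).sum()
                          - (np.abs(w[kept]) == boundary).sum()))
        w_sparse = np.zeros(p)
        w_sparse[kept] = w[kept]
        norm = np.linalg.norm(w_sparse)
        if norm == 0:
            raise ValidationError(
                f"component {h}: zero cross-covariance (deflated response "
                "orthogonal to all predictors)"
            )
        w_sparse /= norm
        # sign convention: largest-|entry| coordinate positive
        pivot = np.lexsort((np.arange(p), -np.abs(w_sparse)))[0]
        if w_sparse[pivot] < 0:
            w_sparse = -w_sparse

        t = X @ w_sparse
        tt = float(t @ t)
        if tt == 0:
            raise ValidationError(f"component {h}: degenerate zero score")
        X = X - np.outer(t, (t @ X) / tt)
        y = y - t * (float(t @ y) / tt)

        loadings[:, h] = w_sparse
        scores[:, h] = t
        residual_norms.append(float(np.linalg.norm(X)))

    if n_ties:
        logger.info("fit_spls: %d |w| ties at keepX boundaries", n_ties)
    return SplsFit(
        loadings, scores, list(gm.variants["id"]), config, residual_norms, n_ties
    )


def selected_variants(fit: SplsFit, component: int | str = "all") -> list:
    """Variants with nonzero loading, ordered by |loading| descending.

    ``component`` is a 0-based component index or ``"all"`` for the union
    across components (ranked by each variant's largest |loading|).  Ties are
    broken by variant index order, so the result is deterministic given the
    fit.
    """
    p, ncomp = fit.loadings.shape
    if component == "all":
        mag = np.abs(fit.loadings).max(axis=1)
    else:
        if not (0 <= int(component) < ncomp):
            raise ConfigurationError(f"component out of range: {component}")
        mag = np.abs(fit.loadings[:, int(component)])
    nz = np.flatnonzero(mag > 0)
    order = nz[np.lexsort((nz, -mag[nz]))]
    return [fit.variant_ids[i] for i in order]


def selection_table(fit: SplsFit) -> pd.DataFrame:
    """Long-form (variant, component, loading) table of nonzero loadings."""
    rows = []
    for h in range(fit.loadings.shape[1]):
        nz = np.flatnonzero(fit.loadings[:, h])
        order = nz[np.argsort(-np.abs(fit.loadings[nz, h]), kind="stable")]
        for i in order:
            rows.append(
                {
                    "variant_id": fit.variant_ids[i],
                    "component": h + 1,
                    "loading": fit.loadings[i, h],
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "component", "loading"])
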