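"""Empirical-Bayes location/scale batch adjustment for merging cohorts.

Parametric model: after per-gene standardization, the batch effect on gene g
in batch b is additive (gamma_gb, normal prior across genes) and
multiplicative (delta2_gb, inverse-gamma prior across genes). Priors are
estimated across genes by the method of moments and the posterior
(gamma*, delta2*) solved by the usual fixed-point iteration. No covariates.

After adjustment each gene is recentred to its pre-correction grand mean, so
the overall per-gene level is preserved exactly; EB shrinkage otherwise
leaves a small residual offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix

logger = logging.getLogger("ici_landscape")


@dataclass
class BatchModel:
    """Fitted batch parameters, on the scale of the input (log) data.

    gamma_hat / delta_hat are the raw per-(gene, batch) location/scale
    estimates; gamma_star / delta_star the EB-shrunk versions actually used.
    gamma tables are stored in standardized units; ``gamma_hat_data`` gives
    the location estimates back on the data scale.
    """

    batches: list
    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_hat: pd.DataFrame  # genes x batches, standardized units
    delta_hat: pd.DataFrame  # genes x batches, variances, standardized units
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    gamma_prior: dict  # per batch: mean, var of the normal prior on gamma
    delta_prior: dict  # per batch: a, b of the inverse-gamma prior on delta2
    skipped_genes: list

    @property
    def gamma_hat_data(self) -> pd.DataFrame:
        return self.gamma_hat.mul(np.sqrt(self.pooled_var), axis=0)


def _invgamma_moments(delta2: np.ndarray) -> tuple[float, float]:
    """Inverse-gamma (a, b) from the sample mean/variance of delta2 values."""
    m = float(delta2.mean())
    v = float(delta2.var(ddof=1)) if delta2.size > 1 else 0.0
    if v <= 0:
        return np.inf, np.inf
    a = (2.0 * v + m**2) / v
    b = (m * v + m**3) / v
    return a, b


def _posterior_iteration(
    Zb: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard ComBat fixed point for (gamma*, delta2*) in one batch."""
    n = Zb.shape[1]
    g_star, d_star = g_hat.copy(), d_hat.copy()
    if not np.isfinite(a) or not np.isfinite(b) or t2 <= 0:
        # Degenerate priors (e.g. all estimates identical): no shrinkage.
        return g_star, d_star
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)
        ssq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_star).max(initial=0.0),
            np.abs(d_new - d_star).max(initial=0.0),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def combat_adjust(
    expr: ExpressionMatrix, batch
) -> tuple[ExpressionMatrix, BatchModel]:
    """Fit and apply the EB batch adjustment; returns corrected data + model.

    ``expr`` must be on the log2 scale; ``batch`` gives one label per
    sample. A single batch is returned unchanged. Genes with zero pooled
    variance are passed through unadjusted with a warning.
    """
    if not expr.log2_scale:
        raise ValueError("combat_adjust expects log2-scale expression")
    batch = pd.Series(np.asarray(batch), index=expr.sample_ids)
    levels = sorted(batch.unique().tolist())
    counts = batch.value_counts()
    if len(levels) == 1:
        model = BatchModel(
            batches=levels,
            grand_mean=expr.data.mean(axis=1),
            pooled_var=expr.data.var(axis=1, ddof=0),
            gamma_hat=pd.DataFrame(0.0, index=expr.gene_ids, columns=levels),
            delta_hat=pd.DataFrame(1.0, index=expr.gene_ids, columns=levels),
            gamma_star=pd.DataFrame(0.0, index=expr.gene_ids, columns=levels),
            delta_star=pd.DataFrame(1.0, index=expr.gene_ids, columns=levels),
            gamma_prior={levels[0]: (0.0, 0.0)},
            delta_prior={levels[0]: (np.inf, np.inf)},
            skipped_genes=[],
        )
        return ExpressionMatrix(expr.data.copy(), log2_scale=True), model
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"each batch needs >=2 samples; too small: {small}")

    X = expr.data.to_numpy(dtype=float)
    genes, samples = expr.gene_ids, expr.sample_ids
    n = X.shape[1]
    masks = {b: (batch == b).to_numpy() for b in levels}
    n_b = {b: int(masks[b].sum()) for b in levels}

    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([n_b[b] / n for b in levels])
    grand = batch_means @ weights  # weighted grand mean per gene
    resid = X - np.column_stack(
        [batch_means[:, levels.index(batch.iloc[j])] for j in range(n)]
    )
    var_pooled = (resid**2).mean(axis=1)

    ok = var_pooled > 0
    skipped = [g for g, keep in zip(genes, ok) if not keep]
    if skipped:
        logger.warning("%d constant genes passed through unadjusted", len(skipped))
    sd = np.sqrt(np.where(ok, var_pooled, 1.0))
    Z = (X - grand[:, None]) / sd[:, None]

    gamma_hat = pd.DataFrame(index=genes, columns=levels, dtype=float)
    delta_hat = pd.DataFrame(index=genes, columns=levels, dtype=float)
    gamma_star = pd.DataFrame(index=genes, columns=levels, dtype=float)
    delta_star = pd.DataFrame(index=genes, columns=levels, dtype=float)
    gamma_prior, delta_prior = {}, {}

    Z_adj = Z.copy()
    for b in levels:
        Zb = Z[:, masks[b]]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat[ok].mean()), float(g_hat[ok].var(ddof=1))
        a_pr, b_pr = _invgamma_moments(d_hat[ok])
        g_star, d_star = _posterior_iteration(
            Zb[ok], g_hat[ok], d_hat[ok], g_bar, t2, a_pr, b_pr
        )
        g_full = np.zeros(len(genes))
        d_full = np.ones(len(genes))
        g_full[ok], d_full[ok] = g_star, d_star
        Z_adj[np.ix_(ok, masks[b])] = (Zb[ok] - g_full[ok, None]) / np.sqrt(
            d_full[ok, None]
        )
        gamma_hat[b], delta_hat[b] = g_hat, d_hat
        gamma_star[b], delta_star[b] = g_full, d_full
        gamma_prior[b], delta_prior[b] = (g_bar, t2), (a_pr, b_pr)

    X_adj = Z_adj * sd[:, None] + grand[:, None]
    X_adj[~ok] = X[~ok]
    # Exact grand-mean preservation: recentre each gene to its input mean.
    X_adj[ok] += (X[ok].mean(axis=1) - X_adj[ok].mean(axis=1))[:, None]

    model = BatchModel(
        batches=levels,
        grand_mean=pd.Series(grand, index=genes),
        pooled_var=pd.Series(var_pooled, index=genes),
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_prior=gamma_prior,
        delta_prior=delta_prior,
        skipped_genes=skipped,
    )
    adjusted = ExpressionMatrix(
        pd.DataFrame(X_adj, index=genes, columns=samples), log2_scale=True
    )
    return adjusted, model


def apply_batch_model(
    expr: ExpressionMatrix, batch, model: BatchModel
) -> ExpressionMatrix:
    """Correct a new matrix with a previously fitted :class:`BatchModel`.

    Useful for held-out replicates measured under the same batch structure;
    genes and batch levels must match the fitted model.
    """
    if not expr.log2_scale:
        raise ValueError("apply_batch_model expects log2-scale expression")
    batch = pd.Series(np.asarray(batch), index=expr.sample_ids)
    X = expr.data.to_numpy(dtype=float)
    genes = expr.gene_ids
    if genes != list(model.grand_mean.index):
        raise ValueError("gene ids differ from the fitted model")
    grand = model.grand_mean.to_numpy()
    var_pooled = model.pooled_var.to_numpy()
    ok = var_pooled > 0
    sd = np.sqrt(np.where(ok, var_pooled, 1.0))
    Z = (X - grand[:, None]) / sd[:, None]
    Z_adj = Z.copy()
    for b in model.batches:
        mask = (batch == b).to_numpy()
        if not mask.any():
            continue
        g = model.gamma_star[b].to_numpy()
        d = model.delta_star[b].to_numpy()
        Z_adj[np.ix_(ok, mask)] = (Z[np.ix_(ok, mask)] - g[ok, None]) / np.sqrt(
            d[ok, None]
        )
    X_adj = Z_adj * sd[:, None] + grand[:, None]
    X_adj[~ok] = X[~ok]
    return ExpressionMatrix(
        pd.DataFrame(X_adj, index=genes, columns=expr.sample_ids), log2_scale=True
    )
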