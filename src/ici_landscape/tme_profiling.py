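"""Per-sample characterization of the tumor immune microenvironment.

Three views of the same expression matrix: rank-based single-sample gene-set
enrichment (ssGSEA) for immune signatures, stromal/immune scores whose sum
tracks tumor purity, and reference-based leukocyte deconvolution by
nu-support-vector regression with a permutation p-value per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("ici_landscape")


@dataclass
class ScoreMatrix:
    """samples x signatures enrichment scores."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool


@dataclass
class CellFractionMatrix:
    """samples x cell-type fractions with deconvolution diagnostics.

    Rows sum to one; per-sample permutation p-value, correlation between the
    mixture and its reconstruction, reconstruction RMSE and the nu kept.
    ``filter_significant`` applies the conventional p < 0.05 post-filter.
    """

    fractions: pd.DataFrame
    p_value: pd.Series
    correlation: pd.Series
    rmse: pd.Series
    nu: pd.Series
    invalid: pd.Series  # all-zero raw coefficient rows

    def filter_significant(self, alpha: float = 0.05) -> pd.DataFrame:
        keep = (self.p_value < alpha) & ~self.invalid
        return self.fractions.loc[keep]


def _rank_weights(n_genes: int, alpha: float) -> np.ndarray:
    """Weight of the gene at descending-rank position i (0-based): rank^alpha.

    The top-ranked gene carries rank value n, the bottom 1, so weights are a
    function of ranks only — any monotone transform of a sample's expression
    leaves the scores unchanged.
    """
    return (np.arange(n_genes, 0, -1, dtype=float)) ** alpha


def _ssgsea_one(order: np.ndarray, in_set: np.ndarray, weights: np.ndarray) -> float:
    """Running-sum score for one sample given its descending gene order."""
    hit = in_set[order]
    w = weights * hit
    denom_in = w.sum()
    n_out = (~hit).sum()
    if denom_in == 0 or n_out == 0:
        return np.nan
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~hit) / n_out
    return float((p_in - p_out).sum())


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Per-sample enrichment score for each gene set.

    Genes are ranked by expression (descending, ties broken by gene id for
    determinism); the score is the sum over the ranked list of the running
    in-set weighted mass minus the running out-of-set mass, with in-set
    weights rank^alpha (normalized). ``normalize`` divides the whole matrix
    by its (max - min), the usual cross-sample normalization.

    A set with no overlap with the matrix yields an NA column with a
    warning; a set covering the full gene universe is an error (empty
    complement).
    """
    genes = np.array(expr.gene_ids)
    X = expr.data.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    weights = _rank_weights(n_genes, alpha)

    memberships = {}
    for name, gset in sets.items():
        member = np.isin(genes, list(gset))
        if member.all():
            raise ValueError(f"gene set {name!r} equals the full gene universe")
        if not member.any():
            logger.warning("gene set %r has no overlap with the matrix", name)
        memberships[name] = member

    # Deterministic descending order: sort by (-expression, gene id).
    gene_rank_tiebreak = np.argsort(genes, kind="stable")
    out = np.full((n_samples, len(memberships)), np.nan)
    for j in range(n_samples):
        x = X[:, j]
        order = gene_rank_tiebreak[np.argsort(-x[gene_rank_tiebreak], kind="stable")]
        for k, (name, member) in enumerate(memberships.items()):
            if member.any():
                out[j, k] = _ssgsea_one(order, member, weights)

    scores = pd.DataFrame(out, index=expr.sample_ids, columns=list(memberships))
    if normalize:
        finite = out[np.isfinite(out)]
        span = finite.max() - finite.min() if finite.size else 0.0
        if span > 0:
            scores = scores / span
    return ScoreMatrix(scores, alpha=alpha, normalized=normalize)


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: set,
    immune_set: set,
    alpha: float = 0.25,
    purity_transform: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Stromal/immune enrichment and their sum; optional purity transform.

    The stromal and immune scores are ssGSEA scores on the two sets
    (unnormalized, so the definitional identity estimate = stromal + immune
    is exact); tumor purity = cos(a + b*estimate) only when the caller
    supplies the published, platform-specific (a, b) constants.
    """
    sets = GeneSetCollection({"stromal": set(stromal_set), "immune": set(immune_set)})
    sm = ssgsea_scores(expr, sets, alpha=alpha, normalize=False)
    table = pd.DataFrame(
        {
            "stromal_score": sm.scores["stromal"],
            "immune_score": sm.scores["immune"],
        }
    )
    table["estimate_score"] = table["stromal_score"] + table["immune_score"]
    if purity_transform is not None:
        a, b = purity_transform
        table["tumor_purity"] = np.clip(
            np.cos(a + b * table["estimate_score"]), 0.0, 1.0
        )
    return table


def _fit_sample(
    y: np.ndarray, S: np.ndarray, nu_grid
) -> tuple[np.ndarray, float, float, float]:
    """nu-SVR fits over the grid; keep the nu minimizing reconstruction RMSE.

    Returns (raw coefficients clamped at 0, rmse, correlation, nu).
    """
    best = None
    for nu in nu_grid:
        svr = NuSVR(kernel="linear", nu=nu, C=1.0)
        svr.fit(S, y)
        coef = np.asarray(svr.coef_).ravel()
        coef = np.clip(coef, 0.0, None)
        recon = S @ coef
        rmse = float(np.sqrt(np.mean((y - recon) ** 2)))
        if best is None or rmse < best[1]:
            if coef.sum() > 0 and np.std(recon) > 0:
                corr = float(np.corrcoef(y, recon)[0, 1])
            else:
                corr = 0.0
            best = (coef, rmse, corr, nu)
    return best


def deconvolve_fractions(
    expr: ExpressionMatrix,
    signature_matrix: pd.DataFrame,
    nu_grid=(0.25, 0.5, 0.75),
    n_perm: int = 100,
    seed: int = 0,
) -> CellFractionMatrix:
    """Reference-based leukocyte fractions by linear nu-SVR.

    Mixture and signature are z-scored over the shared signature genes; for
    each sample the nu in ``nu_grid`` minimizing reconstruction RMSE is
    kept; negative coefficients are clamped to zero and the rest
    renormalized to sum to one. The permutation p-value is the fraction of
    ``n_perm`` random mixtures (values resampled from the full expression
    matrix) achieving a reconstruction correlation at least as high as the
    observed one.
    """
    common = [g for g in signature_matrix.index if g in expr.data.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 signature genes found in the expression matrix")
    logger.info(
        "deconvolution uses %d/%d signature genes", len(common), len(signature_matrix)
    )
    S_raw = signature_matrix.loc[common].to_numpy(dtype=float)
    Y = expr.data.loc[common].to_numpy(dtype=float)
    S = (S_raw - S_raw.mean()) / S_raw.std()

    n_samples = Y.shape[1]
    k = S.shape[1]
    fractions = np.zeros((n_samples, k))
    rmse = np.zeros(n_samples)
    corr = np.zeros(n_samples)
    nus = np.zeros(n_samples)
    invalid = np.zeros(n_samples, dtype=bool)

    for j in range(n_samples):
        y = Y[:, j]
        if np.allclose(y, 0):
            raise ValueError(f"all-zero mixture for sample {expr.sample_ids[j]}")
        y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        coef, r, c, nu = _fit_sample(y, S, nu_grid)
        total = coef.sum()
        if total <= 0:
            invalid[j] = True
        else:
            fractions[j] = coef / total
        rmse[j], corr[j], nus[j] = r, c, nu

    # Shared null: random mixtures drawn from the pooled expression values.
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pool = expr.data.to_numpy(dtype=float).ravel()
        null_corr = np.empty(n_perm)
        for p in range(n_perm):
            y = pool[rng.integers(0, pool.size, size=len(common))]
            if y.std() == 0:
                null_corr[p] = 0.0
                continue
            y = (y - y.mean()) / y.std()
            _, _, c, _ = _fit_sample(y, S, nu_grid)
            null_corr[p] = c
        pvals = np.array([(null_corr >= c).mean() for c in corr])
    else:
        pvals = np.full(n_samples, np.nan)

    idx = expr.sample_ids
    return CellFractionMatrix(
        fractions=pd.DataFrame(fractions, index=idx, columns=signature_matrix.columns),
        p_value=pd.Series(pvals, index=idx, name="p_value"),
        correlation=pd.Series(corr, index=idx, name="correlation"),
        rmse=pd.Series(rmse, index=idx, name="rmse"),
        nu=pd.Series(nus, index=idx, name="nu"),
        invalid=pd.Series(invalid, index=idx, name="invalid"),
    )
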