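"""From infiltration patterns to the per-sample ICI score.

Pipeline: moderated one-way differential test across the pattern clusters
(empirical-Bayes variance shrinkage); DEG filtering by adjusted p and max
pairwise fold change; Ward clustering of samples on the DEG profile (two
gene clusters); gene partition into signatures A/B by the sign of the
correlation with the gene-cluster label; Boruta all-relevant reduction of
each signature; and finally ICI score = PC1(signature A) - PC1(signature B)
per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix

logger = logging.getLogger("ici_landscape")


@dataclass
class DEGTable:
    """Per-gene moderated one-way test results across clusters."""

    table: pd.DataFrame  # group means (linear), max_fold_change, F, p, adj_p, flagged
    d0: float  # prior degrees of freedom of the variance prior
    s0_sq: float  # prior variance


@dataclass
class SignaturePartition:
    signature_A: list  # genes positively correlated with the gene-cluster label
    signature_B: list
    correlation: pd.Series
    selected_A: list | None = None  # post-Boruta subsets
    selected_B: list | None = None


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        return np.inf
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    if f(lo) < 0:  # y above trigamma(lo): no solution this side
        return lo
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-12, maxiter=200)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior on residual variances.

    Works on e_g = log s2_g - digamma(df/2) + log(df/2): its mean estimates
    log s0^2 and its excess variance over trigamma(df/2) estimates
    trigamma(d0/2). If the observed spread is at or below the sampling
    spread, d0 = inf (complete shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_de_test(
    expr: ExpressionMatrix, labels: pd.Series, d0_override: float | None = None
) -> DEGTable:
    """Moderated one-way F test per gene across >=2 clusters.

    Residual variances are shrunk toward the moment-matched prior,
    s2_tilde = (d0*s0^2 + df*s2)/(d0 + df); the moderated F is
    MS_between/s2_tilde on (k-1, d0+df) degrees of freedom, BH-adjusted over
    the non-degenerate genes. ``d0_override=0`` gives the ordinary one-way F.
    Genes constant within and across groups are flagged and excluded from
    the BH family. Fold change is the max pairwise ratio of group means on
    the linear scale.
    """
    if not expr.log2_scale:
        raise ValueError("moderated_de_test expects log2-scale expression")
    labels = labels.loc[expr.sample_ids]
    groups = sorted(labels.unique().tolist())
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs >=2 samples")

    X = expr.data.to_numpy(dtype=float)
    n = X.shape[1]
    k = len(groups)
    df_resid = n - k

    means = np.column_stack([X[:, (labels == g).to_numpy()].mean(axis=1) for g in groups])
    ss_within = np.zeros(X.shape[0])
    for gi, g in enumerate(groups):
        mask = (labels == g).to_numpy()
        ss_within += ((X[:, mask] - means[:, gi : gi + 1]) ** 2).sum(axis=1)
    s2 = ss_within / df_resid
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    for gi, g in enumerate(groups):
        ss_between += counts[g] * (means[:, gi] - grand) ** 2
    ms_between = ss_between / (k - 1)

    flagged = (s2 <= 0) & (ss_between <= 1e-300)
    ok = ~flagged

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[ok])) if ok.any() else 1.0
    else:
        d0, s0_sq = fit_variance_prior(s2[ok], df_resid)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(s2_tilde > 0, ms_between / s2_tilde, np.inf)
    dfd = df_total if np.isfinite(df_total) else 1e9
    p = stats.f.sf(F, k - 1, dfd)
    p[flagged] = np.nan

    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]

    lin_means = 2.0**means  # group means back on the linear scale
    hi = lin_means.max(axis=1)
    lo = np.maximum(lin_means.min(axis=1), 1e-12)
    fc = hi / lo

    table = pd.DataFrame(
        {
            **{f"mean_{g}": lin_means[:, gi] for gi, g in enumerate(groups)},
            "max_fold_change": fc,
            "F": F,
            "p": p,
            "adj_p": adj,
            "flagged": flagged,
        },
        index=expr.gene_ids,
    )
    return DEGTable(table=table, d0=d0, s0_sq=s0_sq)


def filter_degs(deg: DEGTable, alpha: float = 0.05, fc: float = 1.5) -> list:
    """Genes with adjusted p < alpha AND max pairwise fold change > fc (strict)."""
    t = deg.table
    keep = (t["adj_p"] < alpha) & (t["max_fold_change"] > fc) & ~t["flagged"]
    return t.index[keep.fillna(False)].tolist()


def gene_cluster_samples(
    expr: ExpressionMatrix,
    degs,
    k: int = 2,
    immune_score: pd.Series | None = None,
) -> pd.Series:
    """Ward clustering of samples on z-scored DEG expression, cut at k.

    Labels are 'A'/'B' (k=2); when an immune score is supplied, cluster 'B'
    is the one with the higher mean immune score (deterministic
    orientation), otherwise labels follow discovery order.
    """
    sub = expr.data.loc[[g for g in degs if g in expr.data.index]]
    if len(sub) < 2:
        raise ValueError("need at least two DEGs to cluster samples")
    if k > sub.shape[1]:
        raise ValueError("k exceeds the number of samples")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).all() or np.allclose(X, X[:, :1]):
        raise ValueError("all samples identical on the DEG set; nothing to cluster")
    Xz = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    Z = linkage(Xz.T, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=expr.sample_ids)

    names = [chr(ord("A") + i) for i in range(k)]
    if immune_score is not None and k == 2:
        mean_by = {c: immune_score.loc[labels.index[labels == c]].mean() for c in (1, 2)}
        order = sorted(mean_by, key=lambda c: mean_by[c])  # low -> 'A', high -> 'B'
        mapping = {order[0]: "A", order[1]: "B"}
    else:
        seen = list(dict.fromkeys(raw))
        mapping = {c: names[i] for i, c in enumerate(seen)}
    return labels.map(mapping).rename("gene_cluster")


def partition_signature(
    expr: ExpressionMatrix, degs, sample_labels: pd.Series
) -> SignaturePartition:
    """Split DEGs by the sign of their correlation with the cluster label.

    The label is encoded A -> 0, B -> 1; r > 0 puts the gene in signature A,
    r < 0 in signature B, r = 0 (or undefined for constant genes) in A with
    a warning.
    """
    values = sorted(sample_labels.unique().tolist())
    if len(values) != 2:
        raise ValueError("partition_signature needs exactly two label values")
    y = (sample_labels.loc[expr.sample_ids] == values[1]).astype(float).to_numpy()
    sub = expr.data.loc[[g for g in degs if g in expr.data.index]]
    X = sub.to_numpy(dtype=float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc @ yc) / denom, np.nan)
    n_flat = int(np.isnan(r).sum() + (r == 0).sum())
    if n_flat:
        logger.warning("%d genes with zero/undefined correlation assigned to A", n_flat)
    corr = pd.Series(r, index=sub.index, name="correlation")
    sig_a = sub.index[(np.nan_to_num(r) >= 0)].tolist()
    sig_b = sub.index[np.nan_to_num(r) < 0].tolist()
    return SignaturePartition(signature_A=sig_a, signature_B=sig_b, correlation=corr)


def boruta_select(
    features: pd.DataFrame,
    response: pd.Series,
    max_iter: int = 100,
    alpha: float = 0.01,
    n_trees: int = 500,
    seed: int = 0,
) -> list:
    """All-relevant feature selection against shuffled shadow features.

    Each iteration appends a shuffled copy of every undecided/confirmed
    feature, fits a random forest (impurity importance), and counts a "hit"
    for a feature whose importance beats the best shadow. Features are
    confirmed/rejected by a two-sided binomial test on the hit count at
    ``alpha``; undecided features after ``max_iter`` iterations are resolved
    by comparing their median importance to the median best-shadow
    importance.
    """
    y = response.loc[features.index]
    if y.nunique() < 2:
        raise ValueError("response has a single class")
    if y.value_counts().min() < 5:
        raise ValueError("need >=5 samples per class")
    rng = np.random.default_rng(seed)
    cols = list(features.columns)
    status = {c: "tentative" for c in cols}
    hits = {c: 0 for c in cols}
    trials = 0
    history: dict[str, list[float]] = {c: [] for c in cols}
    shadow_history: list[float] = []
    min_rounds = 5

    y_codes = pd.factorize(y)[0]
    for it in range(max_iter):
        active = [c for c in cols if status[c] != "rejected"]
        if not any(status[c] == "tentative" for c in cols):
            break
        X = features[active].to_numpy(dtype=float)
        # Shadows are shuffled copies of ALL original features, not just the
        # undecided ones: a shrinking shadow pool lets noise features that
        # are spuriously correlated in-sample outrun the max-shadow bar.
        shadow = features[cols].to_numpy(dtype=float).copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        Xfull = np.hstack([X, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xfull, y_codes)
        imp = rf.feature_importances_
        real, sh = imp[: len(active)], imp[len(active) :]
        best_shadow = sh.max()
        shadow_history.append(float(best_shadow))
        trials += 1
        for c, v in zip(active, real):
            history[c].append(float(v))
            if status[c] == "tentative" and v > best_shadow:
                hits[c] += 1
        if trials >= min_rounds:
            # Bonferroni across features (the canonical default): each
            # feature is tested every round, so unadjusted thresholds
            # confirm spuriously in-sample-correlated noise.
            threshold = alpha / len(cols)
            for c in cols:
                if status[c] != "tentative":
                    continue
                res = stats.binomtest(hits[c], trials, 0.5)
                if res.pvalue < threshold:
                    status[c] = "confirmed" if hits[c] > trials / 2 else "rejected"

    med_shadow = float(np.median(shadow_history)) if shadow_history else 0.0
    for c in cols:
        if status[c] == "tentative":
            med = float(np.median(history[c])) if history[c] else 0.0
            status[c] = "confirmed" if med > med_shadow else "rejected"
    return [c for c in cols if status[c] == "confirmed"]


def pc1_score(expr: ExpressionMatrix, genes) -> pd.Series:
    """Each sample's coordinate on PC1 of the z-scored gene set.

    Genes are z-scored across samples; PCA treats samples as observations.
    The PC1 sign is fixed so the score correlates positively with each
    sample's mean z-expression over the set (reproducible across linear
    algebra backends). Zero-variance genes are dropped with a warning.
    """
    sub = expr.data.loc[[g for g in genes if g in expr.data.index]]
    if len(sub) < 2:
        raise ValueError("pc1_score needs at least two genes")
    if sub.shape[1] < 2:
        raise ValueError("pc1_score needs at least two samples")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance genes from PCA", int((sd == 0).sum()))
        X = X[sd > 0]
        if X.shape[0] < 2:
            raise ValueError("fewer than two variable genes for PCA")
        sd = sd[sd > 0]
    Xz = ((X - X.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x genes
    Xz = Xz - Xz.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Xz, full_matrices=False)
    scores = Xz @ vt[0]
    mean_z = Xz.mean(axis=1)
    if np.std(mean_z) > 0 and np.corrcoef(scores, mean_z)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=sub.columns, name="pc1")


def ici_score(
    expr: ExpressionMatrix, partition: SignaturePartition, use_selected: bool = True
) -> pd.DataFrame:
    """Per-sample ICI score = PC1(signature A) - PC1(signature B).

    Uses the post-Boruta subsets when present (``use_selected``); the group
    label column is left unset here — dichotomization belongs to
    survival_analysis.optimal_cutpoint.
    """
    genes_a = partition.selected_A if (use_selected and partition.selected_A) else partition.signature_A
    genes_b = partition.selected_B if (use_selected and partition.selected_B) else partition.signature_B
    if not genes_a or not genes_b:
        raise ValueError("both signatures must be non-empty")
    pc1_a = pc1_score(expr, genes_a)
    pc1_b = pc1_score(expr, genes_b)
    out = pd.DataFrame({"pc1_A": pc1_a, "pc1_B": pc1_b})
    out["ici_score"] = out["pc1_A"] - out["pc1_B"]
    return out


def dichotomize_scores(
    scores: pd.DataFrame, cutpoint: float
) -> pd.DataFrame:
    """Attach high/low group labels at a chosen cutpoint."""
    out = scores.copy()
    out["group"] = np.where(out["ici_score"] > cutpoint, "high", "low")
    out["cutpoint"] = cutpoint
    return out


def derive_ici_signature(
    expr: ExpressionMatrix,
    cluster_labels: pd.Series,
    immune_score: pd.Series | None = None,
    alpha: float = 0.05,
    fc: float = 1.5,
    boruta_max_iter: int = 100,
    boruta_alpha: float = 0.01,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[DEGTable, list, pd.Series, SignaturePartition, pd.DataFrame]:
    """The full DEG -> gene clusters -> partition -> Boruta -> score chain."""
    deg = moderated_de_test(expr, cluster_labels)
    degs = filter_degs(deg, alpha=alpha, fc=fc)
    if len(degs) < 2:
        raise ValueError(f"only {len(degs)} DEGs pass the filter; cannot continue")
    gclust = gene_cluster_samples(expr, degs, k=2, immune_score=immune_score)
    partition = partition_signature(expr, degs, gclust)
    if not partition.signature_A or not partition.signature_B:
        raise ValueError("one of the signatures is empty before reduction")
    feats = expr.data.loc[degs].T
    ss = np.random.SeedSequence(seed)
    s_a, s_b = [int(s) % (2**31 - 1) for s in ss.generate_state(2)]
    sel_a = boruta_select(
        feats[partition.signature_A], gclust, max_iter=boruta_max_iter,
        alpha=boruta_alpha, n_trees=n_trees, seed=s_a,
    )
    sel_b = boruta_select(
        feats[partition.signature_B], gclust, max_iter=boruta_max_iter,
        alpha=boruta_alpha, n_trees=n_trees, seed=s_b,
    )
    # An all-rejected signature would make the score undefined; fall back to
    # the full signature in that case (logged).
    if not sel_a:
        logger.warning("Boruta rejected all of signature A; keeping the full set")
        sel_a = partition.signature_A
    if not sel_b:
        logger.warning("Boruta rejected all of signature B; keeping the full set")
        sel_b = partition.signature_B
    partition.selected_A, partition.selected_B = sel_a, sel_b
    scores = ici_score(expr, partition)
    return deg, degs, gclust, partition, scores
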