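"""Two-group gene set enrichment analysis (GSEA) for the score subgroups.

Genes are ranked by the classic signal-to-noise statistic; each set's
enrichment score is the signed maximum deviation of the weighted running
sum; significance comes from gene-set permutation (random sets of matching
size), with the normalized score (NES) and the sign-pooled FDR q-value of
the standard GSEA convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneSetCollection


@dataclass
class GSEAResult:
    table: pd.DataFrame  # per set: es, nes, p, q, size, leading_edge
    n_perm: int
    weight: float


def rank_genes(expr: ExpressionMatrix, group_labels: pd.Series) -> pd.Series:
    """Signal-to-noise statistic per gene, sorted descending.

    s2n = (mean1 - mean2) / (sd1 + sd2) with each sd floored at
    0.2*|mean| (0.2 when the mean is 0), the classic two-class convention.
    Ties order by gene id.
    """
    labels = group_labels.loc[expr.sample_ids]
    values = sorted(labels.unique().tolist())
    if len(values) != 2:
        raise ValueError("rank_genes needs exactly two groups")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError("each group needs >=3 samples")
    X = expr.data.to_numpy(dtype=float)
    m1_mask = (labels == values[0]).to_numpy()

    def _stats(mask):
        sub = X[:, mask]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        floor = np.where(np.abs(mean) > 0, 0.2 * np.abs(mean), 0.2)
        return mean, np.maximum(sd, floor)

    mean1, sd1 = _stats(m1_mask)
    mean2, sd2 = _stats(~m1_mask)
    s2n = (mean1 - mean2) / (sd1 + sd2)
    out = pd.Series(s2n, index=expr.gene_ids, name="signal_to_noise")
    return out.sort_values(ascending=False, kind="stable").sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )


def _es_from_hits(stat: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, int]:
    """Signed max-deviation running sum; returns (ES, extremum position)."""
    w = np.abs(stat) ** weight * hit
    denom = w.sum()
    n_out = (~hit).sum()
    if denom == 0 or n_out == 0:
        return np.nan, -1
    running = np.cumsum(w / denom - (~hit) / n_out)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def gsea(
    ranked: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Enrichment of each gene set along the ranked list.

    The null is gene-set permutation: ``n_perm`` random draws of the same
    size from the ranked universe. NES = ES / mean(|null ES| of matching
    sign); nominal p is one-sided against the matching-sign null; FDR q uses
    the sign-pooled NES convention. ``n_perm=0`` computes ES only (p/q NA).
    """
    genes = np.array(ranked.index)
    stat = ranked.to_numpy(dtype=float)
    N = len(genes)
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(genes)}

    rows = []
    null_by_set: dict[str, np.ndarray] = {}
    for name, gset in sets.items():
        idx = np.array(sorted(pos[g] for g in gset if g in pos), dtype=int)
        if idx.size == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the ranked list")
        if idx.size == N:
            raise ValueError(f"gene set {name!r} equals the ranked universe")
        hit = np.zeros(N, dtype=bool)
        hit[idx] = True
        es, ipeak = _es_from_hits(stat, hit, weight)
        if es >= 0:
            lead = [genes[i] for i in range(ipeak + 1) if hit[i]]
        else:
            lead = [genes[i] for i in range(ipeak, N) if hit[i]]
        rows.append({"set": name, "size": int(idx.size), "es": es, "leading_edge": lead})
        if n_perm > 0:
            null_es = np.empty(n_perm)
            for p in range(n_perm):
                ridx = rng.choice(N, size=idx.size, replace=False)
                rhit = np.zeros(N, dtype=bool)
                rhit[ridx] = True
                null_es[p], _ = _es_from_hits(stat, rhit, weight)
            null_by_set[name] = null_es

    table = pd.DataFrame(rows).set_index("set")
    if n_perm == 0:
        table["nes"] = np.nan
        table["p"] = np.nan
        table["q"] = np.nan
        return GSEAResult(table=table, n_perm=0, weight=weight)

    def _normalize(es: float, null: np.ndarray) -> tuple[float, float, np.ndarray]:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            return np.nan, np.nan, np.array([])
        mean_abs = np.abs(same).mean()
        nes = es / mean_abs if mean_abs > 0 else np.nan
        p = float((np.abs(same) >= abs(es)).mean())
        return nes, p, null / mean_abs if mean_abs > 0 else np.array([])

    nes_list, p_list, null_nes_pool = [], [], []
    for name in table.index:
        nes, p, null_nes = _normalize(table.loc[name, "es"], null_by_set[name])
        nes_list.append(nes)
        p_list.append(p)
        null_nes_pool.append(null_nes)
    table["nes"] = nes_list
    table["p"] = p_list

    pool = np.concatenate([v for v in null_nes_pool if v.size]) if null_nes_pool else np.array([])
    obs = table["nes"].to_numpy()

    def _fdr(nes: float) -> float:
        if np.isnan(nes) or pool.size == 0:
            return np.nan
        if nes >= 0:
            null_frac_denom = (pool >= 0).sum()
            null_frac = (pool >= nes).sum() / null_frac_denom if null_frac_denom else np.nan
            obs_pos = obs[obs >= 0]
            obs_frac = (obs_pos >= nes).mean() if obs_pos.size else np.nan
        else:
            null_frac_denom = (pool < 0).sum()
            null_frac = (pool <= nes).sum() / null_frac_denom if null_frac_denom else np.nan
            obs_neg = obs[obs < 0]
            obs_frac = (obs_neg <= nes).mean() if obs_neg.size else np.nan
        if not obs_frac or np.isnan(obs_frac) or np.isnan(null_frac):
            return np.nan
        return float(min(1.0, null_frac / obs_frac))

    table["q"] = [_fdr(v) for v in obs]
    return GSEAResult(table=table, n_perm=n_perm, weight=weight)
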