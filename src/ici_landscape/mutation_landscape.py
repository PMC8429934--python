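"""Tumor mutation burden, per-gene mutation frequencies and associations.

TMB counts nonsynonymous MAF records per sample over the interrogated exome
size (default 38 Mb); mutation frequencies feed an oncoprint-style binary
gene x sample matrix with per-group fractions; group comparisons use the
Pearson chi-square (no continuity correction) with BH adjustment across
genes; score associations use Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import NONSYNONYMOUS_CLASSES

logger = logging.getLogger("ici_landscape")


@dataclass
class TMBTable:
    table: pd.DataFrame  # per sample: nonsyn_count, tmb
    exome_mb: float


@dataclass
class MutationFrequencyTable:
    table: pd.DataFrame  # per gene: counts & fractions overall and per group
    oncoprint: pd.DataFrame  # binary genes x samples alteration matrix


def compute_tmb(maf: pd.DataFrame, exome_mb: float = 38.0, samples=None) -> TMBTable:
    """Nonsynonymous mutations per megabase per sample.

    Counts records whose Variant_Classification is in the nonsynonymous set;
    samples listed in ``samples`` but absent from the MAF get TMB 0.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    nonsyn = maf[maf["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]
    counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    table = pd.DataFrame({"nonsyn_count": counts.astype(int)})
    table["tmb"] = table["nonsyn_count"] / exome_mb
    table.index.name = "sample_id"
    return TMBTable(table=table, exome_mb=exome_mb)


def mutation_frequencies(
    maf: pd.DataFrame, samples, groups: pd.Series | None = None, top_n: int = 20
) -> MutationFrequencyTable:
    """Top mutated genes with per-group mutated-sample fractions.

    A sample counts once per gene regardless of multiple hits (binary
    oncoprint matrix); genes rank by overall mutated-sample count, ties by
    gene id; the top ``top_n`` rows are returned.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    samples = list(samples)
    hits = maf[maf["Tumor_Sample_Barcode"].isin(samples)][
        ["Hugo_Symbol", "Tumor_Sample_Barcode"]
    ].drop_duplicates()
    onco = (
        hits.assign(v=1)
        .pivot_table(index="Hugo_Symbol", columns="Tumor_Sample_Barcode", values="v", fill_value=0)
        .reindex(columns=samples, fill_value=0)
        .astype(int)
    )
    counts = onco.sum(axis=1)
    order = counts.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    top = order.head(top_n).index.tolist()
    table = pd.DataFrame({"mutated_samples": counts.loc[top]})
    table["fraction"] = table["mutated_samples"] / len(samples)
    if groups is not None:
        groups = pd.Series(groups).reindex(samples)
        for g in sorted(groups.dropna().unique()):
            cols = [s for s in samples if groups[s] == g]
            table[f"count_{g}"] = onco.loc[top, cols].sum(axis=1)
            table[f"fraction_{g}"] = table[f"count_{g}"] / max(len(cols), 1)
    table.index.name = "gene"
    return MutationFrequencyTable(table=table, oncoprint=onco.loc[top])


def chi_square_2x2(table_2x2: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Returns (nan, nan) with a warning when a margin is zero.
    """
    obs = np.asarray(table_2x2, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        logger.warning("zero margin in 2x2 table; chi-square undefined")
        return np.nan, np.nan
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compare_mutation_rates(
    onco: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-gene 2x2 chi-square of mutation frequency across two groups.

    ``onco`` is the binary gene x sample matrix; genes with an undefined
    statistic (zero margin) get NA and are excluded from the BH family.
    """
    groups = groups.reindex(onco.columns)
    labels = sorted(groups.dropna().unique().tolist())
    if len(labels) != 2:
        raise ValueError("compare_mutation_rates needs exactly two groups")
    masks = {g: (groups == g).to_numpy() for g in labels}
    rows = []
    for gene in onco.index:
        v = onco.loc[gene].to_numpy()
        tab = np.array(
            [
                [v[masks[g]].sum(), (1 - v[masks[g]]).sum()]
                for g in labels
            ]
        )
        chi2, p = chi_square_2x2(tab)
        rows.append({"gene": gene, "chi2": chi2, "p": p})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["p"].notna()
    out["adj_p"] = np.nan
    if ok.any():
        out.loc[ok, "adj_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p).

    Returns (nan, nan) for a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >=3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
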