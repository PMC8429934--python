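"""Synthetic cohorts with the statistical structure the analysis assumes.

Expression is generated as noisy convex mixtures of cell-type expression
programs with a planted cluster structure over the mixing proportions and a
two-cohort batch effect; survival times follow an exponential hazard driven
by a latent infiltration score; the MAF plants group-specific mutation rates
and driver-gene frequencies. Every planted quantity is returned as ground
truth so recovery can be tested.

The generator emulates a two-cohort breast-tumor study: ~10^3 samples,
a handful of leukocyte programs mixed per sample, three infiltration
patterns, moderate multiplicative noise, and mutation rates on the order of
1-2 nonsynonymous events per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    ExpressionMatrix,
    GeneSetCollection,
    write_clinical,
    write_expression,
    write_gmt,
    write_maf,
)

_CLASS_PROBS = {
    "Missense_Mutation": 0.60,
    "Nonsense_Mutation": 0.09,
    "Frame_Shift_Del": 0.09,
    "Frame_Shift_Ins": 0.05,
    "Splice_Site": 0.06,
    "In_Frame_Del": 0.04,
    "In_Frame_Ins": 0.02,
    "Nonstop_Mutation": 0.01,
    "Translation_Start_Site": 0.04,
}
_INDEL_CLASSES = {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}


@dataclass
class CohortConfig:
    """Parameters of one simulated cohort.

    Defaults describe the study conditions assumed throughout: 300 samples,
    2,000 genes, 8 leukocyte programs, 3 planted infiltration patterns, 10%
    multiplicative noise, a two-cohort batch effect on the log2 scale, a
    log-hazard of 0.7 per unit latent score with 30% censoring, and planted
    mutation rates of 2.0 vs 1.0 nonsynonymous events/Mb with driver-gene
    frequencies echoing commonly reported breast-tumor rates (TP53 38%/14%,
    MAP3K1 6%/14% in low/high-score groups).
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_cell_types: int = 8
    n_clusters: int = 3
    dirichlet_concentrations: np.ndarray | None = None  # (n_clusters, n_cell_types)
    markers_per_type: int = 25
    noise_sd: float = 0.1
    batch_labels: np.ndarray | None = None  # per-sample cohort index {0,1}
    batch_shift: tuple[float, float] = (0.0, 0.8)
    batch_scale: tuple[float, float] = (1.0, 1.2)
    surv_beta: float = 0.7
    censor_rate: float = 0.3
    baseline_hazard: float = 0.02  # events per month at latent score 0
    tmb_rate_by_group: dict[str, float] = field(
        default_factory=lambda: {"low": 2.0, "high": 1.0}
    )
    driver_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TP53": {"low": 0.38, "high": 0.14},
            "MAP3K1": {"low": 0.06, "high": 0.14},
        }
    )
    exome_mb: float = 38.0
    program_weights: np.ndarray | None = None  # latent-score weights per cell type
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_cell_types <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_cell_types > self.n_genes:
            raise ValueError("n_cell_types must not exceed n_genes")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dirichlet_concentrations is not None:
            conc = np.asarray(self.dirichlet_concentrations, dtype=float)
            if conc.shape != (self.n_clusters, self.n_cell_types):
                raise ValueError(
                    "dirichlet_concentrations must be (n_clusters, n_cell_types)"
                )
            if (conc <= 0).any():
                raise ValueError("Dirichlet concentrations must be strictly positive")
            self.dirichlet_concentrations = conc

    def concentrations(self) -> np.ndarray:
        """Per-cluster Dirichlet vectors; default peaks each cluster on a
        disjoint block of cell types (concentration 4.0 in-block, 0.3 out)."""
        if self.dirichlet_concentrations is not None:
            return self.dirichlet_concentrations
        conc = np.full((self.n_clusters, self.n_cell_types), 0.3)
        blocks = np.array_split(np.arange(self.n_cell_types), self.n_clusters)
        for c, block in enumerate(blocks):
            conc[c, block] = 4.0
        return conc

    def cell_type_blocks(self) -> list[np.ndarray]:
        return np.array_split(np.arange(self.n_cell_types), self.n_clusters)

    @classmethod
    def two_program(cls, strength: float = 10.0, base: float = 0.8, **kwargs) -> "CohortConfig":
        """A cohort whose patterns form a gradient between two opposite
        cell-type programs.

        Program A is the first half of the cell types, program B the second;
        the planted patterns interpolate from A-rich through balanced to
        B-rich, and the latent score is the standardized A-minus-B mass.
        This is the configuration for score-recovery studies, where the two
        programs drive the survival hazard in opposite directions.
        """
        cfg = cls(**kwargs)
        half = cfg.n_cell_types // 2
        conc = np.empty((cfg.n_clusters, cfg.n_cell_types))
        for c in range(cfg.n_clusters):
            t = (cfg.n_clusters - 1 - c) / max(cfg.n_clusters - 1, 1)  # 1 -> A-rich
            conc[c, :half] = base + (strength - base) * t
            conc[c, half:] = base + (strength - base) * (1 - t)
        w = np.zeros(cfg.n_cell_types)
        w[:half], w[half:] = 1.0, -1.0
        cfg.dirichlet_concentrations = conc
        cfg.program_weights = w
        return cfg


@dataclass
class SyntheticCohort:
    """One simulated cohort plus all planted ground truth."""

    expression: ExpressionMatrix
    true_fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    true_cluster: pd.Series  # sample -> {1..n_clusters}
    latent_score: pd.Series  # sample -> real, sd ~1
    clinical: pd.DataFrame
    maf: pd.DataFrame
    signature_matrix: pd.DataFrame  # genes x cell types
    marker_sets: GeneSetCollection
    config: CohortConfig

    @property
    def score_group(self) -> pd.Series:
        """Planted low/high grouping by the median of the latent score."""
        med = self.latent_score.median()
        return pd.Series(
            np.where(self.latent_score > med, "high", "low"),
            index=self.latent_score.index,
            name="score_group",
        )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan a global seed out to per-stage child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def build_signature_matrix(
    n_genes: int, n_cell_types: int, markers_per_type: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Reference profiles with disjoint marker blocks.

    Each cell type overexpresses its own block of marker genes 5-50x over a
    shared baseline, mirroring the marker-gene structure of leukocyte
    signature matrices; the remaining genes are background expressed equally
    in every type.
    """
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError("marker blocks exceed the gene universe")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=1.0, sigma=0.6, size=n_genes)
    S = np.tile(base[:, None], (1, n_cell_types))
    sets: dict[str, set] = {}
    for t in range(n_cell_types):
        idx = np.arange(t * markers_per_type, (t + 1) * markers_per_type)
        fold = rng.uniform(5.0, 50.0, size=markers_per_type)
        S[idx, t] = base[idx] * fold
        sets[f"celltype_{t}_markers"] = {genes[i] for i in idx}
    cols = [f"celltype_{t}" for t in range(n_cell_types)]
    sig = pd.DataFrame(S, index=genes, columns=cols)
    return sig, GeneSetCollection(sets, {k: "planted marker set" for k in sets})


def simulate_expression(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series, pd.DataFrame, GeneSetCollection]:
    """Expression as noisy convex mixtures of cell-type programs.

    expression = signature_matrix @ fractions.T with multiplicative
    log-normal noise of sd ``noise_sd``, then the per-cohort batch effect
    applied on the log2 scale (additive shift, scale of the per-gene
    residual). Deterministic for a fixed seed.
    """
    seeds = _child_seeds(config.seed, 4)
    rng_sig = np.random.default_rng(seeds[0])
    rng_frac = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])

    sig, marker_sets = build_signature_matrix(
        config.n_genes, config.n_cell_types, config.markers_per_type, rng_sig
    )
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    conc = config.concentrations()
    cluster = rng_frac.integers(0, config.n_clusters, size=config.n_samples) + 1
    F = np.vstack(
        [rng_frac.dirichlet(conc[c - 1]) for c in cluster]
    )  # samples x cell types
    fractions = pd.DataFrame(F, index=samples, columns=sig.columns)
    true_cluster = pd.Series(cluster, index=samples, name="true_cluster")

    E = sig.to_numpy() @ F.T  # genes x samples, linear scale
    if config.noise_sd > 0:
        E = E * np.exp(
            rng_noise.normal(0.0, config.noise_sd, size=E.shape)
        )

    batch = config.batch_labels
    if batch is None:
        batch = (np.arange(config.n_samples) >= config.n_samples // 2).astype(int)
    batch = np.asarray(batch, dtype=int)
    if batch.shape != (config.n_samples,):
        raise ValueError("batch_labels must have one entry per sample")

    # Batch effect on the log2 scale: per gene g and batch b,
    # x' = m_g + shift_b + scale_b * (x - m_g), matching the location/scale
    # model the downstream correction assumes.
    X = np.log2(E + 1.0)
    m = X.mean(axis=1, keepdims=True)
    for b in np.unique(batch):
        cols = batch == b
        X[:, cols] = m + config.batch_shift[b] + config.batch_scale[b] * (X[:, cols] - m)
    E = np.clip(2.0**X - 1.0, 0.0, None)

    expr = ExpressionMatrix(
        pd.DataFrame(E, index=sig.index, columns=samples), log2_scale=False
    )
    return expr, fractions, true_cluster, sig, marker_sets


def latent_score_from_fractions(
    fractions: pd.DataFrame, config: CohortConfig
) -> pd.Series:
    """Planted latent infiltration score.

    By default, mass on the first cluster's cell-type block minus mass on
    the last cluster's block, standardized to unit variance; a two-program
    config supplies its own A-minus-B weights. The score is what the
    survival hazard and the mutation-rate grouping act on, and what the
    derived per-sample score should recover (up to sign).
    """
    if config.program_weights is not None:
        w = np.asarray(config.program_weights, dtype=float)
    else:
        blocks = config.cell_type_blocks()
        w = np.zeros(config.n_cell_types)
        w[blocks[0]] = 1.0
        w[blocks[-1]] = -1.0
    raw = fractions.to_numpy() @ w
    raw = (raw - raw.mean()) / raw.std(ddof=0)
    return pd.Series(raw, index=fractions.index, name="latent_score")


def simulate_survival(
    latent_score: pd.Series,
    surv_beta: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 0.02,
    batch_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Event times exponential with hazard h0*exp(surv_beta*score).

    Censoring is independent exponential with its rate solved (bisection) so
    the expected censored fraction matches ``censor_rate``. Ages are drawn
    N(58, 12) clipped to [25, 90] for use as a nomogram covariate.
    """
    score = np.asarray(latent_score, dtype=float)
    if score.size == 0:
        raise ValueError("empty score vector")
    if not np.isfinite(score).all():
        raise ValueError("latent scores must be finite")
    rng = np.random.default_rng(seed)
    h = baseline_hazard * np.exp(surv_beta * score)
    T = rng.exponential(1.0 / h)

    if censor_rate <= 0:
        time, event = T, np.ones_like(T, dtype=int)
    else:
        # E[P(C < T)] = mean(hc / (hc + h_i)); monotone in hc -> bisection.
        lo, hi = 1e-9, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if np.mean(mid / (mid + h)) < censor_rate:
                lo = mid
            else:
                hi = mid
        hc = np.sqrt(lo * hi)
        C = rng.exponential(1.0 / hc, size=T.shape)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)

    age = np.clip(rng.normal(58.0, 12.0, size=T.shape), 25.0, 90.0)
    if batch_labels is None:
        cohort = ["cohort_1"] * len(T)
    else:
        cohort = [f"cohort_{int(b) + 1}" for b in batch_labels]
    return pd.DataFrame(
        {
            "sample_id": latent_score.index,
            "os_time": np.maximum(time, 1e-6),
            "os_event": event,
            "age": age,
            "cohort": cohort,
        }
    ).set_index("sample_id", drop=False)


def simulate_maf(
    samples,
    groups: pd.Series,
    tmb_rate_by_group: dict[str, float],
    driver_rates: dict[str, dict[str, float]],
    seed: int,
    exome_mb: float = 38.0,
    silent_ratio: float = 0.3,
) -> pd.DataFrame:
    """A MAF with planted per-group mutation rates.

    Per-sample nonsynonymous counts are Poisson(group rate * exome_mb),
    spread over a background gene pool; named driver genes are mutated
    Bernoulli with group-specific probabilities. Silent records are added at
    ``silent_ratio`` of the nonsynonymous rate so the classification filter
    has something to reject.
    """
    samples = list(samples)
    rng = np.random.default_rng(seed)
    for s in samples:
        g = groups.loc[s]
        if g not in tmb_rate_by_group:
            raise ValueError(f"unknown group label {g!r} for sample {s}")
        if tmb_rate_by_group[g] < 0:
            raise ValueError("mutation rates must be >= 0")

    classes = list(_CLASS_PROBS)
    probs = np.array([_CLASS_PROBS[c] for c in classes])
    probs = probs / probs.sum()
    pool = [f"BGENE{i:04d}" for i in range(300)]
    records: list[dict] = []

    def _record(sample: str, gene: str, vclass: str) -> dict:
        chrom = str(rng.integers(1, 23))
        start = int(rng.integers(10_000, 100_000_000))
        if vclass in _INDEL_CLASSES:
            length = int(rng.integers(1, 10))
            vtype = "DEL" if "Del" in vclass else "INS"
            end = start + (length - 1 if vtype == "DEL" else 0)
        else:
            vtype, end = "SNP", start
        return {
            "Hugo_Symbol": gene,
            "Tumor_Sample_Barcode": sample,
            "Variant_Classification": vclass,
            "Variant_Type": vtype,
            "Chromosome": chrom,
            "Start_Position": start,
            "End_Position": end,
        }

    for s in samples:
        g = groups.loc[s]
        rate = tmb_rate_by_group[g]
        n_nonsyn = rng.poisson(rate * exome_mb)
        for gene in rng.choice(pool, size=n_nonsyn):
            vclass = classes[rng.choice(len(classes), p=probs)]
            records.append(_record(s, str(gene), vclass))
        n_silent = rng.poisson(silent_ratio * rate * exome_mb)
        for gene in rng.choice(pool, size=n_silent):
            records.append(_record(s, str(gene), "Silent"))
        for gene, rates in driver_rates.items():
            if rng.random() < rates[g]:
                records.append(_record(s, gene, "Missense_Mutation"))

    from .io_core import MAF_COLUMNS

    return pd.DataFrame(records, columns=MAF_COLUMNS)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one full cohort; a single global seed fans out per stage."""
    seeds = _child_seeds(config.seed + 1_000_003, 3)
    expr, fractions, true_cluster, sig, marker_sets = simulate_expression(config)
    latent = latent_score_from_fractions(fractions, config)
    # Convenience composite sets: the marker genes of the cell types with
    # positive/negative latent weight stand in for immune/stromal
    # signatures downstream.
    if config.program_weights is not None:
        w = np.asarray(config.program_weights, dtype=float)
        up_types = np.where(w > 0)[0]
        down_types = np.where(w < 0)[0]
    else:
        blocks = config.cell_type_blocks()
        up_types, down_types = blocks[0], blocks[-1]
    composite = dict(marker_sets.sets)
    composite["immune_signature"] = set().union(
        *(marker_sets[f"celltype_{t}_markers"] for t in up_types)
    )
    composite["stromal_signature"] = set().union(
        *(marker_sets[f"celltype_{t}_markers"] for t in down_types)
    )
    marker_sets = GeneSetCollection(
        composite, {k: marker_sets.descriptions.get(k, "composite set") for k in composite}
    )
    batch = config.batch_labels
    if batch is None:
        batch = (np.arange(config.n_samples) >= config.n_samples // 2).astype(int)
    clinical = simulate_survival(
        latent,
        config.surv_beta,
        config.censor_rate,
        seeds[0],
        baseline_hazard=config.baseline_hazard,
        batch_labels=batch,
    )
    med = latent.median()
    groups = pd.Series(
        np.where(latent > med, "high", "low"), index=latent.index, name="score_group"
    )
    maf = simulate_maf(
        latent.index,
        groups,
        config.tmb_rate_by_group,
        config.driver_rates,
        seeds[1],
        exome_mb=config.exome_mb,
    )
    return SyntheticCohort(
        expression=expr,
        true_fractions=fractions,
        true_cluster=true_cluster,
        latent_score=latent,
        clinical=clinical,
        maf=maf,
        signature_matrix=sig,
        marker_sets=marker_sets,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write expression/clinical/MAF/GMT plus a JSON ground-truth file."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "maf": out / "mutations.maf",
        "gmt": out / "marker_sets.gmt",
        "signature_matrix": out / "signature_matrix.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_maf(cohort.maf, paths["maf"])
    write_gmt(cohort.marker_sets, paths["gmt"])
    sig = cohort.signature_matrix.copy()
    sig.index.name = "gene_id"
    sig.to_csv(paths["signature_matrix"], sep="\t")
    truth = {
        "true_cluster": cohort.true_cluster.to_dict(),
        "latent_score": cohort.latent_score.round(6).to_dict(),
        "true_fractions": {
            s: [round(v, 6) for v in row]
            for s, row in zip(cohort.true_fractions.index, cohort.true_fractions.to_numpy())
        },
        "score_group": cohort.score_group.to_dict(),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh)
    return {k: str(v) for k, v in paths.items()}
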