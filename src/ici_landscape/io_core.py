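"""Readers/writers for the tabular formats the pipeline touches.

Expression matrices, clinical tables and all result tables travel as TSV;
gene sets as GMT; somatic variants as MAF. Readers are strict about their
declared dialects and fail loudly otherwise; ``write`` followed by ``read``
is the identity on valid inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ici_landscape")

# MAF controlled vocabulary (Variant_Classification). The first block is the
# nonsynonymous set used for tumor mutation burden; the second block is
# retained on load but does not count toward TMB.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
    }
)
SYNONYMOUS_CLASSES = frozenset(
    {
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)
VALID_VARIANT_CLASSES = NONSYNONYMOUS_CLASSES | SYNONYMOUS_CLASSES

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
    "Chromosome",
    "Start_Position",
    "End_Position",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance table.

    ``data`` holds genes as rows and samples as columns. Values are
    TPM-like (non-negative) unless ``log2_scale`` is set, in which case they
    live on the log2 scale and may be negative.
    """

    data: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.log2_scale and (self.data.to_numpy() < 0).any():
            raise ValueError("negative values in a linear-scale expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(x + pseudocount) view of a linear-scale matrix."""
        if self.log2_scale:
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), log2_scale=True)

    def to_linear(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Invert :meth:`to_log2`; negative linear values are clipped to 0."""
        if not self.log2_scale:
            return self
        lin = (2.0 ** self.data) - pseudocount
        return ExpressionMatrix(lin.clip(lower=0.0), log2_scale=False)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], log2_scale=self.log2_scale)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_expression(path, log2_scale: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = gene ids).

    Duplicate gene ids are collapsed to the row with the maximum mean
    expression (the common practice when several probes/transcripts map to
    one symbol); the count of dropped rows is logged.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        raise ValueError(f"duplicate sample ids in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression file: {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    if df.index.duplicated().any():
        n_before = len(df)
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index()
        logger.warning(
            "collapsed %d duplicate gene rows by max mean expression", n_before - len(df)
        )
    df.index.name = "gene_id"
    expr = ExpressionMatrix(df, log2_scale=log2_scale)
    logger.info("read expression matrix %s: %d genes x %d samples", path, *expr.shape)
    return expr


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_clinical(path, time_unit: str = "months") -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, os_time, os_event[, age, cohort].

    ``time_unit`` may be 'months', 'days' or 'years'; times are converted to
    months internally. Samples missing os_time/os_event are retained (they
    are excluded from survival stages only, downstream).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in clinical table {path}")
    factor = {"months": 1.0, "days": 1.0 / 30.44, "years": 12.0}
    if time_unit not in factor:
        raise ValueError(f"unknown time unit {time_unit!r}")
    df = df.copy()
    df["os_time"] = df["os_time"].astype(float) * factor[time_unit]
    complete = df["os_time"].notna() & df["os_event"].notna()
    if (df.loc[complete, "os_time"] <= 0).any():
        raise ValueError("non-positive survival times")
    if not df.loc[complete, "os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0/1")
    return df.set_index("sample_id", drop=False)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Genes are de-duplicated within a set (order-preserving is not needed;
    sets are unordered).
    """
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_maf(path) -> pd.DataFrame:
    """Read a MAF file (tab-separated, '#' comment lines allowed).

    Requires Hugo_Symbol, Tumor_Sample_Barcode and Variant_Classification.
    Rows with a Variant_Classification outside the controlled vocabulary are
    rejected with the count logged. Coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF {path} missing mandatory columns: {sorted(missing)}")
    known = df["Variant_Classification"].isin(VALID_VARIANT_CLASSES)
    if (~known).any():
        logger.warning(
            "rejected %d MAF records with unknown Variant_Classification", int((~known).sum())
        )
        df = df[known]
    if {"Start_Position", "End_Position"} <= set(df.columns) and len(df):
        if (df["Start_Position"] > df["End_Position"]).any():
            raise ValueError(f"MAF {path}: Start_Position > End_Position")
    return df.reset_index(drop=True)


def write_maf(maf: pd.DataFrame, path) -> None:
    cols = [c for c in MAF_COLUMNS if c in maf.columns]
    cols += [c for c in maf.columns if c not in cols]
    maf[cols].to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write any result table as TSV."""
    df.to_csv(path, sep="\t", index=index)


def setup_logging(logfile=None, level=logging.INFO) -> None:
    """Log to stderr and optionally to a file, with timings left to callers."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
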