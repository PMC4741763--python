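"""Domain containers and TSV/BED/JSON readers and writers.

All tabular formats are tab-delimited UTF-8 with a header row.  Matrices
are stored probes/features x samples with the identifier in the first
column.  Annotation positions are 1-based (array-manifest convention);
BED export converts to 0-based half-open intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParameterError

# Recognised missing-value tokens, matched case-insensitively.
NA_TOKENS = frozenset({"", "na", "nan", "null"})
_NA_VALUES = sorted({
    "".join(chars)
    for tok in NA_TOKENS
    for chars in __import__("itertools").product(*[(c.lower(), c.upper()) for c in tok])
} | {""})

PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
GENE_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
PHENOTYPES = ("invasive", "non_invasive")

__all__ = [
    "BetaMatrix", "SampleSheet", "ProbeAnnotation", "ExpressionMatrix",
    "read_beta_matrix", "read_probe_annotation", "read_expression_matrix",
    "read_sample_sheet", "write_beta_matrix", "write_expression_matrix",
    "beta_to_m", "m_to_beta", "write_signature_outputs",
    "PROMOTER_REGIONS", "NA_TOKENS",
]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1]; NaN marks missing."""

    data: pd.DataFrame
    n_clipped: int = 0

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise FormatError(
                f"beta value {vals[i, j]} outside [0,1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


@dataclass
class ExpressionMatrix:
    """Features x samples non-negative intensities; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise FormatError("no features in expression matrix")
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        if np.any((vals < 0) & ~np.isnan(vals)):
            i, j = np.argwhere((vals < 0) & ~np.isnan(vals))[0]
            raise FormatError(
                f"negative intensity {vals[i, j]} at feature "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleSheet:
    """Sample metadata: tissue, phenotype (invasive / non_invasive), replicate."""

    data: pd.DataFrame  # columns: sample_id, tissue, phenotype, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "phenotype", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(self.data["sample_id"], "sample ids")
        bad = set(self.data["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise FormatError(f"unknown phenotype labels: {sorted(bad)}")
        if (self.data["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive")
        counts = self.data.groupby(["tissue", "phenotype"]).size()
        for tissue in self.tissues:
            for ph in PHENOTYPES:
                if counts.get((tissue, ph), 0) < 2:
                    raise FormatError(
                        f"tissue {tissue!r} has fewer than 2 {ph} samples")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.data["tissue"].unique())

    def samples_for(self, tissue: str, phenotype: str) -> list[str]:
        if tissue not in set(self.data["tissue"]):
            raise InputError(f"unknown tissue {tissue!r}")
        if phenotype not in PHENOTYPES:
            raise InputError(f"unknown phenotype {phenotype!r}")
        m = (self.data["tissue"] == tissue) & (self.data["phenotype"] == phenotype)
        return self.data.loc[m, "sample_id"].tolist()

    def check_against(self, sample_ids) -> None:
        missing = set(self.data["sample_id"]) - set(sample_ids)
        if missing:
            raise InputError(f"samples in sheet but not in matrix: {sorted(missing)[:5]}")


@dataclass
class ProbeAnnotation:
    """Per-probe genomic and gene context.

    ``data`` is indexed by probe id with columns: chromosome, position
    (1-based), gene_symbols (list), gene_region (list, aligned with
    gene_symbols), island_relation, enhancer (bool).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        if (self.data["position"].astype(int) < 1).any():
            raise FormatError("positions must be >= 1 (1-based)")
        for row_no, (syms, regs) in enumerate(zip(self.data["gene_symbols"], self.data["gene_region"]), start=1):
            if len(syms) != len(regs):
                raise FormatError(
                    f"row {row_no}: gene_symbols ({len(syms)}) and gene_region "
                    f"({len(regs)}) lists are misaligned")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def require_probes(self, probes) -> None:
        unknown = set(probes) - set(self.data.index)
        if unknown:
            raise InputError(f"probes absent from annotation: {sorted(unknown)[:5]}")

    def enhancer_probes(self) -> frozenset:
        return frozenset(self.data.index[self.data["enhancer"].astype(bool)])


def _read_matrix_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_beta_matrix(path, strict: bool = True) -> BetaMatrix:
    """Read a probes x samples beta-value TSV.

    With ``strict`` (default), any value outside [0, 1] is a format error
    naming the probe and sample; otherwise such values are clipped into
    range with a warning and counted in ``n_clipped``.
    """
    df = _read_matrix_frame(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from None
    vals = df.to_numpy()
    out_of_range = ((vals < 0) | (vals > 1)) & ~np.isnan(vals)
    n_clipped = 0
    if out_of_range.any():
        if strict:
            i, j = np.argwhere(out_of_range)[0]
            raise FormatError(
                f"beta value {vals[i, j]} outside [0,1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r} in {path}")
        n_clipped = int(out_of_range.sum())
        warnings.warn(f"clipped {n_clipped} beta values into [0,1] in {path}")
        df = df.clip(0.0, 1.0)
    return BetaMatrix(df, n_clipped=n_clipped)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a features x samples intensity TSV (non-negative values)."""
    df = _read_matrix_frame(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity in {path}: {exc}") from None
    return ExpressionMatrix(df)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES,
                     keep_default_na=False)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def _split_list(cell: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return []
    return [tok for tok in str(cell).split(";") if tok != ""]


_TRUE_TOKENS = {"true", "t", "1", "yes"}


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a manifest-style probe annotation TSV.

    Expected columns: probe_id, chromosome, position, gene_symbols
    (";"-joined), gene_region (";"-joined, aligned), island_relation,
    enhancer (TRUE/FALSE; empty means false).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    required = ["probe_id", "chromosome", "position", "gene_symbols",
                "gene_region", "island_relation", "enhancer"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    out = pd.DataFrame(index=pd.Index(df["probe_id"].astype(str), name="probe_id"))
    out["chromosome"] = df["chromosome"].to_numpy()
    try:
        out["position"] = df["position"].astype(int).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-integer position: {exc}") from None
    out["gene_symbols"] = [_split_list(c) for c in df["gene_symbols"]]
    out["gene_region"] = [_split_list(c) for c in df["gene_region"]]
    out["island_relation"] = df["island_relation"].to_numpy()
    out["enhancer"] = [str(c).strip().lower() in _TRUE_TOKENS for c in df["enhancer"]]
    return ProbeAnnotation(out)


_FLOAT_FORMAT = "%.6g"


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id",
                       float_format=_FLOAT_FORMAT, na_rep="NA")


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id",
                       float_format=_FLOAT_FORMAT, na_rep="NA")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    df = annotation.data
    out = pd.DataFrame({
        "probe_id": df.index,
        "chromosome": df["chromosome"].to_numpy(),
        "position": df["position"].to_numpy(),
        "gene_symbols": [";".join(s) for s in df["gene_symbols"]],
        "gene_region": [";".join(r) for r in df["gene_region"]],
        "island_relation": df["island_relation"].to_numpy(),
        "enhancer": ["TRUE" if e else "" for e in df["enhancer"]],
    })
    out.to_csv(path, sep="\t", index=False)


def beta_to_m(beta, epsilon: float = 1e-6):
    """Map beta values to M-values: log2(b / (1-b)) after clipping to
    [epsilon, 1-epsilon].  Missing (NaN) maps to missing."""
    if not (0.0 < epsilon < 0.5):
        raise ParameterError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    b = np.where(np.isnan(np.asarray(beta, dtype=float)), np.nan, b)
    out = np.log2(b / (1.0 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (base-2 logistic)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.power(2.0, -m))
    if out.ndim == 0:
        return float(out)
    return out


def write_signature_outputs(signature, annotation: ProbeAnnotation, out_dir) -> dict:
    """Export a signature: BED of CpGs, gene lists, and a JSON count report.

    BED records are 0-based half-open single-base intervals; the score
    column is 1000 * |mean delta-beta| rounded to the nearest integer.
    Returns a manifest mapping logical names to written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_probes = sorted(signature.common_hyper_probes | signature.common_hypo_probes)
    annotation.require_probes(all_probes)

    bed_path = out_dir / "signature_cpgs.bed"
    with open(bed_path, "w") as fh:
        for probe in all_probes:
            row = annotation.data.loc[probe]
            pos = int(row["position"])
            delta = abs(signature.mean_delta_beta.get(probe, 0.0))
            strand = "."
            fh.write(f"{row['chromosome']}\t{pos - 1}\t{pos}\t{probe}\t{round(1000 * delta)}\t{strand}\n")

    manifest = {"bed": str(bed_path)}
    from .signature import probes_to_genes  # local import: avoid cycle
    report_counts = {}
    for name, probes in (("hyper", signature.common_hyper_probes),
                         ("hypo", signature.common_hypo_probes)):
        mapping = probes_to_genes(probes, annotation)
        genes_path = out_dir / f"common_{name}_genes.txt"
        genes_path.write_text("".join(g + "\n" for g in sorted(mapping.genes)))
        manifest[f"{name}_genes"] = str(genes_path)
        report_counts[name] = {
            "n_probes": len(probes),
            "n_genes": len(mapping.genes),
            "n_intergenic_probes": mapping.n_intergenic,
        }
    report = {
        "universe_size": len(signature.universe),
        "counts": report_counts,
    }
    report_path = out_dir / "signature_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["report"] = str(report_path)
    return manifest
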