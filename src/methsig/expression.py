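"""Differential expression per tissue pair and methylation-expression overlap.

Expression matrices are quantile-normalized, tested per pair with a
Welch t on log2 intensities, scored with the same DiffScore convention
as methylation (|13| ~ p 0.05), and called at a two-fold change.  The
promoter-hypomethylation / upregulation overlap is assessed with the
exact hypergeometric tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FormatError, InputError, ParameterError
from .io import ExpressionMatrix, SampleSheet
from .stats import (TailTestResult, diff_score_array, hypergeometric_tail,
                    moderated_t_table)

__all__ = [
    "DETable", "OverlapResult", "quantile_normalize", "call_de_pair",
    "intersect_de_common", "gene_list_overlap", "collapse_best_p",
]

FOLD_THRESHOLD = 2.0
SCORE_THRESHOLD = 13.0


@dataclass
class DETable:
    """Differential expression results for one tissue pair.

    ``data`` is indexed by feature with columns mean_invasive,
    mean_noninvasive (post-normalization linear means), fold_change
    (invasive / non-invasive), p_value, diff_score, call (up/down/none).
    """

    tissue: str
    data: pd.DataFrame

    def called(self, direction: str) -> frozenset:
        return frozenset(self.data.index[self.data["call"] == direction])


@dataclass(frozen=True)
class OverlapResult:
    overlap: frozenset
    test: TailTestResult


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization.

    Each column is replaced by the cross-column mean of the sorted
    values at its ranks; ties within a column receive the mean of their
    rank-range averages, so tied inputs stay tied.  A single-sample
    matrix is returned unchanged with a warning.
    """
    df = expr.data
    if df.shape[1] < 2:
        warnings.warn("quantile normalization skipped: single-sample matrix")
        return ExpressionMatrix(df.copy())
    if df.isna().to_numpy().any():
        raise FormatError("quantile normalization requires a complete matrix")
    values = df.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(ref)
        ranked[order] = ref
        # average the reference values across tie groups
        s = pd.Series(ranked)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def call_de_pair(expr: ExpressionMatrix, samples: SampleSheet, tissue: str,
                 fold_threshold: float = FOLD_THRESHOLD,
                 score_threshold: float = SCORE_THRESHOLD,
                 method: str = "moderated") -> DETable:
    """Differential expression for one tissue pair.

    Two-sided p on log2 intensities — empirical-Bayes moderated pooled t
    by default (variance information shared across genes, as needed for
    duplicate/triplicate arrays), plain Welch with ``method="welch"``.
    Calls require both the fold change (>= fold_threshold up,
    <= 1/fold_threshold down) and the DiffScore (|score| >
    score_threshold, i.e. p < ~0.05 at the default).
    """
    if fold_threshold <= 1.0:
        raise ParameterError("fold_threshold must exceed 1")
    if method not in ("moderated", "welch"):
        raise ParameterError(f"unknown method {method!r}")
    inv_ids = samples.samples_for(tissue, "invasive")
    non_ids = samples.samples_for(tissue, "non_invasive")
    missing = (set(inv_ids) | set(non_ids)) - set(expr.sample_ids)
    if missing:
        raise InputError(f"samples missing from expression matrix: {sorted(missing)}")
    if len(inv_ids) < 2 or len(non_ids) < 2:
        raise InputError(f"tissue {tissue!r} needs >= 2 samples per phenotype")

    x_inv = expr.data[inv_ids].to_numpy(dtype=float)
    x_non = expr.data[non_ids].to_numpy(dtype=float)
    tiny = 1e-8
    l_inv = np.log2(np.maximum(x_inv, tiny))
    l_non = np.log2(np.maximum(x_non, tiny))

    n1, n2 = l_inv.shape[1], l_non.shape[1]
    v1 = np.var(l_inv, axis=1, ddof=1) + 1e-12
    v2 = np.var(l_non, axis=1, ddof=1) + 1e-12
    diff = l_inv.mean(axis=1) - l_non.mean(axis=1)
    if method == "welch":
        se2 = v1 / n1 + v2 / n2
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        df_resid = float(n1 + n2 - 2)
        s2_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        _, p, _ = moderated_t_table(diff, s2_pooled, np.full_like(diff, df_resid),
                                    np.full_like(diff, n1), np.full_like(diff, n2))
    p = np.clip(p, 0.0, 1.0)
    p[diff == 0] = 1.0

    mean_inv = x_inv.mean(axis=1)
    mean_non = x_non.mean(axis=1)
    with np.errstate(divide="ignore"):
        fold = mean_inv / np.maximum(mean_non, tiny)
    score = diff_score_array(diff, p)

    up = (fold >= fold_threshold) & (score > score_threshold)
    down = (fold <= 1.0 / fold_threshold) & (score < -score_threshold)
    table = pd.DataFrame({
        "mean_invasive": mean_inv,
        "mean_noninvasive": mean_non,
        "fold_change": fold,
        "p_value": p,
        "diff_score": score,
        "call": np.where(up, "up", np.where(down, "down", "none")),
    }, index=expr.feature_ids)
    return DETable(tissue=tissue, data=table)


def intersect_de_common(tables) -> tuple[frozenset, frozenset]:
    """Features called up (resp. down) in every pair."""
    ups = [t.called("up") for t in tables]
    downs = [t.called("down") for t in tables]
    return frozenset.intersection(*ups), frozenset.intersection(*downs)


def gene_list_overlap(list_a, list_b, universe_size: int) -> OverlapResult:
    """Hypergeometric overlap significance of two gene lists.

    Symmetric in its arguments; p = P(overlap >= observed) when one list
    is drawn at random from a universe containing the other.
    """
    a, b = frozenset(list_a), frozenset(list_b)
    if max(len(a), len(b)) > universe_size:
        raise ParameterError("universe smaller than one of the lists")
    overlap = a & b
    test = hypergeometric_tail(universe_size, len(a), len(b), len(overlap))
    return OverlapResult(overlap=overlap, test=test)


def collapse_best_p(table: DETable, feature_to_gene) -> DETable:
    """Collapse platform probes to genes keeping each gene's smallest p.

    ``feature_to_gene`` maps feature ids to gene symbols; unmapped
    features are dropped.
    """
    df = table.data.copy()
    genes = df.index.map(lambda f: feature_to_gene.get(f))
    df = df[genes.notna()]
    df = df.assign(_gene=genes[genes.notna()])
    best = df.sort_values("p_value", kind="stable").groupby("_gene", sort=True).head(1)
    best = best.set_index("_gene")
    best.index.name = "gene"
    return DETable(tissue=table.tissue, data=best)
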