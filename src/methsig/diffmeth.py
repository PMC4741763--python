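"""Per-tissue-pair differential methylation testing and DMP calling.

Effect sizes (delta-beta) are computed on the beta scale as invasive
minus non-invasive group means; significance is tested on M-values,
where the noise is closer to Gaussian and homoscedastic.  The default
test is an empirical-Bayes moderated pooled t: each probe's variance is
shrunk toward a prior fitted across all probes, which is what makes
p < 0.001 calling workable with two or three cultures per line.  A plain
Welch t (no information sharing across probes) is available with
``method="welch"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, ParameterError
from .io import BetaMatrix, SampleSheet, beta_to_m
from .stats import bh_fdr, diff_score_array, moderated_t_table

__all__ = ["DMPTable", "test_pair", "call_dmps"]

#: default calling thresholds: |delta-beta| > 0.25 at p < 0.001
DELTA_THRESHOLD = 0.25
P_THRESHOLD = 0.001
Q_THRESHOLD = 0.05


@dataclass
class DMPTable:
    """Differential methylation results for one tissue pair.

    ``data`` is indexed by probe id with columns mean_beta_invasive,
    mean_beta_noninvasive, delta_beta, p_value, q_value, diff_score,
    direction, n_invasive, n_noninvasive.  ``delta_beta`` is invasive
    minus non-invasive, so hypomethylation in the invasive line is
    negative.
    """

    tissue: str
    data: pd.DataFrame
    n_excluded: int = 0
    method: str = "moderated"

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def tested_probes(self) -> frozenset:
        return frozenset(self.data.index)


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise (n, mean, variance) ignoring NaN; NaN where undefined."""
    finite = ~np.isnan(values)
    n = finite.sum(axis=1)
    filled = np.where(finite, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, filled.sum(axis=1) / np.maximum(n, 1), np.nan)
        sq = np.where(finite, (values - mean[:, None]) ** 2, 0.0)
        var = np.where(n >= 2, sq.sum(axis=1) / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


_VAR_FLOOR = 1e-12


def test_pair(beta: BetaMatrix, samples: SampleSheet, tissue: str,
              epsilon: float = 1e-6, method: str = "moderated") -> DMPTable:
    """Differential methylation for one tissue's invasive vs non-invasive pair.

    Probes with fewer than 2 non-missing values in either group are
    excluded and counted in ``n_excluded``.  Returns delta-beta on the
    beta scale, two-sided p on M-values (moderated pooled t by default,
    Welch with ``method="welch"``), BH q-values across all tested probes,
    and the Illumina-style DiffScore.
    """
    if method not in ("moderated", "welch"):
        raise ParameterError(f"unknown method {method!r}")
    inv_ids = samples.samples_for(tissue, "invasive")
    non_ids = samples.samples_for(tissue, "non_invasive")
    missing = (set(inv_ids) | set(non_ids)) - set(beta.sample_ids)
    if missing:
        raise InputError(f"samples missing from beta matrix: {sorted(missing)}")
    if len(inv_ids) < 2 or len(non_ids) < 2:
        raise InputError(f"tissue {tissue!r} needs >= 2 samples per phenotype")

    b_inv = beta.data[inv_ids].to_numpy(dtype=float)
    b_non = beta.data[non_ids].to_numpy(dtype=float)
    m_inv = beta_to_m(b_inv, epsilon)
    m_non = beta_to_m(b_non, epsilon)

    n1, mb_inv, _ = _group_stats(b_inv)
    n2, mb_non, _ = _group_stats(b_non)
    _, mm_inv, v1 = _group_stats(m_inv)
    _, mm_non, v2 = _group_stats(m_non)

    usable = (n1 >= 2) & (n2 >= 2)
    n_excluded = int((~usable).sum())
    idx = beta.probe_ids[usable]
    n1u, n2u = n1[usable].astype(float), n2[usable].astype(float)
    v1u = v1[usable] + _VAR_FLOOR
    v2u = v2[usable] + _VAR_FLOOR
    diff_m = mm_inv[usable] - mm_non[usable]
    delta_beta = mb_inv[usable] - mb_non[usable]

    if method == "welch":
        se2 = v1u / n1u + v2u / n2u
        t = diff_m / np.sqrt(se2)
        df = se2 ** 2 / ((v1u / n1u) ** 2 / (n1u - 1) + (v2u / n2u) ** 2 / (n2u - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        df_resid = n1u + n2u - 2.0
        s2_pooled = ((n1u - 1) * v1u + (n2u - 1) * v2u) / df_resid
        t, p, df = moderated_t_table(diff_m, s2_pooled, df_resid, n1u, n2u)
    p = np.clip(p, 0.0, 1.0)
    p[diff_m == 0] = 1.0

    table = pd.DataFrame({
        "mean_beta_invasive": mb_inv[usable],
        "mean_beta_noninvasive": mb_non[usable],
        "delta_beta": delta_beta,
        "p_value": p,
        "q_value": bh_fdr(p),
        "diff_score": diff_score_array(delta_beta, p),
        "direction": "none",
        "n_invasive": n1[usable],
        "n_noninvasive": n2[usable],
    }, index=idx)
    result = DMPTable(tissue=tissue, data=table, n_excluded=n_excluded, method=method)
    call_dmps(result)  # populate direction at the default thresholds
    return result


def call_dmps(table: DMPTable, delta_threshold: float = DELTA_THRESHOLD,
              p_threshold: float = P_THRESHOLD, mode: str = "raw_p",
              q_threshold: float = Q_THRESHOLD) -> tuple[frozenset, frozenset]:
    """Call hyper-/hypomethylated probes with strict thresholds.

    ``mode="raw_p"`` (default) requires |delta-beta| > delta_threshold and
    raw p < p_threshold; ``mode="fdr"`` uses BH q < q_threshold instead of
    the raw p.  Both inequalities are strict, so a delta-beta of exactly
    0.25 is never called.  Updates the table's ``direction`` column and
    returns (hyper, hypo) probe sets.
    """
    if not (0.0 < delta_threshold < 1.0):
        raise ParameterError(f"delta_threshold must lie in (0,1), got {delta_threshold}")
    if not (0.0 < p_threshold < 1.0) or not (0.0 < q_threshold < 1.0):
        raise ParameterError("p/q thresholds must lie in (0,1)")
    if mode not in ("raw_p", "fdr"):
        raise ParameterError(f"unknown calling mode {mode!r}")
    df = table.data
    sig = df["p_value"] < p_threshold if mode == "raw_p" else df["q_value"] < q_threshold
    hyper = sig & (df["delta_beta"] > delta_threshold)
    hypo = sig & (df["delta_beta"] < -delta_threshold)
    df["direction"] = np.where(hyper, "hyper", np.where(hypo, "hypo", "none"))
    return frozenset(df.index[hyper]), frozenset(df.index[hypo])


def write_dmp_table(table: DMPTable, path) -> None:
    """Serialise a DMP table as TSV with a stable column order."""
    cols = ["mean_beta_invasive", "mean_beta_noninvasive", "delta_beta",
            "p_value", "q_value", "diff_score", "direction",
            "n_invasive", "n_noninvasive"]
    table.data[cols].to_csv(path, sep="\t", index_label="probe_id",
                            float_format="%.6g")
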