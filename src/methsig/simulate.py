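"""Synthetic methylation + expression datasets with planted ground truth.

The generator emulates the study design the pipeline targets: three
tissue pairs of cancer lines (invasive vs non-invasive), 450K-style beta
values, a planted set of CpGs concordantly hypo-/hypermethylated across
all three pairs, tissue-specific differential probes as background, an
enhancer annotation with a realistic ~21% background rate, and an
expression matrix in which a configurable fraction of the planted
promoter-hypomethylated genes is upregulated at least two-fold in every
invasive line.

Noise is Gaussian on the M (log2-logit) scale and mapped back through the
logistic, which keeps betas inside (0, 1) and reproduces the shrinking
variance of beta values near the boundaries.  Every stage is a pure
function of (config, seed); child seeds are derived from the master seed
by fixed stream labels so stages are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import BetaMatrix, ExpressionMatrix, ProbeAnnotation, SampleSheet, m_to_beta, beta_to_m

__all__ = [
    "SimulationConfig", "SimulationTruth",
    "generate_annotation", "generate_methylation_dataset",
    "generate_expression_dataset", "simulate_dataset", "SimulatedDataset",
]

_REGION_5PRIME = ("TSS1500", "TSS200", "5UTR", "1stExon")
_REGION_OTHER = ("Body", "3UTR")
# Annotation, methylation and expression draw from separate child streams.
_STREAMS = {"classes": 11, "annotation": 23, "methylation": 37, "expression": 53}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults reproduce the targeted design: three tissue pairs with
    triplicate cultures (the last tissue's non-invasive line duplicate
    only), a planted |delta-beta| of 0.40, M-scale replicate noise of
    0.5, a 21% enhancer background with 47% enhancer prevalence among the
    planted common-hypo CpGs, and 80% methylation-expression concordance.
    """

    n_probes: int = 20_000
    tissues: tuple[str, str, str] = ("breast", "liver", "prostate")
    replicates: int = 3
    duplicate_line: bool = True  # last tissue, non-invasive: 2 replicates
    n_common_hypo: int = 300
    n_common_hyper: int = 300
    n_tissue_specific: int = 200
    effect_delta_beta: float = 0.40
    noise_sd_m: float = 0.5
    enhancer_fraction: float = 0.21
    promoter_fraction: float = 0.35
    enhancer_enrichment_in_hypo: float = 0.47
    intergenic_fraction: float = 0.10
    n_genes: int = 2_000
    concordance: float = 0.8
    expression_noise_sd_log2: float = 0.25
    expression_log2fc_range: tuple[float, float] = (1.5, 2.5)
    tissue_specific_expr_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_common_hypo + self.n_common_hyper + 3 * self.n_tissue_specific
        if planted > self.n_probes:
            raise ConfigError(
                f"planted probes ({planted}) exceed n_probes ({self.n_probes})")
        if len(self.tissues) != 3 or len(set(self.tissues)) != 3:
            raise ConfigError("exactly three distinct tissues are required")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        for name in ("enhancer_fraction", "promoter_fraction",
                     "enhancer_enrichment_in_hypo", "intergenic_fraction",
                     "concordance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if not (0.0 < self.effect_delta_beta <= 0.5):
            raise ConfigError("effect_delta_beta must lie in (0, 0.5]")
        n_enh = round(self.enhancer_fraction * self.n_probes)
        n_enh_hypo = round(self.enhancer_enrichment_in_hypo * self.n_common_hypo)
        if n_enh_hypo > n_enh:
            raise ConfigError("enhancer count among planted hypo probes exceeds total enhancer count")
        if n_enh - n_enh_hypo > self.n_probes - self.n_common_hypo:
            raise ConfigError("enhancer fraction infeasible outside planted hypo probes")
        if self.n_genes < self.n_common_hypo + self.n_common_hyper:
            raise ConfigError("need at least one dedicated gene per planted common probe")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class SimulationTruth:
    """Planted effects: which probes and genes differ, and by how much."""

    probe_class: pd.Series  # probe -> {common_hypo, common_hyper, tissue_specific:<t>, null}
    true_delta_beta: pd.DataFrame  # probes x tissues, invasive - non_invasive
    gene_log2fc: pd.DataFrame | None = None  # genes x tissues
    promoter_hypo_genes: frozenset = frozenset()
    concordant_up_genes: frozenset = frozenset()

    def probes_of_class(self, label: str) -> frozenset:
        return frozenset(self.probe_class.index[self.probe_class == label])


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def _planted_classes(config: SimulationConfig) -> pd.Series:
    """Deterministic probe-class assignment shared by all stages."""
    rng = config.rng("classes")
    probes = _probe_ids(config.n_probes)
    labels = np.array(["null"] * config.n_probes, dtype=object)
    order = rng.permutation(config.n_probes)
    cursor = 0
    labels[order[cursor:cursor + config.n_common_hypo]] = "common_hypo"
    cursor += config.n_common_hypo
    labels[order[cursor:cursor + config.n_common_hyper]] = "common_hyper"
    cursor += config.n_common_hyper
    for tissue in config.tissues:
        labels[order[cursor:cursor + config.n_tissue_specific]] = f"tissue_specific:{tissue}"
        cursor += config.n_tissue_specific
    return pd.Series(labels, index=probes, name="probe_class")


def generate_annotation(config: SimulationConfig) -> ProbeAnnotation:
    """Probe annotation with genes, region labels, islands and enhancers.

    Every gene receives at least one probe; each planted common probe
    gets a dedicated gene so promoter-level truth is unambiguous.  The
    global enhancer count is exact (round(enhancer_fraction * n_probes))
    and planted common-hypo probes are enhancer-flagged at the configured
    enrichment rate.
    """
    classes = _planted_classes(config)
    rng = config.rng("annotation")
    probes = classes.index
    n = config.n_probes

    is_hypo = (classes == "common_hypo").to_numpy()
    is_hyper = (classes == "common_hyper").to_numpy()
    planted_common = is_hypo | is_hyper

    genes = _gene_ids(config.n_genes)
    gene_of = np.array([None] * n, dtype=object)
    # dedicated genes for planted common probes, one gene per probe
    common_idx = np.flatnonzero(planted_common)
    for g_i, p_i in enumerate(common_idx):
        gene_of[p_i] = genes[g_i]
    remaining_genes = genes[len(common_idx):]
    other_idx = np.flatnonzero(~planted_common)
    other_idx = other_idx[rng.permutation(other_idx.size)]
    n_intergenic = int(round(config.intergenic_fraction * other_idx.size))
    intergenic_idx = other_idx[:n_intergenic]
    gene_carrying = other_idx[n_intergenic:]
    if remaining_genes and gene_carrying.size < len(remaining_genes):
        raise ConfigError("not enough probes to give every gene a probe")
    # guarantee coverage, then fill the rest at random
    for g_i, p_i in enumerate(gene_carrying[:len(remaining_genes)]):
        gene_of[p_i] = remaining_genes[g_i]
    rest = gene_carrying[len(remaining_genes):]
    if rest.size and remaining_genes:
        gene_of[rest] = rng.choice(np.array(remaining_genes, dtype=object), size=rest.size)
    elif rest.size:
        gene_of[rest] = rng.choice(np.array(genes, dtype=object), size=rest.size)

    has_gene = np.array([g is not None for g in gene_of])
    gene_frac = has_gene.mean()
    if config.promoter_fraction > gene_frac + 1e-12:
        raise ConfigError(
            f"promoter_fraction {config.promoter_fraction} exceeds the fraction "
            f"of gene-mapped probes ({gene_frac:.3f})")
    p_promoter = 0.0 if gene_frac == 0 else config.promoter_fraction / gene_frac
    promoter_draw = rng.random(n) < p_promoter

    gene_symbols, gene_region = [], []
    region_5p = rng.choice(len(_REGION_5PRIME), size=n)
    region_ot = rng.choice(len(_REGION_OTHER), size=n)
    for i in range(n):
        if not has_gene[i]:
            gene_symbols.append([])
            gene_region.append([])
        else:
            gene_symbols.append([gene_of[i]])
            if promoter_draw[i]:
                gene_region.append([_REGION_5PRIME[region_5p[i]]])
            else:
                gene_region.append([_REGION_OTHER[region_ot[i]]])

    # enhancer flags with exact global count and exact planted-hypo rate
    enhancer = np.zeros(n, dtype=bool)
    n_enh = round(config.enhancer_fraction * n)
    n_enh_hypo = min(round(config.enhancer_enrichment_in_hypo * config.n_common_hypo), n_enh)
    hypo_idx = np.flatnonzero(is_hypo)
    chosen_hypo = rng.choice(hypo_idx, size=n_enh_hypo, replace=False) if n_enh_hypo else np.array([], dtype=int)
    enhancer[chosen_hypo] = True
    non_hypo_idx = np.flatnonzero(~is_hypo)
    n_rest = n_enh - n_enh_hypo
    if n_rest:
        enhancer[rng.choice(non_hypo_idx, size=n_rest, replace=False)] = True

    island = rng.choice(["island", "shore", "shelf", "open_sea"], size=n,
                        p=[0.31, 0.23, 0.10, 0.36])
    chromosome = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    position = rng.integers(1, 150_000_000, size=n)

    df = pd.DataFrame({
        "chromosome": chromosome,
        "position": position,
        "gene_symbols": gene_symbols,
        "gene_region": gene_region,
        "island_relation": island,
        "enhancer": enhancer,
    }, index=probes)
    return ProbeAnnotation(df)


def _sample_sheet(config: SimulationConfig) -> SampleSheet:
    rows = []
    for t_i, tissue in enumerate(config.tissues):
        for phenotype in ("invasive", "non_invasive"):
            n_rep = config.replicates
            if (config.duplicate_line and phenotype == "non_invasive"
                    and t_i == len(config.tissues) - 1):
                n_rep = 2
            for r in range(1, n_rep + 1):
                tag = "inv" if phenotype == "invasive" else "noninv"
                rows.append({"sample_id": f"{tissue}_{tag}_{r}", "tissue": tissue,
                             "phenotype": phenotype, "replicate": r})
    return SampleSheet(pd.DataFrame(rows))


def _baseline_mixture(rng: np.random.Generator, size: int) -> np.ndarray:
    """Bimodal baseline betas: modes near 0.1 and 0.9 plus a uniform body."""
    comp = rng.choice(3, size=size, p=[0.35, 0.35, 0.30])
    out = np.empty(size)
    lo = comp == 0
    hi = comp == 1
    mid = comp == 2
    out[lo] = rng.beta(5, 45, size=int(lo.sum()))
    out[hi] = rng.beta(45, 5, size=int(hi.sum()))
    out[mid] = rng.uniform(0.05, 0.95, size=int(mid.sum()))
    return out


def generate_methylation_dataset(config: SimulationConfig
                                 ) -> tuple[BetaMatrix, SampleSheet, SimulationTruth]:
    """Beta matrix + sample sheet + truth with the planted signature.

    For planted probes the invasive and non-invasive group means differ
    by exactly +/- ``effect_delta_beta`` on the beta scale (sign by
    class); replicate values are logistic(M_groupmean + N(0, noise_sd_m)).
    """
    classes = _planted_classes(config)
    rng = config.rng("methylation")
    sheet = _sample_sheet(config)
    probes = classes.index
    n = config.n_probes
    delta = config.effect_delta_beta

    mean_noninv = pd.DataFrame(index=probes, columns=list(config.tissues), dtype=float)
    mean_inv = pd.DataFrame(index=probes, columns=list(config.tissues), dtype=float)

    is_hypo = (classes == "common_hypo").to_numpy()
    is_hyper = (classes == "common_hyper").to_numpy()
    # tissue-specific sign: one draw per probe, fixed across its tissue
    ts_sign = rng.choice([-1.0, 1.0], size=n)

    for tissue in config.tissues:
        base = _baseline_mixture(rng, n)
        noninv = base.copy()
        inv = base.copy()
        # planted common effects: re-anchor the non-invasive mean so the
        # shifted mean stays well inside (0, 1)
        noninv[is_hypo] = rng.uniform(0.5, 0.9, size=int(is_hypo.sum()))
        inv[is_hypo] = noninv[is_hypo] - delta
        noninv[is_hyper] = rng.uniform(0.1, 0.5, size=int(is_hyper.sum()))
        inv[is_hyper] = noninv[is_hyper] + delta
        is_ts = (classes == f"tissue_specific:{tissue}").to_numpy()
        if is_ts.any():
            sgn = ts_sign[is_ts]
            anchor = np.where(sgn < 0,
                              rng.uniform(0.5, 0.9, size=int(is_ts.sum())),
                              rng.uniform(0.1, 0.5, size=int(is_ts.sum())))
            noninv[is_ts] = anchor
            inv[is_ts] = anchor + sgn * delta
        mean_noninv[tissue] = noninv
        mean_inv[tissue] = inv

    data = {}
    for _, row in sheet.data.iterrows():
        means = mean_inv if row["phenotype"] == "invasive" else mean_noninv
        m = beta_to_m(means[row["tissue"]].to_numpy())
        noise = rng.normal(0.0, config.noise_sd_m, size=n)
        data[row["sample_id"]] = m_to_beta(m + noise)
    beta = BetaMatrix(pd.DataFrame(data, index=probes))

    truth = SimulationTruth(
        probe_class=classes,
        true_delta_beta=(mean_inv - mean_noninv).astype(float),
    )
    return beta, sheet, truth


def _promoter_hypo_genes(config: SimulationConfig, truth: SimulationTruth,
                         annotation: ProbeAnnotation) -> frozenset:
    from .signature import filter_promoter_probes, probes_to_genes
    hypo = truth.probes_of_class("common_hypo")
    promoter = filter_promoter_probes(hypo, annotation)
    return frozenset(probes_to_genes(promoter, annotation).genes)


def generate_expression_dataset(config: SimulationConfig, truth: SimulationTruth,
                                annotation: ProbeAnnotation | None = None,
                                ) -> tuple[dict[str, ExpressionMatrix], SimulationTruth]:
    """Per-tissue-pair expression matrices with planted concordant genes.

    A fraction ``concordance`` of the genes whose promoter CpGs carry the
    planted common hypomethylation receives a log2 fold change of at
    least 1 (drawn from ``expression_log2fc_range``) in the invasive
    samples of all three tissues.  Remaining genes are unchanged except
    for a small tissue-specific background.  Returns one matrix per
    tissue (samples match the methylation sample sheet) and the truth
    updated with per-gene log2 fold changes.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    rng = config.rng("expression")
    sheet = _sample_sheet(config)
    genes = _gene_ids(config.n_genes)
    gene_index = pd.Index(genes, name="gene")

    promoter_hypo = sorted(_promoter_hypo_genes(config, truth, annotation))
    n_conc = int(round(config.concordance * len(promoter_hypo)))
    concordant = (list(rng.choice(np.array(promoter_hypo, dtype=object), size=n_conc,
                                  replace=False)) if n_conc else [])
    concordant_set = frozenset(concordant)

    lfc = pd.DataFrame(0.0, index=gene_index, columns=list(config.tissues))
    lo, hi = config.expression_log2fc_range
    if lo < 1.0:
        raise ConfigError("expression_log2fc_range must keep planted genes >= 2-fold (log2fc >= 1)")
    for g in concordant:
        lfc.loc[g, :] = rng.uniform(lo, hi, size=len(config.tissues))
    # tissue-specific background changes among the remaining genes
    others = [g for g in genes if g not in concordant_set]
    n_ts = int(round(config.tissue_specific_expr_fraction * len(others)))
    for tissue in config.tissues:
        if n_ts == 0:
            continue
        picked = rng.choice(np.array(others, dtype=object), size=n_ts, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_ts)
        lfc.loc[picked, tissue] += signs * rng.uniform(1.0, 2.5, size=n_ts)

    base_log2 = rng.uniform(6.0, 12.0, size=len(genes))
    matrices: dict[str, ExpressionMatrix] = {}
    for tissue in config.tissues:
        tissue_offset = rng.normal(0.0, 0.5, size=len(genes))
        cols = {}
        for _, row in sheet.data[sheet.data["tissue"] == tissue].iterrows():
            shift = lfc[tissue].to_numpy() if row["phenotype"] == "invasive" else 0.0
            noise = rng.normal(0.0, config.expression_noise_sd_log2, size=len(genes))
            cols[row["sample_id"]] = np.power(2.0, base_log2 + tissue_offset + shift + noise)
        matrices[tissue] = ExpressionMatrix(pd.DataFrame(cols, index=gene_index))

    updated = replace_truth(truth, gene_log2fc=lfc,
                            promoter_hypo_genes=frozenset(promoter_hypo),
                            concordant_up_genes=concordant_set)
    return matrices, updated


def replace_truth(truth: SimulationTruth, **kw) -> SimulationTruth:
    return SimulationTruth(
        probe_class=truth.probe_class,
        true_delta_beta=truth.true_delta_beta,
        gene_log2fc=kw.get("gene_log2fc", truth.gene_log2fc),
        promoter_hypo_genes=kw.get("promoter_hypo_genes", truth.promoter_hypo_genes),
        concordant_up_genes=kw.get("concordant_up_genes", truth.concordant_up_genes),
    )


@dataclass
class SimulatedDataset:
    """Everything one run of the generator produces, bundled."""

    config: SimulationConfig
    annotation: ProbeAnnotation
    beta: BetaMatrix
    samples: SampleSheet
    expression: dict[str, ExpressionMatrix]
    truth: SimulationTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all three generator stages with consistent child seeds."""
    annotation = generate_annotation(config)
    beta, samples, truth = generate_methylation_dataset(config)
    expression, truth = generate_expression_dataset(config, truth, annotation)
    return SimulatedDataset(config=config, annotation=annotation, beta=beta,
                            samples=samples, expression=expression, truth=truth)
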