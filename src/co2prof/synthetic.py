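"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a three-condition microarray series (ambient /
elevated / high CO2, 3 biological replicates each) under the exact model
the moderated F-test fits: per-gene residual precision 1/sigma^2 drawn from
Gamma(shape a, scale b), replicate log2 signals Normal around per-condition
means, and a planted fraction of differentially expressed genes whose
condition means follow one of the 16 model profiles scaled by a log2
effect size.  Signals are exponentiated to the linear scale before
emission, matching what array normalization delivers.

Companion generators plant enrichment structure (annotation categories
whose membership is biased toward DE genes), an interaction catalog with a
high-betweenness bridge motif among same-profile DE genes, and qPCR plates
whose expected 2^-ddCt equals the planted fold change.

All randomness flows from one global seed through fixed per-generator
stream offsets (expression 0, annotations 1, qPCR 2), so stages are
reproducible independently of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet,
    ExpressionMatrix,
    InteractionCatalog,
    QpcrPlate,
    write_expression_matrix,
    write_gmt,
    write_qpcr_csv,
    write_sif,
)
from .profiles import ModelProfile, default_profiles

# stream-splitting offsets: default_rng([seed, offset])
_STREAM_EXPRESSION = 0
_STREAM_ANNOTATIONS = 1
_STREAM_QPCR = 2

_RELATION_TYPES = ("activation", "phosphorylation", "inhibition", "expression")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults mirror the desk-scale demo: 5,000 genes, 3 conditions x 3
    replicates, precision prior Gamma(a=3, scale b=0.5) (mean residual
    variance 1/(b(a-1)) = 1 on the log2 scale), 10% DE genes spread over
    the five historically significant profiles, and a planted log2 effect
    of 4 per profile unit step (four noise SDs, so ground truth is
    recoverable).
    """

    n_genes: int = 5000
    conditions: tuple[str, ...] = ("T0", "T1", "T2")
    reps_per_condition: int = 3
    rvm_a: float = 3.0
    rvm_b: float = 0.5
    de_fraction: float = 0.10
    profile_mix: dict[int, float] = field(
        default_factory=lambda: {12: 0.35, 16: 0.20, 10: 0.15, 6: 0.15, 5: 0.15}
    )
    effect_scale: float = 4.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    seed: int = 0
    # enrichment structure
    n_categories: int = 50
    category_size: int = 50
    n_planted_categories: int = 5
    planted_enrichment_odds: float = 20.0
    # interaction structure
    interaction_density: float = 2e-4
    bridge_clique_size: int = 6
    # qPCR structure
    ct_noise_sd: float = 0.1
    qpcr_reference_gene: str = "actin"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.reps_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        if len(self.conditions) < 2:
            raise ValueError("need >= 2 conditions")
        if not (self.rvm_a > 0 and self.rvm_b > 0):
            raise ValueError("prior parameters must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (0.0 <= self.interaction_density <= 1.0):
            raise ValueError("interaction_density must lie in [0, 1]")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")
        if self.profile_mix:
            w = sum(self.profile_mix.values())
            if not np.isclose(w, 1.0):
                raise ValueError(f"profile_mix weights sum to {w}, expected 1")

    def profiles(self) -> list[ModelProfile]:
        return default_profiles(len(self.conditions))


@dataclass
class TruthLabels:
    """Latent values behind a generated dataset."""

    genes: pd.DataFrame  # gene, is_de, profile, sigma2 + true_mean_<cond> columns
    conditions: tuple[str, ...]
    planted_categories: list[str] = field(default_factory=list)
    interaction_pairs: list[tuple[str, str]] = field(default_factory=list)
    bridge_gene: str | None = None

    @property
    def de_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_de"]])

    def true_log2_ratios(self, gene: str) -> np.ndarray:
        cols = [f"true_mean_{c}" for c in self.conditions]
        means = self.genes.loc[gene, cols].to_numpy(dtype=float)
        return means - means[0]


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Draw a seeded expression matrix and its ground truth.

    Per gene g: precision tau_g ~ Gamma(a, scale b), baseline mu_g ~
    Normal(baseline_log2_mean, baseline_log2_sd); DE genes get condition
    means mu_g + effect_scale * shape; every replicate log2 signal is
    Normal(condition mean, 1/tau_g) and emitted as 2**value.
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPRESSION])
    n = config.n_genes
    k = len(config.conditions)
    reps = config.reps_per_condition
    gene_ids = [f"g{i:05d}" for i in range(n)]

    sigma2 = 1.0 / rng.gamma(shape=config.rvm_a, scale=config.rvm_b, size=n)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    profile_by_id = {p.id: np.asarray(p.shape, dtype=float) for p in config.profiles()}
    if config.profile_mix:
        mix_ids = sorted(config.profile_mix)
        mix_w = np.array([config.profile_mix[i] for i in mix_ids])
    else:
        mix_ids = sorted(profile_by_id)
        mix_w = np.full(len(mix_ids), 1.0 / len(mix_ids))
    assigned_profiles = rng.choice(mix_ids, size=n_de, p=mix_w / mix_w.sum())

    true_means = np.tile(baseline[:, None], (1, k))
    profile_col = np.full(n, -1, dtype=int)
    for gi, pid in zip(de_idx, assigned_profiles):
        true_means[gi] += config.effect_scale * profile_by_id[int(pid)]
        profile_col[gi] = int(pid)

    noise = rng.normal(0.0, 1.0, size=(n, k * reps)) * np.sqrt(sigma2)[:, None]
    log2_signals = np.repeat(true_means, reps, axis=1) + noise
    signals = 2.0 ** log2_signals

    sample_ids = [
        f"{c}_r{r + 1}" for c in config.conditions for r in range(reps)
    ]
    matrix = ExpressionMatrix(
        signals=pd.DataFrame(signals, index=gene_ids, columns=sample_ids),
        condition_of_sample={
            s: c for c in config.conditions for s in sample_ids if s.startswith(f"{c}_")
        },
        condition_order=list(config.conditions),
        replicate_of_sample={s: int(s.rsplit("_r", 1)[1]) for s in sample_ids},
    )
    genes = pd.DataFrame(
        {
            "is_de": profile_col >= 0,
            "profile": [int(p) if p >= 0 else pd.NA for p in profile_col],
            "sigma2": sigma2,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    for ci, c in enumerate(config.conditions):
        genes[f"true_mean_{c}"] = true_means[:, ci]
    truth = TruthLabels(genes=genes, conditions=tuple(config.conditions))
    return matrix, truth


def generate_annotations(
    truth: TruthLabels, config: SyntheticConfig
) -> tuple[AnnotationSet, InteractionCatalog]:
    """Plant enrichment and interaction structure over the generated genes.

    Planted categories sample members with DE genes weighted
    ``planted_enrichment_odds`` : 1 over background; the rest are uniform.
    The interaction catalog holds a bridge motif — two cliques of
    same-profile DE genes joined only through one bridge gene, giving that
    gene the dominant betweenness — plus background relations covering
    ``interaction_density`` of the remaining ordered DE-gene pairs.
    Results are recorded back onto ``truth``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ANNOTATIONS])
    all_genes = np.array(truth.genes.index)
    is_de = truth.genes["is_de"].to_numpy(dtype=bool)

    categories: dict[str, tuple[str, frozenset[str]]] = {}
    planted: list[str] = []
    size = min(config.category_size, len(all_genes))
    for i in range(config.n_categories):
        cid = f"CAT{i:03d}"
        if i < config.n_planted_categories and is_de.any():
            weights = np.where(is_de, config.planted_enrichment_odds, 1.0)
            weights = weights / weights.sum()
            members = rng.choice(all_genes, size=size, replace=False, p=weights)
            planted.append(cid)
            desc = "planted enriched category"
        else:
            members = rng.choice(all_genes, size=size, replace=False)
            desc = "background category"
        categories[cid] = (desc, frozenset(members))
    annotations = AnnotationSet(namespace="synthetic", categories=categories)

    relations: list[tuple[str, str, str]] = []
    bridge_gene: str | None = None
    de_pool = list(all_genes[is_de])
    motif_genes: set[str] = set()
    if de_pool:
        # bridge motif among genes of the heaviest planted profile
        if config.profile_mix:
            top_profile = max(config.profile_mix, key=config.profile_mix.get)
        else:
            top_profile = None
        if top_profile is not None:
            pool = [
                g
                for g in de_pool
                if truth.genes.loc[g, "profile"] is not pd.NA
                and int(truth.genes.loc[g, "profile"]) == top_profile
            ]
        else:
            pool = de_pool
        need = 2 * config.bridge_clique_size + 1
        if len(pool) >= need:
            chosen = list(rng.choice(pool, size=need, replace=False))
            bridge_gene = chosen[0]
            left = chosen[1 : 1 + config.bridge_clique_size]
            right = chosen[1 + config.bridge_clique_size :]
            motif_genes = set(chosen)
            t = 0
            for side in (left, right):
                for g in side:
                    relations.append((bridge_gene, _RELATION_TYPES[t % 4], g))
                    t += 1
                for a_i in range(len(side)):
                    for b_i in range(a_i + 1, len(side)):
                        relations.append((side[a_i], _RELATION_TYPES[t % 4], side[b_i]))
                        t += 1
        # background relations among the remaining DE genes
        rest = [g for g in de_pool if g not in motif_genes]
        if len(rest) >= 2 and config.interaction_density > 0:
            n_pairs = len(rest) * (len(rest) - 1)
            n_draw = int(round(config.interaction_density * n_pairs))
            for t in range(n_draw):
                a_i, b_i = rng.choice(len(rest), size=2, replace=False)
                relations.append(
                    (rest[a_i], _RELATION_TYPES[int(rng.integers(4))], rest[b_i])
                )
    catalog = InteractionCatalog(relations=relations)
    truth.planted_categories = planted
    truth.interaction_pairs = [(s, t_) for s, _, t_ in catalog.relations]
    truth.bridge_gene = bridge_gene
    return annotations, catalog


def generate_qpcr(
    truth: TruthLabels, genes: Sequence[str], config: SyntheticConfig
) -> QpcrPlate:
    """Inverse-model qPCR plate: Ct = Ct0 - log2 fold(cond vs reference
    condition) + Normal(0, ct_noise_sd) noise; the reference gene's planted
    fold is 1 in every condition.

    Triplicate technical wells x 3 biological replicates per (gene,
    condition); the expected 2^-ddCt equals the planted fold change.
    """
    rng = np.random.default_rng([config.seed, _STREAM_QPCR])
    unknown = [g for g in genes if g not in truth.genes.index]
    if unknown:
        raise KeyError(f"genes not in truth: {unknown[:5]}")
    n_bio, n_tech = 3, 3
    rows = []
    targets = list(genes) + [config.qpcr_reference_gene]
    base_ct = {g: 24.0 for g in genes}
    base_ct[config.qpcr_reference_gene] = 20.0
    for g in targets:
        if g == config.qpcr_reference_gene:
            log2_fold = np.zeros(len(truth.conditions))
        else:
            log2_fold = truth.true_log2_ratios(g)
        for ci, cond in enumerate(truth.conditions):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = (
                        base_ct[g]
                        - log2_fold[ci]
                        + (rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0)
                    )
                    rows.append(
                        {"gene": g, "condition": cond, "bio_rep": b, "tech_rep": t, "ct": ct}
                    )
    wells = pd.DataFrame(rows)
    return QpcrPlate(wells=wells, reference_gene=config.qpcr_reference_gene)


def write_demo_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, str]:
    """Write a complete demo dataset (expression, sheet, GMT, SIF, qPCR,
    truth table) in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    annotations, catalog = generate_annotations(truth, config)
    qpcr_genes = truth.de_genes[: min(8, len(truth.de_genes))]
    paths = {
        "expression": str(out / "expression.tsv"),
        "sample_sheet": str(out / "samples.csv"),
        "annotations": str(out / "annotations.gmt"),
        "interactions": str(out / "interactions.sif"),
        "qpcr": str(out / "qpcr.csv"),
        "truth": str(out / "truth.tsv"),
    }
    write_expression_matrix(matrix, paths["expression"], paths["sample_sheet"])
    write_gmt(annotations, paths["annotations"])
    write_sif(catalog, paths["interactions"])
    if qpcr_genes:
        write_qpcr_csv(generate_qpcr(truth, qpcr_genes, config), paths["qpcr"])
    truth_out = truth.genes.copy()
    truth_out["profile"] = [
        "" if p is pd.NA else str(p) for p in truth_out["profile"]
    ]
    truth_out.to_csv(paths["truth"], sep="\t", float_format="%.10g")
    return paths
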