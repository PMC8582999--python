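"""Synthetic exon-level count data with known truth.

The generator emulates the statistical structure that feature-level DE
testing has to cope with:

* negative-binomial marginal counts per exon with a common dispersion,
* positive within-gene correlation, produced by a shared multiplicative
  lognormal random effect per (gene, sample) — exons of one gene rise and
  fall together, which is what makes naive p-value combination
  anti-conservative,
* per-sample sequencing-depth factors (log-uniform over [0.5, 2]) so that
  RLE normalization is exercised non-trivially, and
* three regulation patterns for DE genes: ``uniform`` (all exons shifted by
  the same log2 effect), ``partial`` (only k of K exons shifted), and
  ``discordant`` (some exons up, some down, with baselines balanced so the
  gene-level total is unchanged in expectation — the pattern that summed-count
  gene-level testing cannot see).

The mean model for exon k of gene g in sample j is::

    mu = depth_j * base_gk * L_gj * fold_gk(group_j)

with ``L_gj`` lognormal, mean 1, variance chosen so that the expected count
correlation between two exons of one gene approaches the configured ``rho``
for well-expressed exons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import CountMatrix, FeatureMap

__all__ = ["SimConfig", "SimTruth", "simulate", "make_discordant_gene"]

PATTERNS = ("uniform", "partial", "discordant")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a two-group bulk RNA-seq experiment of moderate size:
    14 samples per group, exon counts in the tens-to-hundreds, NB dispersion
    0.1 and strong within-gene correlation (rho = 0.7), with 10% of genes DE
    at a log2 effect of 1.
    """

    n_genes: int = 1000
    exons_per_gene: object = (2, 10)  # int for fixed K, (lo, hi) inclusive range
    n_samples: int = 14  # per group
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    exon_profile_log_sd: float = 0.5
    dispersion: float = 0.1
    rho: float = 0.7
    de_fraction: float = 0.1
    pattern: str = "uniform"
    effect_log2: float = 1.0
    partial_k: int = 2
    discordant_up: int | None = None  # default: ~60% of exons up
    discordant_down: int | None = None  # default: ~40% down
    depth_range: tuple = (0.5, 2.0)
    group_labels: tuple = ("group1", "group2")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    genes: pd.DataFrame  # index gene_id: is_de, pattern
    exon_log2fc: pd.Series  # index feature_id: true per-exon log2FC

    @property
    def de_genes(self) -> pd.Index:
        return self.genes.index[self.genes["is_de"]]


def make_discordant_gene(K: int, k_up: int, k_down: int,
                         effect: float) -> np.ndarray:
    """Per-exon log2FC vector of a discordant gene: k_up exons at +effect,
    k_down at −effect, the rest at 0.

    The generator balances the baselines of the down-regulated exons so that
    the count-weighted mean effect is ~0 and the gene-level summed counts are
    unchanged in expectation (a fold f up adds more counts than a fold 1/f
    down removes, so equal baselines cannot cancel).
    """
    if k_up + k_down > K:
        raise ValueError(f"infeasible split: {k_up} up + {k_down} down > {K} exons")
    if k_up < 0 or k_down < 0:
        raise ValueError("exon counts must be nonnegative")
    lfc = np.zeros(K)
    lfc[:k_up] = effect
    lfc[k_up:k_up + k_down] = -effect
    return lfc


def _balance_discordant(base: np.ndarray, lfc: np.ndarray) -> np.ndarray:
    """Rescale baselines of down-regulated exons so the expected total count
    change of the gene is exactly zero."""
    up = lfc > 0
    down = lfc < 0
    if not up.any() or not down.any():
        return base
    gain = float(np.sum(base[up] * (2.0 ** lfc[up] - 1.0)))
    loss_unit = float(np.sum(base[down] * (1.0 - 2.0 ** lfc[down])))
    if loss_unit <= 0:
        return base
    out = base.copy()
    out[down] *= gain / loss_unit
    return out


def _variance_split(rho: float, dispersion: float) -> tuple:
    """Split the marginal NB dispersion into shared and exon-specific parts.

    The shared (gene, sample) lognormal effect L carries variance
    ``v = rho * dispersion`` and the conditional NB dispersion is
    ``alpha_c = (dispersion − v) / (1 + v)``, so the marginal excess
    dispersion of every exon equals ``dispersion`` exactly
    (``alpha_c (1 + v) + v``) while the count correlation between two
    well-expressed exons of one gene approaches ``v / dispersion = rho``.
    Returns ``(sigma, alpha_c)`` with sigma the lognormal scale.
    """
    if rho <= 0 or dispersion <= 0:
        return 0.0, dispersion
    v = rho * dispersion
    alpha_c = (dispersion - v) / (1.0 + v)
    return float(np.sqrt(np.log1p(v))), float(alpha_c)


def _draw_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate(config: SimConfig):
    """Generate (CountMatrix, FeatureMap, SimTruth) under ``config``.

    Deterministic given ``config.seed``.  DE genes are the first
    ``round(de_fraction * n_genes)`` genes (the truth table records them); the
    regulation direction of uniform and partial genes alternates up/down.
    """
    rng = np.random.default_rng(config.seed)
    n_de = int(round(config.de_fraction * config.n_genes))

    if isinstance(config.exons_per_gene, int):
        ks = np.full(config.n_genes, config.exons_per_gene)
    else:
        lo, hi = config.exons_per_gene
        ks = rng.integers(lo, hi + 1, size=config.n_genes)

    n = config.n_samples
    s_total = 2 * n
    lo_d, hi_d = config.depth_range
    depth = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), size=s_total))
    group = np.array([config.group_labels[0]] * n + [config.group_labels[1]] * n)
    condition = (group == config.group_labels[1]).astype(float)
    sample_ids = [f"s{j + 1:02d}" for j in range(s_total)]

    sigma, alpha_c = _variance_split(config.rho, config.dispersion)

    feature_ids, gene_of_feature, lfc_all = [], [], []
    blocks = []
    gene_rows = []
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:05d}"
        K = int(ks[g])
        base_gene = np.exp(rng.normal(config.baseline_log_mean,
                                      config.baseline_log_sd))
        base = base_gene * np.exp(rng.normal(0.0, config.exon_profile_log_sd,
                                             size=K))
        is_de = g < n_de
        lfc = np.zeros(K)
        if is_de:
            sign = 1.0 if g % 2 == 0 else -1.0
            if config.pattern == "uniform":
                lfc[:] = sign * config.effect_log2
            elif config.pattern == "partial":
                k = min(config.partial_k, K)
                chosen = rng.choice(K, size=k, replace=False)
                lfc[chosen] = sign * config.effect_log2
            else:  # discordant
                k_up = config.discordant_up
                k_down = config.discordant_down
                if k_up is None:
                    k_up = max(1, int(round(0.6 * K)))
                if k_down is None:
                    k_down = max(1, min(K - k_up, int(round(0.4 * K))))
                pattern_lfc = make_discordant_gene(K, k_up, k_down,
                                                   config.effect_log2)
                perm = rng.permutation(K)
                lfc = pattern_lfc[perm]
                base = _balance_discordant(base, lfc)

        if sigma > 0:
            L = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=s_total))
        else:
            L = np.ones(s_total)
        fold = 2.0 ** (np.outer(lfc, condition))  # K × S
        mu = depth[None, :] * L[None, :] * base[:, None] * fold
        blocks.append(_draw_counts(rng, mu, alpha_c))

        ids = [f"{gene_id}:E{k + 1:03d}" for k in range(K)]
        feature_ids.extend(ids)
        gene_of_feature.extend([gene_id] * K)
        lfc_all.extend(lfc)
        gene_rows.append((gene_id, is_de,
                          config.pattern if is_de else "none"))

    counts = pd.DataFrame(np.vstack(blocks), index=feature_ids,
                          columns=sample_ids)
    cm = CountMatrix(counts, pd.Series(group, index=sample_ids, name="group"))
    fm = FeatureMap(pd.Series(gene_of_feature, index=feature_ids), level="exon")
    truth = SimTruth(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "is_de", "pattern"]
                           ).set_index("gene_id"),
        exon_log2fc=pd.Series(lfc_all, index=feature_ids, name="log2fc"),
    )
    return cm, fm, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
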