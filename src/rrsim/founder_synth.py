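"""Synthetic founders, trait architectures, and recombination maps.

This module makes the whole framework self-contained: instead of a real
inbred panel it generates a founder population of diploid SNP
haplotypes, a ground-truth effect architecture calibrated so that the
additive effects sum to 30, the positive dominance effects to 20, and
the negative dominance effects to -5 (both for the observed markers and
for the full genome), and per-interval recombination frequencies.

Defaults mirror a maize-scale setting: N = 369 founders, L = 1,000
observed markers embedded in an L-bar = 10,000-locus genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_core import FULL, Population, TraitArchitecture


@dataclass
class RecombinationMap:
    """Recombination frequencies per adjacent-locus interval.

    ``r_full`` has one entry per interval of the full genome
    (length L-bar - 1); ``r_obs`` is the induced map between consecutive
    observed markers (length L - 1), obtained by folding the intervening
    full-genome intervals with the no-interference combination
    r12 = r1(1-r2) + r2(1-r1).
    """

    r_obs: np.ndarray
    r_full: np.ndarray

    def __post_init__(self) -> None:
        self.r_obs = np.asarray(self.r_obs, dtype=float)
        self.r_full = np.asarray(self.r_full, dtype=float)
        for name, r in (("r_obs", self.r_obs), ("r_full", self.r_full)):
            if r.size and (r.min() < 0 or r.max() > 0.5):
                raise ValueError(f"{name} entries must lie in [0, 0.5]")

    def for_scope(self, scope: str) -> np.ndarray:
        return self.r_full if scope == FULL else self.r_obs


@dataclass
class SynthesisConfig:
    """Knobs of the synthetic founder generator.

    ``n_founders``/``n_observed``/``n_full`` default to the 369 / 1,000 /
    10,000 study scale.  ``maf_range`` bounds the per-locus minor-allele
    frequency.  The three effect sums are the default calibration
    targets; ``effect_sparsity_dom`` is the fraction of loci carrying a
    nonzero dominance effect (additive effects are dense by default).
    """

    n_founders: int = 369
    n_observed: int = 1000
    n_full: int = 10000
    maf_range: tuple[float, float] = (0.05, 0.5)
    additive_sum: float = 30.0
    dominance_pos_sum: float = 20.0
    dominance_neg_sum: float = -5.0
    effect_sparsity_add: float = 1.0
    effect_sparsity_dom: float = 0.1
    neg_dominance_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_full < self.n_observed:
            raise ValueError("n_full must be >= n_observed")
        if min(self.n_founders, self.n_observed) < 2:
            raise ValueError("need at least 2 founders and 2 observed loci")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (self.dominance_pos_sum >= 0.0 >= self.dominance_neg_sum):
            raise ValueError("dominance sums must satisfy pos >= 0 >= neg")
        if self.effect_sparsity_dom == 0.0 and (
            self.dominance_pos_sum != 0.0 or self.dominance_neg_sum != 0.0
        ):
            raise ValueError("zero dominance sparsity is incompatible with nonzero dominance sums")
        if not (0 < self.effect_sparsity_add <= 1 and 0 <= self.effect_sparsity_dom <= 1):
            raise ValueError("sparsities must lie in (0,1] / [0,1]")


def _rng(cfg_or_rng) -> np.random.Generator:
    if isinstance(cfg_or_rng, np.random.Generator):
        return cfg_or_rng
    return np.random.default_rng(cfg_or_rng)


def generate_founder_haplotypes(
    cfg: SynthesisConfig, rng: np.random.Generator | None = None
) -> Population:
    """Sample N diploid founders over the full genome.

    Each locus draws a major-allele frequency from the complement of
    ``maf_range``; haplotype alleles are independent Bernoulli draws per
    locus (linkage disequilibrium builds up only through subsequent
    meiosis).
    """
    rng = _rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.maf_range
    major_freq = 1.0 - rng.uniform(lo, hi, size=cfg.n_full)
    geno = (
        rng.random((cfg.n_founders, cfg.n_full, 2)) < major_freq[None, :, None]
    ).astype(np.int8)
    return Population(genotypes=geno, scope=FULL, pool_label="raw")


def _sparse_exponential(
    n: int, sparsity: float, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative long-tailed magnitudes on a sparse support (>=1 nonzero)."""
    k = max(1, int(round(sparsity * n)))
    support = rng.choice(n, size=k, replace=False)
    out = np.zeros(n)
    out[support] = rng.exponential(1.0, size=k)
    if out.sum() == 0.0:  # pathological exponential draw of all zeros
        out[support] = 1.0
    return out


def _rescale(vec: np.ndarray, target: float) -> np.ndarray:
    """Scale a one-signed vector so it sums exactly to ``target``."""
    s = vec.sum()
    if target == 0.0:
        return np.zeros_like(vec)
    if s == 0.0:
        raise ValueError("cannot rescale an all-zero vector to a nonzero sum")
    return vec * (target / s)


def _calibrated_effects(
    n: int, cfg: SynthesisConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One calibrated (additive, dominance) pair of length ``n``."""
    alpha = _rescale(_sparse_exponential(n, cfg.effect_sparsity_add, rng), cfg.additive_sum)
    beta = np.zeros(n)
    if cfg.effect_sparsity_dom > 0:
        need_pos = cfg.dominance_pos_sum != 0.0
        need_neg = cfg.dominance_neg_sum != 0.0
        k = max(int(need_pos) + int(need_neg), int(round(cfg.effect_sparsity_dom * n)))
        support = rng.choice(n, size=min(k, n), replace=False)
        mags = rng.exponential(1.0, size=support.size)
        mags[mags == 0.0] = 1.0
        # each required sign gets at least one support locus
        n_neg = int(np.clip(
            rng.binomial(support.size, cfg.neg_dominance_fraction),
            int(need_neg),
            support.size - int(need_pos),
        ))
        pos_part = np.zeros(n)
        neg_part = np.zeros(n)
        neg_idx = support[:n_neg] if need_neg else support[:0]
        pos_idx = support[n_neg:]
        neg_part[neg_idx] = -mags[:n_neg]
        pos_part[pos_idx] = mags[n_neg:]
        if need_pos:
            pos_part = _rescale(pos_part, cfg.dominance_pos_sum)
        if need_neg:
            neg_part = _rescale(neg_part, cfg.dominance_neg_sum)
        beta = pos_part + neg_part
    return alpha, beta


def generate_trait_architecture(
    cfg: SynthesisConfig, rng: np.random.Generator | None = None
) -> TraitArchitecture:
    """Draw ground-truth effects and the observed-marker index map.

    Effect magnitudes are exponential on a sparse support, then rescaled
    so the observed-basis vectors AND the full-genome vectors each hit
    the calibration sums exactly.  Observed markers sit at a uniform
    random subset of the full genome.
    """
    rng = _rng(cfg.seed) if rng is None else rng
    index_map = np.sort(rng.choice(cfg.n_full, size=cfg.n_observed, replace=False))

    alpha_obs, beta_obs = _calibrated_effects(cfg.n_observed, cfg, rng)
    alpha_full, beta_full = _calibrated_effects(cfg.n_full, cfg, rng)

    hidden_mask = np.ones(cfg.n_full, dtype=bool)
    hidden_mask[index_map] = False
    return TraitArchitecture(
        additive_obs=alpha_obs,
        dominance_obs=beta_obs,
        additive_hidden=alpha_full[hidden_mask],
        dominance_hidden=beta_full[hidden_mask],
        observed_index_map=index_map,
        additive_obs_full=alpha_full[index_map],
        dominance_obs_full=beta_full[index_map],
    )


def combine_recombination(rates: np.ndarray) -> float:
    """Fold adjacent interval rates with r12 = r1(1-r2) + r2(1-r1).

    This is the probability of an odd number of crossovers across the
    combined span under independent per-interval crossover decisions.
    """
    acc = 0.0
    for r in np.asarray(rates, dtype=float):
        acc = acc * (1.0 - r) + r * (1.0 - acc)
    return acc


def derive_observed_map(r_full: np.ndarray, observed_index_map: np.ndarray) -> np.ndarray:
    """Aggregate full-genome intervals into between-marker frequencies."""
    idx = np.asarray(observed_index_map, dtype=np.intp)
    return np.array(
        [combine_recombination(r_full[idx[j] : idx[j + 1]]) for j in range(idx.size - 1)]
    )


def generate_recombination_map(
    cfg: SynthesisConfig,
    observed_index_map: np.ndarray,
    method: str = "uniform",
    rng: np.random.Generator | None = None,
    expected_crossovers: float = 15.0,
) -> RecombinationMap:
    """Draw per-interval recombination frequencies for the full genome.

    ``expected_crossovers`` is the expected number of source-homolog
    switches per meiosis summed over the whole genome (default 15, a
    maize-like total map length of roughly ten chromosomes of 1.5
    Morgans); the per-interval mean rate is derived from it, so genomes
    of different locus counts share a comparable map length.

    method="uniform"
        Each interval rate is uniform on [0, 2*mean] (clipped at 0.5).
    method="truncate-largest"
        Draw candidate rates for twice as many intervals as needed and
        keep the largest L-bar - 1, biasing toward well-separated loci.
    """
    rng = _rng(cfg.seed + 1) if rng is None else rng
    n_int = cfg.n_full - 1
    mean_rate = min(expected_crossovers / n_int, 0.25)
    if method == "uniform":
        r_full = np.clip(rng.uniform(0.0, 2.0 * mean_rate, size=n_int), 0.0, 0.5)
    elif method == "truncate-largest":
        cand = np.clip(rng.uniform(0.0, 2.0 * mean_rate, size=2 * n_int), 0.0, 0.5)
        r_full = np.sort(cand)[-n_int:]
        rng.shuffle(r_full)
    else:
        raise ValueError(f"unknown method {method!r}")
    r_obs = derive_observed_map(r_full, observed_index_map)
    return RecombinationMap(r_obs=r_obs, r_full=r_full)


def make_homozygous_founders(pop: Population, rng: np.random.Generator) -> Population:
    """Duplicate one uniformly chosen gamete of every individual."""
    pick = rng.integers(0, 2, size=pop.n)
    hap = np.take_along_axis(pop.genotypes, pick[:, None, None], axis=2)
    geno = np.repeat(hap, 2, axis=2)
    return Population(
        genotypes=geno,
        ids=list(pop.ids),
        scope=pop.scope,
        pool_label=pop.pool_label,
        homozygous=True,
    )


@dataclass
class SyntheticStudy:
    """A founder population plus its architecture and recombination map."""

    config: SynthesisConfig
    founders: Population
    architecture: TraitArchitecture
    recomb_map: RecombinationMap


def synthesize_study(
    cfg: SynthesisConfig, map_method: str = "uniform", expected_crossovers: float = 15.0
) -> SyntheticStudy:
    """One-call generation of founders + architecture + map from a seed."""
    rng = _rng(cfg.seed)
    founders = generate_founder_haplotypes(cfg, rng)
    arch = generate_trait_architecture(cfg, rng)
    rmap = generate_recombination_map(
        cfg, arch.observed_index_map, method=map_method, rng=rng,
        expected_crossovers=expected_crossovers,
    )
    return SyntheticStudy(config=cfg, founders=founders, architecture=arch, recomb_map=rmap)


def desk_synthesis_config(seed: int = 0, **overrides) -> SynthesisConfig:
    """A scaled-down genome for interactive runs and tests.

    60 founders over 2,000 loci with 200 observed markers — the same
    10:1 hidden-to-observed ratio and per-meiosis map length as the
    default scale, so scaled runs preserve the qualitative behaviour of
    the full study.
    """
    base = dict(n_founders=60, n_observed=200, n_full=2000, seed=seed)
    base.update(overrides)
    return SynthesisConfig(**base)
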