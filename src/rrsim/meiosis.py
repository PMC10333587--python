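"""Meiosis: gamete formation, crossing, and homozygote conversion.

Crossovers follow the per-interval independent-switch (Markov) model:
a gamete starts on a uniformly chosen homolog and switches its source
homolog between loci j and j+1 with probability r_j, independently per
interval.  There is no crossover interference, mutation, or gene
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_core import Population


@dataclass
class Gamete:
    """One haploid product of meiosis with its crossover-switch count."""

    haplotype: np.ndarray
    origin_switches: int


def _check_rates(r: np.ndarray, n_loci: int) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (n_loci - 1,):
        raise ValueError(f"need {n_loci - 1} interval rates, got shape {r.shape}")
    if r.size and (r.min() < 0 or r.max() > 0.5):
        raise ValueError("recombination rates must lie in [0, 0.5]")
    return r


def _sample_sources(
    n_gametes: int, r: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Source-homolog indicator per (gamete, locus) and switch counts."""
    start = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    switches = (rng.random((n_gametes, r.size)) < r[None, :]).astype(np.int8)
    # parity of switch prefix decides the source homolog at each locus
    source = np.concatenate(
        [start[:, None], (start[:, None] + np.cumsum(switches, axis=1)) % 2], axis=1
    ).astype(np.int8)
    return source, switches.sum(axis=1)


def make_gamete(genotype: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> Gamete:
    """Recombine one individual's two homologs into a single gamete."""
    genotype = np.asarray(genotype)
    if genotype.ndim != 2 or genotype.shape[1] != 2:
        raise ValueError("genotype must have shape (L, 2)")
    r = _check_rates(r, genotype.shape[0])
    source, n_switch = _sample_sources(1, r, rng)
    hap = genotype[np.arange(genotype.shape[0]), source[0]]
    return Gamete(haplotype=hap.astype(np.int8), origin_switches=int(n_switch[0]))


def make_gametes(genotype: np.ndarray, r: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent gametes from one parent, shape (n, L)."""
    genotype = np.asarray(genotype)
    r = _check_rates(r, genotype.shape[0])
    source, _ = _sample_sources(n, r, rng)
    return genotype[np.arange(genotype.shape[0])[None, :], source].astype(np.int8)


def cross(
    parent1: np.ndarray, parent2: np.ndarray, r: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring genotype: one independent gamete from each parent."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    if p1.shape != p2.shape:
        raise ValueError("parents must share genome scope (shapes differ)")
    g1 = make_gamete(p1, r, rng).haplotype
    g2 = make_gamete(p2, r, rng).haplotype
    return np.stack([g1, g2], axis=1)


def cross_many(
    parent1: np.ndarray,
    parent2: np.ndarray,
    r: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n_offspring`` independent offspring of one pair, shape (n, L, 2)."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    if p1.shape != p2.shape:
        raise ValueError("parents must share genome scope (shapes differ)")
    g1 = make_gametes(p1, r, n_offspring, rng)
    g2 = make_gametes(p2, r, n_offspring, rng)
    return np.stack([g1, g2], axis=2)


def self_cross(genotype: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One selfing round: cross an individual with itself."""
    return cross(genotype, genotype, r, rng)


def doubled_haploid(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Duplicate one uniformly chosen existing homolog (single-step DH)."""
    genotype = np.asarray(genotype)
    hap = genotype[:, rng.integers(0, 2)]
    return np.stack([hap, hap], axis=1)


def doubled_haploid_meiotic(
    genotype: np.ndarray, r: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """DH variant that duplicates a freshly recombined meiotic gamete."""
    hap = make_gamete(genotype, r, rng).haplotype
    return np.stack([hap, hap], axis=1)


def doubled_haploid_population(
    pop: Population,
    rng: np.random.Generator,
    r: np.ndarray | None = None,
    meiotic: bool = False,
) -> Population:
    """Convert every individual of a population to a homozygous line."""
    if meiotic:
        if r is None:
            raise ValueError("meiotic DH needs a recombination-rate vector")
        geno = np.stack(
            [doubled_haploid_meiotic(pop.genotypes[i], r, rng) for i in range(pop.n)]
        )
    else:
        pick = rng.integers(0, 2, size=pop.n)
        hap = np.take_along_axis(pop.genotypes, pick[:, None, None], axis=2)
        geno = np.repeat(hap, 2, axis=2)
    return Population(
        genotypes=geno,
        ids=[f"{i}.dh" for i in pop.ids],
        scope=pop.scope,
        pool_label=pop.pool_label,
        homozygous=True,
    )
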