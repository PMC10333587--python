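"""Mating designs: pairing selected parents and producing progeny.

Given 2K selected parents sorted by decreasing predicted GEBV, two
perfect-matching designs are supported:

* adjacent — rank 1 with rank 2, rank 3 with rank 4, ...: concentrates
  the best material in few crosses;
* complementary — rank i with rank K+i: every top-half parent meets a
  bottom-half parent, betting on complementary favorable alleles.

Each pair is crossed to produce S heterozygous progeny by meiosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .genome_core import Population
from .meiosis import cross_many


@dataclass
class MatingPlan:
    """An ordered perfect matching on 2K parents, plus progeny count."""

    pairs: list[tuple[Hashable, Hashable]]
    progeny_per_pair: int = 1

    def __post_init__(self) -> None:
        flat = [p for pair in self.pairs for p in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("each parent may appear in exactly one pair")
        if self.progeny_per_pair < 1:
            raise ValueError("progeny_per_pair must be >= 1")


def _check_even(sorted_ids: Sequence[Hashable]) -> list[Hashable]:
    ids = list(sorted_ids)
    if len(ids) == 0 or len(ids) % 2:
        raise ValueError("need a positive even number of sorted parents")
    return ids


def pair_adjacent(sorted_ids: Sequence[Hashable], progeny_per_pair: int = 1) -> MatingPlan:
    """Pair consecutive ranks: (1,2), (3,4), ..., (2K-1, 2K)."""
    ids = _check_even(sorted_ids)
    pairs = [(ids[i], ids[i + 1]) for i in range(0, len(ids), 2)]
    return MatingPlan(pairs=pairs, progeny_per_pair=progeny_per_pair)


def pair_complementary(sorted_ids: Sequence[Hashable], progeny_per_pair: int = 1) -> MatingPlan:
    """Pair rank i with rank K+i for i = 1..K."""
    ids = _check_even(sorted_ids)
    k = len(ids) // 2
    pairs = [(ids[i], ids[k + i]) for i in range(k)]
    return MatingPlan(pairs=pairs, progeny_per_pair=progeny_per_pair)


MATING_DESIGNS = {"adjacent": pair_adjacent, "complementary": pair_complementary}


def execute_matings(
    plan: MatingPlan, pop: Population, r: np.ndarray, rng: np.random.Generator
) -> Population:
    """Cross every pair to produce K*S progeny carrying pair provenance."""
    id_index = {pid: i for i, pid in enumerate(pop.ids)}
    missing = [p for pair in plan.pairs for p in pair if p not in id_index]
    if missing:
        raise KeyError(f"parents not in population: {missing}")
    geno_blocks = []
    ids = []
    for n_pair, (p1, p2) in enumerate(plan.pairs):
        off = cross_many(
            pop.genotypes[id_index[p1]], pop.genotypes[id_index[p2]], r, plan.progeny_per_pair, rng
        )
        geno_blocks.append(off)
        ids.extend(f"{p1}x{p2}.{s}" for s in range(plan.progeny_per_pair))
    return Population(
        genotypes=np.concatenate(geno_blocks, axis=0),
        ids=ids,
        scope=pop.scope,
        pool_label=pop.pool_label,
        homozygous=False,
    )
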