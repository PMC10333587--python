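"""Genome representation and breeding-value arithmetic.

The simulator works on diploid, biallelic SNP genomes coded as binary
tensors of shape ``(N, L, 2)``: entry 1 is the major allele, 0 the minor
allele.  Two genome scopes exist: the *observed* scope holds only the L
marker loci visible to prediction and selection, while the *full* scope
holds all L-bar loci (markers plus hidden QTL) used by the opaque
phenotype simulator.

A genomic estimated breeding value (GEBV) is the linear score

    v_i = sum_j alpha_j * g_ij + sum_j beta_j * d_ij

where ``g_ij`` counts major alleles (0/1/2) and ``d_ij`` indicates a
heterozygote.  Dominance effects therefore act only on heterozygous
loci, which is how heterosis enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Scope = Literal["observed", "full"]
SimulatorMode = Literal["transparent", "opaque"]

OBSERVED = "observed"
FULL = "full"
TRANSPARENT = "transparent"
OPAQUE = "opaque"


class ScopeError(ValueError):
    """Raised when a population's genome scope does not match an operation."""


@dataclass
class Population:
    """A diploid population over one linear genome.

    Parameters
    ----------
    genotypes
        Binary tensor ``(N, L_scope, 2)``; 1 = major allele, 0 = minor.
    ids
        Unique individual labels, length N.
    scope
        ``"observed"`` (marker loci only) or ``"full"`` (markers + hidden).
    pool_label
        Optional heterotic-pool tag (``"A"``, ``"B"``, ``"C"``, ``"raw"``).
    homozygous
        Declared homozygosity; validated on construction.
    """

    genotypes: np.ndarray
    ids: list[str] = field(default_factory=list)
    scope: Scope = OBSERVED
    pool_label: str | None = None
    homozygous: bool = False

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError(f"genotypes must have shape (N, L, 2), got {g.shape}")
        if g.shape[0] < 1 or g.shape[1] < 2:
            raise ValueError("need N >= 1 individuals and L >= 2 loci")
        if not np.isin(g, (0, 1)).all():
            bad = np.unique(g[~np.isin(g, (0, 1))])
            raise ValueError(f"non-binary genotype entries: {bad!r}")
        self.genotypes = np.ascontiguousarray(g, dtype=np.int8)
        if not self.ids:
            self.ids = [f"ind{i}" for i in range(g.shape[0])]
        if len(self.ids) != g.shape[0]:
            raise ValueError("ids length must equal N")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        if self.scope not in (OBSERVED, FULL):
            raise ValueError(f"scope must be 'observed' or 'full', got {self.scope!r}")
        if self.homozygous and not bool(
            (self.genotypes[:, :, 0] == self.genotypes[:, :, 1]).all()
        ):
            raise ValueError("population declared homozygous but homologs differ")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, index: Sequence[int], pool_label: str | None = None) -> "Population":
        idx = np.asarray(index, dtype=np.intp)
        return Population(
            genotypes=self.genotypes[idx].copy(),
            ids=[self.ids[i] for i in idx],
            scope=self.scope,
            pool_label=pool_label if pool_label is not None else self.pool_label,
            homozygous=self.homozygous,
        )

    def observed_view(self, index_map: np.ndarray) -> "Population":
        """Project a full-scope population onto its observed marker columns."""
        if self.scope != FULL:
            raise ScopeError("observed_view requires a full-scope population")
        return Population(
            genotypes=self.genotypes[:, np.asarray(index_map, dtype=np.intp), :].copy(),
            ids=list(self.ids),
            scope=OBSERVED,
            pool_label=self.pool_label,
            homozygous=self.homozygous,
        )


@dataclass
class TraitArchitecture:
    """Ground-truth additive and dominance effects for one trait.

    Two calibrated effect sets coexist.  The *observed-basis* set
    (``additive_obs``, ``dominance_obs``, length L) drives the
    transparent simulator.  The *full-genome* set spans all L-bar loci
    and drives the opaque simulator; it is stored as its values at the
    observed marker positions (``additive_obs_full``/``dominance_obs_full``)
    plus the hidden block (``additive_hidden``/``dominance_hidden``).
    When the full-set observed slice is not given it defaults to the
    observed-basis vectors, so for hand-built architectures the full
    GEBV decomposes exactly as observed contribution + hidden
    contribution.

    ``observed_index_map`` is the strictly increasing injection from
    observed locus j to its column in the full genome.
    """

    additive_obs: np.ndarray
    dominance_obs: np.ndarray
    additive_hidden: np.ndarray
    dominance_hidden: np.ndarray
    observed_index_map: np.ndarray
    additive_obs_full: np.ndarray | None = None
    dominance_obs_full: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.additive_obs = np.asarray(self.additive_obs, dtype=float)
        self.dominance_obs = np.asarray(self.dominance_obs, dtype=float)
        self.additive_hidden = np.asarray(self.additive_hidden, dtype=float)
        self.dominance_hidden = np.asarray(self.dominance_hidden, dtype=float)
        self.observed_index_map = np.asarray(self.observed_index_map, dtype=np.intp)
        if self.additive_obs.shape != self.dominance_obs.shape:
            raise ValueError("observed additive/dominance lengths differ")
        if self.additive_hidden.shape != self.dominance_hidden.shape:
            raise ValueError("hidden additive/dominance lengths differ")
        if self.observed_index_map.shape != self.additive_obs.shape:
            raise ValueError("observed_index_map length must equal L")
        if self.n_observed and (
            np.diff(self.observed_index_map).min(initial=1) <= 0
            or self.observed_index_map.min() < 0
            or self.observed_index_map.max() >= self.n_full
        ):
            raise ValueError("observed_index_map must be strictly increasing within [0, L_full)")
        if self.additive_obs_full is None:
            self.additive_obs_full = self.additive_obs.copy()
        else:
            self.additive_obs_full = np.asarray(self.additive_obs_full, dtype=float)
        if self.dominance_obs_full is None:
            self.dominance_obs_full = self.dominance_obs.copy()
        else:
            self.dominance_obs_full = np.asarray(self.dominance_obs_full, dtype=float)
        if self.additive_obs_full.shape != self.additive_obs.shape:
            raise ValueError("full-set observed slice length must equal L")

    @property
    def n_observed(self) -> int:
        return self.additive_obs.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.additive_hidden.shape[0]

    @property
    def n_full(self) -> int:
        return self.n_observed + self.n_hidden

    @property
    def hidden_index_map(self) -> np.ndarray:
        """Full-genome columns not covered by the observed markers."""
        mask = np.ones(self.n_full, dtype=bool)
        mask[self.observed_index_map] = False
        return np.flatnonzero(mask)

    def full_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Assemble the full-genome (alpha-bar, beta-bar) vectors, length L-bar."""
        a = np.empty(self.n_full)
        b = np.empty(self.n_full)
        a[self.observed_index_map] = self.additive_obs_full
        b[self.observed_index_map] = self.dominance_obs_full
        hid = self.hidden_index_map
        a[hid] = self.additive_hidden
        b[hid] = self.dominance_hidden
        return a, b

    @staticmethod
    def split_dominance(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a dominance vector into its beta+ (>=0) and beta- (<=0) parts."""
        beta = np.asarray(beta, dtype=float)
        return np.where(beta > 0, beta, 0.0), np.where(beta < 0, beta, 0.0)


@dataclass
class DosageMatrices:
    """Major-allele dosage g (0/1/2) and heterozygosity indicator d."""

    g: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g)
        self.d = np.asarray(self.d)
        if self.g.shape != self.d.shape:
            raise ValueError("g and d shapes differ")


@dataclass
class GEBVVector:
    """True or predicted breeding values with the basis that produced them."""

    v: np.ndarray
    basis: Scope

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not np.isfinite(self.v).all():
            raise ValueError("GEBV entries must be finite")


def compute_dosages(pop: Population) -> DosageMatrices:
    """Collapse homolog pairs to dosage g = G[..,0] + G[..,1] and het flag d."""
    g = pop.genotypes[:, :, 0].astype(np.int8) + pop.genotypes[:, :, 1]
    d = (g == 1).astype(np.int8)
    return DosageMatrices(g=g, d=d)


def compute_gebv(pop: Population, arch: TraitArchitecture, basis: Scope = OBSERVED) -> GEBVVector:
    """Linear GEBV over the loci of the requested basis.

    With ``basis="full"`` the score uses the full-genome effect set
    (observed slice + hidden block) and requires a full-scope population.
    """
    dos = compute_dosages(pop)
    if basis == OBSERVED:
        if pop.scope == FULL:
            dos = DosageMatrices(
                g=dos.g[:, arch.observed_index_map], d=dos.d[:, arch.observed_index_map]
            )
        if dos.g.shape[1] != arch.n_observed:
            raise ValueError(
                f"population has {dos.g.shape[1]} loci but architecture expects {arch.n_observed}"
            )
        v = dos.g @ arch.additive_obs + dos.d @ arch.dominance_obs
    elif basis == FULL:
        if pop.scope != FULL:
            raise ScopeError("full-basis GEBV requires a full-scope population")
        if dos.g.shape[1] != arch.n_full:
            raise ValueError(
                f"population has {dos.g.shape[1]} loci but architecture expects {arch.n_full}"
            )
        a_full, b_full = arch.full_vectors()
        v = dos.g @ a_full + dos.d @ b_full
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return GEBVVector(v=v, basis=basis)


def true_gebv(pop: Population, arch: TraitArchitecture, simulator_mode: SimulatorMode) -> GEBVVector:
    """Ground-truth GEBV under the given simulator regime.

    Transparent mode scores the observed markers with the observed-basis
    effects; opaque mode scores the whole genome (hidden loci included)
    with the full-genome effect set.
    """
    if simulator_mode == TRANSPARENT:
        return compute_gebv(pop, arch, basis=OBSERVED)
    if simulator_mode == OPAQUE:
        if pop.scope != FULL:
            raise ScopeError("opaque mode requires a full-scope population")
        return compute_gebv(pop, arch, basis=FULL)
    raise ValueError(f"simulator_mode must be 'transparent' or 'opaque', got {simulator_mode!r}")
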