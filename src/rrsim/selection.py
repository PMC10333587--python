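"""Truncation selection, the test-cross GEBV matrix, and GCA/SCA selection.

Truncation selection is the integer program "pick M individuals
maximizing the sum of their predicted GEBVs", solved exactly by ranking.

A test cross mates every inbred of pool A with every inbred of pool B;
because the parents are fully homozygous, each F1 genotype is
deterministic (one fixed gamete per parent) and the N_A x N_B matrix of
predicted hybrid GEBVs summarizes all combining ability:

* GCA (general combining ability) scores a parent by its row (or
  column) mean and the selection IP reduces to top-2K row means;
* SCA (specific combining ability) scores a parent by its row (or
  column) maximum — each selected parent is credited with its single
  best mate — and reduces to top-2K row maxima.

Both reductions are exact for the (repaired) assignment formulation
with one chosen mate per selected parent; the test suite checks them
against brute-force subset enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .genome_core import (
    FULL,
    OBSERVED,
    OPAQUE,
    DosageMatrices,
    GEBVVector,
    Population,
    SimulatorMode,
    TraitArchitecture,
)
from .phenotype import environmental_variance
from .prediction import MCMCConfig, MarkerEffectResults, fit_bayesian

PredictorKind = Literal["perfect", "phenotypic", "bayesian"]


@dataclass
class PredictorContext:
    """Which GEBV predictor to apply, and how.

    ``train_fraction`` subsamples the phenotyped hybrid set used to fit
    the Bayesian model for the test-cross matrix (1.0 = all hybrids);
    ``replicates`` is the number of phenotype draws averaged per hybrid
    under the phenotypic predictor.
    """

    kind: PredictorKind
    simulator_mode: SimulatorMode = "transparent"
    h2: float = 0.2
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    train_fraction: float = 1.0
    replicates: int = 1
    model: MarkerEffectResults | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "phenotypic", "bayesian"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if not (0.0 < self.train_fraction <= 1.0):
            raise ValueError("train_fraction must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SelectionResult:
    """Indices chosen by a selection rule plus the achieved objective."""

    selected: np.ndarray
    objective: float
    assignment: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=np.intp)
        if np.unique(self.selected).size != self.selected.size:
            raise ValueError("selected indices must be unique")


@dataclass
class TestCrossMatrix:
    """Predicted hybrid GEBVs for all pool-A x pool-B crosses."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    predictor_kind: PredictorKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix dimensions must match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("test-cross entries must be finite")


def _top_m(scores: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest scores; ties broken by lowest index."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= m <= scores.size:
        raise ValueError(f"cannot select {m} from {scores.size} candidates")
    order = np.argsort(-scores, kind="stable")
    return order[:m]


def truncation_select(v_hat: GEBVVector | np.ndarray, m: int) -> SelectionResult:
    """Select the M individuals with the highest predicted GEBVs."""
    scores = v_hat.v if isinstance(v_hat, GEBVVector) else np.asarray(v_hat, dtype=float)
    sel = _top_m(scores, m)
    return SelectionResult(selected=sel, objective=float(scores[sel].sum()))


def select_gca(
    matrix: TestCrossMatrix | np.ndarray, size: int, axis: str = "rows"
) -> SelectionResult:
    """Top-``size`` parents by test-cross mean (general combining ability)."""
    values = matrix.values if isinstance(matrix, TestCrossMatrix) else np.asarray(matrix, float)
    if axis == "cols":
        values = values.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    means = values.mean(axis=1)
    sel = _top_m(means, size)
    return SelectionResult(selected=sel, objective=float(means[sel].sum()))


def select_sca(
    matrix: TestCrossMatrix | np.ndarray, size: int, axis: str = "rows"
) -> SelectionResult:
    """Top-``size`` parents by best single cross (specific combining ability).

    The assignment maps each selected parent to the mate achieving its
    row (or column) maximum.
    """
    values = matrix.values if isinstance(matrix, TestCrossMatrix) else np.asarray(matrix, float)
    if axis == "cols":
        values = values.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    maxima = values.max(axis=1)
    best_mate = values.argmax(axis=1)  # first maximum = lowest index on ties
    sel = _top_m(maxima, size)
    return SelectionResult(
        selected=sel,
        objective=float(maxima[sel].sum()),
        assignment={int(k): int(best_mate[k]) for k in sel},
    )


def _parent_haplotypes(pop: Population) -> np.ndarray:
    if not pop.homozygous or not (pop.genotypes[:, :, 0] == pop.genotypes[:, :, 1]).all():
        raise ValueError("test cross requires fully homozygous parents")
    return pop.genotypes[:, :, 0].astype(float)


def hybrid_value_matrix(
    hap_a: np.ndarray, hap_b: np.ndarray, alpha: np.ndarray, beta: np.ndarray, mu: float = 0.0
) -> np.ndarray:
    """Linear GEBV of every deterministic F1, without materializing genotypes.

    For inbred parents with haplotypes u, w the hybrid has g = u + w and
    d = u XOR w = u + w - 2uw, so the bilinear identity

        v = mu + (u @ (alpha+beta)) + (w @ (alpha+beta)) - 2 (u*beta) @ w

    evaluates the whole matrix with three matrix products.
    """
    ab = alpha + beta
    return (
        mu
        + (hap_a @ ab)[:, None]
        + (hap_b @ ab)[None, :]
        - 2.0 * (hap_a * beta) @ hap_b.T
    )


def true_hybrid_matrix(
    a: Population, b: Population, arch: TraitArchitecture, simulator_mode: SimulatorMode
) -> np.ndarray:
    """Ground-truth GEBV of every A x B hybrid under the simulator regime."""
    hap_a = _parent_haplotypes(a)
    hap_b = _parent_haplotypes(b)
    if simulator_mode == OPAQUE:
        if a.scope != FULL or b.scope != FULL:
            raise ValueError("opaque test cross requires full-scope parents")
        alpha, beta = arch.full_vectors()
    else:
        if a.scope == FULL:
            hap_a = hap_a[:, arch.observed_index_map]
            hap_b = hap_b[:, arch.observed_index_map]
        alpha, beta = arch.additive_obs, arch.dominance_obs
    return hybrid_value_matrix(hap_a, hap_b, alpha, beta)


def _observed_haplotypes(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    hap = _parent_haplotypes(pop)
    if pop.scope == FULL:
        hap = hap[:, arch.observed_index_map]
    return hap


def build_testcross_matrix(
    a: Population,
    b: Population,
    predictor: PredictorContext,
    arch: TraitArchitecture,
    rng: np.random.Generator,
) -> TestCrossMatrix:
    """Predicted-GEBV matrix of all A x B test-cross hybrids.

    perfect
        the true hybrid GEBV (simulator-regime basis), no randomness;
    phenotypic
        one (or ``replicates`` averaged) simulated hybrid phenotype per
        cell, noise variance set from the hybrid genetic variance and H2;
    bayesian
        a marker model trained on the phenotyped hybrids (optionally a
        subsample), then the plug-in score of every hybrid's observed
        dosages.
    """
    v_true = true_hybrid_matrix(a, b, arch, predictor.simulator_mode)
    if predictor.kind == "perfect":
        return TestCrossMatrix(v_true, list(a.ids), list(b.ids), "perfect")

    sigma_e2 = environmental_variance(v_true.ravel(), predictor.h2)
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=(predictor.replicates,) + v_true.shape)
    phen = v_true[None, :, :] + noise
    p_mean = phen.mean(axis=0)
    if predictor.kind == "phenotypic":
        return TestCrossMatrix(p_mean, list(a.ids), list(b.ids), "phenotypic")

    # bayesian: train on (subsampled) phenotyped hybrids' observed dosages
    hap_a = _observed_haplotypes(a, arch)
    hap_b = _observed_haplotypes(b, arch)
    n_a, n_b = v_true.shape
    n_all = n_a * n_b
    n_train = max(2, int(round(predictor.train_fraction * n_all)))
    flat = rng.choice(n_all, size=n_train, replace=False) if n_train < n_all else np.arange(n_all)
    ka, kb = np.divmod(flat, n_b)
    g_train = hap_a[ka] + hap_b[kb]
    d_train = (g_train == 1).astype(float)
    model = fit_bayesian(
        DosageMatrices(g=g_train, d=d_train), p_mean.ravel()[flat], predictor.mcmc
    )
    predictor.model = model
    v_hat = hybrid_value_matrix(
        hap_a, hap_b, model.additive_hat, model.dominance_hat, mu=model.mu_hat
    )
    return TestCrossMatrix(v_hat, list(a.ids), list(b.ids), "bayesian")
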