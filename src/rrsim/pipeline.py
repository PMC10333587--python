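"""The reciprocal recurrent selection (RRS) experiment harness.

One RRS cycle takes two homozygous heterotic pools A and B through:

1. mutual test cross and combining-ability selection (GCA or SCA) of
   2K parents per pool,
2. mating of the selected parents (adjacent or complementary design)
   producing K*S heterozygous progeny per pool,
3. one or more rounds of intra-population breeding (phenotype, predict,
   truncation-select M, mate, cross),
4. doubled-haploid conversion and truncation down-selection back to the
   pool size.

After every cycle the two pools are mutually crossed and the mean
ground-truth GEBV of the top-n hybrids (the "children" population C) is
recorded; genetic gain is that mean minus its cycle-0 baseline.  The
full study is a 24-run factorial over {transparent, opaque} simulators,
{perfect, phenotypic, bayesian} predictors, {adjacent, complementary}
mating, and {GCA, SCA} selection, each replicated over independent
founder splits, plus a broad-sense-heritability sensitivity sweep.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .founder_synth import RecombinationMap, make_homozygous_founders
from .genome_core import (
    FULL,
    OBSERVED,
    OPAQUE,
    TRANSPARENT,
    Population,
    TraitArchitecture,
    compute_dosages,
    true_gebv,
)
from .mating import MATING_DESIGNS, execute_matings
from .meiosis import doubled_haploid_population
from .phenotype import simulate_phenotypes
from .prediction import DESK_MCMC, MCMCConfig, fit_bayesian
from .selection import (
    PredictorContext,
    build_testcross_matrix,
    select_gca,
    select_sca,
    true_hybrid_matrix,
    truncation_select,
)

logger = logging.getLogger(__name__)

SIMULATORS = (TRANSPARENT, OPAQUE)
PREDICTORS = ("perfect", "phenotypic", "bayesian")
MATINGS = ("adjacent", "complementary")
SELECTIONS = ("GCA", "SCA")


@dataclass
class ExperimentConfig:
    """One cell of the factorial design plus all numeric parameters.

    Defaults are the headline study conditions: M=40 truncation size,
    K=10 pairs (2K=20 selected per pool), S=20 progeny per pair, T=6
    cycles, H2=0.2, pools of 100 drawn from a 200-founder split, top-100
    hybrid evaluation, 100 replicates.
    """

    simulator: str = TRANSPARENT
    predictor: str = "perfect"
    mating: str = "adjacent"
    selection: str = "GCA"
    m_truncation: int = 40
    k_pairs: int = 10
    s_progeny: int = 20
    t_cycles: int = 6
    h2: float = 0.2
    pool_size: int = 100
    raw_sample: int = 200
    top_n_eval: int = 100
    n_reps: int = 100
    n_intra: int = 1
    master_seed: int = 0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    train_fraction: float = 1.0
    freeze_sigma_e2: bool = False
    dh_meiotic: bool = False
    experiment_index: int | None = None

    def __post_init__(self) -> None:
        if self.simulator not in SIMULATORS:
            raise ValueError(f"simulator must be one of {SIMULATORS}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        if self.mating not in MATINGS:
            raise ValueError(f"mating must be one of {MATINGS}")
        if self.selection not in SELECTIONS:
            raise ValueError(f"selection must be one of {SELECTIONS}")
        if 2 * self.k_pairs > self.pool_size:
            raise ValueError("2K must not exceed the pool size")
        if self.m_truncation > self.k_pairs * self.s_progeny:
            raise ValueError("truncation size M must not exceed K*S progeny")
        if self.m_truncation % 2:
            raise ValueError("M must be even (selected parents are paired)")
        if self.raw_sample != 2 * self.pool_size:
            raise ValueError("raw_sample must equal 2 * pool_size")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("H2 must lie in (0, 1]")
        for name in ("t_cycles", "n_reps", "top_n_eval", "k_pairs", "s_progeny"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_intra < 0:
            raise ValueError("n_intra must be >= 0")

    @property
    def label(self) -> str:
        idx = f"{self.experiment_index}:" if self.experiment_index else ""
        return f"{idx}{self.simulator}/{self.predictor}/{self.mating}/{self.selection}"


def desk_config(**overrides) -> ExperimentConfig:
    """A scaled-down configuration for interactive runs and tests.

    Pools of 20 over T=3 cycles with 20 replicates and K=5 pairs;
    M=40, S=20, and the top-100 hybrid evaluation keep their default
    values, and MCMC chains are shortened.  Pairs with
    :func:`rrsim.founder_synth.desk_synthesis_config`.
    """
    base = dict(
        pool_size=20,
        raw_sample=40,
        k_pairs=5,
        t_cycles=3,
        n_reps=20,
        mcmc=DESK_MCMC,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@dataclass
class CycleRecord:
    """Per-cycle evaluation: pool means and the top-n hybrid mean."""

    cycle: int
    mean_a: float
    mean_b: float
    mean_c_top: float
    realized_h2: float = float("nan")


def heterotic_split(
    raw: Population,
    raw_sample: int,
    pool_size: int,
    rng: np.random.Generator,
) -> tuple[Population, Population]:
    """Sample founders and split them into two homozygous heterotic pools.

    ``raw_sample`` individuals are drawn without replacement and
    partitioned uniformly at random into pools A and B of ``pool_size``
    each, then made homozygous by duplicating one random gamete per
    individual.
    """
    if raw_sample % 2 or raw_sample > raw.n:
        raise ValueError("raw_sample must be even and at most the raw population size")
    if 2 * pool_size != raw_sample:
        raise ValueError("the two pools must partition the sampled founders")
    chosen = rng.choice(raw.n, size=raw_sample, replace=False)
    rng.shuffle(chosen)
    a = make_homozygous_founders(raw.subset(chosen[:pool_size], pool_label="A"), rng)
    b = make_homozygous_founders(raw.subset(chosen[pool_size:], pool_label="B"), rng)
    return a, b


def _predict_pool(
    pop: Population,
    cfg: ExperimentConfig,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    sigma_e2: float | None = None,
) -> np.ndarray:
    """Predicted GEBVs for one pool under the configured predictor."""
    if cfg.predictor == "perfect":
        return true_gebv(pop, arch, cfg.simulator).v
    phen = simulate_phenotypes(pop, arch, cfg.h2, cfg.simulator, rng, sigma_e2=sigma_e2)
    if cfg.predictor == "phenotypic":
        return phen.p
    obs = pop.observed_view(arch.observed_index_map) if pop.scope == FULL else pop
    dos = compute_dosages(obs)
    mcmc = replace(cfg.mcmc, seed=int(rng.integers(2**31)))
    model = fit_bayesian(dos, phen.p, mcmc)
    return model.predict(dos).v


def intra_population_cycle(
    pool: Population,
    cfg: ExperimentConfig,
    arch: TraitArchitecture,
    rmap: RecombinationMap,
    rng: np.random.Generator,
    sigma_e2: float | None = None,
) -> Population:
    """One intra-population breeding round: predict, select M, mate, cross."""
    if cfg.m_truncation > pool.n:
        raise ValueError("truncation size exceeds pool size")
    v_hat = _predict_pool(pool, cfg, arch, rng, sigma_e2=sigma_e2)
    sel = truncation_select(v_hat, cfg.m_truncation)
    # sort the selected parents by predicted value, best first
    order = sel.selected[np.argsort(-v_hat[sel.selected], kind="stable")]
    parents = pool.subset(order)
    plan = MATING_DESIGNS[cfg.mating](parents.ids, progeny_per_pair=cfg.s_progeny)
    return execute_matings(plan, parents, rmap.for_scope(pool.scope), rng)


def evaluate_hybrid_population(
    a: Population,
    b: Population,
    arch: TraitArchitecture,
    simulator_mode: str,
    top_n: int,
) -> CycleRecord:
    """Mutually cross the pools and score the top-n hybrids by true GEBV."""
    v_matrix = true_hybrid_matrix(a, b, arch, simulator_mode)
    if top_n > v_matrix.size:
        raise ValueError("top_n exceeds the number of hybrids")
    flat = np.sort(v_matrix.ravel())[::-1]
    return CycleRecord(
        cycle=-1,
        mean_a=float(true_gebv(a, arch, simulator_mode).v.mean()),
        mean_b=float(true_gebv(b, arch, simulator_mode).v.mean()),
        mean_c_top=float(flat[:top_n].mean()),
    )


def run_rrs_cycle(
    a: Population,
    b: Population,
    cfg: ExperimentConfig,
    arch: TraitArchitecture,
    rmap: RecombinationMap,
    rng: np.random.Generator,
    sigma_e2: float | None = None,
) -> tuple[Population, Population]:
    """One full RRS cycle; returns the next-cycle homozygous pools."""
    predictor = PredictorContext(
        kind=cfg.predictor,
        simulator_mode=cfg.simulator,
        h2=cfg.h2,
        mcmc=replace(cfg.mcmc, seed=int(rng.integers(2**31))),
        train_fraction=cfg.train_fraction,
    )
    tcm = build_testcross_matrix(a, b, predictor, arch, rng)
    select = select_gca if cfg.selection == "GCA" else select_sca

    next_pools: list[Population] = []
    for pool, axis in ((a, "rows"), (b, "cols")):
        res = select(tcm, 2 * cfg.k_pairs, axis=axis)
        scores = (
            tcm.values.mean(axis=1 if axis == "rows" else 0)
            if cfg.selection == "GCA"
            else tcm.values.max(axis=1 if axis == "rows" else 0)
        )
        order = res.selected[np.argsort(-scores[res.selected], kind="stable")]
        parents = pool.subset(order)
        plan = MATING_DESIGNS[cfg.mating](parents.ids, progeny_per_pair=cfg.s_progeny)
        progeny = execute_matings(plan, parents, rmap.for_scope(pool.scope), rng)
        for _ in range(cfg.n_intra):
            progeny = intra_population_cycle(progeny, cfg, arch, rmap, rng, sigma_e2=sigma_e2)
        dh = doubled_haploid_population(
            progeny, rng, r=rmap.for_scope(pool.scope), meiotic=cfg.dh_meiotic
        )
        v_hat = _predict_pool(dh, cfg, arch, rng, sigma_e2=sigma_e2)
        keep = truncation_select(v_hat, cfg.pool_size)
        next_pools.append(dh.subset(keep.selected, pool_label=pool.pool_label))
    return next_pools[0], next_pools[1]


def genetic_gain(series: np.ndarray) -> np.ndarray:
    """Per-cycle gain relative to the cycle-0 baseline."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return series - series[0]


def _rep_rng(master_seed: int, rep: int, tag: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, rep, tag]))


def run_experiment(
    cfg: ExperimentConfig,
    arch: TraitArchitecture,
    rmap: RecombinationMap,
    raw: Population,
) -> pd.DataFrame:
    """Replicate one experiment and return long-format per-cycle results.

    Each replicate draws its own founder split and runs T cycles with a
    cycle-0 baseline evaluation; rows are (experiment, rep, cycle, pool,
    metric, value).
    """
    if raw.scope != FULL and cfg.simulator == OPAQUE:
        raise ValueError("opaque experiments need full-scope founders")
    records: list[dict] = []
    for rep in range(cfg.n_reps):
        rng = _rep_rng(cfg.master_seed, rep)
        founders = raw
        if cfg.simulator == TRANSPARENT and raw.scope == FULL:
            founders = raw.observed_view(arch.observed_index_map)
        a, b = heterotic_split(founders, cfg.raw_sample, cfg.pool_size, rng)
        sigma_e2 = None
        if cfg.freeze_sigma_e2 and cfg.predictor != "perfect":
            from .phenotype import environmental_variance

            baseline_v = true_hybrid_matrix(a, b, arch, cfg.simulator).ravel()
            sigma_e2 = environmental_variance(baseline_v, cfg.h2)
        means_c = []
        for t in range(cfg.t_cycles + 1):
            rec = evaluate_hybrid_population(a, b, arch, cfg.simulator, cfg.top_n_eval)
            rec.cycle = t
            means_c.append(rec.mean_c_top)
            for pool, value in (("A", rec.mean_a), ("B", rec.mean_b), ("C", rec.mean_c_top)):
                records.append(
                    dict(
                        experiment=cfg.label,
                        rep=rep,
                        cycle=t,
                        pool=pool,
                        metric="mean_true_gebv",
                        value=value,
                    )
                )
            if t < cfg.t_cycles:
                a, b = run_rrs_cycle(a, b, cfg, arch, rmap, rng, sigma_e2=sigma_e2)
        for t, gain in enumerate(genetic_gain(np.array(means_c))):
            records.append(
                dict(
                    experiment=cfg.label,
                    rep=rep,
                    cycle=t,
                    pool="C",
                    metric="gain",
                    value=float(gain),
                )
            )
        logger.info(
            "experiment %s rep %d final C mean %.3f", cfg.label, rep, means_c[-1]
        )
    return pd.DataFrame.from_records(records)


def build_experiment_grid(**overrides) -> list[ExperimentConfig]:
    """The 24-configuration factorial, indexed 1..24.

    Order: simulator slowest-varying, then predictor, mating, selection
    (so index 1 is transparent/perfect/adjacent/GCA and index 24 is
    opaque/bayesian/complementary/SCA).
    """
    grid = []
    for i, (sim, pred, mat, sel) in enumerate(
        itertools.product(SIMULATORS, PREDICTORS, MATINGS, SELECTIONS), start=1
    ):
        grid.append(
            ExperimentConfig(
                simulator=sim,
                predictor=pred,
                mating=mat,
                selection=sel,
                experiment_index=i,
                **overrides,
            )
        )
    return grid


def sensitivity_h2(
    configs: list[ExperimentConfig],
    arch: TraitArchitecture,
    rmap: RecombinationMap,
    raw: Population,
    h2_values: tuple[float, ...] = (0.2, 0.5, 0.8),
) -> pd.DataFrame:
    """Genetic-gain sweep over heritability for noise-sensitive predictors.

    Each phenotypic/bayesian configuration is rerun at every H2 value;
    a matching perfect-predictor reference series (independent of H2) is
    added per (simulator, mating, selection) combination.
    """
    for h2 in h2_values:
        if not (0.0 < h2 <= 1.0):
            raise ValueError("H2 values must lie in (0, 1]")
    frames = []
    seen_refs = set()
    for cfg in configs:
        if cfg.predictor == "perfect":
            continue
        for h2 in h2_values:
            sub = run_experiment(replace(cfg, h2=h2), arch, rmap, raw)
            sub["h2"] = h2
            frames.append(sub)
        ref_key = (cfg.simulator, cfg.mating, cfg.selection)
        if ref_key not in seen_refs:
            seen_refs.add(ref_key)
            ref_cfg = replace(cfg, predictor="perfect")
            sub = run_experiment(ref_cfg, arch, rmap, raw)
            sub["h2"] = float("nan")
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def summarize_gains(results: pd.DataFrame) -> pd.DataFrame:
    """Mean gain of the hybrid population C per experiment and cycle."""
    gains = results[(results["metric"] == "gain") & (results["pool"] == "C")]
    keys = ["experiment", "cycle"] + (["h2"] if "h2" in results.columns else [])
    return gains.groupby(keys, dropna=False)["value"].mean().reset_index(name="mean_gain")
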