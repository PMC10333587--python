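"""Phenotype generation with heritability-controlled environmental noise.

A phenotype is the true genetic value plus i.i.d. Gaussian environmental
noise, p_i = v_i + e_i with e_i ~ N(0, sigma_e^2).  The noise variance
is tied to broad-sense heritability through

    sigma_e^2 = Var(v) * (1 - H^2) / H^2

where Var(v) is the (n-1) sample variance of the true genetic values of
the population being phenotyped.  Under the transparent regime v comes
from the observed markers only; under the opaque regime it comes from
the whole genome, hidden loci included, so phenotypes leak information
about loci no decision module ever sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_core import GEBVVector, Population, SimulatorMode, TraitArchitecture, true_gebv

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeRecord:
    """Phenotypes p, noise draws e, and the noise variance that produced them."""

    p: np.ndarray
    e: np.ndarray
    v: GEBVVector
    sigma_e2: float
    h2: float

    @property
    def realized_h2(self) -> float:
        """Diagnostic Var(v)/Var(p) on this finite sample."""
        var_p = float(np.var(self.p, ddof=1))
        if var_p == 0.0:
            return float("nan")
        return float(np.var(self.v.v, ddof=1)) / var_p


def environmental_variance(v: GEBVVector | np.ndarray, h2: float) -> float:
    """Noise variance achieving heritability ``h2`` for genetic values ``v``."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"H2 must lie in (0, 1], got {h2}")
    vv = v.v if isinstance(v, GEBVVector) else np.asarray(v, dtype=float)
    if vv.size < 2:
        raise ValueError("need at least 2 individuals to estimate genetic variance")
    var_v = float(np.var(vv, ddof=1))
    if var_v == 0.0:
        logger.warning("constant genetic values: sigma_e^2 = 0 regardless of H2")
        return 0.0
    return var_v * (1.0 - h2) / h2


def simulate_phenotypes(
    pop: Population,
    arch: TraitArchitecture,
    h2: float,
    mode: SimulatorMode,
    rng: np.random.Generator,
    sigma_e2: float | None = None,
) -> PhenotypeRecord:
    """Phenotype a population under the given simulator regime.

    ``sigma_e2`` overrides the per-population noise variance (used when
    the noise level is frozen at a baseline cycle instead of recomputed).
    """
    v = true_gebv(pop, arch, mode)
    if sigma_e2 is None:
        sigma_e2 = environmental_variance(v, h2)
    elif sigma_e2 < 0:
        raise ValueError("sigma_e2 must be nonnegative")
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=v.v.shape) if sigma_e2 > 0 else np.zeros_like(v.v)
    rec = PhenotypeRecord(p=v.v + e, e=e, v=v, sigma_e2=float(sigma_e2), h2=h2)
    logger.debug("phenotyped n=%d mode=%s realized_H2=%.3f", pop.n, mode, rec.realized_h2)
    return rec
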