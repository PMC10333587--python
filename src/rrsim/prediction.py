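"""GEBV predictors: perfect, phenotypic, and a Bayesian marker model.

The Bayesian predictor regresses phenotypes on marker dosages with both
additive and dominance covariates,

    p_i = mu + sum_j a_j g_ij + sum_j b_j d_ij + eps_i,

with zero-mean normal priors on the marker effects and scaled-inverse-
chi-square priors on the variances, fitted by Gibbs sampling.  Two
prior regimes are available: ``"bayes_a"`` gives every marker effect its
own variance (the default), ``"common"`` shares one variance per effect
class (one for all a_j, one for all b_j).  Point estimates are posterior
means after burn-in and thinning; prediction is the plug-in linear score
v-hat_i = mu-hat + sum a-hat_j g_ij + sum b-hat_j d_ij.

The model never sees hidden loci: its design matrices are observed-
marker dosages only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_core import (
    DosageMatrices,
    GEBVVector,
    Population,
    SimulatorMode,
    TraitArchitecture,
    true_gebv,
)
from .phenotype import PhenotypeRecord

logger = logging.getLogger(__name__)


def predict_perfect(
    pop: Population, arch: TraitArchitecture, simulator_mode: SimulatorMode
) -> GEBVVector:
    """Oracle predictor: returns the ground-truth GEBV exactly."""
    return true_gebv(pop, arch, simulator_mode)


def predict_phenotypic(phen: PhenotypeRecord) -> GEBVVector:
    """Use the observed phenotype itself as the estimated GEBV."""
    p = np.asarray(phen.p, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("missing or non-finite phenotypes")
    return GEBVVector(v=p.copy(), basis=phen.v.basis)


@dataclass
class MCMCConfig:
    """Gibbs-chain settings for the Bayesian marker model."""

    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    prior: str = "bayes_a"
    prior_df: float = 4.0
    scale_a: float | None = None  # override the data-derived prior scales
    scale_d: float | None = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1 or self.burn_in < 0:
            raise ValueError("thin >= 1 and burn_in >= 0 required")
        if self.prior not in ("bayes_a", "common"):
            raise ValueError("prior must be 'bayes_a' or 'common'")


# desk-scale chain used inside multi-cycle pipeline runs
DESK_MCMC = MCMCConfig(iterations=600, burn_in=200, thin=2)


@dataclass
class MarkerEffectResults:
    """Posterior-mean marker effects and variance components.

    Attributes mirror the fitted model: ``mu_hat``, per-marker additive
    (``additive_hat``) and dominance (``dominance_hat``) effects, and
    posterior-mean variance components in ``variance_hats``.
    """

    mu_hat: float
    additive_hat: np.ndarray
    dominance_hat: np.ndarray
    variance_hats: dict[str, float]
    mcmc: MCMCConfig
    n_obs: int
    null_model: bool = False

    @property
    def n_markers(self) -> int:
        return self.additive_hat.shape[0]

    def predict(self, dosages: DosageMatrices) -> GEBVVector:
        """Plug-in GEBV score for new individuals' observed dosages."""
        g = np.asarray(dosages.g, dtype=float)
        d = np.asarray(dosages.d, dtype=float)
        if g.shape[1] != self.n_markers:
            raise ValueError(
                f"dosage width {g.shape[1]} does not match model width {self.n_markers}"
            )
        v = self.mu_hat + g @ self.additive_hat + d @ self.dominance_hat
        return GEBVVector(v=v, basis="observed")

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": np.arange(self.n_markers),
                "additive_hat": self.additive_hat,
                "dominance_hat": self.dominance_hat,
            }
        )

    def summary(self) -> str:
        lines = [
            "Bayesian marker-effect model (Gibbs)",
            "=" * 40,
            f"observations:      {self.n_obs}",
            f"markers:           {self.n_markers}",
            f"prior regime:      {self.mcmc.prior}",
            f"chain:             {self.mcmc.iterations} iters, "
            f"{self.mcmc.burn_in} burn-in, thin {self.mcmc.thin}",
            f"mu_hat:            {self.mu_hat:.6g}",
        ]
        for k, val in self.variance_hats.items():
            lines.append(f"{k + ':':<19}{val:.6g}")
        if self.null_model:
            lines.append("NOTE: degenerate input; null model returned")
        return "\n".join(lines)


class BayesianMarkerModel:
    """Bayesian linear mixed model of phenotypes on marker dosages.

    Parameters
    ----------
    p
        Phenotype vector, length n.
    dosages
        Observed-marker dosage matrices (g in {0,1,2}, d in {0,1}).
    """

    def __init__(self, p: np.ndarray, dosages: DosageMatrices):
        self.p = np.asarray(p, dtype=float)
        self.g = np.asarray(dosages.g, dtype=float)
        self.d = np.asarray(dosages.d, dtype=float)
        if self.p.ndim != 1 or self.g.shape[0] != self.p.size:
            raise ValueError("phenotype length must match dosage rows")
        if self.p.size < 2:
            raise ValueError("need at least 2 training observations")
        if self.g.shape[1] < 1:
            raise ValueError("need at least 1 marker")
        if not np.isfinite(self.p).all():
            raise ValueError("phenotypes must be finite")

    @classmethod
    def from_population(
        cls, pop: Population, phen: PhenotypeRecord, arch: TraitArchitecture | None = None
    ) -> "BayesianMarkerModel":
        """Build from a phenotyped population, projecting to observed markers."""
        from .genome_core import FULL, compute_dosages

        if pop.scope == FULL:
            if arch is None:
                raise ValueError("projecting a full-scope population needs the architecture")
            pop = pop.observed_view(arch.observed_index_map)
        return cls(phen.p, compute_dosages(pop))

    def fit(self, mcmc: MCMCConfig | None = None) -> MarkerEffectResults:
        """Run the Gibbs sampler and return posterior-mean estimates."""
        mcmc = mcmc or MCMCConfig()
        rng = np.random.default_rng(mcmc.seed)
        n, L = self.g.shape
        var_p = float(np.var(self.p, ddof=1))
        if var_p <= 1e-12 * max(1.0, float(np.mean(self.p)) ** 2):
            warnings.warn("zero-variance phenotypes: returning null model", stacklevel=2)
            return MarkerEffectResults(
                mu_hat=float(self.p.mean()),
                additive_hat=np.zeros(L),
                dominance_hat=np.zeros(L),
                variance_hats={"sigma_a2": 0.0, "sigma_d2": 0.0, "sigma_e2": 0.0},
                mcmc=mcmc,
                n_obs=n,
                null_model=True,
            )

        # stacked design: additive columns then dominance columns
        X = np.concatenate([self.g, self.d], axis=1)
        xtx = np.einsum("ij,ij->j", X, X)
        active = xtx > 0.0
        nu = mcmc.prior_df
        # weakly-informative scales from a 1/2 additive, 1/4 dominance,
        # 1/4 residual partition of the phenotypic variance
        mean_ss = float(xtx[active].mean()) if active.any() else 1.0
        scale_a = mcmc.scale_a if mcmc.scale_a is not None else max(
            0.5 * var_p / (L * mean_ss / n), 1e-12
        )
        scale_d = mcmc.scale_d if mcmc.scale_d is not None else max(
            0.25 * var_p / (L * mean_ss / n), 1e-12
        )
        scale_e = max(0.25 * var_p, 1e-12)
        col_scale = np.where(np.arange(2 * L) < L, scale_a, scale_d)

        theta = np.zeros(2 * L)
        var_theta = col_scale.copy()
        mu = float(self.p.mean())
        sigma_e2 = scale_e
        resid = self.p - mu  # theta starts at zero

        keep = 0
        mu_acc = 0.0
        theta_acc = np.zeros(2 * L)
        var_acc = {"sigma_a2": 0.0, "sigma_d2": 0.0, "sigma_e2": 0.0}
        cols = np.flatnonzero(active)
        Xc = [np.ascontiguousarray(X[:, j]) for j in range(2 * L)]

        for it in range(mcmc.iterations):
            # intercept
            resid += mu
            mu = rng.normal(resid.mean(), np.sqrt(sigma_e2 / n))
            resid -= mu
            # marker effects, one coordinate at a time on the running residual
            for j in cols:
                xj = Xc[j]
                old = theta[j]
                if old != 0.0:
                    resid += xj * old
                c = xtx[j] + sigma_e2 / var_theta[j]
                mean_j = (xj @ resid) / c
                new = rng.normal(mean_j, np.sqrt(sigma_e2 / c))
                theta[j] = new
                resid -= xj * new
            # effect variances
            if mcmc.prior == "bayes_a":
                var_theta = (nu * col_scale + theta**2) / rng.chisquare(nu + 1.0, size=2 * L)
            else:
                ssa = float((theta[:L] ** 2).sum())
                ssd = float((theta[L:] ** 2).sum())
                var_theta[:L] = (nu * scale_a + ssa) / rng.chisquare(nu + L)
                var_theta[L:] = (nu * scale_d + ssd) / rng.chisquare(nu + L)
            # residual variance
            sigma_e2 = (resid @ resid + nu * scale_e) / rng.chisquare(n + nu)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                keep += 1
                mu_acc += mu
                theta_acc += theta
                var_acc["sigma_a2"] += float(var_theta[:L].mean())
                var_acc["sigma_d2"] += float(var_theta[L:].mean())
                var_acc["sigma_e2"] += sigma_e2

        theta_mean = theta_acc / keep
        res = MarkerEffectResults(
            mu_hat=mu_acc / keep,
            additive_hat=theta_mean[:L],
            dominance_hat=theta_mean[L:],
            variance_hats={k: val / keep for k, val in var_acc.items()},
            mcmc=mcmc,
            n_obs=n,
        )
        logger.debug("fit n=%d L=%d kept=%d sigma_e2=%.4g", n, L, keep, res.variance_hats["sigma_e2"])
        return res


def fit_bayesian(
    dosages: DosageMatrices, p: np.ndarray, mcmc: MCMCConfig | None = None
) -> MarkerEffectResults:
    """Functional wrapper: fit the Bayesian marker model on training dosages."""
    return BayesianMarkerModel(p, dosages).fit(mcmc)


def predict_bayesian(model: MarkerEffectResults, dosages: DosageMatrices) -> GEBVVector:
    """Functional wrapper: score new dosages with a fitted model."""
    return model.predict(dosages)
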