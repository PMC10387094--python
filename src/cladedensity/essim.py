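"""ES-sim: a semi-parametric test of trait-dependent speciation.

Instead of fitting a state-dependent diversification model, the test asks
whether an observed tip trait is more strongly correlated with the tip
speciation rate (lambda_DR) than traits evolving neutrally on the same
tree would be.  Procedure:

1. transform the trait (identity, or log(x + c) for right-skewed,
   zero-inflated traits such as clade density) and take log lambda_DR;
2. compute the observed Pearson correlation rho_obs;
3. fit Brownian motion to the transformed trait by GLS on the
   phylogenetic VCV (ancestral mean and rate sigma^2);
4. simulate ``n_sim`` neutral traits from N(a, sigma^2 C) via the Cholesky
   factor of C, correlate each against log lambda_DR, and report the
   two-tailed simulation p-value with the +1 finite-sample correction,
   ``p = (1 + #{|rho_k| >= |rho_obs|}) / (n_sim + 1)``.

Because the null traits inherit the tree's covariance structure, the test
controls for the phylogenetic non-independence that inflates naive
trait-rate correlations.  The ensemble wrapper repeats the analysis over
alternative topologies, recomputing the VCV, lambda_DR, and clade density
per tree, to propagate phylogenetic uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from .density import clade_density, align_species
from .geometry import OverlapMatrix
from .phylo import PhyloTree, TreeEnsemble, VcvMatrix, dr_statistic, vcv as _vcv

logger = logging.getLogger(__name__)

__all__ = [
    "EssimError",
    "BmFit",
    "ESSimResult",
    "EnsembleResult",
    "fit_bm",
    "simulate_bm_traits",
    "essim",
    "ensemble",
]


class EssimError(ValueError):
    pass


@dataclass(frozen=True)
class BmFit:
    """GLS/ML fit of single-rate Brownian motion to tip values."""

    ancestral_mean: float
    rate: float  # sigma^2, trait variance per unit time

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise EssimError("negative BM rate")


def _align_trait(vcv_m: VcvMatrix, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [s for s in vcv_m.species if s not in trait.index]
        if missing:
            raise EssimError(f"trait missing for species: {missing[:5]}")
        return trait.loc[list(vcv_m.species)].to_numpy(dtype=float)
    x = np.asarray(trait, dtype=float)
    if x.shape != (vcv_m.n,):
        raise EssimError("trait vector length does not match VCV")
    return x


def fit_bm(vcv_m: VcvMatrix, trait) -> BmFit:
    """Fit BM by GLS: a = (1'C^-1 1)^-1 1'C^-1 x and
    sigma^2 = (x - a 1)' C^-1 (x - a 1) / n (the ML estimator)."""
    x = _align_trait(vcv_m, trait)
    C = vcv_m.matrix
    try:
        cf = cho_factor(C)
    except LinAlgError as exc:
        raise EssimError(
            "singular phylogenetic covariance (duplicate tips at zero "
            "distance?); jitter branch lengths or drop duplicates"
        ) from exc
    ones = np.ones(vcv_m.n)
    Ci1 = cho_solve(cf, ones)
    a = float(ones @ cho_solve(cf, x)) / float(ones @ Ci1)
    resid = x - a
    sigma2 = float(resid @ cho_solve(cf, resid)) / vcv_m.n
    return BmFit(a, max(sigma2, 0.0))


def simulate_bm_traits(
    vcv_m: VcvMatrix, fit: BmFit, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_sim`` neutral trait vectors from N(a, sigma^2 C); returns
    an (n_species, n_sim) array."""
    L = cholesky(vcv_m.matrix + 1e-12 * np.eye(vcv_m.n), lower=True)
    Z = rng.standard_normal((vcv_m.n, n_sim))
    return fit.ancestral_mean + np.sqrt(fit.rate) * (L @ Z)


@dataclass(frozen=True)
class ESSimResult:
    rho_obs: float
    slope: float
    p_value: float
    null_rho: np.ndarray = field(repr=False)
    n_sim: int = 100
    seed: int | None = None
    n_species: int = 0
    trait_transform: str = "identity"
    rate_transform: str = "log"
    trait_shift: float = 0.0  # the c in log(x + c)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho_obs <= 1.0 + 1e-12:
            raise EssimError("correlation outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise EssimError("p-value outside (0, 1]")


def _transform_trait(x: np.ndarray, how: str) -> tuple[np.ndarray, float]:
    if how == "identity":
        return x, 0.0
    if how == "log_shift":
        # Shift only when needed to absorb exact zeros: c is the smallest
        # positive value observed, 0 if the trait is already positive.
        if np.any(x < 0):
            raise EssimError("log_shift transform requires non-negative trait")
        positive = x[x > 0]
        if positive.size == 0:
            raise EssimError("trait is identically zero; log transform undefined")
        c = float(positive.min()) if np.any(x == 0) else 0.0
        return np.log(x + c), c
    raise EssimError(f"unknown trait transform {how!r}")


def _pearson_many(Y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of Y with r."""
    Yc = Y - Y.mean(axis=0, keepdims=True)
    rc = r - r.mean()
    denom = np.linalg.norm(Yc, axis=0) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Yc.T @ rc) / denom
    return np.nan_to_num(rho, nan=0.0)


def essim(
    tree: PhyloTree | VcvMatrix,
    trait,
    rates=None,
    n_sim: int = 100,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    trait_transform: str = "identity",
    rate_transform: str = "log",
) -> ESSimResult:
    """Test the association between a tip trait and lambda_DR against a
    Brownian-motion null simulated on the same tree.

    ``tree`` may be a :class:`PhyloTree` (the VCV and, if ``rates`` is
    omitted, lambda_DR are computed from it) or a precomputed
    :class:`VcvMatrix` (then ``rates`` is required).  ``trait`` and
    ``rates`` may be pandas Series indexed by species or arrays in VCV
    order.  The reported slope is the OLS slope of lambda_DR on the
    *untransformed* trait.
    """
    if n_sim < 1:
        raise EssimError("n_sim must be >= 1")
    if isinstance(tree, VcvMatrix):
        vcv_m = tree
        if rates is None:
            raise EssimError("rates are required when passing a VcvMatrix")
    else:
        vcv_m = _vcv(tree)
        if rates is None:
            rates = dr_statistic(tree)
    if hasattr(rates, "series"):
        rates = rates.series()
    lam = _align_trait(vcv_m, rates)
    x_raw = _align_trait(vcv_m, trait)
    if vcv_m.n < 4:
        raise EssimError("need at least 4 species")
    if np.ptp(x_raw) == 0:
        raise EssimError("constant trait: correlation undefined")

    y, shift = _transform_trait(x_raw, trait_transform)
    if np.ptp(y) == 0:
        raise EssimError("trait constant after transformation")
    if rate_transform == "log":
        r = np.log(lam)
    elif rate_transform == "identity":
        r = lam.astype(float)
    else:
        raise EssimError(f"unknown rate transform {rate_transform!r}")

    rho_obs = float(_pearson_many(y[:, None], r)[0])
    slope = float(np.cov(x_raw, lam, ddof=1)[0, 1] / np.var(x_raw, ddof=1))

    fit = fit_bm(vcv_m, y)
    if rng is None:
        rng = np.random.default_rng(seed)
    null_traits = simulate_bm_traits(vcv_m, fit, n_sim, rng)
    null_rho = _pearson_many(null_traits, r)
    n_extreme = int(np.sum(np.abs(null_rho) >= abs(rho_obs)))
    p = (1 + n_extreme) / (n_sim + 1)
    return ESSimResult(
        rho_obs=rho_obs,
        slope=slope,
        p_value=p,
        null_rho=null_rho,
        n_sim=n_sim,
        seed=seed,
        n_species=vcv_m.n,
        trait_transform=trait_transform,
        rate_transform=rate_transform,
        trait_shift=shift,
    )


# ---------------------------------------------------------------------
# Topology ensembles
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleResult:
    """Per-topology test records plus the slope distribution across trees.

    One record per input tree (failed trees are listed in ``failures``
    and skipped, not fatal).  ``frac_significant`` is the fraction of
    per-topology p-values below alpha, with no multiple-testing
    correction: each topology is a complete re-analysis, not an
    independent hypothesis.
    """

    records: pd.DataFrame
    alpha: float
    seed: int | None
    failures: tuple[tuple[int, str], ...] = ()

    @property
    def slopes(self) -> np.ndarray:
        return self.records["slope"].to_numpy()

    @property
    def frac_significant(self) -> float:
        return float((self.records["p"] < self.alpha).mean())

    def slope_summary(self) -> dict:
        s = self.slopes
        qs = np.percentile(s, [2.5, 25, 50, 75, 97.5]) if s.size else [np.nan] * 5
        return {
            "n_topologies": int(s.size),
            "slope_min": float(s.min()) if s.size else np.nan,
            "slope_q025": float(qs[0]),
            "slope_q25": float(qs[1]),
            "slope_median": float(qs[2]),
            "slope_q75": float(qs[3]),
            "slope_q975": float(qs[4]),
            "slope_max": float(s.max()) if s.size else np.nan,
            "frac_positive": float((s > 0).mean()) if s.size else np.nan,
            "frac_significant": self.frac_significant,
        }


def ensemble(
    trees: TreeEnsemble | list[PhyloTree],
    overlap: OverlapMatrix,
    *,
    trait: pd.Series | None = None,
    n_sim: int = 100,
    seed: int | None = 0,
    alpha: float = 0.05,
    include_self: bool = False,
    weight: str = "vcv",
    area_scale: float = 1.0,
    trait_transform: str = "log_shift",
    rate_transform: str = "log",
) -> EnsembleResult:
    """Run the trait-rate test across alternative topologies.

    For each tree: recompute the VCV and lambda_DR, recompute clade
    density from ``overlap`` and that tree's VCV (unless a fixed ``trait``
    Series overrides it), and run :func:`essim` with the *same* seed, so a
    repeated identical tree yields identical records and a one-tree
    ensemble equals a single :func:`essim` call.
    """
    tree_list = list(trees)
    rows = []
    failures: list[tuple[int, str]] = []
    for k, tree in enumerate(tree_list):
        try:
            vcv_k = _vcv(tree)
            rates_full = dr_statistic(tree)
            if trait is None:
                o_k, v_k, rep = align_species(overlap, vcv_k)
                cd = clade_density(
                    o_k,
                    v_k,
                    include_self=include_self,
                    weight=weight,
                    area_scale=area_scale,
                    tree_id=f"tree_{k}",
                    alignment=rep,
                )
                trait_k = cd.series()
            else:
                trait_k = trait
            common = [s for s in vcv_k.species if s in trait_k.index]
            sub_v = _subset_vcv(vcv_k, common)
            res = essim(
                sub_v,
                trait_k.loc[common],
                rates=rates_full.series().loc[common],
                n_sim=n_sim,
                seed=seed,
                trait_transform=trait_transform,
                rate_transform=rate_transform,
            )
            rows.append(
                {
                    "tree_id": k,
                    "n_species": res.n_species,
                    "rho": res.rho_obs,
                    "slope": res.slope,
                    "p": res.p_value,
                }
            )
        except Exception as exc:  # record and continue: one bad topology
            logger.warning("tree %d failed: %s", k, exc)
            failures.append((k, str(exc)))
    records = pd.DataFrame(
        rows, columns=["tree_id", "n_species", "rho", "slope", "p"]
    )
    return EnsembleResult(records, alpha=alpha, seed=seed, failures=tuple(failures))


def _subset_vcv(vcv_m: VcvMatrix, keep: list[str]) -> VcvMatrix:
    idx = {s: i for i, s in enumerate(vcv_m.species)}
    sel = np.array([idx[s] for s in keep])
    return VcvMatrix(tuple(keep), vcv_m.matrix[np.ix_(sel, sel)])
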