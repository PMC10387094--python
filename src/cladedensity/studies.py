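"""Reusable simulation studies: calibration and power of the trait-rate test.

These are the experiments a user runs to convince themselves the test is
trustworthy on data like theirs: type-I error under the neutral generator,
power against trait-dependent speciation, and the behavior of a full
topology-ensemble analysis when nothing is going on.  Each function is
deterministic given its seed (replicate seeds are spawned from a single
SeedSequence) and returns plain numbers.
"""

from __future__ import annotations

import numpy as np

from .essim import EnsembleResult, ensemble, essim
from .geometry import compute_overlap_matrix
from .synthetic import ScenarioConfig, simulate_ranges, simulate_tree

__all__ = ["type_one_error", "power_curve", "null_ensemble_study"]


def type_one_error(
    n_replicates: int = 500,
    n_tips: int = 100,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the trait-rate test when the trait is neutral BM.

    Each replicate simulates a fresh constant-rate tree with a Brownian
    tip trait and tests it against lambda_DR; under this null the
    rejection rate should sit at ``alpha``.
    """
    cfg = ScenarioConfig(n_tips=n_tips, seed=0)
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        tree, trait = simulate_tree(cfg, rng)
        res = essim(tree, trait, n_sim=n_sim, rng=rng)
        rejections += res.p_value <= alpha
    return rejections / n_replicates


def power_curve(
    betas=(0.0, 0.5, 1.0, 2.0),
    n_replicates: int = 100,
    n_tips: int = 100,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[float, float]:
    """Rejection rate versus the strength beta of trait-dependent
    speciation (lambda(x) = lambda0 exp(beta x)); beta = 0 is the null."""
    out: dict[float, float] = {}
    for b_index, beta in enumerate(betas):
        cfg = ScenarioConfig(
            n_tips=n_tips,
            trait_model="speciation_dependent",
            speciation_effect=float(beta),
            seed=0,
        )
        ss = np.random.SeedSequence([seed, b_index])
        rejections = 0
        for child in ss.spawn(n_replicates):
            rng = np.random.default_rng(child)
            tree, trait = simulate_tree(cfg, rng)
            res = essim(tree, trait, n_sim=n_sim, rng=rng)
            rejections += res.p_value <= alpha
        out[float(beta)] = rejections / n_replicates
    return out


def null_ensemble_study(
    n_topologies: int = 100,
    n_tips: int = 100,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> EnsembleResult:
    """A full clade-density analysis across alternative topologies when
    speciation is trait-independent.

    Ranges are simulated once (on the first topology); every topology then
    contributes its own VCV, lambda_DR, and clade density.  Because
    nothing links geography to speciation, per-topology slopes should
    scatter around zero and significance should be at chance level.
    """
    cfg = ScenarioConfig(n_tips=n_tips, seed=0)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_topologies + 1)
    trees = [
        simulate_tree(cfg, np.random.default_rng(child))[0]
        for child in children[:n_topologies]
    ]
    ranges = simulate_ranges(trees[0], cfg, np.random.default_rng(children[-1]))
    overlap = compute_overlap_matrix(ranges)
    return ensemble(trees, overlap, n_sim=n_sim, seed=seed, alpha=alpha)
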