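"""Tree prior, molecular-clock models, and the joint log-prior.

The tree prior is a Yule (pure-birth) process with birth rate ``lambda``
(events/lineage/Ma) and an optional uniform hyperprior on ``lambda``.  Two
clock models are provided: a strict clock (one rate, substitutions/site/Ma)
and an uncorrelated log-normal (ULN) relaxed clock with i.i.d. per-branch
rates whose *real-space* mean equals the clock's mean rate.

Calibration densities multiply the tree prior without any interaction
correction for nested calibrated nodes — the behaviour of the standard
node-dating tools this package mirrors; it is an approximation whenever
calibrated nodes are nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .calibration import CalibrationScheme, make_logpdf
from .timetree import TimeTree, TreeError

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class ClockModel:
    """Strict or uncorrelated-lognormal branch-rate model.

    ``branch_rates`` (ULN state) holds the per-branch rate *multipliers*
    indexed by child-node index; the realized branch rate is
    ``mean_rate * multiplier`` with multipliers i.i.d. log-normal with
    real-space mean 1 and log-sd ``uln_sigma``.
    """

    kind: str = "strict"  # strict | ULN
    mean_rate: float = 0.01
    uln_sigma: float = 0.0
    branch_rates: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("strict", "ULN"):
            raise ValueError(f"clock kind must be strict or ULN, got {self.kind!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")
        if self.kind == "ULN" and self.uln_sigma < 0:
            raise ValueError("uln_sigma must be >= 0")


def sample_branch_rates(
    clock: ClockModel, tree: TimeTree, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. ULN branch-rate multipliers (real-space mean 1).

    Indexed by child-node index; the root slot is unused and set to 1.
    """
    if clock.kind != "ULN":
        raise ValueError("branch rates are only sampled under the ULN clock")
    n = 2 * tree.n_tips - 1
    s = clock.uln_sigma
    m = -s * s / 2.0  # real-space mean 1
    mult = np.exp(rng.normal(m, s, size=n)) if s > 0 else np.ones(n)
    mult[-1] = 1.0  # root has no branch
    return mult


def branch_rate_vector(tree: TimeTree, clock: ClockModel) -> np.ndarray:
    """Per-branch rates (subs/site/Ma) indexed by child-node index."""
    n = 2 * tree.n_tips - 1
    if clock.kind == "strict":
        return np.full(n, clock.mean_rate)
    if clock.branch_rates is None:
        raise ValueError("ULN clock without assigned branch rates")
    return clock.mean_rate * np.asarray(clock.branch_rates)


def branch_distances(tree: TimeTree, clock: ClockModel) -> np.ndarray:
    """Expected substitutions/site per branch, indexed by child-node index."""
    rates = branch_rate_vector(tree, clock)
    dist = np.zeros_like(rates)
    for node in tree.postorder():
        if node.parent is not None:
            dist[node.index] = (node.parent.age - node.age) * rates[node.index]
    return dist


def uln_multiplier_logpdf(mult: float, sigma: float) -> float:
    """Log density of one ULN multiplier (log-normal, real-space mean 1)."""
    if mult <= 0:
        return -math.inf
    if sigma == 0:
        return 0.0
    m = -sigma * sigma / 2.0
    lx = math.log(mult)
    return -lx - math.log(sigma) - _LOG_SQRT_2PI - (lx - m) ** 2 / (2 * sigma * sigma)


@dataclass(frozen=True)
class YulePrior:
    """Pure-birth tree prior with a uniform hyperprior on the birth rate."""

    birth_rate: float = 0.1
    hyper_lo: float = 0.0
    hyper_hi: float = 100.0

    def __post_init__(self):
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if not 0 <= self.hyper_lo < self.hyper_hi:
            raise ValueError("hyperprior bounds must satisfy 0 <= lo < hi")

    def hyper_logpdf(self, lam: float) -> float:
        if self.hyper_lo < lam < self.hyper_hi:
            return -math.log(self.hyper_hi - self.hyper_lo)
        return -math.inf


def yule_log_density(tree: TimeTree, birth_rate: float) -> float:
    """Unnormalized Yule log density: (n-1) ln(lambda) - lambda * tree length.

    Constants free of ``lambda`` and of node ages are dropped; for a 2-tip
    tree this makes the root-age marginal Exponential(2 lambda).
    """
    if birth_rate <= 0:
        return -math.inf
    n = tree.n_tips
    return (n - 1) * math.log(birth_rate) - birth_rate * tree.total_branch_length()


def yule_log_density_from_arrays(
    n_tips: int, total_length: float, birth_rate: float
) -> float:
    if birth_rate <= 0:
        return -math.inf
    return (n_tips - 1) * math.log(birth_rate) - birth_rate * total_length


def joint_log_prior(
    tree: TimeTree,
    birth_rate: float,
    clock: ClockModel,
    scheme: CalibrationScheme,
    yule: Optional[YulePrior] = None,
    tree_prior: str = "yule",
) -> float:
    """Yule term + calibration log-densities + hyperpriors + ULN rate terms.

    Returns ``-inf`` when any calibrated node age leaves its support or the
    age ordering is violated; a rejection signal, not an error.
    ``tree_prior="none"`` drops the Yule term (flat prior over valid ages), a
    validation mode for comparing sampled node ages with analytic calibration
    quantiles.
    """
    yule = yule or YulePrior(birth_rate)
    for node in tree.postorder():
        if node.parent is not None and node.parent.age <= node.age:
            return -math.inf
    total = 0.0
    if tree_prior == "yule":
        total += yule_log_density(tree, birth_rate) + yule.hyper_logpdf(birth_rate)
    elif tree_prior != "none":
        raise ValueError(f"unknown tree prior {tree_prior!r}")
    for node_idx, density, _name in scheme.resolve(tree):
        age = tree.nodes()[node_idx].age
        lp = density.log_pdf(age)
        if not math.isfinite(lp):
            return -math.inf
        total += lp
    if clock.kind == "ULN" and clock.branch_rates is not None:
        for node in tree.postorder():
            if node.parent is None:
                continue
            total += uln_multiplier_logpdf(
                float(clock.branch_rates[node.index]), clock.uln_sigma
            )
    return total
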