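"""Metropolis-Hastings sampler over node ages and clock/model parameters.

The sampler targets the usual node-dating posterior: pruning likelihood
(optional; switch it off for prior-only validation) times Yule tree prior,
calibration densities, hyperpriors and — under the relaxed clock — the ULN
branch-rate prior.  Topology is fixed by default (all reported quantities are
node ages); a constrained nearest-neighbour-interchange mode mirrors runs
started from a random tree.

Moves: node-age uniform slide, root-age scale, whole-tree scale, a
rate/tree anti-scale that moves along the rate-time ridge without changing
branch distances, scale moves on the birth rate and clock mean, ULN
single-branch resampling, and (optionally) constrained NNI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationScheme, make_logpdf
from .prior_clock import (
    ClockModel,
    YulePrior,
    sample_branch_rates,
    uln_multiplier_logpdf,
    yule_log_density_from_arrays,
)
from .seqlike import (
    Alignment,
    PartitionScheme,
    SubstitutionModel,
    build_partition_likelihoods,
)
from .timetree import CladeConstraint, TimeTree, TreeError, check_constraints

__all__ = [
    "McmcSettings",
    "DatingProblem",
    "PosteriorTrace",
    "NodeAgeSummary",
    "init_state",
    "run_chain",
    "ess",
    "hpd_interval",
    "summarize_clades",
]


class McmcError(RuntimeError):
    pass


@dataclass(frozen=True)
class McmcSettings:
    """Chain length is in states; one trace row every ``sample_interval``."""

    chain_length: int = 1_000_000
    sample_interval: int = 1_000
    burnin_fraction: float = 0.1
    topology_mode: str = "fixed"  # fixed | constrained-sampled
    sample_substitution: bool = False
    sample_trees: bool = False
    move_weights: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.chain_length < self.sample_interval:
            raise ValueError("chain_length must be >= sample_interval")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.topology_mode not in ("fixed", "constrained-sampled"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")


@dataclass
class DatingProblem:
    """Everything one chain needs.

    ``alignment`` of ``None`` runs prior-only (likelihood identically 0).
    ``tree_prior`` is ``"yule"`` or ``"none"`` (flat over valid age
    configurations; used to validate prior sampling against analytic
    calibration quantiles).
    """

    tree: TimeTree
    settings: McmcSettings
    alignment: Optional[Alignment] = None
    partition_scheme: Optional[PartitionScheme] = None
    models: SubstitutionModel | dict[str, SubstitutionModel] | None = None
    clock: ClockModel = field(default_factory=ClockModel)
    yule: YulePrior = field(default_factory=YulePrior)
    scheme: CalibrationScheme = field(default_factory=CalibrationScheme)
    constraints: tuple[CladeConstraint, ...] = ()
    tracked_clades: tuple[CladeConstraint, ...] = ()
    tree_prior: str = "yule"


@dataclass(frozen=True)
class NodeAgeSummary:
    clade: str
    median: float
    mean: float
    hpd_lo: float
    hpd_hi: float
    ess: float
    n: int

    def __post_init__(self):
        if not (self.hpd_lo <= self.median <= self.hpd_hi):
            raise ValueError("HPD interval must bracket the median")


@dataclass
class PosteriorTrace:
    """MCMC samples: a data frame plus optional sampled trees (Newick)."""

    df: pd.DataFrame
    settings: McmcSettings
    seed_info: str = ""
    trees: list[str] = field(default_factory=list)

    def post_burnin(self, burnin_fraction: Optional[float] = None) -> pd.DataFrame:
        frac = (
            self.settings.burnin_fraction
            if burnin_fraction is None
            else burnin_fraction
        )
        drop = math.floor(frac * len(self.df))
        return self.df.iloc[drop:]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# carabclock trace; seed={self.seed_info}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str, settings: Optional[McmcSettings] = None) -> "PosteriorTrace":
        df = pd.read_csv(path, sep="\t", comment="#")
        return PosteriorTrace(df, settings or McmcSettings(chain_length=1, sample_interval=1))


# ----------------------------------------------------------------------
# diagnostics


def ess(samples: Sequence[float]) -> float:
    """Effective sample size, n / (1 + 2 sum of autocorrelations).

    Autocorrelations are truncated by Geyer's initial positive sequence
    (pair sums of successive lags kept while positive).  A zero-variance
    series has ESS defined as n (with a warning).
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("ESS needs at least 10 samples")
    if np.all(x == x[0]):
        warnings.warn("zero-variance series; ESS defined as n", stacklevel=2)
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    total = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        total += pair
        k += 2
    return float(n / (1.0 + 2.0 * total))


def hpd_interval(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ceil(level*n).

    Ties in width resolve to the smallest lower endpoint.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("HPD needs at least 20 samples")
    m = math.ceil(level * n)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> smallest lower endpoint
    return float(x[i]), float(x[i + m - 1])


def summarize_clades(
    trace: PosteriorTrace,
    clades: Sequence[str],
    burnin_fraction: Optional[float] = None,
) -> list[NodeAgeSummary]:
    """Median / mean / 95% HPD / ESS per tracked clade column."""
    df = trace.post_burnin(burnin_fraction)
    out = []
    for clade in clades:
        col = "root_age" if clade == "root" else f"tmrca.{clade}"
        if col not in df.columns:
            raise McmcError(f"clade {clade!r} not tracked in trace")
        x = df[col].to_numpy()
        lo, hi = hpd_interval(x)
        out.append(
            NodeAgeSummary(
                clade=clade,
                median=float(np.median(x)),
                mean=float(x.mean()),
                hpd_lo=lo,
                hpd_hi=hi,
                ess=ess(x),
                n=len(x),
            )
        )
    return out


# ----------------------------------------------------------------------
# sampler internals


class _State:
    """Mutable sampler state bound to a TimeTree's index layout."""

    def __init__(self, problem: DatingProblem, rng: np.random.Generator):
        self.problem = problem
        self.tree = problem.tree.copy()
        self.nodes = self.tree.nodes()
        self.n_tips = self.tree.n_tips
        self.n_nodes = 2 * self.n_tips - 1
        self.root = self.n_nodes - 1
        self.refresh_topology_arrays()
        self.ages = np.array([n.age for n in self.nodes])
        self.lam = problem.yule.birth_rate
        self.rate = problem.clock.mean_rate
        clock = problem.clock
        if clock.kind == "ULN":
            self.multipliers = (
                np.asarray(clock.branch_rates, dtype=float)
                if clock.branch_rates is not None
                else sample_branch_rates(clock, self.tree, rng)
            )
        else:
            self.multipliers = np.ones(self.n_nodes)
        self.uln_sigma = clock.uln_sigma

    def refresh_topology_arrays(self) -> None:
        self.nodes = self.tree.nodes()
        self.parent = np.full(self.n_nodes if hasattr(self, "n_nodes") else 2 * self.tree.n_tips - 1, -1, dtype=int)
        for node in self.nodes:
            if node.parent is not None:
                self.parent[node.index] = node.parent.index
        self.children = {
            node.index: [c.index for c in node.children]
            for node in self.nodes
            if node.children
        }

    def rates(self) -> np.ndarray:
        return self.rate * self.multipliers

    def total_length(self) -> float:
        a = self.ages
        return float(np.sum(a[self.parent[:-1]] - a[:-1]))

    def sync_node_ages(self) -> None:
        for node in self.nodes:
            node.age = float(self.ages[node.index])


def _resolve_calibrations(scheme: CalibrationScheme, tree: TimeTree):
    return [
        (idx, make_logpdf(dens), dens, name) for idx, dens, name in scheme.resolve(tree)
    ]


def _log_prior(state: _State, calibs) -> float:
    p = state.problem
    total = 0.0
    if p.tree_prior == "yule":
        y = p.yule
        if not (y.hyper_lo < state.lam < y.hyper_hi):
            return -math.inf
        total += yule_log_density_from_arrays(
            state.n_tips, state.total_length(), state.lam
        )
        total += y.hyper_logpdf(state.lam)
    for idx, f, _d, _n in calibs:
        lp = f(float(state.ages[idx]))
        if lp == -math.inf:
            return -math.inf
        total += lp
    if p.clock.kind == "ULN" and state.uln_sigma > 0:
        s = state.uln_sigma
        m = np.delete(state.multipliers, state.root)
        if np.any(m <= 0):
            return -math.inf
        lx = np.log(m)
        total += float(
            np.sum(-lx - math.log(s) - 0.5 * math.log(2 * math.pi) - (lx + s * s / 2) ** 2 / (2 * s * s))
        )
    return total


def init_state(
    problem: DatingProblem, rng: np.random.Generator, max_tries: int = 10_000
) -> _State:
    """Build a starting state whose joint prior is finite.

    Node ages are rejection-sampled: the root age is drawn from the root
    calibration (when present), internal ages rescaled proportionally and
    jittered, strict ordering restored, until every calibrated node sits
    inside its support.
    """
    state = _State(problem, rng)
    calibs = _resolve_calibrations(problem.scheme, state.tree)
    base_ages = state.ages.copy()
    root_entry = problem.scheme.root_entry
    for attempt in range(max_tries):
        ages = base_ages.copy()
        if attempt > 0:
            if root_entry is not None:
                target_root = root_entry.density.quantile(rng.uniform(0.1, 0.9))
                scale = target_root / base_ages[state.root]
            else:
                scale = math.exp(rng.normal(0.0, 0.3))
            internal = slice(state.n_tips, state.n_nodes)
            ages[internal] = base_ages[internal] * scale * rng.uniform(
                0.95, 1.05, state.n_tips - 1
            )
            # restore strict ordering, raising parents above children
            for idx in range(state.n_tips, state.n_nodes):
                top = max(ages[c] for c in state.children[idx])
                if ages[idx] <= top:
                    ages[idx] = top + 1e-6
        if attempt > 0:
            # nudge calibrated internal nodes into their supports
            for idx, f, dens, _name in sorted(calibs):
                if idx == state.root or f(float(ages[idx])) > -math.inf:
                    continue
                draw = dens.quantile(rng.uniform(0.05, 0.95))
                lo = max(ages[c] for c in state.children[idx])
                hi = ages[state.parent[idx]] if state.parent[idx] != -1 else math.inf
                if hi > lo:
                    ages[idx] = min(max(draw, lo + 1e-6), hi - 1e-6) if math.isfinite(hi) else max(draw, lo + 1e-6)
            for idx in range(state.n_tips, state.n_nodes):
                top = max(ages[c] for c in state.children[idx])
                if ages[idx] <= top:
                    ages[idx] = top + 1e-6
        state.ages = ages
        if _log_prior(state, calibs) > -math.inf:
            state.sync_node_ages()
            report = check_constraints(state.tree, list(problem.constraints))
            bad = [k for k, ok in report.items() if not ok]
            if bad:
                raise McmcError(f"starting tree violates constraints: {bad}")
            return state
    blocking = [
        name
        for idx, f, _d, name in calibs
        if f(float(state.ages[idx])) == -math.inf
    ]
    raise McmcError(
        f"could not initialize a state with finite prior after {max_tries} tries; "
        f"blocking calibrations: {blocking or 'age ordering'}"
    )


_DEFAULT_WEIGHTS = {
    "node_slide": 0.40,
    "root_cal_draw": 0.10,
    "root_scale": 0.10,
    "tree_scale": 0.08,
    "rate_time_ridge": 0.12,
    "lam_scale": 0.10,
    "rate_scale": 0.10,
    "uln_branch": 0.10,
    "nni": 0.0,
}


def _move_table(
    problem: DatingProblem, extra_zero: Optional[dict[str, float]] = None
) -> tuple[list[str], np.ndarray]:
    weights = dict(_DEFAULT_WEIGHTS)
    if problem.settings.move_weights:
        weights.update(problem.settings.move_weights)
    if extra_zero:
        weights.update(extra_zero)
    if problem.clock.kind != "ULN":
        weights["uln_branch"] = 0.0
    if problem.alignment is None:
        # prior-only: rate moves are meaningless, ridge move still valid for ages
        weights["rate_scale"] = 0.0
        weights["rate_time_ridge"] = 0.0
    if problem.tree_prior == "none":
        weights["lam_scale"] = 0.0
    if problem.settings.topology_mode == "constrained-sampled":
        weights.setdefault("nni", 0.0)
        if weights["nni"] == 0.0:
            weights["nni"] = 0.10
    names = [k for k, w in weights.items() if w > 0]
    w = np.array([weights[k] for k in names])
    return names, w / w.sum()


def run_chain(problem: DatingProblem, rng: np.random.Generator) -> PosteriorTrace:
    """Run Metropolis-Hastings and return the posterior trace.

    Deterministic given the generator state; the trace has
    ``floor(chain_length / sample_interval) + 1`` rows (state 0 included).
    """
    settings = problem.settings
    state = init_state(problem, rng)
    calibs = _resolve_calibrations(problem.scheme, state.tree)
    tracked = [
        (c.name, state.tree.mrca(c.taxon_set).index) for c in problem.tracked_clades
    ]

    engines = []
    if problem.alignment is not None:
        scheme = problem.partition_scheme or PartitionScheme.single(
            problem.alignment.length
        )
        models = problem.models or SubstitutionModel("HKY", gamma_shape=None)
        engines = build_partition_likelihoods(
            problem.alignment, state.tree, scheme, models
        )

    def full_loglik() -> float:
        if not engines:
            return 0.0
        rates = state.rates()
        return sum(e.full(state.ages, rates) for e in engines)

    log_prior = _log_prior(state, calibs)
    if not math.isfinite(log_prior):
        raise McmcError("initial state has zero prior probability")
    loglik = full_loglik()
    if not math.isfinite(loglik):
        raise McmcError("non-finite likelihood at the initial state")

    internal_non_root = np.arange(state.n_tips, state.n_nodes - 1)
    branch_nodes = np.arange(0, state.n_nodes - 1)
    n_internal = state.n_tips - 1
    # independence kernel for the root age, proposing from the root
    # calibration density (sharp offset priors mix poorly under scale moves)
    root_calib = next(
        ((f, d) for idx, f, d, _n in calibs if idx == state.root), None
    )
    extra_zero = {"node_slide": 0.0} if len(internal_non_root) == 0 else {}
    if root_calib is None:
        extra_zero["root_cal_draw"] = 0.0
    move_names, move_probs = _move_table(problem, extra_zero)

    move_cumprobs = np.cumsum(move_probs)

    # batched draws for the root-calibration independence kernel (scalar
    # scipy ppf calls are far slower than one vectorized batch)
    _draw_buf: list[float] = []

    def next_root_draw() -> float:
        if not _draw_buf:
            _draw_buf.extend(root_calib[1].sample(rng, size=4096))
        return _draw_buf.pop()

    rows: list[list[float]] = []
    tree_samples: list[str] = []
    columns = (
        ["state", "posterior", "likelihood", "prior", "root_age"]
        + [f"tmrca.{name}" for name, _ in tracked]
        + ["lambda", "clock.rate"]
    )

    def record(step: int) -> None:
        rows.append(
            [
                step,
                loglik + log_prior,
                loglik,
                log_prior,
                float(state.ages[state.root]),
            ]
            + [float(state.ages[idx]) for _, idx in tracked]
            + [state.lam, state.rate]
        )
        if settings.sample_trees:
            from .timetree import write_newick

            state.sync_node_ages()
            tree_samples.append(write_newick(state.tree, precision=8))

    record(0)

    for step in range(1, settings.chain_length + 1):
        move = move_names[int(np.searchsorted(move_cumprobs, rng.random()))]
        log_hastings = 0.0
        dirty: Optional[list[int]] = None  # None -> full recompute
        touched_likelihood = True
        undo = None

        if move == "node_slide":
            v = int(internal_non_root[rng.integers(len(internal_non_root))])
            lo = max(state.ages[c] for c in state.children[v])
            hi = state.ages[state.parent[v]]
            old = state.ages[v]
            state.ages[v] = rng.uniform(lo, hi)
            undo = ("age", v, old)
            dirty = [v] + state.children[v]
        elif move == "root_cal_draw":
            f, dens = root_calib
            old = state.ages[state.root]
            new = next_root_draw()
            if new <= max(state.ages[c] for c in state.children[state.root]):
                if step % settings.sample_interval == 0:
                    record(step)
                continue
            state.ages[state.root] = new
            log_hastings = f(old) - f(new)
            undo = ("age", state.root, old)
            dirty = state.children[state.root]
        elif move == "root_scale":
            m = math.exp(0.2 * (rng.random() - 0.5))
            old = state.ages[state.root]
            new = m * old
            if new <= max(state.ages[c] for c in state.children[state.root]):
                if step % settings.sample_interval == 0:
                    record(step)
                continue  # ordering violated; reject outright
            state.ages[state.root] = new
            log_hastings = math.log(m)
            undo = ("age", state.root, old)
            dirty = state.children[state.root]
        elif move == "tree_scale":
            m = math.exp(0.15 * (rng.random() - 0.5))
            old_ages = state.ages[state.n_tips :].copy()
            state.ages[state.n_tips :] *= m
            log_hastings = n_internal * math.log(m)
            undo = ("ages", old_ages)
            dirty = None
        elif move == "rate_time_ridge":
            # scale all ages by m and the clock rate by 1/m: distances fixed
            m = math.exp(0.3 * (rng.random() - 0.5))
            old_ages = state.ages[state.n_tips :].copy()
            old_rate = state.rate
            state.ages[state.n_tips :] *= m
            state.rate = old_rate / m
            log_hastings = (n_internal - 1) * math.log(m)
            undo = ("ages_rate", old_ages, old_rate)
            touched_likelihood = False  # branch distances unchanged
        elif move == "lam_scale":
            m = math.exp(0.5 * (rng.random() - 0.5))
            old = state.lam
            state.lam = m * old
            log_hastings = math.log(m)
            undo = ("lam", old)
            touched_likelihood = False
        elif move == "rate_scale":
            m = math.exp(0.2 * (rng.random() - 0.5))
            old = state.rate
            state.rate = m * old
            log_hastings = math.log(m)
            undo = ("rate", old)
            dirty = list(branch_nodes)
        elif move == "uln_branch":
            v = int(branch_nodes[rng.integers(len(branch_nodes))])
            old = state.multipliers[v]
            s = state.uln_sigma
            new = math.exp(rng.normal(-s * s / 2.0, s)) if s > 0 else 1.0
            state.multipliers[v] = new
            # independence proposal from the prior
            log_hastings = uln_multiplier_logpdf(old, s) - uln_multiplier_logpdf(new, s)
            undo = ("mult", v, old)
            dirty = [v]
        elif move == "nni":
            accepted = _try_nni(state, problem, engines, calibs, log_prior, rng)
            if accepted is not None:
                log_prior, loglik, calibs = accepted
                tracked = [
                    (c.name, state.tree.mrca(c.taxon_set).index)
                    for c in problem.tracked_clades
                ]
            if step % settings.sample_interval == 0:
                record(step)
            continue
        else:  # pragma: no cover
            raise McmcError(f"unknown move {move}")

        new_prior = _log_prior(state, calibs)
        if new_prior == -math.inf:
            _undo(state, undo)
            if step % settings.sample_interval == 0:
                record(step)
            continue

        if touched_likelihood and engines:
            rates = state.rates()
            if dirty is None:
                backup = [
                    (e.pmats.copy(), e.partials.copy(), e.scalers.copy(), e.loglik)
                    for e in engines
                ]
                new_loglik = sum(e.full(state.ages, rates) for e in engines)
            else:
                backup = None
                new_loglik = sum(e.update(dirty, state.ages, rates) for e in engines)
        else:
            backup = None
            new_loglik = loglik

        log_alpha = (new_loglik + new_prior) - (loglik + log_prior) + log_hastings
        if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
            log_prior, loglik = new_prior, new_loglik
            if touched_likelihood and engines and dirty is not None:
                for e in engines:
                    e.accept()
        else:
            _undo(state, undo)
            if touched_likelihood and engines:
                if dirty is None:
                    for e, (pm, pa, sc, ll) in zip(engines, backup):
                        e.pmats, e.partials, e.scalers, e._loglik = pm, pa, sc, ll
                else:
                    for e in engines:
                        e.revert()

        if not math.isfinite(loglik):
            raise McmcError(f"non-finite likelihood at state {step}")
        if step % settings.sample_interval == 0:
            record(step)

    df = pd.DataFrame(rows, columns=columns)
    return PosteriorTrace(df, settings, trees=tree_samples)


def _undo(state: _State, undo) -> None:
    kind = undo[0]
    if kind == "age":
        state.ages[undo[1]] = undo[2]
    elif kind == "ages":
        state.ages[state.n_tips :] = undo[1]
    elif kind == "ages_rate":
        state.ages[state.n_tips :] = undo[1]
        state.rate = undo[2]
    elif kind == "lam":
        state.lam = undo[1]
    elif kind == "rate":
        state.rate = undo[1]
    elif kind == "mult":
        state.multipliers[undo[1]] = undo[2]


def _try_nni(
    state, problem, engines, calibs, old_prior, rng
) -> Optional[tuple[float, float, list]]:
    """Constrained nearest-neighbour interchange.

    Returns (new prior, new loglik, re-resolved calibrations) on acceptance,
    None on rejection.  The proposal is symmetric (Hastings 0).
    """
    state.sync_node_ages()
    tree = state.tree
    candidates = [n for n in tree.internal_nodes if n.parent is not None]
    if not candidates:
        return None
    v = candidates[rng.integers(len(candidates))]
    parent = v.parent
    sibling = parent.children[0] if parent.children[1] is v else parent.children[1]
    child = v.children[rng.integers(2)]
    if sibling.age >= v.age or child.age >= parent.age:
        return None  # ages incompatible with the swap
    # swap child <-> sibling
    v.children[v.children.index(child)] = sibling
    parent.children[parent.children.index(sibling)] = child
    sibling.parent, child.parent = v, parent

    def undo_swap():
        v.children[v.children.index(sibling)] = child
        parent.children[parent.children.index(child)] = sibling
        sibling.parent, child.parent = parent, v

    report = check_constraints(
        tree, list(problem.constraints) + [e.constraint for e in problem.scheme.entries]
    )
    if not all(report.values()):
        undo_swap()
        return None
    state.refresh_topology_arrays()
    new_calibs = _resolve_calibrations(problem.scheme, tree)
    new_prior = _log_prior(state, new_calibs)
    if new_prior == -math.inf:
        undo_swap()
        state.refresh_topology_arrays()
        return None
    rates = state.rates()
    if engines:
        backups = [
            (
                e.parent.copy(),
                e.children.copy(),
                e.pmats.copy(),
                e.partials.copy(),
                e.scalers.copy(),
                e.loglik,
            )
            for e in engines
        ]
        old_loglik = sum(e.loglik for e in engines)
        for e in engines:
            _engine_set_topology(e, state)
        new_loglik = sum(e.full(state.ages, rates) for e in engines)
    else:
        backups = None
        old_loglik = new_loglik = 0.0
    log_alpha = (new_loglik + new_prior) - (old_loglik + old_prior)
    if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
        return new_prior, new_loglik, new_calibs
    undo_swap()
    state.refresh_topology_arrays()
    if engines:
        for e, (pa, ch, pm, pt, sc, ll) in zip(engines, backups):
            e.parent, e.children, e.pmats, e.partials, e.scalers, e._loglik = (
                pa,
                ch,
                pm,
                pt,
                sc,
                ll,
            )
    return None


def _engine_set_topology(engine, state: _State) -> None:
    engine.parent = state.parent.copy()
    for idx, kids in state.children.items():
        engine.children[idx - state.n_tips] = kids
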