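"""Calibration prior densities on node ages.

Five density families are supported, matching the vocabulary of BEAST-style
node dating: offset log-normal parameterized by its *real-space* mean
("meanInRealSpace"), truncated normal, uniform, offset exponential, and
gamma.  Every density may carry a hard minimum (``offset``, e.g. a fossil's
minimum age) and an optional hard ceiling (``hard_max``, e.g. the oldest
fossil of the family), both in Ma.

The log-normal convention used throughout: a density with real-space mean
``mu_real`` and log-space standard deviation ``sigma_log`` has log-mean
``M = ln(mu_real) - sigma_log**2 / 2``.  This is the unique convention under
which the published prior 95% intervals for the Canary-Islands, fossil and
root calibrations are reproduced analytically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .timetree import CladeConstraint, TimeTree, TreeError, mrca_node

KINDS = ("lognormal_realmean", "truncated_normal", "uniform", "exponential", "gamma")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class CalibrationError(ValueError):
    """Invalid calibration density or scheme."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CalibrationDensity:
    """A prior density on one node age (Ma).

    Parameters are family specific:

    ``lognormal_realmean``
        ``mu_real`` (real-space mean, Ma), ``sigma_log`` (log-space sd).
    ``truncated_normal``
        ``mu``, ``sigma``, ``a``, ``b`` — normal renormalized on [a, b].
    ``uniform``
        ``lower``, ``upper``.
    ``exponential``
        ``mean``.
    ``gamma``
        ``shape``, ``scale``.

    ``offset`` shifts the whole support older; ``hard_max`` truncates it.
    When ``interval_ignores_hard_max`` is set (the default, matching how the
    published tables report log-normal intervals), the 95% prior interval is
    computed on the un-truncated density even though the density itself is
    renormalized on the truncated support.
    """

    kind: str
    params: tuple[tuple[str, float], ...]
    offset: float = 0.0
    hard_max: Optional[float] = None
    interval_ignores_hard_max: bool = True

    # ------------------------------------------------------------------
    @staticmethod
    def create(
        kind: str,
        offset: float = 0.0,
        hard_max: Optional[float] = None,
        interval_ignores_hard_max: bool = True,
        **params: float,
    ) -> "CalibrationDensity":
        if kind not in KINDS:
            raise CalibrationError(f"unknown density kind {kind!r}; one of {KINDS}")
        d = CalibrationDensity(
            kind=kind,
            params=tuple(sorted((k, float(v)) for k, v in params.items())),
            offset=float(offset),
            hard_max=None if hard_max is None else float(hard_max),
            interval_ignores_hard_max=interval_ignores_hard_max,
        )
        d._check()
        return d

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)

    def _check(self) -> None:
        p = self.p
        need = {
            "lognormal_realmean": {"mu_real", "sigma_log"},
            "truncated_normal": {"mu", "sigma", "a", "b"},
            "uniform": {"lower", "upper"},
            "exponential": {"mean"},
            "gamma": {"shape", "scale"},
        }[self.kind]
        if set(p) != need:
            raise CalibrationError(
                f"{self.kind} needs params {sorted(need)}, got {sorted(p)}"
            )
        positive = {
            "lognormal_realmean": ("mu_real", "sigma_log"),
            "truncated_normal": ("sigma",),
            "uniform": (),
            "exponential": ("mean",),
            "gamma": ("shape", "scale"),
        }[self.kind]
        for name in positive:
            if p[name] <= 0:
                raise CalibrationError(f"{self.kind}: {name} must be > 0")
        if self.kind == "uniform" and not p["lower"] < p["upper"]:
            raise CalibrationError("uniform: lower must be < upper")
        if self.kind == "truncated_normal" and not p["a"] < p["b"]:
            raise CalibrationError("truncated_normal: a must be < b")
        if self.hard_max is not None and self.hard_max <= self.support(False)[0]:
            raise CalibrationError("hard_max below the lower support bound")

    # ------------------------------------------------------------------
    def _base(self) -> stats.rv_continuous:
        """Frozen scipy distribution of the un-offset, un-hard-maxed quantity."""
        cached = getattr(self, "_base_cache", None)
        if cached is not None:
            return cached
        frozen = self._make_base()
        object.__setattr__(self, "_base_cache", frozen)
        return frozen

    def _make_base(self) -> stats.rv_continuous:
        p = self.p
        if self.kind == "lognormal_realmean":
            m = math.log(p["mu_real"]) - p["sigma_log"] ** 2 / 2.0
            return stats.lognorm(p["sigma_log"], scale=math.exp(m))
        if self.kind == "truncated_normal":
            a = (p["a"] - p["mu"]) / p["sigma"]
            b = (p["b"] - p["mu"]) / p["sigma"]
            return stats.truncnorm(a, b, loc=p["mu"], scale=p["sigma"])
        if self.kind == "uniform":
            return stats.uniform(p["lower"], p["upper"] - p["lower"])
        if self.kind == "exponential":
            return stats.expon(scale=p["mean"])
        return stats.gamma(p["shape"], scale=p["scale"])

    def _hard_max_mass(self) -> float:
        """CDF of the base density at the hard ceiling (1 when absent)."""
        if self.hard_max is None:
            return 1.0
        z = float(self._base().cdf(self.hard_max - self.offset))
        if z <= 0:
            raise CalibrationError("hard_max leaves no probability mass")
        return z

    def support(self, with_hard_max: bool = True) -> tuple[float, float]:
        p = self.p
        lo = {
            "lognormal_realmean": 0.0,
            "truncated_normal": p.get("a", 0.0),
            "uniform": p.get("lower", 0.0),
            "exponential": 0.0,
            "gamma": 0.0,
        }[self.kind]
        hi = {
            "lognormal_realmean": math.inf,
            "truncated_normal": p.get("b", math.inf),
            "uniform": p.get("upper", math.inf),
            "exponential": math.inf,
            "gamma": math.inf,
        }[self.kind]
        lo, hi = lo + self.offset, hi + self.offset
        lo = max(lo, 0.0)
        if with_hard_max and self.hard_max is not None:
            hi = min(hi, self.hard_max)
        return lo, hi

    # ------------------------------------------------------------------
    def log_pdf(self, age: float) -> float:
        """Log density at ``age`` (Ma); ``-inf`` outside the support."""
        lo, hi = self.support()
        if not (lo <= age <= hi):
            return -math.inf
        x = age - self.offset
        p = self.p
        if self.kind == "lognormal_realmean":
            if x <= 0:
                return -math.inf
            s = p["sigma_log"]
            m = math.log(p["mu_real"]) - s * s / 2.0
            lx = math.log(x)
            val = -lx - math.log(s) - _LOG_SQRT_2PI - (lx - m) ** 2 / (2 * s * s)
        elif self.kind == "truncated_normal":
            mu, sg = p["mu"], p["sigma"]
            z = (x - mu) / sg
            mass = stats.norm.cdf((p["b"] - mu) / sg) - stats.norm.cdf(
                (p["a"] - mu) / sg
            )
            val = -0.5 * z * z - math.log(sg) - _LOG_SQRT_2PI - math.log(mass)
        elif self.kind == "uniform":
            val = -math.log(p["upper"] - p["lower"])
        elif self.kind == "exponential":
            val = -math.log(p["mean"]) - x / p["mean"]
        else:  # gamma
            k, th = p["shape"], p["scale"]
            if x <= 0:
                return -math.inf
            val = (
                (k - 1) * math.log(x)
                - x / th
                - k * math.log(th)
                - math.lgamma(k)
            )
        if self.hard_max is not None:
            val -= math.log(self._hard_max_mass())
        return val

    def cdf(self, age: float) -> float:
        lo, hi = self.support()
        if age <= lo:
            return 0.0
        if age >= hi:
            return 1.0
        c = float(self._base().cdf(age - self.offset))
        return c / self._hard_max_mass()

    def quantile(self, prob: float, apply_hard_max: bool = True) -> float:
        """Inverse CDF on the (optionally hard-max-truncated) offset support."""
        if not 0.0 < prob < 1.0:
            raise CalibrationError(f"quantile probability must be in (0,1), got {prob}")
        z = self._hard_max_mass() if apply_hard_max else 1.0
        return float(self._base().ppf(prob * z)) + self.offset

    def prior_interval_95(
        self, ndigits: Optional[int] = None
    ) -> tuple[float, float]:
        """Central 95% prior interval ``(q_{0.025}, q_{0.975})`` in Ma.

        When the density carries a hard ceiling and
        ``interval_ignores_hard_max`` is set, the interval is computed on the
        un-truncated density — the reporting convention of the published
        calibration tables.
        """
        apply_hm = not self.interval_ignores_hard_max
        lo = self.quantile(0.025, apply_hard_max=apply_hm)
        hi = self.quantile(0.975, apply_hard_max=apply_hm)
        if ndigits is not None:
            lo, hi = round_half_up(lo, ndigits), round_half_up(hi, ndigits)
        return lo, hi

    def mean(self) -> float:
        m = float(self._base().mean()) + self.offset
        return m

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw from the density (hard-max truncation by inverse-CDF)."""
        u = rng.random(size)
        z = self._hard_max_mass()
        return self._base().ppf(u * z) + self.offset

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params)
        s = f"{self.kind}({inner}"
        if self.offset:
            s += f", offset={self.offset:g}"
        s += ")"
        if self.hard_max is not None:
            s += f" cap {self.hard_max:g}"
        return s


def make_logpdf(d: CalibrationDensity):
    """Return a fast ``age -> log pdf`` closure with all constants precomputed.

    Equivalent to :meth:`CalibrationDensity.log_pdf` but free of per-call
    scipy overhead; used inside the MCMC prior evaluation.
    """
    lo, hi = d.support()
    offset = d.offset
    p = d.p
    log_hm = math.log(d._hard_max_mass())
    if d.kind == "lognormal_realmean":
        s = p["sigma_log"]
        m = math.log(p["mu_real"]) - s * s / 2.0
        const = -math.log(s) - _LOG_SQRT_2PI - log_hm
        inv2ss = 1.0 / (2 * s * s)

        def f(age: float) -> float:
            x = age - offset
            if x <= 0 or age > hi:
                return -math.inf
            lx = math.log(x)
            return const - lx - (lx - m) ** 2 * inv2ss

    elif d.kind == "truncated_normal":
        mu, sg = p["mu"], p["sigma"]
        mass = float(
            stats.norm.cdf((p["b"] - mu) / sg) - stats.norm.cdf((p["a"] - mu) / sg)
        )
        const = -math.log(sg) - _LOG_SQRT_2PI - math.log(mass) - log_hm

        def f(age: float) -> float:
            if not (lo <= age <= hi):
                return -math.inf
            z = (age - offset - mu) / sg
            return const - 0.5 * z * z

    elif d.kind == "uniform":
        const = -math.log(p["upper"] - p["lower"]) - log_hm

        def f(age: float) -> float:
            return const if lo <= age <= hi else -math.inf

    elif d.kind == "exponential":
        mean = p["mean"]
        const = -math.log(mean) - log_hm

        def f(age: float) -> float:
            if not (lo <= age <= hi):
                return -math.inf
            return const - (age - offset) / mean

    else:  # gamma
        k, th = p["shape"], p["scale"]
        const = -k * math.log(th) - math.lgamma(k) - log_hm

        def f(age: float) -> float:
            x = age - offset
            if x <= 0 or age > hi:
                return -math.inf
            return const + (k - 1) * math.log(x) - x / th

    return f


# ----------------------------------------------------------------------
# schemes


@dataclass(frozen=True)
class CalibrationEntry:
    constraint: CladeConstraint
    density: CalibrationDensity
    group: str

    def __post_init__(self):
        if not self.group:
            raise CalibrationError("calibration group label must be nonempty")


@dataclass(frozen=True)
class CalibrationScheme:
    """A full set of node-age priors with grouping labels for sensitivity runs."""

    entries: tuple[CalibrationEntry, ...] = ()

    def __post_init__(self):
        seen: set[tuple[frozenset, str]] = set()
        for e in self.entries:
            key = (e.constraint.taxon_set, e.constraint.placement)
            if key in seen:
                raise CalibrationError(
                    f"two densities target the same node ({e.constraint.name})"
                )
            seen.add(key)

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.group not in out:
                out.append(e.group)
        return out

    @property
    def root_entry(self) -> Optional[CalibrationEntry]:
        for e in self.entries:
            if e.group.upper() in ("RO", "ROOT"):
                return e
        return None

    def without_groups(self, groups: Iterable[str]) -> "CalibrationScheme":
        drop = set(groups)
        unknown = drop - set(self.groups)
        if unknown:
            raise CalibrationError(f"unknown calibration groups: {sorted(unknown)}")
        return CalibrationScheme(
            tuple(e for e in self.entries if e.group not in drop)
        )

    def resolve(self, tree: TimeTree) -> list[tuple[int, CalibrationDensity, str]]:
        """Map each entry to a node index of ``tree``."""
        out = []
        for e in self.entries:
            node = mrca_node(tree, e.constraint.taxon_set, e.constraint.placement)
            out.append((node.index, e.density, e.constraint.name))
        return out


def scheme_from_config(
    rows: Sequence[dict], taxa: Optional[Sequence[str]] = None
) -> CalibrationScheme:
    """Build a scheme from config rows.

    Each row: ``{name, taxa (list or "all"), placement, group, kind,
    params: {...}, offset, hard_max}``.  ``taxa: all`` (valid only when the
    full taxon list is supplied) targets the tree root.
    """
    entries = []
    for row in rows:
        row = dict(row)
        try:
            name = row.pop("name")
            kind = row.pop("kind")
            params = dict(row.pop("params"))
            taxon_spec = row.pop("taxa")
            group = row.pop("group", name)
        except KeyError as exc:
            raise CalibrationError(f"calibration row missing key: {exc}") from exc
        placement = row.pop("placement", "crown")
        offset = float(row.pop("offset", 0.0))
        hard_max = row.pop("hard_max", None)
        ignore_hm = bool(row.pop("interval_ignores_hard_max", True))
        if row:
            raise CalibrationError(
                f"calibration row {name!r}: unknown keys {sorted(row)}"
            )
        if isinstance(taxon_spec, str) and taxon_spec == "all":
            if taxa is None:
                raise CalibrationError(
                    f"row {name!r}: 'taxa: all' needs the dataset taxon list"
                )
            taxon_set = frozenset(taxa)
        else:
            taxon_set = frozenset(taxon_spec)
        constraint = CladeConstraint(name=name, taxon_set=taxon_set, placement=placement)
        density = CalibrationDensity.create(
            kind,
            offset=offset,
            hard_max=hard_max,
            interval_ignores_hard_max=ignore_hm,
            **params,
        )
        entries.append(CalibrationEntry(constraint, density, group))
    return CalibrationScheme(tuple(entries))


def validate_scheme(scheme: CalibrationScheme, taxa: Sequence[str]) -> list[str]:
    """Check taxon resolution and structural coherence; returns warnings.

    A calibrated clade nested inside another calibrated clade whose density
    has a hard upper bound, but whose own support extends older than that
    bound, is flagged (the joint prior then silently reshapes both); this is
    reported as a warning, not an error.
    """
    taxa_set = set(taxa)
    notes: list[str] = []
    for e in scheme.entries:
        missing = sorted(e.constraint.taxon_set - taxa_set)
        if missing:
            raise CalibrationError(
                f"calibration {e.constraint.name!r}: unresolvable taxa {missing}"
            )
    for child in scheme.entries:
        for parent in scheme.entries:
            if child is parent:
                continue
            if not child.constraint.taxon_set < parent.constraint.taxon_set:
                continue
            _, parent_hi = parent.density.support()
            _, child_hi = child.density.support()
            if child_hi > parent_hi:
                msg = (
                    f"calibration {child.constraint.name!r} support extends to "
                    f"{child_hi:g} Ma, older than the hard bound {parent_hi:g} Ma "
                    f"of its calibrated ancestor {parent.constraint.name!r}"
                )
                notes.append(msg)
                warnings.warn(msg, stacklevel=2)
    return notes


def prior_report(scheme: CalibrationScheme, ndigits: int = 2):
    """Tabulate the scheme as node / group / density / 95% interval rows."""
    import pandas as pd

    rows = []
    for e in scheme.entries:
        lo, hi = e.density.prior_interval_95()
        rows.append(
            {
                "node": e.constraint.name,
                "group": e.group,
                "density": e.density.describe(),
                "q2.5": round_half_up(lo, ndigits),
                "q97.5": round_half_up(hi, ndigits),
                "interval": f"{round_half_up(lo, ndigits):g}–{round_half_up(hi, ndigits):g}",
            }
        )
    return pd.DataFrame(rows, columns=["node", "group", "density", "q2.5", "q97.5", "interval"])
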