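"""Experiment drivers: leave-one-out calibration sensitivity, violin-table
export, gamma secondary-calibration fitting, and the per-gene dataset panel.

The sensitivity design runs one chain with every calibration group active
("all") plus one chain per group with exactly that group's densities removed
(labels "-C", "-RO", ...); monophyly constraints of removed calibrations are
retained.  Posterior node-age samples from a reference run can be condensed
into gamma densities (maximum-likelihood fit) and re-used as secondary
calibration priors on another dataset.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .calibration import (
    CalibrationDensity,
    CalibrationEntry,
    CalibrationScheme,
)
from .mcmc import (
    DatingProblem,
    McmcSettings,
    NodeAgeSummary,
    PosteriorTrace,
    run_chain,
    summarize_clades,
)
from .timetree import CladeConstraint


class PipelineError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# leave-one-out sensitivity


@dataclass
class SensitivityResult:
    label: str  # "all" or "-<group>"
    summaries: list[NodeAgeSummary]
    samples: dict[str, np.ndarray]
    trace: Optional[PosteriorTrace] = None

    def summary(self, clade: str) -> NodeAgeSummary:
        for s in self.summaries:
            if s.clade == clade:
                return s
        raise PipelineError(f"clade {clade!r} not summarized in run {self.label!r}")


def build_loo_configs(
    base: DatingProblem, groups: Sequence[str]
) -> list[tuple[str, DatingProblem]]:
    """The "all" run plus one run per omitted calibration group.

    Monophyly constraints of removed calibrations are kept (only the age
    densities are dropped), so every run samples the same topology space.
    """
    known = set(base.scheme.groups)
    unknown = sorted(set(groups) - known)
    if unknown:
        raise PipelineError(f"unknown calibration groups: {unknown}")
    configs: list[tuple[str, DatingProblem]] = [("all", base)]
    for group in groups:
        removed = [e.constraint for e in base.scheme.entries if e.group == group]
        cfg = replace(
            base,
            scheme=base.scheme.without_groups([group]),
            constraints=tuple(base.constraints) + tuple(removed),
        )
        configs.append((f"-{group}", cfg))
    return configs


def derive_seed(base_seed: int, label: str) -> int:
    """Deterministic per-run seed from the base seed and the run label."""
    return (int(base_seed) + zlib.crc32(label.encode())) % (2**31 - 1)


def run_sensitivity(
    configs: Sequence[tuple[str, DatingProblem]],
    base_seed: int,
    clades: Optional[Sequence[str]] = None,
    keep_traces: bool = False,
) -> list[SensitivityResult]:
    """One chain per config, seeds derived from ``base_seed`` + run label."""
    if not configs:
        raise PipelineError("no configurations to run")
    results = []
    for label, problem in configs:
        rng = np.random.default_rng(derive_seed(base_seed, label))
        trace = run_chain(problem, rng)
        tracked = ["root"] + [c.name for c in problem.tracked_clades]
        use = list(clades) if clades is not None else tracked
        summaries = summarize_clades(trace, use)
        df = trace.post_burnin()
        samples = {}
        for clade in use:
            col = "root_age" if clade == "root" else f"tmrca.{clade}"
            samples[clade] = df[col].to_numpy()
        results.append(
            SensitivityResult(
                label=label,
                summaries=summaries,
                samples=samples,
                trace=trace if keep_traces else None,
            )
        )
    return results


def export_violin_table(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    """Long-format (run, clade, age) table of post-burn-in samples."""
    if not results:
        raise PipelineError("no sensitivity results to export")
    frames = []
    for res in results:
        for clade, ages in res.samples.items():
            frames.append(
                pd.DataFrame({"run": res.label, "clade": clade, "age": ages})
            )
    return pd.concat(frames, ignore_index=True)


def violin_plot(results: Sequence[SensitivityResult], clade: str, path: str) -> None:
    """Violin plot of one clade's age across runs (smoke-level plotting)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [res.samples[clade] for res in results]
    labels = [res.label for res in results]
    fig, ax = plt.subplots(figsize=(1.2 * len(results) + 1, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel(f"TMRCA {clade} (Ma)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ----------------------------------------------------------------------
# gamma secondary calibrations


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit to a posterior node-age sample."""

    shape: float
    scale: float
    clade: str = ""
    n: int = 0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma fit needs positive shape and scale")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def gamma_moment_init(samples: Sequence[float]) -> tuple[float, float]:
    """Method-of-moments (shape = mean^2/var, scale = var/mean)."""
    x = np.asarray(samples, dtype=float)
    mean = float(x.mean())
    var = float(x.var())
    if var <= 0:
        raise ValueError("zero-variance sample")
    return mean * mean / var, var / mean


def fit_gamma(
    samples: Sequence[float], clade: str = "", min_n: int = 100
) -> GammaFit:
    """ML gamma fit: moment initialization, Newton on the shape profile.

    The profile score in the shape k is ``ln k - psi(k) - s`` with
    ``s = ln(mean) - mean(ln x)``; scale follows as ``mean / k``.  Newton
    iterations run to relative tolerance 1e-8.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} samples, got {len(x)}")
    if np.any(x <= 0):
        raise ValueError("gamma fit requires strictly positive samples")
    mean = float(x.mean())
    s = math.log(mean) - float(np.mean(np.log(x)))
    k, _ = gamma_moment_init(x)
    for _ in range(200):
        f = math.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) <= 1e-8 * k:
            k = k_new
            break
        k = k_new
    return GammaFit(shape=float(k), scale=mean / float(k), clade=clade, n=len(x))


def fit_secondary_calibrations(
    trace: PosteriorTrace,
    clades: Sequence[str],
    burnin_fraction: Optional[float] = None,
) -> list[GammaFit]:
    """Gamma fits to the post-burn-in age samples of the named clades."""
    df = trace.post_burnin(burnin_fraction)
    fits = []
    for clade in clades:
        col = "root_age" if clade == "root" else f"tmrca.{clade}"
        if col not in df.columns:
            raise PipelineError(f"clade {clade!r} not tracked in trace")
        fits.append(fit_gamma(df[col].to_numpy(), clade=clade))
    return fits


def make_secondary_scheme(
    fits: Sequence[GammaFit], clades: dict[str, frozenset[str]]
) -> CalibrationScheme:
    """Gamma priors (offset 0) on the fitted crown clades, group "secondary"."""
    seen = set()
    entries = []
    for fit in fits:
        if fit.clade in seen:
            raise PipelineError(f"duplicate clade {fit.clade!r} in secondary fits")
        seen.add(fit.clade)
        try:
            taxon_set = clades[fit.clade]
        except KeyError:
            raise PipelineError(f"no taxon set for clade {fit.clade!r}") from None
        entries.append(
            CalibrationEntry(
                CladeConstraint(fit.clade, taxon_set),
                CalibrationDensity.create("gamma", shape=fit.shape, scale=fit.scale),
                "secondary",
            )
        )
    return CalibrationScheme(tuple(entries))


# ----------------------------------------------------------------------
# per-gene panel


@dataclass
class GenePanelDataset:
    """One row of the per-gene panel: a dataset with its run conventions."""

    name: str
    problem: DatingProblem
    partition_clock: str = ""


def run_gene_panel(
    datasets: Sequence[GenePanelDataset],
    base_seed: int,
    target_clade: str = "carabus",
) -> pd.DataFrame:
    """Dated crown age of the target clade per dataset.

    Returns a table with one row per dataset: median, mean and 95% HPD of
    the target clade's TMRCA, mirroring the per-gene comparison layout.
    """
    rows = []
    for ds in datasets:
        rng = np.random.default_rng(derive_seed(base_seed, ds.name))
        trace = run_chain(ds.problem, rng)
        (summary,) = summarize_clades(trace, [target_clade])
        rows.append(
            {
                "dataset": ds.name,
                "partition_clock": ds.partition_clock,
                "median": summary.median,
                "mean": summary.mean,
                "hpd_lo": summary.hpd_lo,
                "hpd_hi": summary.hpd_hi,
                "ess": summary.ess,
            }
        )
    return pd.DataFrame(rows)
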