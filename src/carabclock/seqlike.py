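"""Alignments, substitution models, and the pruning log-likelihood.

The likelihood of an alignment given a dated tree and a clock follows the
standard phylogenetic setup: per-branch expected distance = branch duration
(Ma) x branch rate (substitutions/site/Ma), a reversible nucleotide CTMC per
partition (JC69 / K80 / HKY / GTR, each normalized to one expected
substitution per unit distance), optional discrete-gamma rate heterogeneity
(mean of quantile slices), and Felsenstein pruning over compressed site
patterns.  Gaps and IUPAC ambiguity codes are missing data: their partial
likelihood vector is 1 for every compatible state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import special, stats

from .timetree import TimeTree, TreeError

try:  # optional JIT acceleration of the pruning inner loops
    from . import _pruning_kernels as _jit
except Exception:  # pragma: no cover - numba missing or broken
    _jit = None

BASES = "ACGT"

# IUPAC -> partial likelihood row over (A, C, G, T)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}
CODES = {sym: i for i, sym in enumerate(_IUPAC)}
PARTIALS_TABLE = np.zeros((len(_IUPAC), 4))
for _sym, _states in _IUPAC.items():
    for _s in _states:
        PARTIALS_TABLE[CODES[_sym], BASES.index(_s)] = 1.0


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """A multiple sequence alignment of IUPAC DNA."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa / sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxa: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = [
                t for t, s in zip(self.taxa, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise AlignmentError(f"ragged alignment; offending taxa: {bad}")
        self.sequences = [s.upper() for s in self.sequences]
        for t, s in zip(self.taxa, self.sequences):
            illegal = sorted(set(s) - set(_IUPAC))
            if illegal:
                raise AlignmentError(f"illegal symbols {illegal} in {t!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codes(self) -> np.ndarray:
        """(n_taxa, length) matrix of IUPAC code indices."""
        lut = np.full(128, -1, dtype=np.int8)
        for sym, idx in CODES.items():
            lut[ord(sym)] = idx
        mat = np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(self.n_taxa, self.length)
        return lut[mat]

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        return Alignment(list(taxa), [self.sequences[index[t]] for t in taxa])

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n")
                for i in range(0, len(s), 70):
                    fh.write(s[i : i + 70] + "\n")


def read_alignment(path: str, fmt: Optional[str] = None) -> Alignment:
    """Read FASTA or NEXUS (sequential or interleaved) via Biopython."""
    from Bio import AlignIO, SeqIO

    if fmt is None:
        low = str(path).lower()
        fmt = "nexus" if low.endswith((".nex", ".nexus", ".nxs")) else "fasta"
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return Alignment([r.id for r in records], [str(r.seq) for r in records])
    if fmt == "nexus":
        aln = AlignIO.read(path, "nexus")
        return Alignment([r.id for r in aln], [str(r.seq) for r in aln])
    raise AlignmentError(f"unknown alignment format {fmt!r}")


# ----------------------------------------------------------------------
# partitions


@dataclass(frozen=True)
class PartitionBlock:
    """A named, 1-based inclusive site range with its partitioning scheme.

    ``scheme`` is ``"NP"`` (one partition) or ``"2P"`` (codon positions 1+2
    versus 3; ``frame`` gives the alignment column of codon position 1).
    """

    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    scheme: str = "NP"
    frame: int = 1
    rel_rate: float = 1.0

    def __post_init__(self):
        if self.scheme not in ("NP", "2P"):
            raise AlignmentError(f"block {self.name!r}: scheme must be NP or 2P")
        if self.frame not in (1, 2, 3):
            raise AlignmentError(f"block {self.name!r}: frame must be 1, 2 or 3")
        if not 1 <= self.start <= self.end:
            raise AlignmentError(f"block {self.name!r}: bad range")


@dataclass(frozen=True)
class PartitionScheme:
    blocks: tuple[PartitionBlock, ...]

    def __post_init__(self):
        covered: set[int] = set()
        for b in self.blocks:
            sites = set(range(b.start, b.end + 1))
            overlap = covered & sites
            if overlap:
                raise AlignmentError(
                    f"block {b.name!r} overlaps previously covered sites "
                    f"(e.g. {min(overlap)})"
                )
            covered |= sites

    def check_covers(self, length: int) -> None:
        covered: set[int] = set()
        for b in self.blocks:
            if b.end > length:
                raise AlignmentError(
                    f"block {b.name!r} ends at {b.end} beyond alignment length {length}"
                )
            covered |= set(range(b.start, b.end + 1))
        gaps = set(range(1, length + 1)) - covered
        if gaps:
            raise AlignmentError(f"partition scheme leaves gaps (e.g. site {min(gaps)})")

    @staticmethod
    def single(length: int, scheme: str = "NP", frame: int = 1) -> "PartitionScheme":
        return PartitionScheme(
            (PartitionBlock("all", 1, length, scheme=scheme, frame=frame),)
        )


def partition_sites(
    alignment: Alignment, scheme: PartitionScheme
) -> dict[str, np.ndarray]:
    """Map partition names to 0-based site index arrays.

    2P blocks emit ``<name>/p12`` (codon positions 1 and 2) and
    ``<name>/p3`` (third positions).
    """
    scheme.check_covers(alignment.length)
    out: dict[str, np.ndarray] = {}
    for b in scheme.blocks:
        positions = np.arange(b.start, b.end + 1)  # 1-based
        if b.scheme == "NP":
            out[b.name] = positions - 1
        else:
            codon_pos = (positions - b.frame) % 3  # 0,1 -> p12; 2 -> p3
            out[f"{b.name}/p12"] = positions[codon_pos != 2] - 1
            out[f"{b.name}/p3"] = positions[codon_pos == 2] - 1
    return out


def compress_patterns(
    alignment: Alignment, sites: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (first-occurrence order) and multiplicities.

    Returns ``(patterns, counts)`` with ``patterns`` an (n_taxa, n_patterns)
    matrix of IUPAC code indices and ``sum(counts) == len(sites)``.
    """
    codes = alignment.codes()
    if sites is not None:
        codes = codes[:, np.asarray(sites, dtype=int)]
    seen: dict[bytes, int] = {}
    order: list[int] = []
    counts: list[int] = []
    cols = np.ascontiguousarray(codes.T)
    for j in range(cols.shape[0]):
        key = cols[j].tobytes()
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(order)
            order.append(j)
            counts.append(1)
    return codes[:, order], np.asarray(counts, dtype=float)


# ----------------------------------------------------------------------
# substitution models


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide CTMC, normalized to mean rate 1.

    ``gamma_shape`` of ``None`` disables rate heterogeneity (one category).
    """

    model_id: str = "HKY"
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 2.0
    exchangeabilities: Optional[tuple[float, ...]] = None  # GTR: AC,AG,AT,CG,CT,GT
    gamma_shape: Optional[float] = None
    n_categories: int = 4

    def __post_init__(self):
        if self.model_id not in ("JC69", "K80", "HKY", "GTR"):
            raise AlignmentError(f"unknown model {self.model_id!r}")
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise AlignmentError("base_freqs must be a 4-vector summing to 1")
        if self.model_id in ("JC69", "K80"):
            object.__setattr__(self, "base_freqs", (0.25, 0.25, 0.25, 0.25))
        if self.model_id == "JC69":
            object.__setattr__(self, "kappa", 1.0)
        if self.model_id == "GTR" and self.exchangeabilities is None:
            object.__setattr__(self, "exchangeabilities", (1.0,) * 6)
        if self.kappa <= 0:
            raise AlignmentError("kappa must be > 0")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise AlignmentError("gamma_shape must be > 0")

    # ------------------------------------------------------------------
    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)

    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q with rows summing to zero."""
        pi = self.pi
        q = np.zeros((4, 4))
        if self.model_id == "GTR":
            ex = self.exchangeabilities
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            for r, (i, j) in zip(ex, pairs):
                q[i, j] = r * pi[j]
                q[j, i] = r * pi[i]
        else:
            transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    rate = self.kappa if (i, j) in transitions else 1.0
                    q[i, j] = rate * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def _eigen(self):
        """Symmetrized eigendecomposition of Q (cached lazily)."""
        cache = getattr(self, "_eigen_cache", None)
        if cache is not None:
            return cache
        pi = self.pi
        q = self.rate_matrix()
        sq = np.sqrt(pi)
        s = (sq[:, None] * q) / sq[None, :]
        lam, u = np.linalg.eigh((s + s.T) / 2.0)
        left = u.T * sq[None, :]
        right = u / sq[:, None]
        object.__setattr__(self, "_eigen_cache", (lam, right, left))
        return lam, right, left

    def transition_matrix(self, distance: float) -> np.ndarray:
        """P(distance), rows summing to 1; distance in expected subs/site."""
        if distance < 0:
            raise AlignmentError(f"negative distance {distance}")
        if self.model_id == "GTR":
            lam, right, left = self._eigen()
            p = (right * np.exp(lam * distance)) @ left
        else:
            p = _hky_transition(self.pi, self.kappa, distance)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def _hky_coeffs(self):
        """Constant matrices of the spectral HKY form P = A + e2 B + e3_j C."""
        cache = getattr(self, "_hky_cache", None)
        if cache is not None:
            return cache
        pi = self.pi
        kappa = self.kappa
        pi_r, pi_y = pi[0] + pi[2], pi[1] + pi[3]
        beta = 1.0 / (2.0 * (pi_r * pi_y + kappa * (pi[0] * pi[2] + pi[1] * pi[3])))
        group = np.array([pi_r, pi_y, pi_r, pi_y])
        rate3 = np.array(
            [1.0 + pi_r * (kappa - 1.0), 1.0 + pi_y * (kappa - 1.0)]
        )[[0, 1, 0, 1]]
        gid = np.array([0, 1, 0, 1])
        same_group = gid[:, None] == gid[None, :]
        pj = np.broadcast_to(pi, (4, 4))
        gj = np.broadcast_to(group, (4, 4))
        a = pj.copy()
        b = np.where(same_group, pj * (1.0 / gj - 1.0), -pj)
        c = np.where(
            np.eye(4, dtype=bool),
            (gj - pj) / gj,
            np.where(same_group, -pj / gj, 0.0),
        )
        cache = (beta, rate3, a, b, c)
        object.__setattr__(self, "_hky_cache", cache)
        return cache

    def transition_matrices(self, distances: np.ndarray) -> np.ndarray:
        """Batched P(d) for an array of distances -> (len(distances), 4, 4)."""
        d = np.asarray(distances, dtype=float)
        if d.min() < 0:
            raise AlignmentError("negative distance")
        if self.model_id == "GTR":
            lam, right, left = self._eigen()
            p = np.einsum("ij,kj,jl->kil", right, np.exp(np.outer(d, lam)), left)
        else:
            beta, rate3, a, b, c = self._hky_coeffs()
            bt = beta * d
            e2 = np.exp(-bt)
            e3 = np.exp(-np.outer(bt, rate3))  # (k, 4) per destination base
            p = a[None] + e2[:, None, None] * b[None] + e3[:, None, :] * c[None]
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean of quantile slices), mean 1."""
        if self.gamma_shape is None or self.n_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def _hky_transition(pi: np.ndarray, kappa: float, t: float) -> np.ndarray:
    """Closed-form HKY transition probabilities (JC/K80 as special cases)."""
    pi_a, pi_c, pi_g, pi_t = pi
    pi_r, pi_y = pi_a + pi_g, pi_c + pi_t
    # normalization so that mean rate is 1
    beta = 1.0 / (2.0 * (pi_r * pi_y + kappa * (pi_a * pi_g + pi_c * pi_t)))
    bt = beta * t
    e2 = math.exp(-bt)
    group = np.array([pi_r, pi_y, pi_r, pi_y])  # group frequency of each base
    e3 = np.array(
        [
            math.exp(-bt * (1.0 + pi_r * (kappa - 1.0))),
            math.exp(-bt * (1.0 + pi_y * (kappa - 1.0))),
        ]
    )
    p = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            pj, gj = pi[j], group[j]
            e3j = e3[0] if j in (0, 2) else e3[1]
            same_group = (i in (0, 2)) == (j in (0, 2))
            if i == j:
                p[i, j] = pj + pj * (1.0 / gj - 1.0) * e2 + ((gj - pj) / gj) * e3j
            elif same_group:
                p[i, j] = pj + pj * (1.0 / gj - 1.0) * e2 - (pj / gj) * e3j
            else:
                p[i, j] = pj * (1.0 - e2)
    return p


def _hky_transition_batch(pi: np.ndarray, kappa: float, t: np.ndarray) -> np.ndarray:
    """Vectorized closed-form HKY over an array of distances."""
    pi_a, pi_c, pi_g, pi_t = pi
    pi_r, pi_y = pi_a + pi_g, pi_c + pi_t
    beta = 1.0 / (2.0 * (pi_r * pi_y + kappa * (pi_a * pi_g + pi_c * pi_t)))
    bt = beta * np.asarray(t)[:, None, None]
    e2 = np.exp(-bt)
    group = np.array([pi_r, pi_y, pi_r, pi_y])
    rate3 = np.array(
        [1.0 + pi_r * (kappa - 1.0), 1.0 + pi_y * (kappa - 1.0)]
    )[[0, 1, 0, 1]]
    e3 = np.exp(-bt * rate3[None, None, :])  # per destination base j
    pj = pi[None, None, :]
    gj = group[None, None, :]
    same_base = np.eye(4, dtype=bool)[None, :, :]
    gid = np.array([0, 1, 0, 1])  # purine / pyrimidine
    same_group = (gid[:, None] == gid[None, :])[None, :, :]
    diag_term = pj + pj * (1.0 / gj - 1.0) * e2 + ((gj - pj) / gj) * e3
    transition_term = pj + pj * (1.0 / gj - 1.0) * e2 - (pj / gj) * e3
    transversion_term = pj * (1.0 - e2)
    out = np.where(
        same_base, diag_term, np.where(same_group, transition_term, transversion_term)
    )
    return out


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Category rates as the mean of equal-probability quantile slices."""
    k = n_categories
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    upper = special.gammainc(shape + 1.0, edges[1:] * shape)
    lower = special.gammainc(shape + 1.0, edges[:-1] * shape)
    rates = k * (upper - lower)
    return rates / rates.mean()


# ----------------------------------------------------------------------
# pruning likelihood


class PartitionLikelihood:
    """Felsenstein pruning for one partition on a fixed topology.

    Supports full evaluation and incremental re-evaluation after a proposal
    that dirties a subset of branches, with revert.  Node indexing follows
    :class:`~carabclock.timetree.TimeTree` (tips ``0..n-1``, internal
    postorder ``n..2n-2``, root last).
    """

    def __init__(
        self,
        alignment: Alignment,
        sites: Optional[np.ndarray],
        model: SubstitutionModel,
        tree: TimeTree,
        rel_rate: float = 1.0,
    ):
        order = [t.name for t in tree.tips]
        missing = set(order) ^ set(alignment.taxa)
        if missing:
            raise AlignmentError(f"tree tips and alignment taxa differ: {sorted(missing)}")
        sub = alignment.subset_taxa(order)
        patterns, counts = compress_patterns(sub, sites)
        self.model = model
        self.rel_rate = rel_rate
        self.counts = counts
        self.n_tips = tree.n_tips
        self.n_nodes = 2 * tree.n_tips - 1
        self.cat_rates = model.category_rates()
        self.ncat = len(self.cat_rates)
        self.npat = patterns.shape[1]
        self.pi = model.pi
        # topology arrays
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children = np.zeros((self.n_tips - 1, 2), dtype=int)
        for node in tree.postorder():
            if node.parent is not None:
                self.parent[node.index] = node.parent.index
            if not node.is_tip:
                self.children[node.index - self.n_tips] = [
                    c.index for c in node.children
                ]
        self.root = self.n_nodes - 1
        self.internal_order = list(range(self.n_tips, self.n_nodes))
        self._children_arr = np.ascontiguousarray(self.children, dtype=np.int64)
        self.pi = np.ascontiguousarray(self.pi)
        # tip partials: (n_tips, 4, npat), shared across categories
        self.tip_partials = np.empty((self.n_tips, 4, self.npat))
        for i in range(self.n_tips):
            self.tip_partials[i] = PARTIALS_TABLE[patterns[i]].T
        # state arrays
        self.pmats = np.zeros((self.n_nodes, self.ncat, 4, 4))
        self.partials = np.zeros((self.n_tips - 1, self.ncat, 4, self.npat))
        self.scalers = np.zeros((self.n_tips - 1, self.npat))  # accumulated log
        self._loglik = np.nan
        self._backup: Optional[dict] = None

    # -- internals -----------------------------------------------------
    def _child_partial(self, idx: int, cat: int) -> np.ndarray:
        if idx < self.n_tips:
            return self.tip_partials[idx]
        return self.partials[idx - self.n_tips, cat]

    def _set_pmat(self, node_idx: int, ages: np.ndarray, rates: np.ndarray) -> None:
        dist_base = (
            (ages[self.parent[node_idx]] - ages[node_idx])
            * rates[node_idx]
            * self.rel_rate
        )
        if dist_base < 0:
            raise AlignmentError("negative branch distance (age ordering violated)")
        self.pmats[node_idx] = self.model.transition_matrices(
            dist_base * self.cat_rates
        )

    def _set_pmats_batch(
        self, nodes: np.ndarray, ages: np.ndarray, rates: np.ndarray
    ) -> None:
        dist_base = (ages[self.parent[nodes]] - ages[nodes]) * rates[nodes] * self.rel_rate
        if dist_base.min() < 0:
            raise AlignmentError("negative branch distance (age ordering violated)")
        dists = np.outer(dist_base, self.cat_rates).ravel()
        self.pmats[nodes] = self.model.transition_matrices(dists).reshape(
            len(nodes), self.ncat, 4, 4
        )

    def _update_partials(self, node_indices: Sequence[int]) -> None:
        """Recompute partials/scalers of the given internal nodes (ascending)."""
        if _jit is not None:
            _jit.update_partials(
                self.pmats,
                self.partials,
                self.scalers,
                self.tip_partials,
                self._children_arr,
                np.asarray(node_indices, dtype=np.int64),
                self.n_tips,
            )
            return
        for idx in node_indices:
            slot = idx - self.n_tips
            c1, c2 = self.children[slot]
            res = self.partials[slot]
            for cat in range(self.ncat):
                res[cat] = (self.pmats[c1, cat] @ self._child_partial(c1, cat)) * (
                    self.pmats[c2, cat] @ self._child_partial(c2, cat)
                )
            scale = res.max(axis=(0, 1))
            scale[scale <= 0] = 1.0
            res /= scale[None, None, :]
            acc = np.log(scale)
            for child in (c1, c2):
                if child >= self.n_tips:
                    acc = acc + self.scalers[child - self.n_tips]
            self.scalers[slot] = acc

    def _root_loglik(self) -> float:
        slot = self.root - self.n_tips
        if _jit is not None:
            return float(
                _jit.root_loglik(
                    self.partials[slot], self.scalers[slot], self.pi, self.counts
                )
            )
        site_lik = np.einsum("s,csp->p", self.pi, self.partials[slot]) / self.ncat
        if np.any(site_lik <= 0):
            return -math.inf
        return float(np.dot(self.counts, np.log(site_lik) + self.scalers[slot]))

    # -- public API ----------------------------------------------------
    def full(self, ages: np.ndarray, rates: np.ndarray) -> float:
        """Full recomputation from scratch; sets the cached state."""
        self._set_pmats_batch(np.arange(self.n_nodes - 1), ages, rates)
        self._update_partials(self.internal_order)
        self._loglik = self._root_loglik()
        self._backup = None
        return self._loglik

    @property
    def loglik(self) -> float:
        return self._loglik

    def update(
        self, dirty_branches: Iterable[int], ages: np.ndarray, rates: np.ndarray
    ) -> float:
        """Re-evaluate after the listed branches changed; call accept/revert after.

        ``dirty_branches`` are node indices whose parent-edge distance (age or
        rate) changed.  Partials of every ancestor touched are recomputed.
        """
        dirty_branches = [b for b in set(dirty_branches) if b != self.root]
        dirty_nodes: set[int] = set()
        for b in dirty_branches:
            n = self.parent[b]
            while n != -1 and n not in dirty_nodes:
                dirty_nodes.add(n)
                n = self.parent[n]
        order = sorted(dirty_nodes)  # postorder indices increase rootward
        self._backup = {
            "branches": {b: self.pmats[b].copy() for b in dirty_branches},
            "partials": {
                n: (
                    self.partials[n - self.n_tips].copy(),
                    self.scalers[n - self.n_tips].copy(),
                )
                for n in order
            },
            "loglik": self._loglik,
        }
        if len(dirty_branches) > 4:
            self._set_pmats_batch(np.asarray(dirty_branches), ages, rates)
        else:
            for b in dirty_branches:
                self._set_pmat(b, ages, rates)
        self._update_partials(order)
        self._loglik = self._root_loglik()
        return self._loglik

    def accept(self) -> None:
        self._backup = None

    def revert(self) -> None:
        if self._backup is None:
            return
        for b, mat in self._backup["branches"].items():
            self.pmats[b] = mat
        for n, (part, scal) in self._backup["partials"].items():
            self.partials[n - self.n_tips] = part
            self.scalers[n - self.n_tips] = scal
        self._loglik = self._backup["loglik"]
        self._backup = None


def build_partition_likelihoods(
    alignment: Alignment,
    tree: TimeTree,
    scheme: PartitionScheme,
    models: dict[str, SubstitutionModel] | SubstitutionModel,
) -> list[PartitionLikelihood]:
    """One :class:`PartitionLikelihood` per partition of ``scheme``.

    ``models`` is either a single model applied to every partition or a dict
    keyed by partition name (``block`` or ``block/p12`` style).
    """
    parts = partition_sites(alignment, scheme)
    rel = {}
    for b in scheme.blocks:
        if b.scheme == "NP":
            rel[b.name] = b.rel_rate
        else:
            rel[f"{b.name}/p12"] = b.rel_rate
            rel[f"{b.name}/p3"] = b.rel_rate
    out = []
    for name, sites in parts.items():
        if isinstance(models, SubstitutionModel):
            model = models
        else:
            model = models.get(name) or models.get(name.split("/")[0])
            if model is None:
                raise AlignmentError(f"no substitution model for partition {name!r}")
        out.append(PartitionLikelihood(alignment, sites, model, tree, rel.get(name, 1.0)))
    return out


def pruning_loglik(
    alignment: Alignment,
    tree: TimeTree,
    clock,
    scheme: Optional[PartitionScheme] = None,
    models: dict[str, SubstitutionModel] | SubstitutionModel | None = None,
) -> float:
    """Total log-likelihood over all partitions (stateless convenience)."""
    from .prior_clock import branch_rate_vector

    if scheme is None:
        scheme = PartitionScheme.single(alignment.length)
    if models is None:
        models = SubstitutionModel("HKY", gamma_shape=None)
    engines = build_partition_likelihoods(alignment, tree, scheme, models)
    ages = np.array([n.age for n in tree.nodes()])
    rates = branch_rate_vector(tree, clock)
    return sum(e.full(ages, rates) for e in engines)
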