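"""Genes as constant-area Gaussian uptake kernels, and genome-level fitness.

A gene is represented purely by its phenotype: a Gaussian resource-uptake
kernel over the environmental axis ``x ∈ [-1, 1]``::

    u(x) = A * exp(-(x - c)^2 / (2 sigma^2))

``c`` is the condition of peak uptake, ``A ∈ (0, 1]`` the peak efficiency.
The area under every kernel is pinned to a constant ``alpha``::

    A * sigma * sqrt(2 pi) = alpha    =>    sigma = alpha / (A sqrt(2 pi))

so a gene trades peak efficiency against niche width — a specialist
(high A, narrow) covers little of the axis; a generalist (low A, wide)
covers much of it poorly.

A genome is an ordered multiset of genes.  Its uptake at condition ``x`` is
the *envelope* — the pointwise maximum over its genes — so an exact
duplicate never raises uptake, it only raises cost.  Carrying ``n`` genes
costs, per time step::

    K(n) = gamma * (n + n^2) + kappa

the linear term for the metabolic genes themselves and the quadratic term
for the regulatory apparatus, whose size empirically scales roughly with the
square of the number of regulated genes; ``kappa`` is a flat cost of living.

Three mutation types act on genomes at reproduction: deletion of a random
gene, verbatim duplication of a random gene, and modification (a local
perturbation of ``c`` and ``A``, with ``sigma`` recomputed to keep the area
constraint).  Each mutation function returns a *new* genome plus a record of
what changed; genomes are never mutated in place, so they can be shared
safely between clonal siblings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Gene",
    "Genome",
    "CostParams",
    "sigma_of",
    "gene_uptake",
    "genotype_uptake",
    "genome_cost",
    "mutate_deletion",
    "mutate_duplication",
    "mutate_modification",
    "MutationInfo",
    "A_FLOOR",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: Smallest admissible peak efficiency.  A is clamped here (not to 0) after a
#: modification so that sigma = alpha / (A sqrt(2 pi)) stays finite.
A_FLOOR = 1e-6


def sigma_of(A, alpha: float):
    """Gaussian dispersion implied by the constant-area constraint.

    Solves ``A * sigma * sqrt(2 pi) = alpha`` for sigma.  Accepts scalar or
    array ``A``.
    """
    A_arr = np.asarray(A, dtype=float)
    if np.any(A_arr <= 0.0):
        raise ValueError("peak efficiency A must be positive")
    if not alpha > 0.0:
        raise ValueError("area constant alpha must be positive")
    sigma = alpha / (A_arr * SQRT_2PI)
    return float(sigma) if np.isscalar(A) or A_arr.ndim == 0 else sigma


@dataclass(frozen=True)
class Gene:
    """A single uptake kernel: peak location ``c``, peak efficiency ``A``,
    dispersion ``sigma`` (derived), and the id of the mutation event that
    created this variant."""

    c: float
    A: float
    sigma: float
    origin_id: int = -1

    @classmethod
    def make(cls, c: float, A: float, alpha: float, origin_id: int = -1) -> "Gene":
        if not -1.0 <= c <= 1.0:
            raise ValueError(f"gene centre must lie in [-1, 1], got {c}")
        if not 0.0 < A <= 1.0:
            raise ValueError(f"peak efficiency must lie in (0, 1], got {A}")
        return cls(float(c), float(A), sigma_of(A, alpha), int(origin_id))


@dataclass(frozen=True)
class CostParams:
    """Cost model parameters.

    gamma : scaling of gene-associated costs (per gene and per gene pair).
    kappa : flat cost of living, paid even by an empty genome.
    alpha : constant area under every gene's Gaussian kernel.
    """

    gamma: float
    kappa: float
    alpha: float

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.kappa < 0:
            raise ValueError("gamma and kappa must be non-negative")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


class Genome:
    """Ordered multiset of genes, stored as parallel numpy arrays.

    Attributes
    ----------
    c, A : float arrays of per-gene peak locations / efficiencies.
    origin : int array of variant ids (the mutation event that created each
        variant; exact duplicates share their template's id).
    alpha : the shared area constant, from which ``sigma`` is derived.
    """

    __slots__ = ("c", "A", "origin", "alpha")

    def __init__(self, c, A, alpha: float, origin=None):
        self.c = np.atleast_1d(np.asarray(c, dtype=float))
        self.A = np.atleast_1d(np.asarray(A, dtype=float))
        if self.c.shape != self.A.shape:
            raise ValueError("c and A must have the same length")
        if origin is None:
            origin = np.full(self.c.shape, -1, dtype=np.int64)
        self.origin = np.atleast_1d(np.asarray(origin, dtype=np.int64))
        if self.origin.shape != self.c.shape:
            raise ValueError("origin must have the same length as c")
        if not alpha > 0:
            raise ValueError("alpha must be positive")
        self.alpha = float(alpha)
        if self.n:
            if np.any(np.abs(self.c) > 1.0):
                raise ValueError("gene centres must lie in [-1, 1]")
            if np.any(self.A <= 0.0) or np.any(self.A > 1.0):
                raise ValueError("peak efficiencies must lie in (0, 1]")

    @classmethod
    def empty(cls, alpha: float) -> "Genome":
        return cls(np.empty(0), np.empty(0), alpha, np.empty(0, dtype=np.int64))

    @classmethod
    def from_genes(cls, genes: Iterable[Gene], alpha: float) -> "Genome":
        genes = list(genes)
        return cls(
            [g.c for g in genes],
            [g.A for g in genes],
            alpha,
            [g.origin_id for g in genes],
        )

    @property
    def n(self) -> int:
        """Gene count, duplicates included."""
        return self.c.size

    @property
    def sigma(self) -> np.ndarray:
        return self.alpha / (self.A * SQRT_2PI)

    @property
    def genes(self) -> list[Gene]:
        s = self.sigma
        return [
            Gene(float(self.c[i]), float(self.A[i]), float(s[i]), int(self.origin[i]))
            for i in range(self.n)
        ]

    def copy(self) -> "Genome":
        return Genome(self.c.copy(), self.A.copy(), self.alpha, self.origin.copy())

    def uptake(self, x):
        return genotype_uptake(self, x)

    def strain_key(self) -> tuple:
        """Hashable genotype identity: the sorted multiset of variant ids."""
        return tuple(sorted(self.origin.tolist()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genome(n={self.n}, alpha={self.alpha})"


def gene_uptake(gene: Gene, x):
    """Uptake efficiency ``u(x)`` of one gene; ``x`` scalar or array."""
    x = np.asarray(x, dtype=float)
    u = gene.A * np.exp(-((x - gene.c) ** 2) / (2.0 * gene.sigma**2))
    return float(u) if u.ndim == 0 else u


def genotype_uptake(genome: Genome, x):
    """Envelope uptake ``U(x) = max_i u_i(x)``; 0 for an empty genome."""
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    if genome.n == 0:
        out = np.zeros(x_arr.shape)
        return 0.0 if scalar else out
    sig = genome.sigma
    # (n_genes, n_x) broadcast; genomes are small so this is cheap.
    d = x_arr.reshape((1,) + x_arr.shape) - genome.c.reshape((-1,) + (1,) * x_arr.ndim)
    u = genome.A.reshape((-1,) + (1,) * x_arr.ndim) * np.exp(
        -(d**2) / (2.0 * sig.reshape((-1,) + (1,) * x_arr.ndim) ** 2)
    )
    env = u.max(axis=0)
    return float(env) if scalar else env


def genome_cost(n: int, params: CostParams) -> float:
    """Per-step cost ``K(n) = gamma (n + n^2) + kappa`` of running ``n`` genes."""
    if n < 0:
        raise ValueError("gene count must be non-negative")
    return params.gamma * (n + n * n) + params.kappa


# ---------------------------------------------------------------------------
# Mutations


@dataclass(frozen=True)
class MutationInfo:
    """Record of a single mutation applied to a genome."""

    type: str  # "deletion" | "duplication" | "modification"
    gene_index: int
    old_c: float = np.nan
    old_A: float = np.nan
    new_c: float = np.nan
    new_A: float = np.nan
    new_origin_id: int = -1


# Fallback variant-id source for standalone use of mutate_modification; the
# simulation engine always passes explicit event ids instead.
_auto_variant_ids = count(start=-2, step=-1)


def _pick_gene(genome: Genome, rng: np.random.Generator) -> int:
    return int(rng.integers(genome.n))


def mutate_deletion(
    genome: Genome, rng: np.random.Generator
) -> tuple[Genome, Optional[MutationInfo]]:
    """Remove one uniformly chosen gene.  No-op on an empty genome."""
    if genome.n == 0:
        return genome, None
    i = _pick_gene(genome, rng)
    keep = np.ones(genome.n, dtype=bool)
    keep[i] = False
    new = Genome(genome.c[keep], genome.A[keep], genome.alpha, genome.origin[keep])
    info = MutationInfo(
        "deletion", i, old_c=float(genome.c[i]), old_A=float(genome.A[i])
    )
    return new, info


def mutate_duplication(
    genome: Genome, rng: np.random.Generator
) -> tuple[Genome, Optional[MutationInfo]]:
    """Append a verbatim copy of one uniformly chosen gene.

    The copy keeps its template's variant id, so the genotype envelope is
    unchanged at every ``x``; only the cost rises.
    """
    if genome.n == 0:
        return genome, None
    i = _pick_gene(genome, rng)
    new = Genome(
        np.append(genome.c, genome.c[i]),
        np.append(genome.A, genome.A[i]),
        genome.alpha,
        np.append(genome.origin, genome.origin[i]),
    )
    info = MutationInfo(
        "duplication",
        i,
        old_c=float(genome.c[i]),
        old_A=float(genome.A[i]),
        new_c=float(genome.c[i]),
        new_A=float(genome.A[i]),
        new_origin_id=int(genome.origin[i]),
    )
    return new, info


def mutate_modification(
    genome: Genome,
    rng: np.random.Generator,
    m_c: float = 0.1,
    m_A: float = 0.1,
    new_origin_id: Optional[int] = None,
) -> tuple[Genome, Optional[MutationInfo]]:
    """Perturb the shape of one uniformly chosen gene.

    ``c`` and ``A`` each receive an independent uniform perturbation from
    ``[-m_c, m_c]`` / ``[-m_A, m_A]``; ``c`` is clamped to ``[-1, 1]``, ``A``
    to ``[A_FLOOR, 1]``, and sigma follows from the area constraint.  The
    modified gene becomes a new variant and is assigned ``new_origin_id``.
    """
    if genome.n == 0:
        return genome, None
    if m_c < 0 or m_A < 0:
        raise ValueError("perturbation half-widths must be non-negative")
    i = _pick_gene(genome, rng)
    dc = rng.uniform(-m_c, m_c) if m_c > 0 else 0.0
    dA = rng.uniform(-m_A, m_A) if m_A > 0 else 0.0
    new_c = float(np.clip(genome.c[i] + dc, -1.0, 1.0))
    new_A = float(np.clip(genome.A[i] + dA, A_FLOOR, 1.0))
    if new_origin_id is None:
        new_origin_id = next(_auto_variant_ids)
    c = genome.c.copy()
    A = genome.A.copy()
    origin = genome.origin.copy()
    c[i], A[i], origin[i] = new_c, new_A, new_origin_id
    new = Genome(c, A, genome.alpha, origin)
    info = MutationInfo(
        "modification",
        i,
        old_c=float(genome.c[i]),
        old_A=float(genome.A[i]),
        new_c=new_c,
        new_A=new_A,
        new_origin_id=int(new_origin_id),
    )
    return new, info
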