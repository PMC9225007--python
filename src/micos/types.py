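"""Core domain types: simulator parameters, community designs and trajectory tables.

The system modeled throughout the package is a bottom-up synthetic gut
bacterial community: up to 25 species grown together in defined medium, with
species abundances measured in OD-equivalent units and four fermentation end
products (butyrate, lactate, acetate, succinate) measured in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default 25-species pool (two-letter strain codes, fixed order).
DEFAULT_POOL: tuple[str, ...] = (
    "PC", "PJ", "BV", "BF", "BO", "BT", "BC", "BY", "BU", "DP",
    "BL", "BA", "BP", "CA", "EL", "FP", "CH", "AC", "BH", "CG",
    "ER", "RI", "CC", "DL", "DF",
)

#: Metabolite column order used everywhere (concentrations in mM).
METABOLITES: tuple[str, ...] = ("butyrate", "lactate", "acetate", "succinate")


@dataclass
class GLVParams:
    """Parameters of a generalized Lotka-Volterra system with optional
    third-order interaction terms.

    The per-capita growth rate of species i is
    ``r[i] + sum_j A[i, j] x_j + sum_{j != i} sum_{k != i, j} B[i, j, k] x_j x_k``.

    Attributes
    ----------
    r : (n,) intrinsic growth rates, 1/h.
    A : (n, n) pairwise interaction matrix; ``A[i, j]`` is the effect of
        species j on species i (1/(h·abundance)). Diagonal entries must be
        negative (self-limitation) for bounded dynamics.
    B : (n, n, n) third-order tensor; ``B[i, j, k]`` modifies the effect of
        the (j, k) product on species i and is defined only for ``j != i`` and
        ``k not in (i, j)``; all other entries are exactly zero. May be None
        for a purely pairwise system.
    """

    r: np.ndarray
    A: np.ndarray
    B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = self.r.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be ({n}, {n}), got {self.A.shape}")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be negative (self-limitation)")
        if self.B is not None:
            self.B = np.asarray(self.B, dtype=float)
            if self.B.shape != (n, n, n):
                raise ValueError(f"B must be ({n}, {n}, {n}), got {self.B.shape}")
            mask = _admissible_mask(n)
            if np.any(self.B[~mask] != 0.0):
                raise ValueError("B entries with j=i or k in {i, j} must be zero")

    @property
    def n_species(self) -> int:
        return self.r.shape[0]


def _admissible_mask(n: int) -> np.ndarray:
    """Boolean (n,n,n) mask of admissible third-order entries (j!=i, k!=i,j)."""
    i, j, k = np.ogrid[:n, :n, :n]
    return (j != i) & (k != i) & (k != j)


@dataclass(frozen=True)
class CommunityDesign:
    """A binary presence/absence plan over an ordered species pool."""

    present: tuple[int, ...]
    pool: tuple[str, ...] = DEFAULT_POOL

    def __post_init__(self) -> None:
        if len(self.present) != len(self.pool):
            raise ValueError("presence vector length must match pool size")
        if len(set(self.pool)) != len(self.pool):
            raise ValueError("pool entries must be unique")
        if any(p not in (0, 1) for p in self.present):
            raise ValueError("presence vector must be binary")
        if sum(self.present) < 1:
            raise ValueError("richness must be >= 1")

    @classmethod
    def from_species(cls, species: list[str] | set[str],
                     pool: tuple[str, ...] = DEFAULT_POOL) -> "CommunityDesign":
        sp = set(species)
        unknown = sp - set(pool)
        if unknown:
            raise ValueError(f"unknown species codes: {sorted(unknown)}")
        return cls(tuple(1 if s in sp else 0 for s in pool), pool)

    @property
    def richness(self) -> int:
        return sum(self.present)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, p in zip(self.pool, self.present) if p)

    def mask(self) -> np.ndarray:
        return np.array(self.present, dtype=bool)


@dataclass
class TrajectoryTable:
    """Time-resolved abundances (and optionally metabolites) for one community.

    Attributes
    ----------
    sample_id : identifier of the sample/community.
    design : the community design that was inoculated.
    times : (T,) strictly increasing time grid in hours.
    X : (T, n_species) abundance matrix in OD units, nonnegative; species
        absent from the design are exactly zero at every time.
    C : optional (T, 4) metabolite concentrations in mM, column order
        butyrate, lactate, acetate, succinate.
    """

    sample_id: str
    design: CommunityDesign
    times: np.ndarray
    X: np.ndarray
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        T = self.times.shape[0]
        n = len(self.design.pool)
        if self.X.shape != (T, n):
            raise ValueError(f"X must be ({T}, {n}), got {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if np.any(self.X < 0):
            raise ValueError("X contains negative abundances")
        absent = ~self.design.mask()
        if np.any(self.X[:, absent] != 0.0):
            raise ValueError("absent species must have abundance exactly 0")
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=float)
            if self.C.shape[0] != T:
                raise ValueError("C must have one row per time point")

    @property
    def n_times(self) -> int:
        return self.times.shape[0]
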