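"""Brain connectivity graphs: thresholded FC, Laplacians, patient-specific low-rank perturbations.

The brain is modeled as an undirected weighted graph whose nodes are cortical
regions (Desikan-Killiany 68-region atlas by default) and whose edges come from
thresholded resting-state functional connectivity.  A patient-specific graph is
parameterized as a symmetric rank-2 deviation from a population-mean adjacency,

    A = Ap + (u v' + v u')/2 - diag(u o v),

with ``u``, ``v`` unit vectors; the diagonal correction removes the
self-connections the rank-2 term would otherwise introduce.  The corresponding
Laplacian admits a closed form that avoids rebuilding A (see
:func:`patient_laplacian`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_REGIONS = 68  # Desikan-Killiany cortical parcellation

__all__ = [
    "FcMatrix",
    "BrainGraph",
    "PopulationGraph",
    "LowRankPerturbation",
    "threshold_fc",
    "build_laplacian",
    "population_graph",
    "patient_adjacency",
    "patient_laplacian",
    "check_weight_constraints",
    "graph_integral",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class FcMatrix:
    """Functional-connectivity matrix: Pearson r, optional parallel p-values."""

    r: np.ndarray
    p: np.ndarray | None = None

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {r.shape}")
        if np.max(np.abs(r - r.T)) > _SYM_TOL:
            raise ValueError("FC matrix is not symmetric within tolerance 1e-8")
        if self.p is not None:
            p = np.asarray(self.p, dtype=float)
            object.__setattr__(self, "p", p)
            if p.shape != r.shape:
                raise ValueError("p-value matrix shape does not match r")

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class BrainGraph:
    """Weighted undirected graph with cached degree vector and Laplacian L = D - A."""

    adjacency: np.ndarray
    degree: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        d, L = build_laplacian(A)
        object.__setattr__(self, "degree", d)
        object.__setattr__(self, "laplacian", L)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class PopulationGraph:
    """Cohort-mean adjacency and Laplacian (each member symmetrized first)."""

    adjacency: np.ndarray
    laplacian: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def as_graph(self) -> BrainGraph:
        return BrainGraph(self.adjacency)


@dataclass(frozen=True)
class LowRankPerturbation:
    """Unit-vector pair (u, v) encoding a patient's rank-2 deviation from the population graph.

    Unit norms are soft-penalized during fitting, so they are expected only
    within tolerance after optimization, never asserted here.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float).ravel()
        v = np.asarray(self.v, dtype=float).ravel()
        if u.shape != v.shape:
            raise ValueError("u and v must have the same length")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @classmethod
    def zero(cls, n: int = N_REGIONS) -> "LowRankPerturbation":
        return cls(np.zeros(n), np.zeros(n))


def threshold_fc(fc: FcMatrix, r_min: float = 0.75, p_max: float = 1e-5) -> BrainGraph:
    """Build a brain graph by statistical truncation of an FC matrix.

    An off-diagonal edge (i, j) is kept iff r_ij > r_min and, when p-values are
    supplied, p_ij < p_max (both strict).  Kept edges are weighted by r_ij;
    self-connections are removed.
    """
    A = fc.r.copy()
    keep = A > r_min
    if fc.p is not None:
        keep &= fc.p < p_max
    A = np.where(keep, A, 0.0)
    np.fill_diagonal(A, 0.0)
    A = (A + A.T) / 2.0  # exact symmetry despite float representation noise
    return BrainGraph(A)


def build_laplacian(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree vector d_i = sum_k a_ik and combinatorial Laplacian L = diag(d) - A."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if np.max(np.abs(A - A.T)) > _SYM_TOL:
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0.0):
        raise ValueError("adjacency must have zero diagonal")
    if np.any(A < 0):
        raise ValueError("negative edge weight")
    d = A.sum(axis=1)
    L = np.diag(d) - A
    return d, L


def population_graph(graphs: list[BrainGraph]) -> PopulationGraph:
    """Average a set of subject graphs into a population graph.

    Each adjacency is symmetrized as (A + A')/2 before averaging; by linearity
    the population Laplacian equals the Laplacian of the mean adjacency.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    n = graphs[0].n
    if any(g.n != n for g in graphs):
        raise ValueError("graphs have inconsistent dimensions")
    Ap = np.mean([(g.adjacency + g.adjacency.T) / 2.0 for g in graphs], axis=0)
    _, Lp = build_laplacian(Ap)
    return PopulationGraph(adjacency=Ap, laplacian=Lp)


def _rank2_term(pert: LowRankPerturbation) -> np.ndarray:
    u, v = pert.u, pert.v
    return 0.5 * (np.outer(u, v) + np.outer(v, u)) - np.diag(u * v)


def patient_adjacency(Ap: np.ndarray, pert: LowRankPerturbation) -> np.ndarray:
    """A = Ap + (u v' + v u')/2 - diag(u o v).

    The diagonal subtraction exactly cancels the rank-2 term's diagonal, so the
    result is hollow whenever Ap is.
    """
    return np.asarray(Ap, dtype=float) + _rank2_term(pert)


def patient_laplacian(LpG: np.ndarray, pert: LowRankPerturbation) -> np.ndarray:
    """Patient Laplacian directly from the population Laplacian.

    L = LpG + diag(u (v'1) + v (u'1))/2 - (u v' + v u')/2 + diag(u o v)
    - diag(u o v) collapses to the closed form below; algebraically identical
    to ``build_laplacian(patient_adjacency(Ap, pert))`` when LpG is the
    Laplacian of Ap (property-tested).
    """
    u, v = pert.u, pert.v
    su, sv = u.sum(), v.sum()
    # degree change of the hollow rank-2 update: row sums of _rank2_term
    d_delta = 0.5 * (u * sv + v * su) - u * v
    return np.asarray(LpG, dtype=float) + np.diag(d_delta) - _rank2_term(pert)


def check_weight_constraints(
    Ap: np.ndarray, pert: LowRankPerturbation, tol: float = 0.0
) -> list[tuple[int, int, float]]:
    """Audit the box constraint 0 <= a_kh + perturbation <= 1 on every off-diagonal pair.

    Returns a list of (k, h, offending_value); empty list means feasible.  New
    edges lighted up inside [0, 1] where Ap is zero are not violations.
    """
    A = patient_adjacency(Ap, pert)
    n = A.shape[0]
    mask = ~np.eye(n, dtype=bool)
    bad = mask & ((A < -tol) | (A > 1.0 + tol))
    return [(int(k), int(h), float(A[k, h])) for k, h in zip(*np.nonzero(bad))]


def graph_integral(field: np.ndarray, graph: BrainGraph | PopulationGraph) -> float:
    """Degree-weighted mean of a nodal field: sum_v d_v f(v) / sum_v d_v."""
    if isinstance(graph, PopulationGraph):
        d = np.asarray(graph.adjacency).sum(axis=1)
    else:
        d = graph.degree
    total = d.sum()
    if total <= 0:
        raise ValueError("graph has no edges; degree-weighted mean undefined")
    return float(np.dot(d, np.asarray(field, dtype=float)) / total)
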