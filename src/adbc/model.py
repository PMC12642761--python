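"""Forward dynamics of the graph-coupled biomarker cascade.

Four biomarkers evolve on a weighted brain graph with Laplacian L:

    dAb/dt = -D_Ab L Ab + lam_Ab o Ab o (K_Ab - Ab)
    dtau/dt = -D_tau L tau + lam_tauAb o Ab + lam_tau o tau o (K_tau - tau)
    dN/dt  = -D_N L N + lam_Ntau o tau + lam_N o N o (K_N - N)
    dC/dt  = lam_CN * <N>_d + lam_C * C * (K_C - C)

where ``o`` is elementwise, <N>_d is the degree-weighted mean of N over the
graph, and C is a whole-brain scalar with no diffusion term.  Each biomarker
follows logistic self-growth toward a regional carrying capacity, is forced
linearly by its upstream biomarker (amyloid -> tau -> neurodegeneration ->
cognition), and the three regional fields diffuse along functional
connections.  Since L is positive semi-definite the -D L y terms are
dissipative; a spatially uniform field is in the kernel of L, so diffusion
only acts on regional heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .graph import BrainGraph, PopulationGraph, N_REGIONS

__all__ = ["AdbcParameters", "AdbcState", "Trajectory", "rhs", "simulate", "accuracy"]

GLOBAL_PARAMS = ("D_Abeta", "D_tau", "D_N", "lambda_CN", "lambda_C", "K_C")
REGIONAL_PARAMS = (
    "lambda_Abeta",
    "lambda_tau",
    "lambda_N",
    "lambda_tauAbeta",
    "lambda_Ntau",
    "K_Abeta",
    "K_tau",
    "K_N",
)

T0_DEFAULT = 50.0  # model clock is chronological age; common onset-time origin
T_END_DEFAULT = 100.0


@dataclass(frozen=True)
class AdbcParameters:
    """Cascade parameters: 6 global scalars + 8 region-specific vectors.

    Diffusivities and the cognition couplings are global; logistic rates,
    cross-couplings and carrying capacities are per-region (units 1/yr except
    the dimensionless capacities).
    """

    D_Abeta: float
    D_tau: float
    D_N: float
    lambda_CN: float
    lambda_C: float
    K_C: float
    lambda_Abeta: np.ndarray
    lambda_tau: np.ndarray
    lambda_N: np.ndarray
    lambda_tauAbeta: np.ndarray
    lambda_Ntau: np.ndarray
    K_Abeta: np.ndarray
    K_tau: np.ndarray
    K_N: np.ndarray

    def __post_init__(self):
        n = None
        for name in REGIONAL_PARAMS:
            vec = np.asarray(getattr(self, name), dtype=float).ravel()
            object.__setattr__(self, name, vec)
            if n is None:
                n = vec.size
            elif vec.size != n:
                raise ValueError(f"regional parameter {name} has length {vec.size}, expected {n}")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite entries in {name}")
        for name in GLOBAL_PARAMS:
            val = float(getattr(self, name))
            object.__setattr__(self, name, val)
            if not np.isfinite(val):
                raise ValueError(f"non-finite {name}")
        for name in ("D_Abeta", "D_tau", "D_N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("K_Abeta", "K_tau", "K_N"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be > 0")
        if self.K_C <= 0:
            raise ValueError("K_C must be > 0")

    @property
    def n_regions(self) -> int:
        return self.lambda_Abeta.size

    @classmethod
    def homogeneous(cls, n_regions: int = N_REGIONS, **scalars) -> "AdbcParameters":
        """Broadcast scalar values of the regional parameters to all regions."""
        kwargs = {}
        for name in GLOBAL_PARAMS:
            kwargs[name] = scalars.pop(name)
        for name in REGIONAL_PARAMS:
            kwargs[name] = np.full(n_regions, float(scalars.pop(name)))
        if scalars:
            raise TypeError(f"unknown parameters: {sorted(scalars)}")
        return cls(**kwargs)

    def with_updates(self, **updates) -> "AdbcParameters":
        return replace(self, **updates)


@dataclass(frozen=True)
class AdbcState:
    """Model state: three regional fields plus whole-brain cognitive impairment."""

    Abeta: np.ndarray
    tau: np.ndarray
    N: np.ndarray
    C: float

    def __post_init__(self):
        for name in ("Abeta", "tau", "N"):
            vec = np.asarray(getattr(self, name), dtype=float).ravel()
            object.__setattr__(self, name, vec)
        object.__setattr__(self, "C", float(self.C))
        if self.Abeta.size != self.tau.size or self.tau.size != self.N.size:
            raise ValueError("regional fields must have equal length")

    @property
    def n_regions(self) -> int:
        return self.Abeta.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.Abeta, self.tau, self.N, [self.C]])

    @classmethod
    def from_vector(cls, y: np.ndarray, n: int) -> "AdbcState":
        return cls(Abeta=y[:n], tau=y[n : 2 * n], N=y[2 * n : 3 * n], C=y[3 * n])

    @classmethod
    def uniform(cls, n_regions: int, Abeta=0.0, tau=0.0, N=0.0, C=0.0) -> "AdbcState":
        return cls(
            Abeta=np.full(n_regions, float(Abeta)),
            tau=np.full(n_regions, float(tau)),
            N=np.full(n_regions, float(N)),
            C=float(C),
        )


@dataclass(frozen=True)
class Trajectory:
    """Solution evaluated on an age grid, with solver metadata."""

    ages: np.ndarray
    states: list[AdbcState]
    rtol: float
    atol: float
    n_steps: int

    def field(self, biomarker: str) -> np.ndarray:
        """Stack one biomarker over time: shape (n_ages, n_regions) or (n_ages,) for C."""
        if biomarker == "C":
            return np.array([s.C for s in self.states])
        return np.vstack([getattr(s, biomarker) for s in self.states])

    def at_age(self, age: float, atol: float = 1e-9) -> AdbcState:
        i = int(np.argmin(np.abs(self.ages - age)))
        if abs(self.ages[i] - age) > atol:
            raise KeyError(f"age {age} not on trajectory grid")
        return self.states[i]


def rhs(state: AdbcState, params: AdbcParameters, graph: BrainGraph | PopulationGraph):
    """Time derivative of the cascade at a given state."""
    L = graph.laplacian
    if state.n_regions != params.n_regions or L.shape[0] != state.n_regions:
        raise ValueError("state, parameters and graph dimensions disagree")
    d = np.asarray(graph.adjacency).sum(axis=1)
    dsum = d.sum()
    n_mean = float(d @ state.N / dsum) if dsum > 0 else float(state.N.mean())
    dAb = -params.D_Abeta * (L @ state.Abeta) + params.lambda_Abeta * state.Abeta * (
        params.K_Abeta - state.Abeta
    )
    dtau = (
        -params.D_tau * (L @ state.tau)
        + params.lambda_tauAbeta * state.Abeta
        + params.lambda_tau * state.tau * (params.K_tau - state.tau)
    )
    dN = (
        -params.D_N * (L @ state.N)
        + params.lambda_Ntau * state.tau
        + params.lambda_N * state.N * (params.K_N - state.N)
    )
    dC = params.lambda_CN * n_mean + params.lambda_C * state.C * (params.K_C - state.C)
    return AdbcState(Abeta=dAb, tau=dtau, N=dN, C=dC)


def simulate(
    params: AdbcParameters,
    y0: AdbcState,
    graph: BrainGraph | PopulationGraph,
    t0: float = T0_DEFAULT,
    t_end: float = T_END_DEFAULT,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the cascade with adaptive RK45 and evaluate on an age grid."""
    if t0 >= t_end:
        raise ValueError("t0 must be < t_end")
    if t_eval is None:
        t_eval = np.linspace(t0, t_end, 101)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.min() < t0 - 1e-12 or t_eval.max() > t_end + 1e-12:
        raise ValueError("t_eval must lie within [t0, t_end]")
    n = params.n_regions
    L = np.asarray(graph.laplacian)
    d = np.asarray(graph.adjacency).sum(axis=1)
    dsum = d.sum()
    w = d / dsum if dsum > 0 else np.full(n, 1.0 / n)
    la, lt, ln = params.lambda_Abeta, params.lambda_tau, params.lambda_N
    lta, lnt = params.lambda_tauAbeta, params.lambda_Ntau
    ka, kt, kn = params.K_Abeta, params.K_tau, params.K_N
    Da, Dt, Dn = params.D_Abeta, params.D_tau, params.D_N
    lcn, lc, kc = params.lambda_CN, params.lambda_C, params.K_C

    def f(t, y):
        ab, tau_, nn, c = y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n]
        out = np.empty_like(y)
        out[:n] = -Da * (L @ ab) + la * ab * (ka - ab)
        out[n : 2 * n] = -Dt * (L @ tau_) + lta * ab + lt * tau_ * (kt - tau_)
        out[2 * n : 3 * n] = -Dn * (L @ nn) + lnt * tau_ + ln * nn * (kn - nn)
        out[3 * n] = lcn * (w @ nn) + lc * c * (kc - c)
        return out

    sol = solve_ivp(f, (t0, t_end), y0.to_vector(), method="RK45", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}; params={params}")
    states = [AdbcState.from_vector(sol.y[:, i], n) for i in range(sol.y.shape[1])]
    return Trajectory(ages=t_eval, states=states, rtol=rtol, atol=atol, n_steps=sol.nfev)


def accuracy(trajectory: Trajectory, records) -> dict[str, float]:
    """Percent agreement between a trajectory and observed records, per biomarker.

    accuracy_b = 100 * (1 - sum_i ||y_b(t_i) - obs_b(t_i)||_2 / sum_i ||obs_b(t_i)||_2),
    clipped below at 0.  Visits are grouped by age; ``overall`` pools all
    biomarkers.  Biomarkers with no records are omitted.
    """
    by_bio: dict[str, dict[float, list]] = {}
    for r in records:
        by_bio.setdefault(r.biomarker, {}).setdefault(round(r.age, 9), []).append(r)
    out: dict[str, float] = {}
    num_all = den_all = 0.0
    for bio, visits in by_bio.items():
        num = den = 0.0
        for age, recs in visits.items():
            state = _interp_state(trajectory, age)
            if bio == "C":
                pred = np.array([state.C for _ in recs])
            else:
                fld = getattr(state, bio)
                pred = np.array([fld[r.region - 1] for r in recs])
            obs = np.array([r.value for r in recs])
            num += float(np.linalg.norm(pred - obs))
            den += float(np.linalg.norm(obs))
        if den == 0:
            den = 1e-12
        out[bio] = max(0.0, 100.0 * (1.0 - num / den))
        num_all += num
        den_all += den
    if out:
        out["overall"] = max(0.0, 100.0 * (1.0 - num_all / den_all))
    return out


def _interp_state(traj: Trajectory, age: float) -> AdbcState:
    """Linear interpolation between trajectory grid points (exact on grid)."""
    ages = traj.ages
    if age < ages[0] - 1e-9 or age > ages[-1] + 1e-9:
        raise ValueError(f"age {age} outside trajectory span [{ages[0]}, {ages[-1]}]")
    i = int(np.searchsorted(ages, age))
    i = min(max(i, 1), len(ages) - 1)
    t0, t1 = ages[i - 1], ages[i]
    if t1 == t0:
        return traj.states[i]
    a = (age - t0) / (t1 - t0)
    s0, s1 = traj.states[i - 1], traj.states[i]
    return AdbcState(
        Abeta=(1 - a) * s0.Abeta + a * s1.Abeta,
        tau=(1 - a) * s0.tau + a * s1.tau,
        N=(1 - a) * s0.N + a * s1.N,
        C=(1 - a) * s0.C + a * s1.C,
    )
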