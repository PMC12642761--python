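"""Variance-based (Sobol) global sensitivity analysis of the cascade model.

Implements the Saltelli sampling design and the standard Monte-Carlo
estimators for first-order (S1), second-order (S2) and total (ST) Sobol
indices, then wires them to the model at two levels:

* **Level 1** — all 14 parameters homogenized to scalars; total indices of the
  whole-brain cognitive output C(t) are tracked over age to screen influential
  parameters.
* **Level 2** — one region-specific parameter is varied across its regions
  (68 factors by default) with everything else fixed; indices of the
  degree-weighted brain total of that parameter's biomarker are aggregated to
  anatomical lobes at fixed disease stages.

Estimators: S1 by Saltelli (2010) / Jansen, ST by Jansen, S2 by the Saltelli
(2002) cross-block formula.  Confidence half-widths come from bootstrap over
sample rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .graph import BrainGraph, PopulationGraph, graph_integral
from .model import AdbcParameters, AdbcState, simulate, GLOBAL_PARAMS, REGIONAL_PARAMS

logger = logging.getLogger(__name__)

__all__ = [
    "SobolProblem",
    "SobolResult",
    "saltelli_sample",
    "sobol_indices",
    "level1_global",
    "level2_regional",
    "rank_regions",
]

LEVEL1_PARAMS = GLOBAL_PARAMS + REGIONAL_PARAMS  # 14 homogenized factors

# which biomarker a region-specific parameter feeds
PARAM_BIOMARKER = {
    "lambda_Abeta": "Abeta", "K_Abeta": "Abeta",
    "lambda_tau": "tau", "K_tau": "tau", "lambda_tauAbeta": "tau",
    "lambda_N": "N", "K_N": "N", "lambda_Ntau": "N",
}


@dataclass(frozen=True)
class SobolProblem:
    """Factor names, box ranges, sampling size and seed for one Sobol analysis."""

    names: list
    bounds: np.ndarray  # (k, 2)
    n_base: int = 1024
    seed: int = 0
    second_order: bool = False

    def __post_init__(self):
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        object.__setattr__(self, "bounds", b)
        object.__setattr__(self, "names", list(self.names))
        if b.shape != (len(self.names), 2):
            raise ValueError("bounds must be (k, 2) matching names")
        if np.any(b[:, 0] > b[:, 1]):
            raise ValueError("bound lower > upper")
        if self.n_base < 2 or (self.n_base & (self.n_base - 1)) != 0:
            raise ValueError("base sample size must be a power of 2")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class SobolResult:
    names: list
    S1: np.ndarray
    ST: np.ndarray
    S2: np.ndarray | None  # (k, k), upper triangle populated; None if not requested
    S1_conf: np.ndarray
    ST_conf: np.ndarray
    n_base: int
    n_evals: int
    var_y: float

    def as_dict(self) -> dict:
        out = {nm: {"S1": float(s1), "ST": float(st)}
               for nm, s1, st in zip(self.names, self.S1, self.ST)}
        return out


def saltelli_sample(problem: SobolProblem) -> np.ndarray:
    """Saltelli design: blocks A, B, AB_1..AB_k (and BA_1..BA_k when second order).

    Rows are ordered [A; B; AB_1; ...; AB_k; (BA_1; ...; BA_k)], each block of
    ``n_base`` rows; total n_base*(k+2) or n_base*(2k+2) rows.
    """
    k, N = problem.k, problem.n_base
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # qmc balance warning for non 2^m draws
        sampler = qmc.Sobol(d=2 * k, scramble=True, seed=problem.seed)
        base = sampler.random(N)
    A01, B01 = base[:, :k], base[:, k:]
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]

    def scale(X):
        return lo + X * (hi - lo)

    blocks = [scale(A01), scale(B01)]
    for i in range(k):
        AB = A01.copy()
        AB[:, i] = B01[:, i]
        blocks.append(scale(AB))
    if problem.second_order:
        for i in range(k):
            BA = B01.copy()
            BA[:, i] = A01[:, i]
            blocks.append(scale(BA))
    return np.vstack(blocks)


def _evaluate(evaluator, X: np.ndarray) -> np.ndarray:
    """Evaluate row-wise; accepts scalar or vector outputs per row."""
    outs = []
    for i, x in enumerate(X):
        y = np.asarray(evaluator(x), dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite model output at sample row {i}: x={x}")
        outs.append(y)
    return np.asarray(outs)


def _indices_from_blocks(fA, fB, fAB, fBA, var_y):
    """Point estimates given block evaluations; output may be vector-valued (last axes kept).

    Evaluations are centered on the A/B sample mean first: the estimators are
    shift-invariant only in expectation, and a large output mean otherwise
    amplifies finite-sample imbalance.
    """
    mu = np.mean(np.concatenate([fA, fB]), axis=0)
    fA = fA - mu
    fB = fB - mu
    fAB = fAB - mu
    if fBA is not None:
        fBA = fBA - mu
    k = fAB.shape[0]
    S1 = np.empty((k,) + fA.shape[1:])
    ST = np.empty_like(S1)
    for i in range(k):
        S1[i] = np.mean(fB * (fAB[i] - fA), axis=0) / var_y
        ST[i] = 0.5 * np.mean((fA - fAB[i]) ** 2, axis=0) / var_y
    S2 = None
    if fBA is not None:
        S2 = np.full((k, k) + fA.shape[1:], np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                vij = np.mean(fBA[i] * fAB[j] - fA * fB, axis=0) / var_y
                S2[i, j] = vij - S1[i] - S1[j]
    return S1, ST, S2


def sobol_indices(problem: SobolProblem, evaluator, n_boot: int = 200) -> SobolResult:
    """Estimate S1/ST (and S2 when requested) for a scalar-output model.

    Zero output variance yields all-zero indices with a warning rather than a
    division error (the output is then insensitive to everything).
    """
    X = saltelli_sample(problem)
    f = _evaluate(evaluator, X).reshape(X.shape[0])
    return _sobol_from_evals(problem, f, n_boot)


def _sobol_from_evals(problem: SobolProblem, f: np.ndarray, n_boot: int = 200,
                      rng: np.random.Generator | None = None) -> SobolResult:
    k, N = problem.k, problem.n_base
    fA, fB = f[:N], f[N : 2 * N]
    fAB = np.stack([f[(2 + i) * N : (3 + i) * N] for i in range(k)])
    fBA = None
    if problem.second_order:
        fBA = np.stack([f[(2 + k + i) * N : (3 + k + i) * N] for i in range(k)])
    var_y = float(np.var(np.concatenate([fA, fB])))
    if var_y < 1e-14:
        logger.warning("output variance ~0; all Sobol indices defined as 0")
        zeros = np.zeros(k)
        S2 = np.full((k, k), np.nan) if problem.second_order else None
        if S2 is not None:
            S2[np.triu_indices(k, 1)] = 0.0
        return SobolResult(problem.names, zeros, zeros.copy(), S2, zeros.copy(),
                           zeros.copy(), N, f.size, var_y)
    S1, ST, S2 = _indices_from_blocks(fA, fB, fAB, fBA, var_y)
    rng = rng or np.random.default_rng(problem.seed + 1)
    if n_boot > 0:
        boots1, bootst = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, N, size=N)
            v = float(np.var(np.concatenate([fA[idx], fB[idx]])))
            if v < 1e-14:
                continue
            s1b, stb, _ = _indices_from_blocks(fA[idx], fB[idx], fAB[:, idx], None, v)
            boots1.append(s1b)
            bootst.append(stb)
        S1_conf = 1.96 * np.std(boots1, axis=0) if boots1 else np.zeros(k)
        ST_conf = 1.96 * np.std(bootst, axis=0) if bootst else np.zeros(k)
    else:
        S1_conf = ST_conf = np.zeros(k)
    return SobolResult(problem.names, S1, ST, S2, S1_conf, ST_conf, N, f.size, var_y)


# ---------------------------------------------------------------- level 1


def level1_global(
    param_ranges: dict,
    graph: BrainGraph | PopulationGraph,
    ages: np.ndarray,
    y0: AdbcState | None = None,
    n_base: int = 256,
    seed: int = 0,
) -> dict:
    """Total sensitivity indices of C(t) for the 14 homogenized parameters, over age.

    ``param_ranges`` maps each of the 14 parameter names to (lo, hi); a
    degenerate (zero-width) range pins the parameter.  Near-constant output at
    early ages is flagged and reported as zero indices.
    """
    names = [nm for nm in LEVEL1_PARAMS]
    missing = [nm for nm in names if nm not in param_ranges]
    if missing:
        raise ValueError(f"missing ranges for parameters: {missing}")
    bounds = np.array([param_ranges[nm] for nm in names], dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = graph.n
    y0 = y0 or AdbcState.uniform(n, Abeta=0.1, tau=0.05, N=0.05, C=0.0)
    problem = SobolProblem(names=names, bounds=bounds, n_base=n_base, seed=seed)
    X = saltelli_sample(problem)
    t_eval = np.unique(np.concatenate([[50.0], ages]))
    pos = [int(np.argmin(np.abs(t_eval - a))) for a in ages]

    def run(x) -> np.ndarray:
        scal = dict(zip(names, x))
        params = AdbcParameters.homogeneous(n, **scal)
        traj = simulate(params, y0, graph, t_eval=t_eval, rtol=1e-5, atol=1e-7)
        return np.array([traj.states[j].C for j in pos])

    F = _evaluate(run, X)  # (rows, n_ages)
    k, N = problem.k, problem.n_base
    ST = np.zeros((k, len(ages)))
    S1 = np.zeros((k, len(ages)))
    flagged = []
    for a in range(len(ages)):
        f = F[:, a]
        fA, fB = f[:N], f[N : 2 * N]
        var_y = float(np.var(np.concatenate([fA, fB])))
        if var_y < 1e-14:
            flagged.append(float(ages[a]))
            continue
        fAB = np.stack([f[(2 + i) * N : (3 + i) * N] for i in range(k)])
        s1, st, _ = _indices_from_blocks(fA, fB, fAB, None, var_y)
        S1[:, a], ST[:, a] = s1, st
    if flagged:
        logger.warning("near-zero output variance at ages %s; indices set to 0", flagged)
    return {"names": names, "ages": ages, "S1": S1, "ST": ST,
            "zero_variance_ages": flagged,
            "ranking": [names[i] for i in np.argsort(-ST.sum(axis=1))]}


# ---------------------------------------------------------------- level 2


def level2_regional(
    param_name: str,
    region_ranges: np.ndarray,
    lobe_map: dict,
    base_params: AdbcParameters,
    graph: BrainGraph | PopulationGraph,
    y0: AdbcState,
    stages: tuple = (60.0, 80.0, 100.0),
    n_base: int = 256,
    seed: int = 0,
) -> dict:
    """Region-level Sobol analysis of one region-specific parameter, aggregated to lobes.

    The parameter's entries over the ``n`` regions are the factors; all other
    parameters stay at ``base_params``.  The output is the degree-weighted
    brain total of the parameter's own biomarker at each stage age.  S1 is
    summed within lobes; S2 is summed over region pairs spanning each lobe pair
    (diagonal = within-lobe interactions).
    """
    if param_name not in PARAM_BIOMARKER:
        raise ValueError(f"{param_name} is not a region-specific parameter")
    bio = PARAM_BIOMARKER[param_name]
    n = graph.n
    region_ranges = np.asarray(region_ranges, dtype=float)
    if region_ranges.shape != (n, 2):
        raise ValueError(f"region_ranges must be ({n}, 2)")
    lobes_of = {}
    for r in range(1, n + 1):
        if r not in lobe_map:
            raise ValueError(f"region {r} missing from lobe map")
        lobes_of[r] = lobe_map[r]
    names = [f"region_{r}" for r in range(1, n + 1)]
    problem = SobolProblem(names=names, bounds=region_ranges, n_base=n_base,
                           seed=seed, second_order=True)
    X = saltelli_sample(problem)
    stages = tuple(float(s) for s in stages)
    t_eval = np.unique(np.concatenate([[50.0], stages]))
    pos = [int(np.argmin(np.abs(t_eval - s))) for s in stages]

    def run(x) -> np.ndarray:
        params = base_params.with_updates(**{param_name: np.asarray(x)})
        traj = simulate(params, y0, graph, t_eval=t_eval, rtol=1e-5, atol=1e-7)
        return np.array([graph_integral(getattr(traj.states[j], bio), graph) for j in pos])

    F = _evaluate(run, X)
    k, N = problem.k, problem.n_base
    lobe_names = sorted(set(lobes_of.values()))
    out: dict = {"param": param_name, "biomarker": bio, "stages": {}, "lobes": lobe_names}
    for s_i, stage in enumerate(stages):
        f = F[:, s_i]
        fA, fB = f[:N], f[N : 2 * N]
        var_y = float(np.var(np.concatenate([fA, fB])))
        if var_y < 1e-14:
            logger.warning("stage %.0f: zero output variance; indices 0", stage)
            S1 = np.zeros(k)
            ST = np.zeros(k)
            S2 = np.zeros((k, k))
        else:
            fAB = np.stack([f[(2 + i) * N : (3 + i) * N] for i in range(k)])
            fBA = np.stack([f[(2 + k + i) * N : (3 + k + i) * N] for i in range(k)])
            S1, ST, S2 = _indices_from_blocks(fA, fB, fAB, fBA, var_y)
        lobe_S1 = {lb: 0.0 for lb in lobe_names}
        for r in range(1, n + 1):
            lobe_S1[lobes_of[r]] += float(S1[r - 1])
        lobe_S2 = {}
        for i in range(k):
            for j in range(i + 1, k):
                v = float(S2[i, j]) if S2 is not None and np.isfinite(S2[i, j]) else 0.0
                key = tuple(sorted((lobes_of[i + 1], lobes_of[j + 1])))
                lobe_S2[key] = lobe_S2.get(key, 0.0) + v
        result = SobolResult(names, S1, ST, S2, np.zeros(k), np.zeros(k), N, f.size, var_y)
        out["stages"][stage] = {"lobe_S1": lobe_S1, "lobe_S2": lobe_S2, "raw": result}
    return out


def rank_regions(result: SobolResult, lobe_map: dict, k: int = 10) -> dict:
    """Top-k regions by S1 (ties by ST, then region index), tagged with lobes.

    Emits per-lobe counts of the selected regions (they sum to k).
    """
    n = len(result.names)
    if k > n:
        logger.warning("k=%d exceeds %d regions; clipping", k, n)
        k = n
    order = sorted(range(n), key=lambda i: (-result.S1[i], -result.ST[i], i))[:k]
    top = []
    counts: dict = {}
    for i in order:
        region = i + 1
        lobe = lobe_map.get(region, "unknown")
        top.append({"region": region, "lobe": lobe,
                    "S1": float(result.S1[i]), "ST": float(result.ST[i])})
        counts[lobe] = counts.get(lobe, 0) + 1
    return {"top": top, "lobe_counts": counts}
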