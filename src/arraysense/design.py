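"""Fisher-information engine: uncertainty forecasts and D-optimal array design.

In the low-noise limit the curvature of the log-likelihood around its
maximum is the Gauss-Newton (Fisher) matrix

    H_kl = sum_r (1/sigma_r^2) sum_m  dI_r(mu_m)/dtheta_k * dI_r(mu_m)/dtheta_l

over the concentration parameters theta = (x_i for i != reference, mu0).
The inverse Hessian's diagonal gives squared parameter uncertainties
``delta_k = sqrt((H^-1)_kk)``; a parameter the readout does not depend on
produces a null direction and an infinite uncertainty.

Design: receptor properties (binding energies, efficacies) are chosen to
maximize det H (D-optimality).  A key structural fact drives everything
here: one receptor's mixture response along a dilution series depends on
the composition only through two scalars — the total binding weight
``K = sum_i x_i exp(-dG_ri/kT) / sum_k x_k`` and its efficacy-weighted
counterpart ``A = sum_i eff_ri x_i exp(-dG_ri/kT) / sum_k x_k`` — so each
receptor contributes at most rank 2 to H (rank 1 when every efficacy is
pinned to 1, since then A = K).  Hence an array of N_R receptors can
discriminate at most 2*N_R ligands with free efficacies and N_R with
agonist-only responses, and the optimum pairs a strong agonist with a
strong antagonist on every receptor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bayes import SamplerSettings, Prior, PriorSpec, nested_sampling
from .model import (
    ArrayParams,
    DilutionSeries,
    MixtureComposition,
    ModelConstants,
)
from .simulate import default_series

logger = logging.getLogger(__name__)

__all__ = [
    "HessianReport",
    "DesignProblem",
    "DesignResult",
    "concentration_hessian",
    "optimize_design",
    "enumerate_optima",
    "capacity_scan",
    "discrimination_thresholds",
    "det_landscape_grid",
    "diagnose_array",
    "robustness_scan",
]

#: Fraction of x_true below which delta-x counts as "successfully
#: discriminated", and the mu0 criterion (a two-fold concentration window).
DISCRIMINATION_X_FRACTION = 0.3


def discrimination_thresholds(const: ModelConstants | None = None) -> tuple[float, float]:
    const = const or ModelConstants()
    return DISCRIMINATION_X_FRACTION, const.kT * np.log(2.0)


# ---------------------------------------------------------------------------
# Hessian of the concentration parameters
# ---------------------------------------------------------------------------


def _receptor_jacobian(dG_row: np.ndarray, eff_row: np.ndarray, x: np.ndarray,
                       free_idx: np.ndarray, mu_tot: np.ndarray, kT: float):
    """Response I(m) and Jacobian d I / d (x_free, mu0) for one receptor."""
    S = x.sum()
    expo = np.clip((mu_tot[None, :] - dG_row[:, None]) / kT, None, 600.0)
    u = np.exp(expo) / S                      # (L, M) per-unit-x Boltzmann weights
    W = x[:, None] * u
    Wt = W.sum(axis=0)
    Z = 1.0 + Wt
    A = eff_row @ W                           # efficacy-weighted bound weight
    I = A / Z
    # dW_i/dx_k = u_i (delta_ik - x_i/S);  dI/dx_k via quotient rule on A/Z
    Jx = ((eff_row[free_idx, None] * u[free_idx] - (A / S)[None, :])
          - I[None, :] * (u[free_idx] - (Wt / S)[None, :])) / Z[None, :]
    Jmu = I * (1.0 - Wt / Z) / kT
    J = np.concatenate([Jx, Jmu[None, :]], axis=0).T   # (M, n_free + 1)
    return I, J


def _delta_from_eig(H: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-parameter uncertainties from the eigendecomposition of H.

    Directions with (numerically) zero curvature contribute infinite
    uncertainty to every parameter they load on, instead of raising.
    """
    evals, evecs = np.linalg.eigh(H)
    emax = float(evals.max(initial=0.0))
    if emax <= 0:
        return np.full(H.shape[0], np.inf), np.inf
    cutoff = emax * 1e-13
    good = evals > cutoff
    comp2 = evecs**2
    delta = np.sqrt(comp2[:, good] @ (1.0 / evals[good]))
    null_load = comp2[:, ~good].sum(axis=1)
    delta[null_load > 1e-10] = np.inf
    cond = emax / float(evals.min()) if good.all() and evals.min() > 0 else np.inf
    return delta, cond


@dataclass
class HessianReport:
    """Fisher matrix over (x ratios, mu0) with derived uncertainties."""

    names: list[str]
    H: np.ndarray
    det: float
    log_det: float
    delta: np.ndarray
    condition: float

    def delta_of(self, name: str) -> float:
        return float(self.delta[self.names.index(name)])

    def to_dict(self) -> dict:
        return {"parameters": self.names, "H": self.H.tolist(), "det": self.det,
                "log_det": self.log_det,
                "delta": [float(d) for d in self.delta],
                "condition": self.condition}


def _hessian_core(dG: np.ndarray, eff: np.ndarray, x: np.ndarray, ref: int,
                  mu0: float, offsets_list: list[np.ndarray],
                  sigma: np.ndarray, replicates, kT: float) -> np.ndarray:
    L = dG.shape[1]
    free_idx = np.array([i for i in range(L) if i != ref], dtype=int)
    n_theta = len(free_idx) + 1
    H = np.zeros((n_theta, n_theta))
    reps = np.broadcast_to(np.asarray(replicates, dtype=float), (dG.shape[0],))
    for j in range(dG.shape[0]):
        mu_tot = mu0 + offsets_list[j]
        _, J = _receptor_jacobian(dG[j], eff[j], x, free_idx, mu_tot, kT)
        H += (reps[j] / sigma[j] ** 2) * (J.T @ J)
    return H


def _report_from_H(H: np.ndarray, names: list[str]) -> HessianReport:
    sign, log_det = np.linalg.slogdet(H)
    det = float(sign * np.exp(log_det)) if np.isfinite(log_det) else 0.0
    delta, cond = _delta_from_eig(H)
    return HessianReport(names=names, H=H, det=det,
                         log_det=float(log_det) if sign > 0 else -np.inf,
                         delta=delta, condition=cond)


def concentration_hessian(params: ArrayParams, comp: MixtureComposition,
                          mu0: float,
                          series: DilutionSeries | dict | None = None,
                          const: ModelConstants | None = None,
                          replicates: int = 4) -> HessianReport:
    """Low-noise Hessian of the concentration parameters for a given array.

    Evaluated at the true composition and reference potential; the sum runs
    over every receptor, series point and replicate, weighted by the
    receptor's noise variance.  Scaling every sigma by c scales H by 1/c^2
    and every delta by c.
    """
    const = const or ModelConstants()
    if list(comp.ligand_ids) != list(params.ligand_ids):
        raise ValueError("composition panel must match the array's ligand panel")
    if series is None:
        series = default_series(const=const)
    if isinstance(series, dict):
        offsets = [series[r].offsets for r in params.receptor_ids]
    else:
        offsets = [series.offsets] * params.n_receptors
    for off in offsets:
        if off.size == 0:
            raise ValueError("empty dilution series")
    ref = comp.reference_index
    H = _hessian_core(params.dG, params.eff, comp.x, ref, mu0, offsets,
                      params.sigma, replicates, const.kT)
    names = [f"x_{l}" for i, l in enumerate(params.ligand_ids) if i != ref] + ["mu0"]
    return _report_from_H(H, names)


# ---------------------------------------------------------------------------
# D-optimal design
# ---------------------------------------------------------------------------


@dataclass
class DesignProblem:
    """Specification of a design search: what to optimize, evaluated where.

    The Hessian is evaluated at ``composition`` (equal parts by default) and
    ``mu0``; the dataset design (series, replicates, noise) is fixed.  With
    ``efficacies_free=False`` every efficacy is pinned to 1 (agonist-only
    array) and only binding energies are searched.
    """

    n_receptors: int
    n_ligands: int
    composition: MixtureComposition | None = None
    mu0: float | None = None
    series: DilutionSeries | None = None
    replicates: int = 4
    sigma: float = 0.02
    dG_bounds: tuple[float, float] = (-14.0, -2.0)
    eff_bounds: tuple[float, float] = (0.0, 1.0)
    efficacies_free: bool = True
    bg: float = 0.0
    const: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (np.isfinite(self.dG_bounds).all() and np.isfinite(self.eff_bounds).all()):
            raise ValueError("bounds must be finite")
        if self.composition is None:
            self.composition = MixtureComposition.equal_parts(self.ligand_ids)
        if self.mu0 is None:
            self.mu0 = self.const.kT * np.log(1e-3)  # 1 mM total at the reference
        if self.series is None:
            self.series = default_series(const=self.const)

    @property
    def ligand_ids(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_ligands)]

    @property
    def receptor_ids(self) -> list[str]:
        return [f"R{j + 1}" for j in range(self.n_receptors)]

    @property
    def theta_names(self) -> list[str]:
        ref = self.composition.reference_index
        return [f"x_{l}" for i, l in enumerate(self.ligand_ids) if i != ref] + ["mu0"]

    @property
    def n_design(self) -> int:
        n = self.n_receptors * self.n_ligands
        return 2 * n if self.efficacies_free else n

    def split_design(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_receptors * self.n_ligands
        dG = np.asarray(v[:n], dtype=float).reshape(self.n_receptors, self.n_ligands)
        if self.efficacies_free:
            eff = np.asarray(v[n:2 * n], dtype=float).reshape(dG.shape)
        else:
            eff = np.ones_like(dG)
        return dG, eff

    def hessian(self, dG: np.ndarray, eff: np.ndarray) -> np.ndarray:
        offsets = [self.series.offsets] * self.n_receptors
        sigma = np.full(self.n_receptors, float(self.sigma))
        return _hessian_core(np.atleast_2d(dG), np.atleast_2d(eff),
                             self.composition.x, self.composition.reference_index,
                             self.mu0, offsets, sigma, self.replicates,
                             self.const.kT)

    def log_det(self, v: np.ndarray) -> float:
        dG, eff = self.split_design(v)
        sign, ld = np.linalg.slogdet(self.hessian(dG, eff))
        return float(ld) if sign > 0 and np.isfinite(ld) else -np.inf

    def report(self, dG: np.ndarray, eff: np.ndarray) -> HessianReport:
        return _report_from_H(self.hessian(dG, eff), self.theta_names)

    def bounds(self) -> list[tuple[float, float]]:
        n = self.n_receptors * self.n_ligands
        b = [self.dG_bounds] * n
        if self.efficacies_free:
            b += [self.eff_bounds] * n
        return b


@dataclass
class DesignResult:
    """Optimal receptor parameters for a design problem."""

    problem: DesignProblem
    dG: np.ndarray
    eff: np.ndarray
    det: float
    log_det: float
    delta: np.ndarray
    report: HessianReport
    pattern: tuple | None = None
    is_global: bool | None = None

    def to_dict(self) -> dict:
        return {"dG": self.dG.tolist(), "eff": self.eff.tolist(),
                "det": self.det, "log_det": self.log_det,
                "delta": [float(d) for d in self.delta],
                "parameters": self.report.names,
                "pattern": self.pattern, "is_global": self.is_global}


def _design_settings(problem: DesignProblem, seed: int = 0) -> SamplerSettings:
    n_live = 200
    return SamplerSettings(n_live=n_live, mcmc_steps_per_replacement=20,
                           stop_tolerance=1e-2,
                           max_iterations=n_live * 30, seed=seed)


def _polish(problem: DesignProblem, v0: np.ndarray,
            maxiter: int | None = None) -> tuple[np.ndarray, float]:
    bounds = problem.bounds()
    v0 = np.clip(v0, [b[0] for b in bounds], [b[1] for b in bounds])

    def neg(v):
        ld = problem.log_det(v)
        return -ld if np.isfinite(ld) else 1e30

    opts = {"xtol": 1e-8, "ftol": 1e-12, "maxiter": maxiter or 20_000}
    res = minimize(neg, v0, method="Powell", bounds=bounds, options=opts)
    # second pass: Powell restarts its direction set, tightening convergence
    res = minimize(neg, res.x, method="Powell", bounds=bounds, options=opts)
    return res.x, problem.log_det(res.x)


def _result_at(problem: DesignProblem, v: np.ndarray) -> DesignResult:
    dG, eff = problem.split_design(v)
    rep = problem.report(dG, eff)
    return DesignResult(problem=problem, dG=dG, eff=eff, det=rep.det,
                        log_det=rep.log_det, delta=rep.delta, report=rep,
                        pattern=_pattern(problem, dG, eff))


def optimize_design(problem: DesignProblem,
                    settings: SamplerSettings | None = None,
                    n_restarts: int = 3) -> DesignResult:
    """Maximize det H over (dG, eff) within bounds.

    A nested-sampling global search over the design box feeds the best point
    to a bounded local polish; a few random restarts guard against the
    search landing on an inferior symmetry-related basin.
    """
    settings = settings or _design_settings(problem)
    rng = np.random.default_rng(settings.seed)
    priors = PriorSpec(
        [Prior(f"dG_{k}", "uniform", *problem.dG_bounds)
         for k in range(problem.n_receptors * problem.n_ligands)]
        + ([Prior(f"eff_{k}", "uniform", *problem.eff_bounds)
            for k in range(problem.n_receptors * problem.n_ligands)]
           if problem.efficacies_free else []))
    starts = []
    try:
        ns = nested_sampling(problem.log_det, priors, settings)
        starts.append(ns.map_estimate)
    except ValueError as exc:  # pragma: no cover - degenerate boxes only
        logger.warning("design global search failed (%s); using random starts", exc)
    lo = np.array([b[0] for b in problem.bounds()])
    hi = np.array([b[1] for b in problem.bounds()])
    while len(starts) < max(1, n_restarts):
        starts.append(lo + rng.random(lo.size) * (hi - lo))

    best_v, best_ld = None, -np.inf
    for v0 in starts:
        v, ld = _polish(problem, v0)
        if ld > best_ld:
            best_v, best_ld = v, ld
    if best_v is None:  # det non-positive everywhere searched
        best_v = starts[0]
    return _result_at(problem, best_v)


# ---------------------------------------------------------------------------
# Symmetry enumeration
# ---------------------------------------------------------------------------


def _pattern(problem: DesignProblem, dG: np.ndarray, eff: np.ndarray,
             rel_tol: float = 0.01) -> tuple:
    """Agonist/antagonist assignment pattern, canonical under receptor relabels.

    Per receptor and ligand: 'A' functional agonist, 'a' functional
    antagonist, '-' irrelevant.  A bond is irrelevant when weakening it to
    the top of the dG box changes det H by less than ``rel_tol`` (flat
    directions of the landscape otherwise leak into the classification).
    """
    sign, ld0 = np.linalg.slogdet(problem.hessian(dG, eff))
    ld0 = ld0 if sign > 0 else -np.inf
    hi = problem.dG_bounds[1]
    rows = []
    for j in range(dG.shape[0]):
        row = []
        for i in range(dG.shape[1]):
            dG_test = dG.copy()
            dG_test[j, i] = hi
            s, ld = np.linalg.slogdet(problem.hessian(dG_test, eff))
            ld = ld if s > 0 else -np.inf
            if not np.isfinite(ld0) or ld > ld0 + np.log1p(-rel_tol):
                row.append("-")
            else:
                row.append("A" if eff[j, i] >= 0.5 else "a")
        rows.append(tuple(row))
    return min(tuple(p) for p in itertools.permutations(rows))


def enumerate_optima(problem: DesignProblem,
                     settings: SamplerSettings | None = None,
                     n_starts: int = 20,
                     global_tol: float = 0.01) -> list[DesignResult]:
    """Multi-start search for all det-landscape maxima, clustered by pattern.

    Restricted to small problems (<= 3 receptors, <= 4 ligands).  Optima are
    grouped by their agonist/antagonist assignment modulo receptor-label
    permutation; those within ``global_tol`` (relative det) of the best are
    labelled global, the rest local.  Results are sorted by det, best first.
    """
    if problem.n_receptors > 3 or problem.n_ligands > 4:
        raise ValueError("symmetry enumeration supported up to 3 receptors, 4 ligands")
    seed = settings.seed if settings is not None else 0
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in problem.bounds()])
    hi = np.array([b[1] for b in problem.bounds()])

    candidates: list[DesignResult] = [optimize_design(
        problem, settings or _design_settings(problem, seed))]
    for _ in range(n_starts):
        v0 = lo + rng.random(lo.size) * (hi - lo)
        v, ld = _polish(problem, v0)
        if np.isfinite(ld):
            candidates.append(_result_at(problem, v))

    best_ld = max(c.log_det for c in candidates)
    by_pattern: dict[tuple, DesignResult] = {}
    for c in candidates:
        key = c.pattern
        if key not in by_pattern or c.log_det > by_pattern[key].log_det:
            by_pattern[key] = c
    out = sorted(by_pattern.values(), key=lambda c: -c.log_det)
    for c in out:
        c.is_global = bool(c.log_det >= best_ld + np.log1p(-global_tol))
    return out


# ---------------------------------------------------------------------------
# Capacity and diagnostics
# ---------------------------------------------------------------------------


def _discriminated(result: DesignResult, thresholds=None) -> bool:
    problem = result.problem
    thr_x, thr_mu = thresholds or discrimination_thresholds(problem.const)
    ref = problem.composition.reference_index
    x_true = np.delete(problem.composition.x, ref)
    delta = result.delta
    dx, dmu = delta[:-1], delta[-1]
    return bool(np.all(dx < thr_x * x_true) and dmu < thr_mu)


def capacity_scan(max_receptors: int, efficacies_free: bool = True,
                  thresholds: tuple[float, float] | None = None,
                  settings: SamplerSettings | None = None,
                  composition: str = "equal",
                  const: ModelConstants | None = None,
                  sigma: float = 0.02, seed: int = 0,
                  **problem_kwargs) -> pd.DataFrame:
    """Maximum number of discriminable ligands vs array size.

    For each number of receptors, the number of ligands grows until the
    D-optimal design can no longer bring every concentration uncertainty
    below threshold.  With free efficacies the capacity is twice the number
    of receptors; with all efficacies pinned to 1 it equals the number of
    receptors.  ``composition='skewed'`` evaluates at a non-uniform mixture
    instead of equal proportions (the capacity law is unchanged).
    """
    const = const or ModelConstants()
    rows = []
    for n_r in range(1, max_receptors + 1):
        expected = (2 * n_r if efficacies_free else n_r)
        capacity = 0
        for n_l in range(1, expected + 2):
            comp = None
            if composition == "skewed" and n_l > 1:
                x = np.array([1.0] + [2.0 ** (-k) for k in range(1, n_l)])
                comp = MixtureComposition([f"L{i+1}" for i in range(n_l)], x, "L1")
            problem = DesignProblem(
                n_receptors=n_r, n_ligands=n_l, efficacies_free=efficacies_free,
                composition=comp, sigma=sigma, const=const, **problem_kwargs)
            st = settings.with_seed(settings.seed + 37 * n_r + n_l) if settings \
                else _design_settings(problem, seed + 37 * n_r + n_l)
            result = optimize_design(problem, st)
            ok = _discriminated(result, thresholds)
            rows.append({"n_receptors": n_r, "n_ligands": n_l,
                         "discriminated": ok, "det": result.det,
                         "max_delta_x": float(np.max(result.delta[:-1], initial=0.0)),
                         "delta_mu0": float(result.delta[-1])})
            if not ok:
                break
            capacity = n_l
        for row in rows:
            if row["n_receptors"] == n_r:
                row["capacity"] = capacity
    return pd.DataFrame(rows)


@dataclass
class DiagnosisReport:
    """Hessian forecast for an array/mixture plus possible improvements."""

    hessian: HessianReport
    improvements: dict[str, DesignResult] = field(default_factory=dict)

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(((m, r.det) for m, r in self.improvements.items()),
                      key=lambda t: -t[1])


def diagnose_array(params: ArrayParams, comp: MixtureComposition, mu0: float,
                   series: DilutionSeries | dict | None = None,
                   const: ModelConstants | None = None, replicates: int = 4,
                   improve: bool = False,
                   dG_bounds: tuple[float, float] = (-14.0, -2.0),
                   seed: int = 0) -> DiagnosisReport:
    """Forecast decoding uncertainties for a calibrated array on one mixture.

    With ``improve=True``, re-optimizes efficacies only, binding energies
    only, and both (starting from the calibrated values, dG within
    ``dG_bounds``) to rank which relaxation most increases det H.
    """
    const = const or ModelConstants()
    rep = concentration_hessian(params, comp, mu0, series, const, replicates)
    out = DiagnosisReport(hessian=rep)
    if not improve:
        return out
    sigma = float(np.mean(params.sigma))
    lig = [f"L{i + 1}" for i in range(params.n_ligands)]
    problem = DesignProblem(
        n_receptors=params.n_receptors, n_ligands=params.n_ligands,
        composition=MixtureComposition(lig, comp.x, lig[comp.reference_index]),
        mu0=mu0, sigma=sigma, dG_bounds=dG_bounds, efficacies_free=True,
        const=const, replicates=replicates,
        series=series if isinstance(series, DilutionSeries) else None)
    v_cur = np.concatenate([params.dG.ravel(), params.eff.ravel()])
    for mode in ("eff_only", "dG_only", "both"):
        out.improvements[mode] = _constrained_reoptimize(problem, v_cur, mode)
    return out


def _constrained_reoptimize(problem: DesignProblem, v_cur: np.ndarray,
                            mode: str) -> DesignResult:
    n = problem.n_receptors * problem.n_ligands
    free = np.zeros(2 * n, dtype=bool)
    if mode in ("dG_only", "both"):
        free[:n] = True
    if mode in ("eff_only", "both"):
        free[n:] = True
    bounds_all = problem.bounds()
    v_cur = np.clip(v_cur, [b[0] for b in bounds_all], [b[1] for b in bounds_all])

    def neg(sub):
        v = v_cur.copy()
        v[free] = sub
        ld = problem.log_det(v)
        return -ld if np.isfinite(ld) else 1e30

    sub_bounds = [b for b, f in zip(bounds_all, free) if f]
    res = minimize(neg, v_cur[free], method="Powell", bounds=sub_bounds)
    v = v_cur.copy()
    v[free] = res.x
    return _result_at(problem, v)


def det_landscape_grid(problem: DesignProblem, eff: np.ndarray,
                       n: int = 41) -> pd.DataFrame:
    """det H over a (dG1, dG2) grid for a one-receptor, two-ligand problem.

    Efficacies are held fixed at ``eff``; the long-format table (dG1, dG2,
    det) plots directly as a determinant landscape.
    """
    if problem.n_receptors != 1 or problem.n_ligands != 2:
        raise ValueError("landscape grids are defined for 1 receptor, 2 ligands")
    eff = np.asarray(eff, dtype=float).reshape(1, 2)
    lo, hi = problem.dG_bounds
    grid = np.linspace(lo, hi, n)
    rows = []
    for g1 in grid:
        for g2 in grid:
            rep = problem.report(np.array([[g1, g2]]), eff)
            rows.append({"dG1": float(g1), "dG2": float(g2), "det": rep.det})
    return pd.DataFrame(rows)


def robustness_scan(design: DesignResult, composition_range,
                    reoptimize: bool = True,
                    settings: SamplerSettings | None = None) -> pd.DataFrame:
    """Det retention of a fixed design across mixture compositions.

    Varies the relative concentration of the first non-reference ligand over
    ``composition_range``, evaluating the fixed design's det and (optionally)
    the per-composition re-optimized det; retention is their ratio.
    """
    problem = design.problem
    ref = problem.composition.reference_index
    free = [i for i in range(problem.n_ligands) if i != ref]
    if not free:
        raise ValueError("need at least two ligands to vary the composition")
    vary = free[0]
    v_design = np.concatenate([design.dG.ravel()]
                              + ([design.eff.ravel()] if problem.efficacies_free else []))
    rows = []
    for x2 in np.asarray(composition_range, dtype=float):
        x = problem.composition.x.copy()
        x[vary] = x2
        comp = replace(problem.composition, x=x)
        prob2 = replace(problem, composition=comp)
        det_fixed = np.exp(prob2.log_det(v_design))
        row = {"x_varied": float(x2), "det_fixed": float(det_fixed)}
        if reoptimize:
            st = settings or _design_settings(prob2, seed=int(1000 * x2) % 2**31)
            res2 = optimize_design(prob2, st)
            row["det_reopt"] = res2.det
            row["retention"] = float(det_fixed / res2.det) if res2.det > 0 else np.nan
            row["dG_opt"] = res2.dG.ravel().tolist()
        rows.append(row)
    return pd.DataFrame(rows)
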