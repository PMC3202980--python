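"""Bayesian inference machinery: priors, nested sampling, Metropolis refinement.

Posteriors are estimated by nested sampling (Skilling's algorithm): live
points are drawn from the prior, the worst is repeatedly replaced by a new
prior draw under a hard likelihood constraint, and the trapezoid over the
shrinking prior mass accumulates the evidence Z alongside weighted posterior
samples.  Sampling happens in the unit cube; the prior quantile transform
maps cube coordinates to parameter space, which makes uniform
(translation-invariant) and Jeffreys (scale-invariant, ``p(t) ~ 1/t``)
priors equally trivial to draw from.

An optional Metropolis Monte-Carlo chain started from the likelihood maximum
found by nested sampling refines the posterior histograms (50 000 models by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ArrayParams,
    MixtureComposition,
    ModelConstants,
    ResponseDataset,
    chemical_potentials,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Prior",
    "PriorSpec",
    "SamplerSettings",
    "PosteriorSummary",
    "DEFAULT_BOUNDS",
    "nested_sampling",
    "metropolis_refine",
    "log_likelihood_single",
    "SingleCurveLikelihood",
    "ArrayLikelihood",
    "log_likelihood_array",
]

#: Default prior bounds covering the experimental dynamic range with margin:
#: binding free energies span weak to very strong binding, the noise scale
#: and concentration ratios get scale-invariant priors over several decades,
#: and mu0 covers a 1 nM .. 100 mM total-concentration window.
DEFAULT_BOUNDS = {
    "dG": ("uniform", -16.0, -1.0),
    "eff": ("uniform", 0.0, 1.0),
    "bg": ("uniform", 0.0, 0.5),
    "sigma": ("jeffreys", 5e-3, 0.5),
    "x": ("jeffreys", 1e-4, 1e4),
    "conc_total": (1e-9, 1e-1),  # molar window for mu0 = kT*ln(c)
}


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prior:
    """One parameter's prior: uniform on [lo, hi] or Jeffreys (log-uniform)."""

    name: str
    kind: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "jeffreys"):
            raise ValueError(f"unknown prior kind {self.kind!r} for {self.name!r}")
        if not self.lo < self.hi:
            raise ValueError(f"prior for {self.name!r}: lo must be < hi "
                             f"({self.lo} >= {self.hi})")
        if self.kind == "jeffreys" and self.lo <= 0:
            raise ValueError(f"Jeffreys prior for {self.name!r} requires lo > 0")


class PriorSpec:
    """Ordered collection of per-parameter priors with a unit-cube transform."""

    def __init__(self, priors: list[Prior]):
        if not priors:
            raise ValueError("at least one prior required")
        self.priors = list(priors)
        self._lo = np.array([p.lo for p in priors])
        self._hi = np.array([p.hi for p in priors])
        self._jeff = np.array([p.kind == "jeffreys" for p in priors])
        lo_safe = np.where(self._jeff, self._lo, 1.0)
        hi_safe = np.where(self._jeff, self._hi, 1.0)
        self._loglo = np.log(lo_safe)
        self._loghi = np.log(hi_safe)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.priors]

    @property
    def ndim(self) -> int:
        return len(self.priors)

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube coordinates to parameter space (prior quantile function)."""
        u = np.asarray(u, dtype=float)
        lin = self._lo + u * (self._hi - self._lo)
        jef = np.exp(self._loglo + u * (self._loghi - self._loglo))
        return np.where(self._jeff, jef, lin)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.transform(rng.random((n, self.ndim)))

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(((theta >= self._lo) & (theta <= self._hi)).all())

    def to_dict(self) -> dict:
        return {p.name: {"kind": p.kind, "lo": p.lo, "hi": p.hi} for p in self.priors}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls([Prior(name, spec["kind"], float(spec["lo"]), float(spec["hi"]))
                    for name, spec in d.items()])


@dataclass(frozen=True)
class SamplerSettings:
    """Nested-sampling knobs.

    ``n_live`` live points; each replacement explores the hard-constrained
    prior with ``mcmc_steps_per_replacement`` Metropolis steps whose scales
    adapt towards ~50% acceptance; the run stops once the remaining prior
    mass times the best live likelihood would add less than
    ``stop_tolerance`` (in log-evidence) to Z.
    """

    n_live: int = 100
    mcmc_steps_per_replacement: int = 20
    stop_tolerance: float = 1e-4
    max_iterations: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 2:
            raise ValueError("n_live must be >= 2")
        if self.stop_tolerance <= 0:
            raise ValueError("stop_tolerance must be > 0")

    def with_seed(self, seed: int) -> "SamplerSettings":
        return SamplerSettings(self.n_live, self.mcmc_steps_per_replacement,
                               self.stop_tolerance, self.max_iterations, int(seed))


#: Reduced-cost preset for routine fits and scans.
FAST_SETTINGS = SamplerSettings(n_live=50, mcmc_steps_per_replacement=15)


@dataclass
class PosteriorSummary:
    """Weighted posterior samples with summary statistics and the evidence."""

    names: list[str]
    samples: np.ndarray          # (n, d)
    weights: np.ndarray          # normalized, sum to 1
    means: np.ndarray
    stds: np.ndarray
    log_evidence: float
    log_evidence_err: float
    map_estimate: np.ndarray
    map_log_likelihood: float
    n_calls: int = 0
    acceptance_rate: float | None = None

    def __getitem__(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.means[i]), float(self.stds[i])

    def quantile(self, name: str, q) -> np.ndarray:
        """Weighted posterior quantile(s) of one parameter."""
        i = self.names.index(name)
        order = np.argsort(self.samples[:, i])
        cdf = np.cumsum(self.weights[order])
        cdf /= cdf[-1]
        return np.interp(np.atleast_1d(q), cdf, self.samples[order, i])

    def resample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        idx = rng.choice(len(self.weights), size=n, p=self.weights)
        return self.samples[idx]

    def to_dict(self) -> dict:
        return {
            "parameters": self.names,
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "log_evidence": self.log_evidence,
            "log_evidence_err": self.log_evidence_err,
            "map_estimate": self.map_estimate.tolist(),
            "map_log_likelihood": self.map_log_likelihood,
        }


def _summarize(names, samples, logw, logz, logz_err, n_calls, acc=None) -> PosteriorSummary:
    w = np.exp(logw - logw.max())
    w /= w.sum()
    means = w @ samples
    var = w @ (samples - means) ** 2
    stds = np.sqrt(np.maximum(var, 0.0))
    return PosteriorSummary(
        names=list(names), samples=samples, weights=w, means=means, stds=stds,
        log_evidence=logz, log_evidence_err=logz_err,
        map_estimate=samples[-1].copy(), map_log_likelihood=np.nan,
        n_calls=n_calls, acceptance_rate=acc,
    )


# ---------------------------------------------------------------------------
# Nested sampling
# ---------------------------------------------------------------------------


def _reflect(u: np.ndarray) -> np.ndarray:
    """Fold proposals back into the unit cube (reflecting boundaries)."""
    v = np.mod(u, 2.0)
    return np.where(v > 1.0, 2.0 - v, v)


def nested_sampling(loglike, priors: PriorSpec,
                    settings: SamplerSettings | None = None) -> PosteriorSummary:
    """Estimate the posterior and the evidence of ``loglike`` under ``priors``.

    Returns weighted samples, their means/stds, log Z with the standard
    information-based error estimate sqrt(H / n_live), and the maximum
    log-likelihood point encountered (used to seed Metropolis refinement).
    Deterministic for a fixed ``settings.seed``.
    """
    settings = settings or SamplerSettings()
    rng = np.random.default_rng(settings.seed)
    d, N = priors.ndim, settings.n_live
    steps = settings.mcmc_steps_per_replacement

    U = rng.random((N, d))
    T = priors.transform(U)
    L = np.array([float(loglike(t)) for t in T])
    if np.isnan(L).any():
        raise ValueError("log-likelihood returned NaN at a prior draw")
    n_calls = N

    scale = np.full(d, 0.2)
    dead_t: list[np.ndarray] = []
    dead_l: list[float] = []
    dead_logw: list[float] = []

    logZ = -np.inf
    log_shrink = -1.0 / N                      # E[ln(X_i/X_{i-1})]
    log_strip = np.log1p(-np.exp(log_shrink))  # ln(X_{i-1} - X_i) - ln X_{i-1}
    logX = 0.0
    it = 0
    while it < settings.max_iterations:
        it += 1
        worst = int(np.argmin(L))
        Lstar = L[worst]
        logw = logX + log_strip  # width of this strip of prior mass
        dead_t.append(T[worst].copy())
        dead_l.append(Lstar)
        dead_logw.append(logw)
        logZ = np.logaddexp(logZ, logw + Lstar)
        logX += log_shrink

        # replace the worst point: constrained Metropolis walk from a survivor
        src = worst if N == 1 else int(rng.choice([k for k in range(N) if k != worst]))
        u, t, l = U[src].copy(), T[src].copy(), L[src]
        n_acc = 0
        for _ in range(steps):
            up = _reflect(u + scale * rng.standard_normal(d))
            tp = priors.transform(up)
            lp = float(loglike(tp))
            n_calls += 1
            if np.isnan(lp):
                raise ValueError("log-likelihood returned NaN inside the prior")
            if lp > Lstar:
                u, t, l = up, tp, lp
                n_acc += 1
        U[worst], T[worst], L[worst] = u, t, l
        # adapt towards ~50% acceptance
        frac = n_acc / steps
        scale = np.clip(scale * np.exp((frac - 0.5) / 2.0), 1e-6, 1.0)

        remaining = L.max() + logX
        if np.isfinite(logZ):
            if np.logaddexp(logZ, remaining) - logZ < settings.stop_tolerance:
                break
        elif not np.isfinite(L.max()) and it >= 10 * N:
            # likelihood is -inf over the whole explored prior; give up
            break
    else:
        logger.warning("nested sampling hit max_iterations=%d", settings.max_iterations)

    # spread the final live points over the remaining prior mass
    logw_live = logX - np.log(N)
    for k in range(N):
        dead_t.append(T[k].copy())
        dead_l.append(L[k])
        dead_logw.append(logw_live)
        logZ = np.logaddexp(logZ, logw_live + L[k])

    samples = np.asarray(dead_t)
    logl = np.asarray(dead_l)
    logw_post = np.asarray(dead_logw) + logl - logZ  # normalized posterior log-weights
    w = np.exp(logw_post)
    with np.errstate(invalid="ignore"):
        H = float(np.nansum(np.where(w > 0, w * (logl - logZ), 0.0)))  # info (nats)
    logz_err = float(np.sqrt(max(H, 0.0) / N))

    summary = _summarize(priors.names, samples, logw_post, float(logZ), logz_err, n_calls)
    best = int(np.argmax(logl))
    summary.map_estimate = samples[best].copy()
    summary.map_log_likelihood = float(logl[best])
    logger.debug("nested sampling: %d iterations, %d calls, logZ=%.3f±%.3f, H=%.1f nats",
                 it, n_calls, logZ, logz_err, H)
    return summary


# ---------------------------------------------------------------------------
# Metropolis refinement
# ---------------------------------------------------------------------------


def metropolis_refine(loglike, start: np.ndarray, n_samples: int = 50_000,
                      step_scales: np.ndarray | None = None, seed: int = 0,
                      priors: PriorSpec | None = None,
                      names: list[str] | None = None) -> PosteriorSummary:
    """Metropolis Monte-Carlo chain from the log-likelihood maximum.

    Produces an ensemble of ``n_samples`` models (default 50 000) whose
    histograms, means and standard deviations summarize the posterior.  Step
    scales adapt towards ~40% acceptance over the first fifth of the chain;
    when ``priors`` is given, proposals outside the prior box are rejected.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(start, dtype=float).copy()
    d = theta.size
    cur = float(loglike(theta))
    if not np.isfinite(cur):
        raise ValueError("start point has non-finite log-likelihood")
    if step_scales is None:
        if priors is not None:
            step_scales = 0.02 * (priors._hi - priors._lo)
        else:
            step_scales = 0.02 * np.maximum(np.abs(theta), 1.0)
    scale = np.asarray(step_scales, dtype=float).copy()

    chain = np.empty((n_samples, d))
    n_adapt = max(n_samples // 5, 1)
    window = max(min(500, n_adapt // 4), 1)
    acc_window = 0
    n_acc_total = 0
    for i in range(n_samples):
        prop = theta + scale * rng.standard_normal(d)
        ok = priors is None or priors.contains(prop)
        if ok:
            lp = float(loglike(prop))
            if np.log(rng.random()) < lp - cur:
                theta, cur = prop, lp
                acc_window += 1
                n_acc_total += 1
        chain[i] = theta
        if i < n_adapt and (i + 1) % window == 0:
            frac = acc_window / window
            if frac == 0.0:
                logger.warning("metropolis_refine: zero acceptance over a full "
                               "adaptation window; shrinking step scales")
            scale = np.clip(scale * np.exp(frac - 0.4), 1e-12, None)
            acc_window = 0

    acc_rate = n_acc_total / n_samples
    logger.debug("metropolis_refine: acceptance rate %.3f", acc_rate)
    names = names or [f"theta_{k}" for k in range(d)]
    w = np.full(n_samples, 1.0 / n_samples)
    means = chain.mean(axis=0)
    stds = chain.std(axis=0)
    return PosteriorSummary(
        names=list(names), samples=chain, weights=w, means=means, stds=stds,
        log_evidence=np.nan, log_evidence_err=np.nan,
        map_estimate=np.asarray(start, dtype=float).copy(),
        map_log_likelihood=float(loglike(np.asarray(start, dtype=float))),
        n_calls=n_samples, acceptance_rate=acc_rate,
    )


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def _gauss_loglike(resid: np.ndarray, sigma: float) -> float:
    return float(-(resid @ resid) / (2.0 * sigma**2)
                 - resid.size * np.log(sigma * np.sqrt(2.0 * np.pi)))


def _occupancy_curve(dG_row: np.ndarray, logx_norm: np.ndarray,
                     mu_tot: np.ndarray, kT: float) -> np.ndarray:
    """Occupancy p_i(m) for each ligand i at each series potential mu_tot[m]."""
    a = (mu_tot[None, :] - dG_row[:, None]) / kT + logx_norm[:, None]
    amax = np.maximum(a.max(axis=0), 0.0)
    expa = np.exp(a - amax[None, :])
    denom = np.exp(-amax) + expa.sum(axis=0)
    return expa / denom[None, :]


class SingleCurveLikelihood:
    """Gaussian log-likelihood of one receptor + one ligand dilution curve.

    theta = (dG, eff, bg, sigma) when the series' mu0 is known, or
    (dG, eff, bg, sigma, mu0) when the reference potential is inferred.
    All replicates and series points enter the sum.
    """

    names = ("dG", "eff", "bg", "sigma")

    def __init__(self, curve: ResponseDataset, const: ModelConstants | None = None,
                 infer_mu0: bool = False):
        self.const = const or ModelConstants()
        if len(curve) == 0:
            raise ValueError("empty dataset")
        receptors = curve.receptors
        if len(receptors) != 1:
            raise ValueError(f"expected a single-receptor curve, got {receptors}")
        self.receptor = receptors[0]
        series = curve.series[self.receptor]
        self.offsets = series.offsets
        self.point_idx = curve.df["point_index"].to_numpy(dtype=int)
        self.F = curve.df["intensity"].to_numpy(dtype=float)
        self.infer_mu0 = infer_mu0
        self.mu0 = None if infer_mu0 else series.mu0
        if not infer_mu0 and self.mu0 is None:
            raise ValueError("series mu0 unknown; use infer_mu0=True")

    @property
    def n_obs(self) -> int:
        return self.F.size

    def model_curve(self, dG: float, eff: float, bg: float, mu0: float) -> np.ndarray:
        a = (mu0 + self.offsets - dG) / self.const.kT
        p = np.where(a >= 0, 1.0 / (1.0 + np.exp(-np.abs(a))),
                     np.exp(-np.abs(a)) / (1.0 + np.exp(-np.abs(a))))
        return bg + eff * p

    def __call__(self, theta: np.ndarray) -> float:
        dG, eff, bg, sigma = theta[:4]
        if sigma <= 0:
            return -np.inf
        mu0 = theta[4] if self.infer_mu0 else self.mu0
        I = self.model_curve(dG, eff, bg, mu0)
        return _gauss_loglike(self.F - I[self.point_idx], sigma)


def log_likelihood_single(curve: ResponseDataset, theta,
                          const: ModelConstants | None = None) -> float:
    """Gaussian log-likelihood of a single-ligand curve at theta.

    theta is (dG, eff, bg, sigma) with the reference potential taken from the
    series, or (dG, eff, bg, sigma, mu0) to supply it explicitly.
    """
    theta = np.asarray(theta, dtype=float)
    return SingleCurveLikelihood(curve, const, infer_mu0=(theta.size == 5))(theta)


class ArrayLikelihood:
    """Gaussian log-likelihood of mixture responses from a receptor subset.

    Parameter vector: ``[x_i for i != reference] + [mu0] + [sigma_r ...]``
    (sigmas optional: pass ``fit_sigma=False`` to use the calibrated values).
    The relative concentrations enter through the per-ligand chemical
    potentials ``mu_i(m) = mu0 + offset_m + kT ln(x_i / sum_k x_k)``.
    """

    def __init__(self, data: ResponseDataset, params: ArrayParams,
                 reference_ligand: str, receptor_subset: list[str] | None = None,
                 const: ModelConstants | None = None, fit_sigma: bool = True,
                 infer_mu0: bool = True):
        self.const = const or ModelConstants()
        self.params = params
        self.ref = params.ligand_index(reference_ligand)
        self.reference_ligand = reference_ligand
        receptors = receptor_subset or data.receptors
        for r in receptors:
            params.receptor_index(r)  # raises on unknown receptor
        if not receptors:
            raise ValueError("receptor subset is empty")
        self.receptors = list(receptors)
        self.fit_sigma = fit_sigma
        self.infer_mu0 = infer_mu0
        self._per_receptor = []
        for r in self.receptors:
            sub = data.df[data.df["receptor"] == r]
            if sub.empty:
                raise ValueError(f"no data for receptor {r!r}")
            series = data.series[r]
            j = params.receptor_index(r)
            self._per_receptor.append({
                "j": j,
                "offsets": series.offsets,
                "mu0_known": series.mu0,
                "point_idx": sub["point_index"].to_numpy(dtype=int),
                "F": sub["intensity"].to_numpy(dtype=float),
            })

    @property
    def names(self) -> list[str]:
        lig = [f"x_{self.params.ligand_ids[i]}"
               for i in range(self.params.n_ligands) if i != self.ref]
        out = lig + (["mu0"] if self.infer_mu0 else [])
        if self.fit_sigma:
            out += [f"sigma_{r}" for r in self.receptors]
        return out

    @property
    def n_obs(self) -> int:
        return sum(pr["F"].size for pr in self._per_receptor)

    def split(self, theta: np.ndarray):
        L = self.params.n_ligands
        nx = L - 1
        x = np.empty(L)
        x[self.ref] = 1.0
        free = [i for i in range(L) if i != self.ref]
        x[free] = theta[:nx]
        k = nx
        if self.infer_mu0:
            mu0 = float(theta[k]); k += 1
        else:
            mu0 = None
        if self.fit_sigma:
            sigmas = np.asarray(theta[k:k + len(self.receptors)], dtype=float)
        else:
            sigmas = self.params.sigma[[pr["j"] for pr in self._per_receptor]]
        return x, mu0, sigmas

    def __call__(self, theta: np.ndarray) -> float:
        x, mu0, sigmas = self.split(np.asarray(theta, dtype=float))
        if (x < 0).any() or (sigmas <= 0).any():
            return -np.inf
        S = x.sum()
        with np.errstate(divide="ignore"):
            logx_norm = np.log(x / S)
        total = 0.0
        p = self.params
        for pr, sig in zip(self._per_receptor, sigmas):
            mu_ref = mu0 if self.infer_mu0 else pr["mu0_known"]
            mu_tot = mu_ref + pr["offsets"]
            occ = _occupancy_curve(p.dG[pr["j"]], logx_norm, mu_tot, self.const.kT)
            I = p.bg[pr["j"]] + p.eff[pr["j"]] @ occ
            total += _gauss_loglike(pr["F"] - I[pr["point_idx"]], float(sig))
        return total


def log_likelihood_array(data: ResponseDataset, params: ArrayParams,
                         comp_theta, const: ModelConstants | None = None,
                         reference_ligand: str | None = None,
                         receptor_subset: list[str] | None = None) -> float:
    """Joint Gaussian log-likelihood of the array's mixture responses.

    ``comp_theta = (x_free, mu0, sigmas)`` with ``x_free`` the relative
    concentrations of every non-reference ligand, in panel order.
    """
    reference_ligand = reference_ligand or params.ligand_ids[0]
    like = ArrayLikelihood(data, params, reference_ligand, receptor_subset, const)
    x_free, mu0, sigmas = comp_theta
    theta = np.concatenate([np.atleast_1d(x_free), [mu0], np.atleast_1d(sigmas)])
    return like(theta)


def composition_from_theta(like: ArrayLikelihood, theta: np.ndarray) -> MixtureComposition:
    """MixtureComposition at a parameter vector of an ArrayLikelihood."""
    x, mu0, _ = like.split(np.asarray(theta, dtype=float))
    total = like.const.concentration_of_mu(mu0) if mu0 is not None else None
    return MixtureComposition(list(like.params.ligand_ids), x,
                              like.reference_ligand, total_concentration=total)
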