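"""Mixture decoding: infer every ligand's absolute concentration from readout.

Given a calibrated array and mixture response curves from any receptor
subset, nested sampling explores (x_i for i != reference, mu0, sigma_r):
the relative concentrations, the total chemical potential at the series
reference point, and per-receptor noise scales.  The full ligand panel is
always modelled even when fewer ligands are actually present — absent
ligands are expected to collapse towards the prior floor.  Relative
concentrations get scale-invariant (Jeffreys) priors, i.e. the sampler
works uniformly in log-x; summaries are reported on the linear scale.

Posterior samples of (x, mu0) convert directly to absolute concentrations
``c_i = exp(mu0/kT) * x_i / sum_k x_k``, which are invariant under the
arbitrary choice of reference ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import (
    ArrayLikelihood,
    DEFAULT_BOUNDS,
    PosteriorSummary,
    Prior,
    PriorSpec,
    SamplerSettings,
    nested_sampling,
)
from .model import ArrayParams, MixtureComposition, ModelConstants, ResponseDataset

__all__ = ["DecodeResult", "decode_priors", "decode_mixture", "rereference"]

#: A ligand is called absent when its posterior mean concentration is below
#: this fraction of the total and its 95% interval touches the prior floor.
ABSENT_FRACTION = 0.05
ABSENT_FLOOR_FACTOR = 3.0


def decode_priors(params: ArrayParams, reference_ligand: str,
                  receptor_subset: list[str],
                  const: ModelConstants | None = None) -> PriorSpec:
    """Default decoding priors: Jeffreys on x and sigma, uniform on mu0."""
    const = const or ModelConstants()
    lo_c, hi_c = DEFAULT_BOUNDS["conc_total"]
    priors = [Prior(f"x_{l}", *DEFAULT_BOUNDS["x"])
              for l in params.ligand_ids if l != reference_ligand]
    priors.append(Prior("mu0", "uniform",
                        const.kT * np.log(lo_c), const.kT * np.log(hi_c)))
    priors += [Prior(f"sigma_{r}", *DEFAULT_BOUNDS["sigma"]) for r in receptor_subset]
    return PriorSpec(priors)


@dataclass
class DecodeResult:
    """Posterior composition of a mixture plus absolute concentrations."""

    ligand_ids: list[str]
    reference_ligand: str
    receptor_subset: list[str]
    x_mean: dict[str, float]
    x_std: dict[str, float]
    mu0_mean: float
    mu0_std: float
    sigma_mean: dict[str, float]
    sigma_std: dict[str, float]
    conc_mean: dict[str, float]           # molar, at the reference point
    conc_std: dict[str, float]
    total_conc_mean: float
    total_conc_std: float
    absent: dict[str, bool]
    log_evidence: float
    log_evidence_err: float
    posterior: PosteriorSummary
    const: ModelConstants = field(default_factory=ModelConstants)

    @property
    def composition(self) -> MixtureComposition:
        x = np.array([1.0 if l == self.reference_ligand else self.x_mean[l]
                      for l in self.ligand_ids])
        return MixtureComposition(list(self.ligand_ids), x, self.reference_ligand,
                                  total_concentration=self.total_conc_mean)

    def to_dict(self) -> dict:
        return {
            "ligand_ids": self.ligand_ids,
            "reference_ligand": self.reference_ligand,
            "receptor_subset": self.receptor_subset,
            "x_mean": self.x_mean, "x_std": self.x_std,
            "mu0_mean": self.mu0_mean, "mu0_std": self.mu0_std,
            "sigma_mean": self.sigma_mean, "sigma_std": self.sigma_std,
            "conc_mean": self.conc_mean, "conc_std": self.conc_std,
            "total_conc_mean": self.total_conc_mean,
            "total_conc_std": self.total_conc_std,
            "absent": self.absent,
            "log_evidence": self.log_evidence,
            "log_evidence_err": self.log_evidence_err,
        }


def _full_x(samples: np.ndarray, ligand_ids: list[str], ref: str) -> np.ndarray:
    """Expand free-x sample columns to the full panel (reference column = 1)."""
    n = samples.shape[0]
    L = len(ligand_ids)
    x = np.empty((n, L))
    k = 0
    for i, l in enumerate(ligand_ids):
        if l == ref:
            x[:, i] = 1.0
        else:
            x[:, i] = samples[:, k]
            k += 1
    return x


def _wstats(values: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = w @ values
    var = w @ (values - mean) ** 2
    return mean, np.sqrt(np.maximum(var, 0.0))


def _wquantile(values: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    cdf = np.cumsum(w[order])
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, values[order]))


def _summarize_decode(like: ArrayLikelihood, summary: PosteriorSummary,
                      const: ModelConstants) -> DecodeResult:
    params = like.params
    ref = like.reference_ligand
    lig = list(params.ligand_ids)
    L = len(lig)
    nx = L - 1
    w = summary.weights
    x = _full_x(summary.samples[:, :nx], lig, ref)
    mu0 = summary.samples[:, nx]
    sig = summary.samples[:, nx + 1:]
    S = x.sum(axis=1)
    total = np.exp(mu0 / const.kT)
    conc = total[:, None] * x / S[:, None]

    x_mean, x_std = _wstats(x, w)
    c_mean, c_std = _wstats(conc, w)
    mu0_mean, mu0_std = _wstats(mu0, w)
    t_mean, t_std = _wstats(total, w)
    s_mean, s_std = _wstats(sig, w)

    x_lo = float(DEFAULT_BOUNDS["x"][1])
    absent = {}
    for i, l in enumerate(lig):
        if l == ref:
            absent[l] = False
            continue
        near_floor = _wquantile(x[:, i], w, 0.025) <= ABSENT_FLOOR_FACTOR * x_lo
        absent[l] = bool(c_mean[i] < ABSENT_FRACTION * t_mean and near_floor)

    ref_i = lig.index(ref)
    return DecodeResult(
        ligand_ids=lig, reference_ligand=ref, receptor_subset=list(like.receptors),
        x_mean={l: float(x_mean[i]) for i, l in enumerate(lig)},
        x_std={l: (0.0 if i == ref_i else float(x_std[i])) for i, l in enumerate(lig)},
        mu0_mean=float(mu0_mean), mu0_std=float(mu0_std),
        sigma_mean={r: float(s_mean[k]) for k, r in enumerate(like.receptors)},
        sigma_std={r: float(s_std[k]) for k, r in enumerate(like.receptors)},
        conc_mean={l: float(c_mean[i]) for i, l in enumerate(lig)},
        conc_std={l: float(c_std[i]) for i, l in enumerate(lig)},
        total_conc_mean=float(t_mean), total_conc_std=float(t_std),
        absent=absent,
        log_evidence=summary.log_evidence, log_evidence_err=summary.log_evidence_err,
        posterior=summary, const=const,
    )


def decode_mixture(data: ResponseDataset, params: ArrayParams,
                   receptor_subset: list[str] | None = None,
                   reference_ligand: str | None = None,
                   priors: PriorSpec | None = None,
                   settings: SamplerSettings | None = None,
                   const: ModelConstants | None = None) -> DecodeResult:
    """Infer the mixture's composition and absolute scale from array readout.

    Fits the full ligand panel of ``params`` regardless of how many ligands
    are truly present; restricting ``receptor_subset`` reproduces
    partial-array analyses.  Returns posterior summaries for relative
    concentrations, mu0, per-receptor noise, absolute concentrations with
    propagated uncertainties, absent-ligand calls and the log-evidence.
    """
    const = const or ModelConstants()
    reference_ligand = reference_ligand or params.ligand_ids[0]
    like = ArrayLikelihood(data, params, reference_ligand,
                           receptor_subset, const, fit_sigma=True, infer_mu0=True)
    priors = priors or decode_priors(params, reference_ligand, like.receptors, const)
    if priors.ndim != (params.n_ligands - 1) + 1 + len(like.receptors):
        raise ValueError("prior dimension does not match the decode parameter vector")
    summary = nested_sampling(like, priors, settings)
    return _summarize_decode(like, summary, const)


def rereference(result: DecodeResult, new_reference_ligand: str) -> DecodeResult:
    """Re-express relative concentrations w.r.t. a different reference ligand.

    Operates sample-by-sample on the stored posterior, so absolute
    concentrations are exactly unchanged; only the x summaries transform.
    Raises if the new reference was called absent (ratios to a near-zero
    ligand are meaningless).
    """
    lig = result.ligand_ids
    if new_reference_ligand not in lig:
        raise KeyError(f"unknown ligand {new_reference_ligand!r}")
    if result.absent.get(new_reference_ligand, False):
        raise ValueError(f"cannot re-reference onto absent ligand "
                         f"{new_reference_ligand!r}")
    if new_reference_ligand == result.reference_ligand:
        return result

    summary = result.posterior
    L = len(lig)
    nx = L - 1
    w = summary.weights
    x_old = _full_x(summary.samples[:, :nx], lig, result.reference_ligand)
    j = lig.index(new_reference_ligand)
    x_new = x_old / x_old[:, [j]]
    x_mean, x_std = _wstats(x_new, w)

    out = DecodeResult(**{**result.__dict__})
    out.reference_ligand = new_reference_ligand
    out.x_mean = {l: (1.0 if i == j else float(x_mean[i])) for i, l in enumerate(lig)}
    out.x_std = {l: (0.0 if i == j else float(x_std[i])) for i, l in enumerate(lig)}
    return out
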