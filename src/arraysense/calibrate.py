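"""Calibration: turn dilution-series data into the array's physical parameters.

Single-receptor, single-ligand binding curves determine (dG, eff, bg, sigma)
for every receptor-ligand pair by nested sampling of the Gaussian
likelihood.  Calibration mixtures are prepared by the experimenter, so the
total concentrations — and hence the series' reference chemical potential —
are treated as exactly known; only mixture decoding infers mu0.

Full antagonists produce a flat single-ligand curve (they bind but emit no
signal), so their binding energy is unidentifiable from their own curve.
They are instead calibrated from a binary mixture with a known agonist: the
antagonist's binding strength is read off the suppression of the agonist
signal.  When several candidate agonist partners are available, the one
yielding the smallest posterior std of the antagonist's dG is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import (
    DEFAULT_BOUNDS,
    PosteriorSummary,
    Prior,
    PriorSpec,
    SamplerSettings,
    SingleCurveLikelihood,
    _gauss_loglike,
    _occupancy_curve,
    metropolis_refine,
    nested_sampling,
)
from .model import (
    ArrayParams,
    MixtureComposition,
    ModelConstants,
    ResponseDataset,
    chemical_potentials,
    single_ligand_intensity,
)

__all__ = [
    "CalibrationEntry",
    "default_calibration_priors",
    "fit_single_ligand",
    "fit_antagonist_in_mixture",
    "select_antagonist_partner",
    "fit_plate_bias",
    "calibrate_array",
]


@dataclass
class CalibrationEntry:
    """Posterior over (dG, eff, bg, sigma) for one receptor-ligand pair."""

    receptor: str
    ligand: str
    posterior: PosteriorSummary
    point_estimate: dict[str, float]
    provenance: str

    def __post_init__(self) -> None:
        if self.point_estimate.get("sigma", 1.0) <= 0:
            raise ValueError("sigma point estimate must be > 0")


def default_calibration_priors() -> PriorSpec:
    return PriorSpec([
        Prior("dG", *DEFAULT_BOUNDS["dG"]),
        Prior("eff", *DEFAULT_BOUNDS["eff"]),
        Prior("bg", *DEFAULT_BOUNDS["bg"]),
        Prior("sigma", *DEFAULT_BOUNDS["sigma"]),
    ])


def _point_estimates(summary: PosteriorSummary, use_map: bool = False) -> dict[str, float]:
    src = summary.map_estimate if use_map else summary.means
    return {n: float(v) for n, v in zip(summary.names, src)}


def fit_single_ligand(curve: ResponseDataset, priors: PriorSpec | None = None,
                      settings: SamplerSettings | None = None,
                      const: ModelConstants | None = None,
                      ligand: str | None = None,
                      point_estimate: str = "mean") -> CalibrationEntry:
    """Fit (dG, eff, bg, sigma) to one receptor's single-ligand dilution curve.

    The series' total concentrations are known, so mu0 is fixed.  Point
    estimates default to posterior means ("mean"); pass
    ``point_estimate="map"`` for the maximum-likelihood model instead.
    """
    const = const or ModelConstants()
    like = SingleCurveLikelihood(curve, const, infer_mu0=False)
    if len(np.unique(like.point_idx)) < 3:
        raise ValueError("need at least 3 distinct concentrations to calibrate")
    priors = priors or default_calibration_priors()
    summary = nested_sampling(like, priors, settings)
    mix = curve.df["mixture_id"].iloc[0]
    return CalibrationEntry(
        receptor=like.receptor,
        ligand=ligand or str(mix),
        posterior=summary,
        point_estimate=_point_estimates(summary, use_map=(point_estimate == "map")),
        provenance="single-ligand",
    )


class _AntagonistLikelihood:
    """Likelihood of a binary agonist+antagonist mixture curve.

    The composition and the series' absolute concentrations are fixed to
    their exact prepared values; the agonist's (dG, eff) are held at their
    calibrated values.  theta = (dG, eff, bg, sigma) of the antagonist.
    """

    names = ("dG", "eff", "bg", "sigma")

    def __init__(self, curve: ResponseDataset, composition: MixtureComposition,
                 antagonist: str, agonist: str, agonist_dG: float,
                 agonist_eff: float, const: ModelConstants):
        receptors = curve.receptors
        if len(receptors) != 1:
            raise ValueError("expected a single-receptor curve")
        self.receptor = receptors[0]
        series = curve.series[self.receptor]
        if series.mu0 is None:
            raise ValueError("composition not fixed: series mu0 must be known")
        self.const = const
        i_ant = composition.ligand_ids.index(antagonist)
        i_ag = composition.ligand_ids.index(agonist)
        if composition.x[i_ant] <= 0 or composition.x[i_ag] <= 0:
            raise ValueError("both mixture partners must be present")
        mu = np.array([chemical_potentials(composition, mt, const)
                       for mt in series.potentials()])  # (M, L)
        # per-ligand log(x/S) folded into mu already; keep the two relevant columns
        self.mu_ag = mu[:, i_ag]
        self.mu_ant = mu[:, i_ant]
        self.dG_ag = float(agonist_dG)
        self.eff_ag = float(agonist_eff)
        self.point_idx = curve.df["point_index"].to_numpy(dtype=int)
        self.F = curve.df["intensity"].to_numpy(dtype=float)

    def model_curve(self, dG_ant: float, eff_ant: float, bg: float) -> np.ndarray:
        kT = self.const.kT
        a = np.stack([(self.mu_ag - self.dG_ag) / kT,
                      (self.mu_ant - dG_ant) / kT])  # (2, M) log weights
        amax = np.maximum(a.max(axis=0), 0.0)
        expa = np.exp(a - amax[None, :])
        denom = np.exp(-amax) + expa.sum(axis=0)
        p = expa / denom[None, :]
        return bg + self.eff_ag * p[0] + eff_ant * p[1]

    def __call__(self, theta: np.ndarray) -> float:
        dG_ant, eff_ant, bg, sigma = theta
        if sigma <= 0:
            return -np.inf
        I = self.model_curve(dG_ant, eff_ant, bg)
        return _gauss_loglike(self.F - I[self.point_idx], sigma)


def fit_antagonist_in_mixture(binary_curve: ResponseDataset,
                              composition: MixtureComposition,
                              antagonist: str, agonist: str,
                              agonist_dG: float, agonist_eff: float,
                              priors: PriorSpec | None = None,
                              settings: SamplerSettings | None = None,
                              const: ModelConstants | None = None,
                              point_estimate: str = "mean") -> CalibrationEntry:
    """Calibrate an antagonist's (dG, eff) from a binary mixture with an agonist.

    The antagonist competitively displaces the agonist, suppressing the
    signal; the depth and position of that suppression pin down its binding
    free energy even though its own curve is flat.
    """
    const = const or ModelConstants()
    like = _AntagonistLikelihood(binary_curve, composition, antagonist, agonist,
                                 agonist_dG, agonist_eff, const)
    priors = priors or default_calibration_priors()
    summary = nested_sampling(like, priors, settings)
    return CalibrationEntry(
        receptor=like.receptor,
        ligand=antagonist,
        posterior=summary,
        point_estimate=_point_estimates(summary, use_map=(point_estimate == "map")),
        provenance=f"antagonist-in-mixture (partner={agonist})",
    )


def select_antagonist_partner(fits: list[CalibrationEntry]) -> CalibrationEntry:
    """Among candidate partner fits, pick the one with smallest std(dG)."""
    if not fits:
        raise ValueError("no candidate fits supplied")
    return min(fits, key=lambda e: e.posterior["dG"][1])


def fit_plate_bias(curves_by_plate: ResponseDataset, dG: float, sigma: float,
                   reference_eff: float | None = None,
                   reference_bg: float | None = None,
                   const: ModelConstants | None = None) -> dict:
    """Per-plate (eff, bg) re-fit with the binding free energy held fixed.

    With dG and sigma fixed, the single-ligand response is linear in
    (eff, bg), so the per-plate maximum-likelihood adjustment is an exact
    weighted least-squares solve.  Returns, per plate, the refit values and
    the multiplicative/additive adjustments relative to the calibration
    values (when supplied).
    """
    const = const or ModelConstants()
    plates = sorted(curves_by_plate.df["plate"].unique())
    if len(plates) < 2:
        raise ValueError("plate-bias refit needs at least two plates to contrast")
    out = {}
    for plate in plates:
        sub = curves_by_plate.df[curves_by_plate.df["plate"] == plate]
        receptor = sub["receptor"].iloc[0]
        series = curves_by_plate.series[receptor]
        occ = single_ligand_intensity(dG, 1.0, 0.0, series.potentials(), const)
        pred = np.atleast_1d(occ)[sub["point_index"].to_numpy(dtype=int)]
        F = sub["intensity"].to_numpy(dtype=float)
        A = np.column_stack([pred, np.ones_like(pred)])
        (eff_hat, bg_hat), *_ = np.linalg.lstsq(A, F, rcond=None)
        entry = {"eff": float(eff_hat), "bg": float(bg_hat)}
        if reference_eff is not None:
            entry["eff_scale"] = float(eff_hat / reference_eff)
        if reference_bg is not None:
            entry["bg_shift"] = float(bg_hat - reference_bg)
        out[plate] = entry
    return out


def calibrate_array(curves: dict[tuple[str, str], ResponseDataset],
                    receptor_ids: list[str], ligand_ids: list[str],
                    priors: PriorSpec | None = None,
                    settings: SamplerSettings | None = None,
                    const: ModelConstants | None = None,
                    ) -> tuple[ArrayParams, dict[tuple[str, str], CalibrationEntry]]:
    """Fit every (receptor, ligand) curve and assemble ArrayParams.

    The per-receptor background and noise scale are averaged over that
    receptor's calibration fits, matching how a shared assay background is
    estimated from all experiments involving the receptor.
    """
    const = const or ModelConstants()
    entries: dict[tuple[str, str], CalibrationEntry] = {}
    R, L = len(receptor_ids), len(ligand_ids)
    dG = np.empty((R, L))
    eff = np.empty((R, L))
    bg_acc = [[] for _ in range(R)]
    sig_acc = [[] for _ in range(R)]
    base_seed = settings.seed if settings is not None else 0
    for j, r in enumerate(receptor_ids):
        for i, l in enumerate(ligand_ids):
            curve = curves[(r, l)]
            st = settings.with_seed(base_seed + 1000 * j + i) if settings else None
            entry = fit_single_ligand(curve, priors, st, const, ligand=l)
            entries[(r, l)] = entry
            dG[j, i] = entry.point_estimate["dG"]
            eff[j, i] = np.clip(entry.point_estimate["eff"], 0.0, 1.0)
            bg_acc[j].append(entry.point_estimate["bg"])
            sig_acc[j].append(entry.point_estimate["sigma"])
    params = ArrayParams(
        receptor_ids=list(receptor_ids), ligand_ids=list(ligand_ids),
        dG=dG, eff=eff,
        bg=np.array([np.mean(b) for b in bg_acc]),
        sigma=np.array([np.mean(s) for s in sig_acc]),
    )
    return params, entries
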