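"""Synthetic response data: calibration curves, mixture datasets, scans.

Datasets emulate plate-style reporter assays: a log-spaced dilution series
spanning a million-fold concentration range (9 points over 1 nM .. 1 mM by
default, reference point at the top of the ladder), four replicates per
point, and iid Gaussian noise on the normalized intensity.  Optional
per-plate bias rescales efficacies and shifts backgrounds, mimicking
systematic plate-to-plate deviations of microtiter assays.

Randomness is reproducible: each (seed, receptor, plate) triple gets its own
generator stream, so restricting a dataset to a receptor subset never
changes the draws of the other receptors.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import SamplerSettings
from .model import (
    ArrayParams,
    DATA_COLUMNS,
    DilutionSeries,
    MixtureComposition,
    ModelConstants,
    ResponseDataset,
    chemical_potentials,
    mixture_occupancies,
    single_ligand_intensity,
)

__all__ = [
    "GeneratorConfig",
    "default_series",
    "generate_calibration_curve",
    "generate_mixture_dataset",
    "enumerate_equal_mixtures",
    "range_scan",
    "noise_scan",
]

#: Default ladder: 9 log-spaced totals over a million-fold range, 4 replicates.
DEFAULT_N_POINTS = 9
DEFAULT_LOG10_RANGE = (-3.0, -9.0)  # reference (point 0) at 1 mM, down to 1 nM
DEFAULT_REPLICATES = 4


@dataclass
class GeneratorConfig:
    """Truth parameters plus series/noise/plate settings for data generation."""

    params: ArrayParams
    n_points: int = DEFAULT_N_POINTS
    log10_range: tuple[float, float] = DEFAULT_LOG10_RANGE
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    plate_bias: dict | None = None  # plate -> {"eff_scale": s, "bg_shift": b}
    plate_of_receptor: dict | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = min(self.log10_range), max(self.log10_range)
        if not np.isfinite([lo, hi]).all():
            raise ValueError("log10_range must be finite")

    def series(self, const: ModelConstants | None = None) -> DilutionSeries:
        return default_series(self.n_points, self.log10_range, const)


def default_series(n_points: int = DEFAULT_N_POINTS,
                   log10_range: tuple[float, float] = DEFAULT_LOG10_RANGE,
                   const: ModelConstants | None = None) -> DilutionSeries:
    """Log-spaced dilution series; point 0 is the (highest) reference total."""
    top, bottom = log10_range
    if top < bottom:
        top, bottom = bottom, top
    log10c = np.linspace(top, bottom, n_points)
    return DilutionSeries.from_log10_concentrations(log10c, const)


def _stream(seed: int, receptor: str, plate: int) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, receptor, plate)."""
    key = zlib.crc32(str(receptor).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(plate)]))


def _records(receptor, mixture_id, series, clean, sigma, replicates, seed, plate,
             const):
    rng = _stream(seed, receptor, plate)
    kTln10 = const.kT * np.log(10.0)
    if series.mu0 is not None:
        log10c = series.potentials() / kTln10
    else:
        log10c = np.full(series.n_points, np.nan)
    rows = []
    for rep in range(replicates):
        noise = rng.normal(0.0, sigma, size=len(clean)) if sigma > 0 else 0.0
        vals = clean + noise
        for m, v in enumerate(vals):
            rows.append((receptor, mixture_id, m, rep, plate, log10c[m], v))
    return rows


def generate_calibration_curve(dG: float, eff: float, bg: float, sigma: float,
                               series: DilutionSeries | None = None,
                               replicates: int = DEFAULT_REPLICATES,
                               seed: int = 0, receptor_id: str = "R1",
                               ligand_id: str = "L1", plate: int = 1,
                               const: ModelConstants | None = None) -> ResponseDataset:
    """Single-receptor, single-ligand dilution curve with Gaussian noise.

    Intensities are the binding-curve model evaluated on the series plus iid
    N(0, sigma) noise; the record count is n_points x replicates (36 for the
    default 9-point, 4-replicate design).
    """
    const = const or ModelConstants()
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    series = series or default_series(const=const)
    if series.mu0 is None:
        raise ValueError("calibration series needs a known mu0")
    clean = single_ligand_intensity(dG, eff, bg, series.potentials(), const)
    rows = _records(receptor_id, ligand_id, series, np.atleast_1d(clean), sigma,
                    replicates, seed, plate, const)
    return ResponseDataset(pd.DataFrame(rows, columns=DATA_COLUMNS),
                           {receptor_id: series})


def generate_mixture_dataset(params: ArrayParams, comp: MixtureComposition,
                             mu0: float,
                             series: DilutionSeries | dict | None = None,
                             replicates: int = DEFAULT_REPLICATES, seed: int = 0,
                             plate_bias: dict | None = None,
                             plate_of_receptor: dict | None = None,
                             mixture_id: str | None = None,
                             const: ModelConstants | None = None) -> ResponseDataset:
    """Responses of every receptor in ``params`` to a mixture along its series.

    ``mu0`` anchors the total chemical potential at the reference point.
    ``series`` may be shared or a per-receptor dict (experimental receptors
    used different ladders).  ``plate_bias`` maps a plate id to
    ``{"eff_scale": s, "bg_shift": b}``; the clean response of a receptor on
    that plate uses ``s * eff`` and ``bg + b``.
    """
    const = const or ModelConstants()
    if list(comp.ligand_ids) != list(params.ligand_ids):
        raise ValueError("composition ligand panel must match the array's")
    if mixture_id is None:
        present = [l for l, xi in zip(comp.ligand_ids, comp.x) if xi > 0]
        mixture_id = "+".join(present)
    if series is None:
        series = default_series(const=const)
    series_map = (dict(series) if isinstance(series, dict)
                  else {r: series for r in params.receptor_ids})
    missing = [r for r in params.receptor_ids if r not in series_map]
    if missing:
        raise ValueError(f"no series for receptors {missing}")
    plate_of_receptor = plate_of_receptor or {}
    plate_bias = plate_bias or {}

    rows = []
    for j, r in enumerate(params.receptor_ids):
        ser = series_map[r]
        plate = plate_of_receptor.get(r, 1)
        bias = plate_bias.get(plate, {})
        es = float(bias.get("eff_scale", 1.0))
        bs = float(bias.get("bg_shift", 0.0))
        mu_tot = mu0 + ser.offsets
        clean = np.empty(ser.n_points)
        for m, mt in enumerate(mu_tot):
            mu = chemical_potentials(comp, mt, const)
            p, _ = mixture_occupancies(params.dG[j], mu, const)
            clean[m] = params.bg[j] + bs + (es * params.eff[j]) @ p
        # emit with known absolute ladder anchored at mu0
        ser_known = DilutionSeries(ser.n_points, ser.delta_mu, mu0=mu0)
        rows += _records(r, mixture_id, ser_known, clean, float(params.sigma[j]),
                         replicates, seed, plate, const)
    out_series = {r: DilutionSeries(series_map[r].n_points, series_map[r].delta_mu,
                                    mu0=mu0) for r in params.receptor_ids}
    return ResponseDataset(pd.DataFrame(rows, columns=DATA_COLUMNS), out_series)


def enumerate_equal_mixtures(ligand_panel: list[str],
                             total_concentration: float | None = None
                             ) -> list[MixtureComposition]:
    """All 2^L - 1 non-empty equal-proportion mixtures of the panel.

    Singles, pairs, triples, ... up to the full panel — 15 compositions for
    a four-ligand panel.
    """
    if not ligand_panel:
        raise ValueError("ligand panel is empty")
    out = []
    for size in range(1, len(ligand_panel) + 1):
        for subset in itertools.combinations(ligand_panel, size):
            out.append(MixtureComposition.equal_parts(
                list(ligand_panel), list(subset),
                total_concentration=total_concentration))
    return out


def _std_dG_of_fits(truth: dict, series: DilutionSeries, sigma: float,
                    replicates: int, n_runs: int, seeds, settings, const):
    from .calibrate import fit_single_ligand

    stds = []
    for k in range(n_runs):
        seed = int(seeds[k])
        curve = generate_calibration_curve(
            truth["dG"], truth["eff"], truth["bg"], sigma, series=series,
            replicates=replicates, seed=seed, const=const)
        entry = fit_single_ligand(curve, settings=settings.with_seed(seed), const=const)
        stds.append(entry.posterior["dG"][1])
    return float(np.mean(stds))


def range_scan(truth: dict, log10_max_grid, log10_min: float = -9.0,
               n_points: int = DEFAULT_N_POINTS,
               replicates: int = DEFAULT_REPLICATES, sigma: float = 0.02,
               n_runs: int = 3, seed: int = 0,
               settings: SamplerSettings | None = None,
               const: ModelConstants | None = None) -> pd.DataFrame:
    """Mean posterior std of dG as the top of the concentration range widens.

    For each maximum total concentration in ``log10_max_grid`` (log10 molar),
    generates ``n_runs`` noisy calibration curves and averages the posterior
    std of the binding free energy — wider ranges yield more complete
    binding curves and tighter estimates.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    const = const or ModelConstants()
    settings = settings or SamplerSettings()
    grid = np.sort(np.asarray(log10_max_grid, dtype=float))
    seeds = np.random.SeedSequence(seed).generate_state(n_runs * len(grid)) % (2**31)
    rows = []
    for gi, top in enumerate(grid):
        series = default_series(n_points, (top, log10_min), const)
        mean_std = _std_dG_of_fits(truth, series, sigma, replicates, n_runs,
                                   seeds[gi * n_runs:(gi + 1) * n_runs],
                                   settings, const)
        rows.append({"log10_max_conc": top, "mean_std_dG": mean_std})
    return pd.DataFrame(rows)


def noise_scan(truth: dict, sigma_grid, n_points: int = DEFAULT_N_POINTS,
               log10_range: tuple[float, float] = DEFAULT_LOG10_RANGE,
               replicates: int = DEFAULT_REPLICATES, n_runs: int = 3,
               seed: int = 0, settings: SamplerSettings | None = None,
               const: ModelConstants | None = None) -> pd.DataFrame:
    """Mean posterior std of dG as the measurement noise grows."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    const = const or ModelConstants()
    settings = settings or SamplerSettings()
    grid = np.sort(np.asarray(sigma_grid, dtype=float))
    series = default_series(n_points, log10_range, const)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs * len(grid)) % (2**31)
    rows = []
    for gi, sig in enumerate(grid):
        mean_std = _std_dG_of_fits(truth, series, float(sig), replicates, n_runs,
                                   seeds[gi * n_runs:(gi + 1) * n_runs],
                                   settings, const)
        rows.append({"sigma": float(sig), "mean_std_dG": mean_std})
    return pd.DataFrame(rows)
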