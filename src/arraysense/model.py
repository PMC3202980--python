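"""Physical model of a cross-specific receptor (biosensor) array.

A panel of receptors with overlapping specificities reports on a mixture of
ligands through a fluorescent readout.  All ligands compete for the same
binding site on each receptor, so the equilibrium occupancy of receptor *j*
by ligand *i* follows a grand-canonical partition function

    p_ij = w_ij / Z_j,    w_ij = exp((mu_i - dG_ij)/kT),
    Z_j  = 1 + sum_i w_ij,

where ``mu_i = kT * ln(c_i / 1 M)`` is the chemical potential of ligand *i*
and ``dG_ij`` the binding free energy (kcal/mol, favourable < 0).  The
normalized reporter intensity of receptor *j* is background plus
efficacy-weighted occupancy,

    I_j = bg_j + sum_i eff_ij * p_ij,

with efficacy 1 for a full agonist and 0 for a full antagonist (which binds,
displaces agonists, and produces no signal).

Absent ligands are represented by a chemical potential of ``-inf`` so that
exact zeros are representable (weight 0, not a small epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ABSENT",
    "ModelConstants",
    "ArrayParams",
    "MixtureComposition",
    "DilutionSeries",
    "ResponseDataset",
    "single_ligand_intensity",
    "mixture_occupancies",
    "mixture_intensity",
    "chemical_potentials",
    "absolute_concentrations",
]

#: Chemical-potential sentinel for a ligand that is absent (zero concentration).
ABSENT = -np.inf


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConstants:
    """Thermodynamic conventions used throughout.

    Parameters
    ----------
    kT
        Thermal energy in kcal/mol.  The default 0.6 kcal/mol corresponds to
        roughly 302 K, a typical yeast incubation temperature.

    Chemical potentials are defined as ``mu = kT * ln(c)`` with the
    concentration ``c`` in molar units (standard state 1 M).
    """

    kT: float = 0.6

    def __post_init__(self) -> None:
        if not np.isfinite(self.kT) or self.kT <= 0:
            raise ValueError(f"kT must be positive and finite, got {self.kT}")

    def mu_of_concentration(self, conc):
        """Chemical potential (kcal/mol) of a molar concentration; 0 maps to -inf."""
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.kT * np.log(conc)
        return out if out.ndim else float(out)

    def concentration_of_mu(self, mu):
        """Molar concentration for a chemical potential; -inf maps to 0."""
        mu = np.asarray(mu, dtype=float)
        out = np.exp(mu / self.kT)
        return out if out.ndim else float(out)


@dataclass
class ArrayParams:
    """Calibrated physical description of a receptor array.

    ``dG`` and ``eff`` are [receptor x ligand] matrices of binding free
    energies (kcal/mol) and efficacies (dimensionless, in [0, 1]);
    ``bg`` and ``sigma`` are per-receptor background intensities and
    Gaussian noise scales in normalized fluorescence units.
    """

    receptor_ids: list[str]
    ligand_ids: list[str]
    dG: np.ndarray
    eff: np.ndarray
    bg: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.dG = np.atleast_2d(np.asarray(self.dG, dtype=float))
        self.eff = np.atleast_2d(np.asarray(self.eff, dtype=float))
        self.bg = np.atleast_1d(np.asarray(self.bg, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        R, L = len(self.receptor_ids), len(self.ligand_ids)
        if self.dG.shape != (R, L) or self.eff.shape != (R, L):
            raise ValueError(
                f"dG/eff must have shape ({R}, {L}); got {self.dG.shape}, {self.eff.shape}"
            )
        if self.bg.shape != (R,) or self.sigma.shape != (R,):
            raise ValueError(f"bg/sigma must have shape ({R},)")
        if not (np.isfinite(self.dG).all() and np.isfinite(self.eff).all()):
            raise ValueError("dG and eff must be finite")
        if ((self.eff < 0) | (self.eff > 1)).any():
            raise ValueError("efficacies must lie in [0, 1]")
        if (self.bg < 0).any():
            raise ValueError("backgrounds must be >= 0")
        if (self.sigma <= 0).any():
            raise ValueError("noise scales must be > 0")

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_ids)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    def receptor_index(self, receptor_id: str) -> int:
        try:
            return self.receptor_ids.index(receptor_id)
        except ValueError:
            raise KeyError(f"unknown receptor {receptor_id!r}") from None

    def ligand_index(self, ligand_id: str) -> int:
        try:
            return self.ligand_ids.index(ligand_id)
        except ValueError:
            raise KeyError(f"unknown ligand {ligand_id!r}") from None

    def subset(self, receptor_ids: list[str]) -> "ArrayParams":
        """Restrict the array to a subset of receptors (order preserved)."""
        idx = [self.receptor_index(r) for r in receptor_ids]
        return ArrayParams(
            receptor_ids=list(receptor_ids),
            ligand_ids=list(self.ligand_ids),
            dG=self.dG[idx],
            eff=self.eff[idx],
            bg=self.bg[idx],
            sigma=self.sigma[idx],
        )

    def to_dict(self) -> dict:
        return {
            "receptor_ids": list(self.receptor_ids),
            "ligand_ids": list(self.ligand_ids),
            "dG": self.dG.tolist(),
            "eff": self.eff.tolist(),
            "bg": self.bg.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayParams":
        return cls(
            receptor_ids=list(d["receptor_ids"]),
            ligand_ids=list(d["ligand_ids"]),
            dG=np.asarray(d["dG"], dtype=float),
            eff=np.asarray(d["eff"], dtype=float),
            bg=np.asarray(d["bg"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
        )


@dataclass
class MixtureComposition:
    """Relative concentrations of a ligand panel.

    ``x[i]`` is the ratio of ligand *i*'s concentration to that of the
    designated reference ligand, so ``x[reference] == 1`` exactly.  Together
    with a total concentration (equivalently a total chemical potential) the
    ratios determine every absolute concentration.
    """

    ligand_ids: list[str]
    x: np.ndarray
    reference_ligand: str
    total_concentration: float | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        if self.x.shape != (len(self.ligand_ids),):
            raise ValueError("x must have one entry per ligand")
        if (self.x < 0).any() or not np.isfinite(self.x).all():
            raise ValueError("relative concentrations must be finite and >= 0")
        ref = self.reference_index
        if self.x[ref] != 1.0:
            raise ValueError("x[reference_ligand] must equal 1 exactly")
        if self.total_concentration is not None and self.total_concentration <= 0:
            raise ValueError("total_concentration must be positive")

    @property
    def reference_index(self) -> int:
        try:
            return self.ligand_ids.index(self.reference_ligand)
        except ValueError:
            raise KeyError(f"reference ligand {self.reference_ligand!r} not in panel") from None

    @classmethod
    def equal_parts(
        cls,
        ligand_ids: list[str],
        present: list[str] | None = None,
        total_concentration: float | None = None,
    ) -> "MixtureComposition":
        """Equal-proportion mixture of ``present`` ligands (all, if omitted)."""
        present = list(ligand_ids) if present is None else list(present)
        if not present:
            raise ValueError("at least one ligand must be present")
        x = np.array([1.0 if l in present else 0.0 for l in ligand_ids])
        return cls(list(ligand_ids), x, reference_ligand=present[0],
                   total_concentration=total_concentration)

    def rereference(self, new_reference: str) -> "MixtureComposition":
        j = self.ligand_ids.index(new_reference)
        if self.x[j] <= 0:
            raise ValueError(f"cannot re-reference onto absent ligand {new_reference!r}")
        return replace(self, x=self.x / self.x[j], reference_ligand=new_reference)


@dataclass
class DilutionSeries:
    """A known ladder of chemical-potential increments with reference offset mu0.

    Point *m* of the series sits at ``mu_m = mu0 + sum_{k<m} delta_mu[k]``.
    For synthetic and calibration data mu0 (the total chemical potential at
    the reference point) is known; when decoding an unknown mixture only mu0
    needs to be inferred — the increments are set by the pipetted dilutions.
    """

    n_points: int
    delta_mu: np.ndarray
    mu0: float | None = None

    def __post_init__(self) -> None:
        self.delta_mu = np.atleast_1d(np.asarray(self.delta_mu, dtype=float)) \
            if self.n_points > 1 else np.zeros(0)
        if self.delta_mu.shape != (self.n_points - 1,):
            raise ValueError("delta_mu must have length n_points - 1")
        if not np.isfinite(self.delta_mu).all():
            raise ValueError("delta_mu must be finite")

    @classmethod
    def from_log10_concentrations(
        cls, log10_conc: np.ndarray, const: ModelConstants | None = None
    ) -> "DilutionSeries":
        """Series from known total concentrations (log10 molar), reference = point 0."""
        const = const or ModelConstants()
        mu = const.kT * np.log(10.0) * np.asarray(log10_conc, dtype=float)
        return cls(n_points=len(mu), delta_mu=np.diff(mu), mu0=float(mu[0]))

    @property
    def offsets(self) -> np.ndarray:
        """Chemical-potential offsets of every point relative to the reference."""
        return np.concatenate([[0.0], np.cumsum(self.delta_mu)])

    def potentials(self, mu0: float | None = None) -> np.ndarray:
        """Total chemical potential at every series point."""
        if mu0 is None:
            mu0 = self.mu0
        if mu0 is None:
            raise ValueError("mu0 unknown: pass it explicitly")
        return mu0 + self.offsets


#: Column schema of the canonical plate-table CSV.
DATA_COLUMNS = [
    "receptor",
    "mixture_id",
    "point_index",
    "replicate",
    "plate",
    "log10_total_conc",
    "intensity",
]


@dataclass
class ResponseDataset:
    """Normalized fluorescence measurements plus the dilution series per receptor.

    ``df`` holds one row per measurement with columns
    receptor / mixture_id / point_index / replicate / plate /
    log10_total_conc (NaN when the absolute scale is unknown) / intensity.
    """

    df: "object"  # pandas.DataFrame with DATA_COLUMNS
    series: dict[str, DilutionSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.df, pd.DataFrame):
            self.df = pd.DataFrame(self.df, columns=DATA_COLUMNS)
        missing = [c for c in DATA_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.df = self.df[DATA_COLUMNS].reset_index(drop=True)
        bad = ~np.isfinite(self.df["intensity"].to_numpy(dtype=float))
        if bad.any():
            rows = list(np.flatnonzero(bad)[:5])
            raise ValueError(f"non-finite intensity at rows {rows}")
        for r, sub in self.df.groupby("receptor"):
            if r not in self.series:
                raise ValueError(f"no dilution series for receptor {r!r}")
            npts = self.series[r].n_points
            if (sub["point_index"] < 0).any() or (sub["point_index"] >= npts).any():
                raise ValueError(f"point_index out of range for receptor {r!r}")

    @property
    def receptors(self) -> list[str]:
        return sorted(self.df["receptor"].unique())

    def restrict(self, receptors: list[str]) -> "ResponseDataset":
        sub = self.df[self.df["receptor"].isin(receptors)].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no data for receptors {receptors}")
        return ResponseDataset(sub, {r: self.series[r] for r in receptors if r in self.series})

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Response functions
# ---------------------------------------------------------------------------


def single_ligand_intensity(dG, eff, bg, mu, const: ModelConstants | None = None):
    """Normalized reporter intensity for one receptor bound by one ligand.

    ``I = bg + eff * w/(1+w)`` with ``w = exp((mu - dG)/kT)``.  Vectorized
    over ``mu``; a chemical potential of -inf (ligand absent) returns bg.
    """
    const = const or ModelConstants()
    dG, eff, bg = float(dG), float(eff), float(bg)
    if not (np.isfinite(dG) and np.isfinite(eff) and np.isfinite(bg)):
        raise ValueError("dG, eff, bg must be finite")
    if not 0.0 <= eff <= 1.0:
        raise ValueError(f"efficacy must be in [0, 1], got {eff}")
    mu = np.asarray(mu, dtype=float)
    if np.isnan(mu).any() or (mu == np.inf).any():
        raise ValueError("mu must not be NaN or +inf")
    # logistic in (mu - dG)/kT, overflow-safe
    a = (mu - dG) / const.kT
    p = np.empty_like(a)
    pos = a >= 0
    p[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    w = np.exp(a[~pos])
    p[~pos] = w / (1.0 + w)
    out = bg + eff * p
    return out if out.ndim else float(out)


def mixture_occupancies(dG_row, mu, const: ModelConstants | None = None):
    """Competitive-binding occupancies of one receptor by each mixture ligand.

    Returns ``(p, p_unbound)`` with ``p_i = w_i / Z``, ``Z = 1 + sum_i w_i``.
    Ligands at ``mu = -inf`` contribute exactly zero.  The probabilities sum
    to one with the unbound state to machine precision (computed through a
    log-sum-exp of the partition function).
    """
    const = const or ModelConstants()
    dG_row = np.atleast_1d(np.asarray(dG_row, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if dG_row.shape != mu.shape:
        raise ValueError(f"dG_row and mu length mismatch: {dG_row.shape} vs {mu.shape}")
    a = (mu - dG_row) / const.kT  # log Boltzmann weights; -inf for absent ligands
    amax = max(0.0, np.max(a, initial=-np.inf))
    expa = np.exp(a - amax)
    Z = np.exp(-amax) + expa.sum()  # partition function scaled by exp(-amax)
    p = expa / Z
    p_unbound = np.exp(-amax) / Z
    return p, float(p_unbound)


def mixture_intensity(params: ArrayParams, receptor_id: str, mu,
                      const: ModelConstants | None = None) -> float:
    """Reporter intensity of one receptor in a mixture: bg + sum_i eff_i p_i."""
    const = const or ModelConstants()
    j = params.receptor_index(receptor_id)
    p, _ = mixture_occupancies(params.dG[j], mu, const)
    return float(params.bg[j] + params.eff[j] @ p)


def chemical_potentials(comp: MixtureComposition, mu_total: float,
                        const: ModelConstants | None = None) -> np.ndarray:
    """Per-ligand chemical potentials from the total potential and the ratios.

    ``mu_i = mu_total + kT * ln(x_i / sum_k x_k)``; zero-ratio ligands map to
    the -inf sentinel.  The implied concentrations sum back to
    ``exp(mu_total/kT)``.
    """
    const = const or ModelConstants()
    if not np.isfinite(mu_total):
        raise ValueError("mu_total must be finite")
    S = comp.x.sum()
    if S <= 0:
        raise ValueError("all relative concentrations are zero")
    with np.errstate(divide="ignore"):
        return mu_total + const.kT * np.log(comp.x / S)


def absolute_concentrations(comp: MixtureComposition, mu0: float,
                            const: ModelConstants | None = None) -> np.ndarray:
    """Molar concentration of every ligand at the series reference point.

    ``c_i = exp(mu0/kT) * x_i / sum_k x_k``, so the concentrations sum to the
    total ``exp(mu0/kT)``.
    """
    const = const or ModelConstants()
    S = comp.x.sum()
    if S <= 0:
        raise ValueError("all relative concentrations are zero")
    return np.exp(mu0 / const.kT) * comp.x / S
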