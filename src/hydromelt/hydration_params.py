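"""Heterogeneity order parameters and bound-water counts.

From a fitted melting diagram three order parameters quantify how
heterogeneously a protein binds its hydration water:

* ``HeR  = (1 − T_fne)/(1 − T_fno)`` — the fraction of the bound-water
  energy range that is heterogeneous (0 = fully homogeneous, bulk-water
  limit; 1 = no plateau, the intrinsically disordered limit);
* ``HeRn = n_he/(n_he + n_ho)`` — the same question asked about bond
  *counts* instead of energy ranges;
* ``HeM  = (B + 2C)/(1 − T_fne)`` — a slope-like (tangent-like) measure
  not bounded by 1; 0 for an equipotential surface.

``n_ho`` is the first-hydration-shell fraction (the plateau level) and
``n_he`` the heterogeneous-region fraction, read from the
highest-temperature reliable point — a lower bound, because points just
below 0 °C are unreliable.  Fractions are converted to waters per
protein molecule via the solvent-water/protein molarity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, MissingHighTError, UndefinedRatioError
from .md_model import MdFit, PlateauDetection
from .melting_diagram import MeltingDiagram, SampleSpec
from .uncertainty import format_paren
from .units_scales import (
    CELSIUS_OFFSET,
    EnergyCalibration,
    excitation_energy_molar,
)

__all__ = [
    "HydrationParams",
    "heterogeneity_ratio",
    "heterogeneity_ratio_error",
    "first_shell_fraction",
    "heterogeneous_fraction",
    "heterogeneity_ratio_n",
    "heterogeneity_measure",
    "waters_per_molecule",
    "summarize",
]


@dataclass(frozen=True)
class HydrationParams:
    """Full set of heterogeneity parameters for one sample."""

    her: float
    her_n: float
    hem: float
    n_ho_fraction: float
    n_he_fraction: float
    n_ho_count: float
    n_he_count: float
    total_bound_count: float
    waters_per_residue: float
    e_at_tfno: float  # kJ/mol
    e_at_tfne: float  # kJ/mol
    n_he_is_lower_bound: bool = True
    uncertainties: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.her <= 1:
            raise InvalidInputError("HeR must be within [0, 1]")
        if not 0 <= self.her_n <= 1:
            raise InvalidInputError("HeRn must be within [0, 1]")
        if self.hem < 0:
            raise InvalidInputError("HeM must be >= 0")
        if not np.isclose(
            self.total_bound_count, self.n_ho_count + self.n_he_count, rtol=1e-9, atol=1e-9
        ):
            raise InvalidInputError("total_bound_count must equal n_ho_count + n_he_count")

    def to_json_dict(self) -> dict:
        return {
            "her": self.her,
            "her_n": self.her_n,
            "hem": self.hem,
            "n_ho_fraction": self.n_ho_fraction,
            "n_he_fraction": self.n_he_fraction,
            "n_ho_count": self.n_ho_count,
            "n_he_count": self.n_he_count,
            "total_bound_count": self.total_bound_count,
            "waters_per_residue": self.waters_per_residue,
            "e_at_tfno_kj_mol": self.e_at_tfno,
            "e_at_tfne_kj_mol": self.e_at_tfne,
            "n_he_is_lower_bound": self.n_he_is_lower_bound,
            "uncertainties": self.uncertainties,
            "provenance": self.provenance,
        }

    def table_row(self, fit: MdFit, protein_name: str = "") -> str:
        """One table row: T_fno, T_fne, HeR, n_ho, n_he, HeRn, HeM."""
        u = self.uncertainties
        cells = [
            protein_name or "-",
            format_paren(fit.t_fno, u.get("t_fno", 0.0)),
            format_paren(fit.t_fne, u.get("t_fne", 0.0)),
            format_paren(round(self.her, 2), u.get("her", 0.0)),
            format_paren(self.n_ho_count, u.get("n_ho_count", 0.0)),
            ">" + format_paren(self.n_he_count, u.get("n_he_count", 0.0)),
            format_paren(round(self.her_n, 1), u.get("her_n", 0.0)),
            format_paren(self.hem, u.get("hem", 0.0)),
        ]
        return "\t".join(cells)


def heterogeneity_ratio(t_fno: float, t_fne: float) -> float:
    """HeR = (1 − T_fne)/(1 − T_fno), the energy-range order parameter.

    1 − T_fn is the normalized energy distance from the melting point
    of ice.  Returns 1 for a degenerate plateau (IDP limit) and 0 when
    the plateau reaches the bulk melting point.
    """
    if not 0 < t_fno <= t_fne <= 1:
        raise InvalidInputError("require 0 < t_fno <= t_fne <= 1")
    if t_fne == t_fno:
        return 1.0
    if t_fne == 1.0:
        return 0.0
    if t_fno == 1.0:
        raise UndefinedRatioError("t_fno = 1 with t_fne < 1 is undefined")
    return (1.0 - t_fne) / (1.0 - t_fno)


def heterogeneity_ratio_error(
    t_fno: float, t_fne: float, t_fno_err: float, t_fne_err: float
) -> float:
    """First-order propagated uncertainty of HeR."""
    her = heterogeneity_ratio(t_fno, t_fne)
    if her in (0.0, 1.0) and t_fne in (t_fno, 1.0):
        return her * 0.0
    rel = np.hypot(t_fne_err / (1.0 - t_fne), t_fno_err / (1.0 - t_fno))
    return float(her * rel)


def first_shell_fraction(
    md: MeltingDiagram, plateau: PlateauDetection | tuple[float, float]
) -> tuple[float, float]:
    """First-shell mobile fraction n_ho: mean ± s.e.m. over the plateau.

    For a degenerate plateau (no plateau, IDP limit) n_ho is taken at
    the top of the onset step and flagged through a zero-width plateau.
    """
    t_fno, t_fne = plateau.as_tuple() if isinstance(plateau, PlateauDetection) else plateau
    mask = md.reliable_mask()
    t, n = md.t_fn[mask], md.n[mask]
    if t_fne > t_fno:
        sel = (t >= t_fno - 1e-12) & (t <= t_fne + 1e-12)
        vals = n[sel]
        if len(vals) == 0:
            raise InvalidInputError("no points on the stated plateau")
    else:
        above = t >= t_fno - 1e-12
        if not np.any(above):
            raise InvalidInputError("no point above the onset for the degenerate plateau")
        vals = n[above][:1]
    err = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), err


def heterogeneous_fraction(
    md: MeltingDiagram,
    n_ho: float,
    n_ho_err: float = 0.0,
    high_cut: float = 0.97,
) -> tuple[float, float, float]:
    """Heterogeneous-region fraction n_he = n(T_fn ≈ 1) − n_ho.

    Uses the highest reliable point with T_fn above ``high_cut``
    (excluding the −1–0 °C band).  Reported as a lower bound; returns
    ``(n_he, err, t_fn_used)``.
    """
    mask = md.reliable_mask() & (md.t_fn >= high_cut)
    if not np.any(mask):
        raise MissingHighTError(f"no reliable point with t_fn >= {high_cut}")
    idx = np.flatnonzero(mask)[-1]
    point_err = float(md.n_err[idx]) if md.n_err is not None else 0.0
    n_he = float(md.n[idx] - n_ho)
    err = float(np.hypot(point_err, n_ho_err))
    return max(n_he, 0.0), err, float(md.t_fn[idx])


def heterogeneity_ratio_n(n_ho: float, n_he: float) -> float:
    """HeRn = n_he/(n_he + n_ho); unit-invariant (fractions or counts)."""
    if n_ho < 0 or n_he < 0:
        raise InvalidInputError("counts must be >= 0")
    if n_ho == 0 and n_he == 0:
        raise UndefinedRatioError("HeRn undefined for n_ho = n_he = 0")
    return n_he / (n_he + n_ho)


def heterogeneity_measure(B: float, C: float, t_fne: float) -> float:
    """HeM = (B + 2C)/(1 − T_fne), the slope-like heterogeneity measure.

    Not bounded by 1 (tangent-like).  At T_fne = 1 — the homogeneous,
    equipotential-surface limit — returns 0 by convention.
    """
    if t_fne > 1:
        raise InvalidInputError("t_fne must be <= 1")
    if t_fne == 1.0:
        return 0.0
    return (B + 2.0 * C) / (1.0 - t_fne)


def waters_per_molecule(fraction: float, spec: SampleSpec) -> float:
    """Convert a mobile-water fraction into waters per protein molecule.

    fraction × (water molarity / protein molarity); protein molarity is
    concentration/molecular weight.  The water molarity defaults to pure
    water (55.35 mol/L); if ``water_mass_fraction`` is set, the molarity
    is scaled accordingly (crudely correcting for protein volume).
    """
    if fraction < 0:
        raise InvalidInputError("fraction must be >= 0")
    water_molarity = spec.water_molarity
    if spec.water_mass_fraction is not None:
        water_molarity = spec.water_molarity * spec.water_mass_fraction
    return fraction * water_molarity / spec.protein_molarity


def summarize(
    fit: MdFit,
    md: MeltingDiagram,
    spec: SampleSpec,
    cal: EnergyCalibration,
    high_cut: float = 0.97,
) -> HydrationParams:
    """Assemble the full hydration-parameter table for one sample."""
    plateau = (fit.t_fno, fit.t_fne)
    degenerate = fit.t_fne <= fit.t_fno + 1e-12
    her = 1.0 if degenerate else heterogeneity_ratio(fit.t_fno, fit.t_fne)
    t_fno_err = fit.param_errors.get("t_fno", 0.0)
    t_fne_err = fit.param_errors.get("t_fne", 0.0)
    her_err = (
        0.0 if degenerate else heterogeneity_ratio_error(fit.t_fno, fit.t_fne, t_fno_err, t_fne_err)
    )

    n_ho, n_ho_err = first_shell_fraction(md, plateau)
    n_he, n_he_err, t_used = heterogeneous_fraction(md, n_ho, n_ho_err, high_cut=high_cut)
    her_n = heterogeneity_ratio_n(n_ho, n_he) if (n_ho or n_he) else 0.0
    hem = max(heterogeneity_measure(fit.B, fit.C, fit.t_fne), 0.0)

    ratio = spec.water_molarity / spec.protein_molarity
    if spec.water_mass_fraction is not None:
        ratio *= spec.water_mass_fraction
    n_ho_count = waters_per_molecule(n_ho, spec)
    n_he_count = waters_per_molecule(n_he, spec)
    her_n_err = 0.0
    tot = n_ho + n_he
    if tot > 0:
        # d(HeRn)/dn_he = n_ho/tot^2 ; d/dn_ho = -n_he/tot^2
        her_n_err = float(np.hypot(n_ho * n_he_err, n_he * n_ho_err) / tot**2)

    e_tfno = excitation_energy_molar(fit.t_fno * CELSIUS_OFFSET, cal)
    e_tfne = excitation_energy_molar(fit.t_fne * CELSIUS_OFFSET, cal)

    return HydrationParams(
        her=float(np.clip(her, 0.0, 1.0)),
        her_n=float(np.clip(her_n, 0.0, 1.0)),
        hem=hem,
        n_ho_fraction=n_ho,
        n_he_fraction=n_he,
        n_ho_count=n_ho_count,
        n_he_count=n_he_count,
        total_bound_count=n_ho_count + n_he_count,
        waters_per_residue=n_ho_count / spec.residue_count,
        e_at_tfno=e_tfno,
        e_at_tfne=e_tfne,
        n_he_is_lower_bound=True,
        uncertainties={
            "her": her_err,
            "her_n": her_n_err,
            "n_ho_fraction": n_ho_err,
            "n_he_fraction": n_he_err,
            "n_ho_count": n_ho_err * ratio,
            "n_he_count": n_he_err * ratio,
            "t_fno": t_fno_err,
            "t_fne": t_fne_err,
        },
        provenance={
            "sample": spec.protein_name,
            "water_molarity_mol_l": spec.water_molarity,
            "water_mass_fraction": spec.water_mass_fraction,
            "protein_molarity_mol_l": spec.protein_molarity,
            "water_to_protein_molar_ratio": ratio,
            "n_he_read_at_t_fn": t_used,
            "high_cut": high_cut,
            "fit_window": list(fit.fit_window),
            "degenerate_plateau": degenerate,
        },
    )
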