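"""Equilibrium ligand occupancy of a receptor with mixed affinity classes.

Cell-surface EGFR presents two affinity subpopulations for EGF: a small
high-affinity class (Kd ≈ 0.1 nM, ~10% of surface receptors) and a majority
low-affinity class (Kd ≈ 2–6 nM, ~90%). At bulk stimulation the free ligand
concentration is approximated by the total concentration (no depletion), so
the occupied fraction of binding sites is a Kd-weighted sum of Langmuir
isotherms:

    θ(c) = Σ_i f_i · c / (c + Kd_i)

with c in nM, converted from the ng/mL concentrations used in cell culture
via the ligand's molar mass (mature human EGF: 6045 Da).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EGF_MW_DA", "BindingModel", "ngml_to_nM", "occupancy", "two_site_egf_model"]

EGF_MW_DA = 6045.0  # mature human EGF, g/mol


def ngml_to_nM(conc_ngml: float, mw_da: float = EGF_MW_DA) -> float:
    """Convert a mass concentration (ng/mL) to molarity (nM).

    1 ng/mL = 1 μg/L, and dividing by the molar mass (g/mol) gives μmol/m³
    = nmol/L, so the conversion is ``conc · 1000 / MW`` (e.g. 200 ng/mL of
    6045 Da EGF ≈ 33 nM).
    """
    if mw_da <= 0:
        raise ValueError("molar mass must be positive")
    if conc_ngml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ngml * 1e3 / mw_da


@dataclass(frozen=True)
class BindingModel:
    """Mixture of independent binding-site classes.

    ``components`` is a list of ``(site_fraction, Kd_nM)`` pairs whose
    fractions sum to one.
    """

    components: tuple
    ligand_MW: float = EGF_MW_DA

    def __post_init__(self):
        comps = tuple((float(f), float(kd)) for f, kd in self.components)
        object.__setattr__(self, "components", comps)
        fracs = np.array([f for f, _ in comps])
        kds = np.array([kd for _, kd in comps])
        if not np.isclose(fracs.sum(), 1.0):
            raise ValueError(f"site fractions must sum to 1, got {fracs.sum()}")
        if np.any(fracs < 0) or np.any(kds <= 0):
            raise ValueError("fractions must be ≥0 and Kd values positive")
        if self.ligand_MW <= 0:
            raise ValueError("ligand molar mass must be positive")


def two_site_egf_model(kd_high: float = 0.1, kd_low: float = 2.0, frac_high: float = 0.1) -> BindingModel:
    """The standard two-class EGF/EGFR model (high-affinity minority)."""
    return BindingModel(components=((frac_high, kd_high), (1.0 - frac_high, kd_low)))


def occupancy(model: BindingModel, conc_ngml: float) -> float:
    """Equilibrium fraction of binding sites occupied at ``conc_ngml`` ng/mL.

    Uses the free-ligand ≈ total-ligand approximation; strictly increasing
    in concentration, 0 at zero ligand and → 1 at saturation.
    """
    c = ngml_to_nM(conc_ngml, model.ligand_MW)
    return float(sum(f * c / (c + kd) for f, kd in model.components))
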