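"""Model parameters for the lattice simulation of receptor nanodomain dynamics.

All lengths are in micrometres, times in seconds, energies in units of
k_B·T, and rates in s⁻¹. The timestep is never stored: it is always derived
from the lattice spacing and diffusivity via ``dt = dx**2 / (4 * D)``, the
standard relation for a two-dimensional nearest-neighbour random walk.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass

import yaml

__all__ = ["SimParams", "compute_timestep", "default_params", "load_params"]


def compute_timestep(dx: float, D: float) -> float:
    """Timestep of the lattice walk, ``dx**2 / (4 * D)``.

    Parameters
    ----------
    dx : float
        Lattice spacing (μm).
    D : float
        Diffusivity (μm²/s).

    Returns
    -------
    float
        Timestep in seconds such that a walker stepping to one of the four
        nearest neighbours each timestep has diffusivity ``D``.
    """
    if dx <= 0 or D <= 0:
        raise ValueError(f"dx and D must be positive, got dx={dx}, D={D}")
    return dx * dx / (4.0 * D)


@dataclass(frozen=True)
class SimParams:
    """Physical and model constants of the nanodomain lattice simulation.

    Defaults are the published operating point of the model: a 0.2 μm
    periodic membrane patch carrying 10 tetraspanin and 10 clathrin discs of
    radius 5.6 nm, with entry/exit barriers (in k_B·T) that confine
    unliganded receptors to tetraspanin domains and liganded receptors to
    clathrin domains.

    Attributes
    ----------
    D : float
        Receptor diffusivity (μm²/s).
    dx : float
        Lattice spacing (μm).
    L : float
        Membrane edge length (μm); periodic boundary conditions.
    n_tet, n_cla : int
        Number of tetraspanin and clathrin domains.
    r_dom : float
        Domain radius (μm), shared by both domain types.
    E_entry_tet, E_exit_tet : float
        Barriers for an *unliganded* receptor entering / leaving a
        tetraspanin domain (k_B·T).
    E_entry_cla, E_exit_cla : float
        Barriers for a *liganded* receptor entering / leaving a clathrin
        domain (k_B·T). All other compartment transitions are barrier-free.
    k_bind : float
        Ligand binding rate while inside a tetraspanin domain (s⁻¹). This is
        the quantity swept to emulate increasing ligand concentration.
    k_remove : float
        Removal (internalisation) rate while liganded inside a clathrin
        domain (s⁻¹).
    T_max : float
        Censoring horizon (s): a trajectory not removed by ``T_max`` is
        truncated and flagged censored.
    seed : int or None
        Root RNG seed used by convenience drivers when no rng is passed.
    """

    D: float = 0.2
    dx: float = 0.002
    L: float = 0.2
    n_tet: int = 10
    n_cla: int = 10
    r_dom: float = 0.0056
    E_entry_tet: float = 11.5
    E_exit_tet: float = 13.0
    E_entry_cla: float = 1.0
    E_exit_cla: float = 4.5
    k_bind: float = 0.0
    k_remove: float = 0.05
    T_max: float = 1000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.D <= 0 or self.L <= 0:
            raise ValueError("dx, D and L must be positive")
        n_side = self.L / self.dx
        if abs(n_side - round(n_side)) > 1e-9 or round(n_side) < 1:
            raise ValueError(f"L/dx must be a positive integer, got {n_side}")
        if self.n_tet < 0 or self.n_cla < 0:
            raise ValueError("domain counts must be non-negative")
        if self.r_dom <= 0:
            raise ValueError("r_dom must be positive")
        for name in ("E_entry_tet", "E_exit_tet", "E_entry_cla", "E_exit_cla"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_bind < 0 or self.k_remove < 0:
            raise ValueError("rates must be non-negative")
        dt = self.dt
        if self.k_bind * dt >= 1 or self.k_remove * dt >= 1:
            raise ValueError("rate * dt must be < 1 for the per-step Bernoulli scheme")
        if self.T_max <= 0:
            raise ValueError("T_max must be positive")

    @property
    def dt(self) -> float:
        """Timestep (s), always recomputed as ``dx²/(4D)``."""
        return compute_timestep(self.dx, self.D)

    @property
    def n_side(self) -> int:
        """Lattice side length in sites."""
        return round(self.L / self.dx)

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dt"] = self.dt
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        dt = d.pop("dt", None)
        p = cls(**d)
        if dt is not None and abs(dt - p.dt) > 1e-12 * p.dt:
            raise ValueError(f"stored dt={dt} inconsistent with dx²/(4D)={p.dt}")
        return p


def default_params(**overrides) -> SimParams:
    """Published default parameters, optionally with fields overridden."""
    ref = importlib.resources.files("nanodomain.data") / "defaults.yaml"
    d = yaml.safe_load(ref.read_text())
    d.update(overrides)
    return SimParams.from_dict(d)


def load_params(path) -> SimParams:
    """Load :class:`SimParams` from a YAML file."""
    with open(path) as fh:
        return SimParams.from_dict(yaml.safe_load(fh))
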