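"""Model parameters and unit conventions.

The simulation works throughout in (pN, um, s).  In these units 1 Pa.s of
viscosity equals 1 pN.s/um^2, and 1 pN/um^2 of stress equals 1 Pa, so
viscosities are accepted in Pa.s and converted only at this boundary.
Concentrations are expressed in uM; 1 uM corresponds to
``AVOGADRO_UM3`` = 602.214 molecules per um^3.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Optional

#: molecules per um^3 at a concentration of 1 uM
AVOGADRO_UM3 = 602.214

#: thermal energy at ~298 K in pN.um
KBT_ROOM = 4.11e-3


class ParameterError(ValueError):
    """Raised when a model parameter is missing, unknown or invalid."""


def bead_drag_coefficient(eta_fluid: float, l0: float, d: float) -> float:
    """Drag coefficient of one bead, i.e. one cylindrical filament segment.

    Uses the orientation-averaged cylinder friction
    ``zeta_b = 4 pi eta l0 / [ln(l0/d) + 0.84]``.

    Parameters
    ----------
    eta_fluid : viscosity of the cytoplasm in Pa.s
    l0 : segment (cylinder) length in um
    d : filament diameter in um

    Returns
    -------
    float
        Drag coefficient in pN.s/um.
    """
    if eta_fluid <= 0 or l0 <= 0 or d <= 0:
        raise ParameterError("eta_fluid, l0 and d must all be positive")
    if l0 <= d:
        raise ParameterError("segment length must exceed the filament diameter")
    # 1 Pa.s == 1 pN.s/um^2, so eta carries straight over
    return 4.0 * math.pi * eta_fluid * l0 / (math.log(l0 / d) + 0.84)


def monomer_count_to_micromolar(n_monomers: float, volume: float) -> float:
    """Convert a monomer count in a volume (um^3) to a concentration in uM."""
    if volume <= 0:
        raise ParameterError("volume must be positive")
    return n_monomers / (AVOGADRO_UM3 * volume)


def micromolar_to_monomer_count(conc: float, volume: float) -> float:
    """Inverse of :func:`monomer_count_to_micromolar`."""
    if volume <= 0:
        raise ParameterError("volume must be positive")
    return conc * AVOGADRO_UM3 * volume


def dynamic_crosslink_cap(c_dynamic: float, box_width: float,
                          box_height: float, depth: float = 9.5) -> int:
    """Maximum number of dynamic crosslinks in the simulation.

    The cap is the number of crosslinker molecules at concentration
    ``c_dynamic`` (uM) contained in the slab of the simulation box that
    extends ``depth`` um back from the leading edge (y in [0, depth]),
    rounded to the nearest integer.
    """
    if c_dynamic < 0:
        raise ParameterError("c_dynamic must be nonnegative")
    return int(round(c_dynamic * AVOGADRO_UM3 * box_width * depth * box_height))


@dataclass
class Parameters:
    """Reference parameter set for the lamellipodium model.

    Defaults reproduce the reference simulation conditions; all values are
    in (pN, um, s) except ``eta_fluid`` which is in Pa.s.
    """

    # integration
    dt: float = 1e-5                 # time step [s]

    # actin filament mechanics
    k_actin: float = 1000.0          # bond spring constant [pN/um]
    l0: float = 0.1                  # segment rest length [um]
    l_p: float = 17.0                # persistence length [um]
    kBT: float = KBT_ROOM            # thermal energy [pN.um]

    # crosslinkers
    k_crosslink: float = 100.0       # crosslink spring constant [pN/um]
    l0_crosslink: float = 0.035      # crosslink rest length [um]
    c_dynamic: float = 1.0           # dynamic crosslinker concentration [uM]
    k_dynamic_off: float = 1.0       # dynamic crosslink decay rate [1/s]
    crosslink_refresh_interval: float = 0.025   # dynamic link cadence [s]
    crosslink_window: tuple = (0.03, 0.04)      # pair-distance window [um]
    max_permanent_per_filament: int = 5
    longlived_lifetime: Optional[float] = None  # mean lifetime of "permanent" links [s]

    # excluded volume
    k_excluded: float = 1690.0       # repulsion constant [pN/um]
    d_excluded: float = 0.007        # filament diameter / cutoff [um]

    # drag
    eta_fluid: float = 0.3           # cytoplasm viscosity [Pa.s]

    # focal adhesion
    kappa_FA: float = 1.0            # adhesion/fluid viscosity ratio
    k_FA_bind: float = 10.0          # binding rate [1/s]
    k_FA_unbind: float = 1.0         # unbinding rate [1/s]
    fa_width: float = 0.25           # capsule width [um]
    fa_length: float = 1.25          # capsule total length [um]
    fa_height: float = 0.1           # capsule height above z=0 [um]
    fa_front_y: float = 1.0          # y where the capsule starts [um]

    # turnover
    tau_age: float = 125.0           # minimum actin bond lifetime [s]
    r_age: float = 0.2               # post-minimum decay rate [1/s]
    filament_add_rate: float = 23.4  # filaments/s
    filament_length: float = 1.0     # [um]
    beads_per_filament: int = 11
    monomers_per_segment: int = 37

    # external forces
    F_push_total: float = 1.5        # pushing force per filament [pN]
    F_pull_uniform: float = 0.002    # per-bead uniform pull [pN]
    F_pull_back: float = 0.004       # per-bead back pull [pN]
    F_pull_membrane: float = 0.02    # per-bead membrane pull [pN]
    pull_mode: str = "uniform"       # uniform | back | membrane
    y_back_threshold: float = 3.25   # back-pull onset [um]
    membrane_z: float = 0.02         # membrane pull layer thickness [um]

    # branching
    eps_angle: float = 1.0           # branch angular stiffness [pN.um]
    theta_0: float = 70.0            # branch angle [degrees]
    branch_window: tuple = (0.20, 0.25)  # mother-bead y window [um]

    # geometry / confinement
    box_width: float = 2.0           # periodic x width [um]
    box_height: float = 0.2          # z extent [um]
    confine_force: float = 1.0       # restoring force at z walls [pN]
    top_wall: bool = True

    # derived, filled in __post_init__
    zeta_b: float = field(default=0.0)

    def __post_init__(self):
        if self.zeta_b == 0.0:
            self.zeta_b = bead_drag_coefficient(self.eta_fluid, self.l0,
                                                self.d_excluded)
        self.validate()

    def validate(self) -> None:
        positive = ["dt", "k_actin", "l0", "l_p", "k_crosslink",
                    "l0_crosslink", "k_excluded", "d_excluded", "eta_fluid",
                    "zeta_b", "box_width", "box_height", "filament_length"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        # kBT = 0 is allowed: athermal relaxation runs
        nonneg = ["kBT", "kappa_FA", "k_FA_bind", "k_FA_unbind", "c_dynamic",
                  "k_dynamic_off", "tau_age", "r_age", "filament_add_rate",
                  "F_push_total", "F_pull_uniform", "F_pull_back",
                  "F_pull_membrane", "confine_force", "eps_angle"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.kappa_FA < 1:
            raise ParameterError("kappa_FA must be >= 1")
        if not (0.0 < self.theta_0 < 180.0):
            raise ParameterError("theta_0 must be in (0, 180) degrees")
        if self.pull_mode not in ("uniform", "back", "membrane"):
            raise ParameterError(f"unknown pull_mode {self.pull_mode!r}")
        if self.beads_per_filament < 2:
            raise ParameterError("beads_per_filament must be >= 2")
        if self.longlived_lifetime is not None and self.longlived_lifetime <= 0:
            raise ParameterError("longlived_lifetime must be positive or None")

    # -- derived quantities ------------------------------------------------
    @property
    def kappa_bend(self) -> float:
        """Flexural rigidity kappa = kBT * l_p [pN.um^2]."""
        return self.kBT * self.l_p

    @property
    def n_dynamic_total(self) -> int:
        """Cap on the number of dynamic crosslinks (from ``c_dynamic``)."""
        return dynamic_crosslink_cap(self.c_dynamic, self.box_width,
                                     self.box_height)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crosslink_window"] = list(self.crosslink_window)
        d["branch_window"] = list(self.branch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter(s): {', '.join(sorted(unknown))}")
        d = dict(d)
        for key in ("crosslink_window", "branch_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def replace(self, **kwargs) -> "Parameters":
        d = self.to_dict()
        d.update(kwargs)
        if "zeta_b" not in kwargs and any(
                k in kwargs for k in ("eta_fluid", "l0", "d_excluded")):
            d["zeta_b"] = 0.0   # force recomputation
        return Parameters.from_dict(d)
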