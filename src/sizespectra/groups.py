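"""Functional-group traits and size-based feeding closures.

Four dynamic groups are modelled: zooplankton, low-activity cephalopods,
high-activity cephalopods and fish, feeding on each other and on a static
phytoplankton spectrum.  Feeding is size-based through a lognormal selection
kernel centred at the preferred predator-prey mass ratio (PPMR).  The PPMR is
either constant with predator mass (the conventional assumption, used for
fish, zooplankton and high-activity cephalopods) or follows a power law of
predator mass (low-activity cephalopods, whose preferred prey stays small as
they grow, so PPMR rises steeply with body size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

GROUP_NAMES = ("zooplankton", "ceph_low_activity", "ceph_high_activity", "fish")
PHYTO = "phytoplankton"

CONSTANT = "constant"
ALLOMETRIC = "allometric"


@dataclass
class SenescenceParams:
    """Background mortality acting above an onset size w_s.

    mu_O(w) = 0 for w < w_s, k_s * (w / w_s)^p_s for w >= w_s
    (value k_s at the onset, i.e. continuous from above).
    """
    w_s: float          # onset mass, g
    k_s: float = 0.1    # rate at onset, 1/yr
    p_s: float = 0.3    # allometric exponent


@dataclass
class FunctionalGroupParams:
    """All trait parameters for one dynamic functional group."""

    name: str
    w_min: float                    # g
    w_mat: float                    # g
    w_max: float                    # g
    ppmr_model: str = CONSTANT      # "constant" | "allometric"
    beta0: float = 100.0            # PPMR (constant), or PPMR at w_min (allometric)
    ppmr_exponent: float = 0.0      # power of (w / w_min); 0 for constant model
    sigma: float = 1.0              # kernel width, ln prey-mass units
    search_coefficient: float = 5000.0   # y_i, m^3 yr^-1 g^-alpha
    search_exponent: float = 0.8         # alpha_i
    net_growth_efficiency: float = 0.2   # K_i in (0, 1)
    interaction: dict = field(default_factory=dict)  # prey name -> theta in [0,1]
    senescence: SenescenceParams | None = None
    recruitment_scalar: float = 1.0      # multiplies the boundary abundance

    def __post_init__(self):
        if not (self.w_min < self.w_mat < self.w_max):
            raise ValueError(
                f"{self.name}: require w_min < w_mat < w_max, got "
                f"({self.w_min}, {self.w_mat}, {self.w_max})")
        if not 0.0 < self.net_growth_efficiency < 1.0:
            raise ValueError(f"{self.name}: net growth efficiency must be in (0,1)")
        if self.beta0 <= 0 or self.sigma <= 0:
            raise ValueError(f"{self.name}: beta0 and sigma must be positive")
        if self.ppmr_model == CONSTANT and self.ppmr_exponent != 0.0:
            raise ValueError(f"{self.name}: constant PPMR model requires exponent 0")
        if self.ppmr_model not in (CONSTANT, ALLOMETRIC):
            raise ValueError(f"{self.name}: unknown ppmr_model {self.ppmr_model!r}")
        if self.senescence is None:
            self.senescence = SenescenceParams(w_s=self.w_mat)

    def theta(self, prey: str) -> float:
        """Interaction coefficient with a prey group (default 1)."""
        return self.interaction.get(prey, 1.0)

    def copy(self, **kw) -> "FunctionalGroupParams":
        kw.setdefault("interaction", dict(self.interaction))
        return replace(self, **kw)


@dataclass
class PhytoSpectrum:
    """Static phytoplankton abundance size spectrum, the model's energy input.

    Density is a power law N_P(w) = a_P * w^b_P (ind m^-3 g^-1) on a log10
    mass range, optionally replaced by a tabulated (e.g. noisy) spectrum.
    """

    log10_range: tuple = (-13.0, -5.0)
    intercept: float = 1e-3     # a_P at the 1 g reference mass
    slope: float = -2.0         # b_P, dimensionless (negative)
    table: tuple | None = None  # (log10 mass centers, densities) overriding the power law

    def density(self, w) -> np.ndarray:
        """Abundance density (ind m^-3 g^-1) at mass w (g); zero outside range."""
        w = np.asarray(w, dtype=float)
        x = np.log10(w)
        if self.table is not None:
            xs, ds = self.table
            out = np.interp(x, xs, ds, left=0.0, right=0.0)
        else:
            out = self.intercept * w ** self.slope
        lo, hi = self.log10_range
        out = np.where((x >= lo) & (x <= hi), out, 0.0)
        return np.maximum(out, 0.0)


def allometric_ppmr_exponent(beta_min: float, beta_max: float,
                             w_min: float, w_max: float) -> float:
    """Exponent of beta(w) = beta_min * (w/w_min)^gamma hitting beta_max at w_max."""
    return math.log(beta_max / beta_min) / math.log(w_max / w_min)


def ppmr_at_mass(group: FunctionalGroupParams, w, check: bool = True):
    """Preferred predator-prey mass ratio of `group` at predator mass w (g).

    Constant model: beta0 for all w.  Allometric model:
    beta(w) = beta0 * (w / w_min)^ppmr_exponent, anchored at the group's
    minimum size.
    """
    w = np.asarray(w, dtype=float)
    if check and (np.any(w < group.w_min * (1 - 1e-9)) or
                  np.any(w > group.w_max * (1 + 1e-9))):
        raise ValueError(
            f"mass outside {group.name} size range "
            f"[{group.w_min}, {group.w_max}]")
    if group.ppmr_model == CONSTANT:
        out = np.full_like(w, group.beta0)
    else:
        out = group.beta0 * (w / group.w_min) ** group.ppmr_exponent
    return out if out.ndim else float(out)


def feeding_kernel(group: FunctionalGroupParams, w_pred, w_prey):
    """Lognormal size-selection preference phi_i(w, w') in [0, 1].

    phi = exp(-[ln(w_pred / (beta(w_pred) * w_prey))]^2 / (2 sigma^2)),
    maximal (=1) when the prey sits exactly at the preferred PPMR.
    """
    w_pred = np.asarray(w_pred, dtype=float)
    w_prey = np.asarray(w_prey, dtype=float)
    beta = ppmr_at_mass(group, w_pred, check=False)
    z = np.log(w_pred / (beta * w_prey))
    out = np.exp(-z * z / (2.0 * group.sigma ** 2))
    return out if out.ndim else float(out)


def search_rate(group: FunctionalGroupParams, w):
    """Volume searched per unit time, V_i(w) = y_i * w^alpha_i (m^3 yr^-1)."""
    w = np.asarray(w, dtype=float)
    out = group.search_coefficient * w ** group.search_exponent
    return out if out.ndim else float(out)


def senescence_mortality(group: FunctionalGroupParams, w):
    """Size-dependent background mortality (1/yr); zero below onset w_s."""
    w = np.asarray(w, dtype=float)
    s = group.senescence
    out = np.where(w >= s.w_s, s.k_s * (w / s.w_s) ** s.p_s, 0.0)
    return out if out.ndim else float(out)
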