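"""Model configurations and the control / trait-resolved experiment sets.

A `ModelConfig` fully specifies one run: the four dynamic functional groups,
the static phytoplankton spectrum, the grid, and the integration settings.
The experiment juxtaposes a *control* set, in which both cephalopod groups
are parameterized identically to fish apart from their size ranges, with a
*feeding + growth* (F+G) set in which cephalopods carry distinct feeding
(PPMR, kernel width) and growth-efficiency traits.  Recruitment sensitivity
is probed by scaling the cephalopod boundary abundances with p_LA/HA, giving
3 control configs and a 3 x 3 x 3 = 27-point factorial for the F+G set.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

from .grid import SizeGrid, build_size_grid
from .groups import (
    ALLOMETRIC,
    CONSTANT,
    GROUP_NAMES,
    FunctionalGroupParams,
    PhytoSpectrum,
    SenescenceParams,
    allometric_ppmr_exponent,
)

ZOO, CEPH_LA, CEPH_HA, FISH = GROUP_NAMES

#: Recruitment-scalar sweep levels p_LA/HA (multiplies the cephalopod
#: boundary abundance, itself half the local zooplankton abundance).
P_LEVELS = (0.5, 1.0, 2.0)
#: High-activity cephalopod PPMR sweep levels (centre value 25).
HA_PPMR_LEVELS = (12.5, 25.0, 50.0)
#: Low-activity PPMR-curve scaling levels (multiply beta0, exponent kept).
LA_SCALE_LEVELS = (0.5, 1.0, 2.0)

#: Net growth efficiencies of the trait-resolved (F+G) parameterization.
FG_EFFICIENCY = {ZOO: 0.2, CEPH_LA: 0.4, CEPH_HA: 0.3, FISH: 0.2}

#: Printed anchors of the size-varying low-activity PPMR curve.
LA_PPMR_AT_WMIN = 1.0e4
LA_PPMR_AT_WMAX = 3.0e6


@dataclass
class ModelConfig:
    """One fully specified simulation run."""

    groups: dict                       # canonical name -> FunctionalGroupParams
    phyto: PhytoSpectrum
    grid_lo: float = -13.0             # log10 g
    grid_hi: float = 5.0
    bin_width: float = 0.1
    years: int = 1000
    dt: float = 1.0 / 52.0             # yr; weekly by default
    averaging_years: int = 500
    label: str = "run"
    sweep_coords: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [n for n in GROUP_NAMES if n not in self.groups]
        extra = [n for n in self.groups if n not in GROUP_NAMES]
        if missing or extra:
            raise ValueError(
                f"config must contain exactly the four dynamic groups "
                f"{GROUP_NAMES}; missing={missing}, unexpected={extra}")
        if self.averaging_years > self.years:
            raise ValueError("averaging_years cannot exceed years")

    def build_grid(self) -> SizeGrid:
        ranges = {n: (math.log10(g.w_min), math.log10(g.w_max))
                  for n, g in self.groups.items()}
        return build_size_grid(self.grid_lo, self.grid_hi, self.bin_width, ranges)

    def copy(self, **kw) -> "ModelConfig":
        new = copy.deepcopy(self)
        for k, v in kw.items():
            setattr(new, k, v)
        new.__post_init__()    # re-validate the modified configuration
        return new

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "grid": {"lo": self.grid_lo, "hi": self.grid_hi,
                     "bin_width": self.bin_width},
            "run": {"years": self.years, "dt": self.dt,
                    "averaging_years": self.averaging_years,
                    "label": self.label},
            "phyto": {"log10_range": list(self.phyto.log10_range),
                      "intercept": self.phyto.intercept,
                      "slope": self.phyto.slope},
            "groups": {n: asdict(g) for n, g in self.groups.items()},
            "sweep_coords": dict(self.sweep_coords),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        groups = {}
        for n, g in d["groups"].items():
            g = dict(g)
            sen = g.pop("senescence", None)
            groups[n] = FunctionalGroupParams(
                **g, senescence=SenescenceParams(**sen) if sen else None)
        ph = d.get("phyto", {})
        phyto = PhytoSpectrum(
            log10_range=tuple(ph.get("log10_range", (-13.0, -5.0))),
            intercept=ph.get("intercept", 1e-3), slope=ph.get("slope", -2.0))
        grid = d.get("grid", {})
        run = d.get("run", {})
        return cls(groups=groups, phyto=phyto,
                   grid_lo=grid.get("lo", -13.0), grid_hi=grid.get("hi", 5.0),
                   bin_width=grid.get("bin_width", 0.1),
                   years=run.get("years", 1000), dt=run.get("dt", 1 / 52),
                   averaging_years=run.get("averaging_years", 500),
                   label=run.get("label", "run"),
                   sweep_coords=dict(d.get("sweep_coords", {})))

    def content_hash(self) -> str:
        """Hash of the resolved configuration; changes iff a parameter does."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentSet:
    """A named collection of runs (control, feeding_only, feeding_growth)."""

    name: str
    configs: list

    def __post_init__(self):
        expected = {"control": 3, "feeding_only": 27, "feeding_growth": 27}
        if self.name in expected and len(self.configs) != expected[self.name]:
            raise ValueError(
                f"{self.name} set must contain {expected[self.name]} configs, "
                f"got {len(self.configs)}")
        if self.configs:
            ref = self.configs[0]
            for c in self.configs[1:]:
                same_grid = (c.grid_lo == ref.grid_lo and c.grid_hi == ref.grid_hi
                             and c.bin_width == ref.bin_width)
                same_phyto = (c.phyto.log10_range == ref.phyto.log10_range
                              and c.phyto.intercept == ref.phyto.intercept
                              and c.phyto.slope == ref.phyto.slope)
                if not (same_grid and same_phyto):
                    raise ValueError(
                        f"all configs in set {self.name} must share the grid "
                        "and phytoplankton input")


# ---------------------------------------------------------------------------
# default parameterization


def default_groups() -> dict:
    """Trait-resolved (F+G, centre point) parameterization of the four groups.

    Size ranges (log10 g): zooplankton [-7, -1], both cephalopod groups
    [-2, 4], fish [-3, 5].  Search rate V = y w^0.8 with a common
    coefficient; kernel widths 1.0 for the narrow-diet groups (fish,
    high-activity cephalopods) and 1.5 for the broad-diet ones (zooplankton,
    low-activity cephalopods).  The low-activity PPMR rises as a power law
    of body mass from 1e4 at the minimum size to 3e6 at the maximum.
    """
    y, alpha = 1000.0, 0.8
    la_exp = allometric_ppmr_exponent(LA_PPMR_AT_WMIN, LA_PPMR_AT_WMAX,
                                      1e-2, 1e4)
    return {
        ZOO: FunctionalGroupParams(
            name=ZOO, w_min=1e-7, w_mat=1e-4, w_max=1e-1,
            ppmr_model=CONSTANT, beta0=1000.0, sigma=1.5,
            search_coefficient=400.0, search_exponent=alpha,
            net_growth_efficiency=0.2,
            senescence=SenescenceParams(w_s=1e-7, k_s=2.0, p_s=0.0),
            recruitment_scalar=1.0),
        CEPH_LA: FunctionalGroupParams(
            name=CEPH_LA, w_min=1e-2, w_mat=1e1, w_max=1e4,
            ppmr_model=ALLOMETRIC, beta0=LA_PPMR_AT_WMIN, ppmr_exponent=la_exp,
            sigma=1.5, search_coefficient=y, search_exponent=alpha,
            net_growth_efficiency=0.4,
            senescence=SenescenceParams(w_s=1e-2, k_s=0.5, p_s=0.0),
            recruitment_scalar=0.5),
        CEPH_HA: FunctionalGroupParams(
            name=CEPH_HA, w_min=1e-2, w_mat=1e1, w_max=1e4,
            ppmr_model=CONSTANT, beta0=25.0, sigma=1.0,
            search_coefficient=y, search_exponent=alpha,
            net_growth_efficiency=0.3,
            senescence=SenescenceParams(w_s=1e-2, k_s=0.5, p_s=0.0),
            recruitment_scalar=0.5),
        FISH: FunctionalGroupParams(
            name=FISH, w_min=1e-3, w_mat=1e2, w_max=1e5,
            ppmr_model=CONSTANT, beta0=100.0, sigma=1.0,
            search_coefficient=y, search_exponent=alpha,
            net_growth_efficiency=0.2,
            senescence=SenescenceParams(w_s=1e-3, k_s=0.3, p_s=0.0),
            recruitment_scalar=1.0),
    }


def default_config(**kw) -> ModelConfig:
    """The centre F+G configuration with default grid and phytoplankton."""
    cfg = ModelConfig(groups=default_groups(), phyto=PhytoSpectrum(),
                      label="fg_centre",
                      sweep_coords={"p": 1.0, "ha_ppmr": 25.0, "la_scale": 1.0})
    return cfg.copy(**kw) if kw else cfg


# ---------------------------------------------------------------------------
# experiment sets


def _fish_like(ceph: FunctionalGroupParams,
               fish: FunctionalGroupParams) -> FunctionalGroupParams:
    """Cephalopod group re-parameterized as fish, keeping only its sizes."""
    return ceph.copy(
        ppmr_model=fish.ppmr_model, beta0=fish.beta0,
        ppmr_exponent=fish.ppmr_exponent, sigma=fish.sigma,
        search_coefficient=fish.search_coefficient,
        search_exponent=fish.search_exponent,
        net_growth_efficiency=fish.net_growth_efficiency,
        senescence=SenescenceParams(w_s=ceph.senescence.w_s,
                                    k_s=fish.senescence.k_s,
                                    p_s=fish.senescence.p_s))


def _with_p(cfg: ModelConfig, p: float) -> ModelConfig:
    new = cfg.copy()
    for n in (CEPH_LA, CEPH_HA):
        new.groups[n] = new.groups[n].copy(recruitment_scalar=0.5 * p)
    new.sweep_coords = dict(new.sweep_coords, p=p)
    return new


def build_control_set(base: ModelConfig, p_levels=P_LEVELS) -> ExperimentSet:
    """Three control configs: cephalopods as fish, sweeping only p_LA/HA."""
    fish = base.groups[FISH]
    ctl = base.copy(label="control")
    for n in (CEPH_LA, CEPH_HA):
        ctl.groups[n] = _fish_like(ctl.groups[n], fish)
    configs = []
    for p in p_levels:
        c = _with_p(ctl, p)
        c.label = f"control_p{p:g}"
        c.sweep_coords = {"p": p}
        configs.append(c)
    return ExperimentSet(name="control", configs=configs)


def _factorial(base: ModelConfig, efficiencies: dict, set_name: str,
               p_levels, ha_levels, la_levels) -> ExperimentSet:
    configs = []
    for p in p_levels:
        for bha in ha_levels:
            for sla in la_levels:
                c = _with_p(base, p)
                c.groups[CEPH_HA] = c.groups[CEPH_HA].copy(beta0=bha)
                la = c.groups[CEPH_LA]
                c.groups[CEPH_LA] = la.copy(beta0=sla * base.groups[CEPH_LA].beta0)
                for n, K in efficiencies.items():
                    c.groups[n] = c.groups[n].copy(net_growth_efficiency=K)
                c.sweep_coords = {"p": p, "ha_ppmr": bha, "la_scale": sla}
                c.label = f"{set_name}_p{p:g}_bha{bha:g}_sla{sla:g}"
                configs.append(c)
    return ExperimentSet(name=set_name, configs=configs)


def build_fg_set(base: ModelConfig, p_levels=P_LEVELS,
                 ha_levels=HA_PPMR_LEVELS, la_levels=LA_SCALE_LEVELS
                 ) -> ExperimentSet:
    """The 27-config feeding + growth factorial (p x HA-PPMR x LA-scaling)."""
    return _factorial(base, FG_EFFICIENCY, "feeding_growth",
                      p_levels, ha_levels, la_levels)


def build_feeding_only_set(base: ModelConfig, p_levels=P_LEVELS,
                           ha_levels=HA_PPMR_LEVELS, la_levels=LA_SCALE_LEVELS
                           ) -> ExperimentSet:
    """Same factorial as F+G but growth efficiency reset to the fish value."""
    K = {n: FG_EFFICIENCY[FISH] for n in GROUP_NAMES}
    return _factorial(base, K, "feeding_only",
                      p_levels, ha_levels, la_levels)
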