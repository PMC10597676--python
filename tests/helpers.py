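"""Shared oracle helpers for the test suite.

These implement independent checks (method of characteristics, heat-equation
spreading, closed-form Gaussian moment integrals) used by both the unit
tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np

import sizespectra as ss
from sizespectra.grid import LN10

GROUPS = ss.GROUP_NAMES
ZOO, CEPH_LA, CEPH_HA, FISH = GROUPS


def passive_config(**kw) -> ss.ModelConfig:
    """Default config with recruitment switched off (for pure-operator tests)."""
    cfg = ss.default_config(**kw)
    for n, g in cfg.groups.items():
        cfg.groups[n] = g.copy(recruitment_scalar=0.0)
    return cfg


def inert_config(mortality: float = 0.0, **kw) -> ss.ModelConfig:
    """Config with all feeding interactions off and a flat mortality.

    With theta = 0 everywhere the rate closures give g = f = mu_p = 0, so
    only the prescribed flat senescence `mortality` acts.
    """
    cfg = passive_config(**kw)
    theta0 = {n: 0.0 for n in list(GROUPS) + ["phytoplankton"]}
    for n, g in cfg.groups.items():
        cfg.groups[n] = g.copy(
            interaction=dict(theta0),
            senescence=ss.SenescenceParams(w_s=g.w_min, k_s=mortality, p_s=0.0))
    return cfg


def pulse_state(sim: ss.Simulation, group: str, log10_w0: float):
    """Unit-mass numerical delta in one bin of `group`; all else empty."""
    st = sim.initial_state()
    for n in st.N:
        st.N[n][:] = 0.0
    i0 = int(np.argmin(np.abs(sim.grid.log10_centers - log10_w0)))
    st.N[group][i0] = 1.0 / sim.grid.dw[i0]
    return st, i0


def advection_centroid_gap(n_steps: int = 100, rate: float = 1.0,
                           dt: float = 0.02) -> float:
    """|numerical centroid - characteristics| in log10 mass for g = rate*w.

    The characteristic of dw/dt = rate*w moves at constant speed rate/ln10
    in log10 mass.
    """
    sim = ss.Simulation(passive_config())
    g = sim.grid
    st, i0 = pulse_state(sim, FISH, 0.05)
    arr = sim._to_array(st)
    i = sim.names.index(FISH)
    G = np.zeros_like(arr)
    G[i] = rate * g.w_centers * sim._maskf[i]
    Z = np.zeros_like(arr)
    for _ in range(n_steps):
        arr = sim._substep(arr, G, Z, Z, dt)
    N = arr[i]
    x_num = float(np.sum(g.log10_centers * N * g.dw) / np.sum(N * g.dw))
    x_char = g.log10_centers[i0] + rate * n_steps * dt / LN10
    return abs(x_num - x_char)


def diffusion_variance_ratio(f0: float = 5.0, dt: float = 0.004) -> float:
    """Measured variance growth rate / f0 for constant diffusivity f0.

    Under dN/dt = 1/2 f d2(f N)/dw2 with constant f, the mass-space variance
    of a pulse grows at exactly rate f (heat-equation spreading).  f is
    confined to a window around the pulse so the pulse never feels the
    domain edges.
    """
    sim = ss.Simulation(passive_config())
    g = sim.grid
    st, _ = pulse_state(sim, FISH, 1.0)
    arr = sim._to_array(st)
    i = sim.names.index(FISH)
    F = np.zeros_like(arr)
    win = (g.log10_centers >= 0.0) & (g.log10_centers <= 2.0)
    F[i, win] = f0
    Z = np.zeros_like(arr)

    def variance(N):
        m = np.sum(N * g.dw)
        mw = np.sum(g.w_centers * N * g.dw) / m
        return float(np.sum((g.w_centers - mw) ** 2 * N * g.dw) / m)

    for _ in range(50):
        arr = sim._substep(arr, Z, F, Z, dt)
    v0 = variance(arr[i])
    for _ in range(150):
        arr = sim._substep(arr, Z, F, Z, dt)
    v1 = variance(arr[i])
    return (v1 - v0) / (150 * dt) / f0


def single_prey_state(sim: ss.Simulation, prey_group: str, log10_wp: float,
                      abundance: float):
    """State whose only content is `abundance` individuals in one prey bin."""
    st = sim.initial_state()
    for n in st.N:
        st.N[n][:] = 0.0
    st.phyto_density = np.zeros_like(st.phyto_density)
    k = int(np.argmin(np.abs(sim.grid.log10_centers - log10_wp)))
    st.N[prey_group][k] = abundance / sim.grid.dw[k]
    return st, k


def powerlaw_prey_state(sim: ss.Simulation, prey_group: str,
                        a: float, b: float):
    """State with a pure power-law spectrum N = a w^b in one prey group."""
    st = sim.initial_state()
    for n in st.N:
        st.N[n][:] = 0.0
    st.phyto_density = np.zeros_like(st.phyto_density)
    s = sim.grid.group_slices[prey_group]
    st.N[prey_group][s] = a * sim.grid.w_centers[s] ** b
    return st


def run_zoo_only(years: int = 60) -> tuple:
    """Zooplankton alone on the static phytoplankton spectrum.

    Returns (log10 mass, steady density) over the zooplankton bins after
    `years` years of weekly stepping — the classic single-consumer
    power-law limit.
    """
    cfg = ss.default_config(years=years, averaging_years=1)
    for n, g in cfg.groups.items():
        if n != ZOO:
            cfg.groups[n] = g.copy(recruitment_scalar=0.0)
    sim = ss.Simulation(cfg)
    st = sim.initial_state()
    for n in st.N:
        if n != ZOO:
            st.N[n][:] = 0.0
    arr = sim._to_array(st)
    for _ in range(52 * years):
        arr = sim._advance(arr, 1.0 / 52.0)
    s = sim.grid.group_slices[ZOO]
    return sim.grid.log10_centers[s], arr[sim.names.index(ZOO), s]


def fish_on_zoo_config() -> ss.ModelConfig:
    """Fish eating only zooplankton; zooplankton eating only phytoplankton."""
    cfg = ss.default_config()
    off = {n: 0.0 for n in list(GROUPS) + ["phytoplankton"]}
    cfg.groups[ZOO] = cfg.groups[ZOO].copy(
        interaction=dict(off, phytoplankton=1.0))
    cfg.groups[FISH] = cfg.groups[FISH].copy(
        interaction=dict(off, zooplankton=1.0))
    for n in (CEPH_LA, CEPH_HA):
        cfg.groups[n] = cfg.groups[n].copy(interaction=dict(off))
    return cfg
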