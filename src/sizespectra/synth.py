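"""Synthetic inputs: phytoplankton spectrum and trophic-position observations.

The dynamic model is driven by a static phytoplankton abundance size
spectrum measured at sea; here it is emulated as a truncated power law over
a log10 mass range, optionally with multiplicative lognormal noise per bin.
Placeholder empirical trophic-position tables for the two cephalopod groups
are likewise drawn from simple generative trophic allometries: a steeper,
higher line for the high-activity group and a shallow, lower line for the
low-activity group.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import PhytoSpectrum

__all__ = ["SynthSpec", "generate_phyto_spectrum", "generate_rtp_observations"]

#: Generative trophic allometry lines (intercept at log10 w = -2, slope per
#: decade of body mass): high-activity cephalopods feed high with a clear
#: allometry; low-activity ones sit lower with little change across sizes.
RTP_LINES = {
    "ceph_high_activity": (3.2, 0.35),
    "ceph_low_activity": (2.8, 0.05),
}


@dataclass
class SynthSpec:
    """Everything the synthetic generators need; same seed, same outputs."""

    seed: int = 0
    phyto_slope: float = -2.0
    phyto_intercept: float = 1e-3       # ind m^-3 g^-1 at 1 g
    phyto_log10_range: tuple = (-13.0, -5.0)
    noise_sd: float = 0.0               # lognormal sd of per-bin density noise
    bin_width: float = 0.1
    rtp_n_points: int = 12
    rtp_log10_range: tuple = (-2.0, 4.0)
    rtp_noise_sd: float = 0.1
    rtp_lines: dict = field(default_factory=lambda: dict(RTP_LINES))


def generate_phyto_spectrum(spec: SynthSpec) -> PhytoSpectrum:
    """Truncated power-law phytoplankton spectrum, optionally noisy.

    N_P(w) = a_P w^b_P on the configured log10 range.  With noise_sd > 0 the
    density is tabulated per 0.1-log10 bin with multiplicative lognormal
    noise exp(eps), eps ~ Normal(0, noise_sd), seeded and reproducible.
    """
    if spec.phyto_slope >= 0:
        raise ValueError("phytoplankton spectrum slope must be negative")
    base = PhytoSpectrum(log10_range=tuple(spec.phyto_log10_range),
                         intercept=spec.phyto_intercept,
                         slope=spec.phyto_slope)
    if spec.noise_sd == 0.0:
        return base
    lo, hi = spec.phyto_log10_range
    n = int(round((hi - lo) / spec.bin_width))
    centers = lo + spec.bin_width * (np.arange(n) + 0.5)
    rng = np.random.default_rng(spec.seed)
    dens = (spec.phyto_intercept * (10.0 ** centers) ** spec.phyto_slope
            * np.exp(rng.normal(0.0, spec.noise_sd, size=n)))
    return PhytoSpectrum(log10_range=tuple(spec.phyto_log10_range),
                         intercept=spec.phyto_intercept,
                         slope=spec.phyto_slope, table=(centers, dens))


def generate_rtp_observations(spec: SynthSpec) -> dict:
    """Synthetic trophic-position observation tables per cephalopod group.

    Points are drawn around each group's generative line with Gaussian noise
    of sd `rtp_noise_sd`.  Returns group -> DataFrame(log10_mass, tp).
    """
    if spec.rtp_n_points < 2:
        raise ValueError("need at least 2 observation points per group")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rtp_log10_range
    out = {}
    for group, (intercept, slope) in spec.rtp_lines.items():
        x = np.linspace(lo, hi, spec.rtp_n_points)
        tp = intercept + slope * (x - lo) + rng.normal(
            0.0, spec.rtp_noise_sd, size=spec.rtp_n_points)
        out[group] = pd.DataFrame({"log10_mass": x, "tp": tp})
    return out


def generative_rtp_line(spec: SynthSpec, group: str):
    """The noise-free line a group's observations are drawn around."""
    intercept, slope = spec.rtp_lines[group]
    lo, hi = spec.rtp_log10_range
    x = np.linspace(lo, hi, spec.rtp_n_points)
    return x, intercept + slope * (x - lo)
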