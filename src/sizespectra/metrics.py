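"""Emergent ecosystem properties and cross-set contrasts.

Per run: standing biomass, somatic production, biomass stability (inverse
coefficient of variation of total annual biomass over the averaging era),
turnover time (B/P), community size-spectrum slope and intercept, and the
trophic-position and realised-PPMR curves implied by the model's diet
composition.  Per set: medians and percent changes against a reference set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CommunityState, Simulation, _prey_fields
from .groups import FunctionalGroupParams, feeding_kernel

__all__ = [
    "MetricsResult", "biomass_and_cv", "production", "turnover_time",
    "spectrum_slope_intercept", "trophic_positions",
    "relative_trophic_position", "realised_ppmr", "rmse",
    "evaluate_run", "summarize_set", "compare_sets",
]

#: Metrics summarized across a set and compared between sets.
SET_METRICS = ("total_biomass", "production", "inv_cv", "pb_rate",
               "turnover_time", "cv_biomass", "spectrum_slope",
               "spectrum_intercept")


def biomass_and_cv(annual_totals) -> tuple:
    """Mean, CV and 1/CV of the total annual biomass over the averaging era.

    CV uses the sample standard deviation (ddof=1).  A perfectly constant
    series has CV 0 and stability reported as +inf.
    """
    x = np.asarray(annual_totals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two annual values to compute a CV")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("mean annual biomass is zero; CV undefined")
    cv = float(np.std(x, ddof=1)) / mean
    inv = math.inf if cv == 0.0 else 1.0 / cv
    return mean, cv, inv


def production(state: CommunityState, sim: Simulation | None = None,
               growth: dict | None = None) -> float:
    """Community somatic production P = sum_i integral g_i N_i dw (g m^-3 yr^-1).

    Growth rates are recomputed from the (era-mean) state unless `growth`
    supplies per-group g fields on each group's mask directly.
    """
    if growth is None:
        if sim is None:
            raise ValueError("production needs either a Simulation or g fields")
        growth = {n: r[0] for n, r in sim.rates(state).items()}
    g = state.grid
    total = 0.0
    for name, gfield in growth.items():
        s = g.group_slices[name]
        total += float(np.sum(gfield * state.N[name][s] * g.dw[s]))
    return total


def turnover_time(biomass: float, prod: float) -> float:
    """Turnover time B/P (yr); +inf sentinel when production is zero."""
    if prod == 0.0:
        return math.inf
    return biomass / prod


def spectrum_slope_intercept(state: CommunityState) -> tuple:
    """OLS slope and intercept of the community abundance size spectrum.

    Regresses log10 of the total dynamic-group density on log10 mass over
    the union of occupied bins; empty bins are excluded.  The intercept is
    reported at log10 w = 0 (w = 1 g).
    """
    g = state.grid
    Ntot = np.zeros(g.n_bins)
    for arr in state.N.values():
        Ntot += arr
    keep = Ntot > 0.0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 non-empty bins; spectrum fit undefined")
    res = stats.linregress(g.log10_centers[keep], np.log10(Ntot[keep]))
    return float(res.slope), float(res.intercept)


# ---------------------------------------------------------------------------
# diet-based curves


def _diet_weights(group: FunctionalGroupParams, w_pred: np.ndarray,
                  state: CommunityState):
    """Biomass diet weights theta * w' * phi * N * dw' per prey pool.

    Returns (pool names, list of (n_pred, n_bins) weight arrays).
    """
    g = state.grid
    names, weights = [], []
    for pname, dens in _prey_fields(state):
        th = group.theta(pname)
        phi = feeding_kernel(group, w_pred[:, None], g.w_centers[None, :])
        weights.append(th * phi * (g.w_centers * dens * g.dw)[None, :])
        names.append(pname)
    return names, weights


def trophic_positions(sim: Simulation, state: CommunityState,
                      tol: float = 1e-10, maxiter: int = 1000):
    """Self-consistent trophic position of every dynamic-group size class.

    Phytoplankton has TP 1 by definition; each consumer size class sits one
    level above the biomass-weighted mean TP of its diet,
    TP(w) = 1 + sum_prey share(w -> w') TP(w').  Solved by fixed-point
    iteration to `tol`; raises if not converged within `maxiter`.

    Returns (tp, residual): dict group -> TP over the group's bins (NaN for
    classes with an empty diet) and the final sup-norm residual.
    """
    g = sim.grid
    weights = {}
    for name, gp in sim.groups.items():
        s = g.group_slices[name]
        pnames, ws = _diet_weights(gp, g.w_centers[s], state)
        weights[name] = (pnames, ws)

    tp = {n: np.full(g.group_slices[n].stop - g.group_slices[n].start, 2.0)
          for n in sim.groups}
    tp_full = {n: np.zeros(g.n_bins) for n in sim.groups}
    residual = math.inf
    for _ in range(maxiter):
        for n in sim.groups:
            tp_full[n][g.group_slices[n]] = tp[n]
        new = {}
        for name in sim.groups:
            pnames, ws = weights[name]
            num = np.zeros_like(tp[name])
            den = np.zeros_like(tp[name])
            for pname, wmat in zip(pnames, ws):
                prey_tp = (np.ones(g.n_bins) if pname not in sim.groups
                           else tp_full[pname])
                # prey classes whose own TP is undefined (empty diet) are
                # excluded from the diet average rather than poisoning it
                fin = np.isfinite(prey_tp)
                num += wmat @ np.where(fin, prey_tp, 0.0)
                den += wmat @ fin.astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                new[name] = np.where(den > 0.0, 1.0 + num / den, np.nan)
        residual = max(
            float(np.nanmax(np.abs(new[n] - tp[n]), initial=0.0))
            for n in sim.groups)
        tp = new
        if residual < tol:
            return tp, residual
    raise RuntimeError(
        f"trophic-position iteration did not converge in {maxiter} steps "
        f"(residual {residual:.2e})")


def relative_trophic_position(sim: Simulation, state: CommunityState,
                              group: str, baseline: float = 0.0):
    """Trophic-position curve of one group over its size range.

    Returns (log10 mass, TP - baseline).  The default baseline 0 reports the
    absolute trophic position; pass e.g. another group's TP at a reference
    size to express a relative position.
    """
    tp, _ = trophic_positions(sim, state)
    s = sim.grid.group_slices[group]
    return sim.grid.log10_centers[s], tp[group] - baseline


def realised_ppmr(sim: Simulation, state: CommunityState, group: str):
    """Diet-realised PPMR curve: w / exp(<ln w'>_diet), biomass-weighted.

    Returns (log10 mass, realised PPMR); NaN where the diet is empty.
    """
    g = sim.grid
    s = g.group_slices[group]
    w_pred = g.w_centers[s]
    _, ws = _diet_weights(sim.groups[group], w_pred, state)
    wtot = sum(ws)
    den = wtot.sum(axis=1)
    ln_prey = np.log(g.w_centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ln = np.where(den > 0.0, (wtot @ ln_prey) / den, np.nan)
        out = w_pred / np.exp(mean_ln)
    return g.log10_centers[s], out


def rmse(model_curve, observations, full: bool = False):
    """Root mean square error of a model curve against (mass, value) points.

    The model curve (log10 mass, value) is interpolated linearly in log10
    mass at each observation mass; observations outside the curve's support
    are excluded (and counted when full=True).
    """
    xm, ym = (np.asarray(a, dtype=float) for a in model_curve)
    xo, yo = (np.asarray(a, dtype=float) for a in observations)
    ok = np.isfinite(ym)
    xm, ym = xm[ok], ym[ok]
    inside = (xo >= xm.min()) & (xo <= xm.max())
    n_excluded = int((~inside).sum())
    if inside.sum() == 0:
        raise ValueError("no observations fall within the model curve support")
    pred = np.interp(xo[inside], xm, ym)
    err = float(np.sqrt(np.mean((pred - yo[inside]) ** 2)))
    if full:
        return err, int(inside.sum()), n_excluded
    return err


# ---------------------------------------------------------------------------
# per-run and per-set summaries


@dataclass
class MetricsResult:
    """Emergent quantities of one run."""

    label: str
    sweep_coords: dict
    total_biomass: float          # era-mean total annual biomass, g m^-3
    production: float             # g m^-3 yr^-1
    cv_biomass: float
    inv_cv: float
    turnover_time: float          # yr, = B/P
    pb_rate: float                # 1/yr, = P/B
    spectrum_slope: float
    spectrum_intercept: float
    rtp: dict = field(default_factory=dict)            # group -> (log10 w, TP)
    realised_ppmr: dict = field(default_factory=dict)  # group -> (log10 w, PPMR)

    def scalars(self) -> dict:
        return {m: getattr(self, m) for m in SET_METRICS}


def evaluate_run(result, sim: Simulation | None = None,
                 curves: bool = True) -> MetricsResult:
    """All per-run metrics from a SimulationResult."""
    if sim is None:
        sim = Simulation(result.config)
    cfg = result.config
    era = result.total_biomass[len(result.total_biomass) - cfg.averaging_years:]
    mean_b, cv, inv = biomass_and_cv(era)
    state = result.mean_state
    P = production(state, sim=sim)
    tt = turnover_time(mean_b, P)
    slope, intercept = spectrum_slope_intercept(state)
    rtp_curves, ppmr_curves = {}, {}
    if curves:
        tp, _ = trophic_positions(sim, state)
        for n in sim.groups:
            s = sim.grid.group_slices[n]
            rtp_curves[n] = (sim.grid.log10_centers[s], tp[n])
            ppmr_curves[n] = realised_ppmr(sim, state, n)
    return MetricsResult(
        label=cfg.label, sweep_coords=dict(cfg.sweep_coords),
        total_biomass=mean_b, production=P, cv_biomass=cv, inv_cv=inv,
        turnover_time=tt, pb_rate=(0.0 if mean_b == 0 else P / mean_b),
        spectrum_slope=slope, spectrum_intercept=intercept,
        rtp=rtp_curves, realised_ppmr=ppmr_curves)


def summarize_set(results) -> dict:
    """Median and range of each scalar metric across a set of runs."""
    out = {}
    for m in SET_METRICS:
        vals = np.array([getattr(r, m) for r in results], dtype=float)
        out[m] = {"median": float(np.median(vals)),
                  "min": float(np.min(vals)), "max": float(np.max(vals))}
    return out


def compare_sets(reference, treatment) -> dict:
    """Percent change of set medians, treatment relative to reference.

    For each metric m, delta% = 100 (median_t - median_r) / median_r.
    Stability is the inverse CV of biomass; the rate of energy turnover is
    P/B (so a faster turnover means a shorter turnover time).  NaN sentinel
    where the reference median is zero or not finite.
    """
    ref = summarize_set(reference) if not isinstance(reference, dict) else reference
    trt = summarize_set(treatment) if not isinstance(treatment, dict) else treatment
    out = {}
    for m in SET_METRICS:
        r, t = ref[m]["median"], trt[m]["median"]
        if r == 0.0 or not (math.isfinite(r) and math.isfinite(t)):
            out[m] = math.nan
        else:
            out[m] = 100.0 * (t - r) / r
    return out
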