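"""Closed-form parameter estimates from localisation curves.

Seeds for fitting come from the model's own structure.  Writing
``N~_o = V~_o C~_o`` for the interstitial cell content of organ *o*, an
initial estimate follows from integrating the interstitial balance while
neglecting the return term (valid close to t = 0):

    e0_o  =  (N~_o(t) - N~_o(0)) / (B_o * int_0^t C_o dt)

and, because the interstitium equilibrates at ``C~ = C / mu``, the
late-time content ratio gives

    mu0_o =  C_o / C~_o        (evaluated at the last time point).

A current estimate ``(e_n, mu_n)`` can then be refined by restoring the
neglected terms:

    e_{n+1}  = (N~(t) - N~(0)) / (B int_0^t (C - mu_n C~) dt)
    mu_{n+1} = (e_n B int_0^t C dt - (N~(t) - N~(0))) / (e_n B int_0^t C~ dt)

All data-side quantities are taken from the observed curves: the blood
curve supplies ``C_h``; organ vascular concentration is approximated by
``C_o ~ C_h`` (vascular spaces equilibrate with blood fast relative to the
first datum); interstitial content is the organ observable minus the
estimated vascular content.  Integrals use the trapezoid rule on the data
grid — no interpolation model.

Organs with special wiring get corrected, still approximate, estimators:
the liver uses its effective flow and a vascular concentration diluted by
portal venous inflow; the lymph node subtracts the afferent lymph flux
(reconstructed from the current iterate and the other organs' curves) from
its interstitial balance; the two lung organs split the lumped lungs curve
in proportion to their uptake flux ``e B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import BLOOD_CURVE, LUNG_CURVE, LocalisationDataset, curve_organ_map
from .kinetics import KineticParameters
from .model import _perfusion_flows
from .physiology import CirculatorySystem

__all__ = ["EstimateTrace", "EstimateError", "estimate_initial", "refine_estimates"]

_MU_FLOOR = 1e-6


class EstimateError(ValueError):
    """No usable estimate (e.g. zero vascular exposure integral)."""


@dataclass
class EstimateTrace:
    """Iteration history of the fixed-point refinement."""

    quadrature: str
    iterates: list = field(default_factory=list)  # [e..., mu...] per iteration
    metrics: list = field(default_factory=list)  # max relative change
    flags: dict = field(default_factory=dict)  # organ -> reason
    converged: bool = False


@dataclass
class _DataQuantities:
    """Data-side curves shared by the estimators (model-independent part)."""

    times: np.ndarray
    C_h: np.ndarray  # blood-pool concentration
    organ_total: dict[int, np.ndarray]  # organ index -> total content N(t)
    lung_indices: list[int]


def _extract(
    dataset: LocalisationDataset, system: CirculatorySystem, dose: float
) -> _DataQuantities:
    if BLOOD_CURVE not in dataset.curves:
        raise EstimateError("dataset has no blood curve")
    blood_t = dataset.times(BLOOD_CURVE)
    if len(blood_t) < 2 or blood_t[0] != 0.0:
        raise EstimateError("need a t = 0 row plus at least one post-initial point")
    C_h = dataset.values(BLOOD_CURVE) * dose / system.blood_pool_volume
    organ_total: dict[int, np.ndarray] = {}
    lung_indices: list[int] = []
    for curve, organ_idx in curve_organ_map(system).items():
        if curve == BLOOD_CURVE or curve not in dataset.curves:
            continue
        t = dataset.times(curve)
        if not np.array_equal(t, blood_t):
            raise EstimateError(
                f"curve {curve!r} is not sampled on the blood curve's grid"
            )
        total = dataset.values(curve) * dose
        if curve == LUNG_CURVE:
            lung_indices = list(organ_idx)
            for i in organ_idx:
                organ_total[i] = total  # shared; split later by uptake flux
        else:
            organ_total[organ_idx[0]] = total
    return _DataQuantities(blood_t, C_h, organ_total, lung_indices)


def _organ_curves(
    q: _DataQuantities,
    system: CirculatorySystem,
    e: np.ndarray,
    mu: np.ndarray,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Per-organ (C_vasc, C_int, N_int) estimates given the current iterate.

    C_vasc defaults to the blood concentration; the liver's is diluted by
    the portal organs' extravasation.  Lung organs share the lungs curve:
    combined interstitial content is split in proportion to uptake flux
    ``e B`` (flow share when both e are zero) and both see the combined
    interstitial concentration.
    """
    B_perf = _perfusion_flows(system)
    liver = system.liver_index
    C_vasc: dict[int, np.ndarray] = {}
    C_int: dict[int, np.ndarray] = {}
    N_int: dict[int, np.ndarray] = {}

    for i in q.organ_total:
        C_vasc[i] = q.C_h
    if liver is not None and liver in q.organ_total:
        portal = system.portal_indices
        inflow = system.arterial_flows[liver] + sum(
            (1.0 - e[m]) * system.arterial_flows[m] for m in portal
        )
        C_vasc[liver] = (inflow / B_perf[liver]) * q.C_h

    lungs = q.lung_indices
    if lungs:
        weights = np.array([max(e[i], 0.0) * B_perf[i] for i in lungs])
        if weights.sum() <= 0:
            weights = np.array([B_perf[i] for i in lungs])
        weights = weights / weights.sum()
        V_vasc = sum(system.organs[i].vascular_volume for i in lungs)
        V_int_total = sum(system.organs[i].interstitial_volume for i in lungs)
        total = q.organ_total[lungs[0]]
        combined = np.maximum(total - V_vasc * q.C_h, 0.0)
        for w, i in zip(weights, lungs):
            N_int[i] = w * combined
            C_int[i] = combined / V_int_total  # shared concentration

    for i, total in q.organ_total.items():
        if i in lungs:
            continue
        V = system.organs[i].vascular_volume
        Vt = system.organs[i].interstitial_volume
        N = np.maximum(total - V * C_vasc[i], 0.0)
        N_int[i] = N
        C_int[i] = N / Vt
    return C_vasc, C_int, N_int


def _first_sound_index(times: np.ndarray, vascular_tau: float) -> int:
    """Earliest post-initial index at which the vascular space has
    equilibrated with blood (~5 vascular time constants), so the
    content-minus-vascular split is meaningful.  Falls back to the last
    index if the grid never reaches that time."""
    threshold = 5.0 * vascular_tau
    for k in range(1, len(times)):
        if times[k] >= threshold:
            return k
    return len(times) - 1


def _trapz(y: np.ndarray, t: np.ndarray, upto: int | None = None) -> float:
    s = slice(0, (upto + 1) if upto is not None else None)
    return float(np.trapezoid(y[s], t[s]))


def _e_update(t, C_vasc, C_int, N_int, B: float, mu: float, upto=None):
    """e = dN~ / (B int (C - mu C~) dt); None on a non-positive denominator."""
    denom = B * (_trapz(C_vasc, t, upto) - mu * _trapz(C_int, t, upto))
    if denom <= 0:
        return None
    end = upto if upto is not None else len(t) - 1
    return (N_int[end] - N_int[0]) / denom


def _mu_update(t, C_vasc, C_int, N_int, B: float, e: float):
    denom = e * B * _trapz(C_int, t)
    if denom <= 0:
        return None
    dN = N_int[-1] - N_int[0]
    return (e * B * _trapz(C_vasc, t) - dN) / denom


def estimate_initial(
    dataset: LocalisationDataset,
    system: CirculatorySystem,
    dose: float = 1.0,
) -> KineticParameters:
    """Initial (e0, mu0) per organ from the observed curves.

    e0 is evaluated at the earliest post-initial time (the estimator
    neglects the return term, which is only valid near t = 0); mu0 at the
    latest time (the content ratio is a t -> infinity limit).  Results are
    clamped into their domains: e into [0, 1], mu onto [1e-6, inf).
    Organs without an observed curve receive the shared lumped estimate:
    the geometric mean of the observed organs' values.
    """
    q = _extract(dataset, system, dose)
    B_perf = _perfusion_flows(system)
    n = system.n_organs
    zeros = np.zeros(n)
    C_vasc, C_int, N_int = _organ_curves(q, system, zeros, zeros)

    e = np.full(n, np.nan)
    mu = np.full(n, np.nan)
    # pass 2 re-estimates the liver with its vascular concentration diluted
    # by the portal organs' (pass-1) extravasation
    passes = 2 if system.liver_index in q.organ_total else 1
    for p in range(passes):
        if p == 1:
            C_vasc, C_int, N_int = _organ_curves(
                q, system, np.nan_to_num(e), np.nan_to_num(mu, nan=1.0)
            )
        for i in q.organ_total:
            if p == 1 and i != system.liver_index:
                continue
            if i in q.lung_indices:
                V = sum(system.organs[j].vascular_volume for j in q.lung_indices)
                B = sum(B_perf[j] for j in q.lung_indices)
            else:
                V, B = system.organs[i].vascular_volume, B_perf[i]
            k0 = _first_sound_index(q.times, V / B)
            val = _e_update(
                q.times, C_vasc[i], C_int[i], N_int[i], B_perf[i], 0.0, upto=k0
            )
            if val is None:
                raise EstimateError(
                    f"organ {system.names[i]!r}: no vascular exposure by the "
                    "first post-initial time"
                )
            e[i] = val
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = C_vasc[i][-1] / C_int[i][-1]
            mu[i] = ratio if np.isfinite(ratio) and ratio > 0 else 1.0

    observed = ~np.isnan(e)
    if not observed.any():
        raise EstimateError("no organ curves in dataset")
    # lumped-other rule: censored organs share one central estimate
    e_obs = np.clip(e[observed], 1e-6, 1.0)
    mu_obs = np.maximum(mu[observed], _MU_FLOOR)
    e[~observed] = np.exp(np.mean(np.log(e_obs)))
    mu[~observed] = np.exp(np.mean(np.log(mu_obs)))

    return KineticParameters(
        system.names, np.clip(e, 0.0, 1.0), np.maximum(mu, _MU_FLOOR)
    )


def refine_estimates(
    dataset: LocalisationDataset,
    system: CirculatorySystem,
    params: KineticParameters | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    dose: float = 1.0,
) -> tuple[KineticParameters, EstimateTrace]:
    """Fixed-point refinement of the analytic estimates.

    Iterates the refined estimators on the full observed window until the
    maximum per-parameter relative change drops below ``tol`` or
    ``max_iter`` is reached.  Out-of-domain iterates are clamped and
    flagged; a non-positive denominator freezes that organ at its last
    valid value.  Liver dilution and the lymph-node afferent flux are
    recomputed from the current iterate each pass.
    """
    if params is None:
        params = estimate_initial(dataset, system, dose)
    q = _extract(dataset, system, dose)
    B_perf = _perfusion_flows(system)
    ln = system.lymph_node_index
    trace = EstimateTrace(quadrature="trapezoid-data-grid")
    e = params.e.copy()
    mu = params.mu.copy()
    trace.iterates.append(np.concatenate([e, mu]))

    # the lumped lung curve and the pass-through lymph node violate the
    # one-organ balance behind the refined estimators: freeze them at
    # their incoming (initial-estimate) values
    frozen = set(q.lung_indices) | ({ln} if ln is not None else set())
    for i in sorted(frozen & set(q.organ_total)):
        trace.flags[system.names[i]] = "frozen_approximate"

    def damped(old: float, update: float) -> float:
        # geometric averaging stabilises the alternating e/mu fixed point
        return float(np.sqrt(max(old, 1e-8) * max(update, 1e-8)))

    t_last = q.times[-1]
    for _ in range(max_iter):
        C_vasc, C_int, N_int = _organ_curves(q, system, e, mu)
        e_new, mu_new = e.copy(), mu.copy()
        for i in q.organ_total:
            if i in frozen:
                continue
            organ = system.organs[i]
            k0 = _first_sound_index(q.times, organ.vascular_volume / B_perf[i])
            # integrate only over the informative span: once the organ's
            # interstitium equilibrates, the e-integrand cancels to noise
            if e[i] > 0 and mu[i] > 0:
                tau_mu = organ.interstitial_volume / (e[i] * mu[i] * B_perf[i])
                t_stop = min(t_last, 3.0 * tau_mu)
            else:
                t_stop = t_last
            k_e = max(k0, int(np.searchsorted(q.times, t_stop)))
            k_e = min(k_e, len(q.times) - 1)
            val = _e_update(
                q.times, C_vasc[i], C_int[i], N_int[i], B_perf[i], mu[i], upto=k_e
            )
            if val is None:
                trace.flags[system.names[i]] = "nonpositive_exposure_integral"
            elif val <= 0:
                trace.flags[system.names[i]] = "nonpositive_e_update"
            else:
                e_new[i] = damped(e[i], val)
            if e_new[i] > 0:
                val = _mu_update(
                    q.times, C_vasc[i], C_int[i], N_int[i], B_perf[i], e_new[i]
                )
                if val is None:
                    trace.flags[system.names[i]] = "nonpositive_interstitial_integral"
                elif val <= 0:
                    trace.flags[system.names[i]] = "nonpositive_mu_update"
                else:
                    mu_new[i] = damped(mu[i], val)
        clipped_e = np.clip(e_new, 0.0, 1.0)
        clipped_mu = np.maximum(mu_new, _MU_FLOOR)
        for i in np.flatnonzero((clipped_e != e_new) | (clipped_mu != mu_new)):
            trace.flags[system.names[i]] = "clamped"
        e_new, mu_new = clipped_e, clipped_mu

        old = np.concatenate([e, mu])
        new = np.concatenate([e_new, mu_new])
        metric = float(np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-12)))
        e, mu = e_new, mu_new
        trace.iterates.append(new)
        trace.metrics.append(metric)
        if metric < tol:
            trace.converged = True
            break

    refined = KineticParameters(system.names, e, mu, params.free_mask.copy())
    return refined, trace
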