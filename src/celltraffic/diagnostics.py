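"""Cheap practical-identifiability indicators.

Two local diagnostics complement parameter recovery studies:

* the **sensitivity matrix** — the change in each data curve's score
  after a 1% perturbation of each parameter at the fit, optionally
  normalised per curve so the dominant parameter for each observable
  stands out; near-zero rows mark parameters the data cannot constrain;
* the **equilibrium timescale table** — each organ's vascular and
  interstitial compartments approach steady state on characteristic
  times

      tau_e  = V_tot / (e B'),      tau_mu = V~ / (e mu B'),

  with V_tot the total blood volume and B' the effective organ flow.
  Parameters whose timescale falls before the first datum or after the
  last cannot move the model within the observed window and are expected
  to be poorly recovered.

``recovery_report`` cross-tabulates fitted/true parameter ratios against
those flags; ``grid_search_cost`` is the back-of-envelope argument for
why naive grid search is hopeless in these models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datasets import LocalisationDataset
from .fitting import ParameterMap, ScoreEngine
from .kinetics import KineticParameters
from .model import effective_flows
from .physiology import CirculatorySystem

__all__ = [
    "SensitivityMatrix",
    "TimescaleTable",
    "GridSearchCost",
    "sensitivity_matrix",
    "timescale_table",
    "recovery_report",
    "grid_search_cost",
]

SECONDS_PER_YEAR = 365.0 * 24 * 3600

FLAG_FAST = "below_first_datum"
FLAG_SLOW = "above_last_datum"
FLAG_IN = "inside_window"


@dataclass
class SensitivityMatrix:
    """Parameters (rows) x data curves (columns).

    ``raw`` holds fractional per-curve score changes (absolute change
    relative to the curve's base score; absolute change where the base
    score is numerically zero).  ``normalised`` rescales each column to
    sum to 1; all-zero columns are left unnormalised and listed in
    ``flags['zero_columns']``.
    """

    raw: pd.DataFrame
    normalised: pd.DataFrame
    delta: float
    flags: dict

    def row_sums(self) -> pd.Series:
        return self.raw.sum(axis=1)


@dataclass
class TimescaleTable:
    """Per-organ equilibrium timescales with data-window flags."""

    table: pd.DataFrame  # organ, tau_e, tau_mu, flag_e, flag_mu
    t_first: float
    t_last: float

    def flagged_parameters(self) -> list[str]:
        """Parameter names whose timescale falls outside the window."""
        out = []
        for _, row in self.table.iterrows():
            if row["flag_e"] != FLAG_IN:
                out.append(f"e_{row['organ']}")
            if row["flag_mu"] != FLAG_IN:
                out.append(f"mu_{row['organ']}")
        return out

    def in_window_parameters(self) -> list[str]:
        """Parameters of organs with *both* timescales inside the window."""
        out = []
        for _, row in self.table.iterrows():
            if row["flag_e"] == FLAG_IN and row["flag_mu"] == FLAG_IN:
                out.extend([f"e_{row['organ']}", f"mu_{row['organ']}"])
        return out


class GridSearchCost(NamedTuple):
    evaluations: float
    seconds: float
    years: float


def sensitivity_matrix(
    system: CirculatorySystem,
    params: KineticParameters,
    dataset: LocalisationDataset,
    delta: float = 0.01,
    dose: float = 1.0,
) -> SensitivityMatrix:
    """Local sensitivity of each curve's score to each free parameter.

    Each free parameter is perturbed by ``+delta`` relative (one-sided
    downward at the upper domain boundary, flagged); the absolute change
    of every per-curve score is recorded, as a fraction of the curve's
    base score where that is nonzero.
    """
    engine = ScoreEngine(system, dataset, dose)
    pmap = ParameterMap(system, dataset, params)
    theta = pmap.pack(params)
    _, base = engine.score(params)
    curves = list(base)
    base_arr = np.array([base[c] for c in curves])

    raw = np.zeros((len(theta), len(curves)))
    one_sided = []
    upper = np.array(
        [1.0 if name.startswith("e_") else np.inf for name in pmap.names]
    )
    for j in range(len(theta)):
        th = theta.copy()
        if th[j] * (1.0 + delta) > upper[j]:
            th[j] *= 1.0 - delta
            one_sided.append(pmap.names[j])
        else:
            th[j] *= 1.0 + delta
        _, pert = engine.score(pmap.apply(params, th))
        change = np.abs(np.array([pert[c] for c in curves]) - base_arr)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(base_arr > 1e-300, change / base_arr, change)
        raw[j] = frac

    raw_df = pd.DataFrame(raw, index=pmap.names, columns=curves)
    col_sums = raw_df.sum(axis=0)
    zero_cols = [c for c in curves if col_sums[c] <= 0]
    norm_df = raw_df.copy()
    for c in curves:
        if c not in zero_cols:
            norm_df[c] = raw_df[c] / col_sums[c]
    flags: dict = {}
    if one_sided:
        flags["one_sided"] = one_sided
    if zero_cols:
        flags["zero_columns"] = zero_cols
    return SensitivityMatrix(raw_df, norm_df, delta, flags)


def timescale_table(
    system: CirculatorySystem,
    params: KineticParameters,
    t_first: float = 0.5,
    t_last: float = 24.0,
) -> TimescaleTable:
    """Equilibrium timescales per organ, flagged against the data window.

    ``tau_e = V_tot/(e B')`` (vascular localisation), ``tau_mu =
    V~/(e mu B')`` (interstitial return).  A vanishing ``e`` or ``mu``
    gives an infinite timescale, flagged beyond the last datum.
    """
    B_eff = effective_flows(system, params)
    V_tot = system.total_blood_volume
    rows = []
    for i, organ in enumerate(system.organs):
        e, mu = params.e[i], params.mu[i]
        with np.errstate(divide="ignore"):
            tau_e = V_tot / (e * B_eff[i]) if e > 0 and B_eff[i] > 0 else np.inf
            tau_mu = (
                organ.interstitial_volume / (e * mu * B_eff[i])
                if e > 0 and mu > 0 and B_eff[i] > 0
                else np.inf
            )

        def flag(tau: float) -> str:
            if tau < t_first:
                return FLAG_FAST
            if tau > t_last:
                return FLAG_SLOW
            return FLAG_IN

        rows.append(
            {
                "organ": organ.name,
                "tau_e_h": tau_e,
                "tau_mu_h": tau_mu,
                "flag_e": flag(tau_e),
                "flag_mu": flag(tau_mu),
            }
        )
    table = pd.DataFrame(rows)
    table = table.rename(columns={"tau_e_h": "tau_e", "tau_mu_h": "tau_mu"})
    return TimescaleTable(table, t_first, t_last)


def recovery_report(
    fit_params: KineticParameters,
    truth_params: KineticParameters,
    timescales: TimescaleTable | None = None,
) -> pd.DataFrame:
    """Per-parameter fitted/true ratios, ranked, with timescale flags.

    Columns: fitted, truth, ratio, abs_log10_ratio, timescale_flag (when
    a table is supplied).  The frame's ``attrs['summary']`` holds counts
    of parameters within 5%, 10% and 50% of truth.
    """
    if fit_params.organ_names != truth_params.organ_names:
        raise ValueError("parameter sets cover different organs")
    names = list(fit_params.names)
    fitted = fit_params.to_vector()
    truth = truth_params.to_vector()
    with np.errstate(divide="ignore"):
        ratio = fitted / truth
        abs_log = np.abs(np.log10(np.maximum(ratio, 1e-300)))
    frame = pd.DataFrame(
        {"parameter": names, "fitted": fitted, "truth": truth, "ratio": ratio,
         "abs_log10_ratio": abs_log}
    )
    if timescales is not None:
        flag_map = {}
        for _, row in timescales.table.iterrows():
            flag_map[f"e_{row['organ']}"] = row["flag_e"]
            flag_map[f"mu_{row['organ']}"] = row["flag_mu"]
        frame["timescale_flag"] = frame["parameter"].map(flag_map)
    frame = frame.sort_values("abs_log10_ratio", ascending=False).reset_index(
        drop=True
    )
    dev = np.abs(frame["ratio"] - 1.0)
    frame.attrs["summary"] = {
        "within_5pct": int((dev <= 0.05).sum()),
        "within_10pct": int((dev <= 0.10).sum()),
        "within_50pct": int((dev <= 0.50).sum()),
        "total": len(frame),
    }
    return frame


def grid_search_cost(
    n_levels: int = 3, n_params: int = 20, seconds_per_eval: float = 1.0
) -> GridSearchCost:
    """Cost of a naive full-factorial parameter grid.

    ``n_levels ** n_params`` model evaluations; with the defaults (three
    values per parameter, ten organs with two parameters each, one second
    per evaluation) that is 3.5e9 evaluations or about 110 years —
    the standing argument for gradient and sampling methods.
    """
    evaluations = float(n_levels) ** n_params
    seconds = evaluations * seconds_per_eval
    return GridSearchCost(evaluations, seconds, seconds / SECONDS_PER_YEAR)
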