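"""Multi-chain adaptive-covariance MCMC for trafficking parameters.

The recommended identifiability instrument: several Markov chains with
random starts are run until the Gelman-Rubin statistic R-hat (the ratio
of between-chain to within-chain variance) falls below a target, and the
spread of the chains — endpoint standard deviations and last-cycle
densities — is read as parameter uncertainty.  Peaked densities mark
well-identified parameters; diffuse or chain-dependent (multimodal)
densities mark practically unidentifiable ones.

Model and noise: measurements carry multiplicative Gaussian noise, so the
likelihood is Gaussian with per-datum standard deviation ``sigma * datum``
(zero data are excluded — they carry no proportional-noise information).
Parameters are sampled as log10 values with Gaussian priors centred on
the analytic initial estimates; the proposal is an adaptive random-walk
Metropolis whose covariance tracks the running sample covariance with a
decaying schedule and whose global scale is tuned toward a target
acceptance rate (Haario-style adaptation with an acceptance-rate
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LocalisationDataset
from .estimates import estimate_initial
from .fitting import FitOptions, ParameterMap, ScoreEngine
from .kinetics import KineticParameters
from .physiology import CirculatorySystem

__all__ = [
    "McmcOptions",
    "ChainSet",
    "PosteriorSummary",
    "GaussianLogPrior",
    "log_likelihood",
    "run_mcmc",
    "rhat",
    "posterior_summary",
    "sample_adaptive_chains",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class McmcOptions:
    """Sampler configuration (all randomness flows from ``seed``)."""

    n_chains: int = 3
    burn_in: int = 1000
    cycle_length: int = 5000
    rhat_target: float = 1.1
    max_cycles: int = 20
    target_acceptance: float = 0.23
    prior_sd_decades: float = 0.5  # +-1 sd spans one decade
    sigma: float = 0.1
    infer_sigma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        if self.rhat_target <= 1.0:
            raise ValueError("rhat_target must be > 1")


class GaussianLogPrior:
    """Independent Gaussians on the sampled (log10) coordinates, truncated
    to box bounds."""

    def __init__(self, center: np.ndarray, sd: np.ndarray, lower, upper):
        self.center = np.asarray(center, dtype=float)
        self.sd = np.broadcast_to(np.asarray(sd, dtype=float), self.center.shape)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)

    def logpdf(self, x: np.ndarray) -> float:
        if np.any(x < self.lower) or np.any(x > self.upper):
            return -np.inf
        z = (x - self.center) / self.sd
        return float(-0.5 * np.sum(z * z) - np.sum(np.log(self.sd)) -
                     0.5 * len(x) * _LOG_2PI)

    def sample(self, rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
        for _ in range(max_tries):
            x = rng.normal(self.center, self.sd)
            if np.all(x >= self.lower) and np.all(x <= self.upper):
                return x
        return np.clip(self.center, self.lower, self.upper)


# ---------------------------------------------------------------------------
# Likelihood


class _Likelihood:
    """Proportional-noise Gaussian likelihood over a dataset's points."""

    def __init__(self, system, dataset, dose=1.0):
        self.engine = ScoreEngine(system, dataset, dose)
        d = np.concatenate(self.engine.data_values)
        self.mask = d > 0
        self.n_excluded_zeros = int((~self.mask).sum())
        self.d = d[self.mask]

    def __call__(self, params: KineticParameters, sigma: float) -> float:
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        r = self.engine.residuals(params)[self.mask]
        sd = sigma * self.d
        return float(
            -np.sum(np.log(sd)) - 0.5 * len(sd) * _LOG_2PI
            - 0.5 * np.sum((r / sd) ** 2)
        )


def log_likelihood(
    system: CirculatorySystem,
    params: KineticParameters,
    dataset: LocalisationDataset,
    sigma: float = 0.1,
    dose: float = 1.0,
) -> float:
    """Gaussian log-likelihood with per-datum sd ``sigma * datum``.

    Data points equal to zero (e.g. the t = 0 organ rows) are excluded:
    proportional noise assigns them zero variance.
    """
    return _Likelihood(system, dataset, dose)(params, sigma)


# ---------------------------------------------------------------------------
# Adaptive-covariance random-walk Metropolis


@dataclass
class _ChainState:
    x: np.ndarray
    lp: float
    rng: np.random.Generator
    mu: np.ndarray = None  # type: ignore[assignment]
    cov: np.ndarray = None  # type: ignore[assignment]
    log_lambda: float = 0.0
    adapt_steps: int = 0
    accepted: int = 0
    total: int = 0

    def __post_init__(self):
        d = len(self.x)
        if self.mu is None:
            self.mu = self.x.copy()
        if self.cov is None:
            self.cov = np.eye(d) * 0.01  # 0.1-decade initial proposal sd


def _chain_step(state: _ChainState, log_post, d: int, adapt: bool, target: float):
    scale = np.exp(state.log_lambda) * (2.38**2 / d)
    cov = scale * (state.cov + 1e-12 * np.eye(d))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.sqrt(np.maximum(np.diag(cov), 1e-12))[:, None] * np.eye(d)
    prop = state.x + L @ state.rng.standard_normal(d)
    lp_prop = log_post(prop)
    if np.isfinite(lp_prop):
        alpha = min(1.0, float(np.exp(min(lp_prop - state.lp, 0.0))))
    else:
        alpha = 0.0  # never accept an impossible state
    if state.rng.random() < alpha:
        state.x = prop
        state.lp = lp_prop
        state.accepted += 1
    state.total += 1
    # the scalar proposal scale is tuned toward the target acceptance rate
    # from the first step (faster schedule than the covariance so a poorly
    # scaled start recovers within the burn-in)
    state.log_lambda += state.total ** -0.6 * (alpha - target)
    if adapt:
        # covariance tracks the running sample covariance with a diminishing
        # but responsive weight; a plain 1/n average freezes before the
        # soft directions of a stiff posterior have been discovered
        state.adapt_steps += 1
        eta = state.adapt_steps ** -0.7
        delta = state.x - state.mu
        state.mu = state.mu + eta * delta
        state.cov = state.cov + eta * (np.outer(delta, delta) - state.cov)


def sample_adaptive_chains(
    log_post,
    starts: list[np.ndarray],
    options: McmcOptions,
) -> "ChainSet":
    """Run adaptive-covariance Metropolis chains against any log-density.

    ``log_post`` maps a parameter vector to a log-posterior value.  Each
    chain burns in with a fixed proposal, then adapts its proposal
    covariance toward the running sample covariance (weight decaying as
    ``1/(n+1)`` past burn-in) and its scale toward the target acceptance
    rate.  After every cycle the per-parameter R-hat over the post-burn-in
    concatenation is computed; sampling stops at the target or at the
    cycle cap (flagged unconverged).
    """
    d = len(starts[0])
    root = np.random.default_rng(options.seed)
    chain_rngs = root.spawn(len(starts))
    states = [
        _ChainState(x=np.array(x, dtype=float), lp=log_post(np.asarray(x)), rng=rng)
        for x, rng in zip(starts, chain_rngs)
    ]
    for st in states:
        if not np.isfinite(st.lp):
            raise ValueError("chain start has non-finite log posterior")

    samples = [[] for _ in states]
    logps = [[] for _ in states]
    for st, buf, lbuf in zip(states, samples, logps):
        for _ in range(options.burn_in):
            _chain_step(st, log_post, d, adapt=False, target=options.target_acceptance)
            buf.append(st.x.copy())
            lbuf.append(st.lp)

    rhat_history: list[np.ndarray] = []
    converged = False
    n_cycles = 0
    for _ in range(options.max_cycles):
        for st, buf, lbuf in zip(states, samples, logps):
            for _ in range(options.cycle_length):
                _chain_step(
                    st, log_post, d, adapt=True, target=options.target_acceptance
                )
                buf.append(st.x.copy())
                lbuf.append(st.lp)
        n_cycles += 1
        post = [np.array(buf)[options.burn_in :] for buf in samples]
        rh = np.array([rhat([c[:, j] for c in post]) for j in range(d)])
        rhat_history.append(rh)
        if np.max(rh) <= options.rhat_target:
            converged = True
            break

    stuck = [
        i for i, st in enumerate(states) if st.accepted == 0 and st.total > 0
    ]
    return ChainSet(
        param_names=[f"x{j}" for j in range(d)],
        chains=[np.array(buf) for buf in samples],
        log_posteriors=[np.array(b) for b in logps],
        burn_in=options.burn_in,
        cycle_length=options.cycle_length,
        n_cycles=n_cycles,
        rhat_history=rhat_history,
        acceptance_rates=[st.accepted / max(st.total, 1) for st in states],
        converged=converged,
        flags={"stuck_chains": stuck} if stuck else {},
    )


def rhat(chains: list[np.ndarray]) -> float:
    """Gelman-Rubin statistic for one scalar parameter.

    ``W`` is the mean within-chain variance, ``B/n`` the variance of the
    chain means; ``R = sqrt(((n-1)/n W + B/n) / W)``.  Equals
    ``sqrt((n-1)/n)`` for identical chains and grows with between-chain
    separation; infinite (flagged by the caller) when chains have zero
    internal variance but distinct means.
    """
    m = len(chains)
    if m < 2:
        raise ValueError("need at least two chains")
    n = len(chains[0])
    if n < 2 or any(len(c) != n for c in chains):
        raise ValueError("chains must share a common length >= 2")
    W = float(np.mean([np.var(c, ddof=1) for c in chains]))
    B_over_n = float(np.var([np.mean(c) for c in chains], ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


# ---------------------------------------------------------------------------
# Chain containers and summaries


@dataclass
class ChainSet:
    """Samples from every chain (in the sampled log10 coordinates)."""

    param_names: list[str]
    chains: list[np.ndarray]  # (n_iterations, d) each, burn-in included
    log_posteriors: list[np.ndarray]
    burn_in: int
    cycle_length: int
    n_cycles: int
    rhat_history: list[np.ndarray]
    acceptance_rates: list[float]
    converged: bool
    flags: dict = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        return float(np.max(self.rhat_history[-1]))

    def post_burn(self, i: int) -> np.ndarray:
        return self.chains[i][self.burn_in :]

    def last_cycle(self, i: int) -> np.ndarray:
        return self.chains[i][-self.cycle_length :]

    def last_cycle_natural(self, i: int) -> np.ndarray:
        return 10.0 ** self.last_cycle(i)

    def endpoint_natural(self) -> np.ndarray:
        """(n_chains, d) natural-scale final samples of each chain."""
        return 10.0 ** np.array([c[-1] for c in self.chains])

    def best_sample(self) -> tuple[np.ndarray, float]:
        """Natural-scale sample with the highest log posterior anywhere."""
        best_lp, best_x = -np.inf, None
        for c, lp in zip(self.chains, self.log_posteriors):
            j = int(np.argmax(lp))
            if lp[j] > best_lp:
                best_lp, best_x = float(lp[j]), c[j]
        return 10.0**best_x, best_lp

    def to_csv(self, directory, prefix: str = "chain") -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, c in enumerate(self.chains):
            frame = pd.DataFrame(10.0**c, columns=self.param_names)
            frame["log_posterior"] = self.log_posteriors[i]
            frame.to_csv(directory / f"{prefix}_{i}.csv", index=False)


@dataclass
class PosteriorSummary:
    """Endpoint spreads, best sample and last-cycle density shape."""

    table: pd.DataFrame  # per parameter: best, endpoint_mean/sd, shape, ...
    converged: bool
    max_rhat: float

    @property
    def coverage_fraction(self) -> float | None:
        if "covered" not in self.table.columns:
            return None
        return float(self.table["covered"].mean())


# density-shape heuristics (log10 decades)
_PEAK_IQR = 0.25  # pooled last-cycle IQR below this = peaked
_MODE_SPLIT = 0.2  # chain medians further apart than this (and > IQR) = multimodal


def posterior_summary(
    chainset: ChainSet,
    truth: dict[str, float] | None = None,
) -> PosteriorSummary:
    """Summarise a chain set the way the uncertainty readout is used.

    Per parameter: the best (highest-posterior) sample, the mean and
    standard deviation of the chains' endpoint values (the headline
    uncertainty band), and a last-cycle density classification —
    ``peaked`` (pooled log10 IQR below 0.25 decades), ``multimodal``
    (chain medians disagree by more than the pooled IQR and 0.2 decades)
    or ``diffuse``.  With ``truth`` given, adds whether the endpoint band
    around the best sample covers the true value.
    """
    names = chainset.param_names
    endpoints = chainset.endpoint_natural()
    best, best_lp = chainset.best_sample()
    pooled = np.concatenate(
        [chainset.last_cycle(i) for i in range(len(chainset.chains))]
    )
    rows = []
    for j, name in enumerate(names):
        q1, q3 = np.percentile(pooled[:, j], [25, 75])
        iqr = float(q3 - q1)
        medians = [float(np.median(chainset.last_cycle(i)[:, j]))
                   for i in range(len(chainset.chains))]
        spread = float(np.max(medians) - np.min(medians))
        if spread > max(_MODE_SPLIT, iqr):
            shape = "multimodal"
        elif iqr <= _PEAK_IQR:
            shape = "peaked"
        else:
            shape = "diffuse"
        row = {
            "parameter": name,
            "best": float(best[j]),
            "endpoint_mean": float(np.mean(endpoints[:, j])),
            "endpoint_sd": float(np.std(endpoints[:, j], ddof=1)),
            "last_cycle_iqr_log10": iqr,
            "chain_median_spread_log10": spread,
            "density_shape": shape,
        }
        if truth is not None and name in truth:
            row["truth"] = truth[name]
            row["covered"] = bool(
                abs(best[j] - truth[name]) <= row["endpoint_sd"]
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["best_log_posterior"] = best_lp
    return PosteriorSummary(table, chainset.converged, chainset.max_rhat)


# ---------------------------------------------------------------------------
# The full fit


def run_mcmc(
    system: CirculatorySystem,
    dataset: LocalisationDataset,
    priors: GaussianLogPrior | None = None,
    options: McmcOptions | None = None,
    init: KineticParameters | None = None,
    dose: float = 1.0,
) -> ChainSet:
    """MCMC fit of the trafficking model to a localisation dataset.

    Free parameters (censored organs lumped, fixed entries held) are
    sampled as log10 values.  Priors default to Gaussians of sd
    ``prior_sd_decades`` centred on the analytic initial estimates; each
    chain starts at an independent prior draw.  With ``infer_sigma`` the
    noise level joins the sampled parameters (Gaussian prior on log10
    sigma centred on ``options.sigma``); otherwise sigma is fixed.
    Returns the chains with R-hat history; unconverged runs are returned
    (not raised) with ``converged = False``.
    """
    options = options or McmcOptions()
    if init is None:
        init = estimate_initial(dataset, system, dose)
    pmap = ParameterMap(system, dataset, init)
    bounds = pmap.log_bounds(FitOptions())
    center = np.log10(np.maximum(pmap.pack(init), 1e-6))
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])
    names = list(pmap.names)
    sd = np.full(len(names), options.prior_sd_decades)

    if options.infer_sigma:
        names = names + ["sigma"]
        center = np.concatenate([center, [np.log10(options.sigma)]])
        sd = np.concatenate([sd, [options.prior_sd_decades]])
        lower = np.concatenate([lower, [-4.0]])
        upper = np.concatenate([upper, [1.0]])

    if priors is None:
        priors = GaussianLogPrior(np.clip(center, lower, upper), sd, lower, upper)

    lik = _Likelihood(system, dataset, dose)
    n_free = len(pmap.names)

    def log_post(x: np.ndarray) -> float:
        lp = priors.logpdf(x)
        if not np.isfinite(lp):
            return -np.inf
        theta = 10.0 ** x[:n_free]
        sigma = 10.0 ** x[n_free] if options.infer_sigma else options.sigma
        params = pmap.apply(init, theta)
        return lp + lik(params, sigma)

    start_rng = np.random.default_rng(options.seed + 1_000_003)
    starts = []
    for _ in range(options.n_chains):
        for _ in range(200):
            x = priors.sample(start_rng)
            if np.isfinite(log_post(x)):
                break
        starts.append(x)

    chainset = sample_adaptive_chains(log_post, starts, options)
    chainset.param_names = names
    return chainset
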