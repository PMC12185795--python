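"""Multi-chain adaptive random-walk Metropolis with convergence diagnostics.

The sampler is a Gaussian random-walk Metropolis kernel whose proposal scales
are adapted during burn-in only (Robbins-Monro on the log scale, frozen
afterwards so the post-burn-in kernel is a valid fixed Metropolis kernel).
Two proposal modes:

* ``componentwise`` (default) - one univariate update per coordinate per
  iteration, adaptation targeting 44% acceptance per coordinate.  Used for
  the low-dimensional two-group (unadjusted) posterior.
* ``joint`` - a single multivariate proposal per iteration with a fixed shape
  matrix (typically the MLE covariance) and a global adapted scale targeting
  23.4% acceptance.  One likelihood pass per iteration, which is what makes
  the adjusted-model simulation study affordable.

Each chain draws from an independent substream spawned from the master seed,
so results are reproducible and extending ``n_iter`` does not perturb earlier
draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DegenerateChainError, MixingFailureError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 12_500
    burn_in: int = 2_500
    n_chains: int = 4
    seed: int = 0
    thinning: int = 1
    adapt_target_acceptance: float | None = None  # mode-dependent default
    init_strategy: str = "mle"  # {"mle", "zeros", "prior_draw"}
    proposal: str = "componentwise"  # {"componentwise", "joint"}

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.n_chains < 2:
            raise ValueError("n_chains >= 2 required for convergence diagnostics")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.proposal not in ("componentwise", "joint"):
            raise ValueError("proposal must be 'componentwise' or 'joint'")

    @property
    def target_acceptance(self) -> float:
        if self.adapt_target_acceptance is not None:
            return self.adapt_target_acceptance
        return 0.44 if self.proposal == "componentwise" else 0.234

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thinning


def analysis_preset(seed: int = 0, **overrides) -> McmcConfig:
    """The published analysis settings: 4 chains x 12,500, burn-in 2,500."""
    return replace(McmcConfig(seed=seed), **overrides)


def diagnostic_preset(seed: int = 0, **overrides) -> McmcConfig:
    """The published convergence-check settings: 4 chains x 10,000 iterations."""
    return replace(McmcConfig(n_iter=10_000, burn_in=2_500, seed=seed), **overrides)


@dataclass
class ChainSet:
    """Post-burn-in draws from all chains, shape (n_chains, n_kept, dim)."""

    draws: np.ndarray
    acceptance_rates: np.ndarray
    config: McmcConfig
    param_names: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    @property
    def dim(self) -> int:
        return self.draws.shape[2]

    def pooled(self, index: int = 0) -> np.ndarray:
        """All post-burn-in draws of one parameter, pooled across chains."""
        return self.draws[:, :, index].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        names = self.param_names or [f"beta{i}" for i in range(self.dim)]
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=names)
            df.insert(0, "chain", c)
            df.insert(1, "draw", np.arange(self.n_kept))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class ConvergenceReport:
    psrf: np.ndarray
    max_rc: float
    ess: np.ndarray
    passed: bool
    threshold: float = 1.1


# ---------------------------------------------------------------------------
# sampling


def _chain_init(
    init: np.ndarray | None, dim: int, rng: np.random.Generator, jitter_sd: np.ndarray
) -> np.ndarray:
    if init is None:
        x0 = np.zeros(dim)
    else:
        x0 = np.array(init, dtype=float)
    return x0 + jitter_sd * rng.standard_normal(dim)


def run_chains(
    logpost: Callable[[np.ndarray], float],
    dim: int,
    config: McmcConfig,
    init: np.ndarray | None = None,
    init_jitter_sd: np.ndarray | float | None = None,
    proposal_scale: np.ndarray | float | None = None,
    proposal_cov: np.ndarray | None = None,
    param_names: list[str] | None = None,
) -> ChainSet:
    """Sample the target with ``config.n_chains`` independent chains.

    ``init`` is the common starting point (e.g. the MLE); each chain jitters
    it with N(0, init_jitter_sd^2) noise from its own substream.  The initial
    log-posterior must be finite for every chain.
    """
    target = config.target_acceptance
    if proposal_scale is None:
        base_scale = np.full(dim, 0.1)
    else:
        base_scale = np.broadcast_to(
            np.asarray(proposal_scale, dtype=float), (dim,)
        ).copy()
    if init_jitter_sd is None:
        jitter = 0.1 * base_scale
    else:
        jitter = np.broadcast_to(np.asarray(init_jitter_sd, dtype=float), (dim,)).copy()

    L = None
    if config.proposal == "joint":
        cov = np.eye(dim) if proposal_cov is None else np.asarray(proposal_cov)
        L = np.linalg.cholesky(cov)

    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    draws = np.empty((config.n_chains, config.n_kept, dim))
    acc_rates = np.empty(config.n_chains)

    for c in range(config.n_chains):
        rng = np.random.default_rng(children[c])
        x = _chain_init(init, dim, rng, jitter)
        lp = float(logpost(x))
        if not np.isfinite(lp):
            raise ValueError(f"chain {c}: initial log-posterior not finite")
        if config.proposal == "componentwise":
            acc_rates[c] = _run_componentwise(
                logpost, x, lp, rng, config, target, base_scale, draws[c], c
            )
        else:
            acc_rates[c] = _run_joint(
                logpost, x, lp, rng, config, target, base_scale, L, draws[c], c
            )
    return ChainSet(
        draws=draws,
        acceptance_rates=acc_rates,
        config=config,
        param_names=list(param_names) if param_names else [],
    )


def _check_burnin_mixing(accepted: int, proposed: int, chain: int) -> None:
    if proposed and accepted / proposed < 0.01:
        raise MixingFailureError(
            f"chain {chain}: burn-in acceptance {accepted}/{proposed} < 1%; "
            "the target may be degenerate or the proposal scale pathological"
        )


def _run_componentwise(logpost, x, lp, rng, config, target, base_scale, out, chain):
    dim = x.shape[0]
    log_s = np.log(base_scale)
    acc_burn = prop_burn = acc_post = prop_post = 0
    kept = 0
    for t in range(1, config.n_iter + 1):
        adapting = t <= config.burn_in
        gamma = t ** -0.6 if adapting else 0.0
        for j in range(dim):
            xp = x.copy()
            xp[j] += np.exp(log_s[j]) * rng.standard_normal()
            lpp = float(logpost(xp))
            accept = np.log(rng.random()) < lpp - lp
            if accept:
                x, lp = xp, lpp
            if adapting:
                prop_burn += 1
                acc_burn += accept
                log_s[j] += gamma * (float(accept) - target)
            else:
                prop_post += 1
                acc_post += accept
        if t == config.burn_in:
            _check_burnin_mixing(acc_burn, prop_burn, chain)
        if t > config.burn_in and (t - config.burn_in) % config.thinning == 0:
            out[kept] = x
            kept += 1
    return acc_post / prop_post if prop_post else acc_burn / max(prop_burn, 1)


def _run_joint(logpost, x, lp, rng, config, target, base_scale, L, out, chain):
    dim = x.shape[0]
    log_s = float(np.log(np.mean(base_scale)))
    acc_burn = prop_burn = acc_post = prop_post = 0
    kept = 0
    for t in range(1, config.n_iter + 1):
        adapting = t <= config.burn_in
        xp = x + np.exp(log_s) * (L @ rng.standard_normal(dim))
        lpp = float(logpost(xp))
        accept = np.log(rng.random()) < lpp - lp
        if accept:
            x, lp = xp, lpp
        if adapting:
            prop_burn += 1
            acc_burn += accept
            log_s += t ** -0.6 * (float(accept) - target)
        else:
            prop_post += 1
            acc_post += accept
        if t == config.burn_in:
            _check_burnin_mixing(acc_burn, prop_burn, chain)
        if t > config.burn_in and (t - config.burn_in) % config.thinning == 0:
            out[kept] = x
            kept += 1
    return acc_post / prop_post if prop_post else acc_burn / max(prop_burn, 1)


# ---------------------------------------------------------------------------
# diagnostics


def _as_3d(draws) -> np.ndarray:
    arr = draws.draws if isinstance(draws, ChainSet) else np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :, None]
    elif arr.ndim == 2:
        arr = arr[None, :, :]
    return arr


def gelman_rubin(chains, split: bool = False, threshold: float = 1.1) -> ConvergenceReport:
    """Potential scale reduction factor Rc per parameter.

    Rc = sqrt( ((n-1)/n * W + B/n) / W ) with W the mean within-chain variance
    and B/n the between-chain variance of the chain means.  ``split=True``
    halves every chain first (the split-Rhat variant).
    """
    arr = _as_3d(chains)
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half, :], arr[:, half : 2 * half, :]], axis=0)
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    within = arr.var(axis=1, ddof=1)  # (m, d)
    if np.any(np.all(within == 0, axis=0)):
        raise DegenerateChainError("zero within-chain variance")
    W = within.mean(axis=0)
    B_over_n = arr.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    psrf = np.sqrt(var_plus / W)
    ess = effective_sample_size(arr)
    max_rc = float(psrf.max())
    return ConvergenceReport(
        psrf=psrf,
        max_rc=max_rc,
        ess=np.asarray(ess),
        passed=bool(max_rc < threshold),
        threshold=threshold,
    )


def _ess_single(x: np.ndarray) -> float:
    n = x.shape[0]
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        raise DegenerateChainError("constant chain: ESS undefined")
    # autocorrelations via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence on consecutive pairs
    tau = 1.0
    t = 1
    while t + 1 < n:
        g = rho[t] + rho[t + 1]
        if g < 0:
            break
        tau += 2.0 * g
        t += 2
    return min(float(n), n / tau)


def effective_sample_size(draws) -> np.ndarray | float:
    """Initial-positive-sequence ESS, summed over chains, per parameter.

    Accepts a ChainSet, a (chains, draws, dim) array, a (draws, dim) array or
    a 1-d draw vector (>= 100 draws); never exceeds the total draw count.
    """
    scalar = not isinstance(draws, ChainSet) and np.asarray(draws).ndim == 1
    arr = _as_3d(draws)
    m, n, d = arr.shape
    if n < 100:
        raise ValueError("need >= 100 draws for an ESS estimate")
    ess = np.zeros(d)
    for j in range(d):
        ess[j] = sum(_ess_single(arr[c, :, j]) for c in range(m))
    return float(ess[0]) if scalar else ess
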