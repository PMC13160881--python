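"""Hierarchical Bayesian shrinkage-prior fitting by MCMC.

Voxel parameters theta_i and per-ROI prior hyperparameters (mu_k,
Sigma_k) are sampled jointly from

    p(theta, mu, Sigma | y)  propto  prod_i p(y_i | theta_i)
                                     * prod_i N(theta_i; mu_k(i), Sigma_k(i))
                                     * prod_k p(mu_k, Sigma_k)

by alternating exact Gibbs draws of each ROI's (mu_k, Sigma_k) with
component-wise Metropolis-Hastings random-walk updates of every voxel's
parameters.  The Gaussian shrinkage prior lives in an unbounded
sampling space reached by a per-parameter scaled-logit transform of the
fitting bounds, which guarantees that every sample -- and hence every
posterior summary -- respects the bounds.

Modelling choices
-----------------
* Prior space: the Gaussian shrinkage prior is defined on the *native*
  (physical-unit) parameters, restricted to the fitting bounds -- a
  bound-truncated Gaussian.  Sampling runs in the unbounded logit
  space, so the MH ratio carries the transform Jacobian.  Defining the
  prior on the transformed parameters instead is tempting but unstable:
  voxels whose likelihood pins them at a bound sit tens of prior SDs
  out in logit space, inflate the Gibbs covariance draw, flatten the
  prior and freeze the whole ROI in a no-shrinkage equilibrium.
* Likelihood: Gaussian residuals with the per-voxel noise variance
  marginalised under a Jeffreys scale prior, giving
  ``log p(y|theta) = -(N/2) ln RSS(theta) + const``.
* Hyperprior: noninformative normal-inverse-Wishart limit with
  nu0 = p + 1 degrees of freedom and scale Psi0 = 1e-6 I, so the
  conditionals stay proper even for tiny or degenerate ROIs.
* Proposal adaptation: per-voxel, per-parameter random-walk widths are
  rescaled every 100 steps during the first half of burn-in toward a
  target acceptance of 0.25 and frozen afterwards, so all retained
  samples come from a fixed kernel.

Posterior summaries are running means of the *native-space*
(back-transformed) samples, so maps are in the model's physical units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .lsq import LsqConfig, VolumeFitResult, fit_volume
from .signal_models import AcquisitionScheme, ModelSpec, normalize_signals

__all__ = [
    "ParameterTransform",
    "BSPState",
    "ChainConfig",
    "PosteriorSummary",
    "log_likelihood",
    "gibbs_update_prior",
    "mh_update_voxel",
    "adapt_proposals",
    "init_chain",
    "run_chain",
]

logger = logging.getLogger(__name__)

_RSS_FLOOR_PER_VOLUME = 1e-12
_FRAC_CLIP = 1e-9  # keeps the logit finite for values at/over the bounds


# ---------------------------------------------------------------------------
# bounded <-> unbounded sampling space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterTransform:
    """Per-parameter scaled-logit map between (lb, ub) and the real line.

    ``u = log((x - lb) / (ub - x))`` with inverse
    ``x = lb + (ub - lb) * sigmoid(u)``; strictly increasing, with
    log-Jacobian ``log dx/du = log(ub - lb) + log sig + log(1 - sig)``.
    """

    lb: np.ndarray
    ub: np.ndarray

    @classmethod
    def for_model(cls, model: ModelSpec) -> "ParameterTransform":
        return cls(lb=model.lb, ub=model.ub)

    def to_unbounded(self, x: np.ndarray) -> np.ndarray:
        frac = (np.asarray(x, dtype=float) - self.lb) / (self.ub - self.lb)
        frac = np.clip(frac, _FRAC_CLIP, 1.0 - _FRAC_CLIP)
        return np.log(frac) - np.log1p(-frac)

    def to_native(self, u: np.ndarray) -> np.ndarray:
        sig = _sigmoid(np.asarray(u, dtype=float))
        return self.lb + (self.ub - self.lb) * sig

    def dx_du(self, u: np.ndarray) -> np.ndarray:
        sig = _sigmoid(np.asarray(u, dtype=float))
        return (self.ub - self.lb) * sig * (1.0 - sig)

    def log_jacobian(self, u: np.ndarray) -> np.ndarray:
        return np.log(self.dx_du(u)).sum(axis=-1)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u, dtype=float)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class BSPState:
    """Per-ROI shrinkage-prior mean vectors and covariances (native space)."""

    mu: np.ndarray     # (K, p)
    sigma: np.ndarray  # (K, p, p), symmetric positive definite

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim == 2:
            self.sigma = self.sigma[None]
        K, p = self.mu.shape
        if self.sigma.shape != (K, p, p):
            raise ValueError("sigma shape must be (K, p, p)")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule and numerical settings.

    ``n_burn`` defaults to ``n_steps // 2``; proposal widths adapt
    every ``adapt_every`` steps during the first half of burn-in and
    are frozen afterwards.
    """

    n_steps: int = 100_000
    n_burn: Optional[int] = None
    adapt_every: int = 100
    target_accept: float = 0.25
    adapt_clip: tuple[float, float] = (0.5, 2.0)
    init_width_frac: float = 0.1
    nu0: Optional[int] = None       # default p + 1
    psi0_scale: float = 1e-6
    seed: int = 0
    log_every: int = 1000
    progress: bool = False

    def resolved_burn(self) -> int:
        n_burn = self.n_steps // 2 if self.n_burn is None else self.n_burn
        if not 0 < n_burn < self.n_steps:
            raise ValueError("need 0 < n_burn < n_steps")
        return n_burn


@dataclass
class PosteriorSummary:
    """Posterior-mean maps, per-ROI prior summaries and diagnostics."""

    mean_maps: dict[str, np.ndarray]
    sd_maps: dict[str, np.ndarray]
    prior_summary: pd.DataFrame     # roi, parameter, prior_mean, prior_sd
    acceptance_map: np.ndarray      # mean post-adaptation acceptance per voxel
    bsp: BSPState                   # final hyperparameter state
    n_steps: int
    n_burn: int
    n_kept: int
    model_name: str = ""
    param_names: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def log_likelihood(
    y: Optional[np.ndarray],
    theta_native: np.ndarray,
    scheme: AcquisitionScheme,
    model: ModelSpec,
) -> np.ndarray:
    """Marginal Gaussian log-likelihood, up to a theta-independent constant.

    With the noise variance integrated out under a Jeffreys prior,
    ``log p(y|theta) = -(N/2) ln RSS(theta) + const``.  ``y`` may have
    any leading shape matching ``theta_native``; ``None`` (no data)
    gives a flat likelihood.  The RSS is floored at ``1e-12 * N`` to
    guard exact fits.
    """
    if y is None:
        return np.zeros(np.asarray(theta_native).shape[:-1])
    y = np.asarray(y, dtype=float)
    pred = model.predict(theta_native, scheme)
    r = y - pred
    rss = np.einsum("...i,...i->...", r, r)
    n = y.shape[-1]
    if n == 0:
        return np.zeros_like(rss)
    return -0.5 * n * np.log(np.maximum(rss, _RSS_FLOOR_PER_VOLUME * n))


def gibbs_update_prior(
    theta_u: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
    nu0: Optional[int] = None,
    psi0_scale: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """One exact Gibbs draw of (mu_k, Sigma_k) for a single ROI.

    ``theta_u`` holds the ROI's current voxel parameters in sampling
    space, shape (I_k, p) with I_k >= 2.  mu is drawn from its full
    conditional ``N(theta_bar, Sigma / I_k)`` (flat mean hyperprior),
    then Sigma from ``InvWishart(nu0 + I_k, Psi0 + S(mu))`` with
    ``S(mu) = sum_i (theta_i - mu)(theta_i - mu)^T``.
    """
    theta_u = np.atleast_2d(np.asarray(theta_u, dtype=float))
    I_k, p = theta_u.shape
    if I_k < 2:
        raise ValueError("ROI needs at least 2 voxels for a Gibbs update")
    nu0 = p + 1 if nu0 is None else int(nu0)
    psi0 = psi0_scale * np.eye(p)

    mean = theta_u.mean(axis=0)
    chol = _safe_cholesky(np.asarray(sigma, dtype=float) / I_k)
    mu = mean + chol @ rng.standard_normal(p)

    dev = theta_u - mu
    scale = psi0 + dev.T @ dev
    scale = 0.5 * (scale + scale.T)
    try:
        sigma_new = invwishart.rvs(df=nu0 + I_k, scale=scale, random_state=rng)
    except np.linalg.LinAlgError:
        scale = scale + 1e-10 * np.eye(p)
        sigma_new = invwishart.rvs(df=nu0 + I_k, scale=scale, random_state=rng)
    sigma_new = np.atleast_2d(sigma_new)
    sigma_new = 0.5 * (sigma_new + sigma_new.T)
    return mu, sigma_new


def _safe_cholesky(a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        p = a.shape[0]
        jitter = 1e-10 * max(1.0, float(np.trace(a)) / p)
        for _ in range(10):
            try:
                return np.linalg.cholesky(a + jitter * np.eye(p))
            except np.linalg.LinAlgError:
                jitter *= 10.0
        raise


def mh_update_voxel(
    theta_u: np.ndarray,
    y: Optional[np.ndarray],
    mu: np.ndarray,
    sigma: np.ndarray,
    widths: np.ndarray,
    rng: np.random.Generator,
    scheme: AcquisitionScheme,
    model: ModelSpec,
    transform: Optional[ParameterTransform] = None,
    loglik_fn=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Component-wise MH random-walk update of voxels sharing one prior.

    ``theta_u`` has shape (V, p) in (unbounded) sampling space, ``y``
    shape (V, N) (or ``None`` for a flat likelihood), ``widths`` shape
    (V, p).  Each parameter is perturbed by a symmetric Gaussian
    proposal in sampling space and accepted with the likelihood ratio
    times the native-space prior-density ratio under N(mu, sigma)
    times the transform Jacobian ratio (the prior lives on the native
    parameters; the walk does not).  Returns
    (new theta_u, accepted flags (V, p)).

    ``loglik_fn`` optionally replaces the marginal likelihood with a
    custom ``f(theta_native) -> (V,)`` log density (e.g. a known-noise
    Gaussian), which the cross-checks against closed-form posteriors
    rely on.
    """
    transform = transform or ParameterTransform.for_model(model)
    theta_u = np.atleast_2d(np.asarray(theta_u, dtype=float)).copy()
    V, p = theta_u.shape
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (V, p))
    mu = np.asarray(mu, dtype=float)
    lam = np.linalg.inv(np.asarray(sigma, dtype=float))
    theta_x = transform.to_native(theta_u)
    if loglik_fn is None:
        loglik_fn = lambda tx: log_likelihood(y, tx, scheme, model)  # noqa: E731
    ll = loglik_fn(theta_x)
    accepted = np.zeros((V, p), dtype=bool)
    rng_span = transform.ub - transform.lb
    for j in range(p):
        step = widths[:, j] * rng.standard_normal(V)
        prop_uj = theta_u[:, j] + step
        sig_prop = _sigmoid(prop_uj)
        prop_x = theta_x.copy()
        prop_x[:, j] = transform.lb[j] + rng_span[j] * sig_prop
        ll_prop = loglik_fn(prop_x)
        d = theta_x - mu
        delta = prop_x[:, j] - theta_x[:, j]
        qlin = d @ lam[j]
        dquad = 2.0 * delta * qlin + delta**2 * lam[j, j]
        sig_cur = (theta_x[:, j] - transform.lb[j]) / rng_span[j]
        with np.errstate(divide="ignore"):
            djac = np.log(sig_prop * (1.0 - sig_prop)) - np.log(
                sig_cur * (1.0 - sig_cur)
            )
        log_alpha = (ll_prop - ll) - 0.5 * dquad + djac
        acc = np.log(rng.random(V)) < log_alpha
        theta_u[acc, j] = prop_uj[acc]
        theta_x[acc, j] = prop_x[acc, j]
        ll = np.where(acc, ll_prop, ll)
        accepted[:, j] = acc
    return theta_u, accepted


def adapt_proposals(
    accept_counts: np.ndarray,
    window: int,
    widths: np.ndarray,
    target: float = 0.25,
    clip: tuple[float, float] = (0.5, 2.0),
) -> np.ndarray:
    """Rescale proposal widths toward the target acceptance rate.

    Each width is multiplied by ``(observed + 0.1) / (target + 0.1)``,
    clipped to ``clip`` per update; the +0.1 regularisation keeps dead
    proposals recoverable.  Only called during the adaptation phase.
    """
    rate = np.asarray(accept_counts, dtype=float) / window
    factor = np.clip((rate + 0.1) / (target + 0.1), clip[0], clip[1])
    return widths * factor


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------


def init_chain(
    lsq_result: VolumeFitResult,
    labels: np.ndarray,
    model: ModelSpec,
    transform: ParameterTransform,
    init_width_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, BSPState, np.ndarray, list[int]]:
    """Initial chain state from the voxelwise least-squares fit.

    Voxel parameters start at the transformed LSQ values (non-finite
    fits replaced by their ROI mean); each ROI's prior starts at the
    mean and *diagonal* covariance of its native-space fits; proposal
    widths start at ``init_width_frac`` times the per-ROI SD of the
    transformed fits.  Degenerate (zero-spread) ROIs are floored so
    the initial covariance stays positive definite.
    """
    labels = np.asarray(labels)
    mask = labels > 0
    lab_v = labels[mask]
    roi_ids = sorted(int(k) for k in np.unique(lab_v))
    p = model.n_params

    theta_nat = np.stack(
        [np.asarray(lsq_result.maps[name])[mask] for name in model.param_names], axis=-1
    )
    for k in roi_ids:
        sel = lab_v == k
        block = theta_nat[sel]
        for j in range(p):
            col = block[:, j]
            bad = ~np.isfinite(col)
            if bad.any():
                good = col[~bad]
                if good.size == 0:
                    raise ValueError(f"ROI {k} has no finite LSQ fit for "
                                     f"{model.param_names[j]!r}")
                col[bad] = good.mean()
                block[:, j] = col
        theta_nat[sel] = block

    theta_u = transform.to_unbounded(theta_nat)
    V = theta_u.shape[0]
    mu = np.zeros((len(roi_ids), p))
    sigma = np.zeros((len(roi_ids), p, p))
    widths = np.zeros((V, p))
    scale = (transform.ub - transform.lb) ** 2
    for ki, k in enumerate(roi_ids):
        sel = lab_v == k
        nat = theta_nat[sel]
        mu[ki] = nat.mean(axis=0)
        var = nat.var(axis=0, ddof=1) if sel.sum() > 1 else np.zeros(p)
        var = np.maximum(var, 1e-10 * scale)  # floor degenerate ROIs
        sigma[ki] = np.diag(var)
        u_sd = theta_u[sel].std(axis=0, ddof=1) if sel.sum() > 1 else np.zeros(p)
        widths[sel] = init_width_frac * np.maximum(u_sd, 1e-3)
    return theta_u, widths, BSPState(mu=mu, sigma=sigma), lab_v, roi_ids


def run_chain(
    data: np.ndarray,
    labels: np.ndarray,
    scheme: AcquisitionScheme,
    model: ModelSpec,
    config: ChainConfig | None = None,
    init: Optional[VolumeFitResult] = None,
    lsq_config: Optional[LsqConfig] = None,
    normalize: bool = True,
) -> PosteriorSummary:
    """Run the full Metropolis-Hastings-within-Gibbs sampler on a volume.

    ``data`` has shape ``(*grid, N)``, ``labels`` shape ``(*grid,)``
    with 0 = background; each positive label defines one regional
    prior (a single label = one global prior).  If ``init`` is not
    given the multistart least-squares fit is computed first.

    Per step: one Gibbs draw of every ROI's (mu_k, Sigma_k), then one
    component-wise MH sweep over all voxels.  After burn-in, running
    means of the native-space voxel parameters and of the
    back-transformed prior means are accumulated; nothing else is
    stored, so memory stays at a few arrays of size (voxels, p).
    Deterministic given ``config.seed``.
    """
    config = config or ChainConfig()
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.shape[:-1] != labels.shape:
        raise ValueError("data grid does not match labels")
    model.validate_scheme(scheme)
    if normalize:
        data = normalize_signals(data, scheme, model)
    if init is None:
        init = fit_volume(data, labels, scheme, model, lsq_config, normalize=False)

    n_steps = int(config.n_steps)
    n_burn = config.resolved_burn()
    adapt_until = n_burn // 2
    if adapt_until % config.adapt_every != 0:
        adapt_until -= adapt_until % config.adapt_every

    transform = ParameterTransform.for_model(model)
    theta_u, widths, bsp, lab_v, roi_ids = init_chain(
        init, labels, model, transform, config.init_width_frac
    )
    mask = labels > 0
    Y = data[mask]
    V, p = theta_u.shape
    N = Y.shape[-1]
    nu0 = p + 1 if config.nu0 is None else config.nu0
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    roi_index = {k: i for i, k in enumerate(roi_ids)}
    lab_i = np.array([roi_index[k] for k in lab_v])
    members = [np.nonzero(lab_i == i)[0] for i in range(len(roi_ids))]
    for i, k in enumerate(roi_ids):
        if members[i].size < 2:
            raise ValueError(f"ROI {k} has fewer than 2 voxels")

    theta_x = transform.to_native(theta_u)
    pred = model.predict(theta_x, scheme)
    r = Y - pred
    rss = np.einsum("ij,ij->i", r, r)
    rss_floor = _RSS_FLOOR_PER_VOLUME * N
    ll = -0.5 * N * np.log(np.maximum(rss, rss_floor))

    win_acc = np.zeros((V, p))
    post_acc = np.zeros((V, p))
    post_acc_steps = 0
    sum_x = np.zeros((V, p))
    sum_x2 = np.zeros((V, p))
    sum_mu_nat = np.zeros((len(roi_ids), p))
    sum_sd_nat = np.zeros((len(roi_ids), p))
    n_kept = 0

    lb, ub = transform.lb, transform.ub
    steps_iter = range(1, n_steps + 1)
    if config.progress:
        from tqdm import tqdm

        steps_iter = tqdm(steps_iter, desc=f"hbm:{model.name}", unit="step")

    for s in steps_iter:
        # ---- Gibbs sweep over ROI hyperparameters (native space)
        for i in range(len(roi_ids)):
            mu_i, sig_i = gibbs_update_prior(
                theta_x[members[i]], bsp.sigma[i], rng, nu0, config.psi0_scale
            )
            bsp.mu[i] = mu_i
            bsp.sigma[i] = sig_i
        lam = np.linalg.inv(bsp.sigma)              # (K, p, p)
        mu_v = bsp.mu[lab_i]                        # (V, p)

        # ---- component-wise MH sweep over voxels (random walk in logit
        # space; prior density and Jacobian evaluated in native space)
        for j in range(p):
            step = widths[:, j] * rng.standard_normal(V)
            prop_uj = theta_u[:, j] + step
            sig_prop = _sigmoid(prop_uj)
            prop_xj = lb[j] + (ub[j] - lb[j]) * sig_prop
            prop_x = theta_x.copy()
            prop_x[:, j] = prop_xj
            pred = model.predict(prop_x, scheme)
            r = Y - pred
            rss_prop = np.einsum("ij,ij->i", r, r)
            ll_prop = -0.5 * N * np.log(np.maximum(rss_prop, rss_floor))
            d = theta_x - mu_v
            delta = prop_xj - theta_x[:, j]
            lam_j = lam[lab_i, j, :]                # (V, p)
            qlin = np.einsum("ij,ij->i", d, lam_j)
            dquad = 2.0 * delta * qlin + delta**2 * lam[lab_i, j, j]
            sig_cur = (theta_x[:, j] - lb[j]) / (ub[j] - lb[j])
            with np.errstate(divide="ignore"):
                djac = np.log(sig_prop * (1.0 - sig_prop)) - np.log(
                    sig_cur * (1.0 - sig_cur)
                )
            log_alpha = (ll_prop - ll) - 0.5 * dquad + djac
            acc = np.log(rng.random(V)) < log_alpha
            theta_u[acc, j] = prop_uj[acc]
            theta_x[acc, j] = prop_xj[acc]
            ll = np.where(acc, ll_prop, ll)
            win_acc[:, j] += acc
            if s > adapt_until:
                post_acc[:, j] += acc
        if s > adapt_until:
            post_acc_steps += 1

        # ---- proposal adaptation (first half of burn-in only)
        if s <= adapt_until and s % config.adapt_every == 0:
            widths = adapt_proposals(
                win_acc, config.adapt_every, widths,
                config.target_accept, config.adapt_clip,
            )
            win_acc[:] = 0.0

        # ---- post-burn-in accumulation (native space)
        if s > n_burn:
            sum_x += theta_x
            sum_x2 += theta_x**2
            sum_mu_nat += bsp.mu
            sum_sd_nat += np.sqrt(np.diagonal(bsp.sigma, axis1=1, axis2=2))
            n_kept += 1

        if s % config.log_every == 0:
            if not np.all(np.isfinite(theta_u)):
                bad = np.nonzero(~np.isfinite(theta_u).all(axis=1))[0]
                coords = np.argwhere(mask)[bad[0]]
                raise FloatingPointError(
                    f"non-finite chain state at step {s}, voxel {tuple(coords)}"
                )
            if logger.isEnabledFor(logging.INFO):
                rate = win_acc.mean() / (s % config.adapt_every or config.adapt_every)
                logger.info(
                    "step %d/%d mean accept %.3f prior means %s",
                    s, n_steps, float(post_acc.mean() / max(post_acc_steps, 1)),
                    np.array2string(bsp.mu, precision=3),
                )

    mean_v = sum_x / n_kept
    var_v = np.maximum(sum_x2 / n_kept - mean_v**2, 0.0)
    mean_maps: dict[str, np.ndarray] = {}
    sd_maps: dict[str, np.ndarray] = {}
    for j, name in enumerate(model.param_names):
        m = np.full(labels.shape, np.nan)
        m[mask] = mean_v[:, j]
        mean_maps[name] = m
        sdm = np.full(labels.shape, np.nan)
        sdm[mask] = np.sqrt(var_v[:, j])
        sd_maps[name] = sdm

    rows = []
    for i, k in enumerate(roi_ids):
        for j, name in enumerate(model.param_names):
            rows.append(
                {
                    "roi": k,
                    "parameter": name,
                    "prior_mean": sum_mu_nat[i, j] / n_kept,
                    "prior_sd": sum_sd_nat[i, j] / n_kept,
                }
            )
    acc_map = np.full(labels.shape, np.nan)
    acc_map[mask] = post_acc.mean(axis=1) / max(post_acc_steps, 1)

    return PosteriorSummary(
        mean_maps=mean_maps,
        sd_maps=sd_maps,
        prior_summary=pd.DataFrame(rows),
        acceptance_map=acc_map,
        bsp=bsp,
        n_steps=n_steps,
        n_burn=n_burn,
        n_kept=n_kept,
        model_name=model.name,
        param_names=model.param_names,
    )
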