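"""Bayesian logistic regression over per-read k-mer statistics.

The class of a read (labeled vs unlabeled) is modeled as

    c_r ~ Bernoulli( logit^-1( m_r'·β + d_r'·γ [+ l_r'·δ + x_r·ν] + α ) )

with independent Normal priors on all coefficients.  The signal-median
weights β and signal-MAD weights γ carry the isotope signal; the dwell (δ)
and non-basecalled (ν) terms are optional and disabled in the simplified
model, which is the identical code path with those blocks switched off.

Two inference backends are provided:

* ``vi_adagrad`` — mean-field Gaussian variational inference with
  reparameterized stochastic gradients and an adagrad update, then
  ``n_posterior_samples`` draws from the fitted approximation;
* ``nuts`` — the No-U-Turn sampler with dual-averaging step-size
  adaptation (unit metric), returning post-warmup draws.

Both use the analytic gradient of the log joint, which for logistic
regression is ``X'(y - p) - θ/s²``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit

from .kmer_features import BoxCoxFit, ReadFeatures

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Model structure, priors and inference settings."""

    k: int = 5
    include_dwell: bool = False
    include_aptamer: bool = False
    prior_scale_coeff: float = 1.0
    prior_scale_intercept: float = 2.0
    backend: str = "vi_adagrad"  # or "nuts"
    vi_iterations: int = 10_000
    vi_learning_rate: float = 0.1
    vi_grad_samples: int = 2
    nuts_warmup: int = 500
    nuts_max_depth: int = 10
    n_posterior_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posterior_samples < 1:
            raise ValueError("n_posterior_samples must be >= 1")
        if self.backend not in ("vi_adagrad", "nuts"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class Centering:
    """Training-set column means/scales used to standardize the design."""

    means: np.ndarray
    scales: np.ndarray


@dataclass
class ModelPosterior:
    """Posterior samples plus everything needed to predict new reads."""

    beta: np.ndarray  # (S, 4^k)
    gamma: np.ndarray  # (S, 4^k)
    alpha: np.ndarray  # (S,)
    delta: np.ndarray | None
    nu: np.ndarray | None
    centering: Centering
    config: ModelConfig
    boxcox_fits: tuple[BoxCoxFit, BoxCoxFit] | None = None
    fit_info: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    def coefficient_matrix(self) -> np.ndarray:
        """Stack all coefficient draws as (S, p) in design-column order."""
        blocks = [self.beta, self.gamma]
        if self.delta is not None:
            blocks.append(self.delta)
        if self.nu is not None:
            blocks.append(self.nu[:, None])
        return np.hstack(blocks)

    def save(self, path: str) -> None:
        """Serialize samples, centering, Box-Cox λs and config to .npz."""
        meta = {"config": asdict(self.config), "fit_info": self.fit_info}
        if self.boxcox_fits is not None:
            meta["boxcox"] = [asdict(f) for f in self.boxcox_fits]
        arrays = {
            "beta": self.beta,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "centering_means": self.centering.means,
            "centering_scales": self.centering.scales,
            "meta_json": np.array(json.dumps(meta)),
        }
        if self.delta is not None:
            arrays["delta"] = self.delta
        if self.nu is not None:
            arrays["nu"] = self.nu
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "ModelPosterior":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta_json"]))
            fits = None
            if "boxcox" in meta:
                fits = tuple(BoxCoxFit(**f) for f in meta["boxcox"])
            return cls(
                beta=data["beta"],
                gamma=data["gamma"],
                alpha=data["alpha"],
                delta=data["delta"] if "delta" in data else None,
                nu=data["nu"] if "nu" in data else None,
                centering=Centering(data["centering_means"], data["centering_scales"]),
                config=ModelConfig(**meta["config"]),
                boxcox_fits=fits,
                fit_info=meta.get("fit_info", {}),
            )


@dataclass
class Prediction:
    """Posterior-predictive class probability for one read."""

    read_id: str
    probability: float
    assigned_class: int
    error_response: float | None = None
    label: int | None = None


def _raw_design(features: Sequence[ReadFeatures], config: ModelConfig) -> np.ndarray:
    """Stack feature blocks (NaN where missing) in column order m|d[|l][|x]."""
    blocks = [
        np.vstack([np.where(f.present, f.m, np.nan) for f in features]),
        np.vstack([np.where(f.present, f.d, np.nan) for f in features]),
    ]
    if config.include_dwell:
        blocks.append(np.vstack([np.where(f.present, f.l, np.nan) for f in features]))
    if config.include_aptamer:
        blocks.append(np.array([[f.x] for f in features]))
    return np.hstack(blocks)


def prepare_design(
    features: Sequence[ReadFeatures],
    config: ModelConfig,
    centering: Centering | None = None,
) -> tuple[np.ndarray, Centering]:
    """Build the standardized design matrix.

    When ``centering`` is None it is estimated from these (training)
    features: per-column mean and standard deviation over the *observed*
    entries.  Missing entries are imputed with the training mean, i.e.,
    zero after centering.  Zero-variance columns get scale 1.
    """
    ks = {f.k for f in features}
    if len(ks) != 1:
        raise ValueError("features mix different k")
    if next(iter(ks)) != config.k:
        raise ValueError(f"features have k={ks.pop()}, config expects k={config.k}")
    X = _raw_design(features, config)
    if centering is None:
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=0)
            scales = np.nanstd(X, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        degenerate = ~np.isfinite(scales) | (scales == 0)
        if degenerate.any():
            logger.info("%d zero-variance design columns, scale clamped to 1", degenerate.sum())
        scales = np.where(degenerate, 1.0, scales)
        centering = Centering(means=means, scales=scales)
    X = (X - centering.means) / centering.scales
    np.nan_to_num(X, copy=False, nan=0.0)
    return X, centering


def _log_posterior_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, prior_scale: np.ndarray
) -> tuple[float, np.ndarray]:
    """Log joint (up to a constant) and its gradient; last column is the intercept."""
    eta = X @ theta
    # log-lik: y*eta - log(1 + exp(eta)), computed stably
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    grad = X.T @ (y - p)
    lp = ll - 0.5 * float(np.sum((theta / prior_scale) ** 2))
    grad -= theta / prior_scale**2
    return lp, grad


def _fit_vi_adagrad(
    X: np.ndarray,
    y: np.ndarray,
    prior_scale: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Mean-field Gaussian VI with reparameterized gradients and adagrad.

    The variational family is N(mu, diag(exp(2*omega))); the ELBO gradient
    is estimated from ``vi_grad_samples`` reparameterized draws per step
    (the entropy term contributes +1 to the omega-gradient exactly).
    """
    p = X.shape[1]
    mu = np.zeros(p)
    omega = np.full(p, -2.0)  # sd ≈ 0.135
    acc_mu = np.zeros(p)
    acc_om = np.zeros(p)
    lr = config.vi_learning_rate
    eps = 1e-10
    M = config.vi_grad_samples
    elbo_trace = []
    for it in range(config.vi_iterations):
        sd = np.exp(omega)
        g_mu = np.zeros(p)
        g_om = np.zeros(p)
        lp_acc = 0.0
        for _ in range(M):
            epsilon = rng.standard_normal(p)
            theta = mu + sd * epsilon
            lp, grad = _log_posterior_grad(theta, X, y, prior_scale)
            g_mu += grad
            g_om += grad * sd * epsilon
            lp_acc += lp
        g_mu /= M
        g_om = g_om / M + 1.0  # entropy gradient d/domega sum(omega) = 1
        acc_mu += g_mu**2
        acc_om += g_om**2
        mu += lr * g_mu / np.sqrt(acc_mu + eps)
        omega += lr * g_om / np.sqrt(acc_om + eps)
        if it % 500 == 0:
            elbo_trace.append(lp_acc / M + float(np.sum(omega)))
    draws = mu + np.exp(omega) * rng.standard_normal((config.n_posterior_samples, p))
    info = {"backend": "vi_adagrad", "iterations": config.vi_iterations, "elbo_trace": elbo_trace}
    return draws, info


def _leapfrog(theta, r, grad, step, X, y, prior_scale):
    r = r + 0.5 * step * grad
    theta = theta + step * r
    lp, grad = _log_posterior_grad(theta, X, y, prior_scale)
    r = r + 0.5 * step * grad
    return theta, r, lp, grad


def _find_reasonable_step(theta, lp, grad, X, y, prior_scale, rng):
    step = 1.0
    r0 = rng.standard_normal(theta.size)
    _, r1, lp1, _ = _leapfrog(theta, r0, grad, step, X, y, prior_scale)
    joint0 = lp - 0.5 * r0 @ r0
    joint1 = lp1 - 0.5 * r1 @ r1
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    while direction * (joint1 - joint0) > -direction * np.log(2.0):
        step *= 2.0**direction
        if step < 1e-10 or step > 1e7:
            break
        _, r1, lp1, _ = _leapfrog(theta, r0, grad, step, X, y, prior_scale)
        joint1 = lp1 - 0.5 * r1 @ r1
    return step


def _fit_nuts(
    X: np.ndarray,
    y: np.ndarray,
    prior_scale: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """No-U-Turn sampler with dual averaging (unit mass matrix)."""
    p = X.shape[1]
    theta = np.zeros(p)
    lp, grad = _log_posterior_grad(theta, X, y, prior_scale)
    step = _find_reasonable_step(theta, lp, grad, X, y, prior_scale, rng)
    mu_da = np.log(10.0 * step)
    log_step_bar, h_bar = 0.0, 0.0
    target_accept, gamma_da, t0, kappa = 0.8, 0.05, 10.0, 0.75
    n_total = config.nuts_warmup + config.n_posterior_samples
    draws = np.empty((config.n_posterior_samples, p))
    delta_max = 1000.0

    def build_tree(theta, r, grad, logu, v, j, step, joint0):
        if j == 0:
            theta1, r1, lp1, grad1 = _leapfrog(theta, r, grad, v * step, X, y, prior_scale)
            joint = lp1 - 0.5 * r1 @ r1
            n1 = int(logu <= joint)
            s1 = int(logu < delta_max + joint)
            a1 = min(1.0, np.exp(joint - joint0))
            return theta1, r1, grad1, theta1, r1, grad1, theta1, grad1, lp1, n1, s1, a1, 1
        (tm, rm, gm, tp, rp, gp, t1, g1, lp1, n1, s1, a1, na1) = build_tree(
            theta, r, grad, logu, v, j - 1, step, joint0
        )
        if s1 == 1:
            if v == -1:
                tm, rm, gm, _, _, _, t2, g2, lp2, n2, s2, a2, na2 = build_tree(
                    tm, rm, gm, logu, v, j - 1, step, joint0
                )
            else:
                _, _, _, tp, rp, gp, t2, g2, lp2, n2, s2, a2, na2 = build_tree(
                    tp, rp, gp, logu, v, j - 1, step, joint0
                )
            if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
                t1, g1, lp1 = t2, g2, lp2
            a1 += a2
            na1 += na2
            dt = tp - tm
            s1 = s2 * int(dt @ rm >= 0) * int(dt @ rp >= 0)
            n1 += n2
        return tm, rm, gm, tp, rp, gp, t1, g1, lp1, n1, s1, a1, na1

    for i in range(n_total):
        r0 = rng.standard_normal(p)
        joint0 = lp - 0.5 * r0 @ r0
        logu = joint0 + np.log(rng.uniform())
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        j, n, s = 0, 1, 1
        alpha_sum, n_alpha = 0.0, 1
        while s == 1 and j < config.nuts_max_depth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                tm, rm, gm, _, _, _, t1, g1, lp1, n1, s1, a1, na1 = build_tree(
                    tm, rm, gm, logu, v, j, step, joint0
                )
            else:
                _, _, _, tp, rp, gp, t1, g1, lp1, n1, s1, a1, na1 = build_tree(
                    tp, rp, gp, logu, v, j, step, joint0
                )
            if s1 == 1 and rng.uniform() < min(1.0, n1 / n):
                theta, grad, lp = t1, g1, lp1
            n += n1
            dt = tp - tm
            s = s1 * int(dt @ rm >= 0) * int(dt @ rp >= 0)
            j += 1
            alpha_sum, n_alpha = a1, max(na1, 1)
        if i < config.nuts_warmup:
            frac = 1.0 / (i + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha_sum / n_alpha)
            log_step = mu_da - np.sqrt(i + 1) / gamma_da * h_bar
            frac2 = (i + 1) ** (-kappa)
            log_step_bar = frac2 * log_step + (1 - frac2) * log_step_bar
            step = float(np.exp(log_step))
        else:
            step = float(np.exp(log_step_bar))
            draws[i - config.nuts_warmup] = theta
    info = {"backend": "nuts", "step_size": step, "warmup": config.nuts_warmup}
    return draws, info


def fit(
    features_train: Sequence[ReadFeatures],
    config: ModelConfig,
    boxcox_fits: tuple[BoxCoxFit, BoxCoxFit] | None = None,
) -> ModelPosterior:
    """Fit the model on labeled training reads.

    Requires both classes to be present; all randomness is driven by
    ``config.seed`` so repeated fits are bit-identical.
    """
    labels = [f.c for f in features_train]
    if any(c is None for c in labels):
        raise ValueError("every training read needs a class label")
    y = np.asarray(labels, dtype=float)
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    X, centering = prepare_design(features_train, config)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    X = np.hstack([X, np.ones((X.shape[0], 1))])  # intercept column
    prior_scale = np.full(X.shape[1], config.prior_scale_coeff)
    prior_scale[-1] = config.prior_scale_intercept

    rng = np.random.default_rng(config.seed)
    if config.backend == "vi_adagrad":
        draws, info = _fit_vi_adagrad(X, y, prior_scale, config, rng)
    else:
        draws, info = _fit_nuts(X, y, prior_scale, config, rng)

    n_k = 4**config.k
    pos = 0
    beta = draws[:, pos : pos + n_k]
    pos += n_k
    gamma = draws[:, pos : pos + n_k]
    pos += n_k
    delta = None
    if config.include_dwell:
        delta = draws[:, pos : pos + n_k]
        pos += n_k
    nu = None
    if config.include_aptamer:
        nu = draws[:, pos]
        pos += 1
    alpha = draws[:, pos]
    return ModelPosterior(
        beta=beta,
        gamma=gamma,
        alpha=alpha,
        delta=delta,
        nu=nu,
        centering=centering,
        config=config,
        boxcox_fits=boxcox_fits,
        fit_info=info,
    )


def predict(posterior: ModelPosterior, features: Sequence[ReadFeatures]) -> list[Prediction]:
    """Posterior-predictive classification of reads.

    The reported probability is the mean over posterior draws of
    logit^-1 of the linear predictor; a probability of exactly 0.5 is
    assigned class 0.  The error response |c_true - probability| is filled
    in when the read carries a label.
    """
    X, _ = prepare_design(features, posterior.config, posterior.centering)
    X = np.hstack([X, np.ones((X.shape[0], 1))])
    theta = np.hstack([posterior.coefficient_matrix(), posterior.alpha[:, None]])  # (S, p)
    eta = X @ theta.T  # (n, S)
    probs = np.mean(expit(eta), axis=1)
    out = []
    for f, prob in zip(features, probs):
        err = None if f.c is None else float(abs(f.c - prob))
        out.append(
            Prediction(
                read_id=f.read_id,
                probability=float(prob),
                assigned_class=int(prob > 0.5),
                error_response=err,
                label=f.c,
            )
        )
    return out
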