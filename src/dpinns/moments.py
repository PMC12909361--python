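"""Log-normal moment algebra and the sampling-based derivative estimators.

This module carries the distributional machinery of the method:

* exact transforms between linear-scale moments (mean, variance) and
  log-scale parameters (mu, s2) of a log-normal variable;
* assembly of the joint log-scale distribution over concentration and ODE
  parameters at each collocation time, with trainable time-invariant
  cross-correlations;
* reparameterised sampling from that joint (differentiable in all
  distributional parameters);
* stochastic denoising of sampled observed concentrations under the
  multiplicative log-normal residual model C = C_true * exp(eps);
* sample-based estimators of the time derivatives of the population mean
  and (unbiased) variance of the true concentration, and the closed-form
  reconstruction of the derivatives of the *observed* moments from them.

Every function accepts either numpy arrays or autodiff Tensors; in the
latter case the operation participates in the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack, concat

__all__ = [
    "MomentPair", "LogMomentPair", "JointLogParams", "SampleBatch",
    "ResidualModel",
    "linear_to_log_moments", "log_to_linear_moments",
    "assemble_joint", "repair_correlation", "chol3", "draw_joint",
    "model_consistent_cross_corr", "joint_covariance",
    "denoise_samples", "denoise_shrinkage",
    "estimate_mean_derivative", "estimate_var_derivative",
    "noisy_mean_derivative", "noisy_var_derivative", "var_to_sd_derivative",
]


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def _sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def _scalar_len(x) -> int:
    if isinstance(x, Tensor):
        return int(x.data.shape[0]) if x.data.ndim else 1
    if hasattr(x, "__len__"):
        return len(x)
    return 1


# ---------------------------------------------------------------------------
# containers

@dataclass
class MomentPair:
    """Linear-scale mean and variance of a positive random variable."""
    mean: object
    variance: object


@dataclass
class LogMomentPair:
    """Log-scale mean and variance parameterising a log-normal."""
    mu_log: object
    var_log: object


@dataclass
class JointLogParams:
    """Per-collocation-time log-scale mean vectors and a shared Cholesky
    structure: cov_j = D_j R D_j with D_j diagonal and R the (repaired)
    time-invariant correlation matrix."""
    mu: object        # (n_times, dim)
    scales: object    # (n_times, dim) log-scale SDs (diagonal of D_j)
    chol_corr: object  # (dim, dim) lower Cholesky factor of R


@dataclass
class SampleBatch:
    """Joint draws at a set of collocation times: observed-scale and
    denoised concentrations, parameter draws, and per-sample RHS values."""
    concentrations_noisy: object = None   # (n_times, n_samples)
    concentrations_true: object = None    # (n_times, n_samples)
    parameters: object = None             # (n_times, n_samples, n_par)
    derivatives: object = None            # (n_times, n_samples)


@dataclass
class ResidualModel:
    """Log-scale residual SD of the multiplicative measurement-error model."""
    sigma: object


# ---------------------------------------------------------------------------
# moment transforms

def linear_to_log_moments(m: MomentPair) -> LogMomentPair:
    """Moment-match a log-normal: mu = ln(mean^2 / sqrt(mean^2 + var)),
    s2 = ln(1 + var / mean^2).  Exact inverse of log_to_linear_moments."""
    mean, var = m.mean, m.variance
    if not _is_tensor(mean, var):
        mean = np.asarray(mean, dtype=float)
        var = np.asarray(var, dtype=float)
        if np.any(mean <= 0):
            raise ValueError("log-normal moment matching requires mean > 0")
        if np.any(var < 0):
            raise ValueError("variance must be nonnegative")
    ratio = var / (mean * mean)
    var_log = _log(1.0 + ratio)
    mu_log = _log(mean) - 0.5 * var_log
    return LogMomentPair(mu_log=mu_log, var_log=var_log)


def log_to_linear_moments(lm: LogMomentPair) -> MomentPair:
    """mean = exp(mu + s2/2); var = (exp(s2) - 1) exp(2 mu + s2)."""
    mu, s2 = lm.mu_log, lm.var_log
    mean = _exp(mu + 0.5 * s2)
    var = (_exp(s2) - 1.0) * _exp(2.0 * mu + s2)
    return MomentPair(mean=mean, variance=var)


# ---------------------------------------------------------------------------
# joint distribution assembly

def repair_correlation(R: np.ndarray, jitter: float = 1e-6):
    """Return a constant diagonal shift c*I making min eig(R + cI) >= jitter,
    or 0.0 if R is already sufficiently positive definite.

    The shift is treated as a constant with respect to the trainable
    correlations, so the sampling path stays differentiable."""
    lam_min = float(np.linalg.eigvalsh(R).min())
    return max(jitter - lam_min, 0.0)


def chol3(R, shift: float = 0.0):
    """Closed-form lower Cholesky factor of a 2x2 or 3x3 SPD matrix built
    from scalar entries (works on Tensors; composes into the AD graph).

    `R` is a nested sequence of scalars; `shift` is added to the diagonal."""
    dim = len(R)
    entries = [R[i][j] for i in range(dim) for j in range(dim)]
    if not _is_tensor(*entries):
        Rm = np.array([[float(R[i][j]) for j in range(dim)]
                       for i in range(dim)]) + shift * np.eye(dim)
        return np.linalg.cholesky(Rm)

    def t1(x):  # scalar -> shape-(1,) Tensor so concat/stack apply
        return x.reshape(1) if isinstance(x, Tensor) \
            else Tensor(np.array([float(x)]))

    from .autodiff import concat
    if dim == 2:
        l11 = _sqrt(t1(R[0][0]) + shift)
        l21 = t1(R[1][0]) / l11
        l22 = _sqrt(t1(R[1][1]) + shift - l21 * l21)
        z = 0.0 * l11
        rows = [concat([l11, z]), concat([l21, l22])]
    elif dim == 3:
        l11 = _sqrt(t1(R[0][0]) + shift)
        l21 = t1(R[1][0]) / l11
        l31 = t1(R[2][0]) / l11
        l22 = _sqrt(t1(R[1][1]) + shift - l21 * l21)
        l32 = (t1(R[2][1]) - l31 * l21) / l22
        l33 = _sqrt(t1(R[2][2]) + shift - l31 * l31 - l32 * l32)
        z = 0.0 * l11
        rows = [concat([l11, z, z]), concat([l21, l22, z]),
                concat([l31, l32, l33])]
    else:
        raise ValueError("chol3 supports dimensions 2 and 3")
    return stack(rows, axis=0)


def _is_time_varying(cross_corr) -> bool:
    if isinstance(cross_corr, Tensor):
        return cross_corr.data.ndim == 2
    return np.ndim(cross_corr) == 2


def _chol_batched(R, dim, shift):
    """Lower Cholesky of a batch of 2x2/3x3 SPD matrices given as nested
    lists of (n_t,)-shaped entries (Tensors or arrays); `shift` (n_t,) is
    added to the diagonal.  Returns (n_t, dim, dim)."""
    tensor_path = _is_tensor(*[R[i][j] for i in range(dim) for j in range(dim)])
    if dim == 2:
        l11 = _sqrt(R[0][0] + shift)
        l21 = R[1][0] / l11
        l22 = _sqrt(R[1][1] + shift - l21 * l21)
        z = 0.0 * l11
        rows = [[l11, z], [l21, l22]]
    elif dim == 3:
        l11 = _sqrt(R[0][0] + shift)
        l21 = R[1][0] / l11
        l31 = R[2][0] / l11
        l22 = _sqrt(R[1][1] + shift - l21 * l21)
        l32 = (R[2][1] - l31 * l21) / l22
        l33 = _sqrt(R[2][2] + shift - l31 * l31 - l32 * l32)
        z = 0.0 * l11
        rows = [[l11, z, z], [l21, l22, z], [l31, l32, l33]]
    else:
        raise ValueError("supported dimensions: 2 and 3")
    if tensor_path:
        from .autodiff import as_tensor
        row_ts = [stack([as_tensor(e) for e in row], axis=-1) for row in rows]
        return stack(row_ts, axis=1)
    return np.stack([np.stack([np.asarray(e, dtype=float) for e in row],
                              axis=-1) for row in rows], axis=1)


def assemble_joint(nn_moments: MomentPair, theta_mu, theta_sd, corr_par,
                   cross_corr, jitter: float = 1e-6) -> JointLogParams:
    """Build the per-time joint log-scale distribution over concentration
    (first block) and ODE parameters (remaining blocks).

    Parameters
    ----------
    nn_moments : MomentPair of arrays/Tensors over collocation times.
    theta_mu, theta_sd : log-scale mean vector and SD vector of the ODE
        parameters (time-invariant).
    corr_par : correlations among ODE parameters; scalar for 2 parameters,
        None/empty for a single parameter.
    cross_corr : concentration-parameter correlations — either a vector
        (one per ODE parameter, time-invariant, typically trainable) or a
        (n_times, n_par) array of time-varying correlations (e.g. derived
        from the structural model by moment propagation).
    """
    lm = linear_to_log_moments(nn_moments)
    time_varying = _is_time_varying(cross_corr)
    if time_varying:
        n_par = (cross_corr.data.shape[1] if isinstance(cross_corr, Tensor)
                 else np.shape(cross_corr)[1])
    else:
        n_par = _scalar_len(cross_corr)
    dim = n_par + 1

    def _v(x):
        return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)

    # correlation matrix entries (Tensors/arrays; scalars broadcast)
    one = 1.0
    if dim == 2:
        c0 = cross_corr[:, 0] if time_varying else (
            cross_corr[0] if hasattr(cross_corr, "__getitem__") else cross_corr)
        R = [[one, c0], [c0, one]]
        flat = [c0]
    elif dim == 3:
        if time_varying:
            c0, c1 = cross_corr[:, 0], cross_corr[:, 1]
        else:
            c0, c1 = cross_corr[0], cross_corr[1]
        rho = corr_par
        R = [[one, c0, c1], [c0, one, rho], [c1, rho, one]]
        flat = [c0, c1, rho]
    else:
        raise ValueError("assemble_joint supports 1 or 2 ODE parameters")

    if time_varying:
        # numpy mirror of R for the PSD repair (constants w.r.t. training)
        n_t_r = len(_v(R[0][1]))
        R_np = np.empty((n_t_r, dim, dim))
        for i in range(dim):
            for j in range(dim):
                R_np[:, i, j] = np.broadcast_to(_v(R[i][j]), (n_t_r,))
        lam_min = np.linalg.eigvalsh(R_np)[:, 0]
        shift = np.maximum(jitter - lam_min, 0.0)
        ones_nt = np.ones(n_t_r)
        R = [[e * ones_nt if np.ndim(_v(e)) == 0 else e for e in row]
             for row in R]
        L = _chol_batched(R, dim, shift)
    else:
        R_np = np.empty((dim, dim))
        for i in range(dim):
            for j in range(dim):
                R_np[i, j] = float(np.asarray(_v(R[i][j])))
        shift = repair_correlation(R_np, jitter)
        L = chol3(R, shift=shift)

    # per-time scale vector: concentration log-SD then parameter log-SDs
    sd_c = _sqrt(lm.var_log + 1e-300) if _is_tensor(lm.var_log) else np.sqrt(lm.var_log)
    n_t = sd_c.shape[0]
    if _is_tensor(sd_c, theta_sd, theta_mu):
        from .autodiff import as_tensor, concat
        ones_t = Tensor(np.ones((n_t, 1)))
        scales = concat([as_tensor(sd_c).reshape(n_t, 1),
                         ones_t * as_tensor(theta_sd).reshape(1, n_par)],
                        axis=1)
        mu = concat([as_tensor(lm.mu_log).reshape(n_t, 1),
                     ones_t * as_tensor(theta_mu).reshape(1, n_par)], axis=1)
    else:
        scales = np.concatenate(
            [sd_c.reshape(n_t, 1),
             np.broadcast_to(np.asarray(theta_sd).reshape(1, n_par), (n_t, n_par))],
            axis=1)
        mu = np.concatenate(
            [np.asarray(lm.mu_log).reshape(n_t, 1),
             np.broadcast_to(np.asarray(theta_mu).reshape(1, n_par), (n_t, n_par))],
            axis=1)
    return JointLogParams(mu=mu, scales=scales, chol_corr=L)


def joint_covariance(jp: JointLogParams) -> np.ndarray:
    """Dense per-time covariance matrices Omega'_j = D_j R_j D_j (numpy)."""
    L = jp.chol_corr.data if isinstance(jp.chol_corr, Tensor) else jp.chol_corr
    sc = jp.scales.data if isinstance(jp.scales, Tensor) else np.asarray(jp.scales)
    if L.ndim == 3:
        R = L @ np.swapaxes(L, -1, -2)
    else:
        R = (L @ L.T)[None]
    return sc[:, :, None] * R * sc[:, None, :]


def draw_joint(jp: JointLogParams, n: int, rng: np.random.Generator,
               z: np.ndarray | None = None):
    """Reparameterised draws from the joint log-normal.

    samples = exp(mu_j + D_j L z), z ~ N(0, I) iid.  Differentiable with
    respect to mu, scales and the correlation Cholesky factor; deterministic
    for a given `z` (or `rng` state).

    Returns (concentration draws (n_t, n), parameter draws (n_t, n, n_par), z).
    """
    if n < 2:
        raise ValueError("need at least 2 samples for variance estimators")
    mu, scales, L = jp.mu, jp.scales, jp.chol_corr
    tensor_path = _is_tensor(mu, scales, L)
    mu_np = mu.data if isinstance(mu, Tensor) else np.asarray(mu)
    n_t, dim = mu_np.shape
    if z is None:
        z = rng.standard_normal((n_t, n, dim))
    if tensor_path:
        from .autodiff import as_tensor
        Lz = (Tensor(z) @ _transpose(L))          # (n_t, n, dim)
        mu_t = as_tensor(mu).reshape(n_t, 1, dim)
        sc_t = as_tensor(scales).reshape(n_t, 1, dim)
        log_s = mu_t + sc_t * Lz
        samples = log_s.exp()
        conc = samples[:, :, 0]
        params = samples[:, :, 1:]
    else:
        L_np = np.asarray(L)
        Lz = z @ (np.swapaxes(L_np, -1, -2) if L_np.ndim == 3 else L_np.T)
        log_s = mu_np[:, None, :] + np.asarray(scales)[:, None, :] * Lz
        samples = np.exp(log_s)
        conc, params = samples[:, :, 0], samples[:, :, 1:]
    return conc, params, z


def model_consistent_cross_corr(times, mu_eta, sd_eta, rho, mean_ke_factor,
                                sd_c_log, clip: float = 0.995,
                                quadrature: bool = True, gh_points: int = 24):
    """Time-varying concentration-parameter correlations implied by the
    one-compartment structural model, by moment propagation.

    With log C(t) = const - log Vd - ke t (+ noise independent of the
    parameters) and (log Vd, log ke) jointly normal, the log-scale
    covariances are

        cov(log C, log Vd) = -s_vd^2 - t E[ke] rho s_vd s_ke   (exact)
        cov(log C, log ke) = -rho s_vd s_ke + ln R(t)

    where R(t) = E[ke e^{-ke t}] / (E[ke] E[e^{-ke t}]) is the exact
    covariance factor of the log-normal elimination rate with its own
    exponential decay, evaluated by Gauss-Hermite quadrature (first-order
    expansion ln R = -t E[ke] s_ke^2 available with quadrature=False).
    Correlations follow by dividing by the observed log-SD of concentration
    and are magnitude-clipped (the clip factor is treated as a constant so
    gradients still flow).

    Returns a (n_times, 2) array/Tensor of correlations.
    """
    t = np.asarray(times, dtype=float).reshape(-1, 1)
    s_vd, s_ke = sd_eta[0], sd_eta[1]
    e_ke = mean_ke_factor
    cov_vd = (0.0 - s_vd) * s_vd - (t * e_ke) * (rho * s_vd * s_ke)
    if quadrature:
        nodes, wts = _gauss_hermite(gh_points)
        mu_x = mu_eta[1]
        ke_nodes = (mu_x + (np.sqrt(2.0) * nodes) * s_ke).exp() \
            if _is_tensor(mu_x, s_ke) else np.exp(mu_x + np.sqrt(2.0) * nodes * s_ke)
        decay = _exp((0.0 - t) * ke_nodes)            # (n_t, gh)
        e0 = (decay * wts).sum(axis=1)                # E[e^{-ke t}]
        e1 = (decay * (ke_nodes * wts)).sum(axis=1)   # E[ke e^{-ke t}]
        log_R = _log(e1 / (e0 * e_ke))
        cov_ke = (0.0 - rho) * s_vd * s_ke + _col(log_R)
    else:
        cov_ke = (0.0 - rho) * s_vd * s_ke - (t * e_ke) * (s_ke * s_ke)
    sc = (sd_c_log.reshape(-1, 1) if isinstance(sd_c_log, Tensor)
          else np.asarray(sd_c_log).reshape(-1, 1))
    corr_vd = cov_vd / (sc * s_vd)
    corr_ke = cov_ke / (sc * s_ke)
    corr = concat([_as_col(corr_vd), _as_col(corr_ke)], axis=1) \
        if _is_tensor(corr_vd, corr_ke) else \
        np.concatenate([np.asarray(corr_vd).reshape(-1, 1),
                        np.asarray(corr_ke).reshape(-1, 1)], axis=1)
    data = corr.data if isinstance(corr, Tensor) else corr
    factor = np.minimum(1.0, clip / np.maximum(np.abs(data), 1e-12))
    return corr * factor


from functools import lru_cache


@lru_cache(maxsize=8)
def _gauss_hermite(n: int):
    nodes, wts = np.polynomial.hermite.hermgauss(n)
    return nodes, wts / np.sqrt(np.pi)


def lognormal_decay_ratios(times, mu_x, s_x, gh_points: int = 24):
    """Exact cross-moment ratios of a log-normal rate with its own decay.

    For ke = exp(x), x ~ N(mu_x, s_x^2), returns (log R1, log R2) with

        R_m(t) = E[ke e^{-m ke t}] / (E[ke] E[e^{-m ke t}]),   m = 1, 2,

    evaluated by Gauss-Hermite quadrature (differentiable in mu_x, s_x).
    R1 calibrates first-order concentration-rate cross moments, R2 the
    second-order ones.
    """
    t = np.asarray(times, dtype=float).reshape(-1, 1)
    nodes, wts = _gauss_hermite(gh_points)
    if _is_tensor(mu_x, s_x):
        ke_nodes = (mu_x + (np.sqrt(2.0) * nodes) * s_x).exp()
        e_ke = (mu_x + 0.5 * s_x * s_x).exp()
    else:
        ke_nodes = np.exp(mu_x + np.sqrt(2.0) * nodes * s_x)
        e_ke = np.exp(mu_x + 0.5 * s_x ** 2)
    out = []
    for m in (1.0, 2.0):
        decay = _exp((0.0 - m * t) * ke_nodes)            # (n_t, gh)
        e0 = (decay * wts).sum(axis=1)
        e1 = (decay * (ke_nodes * wts)).sum(axis=1)
        out.append(_log(e1 / (e0 * e_ke)))
    return out[0], out[1]


def _as_col(x):
    from .autodiff import as_tensor
    t = as_tensor(x)
    return t.reshape(t.data.shape[0], 1) if t.data.ndim == 1 else t


def _col(x):
    if isinstance(x, Tensor):
        return x.reshape(x.data.shape[0], 1) if x.data.ndim == 1 else x
    x = np.asarray(x)
    return x.reshape(-1, 1) if x.ndim == 1 else x


def _transpose(L):
    if isinstance(L, Tensor):
        out = Tensor(np.swapaxes(L.data, -1, -2), (L,))

        def bwd(g):
            if L.requires_grad:
                L.grad += np.swapaxes(g, -1, -2)
        out._backward = bwd
        return out
    return np.swapaxes(np.asarray(L), -1, -2)


def _reshape3(x, n_t, dim):
    return x.reshape(n_t, 1, dim) if isinstance(x, Tensor) \
        else np.asarray(x).reshape(n_t, 1, dim)


# ---------------------------------------------------------------------------
# denoising & derivative estimators

def denoise_shrinkage(c_noisy, mu_c, s2_c, sigma, smooth: float = 1e-12):
    """Moment-consistent denoising in log space.

    Under the residual model log C = log C_true + eps with eps independent
    of C_true, the true concentration shares the log-scale location mu_c of
    the observed one but has log-variance s2_c - sigma^2.  Each sampled
    observed draw is therefore shrunk toward mu_c by the factor
    alpha = sqrt((s2_c - sigma^2)/s2_c), which reproduces the exact moment
    relations E[C_true] = E[C] e^{-sigma^2/2} (and the matching variance
    deflation) that the derivative reconstruction assumes.  The difference
    s2_c - sigma^2 is smoothed through a softabs so the path stays
    differentiable when the predicted variance approaches the noise floor.
    """
    diff = s2_c - sigma * sigma
    # smooth max(diff, ~0): 0.5 (x + sqrt(x^2 + smooth))
    s2_true = 0.5 * (diff + _sqrt(diff * diff + smooth))
    alpha = _sqrt(s2_true / s2_c)
    lc = _log(c_noisy)
    if isinstance(lc, Tensor) or isinstance(alpha, Tensor) or isinstance(mu_c, Tensor):
        mu_b = (mu_c.reshape(-1, 1) if isinstance(mu_c, Tensor)
                else np.asarray(mu_c).reshape(-1, 1))
        al_b = (alpha.reshape(-1, 1) if isinstance(alpha, Tensor)
                else np.asarray(alpha).reshape(-1, 1))
    else:
        mu_b = np.asarray(mu_c).reshape(-1, 1)
        al_b = np.asarray(alpha).reshape(-1, 1)
    return _exp(mu_b + al_b * (lc - mu_b))


def denoise_samples(c_noisy, rm: ResidualModel, rng: np.random.Generator,
                    eps_z: np.ndarray | None = None):
    """Invert the residual model stochastically: per draw, sample
    eps ~ N(0, sigma^2) and return C_noisy * exp(-eps)."""
    shape = c_noisy.data.shape if isinstance(c_noisy, Tensor) else np.shape(c_noisy)
    if eps_z is None:
        eps_z = rng.standard_normal(shape)
    neg_eps = rm.sigma * Tensor(-eps_z) if isinstance(rm.sigma, Tensor) \
        else rm.sigma * (-eps_z)
    return c_noisy * _exp(neg_eps)


def estimate_mean_derivative(derivatives):
    """Arithmetic mean of per-sample RHS derivatives over the sample axis."""
    n = derivatives.data.shape[-1] if isinstance(derivatives, Tensor) \
        else np.shape(derivatives)[-1]
    if n < 1:
        raise ValueError("empty sample batch")
    return derivatives.mean(axis=-1) if isinstance(derivatives, Tensor) \
        else np.mean(derivatives, axis=-1)


def estimate_var_derivative(c_true, derivatives):
    """Sample estimator of d Var[C_true]/dt:
    (2/(N-1)) sum_i (C_i - mean)(dC_i - mean-derivative)."""
    n = c_true.data.shape[-1] if isinstance(c_true, Tensor) else np.shape(c_true)[-1]
    if n < 2:
        raise ValueError("variance derivative needs at least 2 samples")
    if isinstance(c_true, Tensor) or isinstance(derivatives, Tensor):
        m = c_true.mean(axis=-1, keepdims=True)
        dm = derivatives.mean(axis=-1, keepdims=True)
        return ((c_true - m) * (derivatives - dm)).sum(axis=-1) * (2.0 / (n - 1))
    m = np.mean(c_true, axis=-1, keepdims=True)
    dm = np.mean(derivatives, axis=-1, keepdims=True)
    return (2.0 / (n - 1)) * np.sum((c_true - m) * (derivatives - dm), axis=-1)


def noisy_mean_derivative(d_mean_true, rm: ResidualModel):
    """d E[C]/dt = exp(sigma^2/2) d E[C_true]/dt."""
    s2 = rm.sigma * rm.sigma
    return _exp(0.5 * s2) * d_mean_true


def noisy_var_derivative(mean_true, d_mean_true, d_var_true, rm: ResidualModel):
    """d Var[C]/dt = e^{s2} [ 2 E[C_true] dE[C_true]/dt (e^{s2} - 1)
                              + e^{s2} d Var[C_true]/dt ]."""
    s2 = rm.sigma * rm.sigma
    es2 = _exp(s2)
    return es2 * (2.0 * mean_true * d_mean_true * (es2 - 1.0) + es2 * d_var_true)


def var_to_sd_derivative(d_var, sd_hat, floor: float = 1e-8):
    """Chain rule d SD/dt = (d Var/dt) / (2 SD), with the predicted SD
    clamped at `floor` to avoid division blow-ups."""
    if isinstance(sd_hat, Tensor):
        if np.any(sd_hat.data <= floor):
            import warnings
            warnings.warn("predicted SD at or below floor; clamping")
            sd_hat = sd_hat + (np.maximum(floor - sd_hat.data, 0.0))
        return d_var / (2.0 * sd_hat)
    sd = np.asarray(sd_hat, dtype=float)
    if np.any(sd <= floor):
        import warnings
        warnings.warn("predicted SD at or below floor; clamping")
        sd = np.maximum(sd, floor)
    return d_var / (2.0 * sd)
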