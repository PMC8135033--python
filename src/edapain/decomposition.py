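"""Convex decomposition of EDA into tonic and phasic components.

The skin-conductance signal is modelled as the sum of

* a *phasic* component: a sparse non-negative sudomotor driver convolved
  with the Bateman impulse response ``h(t) = exp(-t/tau0) - exp(-t/tau1)``
  (normalized to unit peak), the canonical shape of a single
  skin-conductance response (SCR);
* a *tonic* level: a slowly varying cubic B-spline with knots every
  ``knot_spacing_s`` seconds plus an affine drift term;
* a residual.

Components are recovered by the quadratic program

    minimize  0.5 * ||y - phasic - tonic||^2
              + alpha * sum(driver) + 0.5 * gamma * ||spline coeffs||^2
    subject to  driver >= 0,

a convex problem solved here with a bound-constrained quasi-Newton method
over sparse banded operators. The L1-like ``alpha`` term promotes a sparse
driver (SCRs are isolated events); ``gamma`` keeps the tonic spline smooth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, optimize, sparse

logger = logging.getLogger(__name__)

__all__ = [
    "DecompositionParams",
    "DecomposedSignal",
    "SolverError",
    "bateman_kernel",
    "build_operators",
    "cvxeda_decompose",
    "phasic_for_features",
]


class SolverError(RuntimeError):
    """The QP solver failed to converge."""


@dataclass
class DecompositionParams:
    """Tunables of the tonic/phasic decomposition.

    ``tau0``/``tau1`` are the slow and fast Bateman time constants in
    seconds (defaults 2.0 and 0.7, the standard SCR shape); ``alpha``
    weights driver sparsity and ``gamma`` the tonic-spline ridge penalty.
    """

    tau0: float = 2.0
    tau1: float = 0.7
    knot_spacing_s: float = 10.0
    alpha: float = 8e-4
    gamma: float = 1e-2
    solver_tol: float = 1e-7
    max_iter: int = 50_000

    def __post_init__(self) -> None:
        if not self.tau0 > self.tau1 > 0:
            raise ValueError(f"need tau0 > tau1 > 0, got {self.tau0}, {self.tau1}")
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be positive")


@dataclass
class DecomposedSignal:
    """Tonic, phasic, non-negative sudomotor driver, and residual series.

    All four share the input length and ``tonic + phasic + residual``
    reconstructs the input exactly (the residual is defined that way).
    """

    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray
    residual: np.ndarray
    objective: float

    @property
    def n(self) -> int:
        return len(self.tonic)


def bateman_kernel(tau0: float, tau1: float, fs: float, duration_s: float) -> np.ndarray:
    """Sampled Bateman SCR impulse response, normalized to unit peak.

    ``h(t) = exp(-t/tau0) - exp(-t/tau1)`` for t >= 0; h(0) = 0, a single
    maximum at ``t* = ln(tau0/tau1) * tau0*tau1 / (tau0 - tau1)``, and
    non-negative everywhere because tau0 > tau1.
    """
    if not tau0 > tau1 > 0:
        raise ValueError(f"need tau0 > tau1 > 0, got {tau0}, {tau1}")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    h = np.exp(-t / tau0) - np.exp(-t / tau1)
    peak = h.max()
    if peak <= 0:  # duration too short to reach the peak
        t_star = np.log(tau0 / tau1) * tau0 * tau1 / (tau0 - tau1)
        peak = np.exp(-t_star / tau0) - np.exp(-t_star / tau1)
    return h / peak


def _kernel_length_s(tau0: float, tol: float = 1e-7) -> float:
    # tail of the unit-peak kernel is dominated by exp(-t/tau0)
    return tau0 * np.log(1.0 / tol)


def build_operators(n: int, fs: float, params: DecompositionParams):
    """Sparse convolution matrix M, spline basis B and drift matrix C.

    ``M`` is the lower-triangular banded Toeplitz of the truncated Bateman
    kernel, so ``M @ q`` is the discrete convolution of the driver with the
    SCR shape. ``B`` holds clamped cubic B-splines on knots every
    ``knot_spacing_s`` seconds (empty when the segment is too short for a
    spline); ``C`` is ``[1, t]``.
    """
    dur = n / fs
    kern_dur = min(dur, _kernel_length_s(params.tau0))
    h = bateman_kernel(params.tau0, params.tau1, fs, kern_dur)
    offsets = np.arange(len(h))
    M = sparse.diags([np.full(n - k, h[k]) for k in offsets if k < n],
                     [-int(k) for k in offsets if k < n],
                     shape=(n, n), format="csc")

    t = np.arange(n) / fs
    n_knots = int(np.floor(dur / params.knot_spacing_s)) + 1
    if n_knots >= 2 and n >= 8:
        knots = np.linspace(0.0, t[-1], n_knots)
        tv = np.concatenate(([knots[0]] * 3, knots, [knots[-1]] * 3))
        B = interpolate.BSpline.design_matrix(t, tv, 3).tocsc()
    else:
        B = sparse.csc_matrix((n, 0))

    C = np.column_stack([np.ones(n), t / max(t[-1], 1.0)])
    return M, B, C


def _objective_terms(M, B, C, y, alpha, gamma):
    n, m = M.shape[0], B.shape[1]

    def unpack(x):
        return x[:n], x[n:n + m], x[n + m:]

    def fun(x):
        q, l, d = unpack(x)
        r = M @ q + (B @ l if m else 0.0) + C @ d - y
        f = 0.5 * float(r @ r) + alpha * float(q.sum()) + 0.5 * gamma * float(l @ l)
        g = np.concatenate([M.T @ r + alpha,
                            (B.T @ r + gamma * l) if m else np.empty(0),
                            C.T @ r])
        return f, g

    return fun, unpack


def cvxeda_decompose(samples: np.ndarray, fs: float,
                     params: DecompositionParams | None = None) -> DecomposedSignal:
    """Solve the tonic/phasic QP for one (preprocessed) EDA segment.

    The driver is constrained non-negative; ``tonic + phasic + residual``
    equals the input exactly. Raises :class:`SolverError` on
    non-convergence and ``ValueError`` for too-short or non-finite input.
    """
    params = params or DecompositionParams()
    y = np.asarray(samples, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input contains non-finite values")
    n = y.size
    n_knots = int(np.floor(n / fs / params.knot_spacing_s)) + 1
    if n < 4 * n_knots or n < 8:
        raise ValueError(f"segment of {n} samples too short to decompose "
                         f"({n_knots} tonic knots would be needed)")

    M, B, C = build_operators(n, fs, params)
    m = B.shape[1]
    fun, unpack = _objective_terms(M, B, C, y, params.alpha, params.gamma)

    x0 = np.zeros(n + m + 2)
    bounds = [(0.0, None)] * n + [(None, None)] * (m + 2)
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": params.max_iter, "maxfun": 2 * params.max_iter,
                 "ftol": params.solver_tol ** 2, "gtol": params.solver_tol * 1e-2,
                 "maxcor": 20},
    )
    if not res.success and "ITERATIONS" in (res.message or "").upper():
        raise SolverError(f"QP did not converge after {res.nit} iterations: {res.message}")

    q, l, d = unpack(res.x)
    q = np.maximum(q, 0.0)
    phasic = M @ q
    tonic = (B @ l if m else 0.0) + C @ d
    residual = y - phasic - tonic
    logger.info("decomposed %d samples: objective %.6g, %d iterations",
                n, res.fun, res.nit)
    return DecomposedSignal(tonic=np.asarray(tonic), phasic=np.asarray(phasic),
                            driver=q, residual=residual, objective=float(res.fun))


def phasic_for_features(samples: np.ndarray, fs: float,
                        decomp_params: DecompositionParams | None = None,
                        preprocess_cfg=None) -> np.ndarray:
    """Phasic component low-pass filtered for peak counting."""
    from .preprocess import PreprocessConfig, lowpass_butterworth

    cfg = preprocess_cfg or PreprocessConfig()
    decomp = cvxeda_decompose(samples, fs, decomp_params)
    return lowpass_butterworth(decomp.phasic, fs, cfg.butter_order, cfg.butter_cutoff_hz)
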