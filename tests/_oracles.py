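"""Independent reference implementations used only to check the package.

These deliberately use naive dense formulations and plain loops, sharing no
code path with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def naive_features(pre: np.ndarray, phasic: np.ndarray, min_amp: float) -> dict:
    """Loop-based reimplementation of the 11 per-window statistics."""
    x = [float(v) for v in pre]
    p = [float(v) for v in phasic]
    n = len(x)

    def extrema(vals, cmp):
        out = []
        i = 1
        while i < len(vals) - 1:
            if cmp(vals[i], vals[i - 1]):
                j = i
                while j + 1 < len(vals) and vals[j + 1] == vals[i]:
                    j += 1
                if j < len(vals) - 1 and cmp(vals[i], vals[j + 1]):
                    out.append(i)
                i = j + 1
            else:
                i += 1
        return out

    peak_idx = [i for i in extrema(p, lambda a, b: a > b) if p[i] >= min_amp]
    maxima = extrema(x, lambda a, b: a > b)
    minima = extrema(x, lambda a, b: a < b)
    mean = sum(x) / n
    sorted_x = sorted(x)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return sorted_x[lo] + (pos - lo) * (sorted_x[hi] - sorted_x[lo])

    return {
        "n_peaks": float(len(peak_idx)),
        "mean": mean,
        "max_peak": max((p[i] for i in peak_idx), default=0.0),
        "range": max(x) - min(x),
        "std": (sum((v - mean) ** 2 for v in x) / n) ** 0.5,
        "iqr": quantile(0.75) - quantile(0.25),
        "rms": (sum(v * v for v in x) / n) ** 0.5,
        "mean_minima": (sum(x[i] for i in minima) / len(minima)) if minima else min(x),
        "mean_maxima": (sum(x[i] for i in maxima) / len(maxima)) if maxima else max(x),
        "mavfd": sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1),
        "mavsd": sum(abs(x[i + 2] - x[i]) for i in range(n - 2)) / (n - 2),
    }


def fista_qp(M: np.ndarray, B: np.ndarray, C: np.ndarray, y: np.ndarray,
             alpha: float, gamma: float, n_iter: int = 100_000) -> tuple[np.ndarray, float]:
    """Dense accelerated projected-gradient (FISTA) solve of the tonic/phasic QP.

    minimize 0.5||Mq + Bl + Cd - y||^2 + alpha*sum(q) + 0.5*gamma*||l||^2
    subject to q >= 0. Returns (x, objective).
    """
    n, m = M.shape[1], B.shape[1]
    A = np.hstack([M, B, C])
    H = A.T @ A
    reg = np.zeros(H.shape[0])
    reg[n:n + m] = gamma
    L = float(np.linalg.eigvalsh(H + np.diag(reg))[-1])
    Aty = A.T @ y
    step = 1.0 / L

    def grad(x):
        g = H @ x - Aty
        g[n:n + m] += gamma * x[n:n + m]
        return g

    def prox(x):
        out = x.copy()
        out[:n] = np.maximum(out[:n] - step * alpha, 0.0)
        return out

    x = np.zeros(A.shape[1])
    z = x.copy()
    tk = 1.0
    for _ in range(n_iter):
        x_new = prox(z - step * grad(z))
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = x_new + (tk - 1.0) / t_new * (x_new - x)
        x, tk = x_new, t_new

    r = A @ x - y
    obj = 0.5 * float(r @ r) + alpha * float(x[:n].sum()) \
        + 0.5 * gamma * float(x[n:n + m] @ x[n:n + m])
    return x, obj
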