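"""Generalized raking: calibration of design weights to full-cohort totals.

Given base (inverse-probability) weights ``d_i`` on a validated sample and
auxiliary vectors ``h_i`` known for *every* cohort unit, calibration finds
new weights ``w_i = d_i g(eta' h_i)`` such that the weighted sample totals
of the auxiliaries match their full-cohort totals exactly:

    sum_{i in sample} w_i h_i = sum_{i in cohort} h_i.

With the exponential distance ``g(x) = exp(x)`` this is classical raking
(weights stay positive); the linear distance ``g(x) = 1 + x`` is the GREG
estimator, used as a fallback when Newton iteration on the exponential
distance fails.  Using the influence functions of a phase-1 (error-prone
data) model fit as auxiliaries makes the calibrated IPW estimator both
consistent and efficient under validation sampling.

A constant-1 auxiliary is always appended so calibrated weights sum to
the cohort size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr

logger = logging.getLogger(__name__)


class RakingError(RuntimeError):
    """Calibration failed under both distances; carries the residual."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


@dataclass
class RakingResult:
    """Calibrated weights plus convergence diagnostics."""

    base_weights: np.ndarray
    weights: np.ndarray
    eta: np.ndarray
    calibration_residual: float
    iterations: int
    distance: str
    dropped_columns: tuple = ()

    @property
    def g_weights(self) -> np.ndarray:
        """Multiplicative adjustments w_i / d_i."""
        return self.weights / self.base_weights


def _independent_columns(H: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if H.shape[1] == 0:
        return np.array([], dtype=int)
    _q, r, piv = qr(H, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > tol * diag[0]))
    return np.sort(piv[:rank])


def raking_calibrate(
    d,
    aux_sample,
    aux_full,
    distance: str = "exponential",
    tol: float = 1e-8,
    max_iter: int = 50,
    add_constant: bool = True,
) -> RakingResult:
    """Calibrate base weights ``d`` so auxiliary totals match the cohort.

    Parameters
    ----------
    d
        Base weights for the sampled units, length n.
    aux_sample, aux_full
        Auxiliary matrix rows for the sampled units (n x k) and for the
        full cohort (N x k); column totals of ``aux_full`` are the
        calibration targets.
    distance
        ``"exponential"`` (raking, default; falls back to ``"linear"`` on
        non-convergence) or ``"linear"`` (GREG; may yield non-positive
        weights, logged).
    tol
        Absolute tolerance on the max component of the calibration
        residual ``|sum_sample w h - sum_full h|``.

    Collinear auxiliary columns are dropped with a warning.  Raises
    :class:`RakingError` if neither distance attains the tolerance.
    """
    d = np.asarray(d, dtype=float)
    Hs = np.atleast_2d(np.asarray(aux_sample, dtype=float))
    Hf = np.atleast_2d(np.asarray(aux_full, dtype=float))
    if Hs.ndim == 2 and Hs.shape[0] == 1 and len(d) != 1:
        Hs = Hs.T
    if Hs.shape[0] != len(d):
        raise ValueError("aux_sample rows must match the number of sampled units")
    if add_constant:
        Hs = np.column_stack([np.ones(Hs.shape[0]), Hs])
        Hf = np.column_stack([np.ones(Hf.shape[0]), Hf])

    keep = _independent_columns(Hs * np.sqrt(d)[:, None])
    dropped = tuple(int(j) for j in range(Hs.shape[1]) if j not in set(keep.tolist()))
    if dropped:
        logger.warning("dropping %d collinear auxiliary column(s): %s",
                       len(dropped), dropped)
    H = Hs[:, keep]
    T = Hf[:, keep].sum(axis=0)

    if distance not in ("exponential", "linear"):
        raise ValueError(f"unknown distance {distance!r}")

    def residual(w):
        return H.T @ w - T

    if distance == "exponential":
        eta = np.zeros(H.shape[1])
        r = residual(d)
        best = np.max(np.abs(r))
        it = 0
        ok = best < tol
        while not ok and it < max_iter:
            it += 1
            w = d * np.exp(np.clip(H @ eta, -60, 60))
            J = H.T @ (w[:, None] * H)
            try:
                step = np.linalg.solve(J, r)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, r, rcond=None)[0]
            # backtracking line search on the residual norm
            alpha = 1.0
            for _ in range(30):
                eta_new = eta - alpha * step
                z = H @ eta_new
                if np.max(np.abs(z)) < 60:
                    w_new = d * np.exp(z)
                    r_new = residual(w_new)
                    if np.max(np.abs(r_new)) < best or alpha < 1e-6:
                        break
                alpha /= 2.0
            eta = eta_new
            r = residual(d * np.exp(np.clip(H @ eta, -60, 60)))
            best = np.max(np.abs(r))
            if best < tol:
                ok = True
        if ok:
            w = d * np.exp(np.clip(H @ eta, -60, 60))
            return RakingResult(d, w, _embed(eta, keep, Hs.shape[1]), float(best),
                                it, "exponential", dropped)
        logger.warning("exponential raking did not converge (residual %.3g); "
                       "falling back to linear calibration", best)

    # linear (GREG) distance: closed form
    Dh = H * d[:, None]
    M = H.T @ Dh
    rhs = T - H.T @ d
    try:
        lam = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(M, rhs, rcond=None)[0]
    w = d * (1.0 + H @ lam)
    res = float(np.max(np.abs(residual(w))))
    if res >= max(tol, 1e-6 * max(1.0, np.max(np.abs(T)))):
        raise RakingError(
            f"calibration failed under both distances (residual {res:.3g})",
            residual=res)
    if np.any(w <= 0):
        logger.warning("linear calibration produced %d non-positive weight(s)",
                       int(np.sum(w <= 0)))
    return RakingResult(d, w, _embed(lam, keep, Hs.shape[1]), res, 0, "linear", dropped)


def _embed(eta, keep, k):
    full = np.zeros(k)
    full[keep] = eta
    return full
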