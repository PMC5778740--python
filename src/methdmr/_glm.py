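"""Batched logit-link IRLS shared by probe normalisation and association.

Both stages fit one small GLM per probe (tens of thousands of independent
fits over the same samples), so the iteratively reweighted least squares
update is vectorised over probes: designs of shape (B, n, p), responses
(B, n), with per-probe 0/1 weight masks for missing data. The score
equations are those of a binomial-family GLM with logit link; with a
continuous fraction response this is the quasi-binomial fit (same estimating
equations, variance function mu(1-mu)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MU_EPS = 1e-10
_ETA_CAP = 30.0
# |logit| beyond any clipped beta in [1e-6, 1-1e-6] (13.8): only a runaway
# (quasi-separated) fit can push the linear predictor past this
_SEP_ETA = 15.0


@dataclass
class IRLSFit:
    coef: np.ndarray  # (B, p)
    se: np.ndarray  # (B, p)
    eta: np.ndarray  # (B, n) linear predictor
    mu: np.ndarray  # (B, n) fitted means
    deviance: np.ndarray  # (B,) binomial deviance over unmasked samples
    converged: np.ndarray  # (B,) bool
    separated: np.ndarray  # (B,) bool: runaway linear predictor


def drop_collinear(X: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Return (X with independent columns, boolean keep mask) via pivoted QR."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D design")
    keep = np.zeros(X.shape[1], dtype=bool)
    basis: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].copy()
        for b in basis:
            v -= b * (b @ X[:, j])
        nrm = np.linalg.norm(v)
        if nrm > tol * max(1.0, np.linalg.norm(X[:, j])):
            basis.append(v / nrm)
            keep[j] = True
    return X[:, keep], keep


def binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> np.ndarray:
    """-2 * masked binomial log-likelihood kernel (valid for y in [0,1])."""
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        ty = np.where(y > 0, y * np.log(y / mu), 0.0)
        tc = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * np.sum(w * (ty + tc), axis=-1)


def batched_logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    ridge: float = 0.0,
) -> IRLSFit:
    """Fit logit-link binomial/quasi-binomial GLMs, vectorised over a batch.

    Parameters
    ----------
    X : (n, p) or (B, n, p) design; a 2-D design is broadcast over the batch.
    y : (n,) or (B, n) response in [0, 1] (binary or continuous fraction).
    mask : optional (B, n) or (n,) 0/1 inclusion weights (0 = drop sample).
    ridge : tiny diagonal added to X'WX for ill-conditioned probe designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    n = y.shape[1]
    # batch size: the largest leading dimension among y, X and mask
    B = y.shape[0]
    if X.ndim == 3:
        B = max(B, X.shape[0])
    if mask is not None and np.asarray(mask).ndim == 2:
        B = max(B, np.asarray(mask).shape[0])
    y = np.broadcast_to(y, (B, n))
    if X.ndim == 2:
        X = np.broadcast_to(X[None, :, :], (B, X.shape[0], X.shape[1]))
    p = X.shape[2]
    if mask is None:
        w_in = np.ones((B, n))
    else:
        w_in = np.broadcast_to(np.asarray(mask, dtype=float), (B, n)).copy()
    ysafe = np.where(w_in > 0, y, 0.5)

    mu = np.clip((ysafe + 0.5) / 2.0, 0.01, 0.99)
    eta = np.log(mu / (1 - mu))
    coef = np.zeros((B, p))
    dev = binomial_deviance(ysafe, mu, w_in)
    converged = np.zeros(B, dtype=bool)
    eye = np.eye(p)

    for _ in range(max_iter):
        act = ~converged
        if not act.any():
            break
        Xa, wa, ya = X[act], w_in[act], ysafe[act]
        mua = np.clip(mu[act], _MU_EPS, 1 - _MU_EPS)
        va = mua * (1 - mua)
        w = wa * va
        z = eta[act] + (ya - mua) / va
        XtW = Xa * w[:, :, None]
        XtWX = np.einsum("bnp,bnq->bpq", XtW, Xa)
        if ridge:
            XtWX = XtWX + ridge * eye
        XtWz = np.einsum("bnp,bn->bp", XtW, z)
        try:
            new_coef = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_coef = np.einsum(
                "bpq,bq->bp", np.linalg.pinv(XtWX), XtWz
            )
        bad = ~np.all(np.isfinite(new_coef), axis=1)
        if bad.any():  # fall back to previous estimate for degenerate probes
            new_coef[bad] = coef[act][bad]
        new_eta = np.clip(np.einsum("bnp,bp->bn", Xa, new_coef), -_ETA_CAP, _ETA_CAP)
        new_mu = 1.0 / (1.0 + np.exp(-new_eta))
        new_dev = binomial_deviance(ya, new_mu, wa)
        delta = np.abs(new_dev - dev[act]) / (np.abs(dev[act]) + 0.1)
        idx = np.flatnonzero(act)
        coef[idx] = new_coef
        eta[idx] = new_eta
        mu[idx] = new_mu
        dev[idx] = new_dev
        converged[idx[delta < tol]] = True

    # covariance at the final fit
    va = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    w = w_in * va * (1 - va)
    XtWX = np.einsum("bnp,bn,bnq->bpq", X, w, X)
    if ridge:
        XtWX = XtWX + ridge * eye
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.clip(np.einsum("bpp->bp", cov), 0.0, None))
    separated = np.max(np.abs(eta) * (w_in > 0), axis=1) >= _SEP_ETA
    return IRLSFit(
        coef=coef, se=se, eta=eta, mu=mu, deviance=dev,
        converged=converged, separated=separated,
    )
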