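"""Reference-free cell-composition correction (ReFACTor-style).

Whole-blood methylation is a convolution of leukocyte-subtype profiles, and
case/control composition differences masquerade as probe-level association.
The corrector selects the t probes best explained by a rank-K structure
(cell-type-informative sites), computes K principal components over them,
and regresses those component scores out of every probe. No reference
profiles are used; the components are statistical surrogates for the
unknown mixture proportions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MethylationDataset
from .preprocessing import EPS

logger = logging.getLogger(__name__)

__all__ = ["ReFACTor", "CellTypeComponents", "refactor_components", "regress_out_components", "correct_celltype"]


@dataclass
class CellTypeComponents:
    """Selected informative sites and their principal-component scores."""

    K: int
    t: int
    scores: np.ndarray  # samples x K, mutually orthogonal columns
    selected_probe_ids: list


def _as_matrix(data) -> tuple[np.ndarray, list]:
    """Accept a MethylationDataset or probes x samples frame/array."""
    if isinstance(data, MethylationDataset):
        return data.beta.to_numpy(dtype=float), list(data.beta.index)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index)
    arr = np.asarray(data, dtype=float)
    return arr, list(range(arr.shape[0]))


def _mean_impute(beta: np.ndarray) -> np.ndarray:
    """Per-probe mean imputation (for PCA only; callers restore missingness)."""
    out = beta.copy()
    miss = ~np.isfinite(out)
    if miss.any():
        means = np.where(
            np.isfinite(out).any(axis=1),
            np.nanmean(np.where(miss, np.nan, out), axis=1),
            0.5,
        )
        out[miss] = np.broadcast_to(means[:, None], out.shape)[miss]
    return out


class ReFACTor(BaseEstimator, TransformerMixin):
    """Sparse low-rank site selection + PCA, regressed out per probe.

    Parameters
    ----------
    K : number of components to regress out (5 per the source method).
    t : number of informative sites kept for the final PCA (500 default).
    min_variance : probes below this beta variance are excluded from site
        selection (standardisation of near-constant probes is unstable).
    """

    def __init__(self, K: int = 5, t: int = 500, min_variance: float = 1e-4, eps: float = EPS):
        self.K = K
        self.t = t
        self.min_variance = min_variance
        self.eps = eps

    def fit(self, data, y=None) -> "ReFACTor":
        beta, probe_ids = _as_matrix(data)
        n_probes, n_samples = beta.shape
        if self.K >= n_samples:
            raise ValueError("K must be smaller than the number of samples")
        if self.t > n_probes:
            raise ValueError("t exceeds the number of probes")
        if self.K == 0:
            self.scores_ = np.zeros((n_samples, 0))
            self.selected_probe_ids_ = []
            self.components_ = CellTypeComponents(0, 0, self.scores_, [])
            return self

        filled = _mean_impute(beta)
        var = filled.var(axis=1)
        usable = np.flatnonzero(var >= self.min_variance)
        t = self.t
        if usable.size < t:
            logger.warning(
                "only %d probes pass the variance filter; reducing t from %d",
                usable.size, t,
            )
            t = usable.size
        sub = filled[usable]
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)

        # rank probes by distance to their rank-K reconstruction
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        ZK = (U[:, : self.K] * S[: self.K]) @ Vt[: self.K]
        dist = np.linalg.norm(Z - ZK, axis=1)
        order = np.argsort(dist, kind="stable")[:t]
        sel = usable[order]

        # PCA over the selected sites: samples are observations
        Xs = Z[order].T  # n_samples x t, columns centred by construction
        Us, Ss, _ = np.linalg.svd(Xs, full_matrices=False)
        self.scores_ = Us[:, : self.K] * Ss[: self.K]
        self.selected_probe_ids_ = [probe_ids[i] for i in sel]
        self.components_ = CellTypeComponents(
            K=self.K, t=t, scores=self.scores_, selected_probe_ids=self.selected_probe_ids_
        )
        return self

    def transform(self, data):
        """Regress fitted component scores out of every probe.

        Output is intercept + residual per probe, clipped into [eps, 1-eps];
        missing entries are restored. Returns the same type it was given.
        """
        out_matrix = regress_out_components(
            data.beta if isinstance(data, MethylationDataset) else data,
            self.components_,
            eps=self.eps,
        )
        if isinstance(data, MethylationDataset):
            return MethylationDataset(
                manifest=data.manifest,
                samples=data.samples,
                beta=out_matrix,
                detection_p=data.detection_p,
            )
        return out_matrix


def refactor_components(beta_matrix, K: int = 5, t: int = 500) -> CellTypeComponents:
    """Compute cell-type surrogate components (see :class:`ReFACTor`)."""
    return ReFACTor(K=K, t=t).fit(beta_matrix).components_


def regress_out_components(beta_matrix, components: CellTypeComponents, eps: float = EPS):
    """OLS of each probe on [1, scores]; returns intercept + residual, clipped.

    Residualisation is a projection: applying it twice with the same
    components changes nothing beyond clipping.
    """
    is_frame = isinstance(beta_matrix, pd.DataFrame)
    beta = beta_matrix.to_numpy(dtype=float) if is_frame else np.asarray(beta_matrix, dtype=float)
    scores = np.asarray(components.scores, dtype=float)
    if scores.shape[0] != beta.shape[1]:
        raise ValueError("component score rows must align with samples")
    miss = ~np.isfinite(beta)
    filled = _mean_impute(beta)
    D = np.column_stack([np.ones(beta.shape[1]), scores])
    coef, *_ = np.linalg.lstsq(D, filled.T, rcond=None)  # (K+1) x probes
    fitted = (D @ coef).T
    out = coef[0][:, None] + (filled - fitted)
    out = np.clip(out, eps, 1 - eps)
    out[miss] = np.nan
    if is_frame:
        return pd.DataFrame(out, index=beta_matrix.index, columns=beta_matrix.columns)
    return out


def correct_celltype(ds: MethylationDataset, K: int = 5, t: int = 500) -> tuple[MethylationDataset, CellTypeComponents]:
    """Fit the corrector on a dataset and return (corrected dataset, components)."""
    model = ReFACTor(K=K, t=t).fit(ds)
    return model.transform(ds), model.components_
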