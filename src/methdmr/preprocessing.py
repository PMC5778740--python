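"""Probe QC filtering, covariate normalisation, and beta/M transforms.

QC removes probes with excess missingness or detection failures. The
covariate normalisation fits, per probe, a quasi-binomial (logit link,
variance mu(1-mu)) regression of beta on the technical/demographic design
(chip, chip position, sex, age, age^2, sex x age, sex x age^2) and replaces
each value by the probe mean plus the response-scale residual. Testing is
then done on M-values, the logit-2 transform of beta.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._glm import batched_logit_irls, drop_collinear
from .datatypes import MethylationDataset, QCReport

logger = logging.getLogger(__name__)

EPS = 1e-6  # logit clip constant

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "missingness_threshold",
    "filter_probes",
    "normalize_probes",
    "ProbeFilter",
    "CovariateNormalizer",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("chip", "chip_position", "sex", "age", "age2", "sex_age", "sex_age2")


def beta_to_m(beta, eps: float = EPS):
    """M = log2(beta / (1 - beta)), with beta clipped into [eps, 1 - eps].

    NaN entries pass through; values outside [0, 1] raise.
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^m / (2^m + 1)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.power(2.0, -arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    return beta if beta.ndim else float(beta)


def missingness_threshold(
    n_samples: int, n_probes: int, base_rate: float, alpha: float = 0.05
) -> int:
    """Smallest count k whose binomial upper tail beats a Bonferroni bound.

    Returns the smallest k with P(X >= k; n_samples, base_rate) < alpha/n_probes,
    i.e. the count of missing samples at which a probe's missingness deviates
    significantly from random at level alpha corrected for n_probes tests.
    """
    if not (0 < base_rate < 1):
        raise ValueError("base_rate must lie strictly between 0 and 1")
    if n_samples < 0 or n_probes < 1:
        raise ValueError("n_samples must be >= 0 and n_probes >= 1")
    bound = alpha / n_probes
    if bound >= 1:
        return 0
    for k in range(n_samples + 2):
        # P(X >= k) = sf(k - 1)
        if stats.binom.sf(k - 1, n_samples, base_rate) < bound:
            return k
    return n_samples + 1


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Remove probes with excess missing values or detection-P failures.

    A probe is removed when it has more than ``max_missing`` missing samples
    or more than ``max_detection_fail`` samples with detection P above
    ``detection_alpha``. Passing ``max_missing="auto"`` derives the threshold
    from the binomial/Bonferroni rule at ``base_rate``.
    """

    def __init__(
        self,
        max_missing: int | str = 11,
        max_detection_fail: int = 5,
        detection_alpha: float = 0.001,
        base_rate: float = 0.01,
        alpha: float = 0.05,
    ):
        self.max_missing = max_missing
        self.max_detection_fail = max_detection_fail
        self.detection_alpha = detection_alpha
        self.base_rate = base_rate
        self.alpha = alpha

    def fit(self, ds: MethylationDataset, y=None) -> "ProbeFilter":
        beta = ds.beta.to_numpy(dtype=float)
        n_probes, n_samples = beta.shape
        if self.max_missing == "auto":
            # the binomial rule gives the first significant count; allow up to one less
            max_missing = max(
                missingness_threshold(n_samples, max(n_probes, 1), self.base_rate, self.alpha) - 1,
                0,
            )
        else:
            max_missing = int(self.max_missing)
        n_miss = np.isnan(beta).sum(axis=1)
        fail_missing = n_miss > max_missing
        if ds.detection_p is not None:
            det = ds.detection_p.to_numpy(dtype=float)
            n_fail = (det > self.detection_alpha).sum(axis=1)
            fail_det = n_fail > self.max_detection_fail
        else:
            fail_det = np.zeros(n_probes, dtype=bool)
        removed = fail_missing | fail_det
        self.keep_ = ~removed
        self.report_ = QCReport(
            n_probes_in=n_probes,
            n_removed_missing=int(fail_missing.sum()),
            n_removed_detection=int(fail_det.sum()),
            n_removed_total=int(removed.sum()),
            n_probes_out=int((~removed).sum()),
            max_missing=max_missing,
            max_detection_fail=self.max_detection_fail,
            detection_alpha=self.detection_alpha,
        )
        return self

    def transform(self, ds: MethylationDataset) -> MethylationDataset:
        return ds.subset_probes(self.keep_)


def filter_probes(
    ds: MethylationDataset,
    max_missing: int | str = 11,
    max_detection_fail: int = 5,
    detection_alpha: float = 0.001,
) -> tuple[MethylationDataset, QCReport]:
    """Functional wrapper over :class:`ProbeFilter`; returns (dataset, report)."""
    f = ProbeFilter(
        max_missing=max_missing,
        max_detection_fail=max_detection_fail,
        detection_alpha=detection_alpha,
    ).fit(ds)
    return f.transform(ds), f.report_


def _build_design(samples: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Intercept + one-hot factors + centred age polynomial/interaction terms."""
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    age = samples["age"].to_numpy(dtype=float) if "age" in samples else None
    age_c = age - age.mean() if age is not None else None
    sex = (
        (samples["sex"] == "F").to_numpy(dtype=float) if "sex" in samples else None
    )
    for cov in covariates:
        if cov in ("chip", "chip_position", "cohort"):
            values = samples[cov].astype(str)
            levels = sorted(values.unique())[1:]  # drop-first coding
            for lev in levels:
                cols.append((values == lev).to_numpy(dtype=float))
        elif cov == "sex":
            cols.append(sex)
        elif cov == "age":
            cols.append(age_c)
        elif cov == "age2":
            cols.append(age_c**2)
        elif cov == "sex_age":
            cols.append(sex * age_c)
        elif cov == "sex_age2":
            cols.append(sex * age_c**2)
        else:
            cols.append(samples[cov].to_numpy(dtype=float))
    return np.column_stack(cols)


class CovariateNormalizer(BaseEstimator, TransformerMixin):
    """Per-probe quasi-binomial regression of beta on technical covariates.

    ``transform`` returns a dataset whose beta values are the probe mean plus
    the response-scale residual of the logit-link fit, clipped into
    [eps, 1 - eps]; missing entries stay missing.
    """

    def __init__(
        self,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        eps: float = EPS,
        chunk_size: int = 4000,
    ):
        self.covariates = covariates
        self.eps = eps
        self.chunk_size = chunk_size

    def fit(self, ds: MethylationDataset, y=None) -> "CovariateNormalizer":
        X = _build_design(ds.samples, self.covariates)
        X, keep = drop_collinear(X)
        if not keep.all():
            logger.warning(
                "normalisation design rank-deficient: dropped %d collinear column(s)",
                int((~keep).sum()),
            )
        self.design_ = X
        return self

    def transform(self, ds: MethylationDataset) -> MethylationDataset:
        beta = ds.beta.to_numpy(dtype=float)
        mask = np.isfinite(beta).astype(float)
        y = np.clip(np.where(mask > 0, beta, 0.5), self.eps, 1 - self.eps)
        mu = np.empty_like(y)
        for lo in range(0, y.shape[0], self.chunk_size):  # bound peak memory
            sl = slice(lo, lo + self.chunk_size)
            mu[sl] = batched_logit_irls(self.design_, y[sl], mask=mask[sl], ridge=1e-10).mu
        means = np.nansum(beta * mask, axis=1) / np.maximum(mask.sum(axis=1), 1)
        adjusted = means[:, None] + (y - mu)
        adjusted = np.clip(adjusted, self.eps, 1 - self.eps)
        adjusted[mask == 0] = np.nan
        out = ds.beta.copy()
        out.iloc[:, :] = adjusted
        return MethylationDataset(
            manifest=ds.manifest, samples=ds.samples, beta=out, detection_p=ds.detection_p
        )


def normalize_probes(
    ds: MethylationDataset, covariates: Optional[Sequence[str]] = None
) -> MethylationDataset:
    """Functional wrapper over :class:`CovariateNormalizer`."""
    norm = CovariateNormalizer(covariates=covariates or DEFAULT_COVARIATES)
    return norm.fit(ds).transform(ds)
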