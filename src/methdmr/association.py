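"""Per-probe case/control association and genome-wide calibration diagnostics.

Each probe is tested by logistic regression with disease status as the
outcome: the null model (status ~ cohort) is compared with the full model
(status ~ cohort + M-value) by the change in deviance, referred to a
chi-square with 1 df. The per-probe effect (log-odds per M-value unit), its
standard error, and the descriptive case/control beta means are reported
alongside.

Calibration across the genome is summarised by the inflation factor
lambda — the median observed chi-square statistic divided by the null
median (0.4549 for 1 df) — and by Q-Q confidence bands from the exact
Beta(i, n-i+1) law of uniform order statistics.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._glm import batched_logit_irls
from .datatypes import MethylationDataset
from .preprocessing import beta_to_m, m_to_beta

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "InflationReport",
    "AssociationScan",
    "fit_probe_association",
    "genome_scan",
    "inflation_lambda",
    "qq_band",
    "CHI2_DF1_MEDIAN",
]

# median of the chi-square distribution with one degree of freedom; the
# conventional rounding used when reporting lambda is 0.4549
CHI2_DF1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

RESULT_COLUMNS = [
    "probe_id", "coef", "se", "lrt_stat", "df", "p",
    "mean_beta_case", "mean_beta_control", "delta_beta", "flag",
]


@dataclass
class AssociationResult:
    """One probe's association summary (Wald coef/SE, LRT statistic and P)."""

    probe_id: str
    coef: float
    se: float
    lrt_stat: float
    df: int
    p: float
    mean_beta_case: float
    mean_beta_control: float
    delta_beta: float
    flag: str = "ok"  # ok / constant / separated / all_missing


@dataclass
class InflationReport:
    lambda_: float
    expected_median: float
    n_tests: int


def _status_vector(status) -> np.ndarray:
    arr = np.asarray(status)
    if arr.dtype.kind in "OUS":
        return (arr == "case").astype(float)
    return arr.astype(float)


class AssociationScan(BaseEstimator):
    """Genome scan: one logistic LRT per probe, vectorised over probes.

    ``fit`` accepts a :class:`MethylationDataset` (beta is logit-2
    transformed internally) or a probes x samples M-value matrix together
    with ``status``. Results land in ``results_`` (one row per probe, input
    order preserved).
    """

    def __init__(self, covariates: Sequence[str] = ("cohort",), chunk_size: int = 20000):
        self.covariates = covariates
        self.chunk_size = chunk_size

    def fit(self, data, status=None, samples: Optional[pd.DataFrame] = None) -> "AssociationScan":
        if isinstance(data, MethylationDataset):
            samples = data.samples
            status = samples["status"] if status is None else status
            beta = data.beta.to_numpy(dtype=float)
            probe_ids = list(data.beta.index)
            m = beta_to_m(beta)
        else:
            mat = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
            probe_ids = list(data.index) if isinstance(data, pd.DataFrame) else list(range(mat.shape[0]))
            m = mat
            beta = m_to_beta(mat)
        if status is None:
            raise ValueError("status is required")
        y = _status_vector(status)
        if m.shape[1] != y.size:
            raise ValueError("status length must match the number of samples")

        # null design: intercept + covariates from the sample sheet
        cols = [np.ones(y.size)]
        for cov in self.covariates:
            if samples is None or cov not in samples:
                continue
            values = samples[cov].astype(str)
            for lev in sorted(values.unique())[1:]:
                cols.append((values == lev).to_numpy(dtype=float))
        X0 = np.column_stack(cols)

        n_probes = m.shape[0]
        res = {
            "coef": np.full(n_probes, np.nan),
            "se": np.full(n_probes, np.nan),
            "lrt_stat": np.zeros(n_probes),
            "p": np.full(n_probes, np.nan),
            "flag": np.array(["ok"] * n_probes, dtype=object),
        }
        obs = np.isfinite(m)
        all_missing = ~obs.any(axis=1)
        const = np.zeros(n_probes, dtype=bool)
        with np.errstate(invalid="ignore"):
            rng_ = np.nanmax(np.where(obs, m, np.nan), axis=1) - np.nanmin(np.where(obs, m, np.nan), axis=1)
        const[~all_missing] = rng_[~all_missing] < 1e-12
        testable = ~(all_missing | const)

        # shared null fit for complete probes; per-probe null when masked
        null0 = batched_logit_irls(X0, y)
        null_dev_complete = float(null0.deviance[0])

        idx = np.flatnonzero(testable)
        for lo in range(0, idx.size, self.chunk_size):
            sel = idx[lo : lo + self.chunk_size]
            mm = m[sel]
            mask = np.isfinite(mm).astype(float)
            mm_f = np.where(mask > 0, mm, 0.0)
            B = sel.size
            Xf = np.broadcast_to(X0[None, :, :], (B, X0.shape[0], X0.shape[1]))
            Xf = np.concatenate([Xf, mm_f[:, :, None]], axis=2)
            full = batched_logit_irls(Xf, y, mask=mask, ridge=1e-12)
            complete = mask.all(axis=1)
            null_dev = np.full(B, null_dev_complete)
            if not complete.all():
                part = batched_logit_irls(X0, np.broadcast_to(y, (int((~complete).sum()), y.size)), mask=mask[~complete])
                null_dev[~complete] = part.deviance
            lrt = np.clip(null_dev - full.deviance, 0.0, None)
            res["coef"][sel] = full.coef[:, -1]
            res["se"][sel] = full.se[:, -1]
            res["lrt_stat"][sel] = lrt
            res["p"][sel] = stats.chi2.sf(lrt, 1)
            sep = full.separated
            if sep.any():
                logger.warning("%d probe(s) show quasi-separation; coefficients flagged", int(sep.sum()))
                res["flag"][sel[sep]] = "separated"
                res["coef"][sel[sep]] = np.sign(res["coef"][sel[sep]]) * np.inf
                res["se"][sel[sep]] = np.inf

        res["flag"][const] = "constant"
        res["p"][const] = 1.0
        res["flag"][all_missing] = "all_missing"

        case = y > 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_case = np.nanmean(beta[:, case], axis=1)
            mean_ctrl = np.nanmean(beta[:, ~case], axis=1)
        self.results_ = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "coef": res["coef"],
                "se": res["se"],
                "lrt_stat": res["lrt_stat"],
                "df": 1,
                "p": res["p"],
                "mean_beta_case": mean_case,
                "mean_beta_control": mean_ctrl,
                "delta_beta": mean_case - mean_ctrl,
                "flag": res["flag"],
            }
        )
        return self


def genome_scan(
    ds: MethylationDataset,
    status=None,
    covariates: Sequence[str] = ("cohort",),
) -> pd.DataFrame:
    """One association result per probe, manifest order preserved."""
    if ds.n_probes == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return AssociationScan(covariates=covariates).fit(ds, status=status).results_


def fit_probe_association(
    m_values,
    status,
    cohort=None,
    probe_id: str = "probe",
) -> AssociationResult:
    """Single-probe logistic LRT (status ~ cohort vs status ~ cohort + M)."""
    m = np.asarray(m_values, dtype=float)[None, :]
    samples = pd.DataFrame({"cohort": cohort}) if cohort is not None else None
    scan = AssociationScan(covariates=("cohort",) if cohort is not None else ())
    scan.fit(pd.DataFrame(m, index=[probe_id]), status=status, samples=samples)
    row = scan.results_.iloc[0]
    return AssociationResult(
        probe_id=probe_id,
        coef=float(row["coef"]),
        se=float(row["se"]),
        lrt_stat=float(row["lrt_stat"]),
        df=1,
        p=float(row["p"]) if np.isfinite(row["p"]) else None,
        mean_beta_case=float(row["mean_beta_case"]),
        mean_beta_control=float(row["mean_beta_control"]),
        delta_beta=float(row["delta_beta"]),
        flag=str(row["flag"]),
    )


def inflation_lambda(pvalues) -> InflationReport:
    """Genomic inflation factor: median observed chi-square over 0.4549.

    P values are converted back to chi-square (1 df) quantiles through the
    upper tail; lambda near 1 indicates a calibrated scan.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("need at least one P value")
    if (p > 1).any():
        raise ValueError("P values must be <= 1")
    if (p <= 0).any():
        logger.warning("clipping %d non-positive P value(s)", int((p <= 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, None)
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / CHI2_DF1_MEDIAN)
    return InflationReport(lambda_=lam, expected_median=CHI2_DF1_MEDIAN, n_tests=int(p.size))


def qq_band(n: int, level: float = 0.95) -> pd.DataFrame:
    """Expected -log10 P and a null envelope for each of n ranked P values.

    The rank-i order statistic of n independent Uniform(0,1) draws follows
    Beta(i, n-i+1); the band spans its (1-level)/2 and 1-(1-level)/2
    quantiles and the expected line is its median, all on the -log10 scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(1, n + 1)
    a, b = i, n - i + 1
    tail = (1 - level) / 2
    expected = -np.log10(stats.beta.ppf(0.5, a, b))
    lower = -np.log10(stats.beta.ppf(1 - tail, a, b))
    upper = -np.log10(stats.beta.ppf(tail, a, b))
    return pd.DataFrame({"rank": i, "expected": expected, "lower": lower, "upper": upper})
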