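"""Bump-hunting DMR detection: clusters, smoothed effects, bootstrap FWER.

Probes are chained into clusters (consecutive gap <= maxgap), a linear model
of methylation on case status adjusted for age and sex gives a per-probe
case-control coefficient, the coefficients are smoothed within clusters by a
running median, and maximal same-sign runs exceeding a cutoff become
candidate regions. Significance is assessed against a null built by
permuting case/control labels within sex/age strata: the family-wise error
rate of a candidate is the fraction of null replicates whose genome-wide
maximum bump area reaches the candidate's area.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from ._glm import drop_collinear
from .datatypes import MethylationDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeCluster",
    "CandidateBump",
    "cluster_probes",
    "probe_effects",
    "smooth_cluster",
    "find_bumps",
    "bootstrap_fwer",
    "BumpHunter",
]


@dataclass
class ProbeCluster:
    cluster_id: int
    chrom: str
    probe_ids: list


@dataclass
class CandidateBump:
    chrom: str
    start: int
    end: int
    probe_ids: list = field(default_factory=list)
    area: float = 0.0
    max_abs_coef: float = 0.0
    direction: str = "ambiguous"
    p_boot: float = np.nan
    fwer: float = np.nan


def _cluster_ids(chrom: np.ndarray, pos: np.ndarray, maxgap: int) -> np.ndarray:
    """Greedy chaining: a gap <= maxgap to the previous probe joins its cluster."""
    if len(pos) == 0:
        return np.array([], dtype=int)
    new = np.ones(len(pos), dtype=bool)
    new[1:] = (chrom[1:] != chrom[:-1]) | (pos[1:] - pos[:-1] > maxgap)
    return np.cumsum(new) - 1


def cluster_probes(probes: pd.DataFrame, maxgap: int = 1000) -> list[ProbeCluster]:
    """Group sorted probes into clusters with inter-probe gaps <= maxgap."""
    chrom = probes["chrom"].to_numpy()
    pos = probes["pos"].to_numpy()
    ids = _cluster_ids(chrom, pos, maxgap)
    out = []
    for cid in np.unique(ids):
        sel = ids == cid
        out.append(
            ProbeCluster(
                cluster_id=int(cid),
                chrom=str(chrom[sel][0]),
                probe_ids=list(probes["probe_id"].to_numpy()[sel]),
            )
        )
    return out


def _effect_design(status: np.ndarray, age, sex) -> np.ndarray:
    cols = [np.ones(status.size), status.astype(float)]
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
    if sex is not None:
        s = np.asarray(sex)
        cols.append((s == "F").astype(float) if s.dtype.kind in "OUS" else s.astype(float))
    X = np.column_stack(cols)
    Xk, keep = drop_collinear(X)
    if not keep[1]:
        raise ValueError("case/control indicator is collinear with covariates")
    if not keep.all():
        logger.warning("dropped %d collinear covariate column(s)", int((~keep).sum()))
    return Xk


def probe_effects(values: np.ndarray, status, age=None, sex=None) -> np.ndarray:
    """Per-probe adjusted case-control difference from a linear model.

    ``values`` is probes x samples (missing entries mean-imputed); the model
    is methylation ~ case + age + sex, and the returned coefficient is the
    case term.
    """
    y = np.asarray(values, dtype=float)
    status = np.asarray(status)
    st = (status == "case").astype(float) if status.dtype.kind in "OUS" else status.astype(float)
    X = _effect_design(st, age, sex)
    miss = ~np.isfinite(y)
    if miss.any():
        means = np.nanmean(np.where(miss, np.nan, y), axis=1)
        y = np.where(miss, means[:, None], y)
    pinv = np.linalg.pinv(X)
    coefs = pinv @ y.T  # p x probes; case indicator is column 1 of X
    return coefs[1]


def smooth_cluster(coefs: np.ndarray, k: int = 5) -> np.ndarray:
    """Centred running median, truncated at the edges.

    Clusters shorter than 3 probes are returned unsmoothed; k must be odd.
    """
    if k % 2 == 0:
        raise ValueError("running-median window k must be odd")
    x = np.asarray(coefs, dtype=float)
    if x.size < 3:
        return x.copy()
    half = k // 2
    padded = np.concatenate([np.full(half, np.nan), x, np.full(half, np.nan)])
    return np.nanmedian(sliding_window_view(padded, k), axis=1)


def _smooth_all(coefs: np.ndarray, cluster_ids: np.ndarray, k: int) -> np.ndarray:
    """Running median within every cluster, vectorised via NaN separators."""
    half = k // 2
    n = coefs.size
    starts = np.flatnonzero(np.concatenate([[True], cluster_ids[1:] != cluster_ids[:-1]]))
    sizes = np.diff(np.concatenate([starts, [n]]))
    # lay clusters out with k-1 NaNs between them so windows never span two
    offsets = half + np.concatenate([[0], np.cumsum(sizes[:-1] + (k - 1))])
    total = int(offsets[-1] + sizes[-1] + half)
    padded = np.full(total, np.nan)
    data_pos = np.repeat(offsets, sizes) + (np.arange(n) - np.repeat(starts, sizes))
    padded[data_pos] = coefs
    med = np.nanmedian(sliding_window_view(padded, k), axis=1)
    out = med[data_pos - half]
    short = np.repeat(sizes < 3, sizes)
    out[short] = coefs[short]
    return out


def _bump_runs(smoothed: np.ndarray, cluster_ids: np.ndarray, cutoff: float):
    """Maximal same-sign runs above cutoff: (start_idx, end_idx, sign, area, peak)."""
    state = np.zeros(smoothed.size, dtype=int)
    state[smoothed > cutoff] = 1
    state[smoothed < -cutoff] = -1
    if smoothed.size == 0:
        return []
    change = np.ones(smoothed.size, dtype=bool)
    change[1:] = (state[1:] != state[:-1]) | (cluster_ids[1:] != cluster_ids[:-1])
    starts = np.flatnonzero(change)
    ends = np.concatenate([starts[1:], [smoothed.size]])
    runs = []
    for s, e in zip(starts, ends):
        if state[s] != 0:
            seg = smoothed[s:e]
            runs.append((int(s), int(e), int(state[s]), float(np.abs(seg).sum()), float(np.abs(seg).max())))
    return runs


def find_bumps(
    smoothed: np.ndarray,
    probes: pd.DataFrame,
    cutoff: float,
    cluster_ids: np.ndarray | None = None,
) -> list[CandidateBump]:
    """Candidate regions: maximal runs of consecutive probes beyond +-cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    smoothed = np.asarray(smoothed, dtype=float)
    if cluster_ids is None:
        cluster_ids = np.zeros(smoothed.size, dtype=int)
    out = []
    pos = probes["pos"].to_numpy()
    chrom = probes["chrom"].to_numpy()
    pid = probes["probe_id"].to_numpy()
    for s, e, sign, area, peak in _bump_runs(smoothed, cluster_ids, cutoff):
        out.append(
            CandidateBump(
                chrom=str(chrom[s]),
                start=int(pos[s]),
                end=int(pos[e - 1]),
                probe_ids=list(pid[s:e]),
                area=area,
                max_abs_coef=peak,
                direction="hypermethylated" if sign > 0 else "hypomethylated",
            )
        )
    return out


def _strata(samples: pd.DataFrame) -> np.ndarray:
    """Permutation strata: sex crossed with cohort (or an age median split)."""
    sex = samples["sex"].astype(str) if "sex" in samples else pd.Series("all", index=samples.index)
    if "cohort" in samples:
        grp = samples["cohort"].astype(str)
    elif "age" in samples:
        age = samples["age"].to_numpy(dtype=float)
        grp = pd.Series(np.where(age <= np.median(age), "young", "old"), index=samples.index)
    else:
        grp = pd.Series("all", index=samples.index)
    return (sex + "|" + grp).to_numpy()


def bootstrap_fwer(
    values: np.ndarray,
    samples: pd.DataFrame,
    candidates: list[CandidateBump],
    cutoff: float,
    cluster_ids: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    k: int = 5,
) -> list[CandidateBump]:
    """Attach permutation-null p_boot and FWER to each candidate.

    For each of B replicates, case/control labels are permuted within
    sex/age strata, the effect-smooth-bump pipeline is re-run at the same
    cutoff, and the genome-wide maximum null area is recorded. A candidate's
    FWER is the fraction of replicates whose maximum reaches its area;
    p_boot is its area's upper-tail fraction among all pooled null areas.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 20:
        logger.warning("B=%d gives FWER granularity %.2f; consider more replicates", B, 1 / B)
    rng = np.random.default_rng(seed)
    status = (samples["status"] == "case").to_numpy(dtype=float)
    age = samples["age"].to_numpy(dtype=float) if "age" in samples else None
    sex = samples["sex"].to_numpy() if "sex" in samples else None
    strata = _strata(samples)
    y = np.asarray(values, dtype=float)
    miss = ~np.isfinite(y)
    if miss.any():
        means = np.nanmean(np.where(miss, np.nan, y), axis=1)
        y = np.where(miss, means[:, None], y)

    max_null = np.empty(B)
    pooled: list[np.ndarray] = []
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for b in range(B):
        perm = status.copy()
        for g in groups:
            perm[g] = perm[g][rng.permutation(g.size)]
        X = _effect_design(perm, age, sex)
        coef = (np.linalg.pinv(X) @ y.T)[1]
        sm = _smooth_all(coef, cluster_ids, k)
        areas = np.array([r[3] for r in _bump_runs(sm, cluster_ids, cutoff)])
        max_null[b] = areas.max() if areas.size else 0.0
        if areas.size:
            pooled.append(areas)
    all_null = np.concatenate(pooled) if pooled else np.array([])
    for c in candidates:
        c.fwer = float((max_null >= c.area).mean())
        c.p_boot = float((all_null >= c.area).mean()) if all_null.size else 0.0
    return candidates


class BumpHunter(BaseEstimator):
    """Cluster / fit / smooth / bump / bootstrap, as one fitted estimator.

    ``fit`` takes a :class:`MethylationDataset` (the corrected beta matrix
    is used as the methylation value). Fitted attributes: ``cutoff_``,
    ``candidates_`` (all bumps, with p_boot and fwer) and ``table_``.
    ``cutoff=None`` uses the 99th percentile of |smoothed coefficient|.
    """

    def __init__(
        self,
        maxgap: int = 1000,
        k: int = 5,
        cutoff: float | None = None,
        cutoff_quantile: float = 0.99,
        B: int = 1000,
        seed: int = 0,
    ):
        self.maxgap = maxgap
        self.k = k
        self.cutoff = cutoff
        self.cutoff_quantile = cutoff_quantile
        self.B = B
        self.seed = seed

    def fit(self, ds: MethylationDataset, y=None) -> "BumpHunter":
        probes = ds.manifest
        values = ds.beta.to_numpy(dtype=float)
        samples = ds.samples
        cids = _cluster_ids(probes["chrom"].to_numpy(), probes["pos"].to_numpy(), self.maxgap)
        age = samples["age"].to_numpy(dtype=float) if "age" in samples else None
        sex = samples["sex"].to_numpy() if "sex" in samples else None
        coef = probe_effects(values, samples["status"].to_numpy(), age=age, sex=sex)
        smoothed = _smooth_all(coef, cids, self.k)
        cutoff = self.cutoff
        if cutoff is None:
            cutoff = float(np.quantile(np.abs(smoothed), self.cutoff_quantile))
        self.cutoff_ = cutoff
        self.cluster_ids_ = cids
        self.coef_ = coef
        self.smoothed_ = smoothed
        cands = find_bumps(smoothed, probes, cutoff, cluster_ids=cids)
        self.candidates_ = bootstrap_fwer(
            values, samples, cands, cutoff, cids, B=self.B, seed=self.seed, k=self.k
        )
        self.table_ = pd.DataFrame(
            {
                "chrom": [c.chrom for c in self.candidates_],
                "start": [c.start for c in self.candidates_],
                "end": [c.end for c in self.candidates_],
                "n_probes": [len(c.probe_ids) for c in self.candidates_],
                "area": [c.area for c in self.candidates_],
                "max_abs_coef": [c.max_abs_coef for c in self.candidates_],
                "direction": [c.direction for c in self.candidates_],
                "p_boot": [c.p_boot for c in self.candidates_],
                "fwer": [c.fwer for c in self.candidates_],
            }
        )
        return self
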