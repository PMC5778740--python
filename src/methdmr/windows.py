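"""1 kb sliding-window DMR calling by Fisher's-method P combination.

One window is anchored at each probe's start coordinate and spans
[pos, pos + width - 1] (1-based inclusive), holding that probe and every
subsequent probe within the span on the same chromosome. Per-window,
per-probe association P values are combined with Fisher's method
(-2 * sum(ln p) ~ chi-square with 2k df); windows are converted to Storey
q-values, those below the FDR threshold are merged into non-overlapping
regions, and each region is direction-classified by the majority sign of
its probes' case-control beta differences.

Fisher's method assumes independent P values, which correlated adjacent
probes violate; the combined P values are therefore anti-conservative at
the window level. This is inherent to the approach; an optional Brown-style
scale correction is exposed (off by default) for sensitivity analysis.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import DMRegion

logger = logging.getLogger(__name__)

__all__ = [
    "fishers_method",
    "make_windows",
    "score_windows",
    "storey_qvalues",
    "merge_significant_windows",
    "region_overlap",
    "SlidingWindowDMR",
    "regions_to_frame",
]

_P_FLOOR = 1e-300

WINDOW_COLUMNS = ["chrom", "start", "end", "k", "i0", "i1", "fisher_stat", "df", "p", "q"]


def fishers_method(pvalues) -> tuple[float, int, float]:
    """Combine independent P values: returns (-2*sum(ln p), 2k, combined P)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one P value")
    if (p > 1).any() or (p < 0).any() or not np.isfinite(p).all():
        raise ValueError("P values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("clipping %d zero P value(s) to %.0e", int((p == 0).sum()), _P_FLOOR)
        p = np.clip(p, _P_FLOOR, None)
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return stat, df, float(stats.chi2.sf(stat, df))


def _check_sorted(probes: pd.DataFrame) -> None:
    chrom = probes["chrom"].to_numpy()
    pos = probes["pos"].to_numpy()
    breaks = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate([[0], breaks, [len(probes)]])
    if len(set(chrom[starts[:-1]])) != len(starts) - 1:
        raise ValueError("probes must be sorted by (chrom, pos): chromosomes interleaved")
    for a, b in zip(starts[:-1], starts[1:]):
        if np.any(np.diff(pos[a:b]) < 0):
            raise ValueError("probes must be sorted by (chrom, pos)")


def make_windows(probes: pd.DataFrame, width: int = 1000) -> pd.DataFrame:
    """Anchor one window at each distinct probe position.

    ``probes`` must be sorted by (chrom, pos); probes sharing a position
    share one anchor window. Returns a frame with half-open probe index
    ranges [i0, i1) into ``probes`` and 1-based inclusive coordinates.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if len(probes) == 0:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    _check_sorted(probes)
    chrom_arr = probes["chrom"].to_numpy()
    pos_arr = probes["pos"].to_numpy()
    frames = []
    offset = 0
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        anchors = np.unique(pos)
        i0 = np.searchsorted(pos, anchors, side="left") + offset
        i1 = np.searchsorted(pos, anchors + width, side="left") + offset
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": anchors,
                    "end": anchors + width - 1,
                    "k": i1 - i0,
                    "i0": i0,
                    "i1": i1,
                }
            )
        )
        offset += int(sel.sum())
    win = pd.concat(frames, ignore_index=True)
    win["fisher_stat"] = np.nan
    win["df"] = 2 * win["k"]
    win["p"] = np.nan
    win["q"] = np.nan
    return win


def score_windows(windows: pd.DataFrame, probe_p) -> pd.DataFrame:
    """Fill per-window Fisher statistics from per-probe P values.

    ``probe_p`` is aligned with the probe frame the windows were built on.
    Windows containing a probe without a P value are skipped (P left NaN)
    with a warning.
    """
    p = np.asarray(probe_p, dtype=float)
    win = windows.copy()
    if len(win) == 0:
        return win
    bad = ~np.isfinite(p) | (p <= 0) | (p > 1)
    pc = np.clip(np.where(bad, 1.0, p), _P_FLOOR, 1.0)
    cs = np.concatenate([[0.0], np.cumsum(np.log(pc))])
    cbad = np.concatenate([[0], np.cumsum(bad.astype(int))])
    i0 = win["i0"].to_numpy()
    i1 = win["i1"].to_numpy()
    stat = -2.0 * (cs[i1] - cs[i0])
    nbad = cbad[i1] - cbad[i0]
    skipped = nbad > 0
    if skipped.any():
        logger.warning("skipping %d window(s) containing probes without P values", int(skipped.sum()))
    win["fisher_stat"] = np.where(skipped, np.nan, stat)
    win["df"] = 2 * win["k"]
    win["p"] = np.where(skipped, np.nan, stats.chi2.sf(stat, win["df"].to_numpy()))
    return win


def storey_qvalues(pvalues, pi0: Optional[float] = None) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated by fitting a cubic to pi0(lambda) = #{p > lambda} /
    (n (1 - lambda)) on the grid 0.05, 0.10, ..., 0.95 and evaluating at the
    grid's upper end. For fewer than 100 P values the estimate is unstable
    and pi0 = 1 is used (Benjamini-Hochberg) with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("P values must lie in [0, 1]")
    n = p.size
    if pi0 is None:
        if n < 100:
            logger.warning("n=%d too small for pi0 estimation; using pi0=1 (BH)", n)
            pi0 = 1.0
        else:
            grid = np.arange(0.05, 0.96, 0.05)
            pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in grid])
            coef = np.polyfit(grid, pi0_l, 3)
            pi0 = float(np.polyval(coef, grid[-1]))
            pi0 = min(max(pi0, 1.0 / n), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def _region_direction(delta: np.ndarray) -> str:
    neg = int((delta < 0).sum())
    pos = int((delta > 0).sum())
    total = delta.size
    if neg * 2 > total:
        return "hypomethylated"
    if pos * 2 > total:
        return "hypermethylated"
    return "ambiguous"


def merge_significant_windows(
    windows: pd.DataFrame,
    probes: pd.DataFrame,
    q_threshold: float = 0.05,
    boundary_p: float = 0.05,
) -> list[DMRegion]:
    """Merge q-significant windows into non-overlapping direction-classified regions.

    ``probes`` is the sorted frame the windows index into; it must carry
    ``p`` and ``delta_beta`` columns (``nearest_gene`` is propagated when
    present). Region P is Fisher's method over the deduplicated probe
    union; region FDR is the best member window's q.

    A window anchored up to width-1 bp before a differential run is itself
    significant, so the raw probe union picks up flanking CpGs that show no
    difference; boundary members with per-probe P above ``boundary_p`` are
    trimmed from both edges so the reported extent covers only CpGs with
    at least nominal evidence (a DMR is an interval of CpGs showing the
    difference, not of the windows that detected it).
    """
    sig = windows[(windows["q"] < q_threshold) & np.isfinite(windows["p"])]
    if len(sig) == 0:
        return []
    sig = sig.sort_values(["chrom", "start"], kind="mergesort")
    probe_p = probes["p"].to_numpy(dtype=float)
    delta = probes["delta_beta"].to_numpy(dtype=float)
    genes = probes["nearest_gene"] if "nearest_gene" in probes else None

    regions: list[DMRegion] = []
    cur = None
    for row in sig.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["ranges"].append((row.i0, row.i1))
            cur["qs"].append(row.q)
        else:
            if cur is not None:
                regions.append(_finalise_region(cur, probes, probe_p, delta, genes, boundary_p))
            cur = {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "ranges": [(row.i0, row.i1)], "qs": [row.q],
            }
    regions.append(_finalise_region(cur, probes, probe_p, delta, genes, boundary_p))
    return regions


def _finalise_region(cur, probes, probe_p, delta, genes, boundary_p) -> DMRegion:
    idx = np.unique(np.concatenate([np.arange(i, j) for i, j in cur["ranges"]]))
    # drop unsupported boundary CpGs; keep the contiguous supported core
    support = probe_p[idx] <= boundary_p
    if support.any():
        lo = int(np.argmax(support))
        hi = int(len(idx) - np.argmax(support[::-1]))
        idx = idx[lo:hi]
    else:  # window significance driven by the combination alone
        idx = idx[[int(np.nanargmin(probe_p[idx]))]]
    _, _, p = fishers_method(probe_p[idx])
    gene_list: list[str] = []
    if genes is not None:
        seen = genes.iloc[idx].dropna().astype(str)
        gene_list = sorted(set(seen))
    # region extent is the span of its member CpGs, not the window padding
    pos = probes["pos"].to_numpy()
    return DMRegion(
        chrom=cur["chrom"],
        start=int(pos[idx].min()),
        end=int(pos[idx].max()),
        probe_ids=list(probes["probe_id"].iloc[idx]),
        p=float(p),
        fdr_q=float(min(cur["qs"])),
        direction=_region_direction(delta[idx]),
        source_window_count=len(cur["ranges"]),
        nearest_genes=gene_list,
    )


def _interval_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions[["chrom", "start", "end"]].reset_index(drop=True)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )


def region_overlap(regions_a, regions_b) -> pd.DataFrame:
    """All pairs of intervals sharing >= 1 bp (bedtools-intersect semantics).

    Accepts DMRegion lists or frames with chrom/start/end (1-based
    inclusive). Returns a frame of (index_a, index_b, overlap_bp).
    """
    a = _interval_frame(regions_a)
    b = _interval_frame(regions_b)
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        asub = a[a["chrom"] == chrom].sort_values("start")
        bsub = b[b["chrom"] == chrom].sort_values("start")
        for ia, ra in asub.iterrows():
            for ib, rb in bsub.iterrows():
                if rb["start"] > ra["end"]:
                    break
                ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"]) + 1
                if ov >= 1:
                    rows.append((ia, ib, int(ov)))
    return pd.DataFrame(rows, columns=["index_a", "index_b", "overlap_bp"])


def regions_to_frame(regions: Sequence[DMRegion]) -> pd.DataFrame:
    """Tabular DMR summary (chromosome, span, direction, P, FDR, probes, genes)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "direction": [r.direction for r in regions],
            "p": [r.p for r in regions],
            "fdr_q": [r.fdr_q for r in regions],
            "n_probes": [r.n_probes for r in regions],
            "genes": [";".join(r.nearest_genes) for r in regions],
        }
    )


class SlidingWindowDMR(BaseEstimator):
    """Window -> Fisher -> q-value -> merge, as one fitted estimator.

    ``fit`` takes the sorted probe frame (chrom, pos, probe_id) with
    per-probe ``p`` and ``delta_beta`` columns (e.g. a manifest merged with
    association results). Fitted attributes: ``windows_`` (scored, with q)
    and ``regions_`` (merged significant :class:`DMRegion` list).
    """

    def __init__(self, width: int = 1000, q_threshold: float = 0.05, boundary_p: float = 0.05):
        self.width = width
        self.q_threshold = q_threshold
        self.boundary_p = boundary_p

    def fit(self, probes: pd.DataFrame, y=None) -> "SlidingWindowDMR":
        win = make_windows(probes, width=self.width)
        win = score_windows(win, probes["p"].to_numpy(dtype=float))
        scored = np.isfinite(win["p"].to_numpy(dtype=float))
        q = np.full(len(win), np.nan)
        if scored.any():
            q[scored] = storey_qvalues(win.loc[scored, "p"].to_numpy())
        win["q"] = q
        self.windows_ = win
        self.regions_ = merge_significant_windows(
            win, probes, q_threshold=self.q_threshold, boundary_p=self.boundary_p
        )
        return self
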