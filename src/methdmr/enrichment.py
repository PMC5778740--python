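"""Genomic-feature and gene-set enrichment of DMR probes.

Feature enrichment compares DMR-member CpGs against the full array
background (the background includes the DMR probes themselves, i.e. set vs
whole array) with a two-sided Fisher's exact test per feature level.
Gene-set over-representation maps regions to their nearest gene and tests
each set with a hypergeometric upper tail, Benjamini-Hochberg corrected
across tested sets; sets overlapping the gene list in fewer than
``min_overlap`` genes are excluded before testing.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DMRegion

logger = logging.getLogger(__name__)

__all__ = ["feature_enrichment", "nearest_gene", "geneset_enrichment"]

FEATURE_FIELDS = {"island_relation", "gene_feature", "dnase_hs"}


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def feature_enrichment(
    dmr_probe_ids: Iterable[str],
    manifest: pd.DataFrame,
    feature_field: str = "island_relation",
    exclusive_background: bool = False,
) -> pd.DataFrame:
    """Two-sided Fisher's exact test of DMR probes vs array background per level.

    Rows carry the 2x2 counts (a = DMR probes in the feature level, b = DMR
    probes outside it, c/d likewise for the background), the odds ratio, P,
    and BH q across levels. ``exclusive_background=True`` removes the DMR
    probes from the background counts.
    """
    dmr = set(dmr_probe_ids)
    if not dmr:
        raise ValueError("DMR probe set is empty")
    unknown = dmr - set(manifest["probe_id"])
    if unknown:
        raise ValueError(f"{len(unknown)} DMR probe(s) absent from the manifest")
    in_set = manifest["probe_id"].isin(dmr).to_numpy()
    values = manifest[feature_field]
    if feature_field == "dnase_hs":
        values = values.map({True: "DNase-HS", False: "other"})
    values = values.astype(str).to_numpy()
    bg = ~in_set if exclusive_background else np.ones(len(manifest), dtype=bool)

    rows = []
    for level in sorted(pd.unique(values)):
        hit = values == level
        a = int((in_set & hit).sum())
        b = int(in_set.sum()) - a
        c = int((bg & hit).sum())
        d = int(bg.sum()) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((level, a, b, c, d, _odds_ratio(a, b, c, d), float(p)))
    table = pd.DataFrame(rows, columns=["feature", "a", "b", "c", "d", "odds_ratio", "p"])
    table["fdr_q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def nearest_gene(regions: Sequence[DMRegion] | pd.DataFrame, genes: pd.DataFrame) -> list[list[str]]:
    """Gene(s) overlapping each region, else the closest; ties return all.

    ``genes`` needs chrom/start/end/name columns (1-based inclusive). A
    region on a chromosome absent from the annotation maps to an empty list
    with a warning.
    """
    if isinstance(regions, pd.DataFrame):
        reg_iter = list(regions[["chrom", "start", "end"]].itertuples(index=False))
    else:
        reg_iter = [(r.chrom, r.start, r.end) for r in regions]
    out: list[list[str]] = []
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    for chrom, start, end in reg_iter:
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            logger.warning("chromosome %s absent from gene annotation", chrom)
            out.append([])
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        names = sub["name"].to_numpy()
        overlap = (gs <= end) & (ge >= start)
        if overlap.any():
            out.append(sorted(set(names[overlap])))
            continue
        dist = np.where(ge < start, start - ge, gs - end)
        best = dist.min()
        out.append(sorted(set(names[dist == best])))
    return out


def geneset_enrichment(
    gene_list: Iterable[str],
    gmt_sets: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    min_overlap: int = 2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in annotated sets.

    For a set of size K in a background of size N with a list of size n and
    overlap k, P = P(X >= k) with X ~ Hypergeom(N, K, n). Sets with overlap
    below ``min_overlap`` are skipped. Returns all tested sets with BH q and
    a ``significant`` flag at the given FDR.
    """
    genes = set(gene_list)
    background = set(background_genes)
    if not genes <= background:
        raise ValueError("gene_list must be a subset of background_genes")
    N, n = len(background), len(genes)
    rows = []
    for name, members in gmt_sets.items():
        mem = set(members) & background
        overlap = sorted(genes & mem)
        k, K = len(overlap), len(mem)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b, c, d = k, n - k, K, N - K
        rows.append((name, a, b, c, d, _odds_ratio(a, b, K - k, (N - n) - (K - k)), p, ";".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p", "overlap_genes"]
    )
    if len(table):
        table["fdr_q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["fdr_q"] < fdr
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        table["fdr_q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
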