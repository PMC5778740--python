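"""Synthetic 450K-like methylation datasets with known ground truth.

The generator emulates the statistical structure of whole-blood Illumina
HumanMethylation450 data as used in a matched case/control migraine EWAS:

* a probe grid with spatially coherent CpG island / shore / shelf / sea blocks;
* beta values concentrated near 0 and 1 with an intermediate (40-60%) component;
* a leukocyte mixture folded into every sample's beta values, with an optional
  case/control composition shift to inject cell-type confounding;
* technical (chip) and demographic (age, sex) covariate effects;
* case-only regional beta shifts ("spikes") that serve as ground-truth DMRs.

Spikes are applied on the beta scale before cell-type mixing noise, so that
composition correction cannot erase true signal by construction. A single
integer seed drives one :class:`numpy.random.Generator`; all sub-draws derive
from it.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MANIFEST_COLUMNS,
    CellTypeConfig,
    MethylationDataset,
    SpikeSpec,
)

__all__ = [
    "generate_manifest",
    "classify_id_migraine",
    "simulate_dataset",
    "choose_spike_regions",
    "DEFAULT_CHROM_LENGTHS",
]

# Two moderate pseudo-chromosomes keep simulated grids dense enough for
# windowing at test scale without pretending to be hg19.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {"chr1": 20_000_000, "chr2": 15_000_000}


def classify_id_migraine(items: Sequence[bool]) -> str:
    """ID-Migraine screening rule: case iff >= 2 of the 3 items are affirmative.

    Items are (photophobia, nausea, health-related disability).
    """
    items = tuple(bool(x) for x in items)
    if len(items) != 3:
        raise ValueError("ID-Migraine requires exactly three item responses")
    return "case" if sum(items) >= 2 else "non_case"


def _probe_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Clustered 1-based positions: short within-cluster gaps, sparse long jumps."""
    if n == 0:
        return np.array([], dtype=int)
    long_jump = rng.random(n) < 0.15
    gaps = np.where(
        long_jump,
        rng.integers(2_000, 20_000, size=n),
        rng.integers(30, 800, size=n),
    )
    pos = np.cumsum(gaps) + 1
    if pos[-1] > length:  # rescale into the chromosome, keep ordering
        pos = np.floor(pos * (length - n) / pos[-1]).astype(int) + 1
        pos = np.maximum.accumulate(pos + np.arange(n))  # enforce strict increase
    return pos.astype(int)


def _island_labels(rng: np.random.Generator, n: int, island_fraction: float) -> np.ndarray:
    """Spatially coherent island blocks flanked by shores then shelves, rest sea."""
    labels = np.full(n, "Sea", dtype=object)
    n_island = int(round(island_fraction * n))
    if n_island == 0:
        return labels
    # partition the island budget into blocks of ~4-12 probes
    sizes: list[int] = []
    remaining = n_island
    while remaining > 0:
        s = int(min(remaining, rng.integers(4, 13)))
        sizes.append(s)
        remaining -= s
    # place blocks greedily at shuffled anchors, keeping a 5-probe margin
    taken = np.zeros(n, dtype=bool)
    anchors = rng.permutation(n)
    placed = 0
    for size in sizes:
        for a in anchors[placed:]:
            lo, hi = max(0, a - 5), min(n, a + size + 5)
            if not taken[lo:hi].any() and a + size <= n:
                labels[a : a + size] = "Island"
                taken[lo:hi] = True
                break
        placed += 1
    island = labels == "Island"
    idx = np.flatnonzero(island)
    for off, lab in ((1, "Shore"), (2, "Shore"), (3, "Shelf"), (4, "Shelf")):
        for j in np.concatenate([idx - off, idx + off]):
            if 0 <= j < n and labels[j] == "Sea":
                labels[j] = lab
    return labels


def generate_manifest(
    n_probes: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    island_fraction: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a sorted probe manifest with island/gene/DNase annotations.

    Returns a DataFrame with columns ``probe_id, chrom, pos, island_relation,
    gene_feature, nearest_gene, dnase_hs``, sorted by (chrom, pos) with no
    duplicate positions. Deterministic for a fixed seed.
    """
    if n_probes < 0:
        raise ValueError("n_probes must be non-negative")
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    if not chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    rng = np.random.default_rng(seed)

    total = sum(chrom_lengths.values())
    chroms = sorted(chrom_lengths)
    alloc = {c: int(round(n_probes * chrom_lengths[c] / total)) for c in chroms}
    # fix rounding drift on the largest chromosome
    drift = n_probes - sum(alloc.values())
    alloc[max(chroms, key=lambda c: chrom_lengths[c])] += drift

    frames = []
    gene_counter = 0
    for chrom in chroms:
        n = alloc[chrom]
        if n <= 0:
            continue
        pos = _probe_positions(rng, n, chrom_lengths[chrom])
        labels = _island_labels(rng, n, island_fraction)
        # gene territories of ~60 probes each
        territory = np.arange(n) // 60
        genes = np.array([f"GENE{gene_counter + t:05d}" for t in territory], dtype=object)
        gene_counter += int(territory.max()) + 1 if n else 0
        feature = rng.choice(
            ["TSS1500", "TSS200", "Body", "Intergenic"], size=n, p=[0.15, 0.10, 0.35, 0.40]
        )
        nearest = genes.copy()
        orphan = (feature == "Intergenic") & (rng.random(n) < 0.2)
        nearest[orphan] = None
        p_dnase = np.where(np.isin(labels, ["Island", "Shore"]), 0.25, 0.08)
        dnase = rng.random(n) < p_dnase
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"cg_{chrom}_{p:09d}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "island_relation": labels,
                    "gene_feature": feature,
                    "nearest_gene": nearest,
                    "dnase_hs": dnase,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=MANIFEST_COLUMNS)
    manifest = pd.concat(frames, ignore_index=True)
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return manifest[MANIFEST_COLUMNS]


def choose_spike_regions(
    manifest: pd.DataFrame,
    n_regions: int,
    delta_beta: float = 0.10,
    n_probes: int = 10,
    min_gap_probes: int = 100,
    max_gap: int = 1000,
    seed: int = 0,
) -> list[SpikeSpec]:
    """Pick well-separated runs of consecutive probes to serve as true DMRs.

    Each region spans ``n_probes`` consecutive manifest probes on one
    chromosome with every inter-probe gap at most ``max_gap`` bp (a region
    is only a meaningful ground truth at the 1 kb resolution shared by the
    window and cluster methods); regions are at least ``min_gap_probes``
    probes apart. The sign of ``delta_beta`` alternates across regions
    (half hypo-, half hypermethylated in cases).
    """
    rng = np.random.default_rng(seed)
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    n = len(manifest)
    gap_ok = np.ones(n, dtype=bool)  # gap_ok[i]: gap i -> i+1 usable
    if n > 1:
        gap_ok[:-1] = (np.diff(pos) <= max_gap) & (chrom[1:] == chrom[:-1])
    # run of n_probes starting at i needs n_probes - 1 usable gaps
    ok_run = np.ones(n, dtype=bool)
    for off in range(n_probes - 1):
        shifted = np.roll(gap_ok, -off)
        shifted[n - off :] = False
        ok_run &= shifted
    candidates = np.flatnonzero(ok_run & (np.arange(n) + n_probes <= n))
    rng.shuffle(candidates)
    chosen: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= n_probes + min_gap_probes for j in chosen):
            chosen.append(int(i))
        if len(chosen) == n_regions:
            break
    if len(chosen) < n_regions:
        raise ValueError("manifest too small for the requested spike layout")
    spikes = []
    for r, i in enumerate(sorted(chosen)):
        sign = 1 if r % 2 == 0 else -1
        spikes.append(
            SpikeSpec(
                chrom=str(chrom[i]),
                start=int(pos[i]),
                end=int(pos[i + n_probes - 1]),
                delta_beta=sign * abs(delta_beta),
                n_probes_min=n_probes,
            )
        )
    return spikes


def _baseline_means(
    rng: np.random.Generator, n: int, weights: Sequence[float]
) -> np.ndarray:
    """3-component baseline: modes near 0.1, 0.5 and 0.9."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    means = np.empty(n)
    means[comp == 0] = rng.beta(2.5, 20.0, size=(comp == 0).sum())  # ~0.11
    means[comp == 1] = rng.beta(25.0, 25.0, size=(comp == 1).sum())  # ~0.50
    means[comp == 2] = rng.beta(20.0, 2.5, size=(comp == 2).sum())  # ~0.89
    return means


def _make_samples(
    rng: np.random.Generator,
    n_cases: int,
    n_controls: int,
    adult_fraction: float,
) -> pd.DataFrame:
    """Matched design: each control pairs a case (same cohort and sex, age +-2 y)."""
    rows = []
    n_adult_cases = int(round(adult_fraction * n_cases))
    for i in range(n_cases):
        cohort = "adult" if i < n_adult_cases else "adolescent"
        sex = "F" if rng.random() < 31 / 67 else "M"
        if cohort == "adult":
            age = float(np.clip(rng.normal(48.0, 7.9), 33, 74))
        else:
            age = float(np.clip(rng.normal(14.2, 2.4), 12, 19))
        # cases answer >=2 ID-Migraine items affirmatively
        k = 2 if rng.random() < 0.5 else 3
        items = np.zeros(3, dtype=bool)
        items[rng.choice(3, size=k, replace=False)] = True
        rows.append(("case", cohort, sex, age, tuple(items)))
    for i in range(n_controls):
        if i < len(rows):  # matched to case i
            _, cohort, sex, age_c, _ = rows[i]
            age = float(np.clip(age_c + rng.uniform(-2, 2), 12 if cohort == "adolescent" else 33, 200))
        else:
            cohort = "adult" if rng.random() < adult_fraction else "adolescent"
            sex = "F" if rng.random() < 0.5 else "M"
            age = float(rng.uniform(33, 74) if cohort == "adult" else rng.uniform(12, 19))
        rows.append(("control", cohort, sex, age, (False, False, False)))
    n = len(rows)
    chip_positions = [f"R{r:02d}C{c:02d}" for r in range(1, 7) for c in (1, 2)]
    # samples are randomised across chips (cases and controls interleaved),
    # as in a properly randomised plate layout
    slot = np.empty(n, dtype=int)
    slot[rng.permutation(n)] = np.arange(n)
    sheet = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "status": [r[0] for r in rows],
            "cohort": [r[1] for r in rows],
            "age": [round(r[3], 1) for r in rows],
            "sex": [r[2] for r in rows],
            "chip": [f"chip{s // 12:02d}" for s in slot],
            "chip_position": [chip_positions[s % 12] for s in slot],
            "item_photophobia": [r[4][0] for r in rows],
            "item_nausea": [r[4][1] for r in rows],
            "item_disability": [r[4][2] for r in rows],
        }
    )
    return sheet


def simulate_dataset(
    manifest: pd.DataFrame,
    n_cases: int = 67,
    n_controls: int = 67,
    adult_fraction: float = 28 / 67,
    spikes: Sequence[SpikeSpec] = (),
    celltype: Optional[CellTypeConfig] = None,
    noise_sd: float = 0.02,
    baseline_weights: Sequence[float] = (0.35, 0.30, 0.35),
    chip_effect_sd: float = 0.004,
    age_effect_fraction: float = 0.05,
    sex_effect_fraction: float = 0.02,
    detection_fail_rate: float = 0.002,
    missing_rate: float = 0.002,
    seed: int = 0,
) -> tuple[MethylationDataset, list[SpikeSpec]]:
    """Simulate a case/control methylation dataset with known true DMRs.

    Returns the dataset and the ground-truth region list (the spike specs,
    coordinates preserved verbatim, for recovery testing).

    The defaults mirror the study scale: 67 cases and 67 matched controls,
    28 of the 67 cases adults; missingness and detection-failure rates are
    configurable because the source study does not report them.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("sample counts must be non-negative")
    rng = np.random.default_rng(seed)
    celltype = celltype if celltype is not None else CellTypeConfig()

    samples = _make_samples(rng, n_cases, n_controls, adult_fraction)
    n_probes = len(manifest)
    n_samples = len(samples)

    base = _baseline_means(rng, n_probes, baseline_weights)
    K = celltype.n_cell_types

    # cell-type profiles: informative probes deviate per cell type
    profiles = np.tile(base[:, None], (1, K))
    informative = rng.random(n_probes) < celltype.informative_fraction
    dev = rng.normal(0.0, celltype.profile_sd, size=(int(informative.sum()), K))
    profiles[informative] = np.clip(profiles[informative] + dev, 0.01, 0.99)

    # per-sample mixture proportions, shifted for cases
    alpha = np.asarray(celltype.dirichlet_concentration, dtype=float)
    props = rng.dirichlet(alpha, size=n_samples)
    shift = np.asarray(celltype.case_control_shift, dtype=float)
    is_case = (samples["status"] == "case").to_numpy()
    if np.any(shift != 0):
        shifted = np.clip(props[is_case] + shift, 1e-3, None)
        props[is_case] = shifted / shifted.sum(axis=1, keepdims=True)

    # spikes enter the profiles' mixture additively for cases (pre-mixing shift
    # of every profile by delta is algebraically the same post-mixing delta)
    spike_delta = np.zeros((n_probes, n_samples))
    chrom_arr = manifest["chrom"].to_numpy()
    pos_arr = manifest["pos"].to_numpy()
    truth: list[SpikeSpec] = []
    for sp in spikes:
        in_region = (chrom_arr == sp.chrom) & (pos_arr >= sp.start) & (pos_arr <= sp.end)
        if not in_region.any():
            raise ValueError(f"spike {sp} covers no manifest probes")
        if in_region.sum() < sp.n_probes_min:
            raise ValueError(f"spike {sp} covers fewer than n_probes_min probes")
        spike_delta[np.ix_(in_region, is_case)] += sp.delta_beta
        truth.append(sp)

    beta = profiles @ props.T + spike_delta

    # technical and demographic covariate effects
    chip_ids = samples["chip"].to_numpy()
    chip_eff = {c: rng.normal(0.0, chip_effect_sd) for c in np.unique(chip_ids)}
    beta += np.array([chip_eff[c] for c in chip_ids])[None, :]
    age = samples["age"].to_numpy(dtype=float)
    is_f = (samples["sex"] == "F").to_numpy(dtype=float)
    age_probes = rng.random(n_probes) < age_effect_fraction
    age_coef = np.zeros(n_probes)
    age_coef[age_probes] = rng.normal(0.0, 4e-4, size=int(age_probes.sum()))
    beta += age_coef[:, None] * (age - age.mean())[None, :]
    sex_probes = rng.random(n_probes) < sex_effect_fraction
    sex_coef = np.zeros(n_probes)
    sex_coef[sex_probes] = rng.normal(0.0, 0.01, size=int(sex_probes.sum()))
    beta += sex_coef[:, None] * (is_f - is_f.mean())[None, :]

    # measurement noise is heteroscedastic on the beta scale, shrinking toward
    # the boundaries like intensity-ratio noise (var ~ beta(1-beta)); noise_sd
    # is the standard deviation at beta = 0.5
    mu_clip = np.clip(beta, 0.005, 0.995)
    scale = noise_sd * 2.0 * np.sqrt(mu_clip * (1.0 - mu_clip))
    beta += rng.normal(0.0, 1.0, size=beta.shape) * scale
    beta = np.clip(beta, 0.0, 1.0)

    detection_p = rng.uniform(0.0, 1e-5, size=beta.shape)
    fails = rng.random(beta.shape) < detection_fail_rate
    detection_p[fails] = rng.uniform(0.0011, 1.0, size=int(fails.sum()))
    missing = rng.random(beta.shape) < missing_rate
    beta[missing] = np.nan
    detection_p[missing] = 1.0  # masks consistent with detection P

    probe_ids = manifest["probe_id"].to_numpy()
    sample_ids = samples["sample_id"].to_numpy()
    ds = MethylationDataset(
        manifest=manifest.reset_index(drop=True),
        samples=samples,
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(detection_p, index=probe_ids, columns=sample_ids),
    )
    return ds, truth
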