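"""Synthetic baselines, read counts, and run-timing blocks for testing the
full pipeline without access to real data.

The baseline generator uses a hierarchical two-level F-model: per-locus base
frequencies are drawn from a symmetric Dirichlet; reporting-unit frequencies
from Dirichlet(p0 (1-F_unit)/F_unit); collection frequencies from
Dirichlet(p_unit (1-F_coll)/F_coll).  Under this model the expected
Weir-Cockerham theta between two collections of the same unit is close to
F_coll, and between units close to F_unit + F_coll, so the two parameters
directly set the differentiation scale the panel analyses see.  Genotypes
are drawn under HWE and missingness is MCAR per collection.

The defaults mirror a salmon baseline of 17 collections nested in 7
reporting units (unit sizes 4/2/2/1/3/4/1, two of the units being single
phenotypically distinct collections), roughly 96 fish per collection, 200
microhaplotype loci with 2-5 alleles concentrated at 2-4, and divergence
parameters spanning pairwise FST from near 0 (within units) to roughly 0.3
(against the most differentiated unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import BaselineDataset, MarkerDef, canonicalize_genotypes

_TRIPLETS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]

#: default chromosome lengths (34 chromosomes of 70 Mb)
DEFAULT_MAP = {f"Chr{i}": 70_000_000 for i in range(1, 35)}


@dataclass
class SimConfig:
    """Parameters of the synthetic-baseline generator.

    ``collections_per_unit`` may be a single int or one count per unit.
    ``alleles_per_locus`` maps allele count -> probability.
    ``missing_rate`` may be a scalar or one rate per collection.
    ``depth_model`` is (mean read depth, negative-binomial dispersion k).
    """

    seed: int = 0
    n_units: int = 7
    collections_per_unit: int | tuple[int, ...] = (4, 2, 2, 1, 3, 4, 1)
    n_per_collection: int = 96
    n_loci: int = 200
    alleles_per_locus: dict[int, float] = field(
        default_factory=lambda: {2: 0.40, 3: 0.30, 4: 0.22, 5: 0.08}
    )
    # one divergence parameter per unit; the fourth unit is a strongly
    # bottlenecked single-collection population, pushing its pairwise FST
    # against the others toward the top of the 0-0.3 range
    F_unit: float | tuple[float, ...] = (0.05, 0.06, 0.05, 0.50, 0.03, 0.02, 0.04)
    F_coll: float = 0.015
    # per-collection missingness spanning the 0.008-0.338 range, the largest
    # on the bottlenecked collection (degraded-sample tranche)
    missing_rate: float | Sequence[float] = (
        0.008, 0.021, 0.041, 0.028, 0.036, 0.031, 0.022, 0.037, 0.338,
        0.046, 0.082, 0.108, 0.029, 0.123, 0.130, 0.012, 0.068,
    )
    depth_model: tuple[float, float] = (80.0, 5.0)
    map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MAP))
    base_dirichlet_alpha: float = 1.5

    def __post_init__(self) -> None:
        f_units = (
            [self.F_unit] if np.isscalar(self.F_unit) else list(self.F_unit)
        )
        for f in [*f_units, self.F_coll]:
            if not (0.0 < f < 1.0):
                raise ValueError("F parameters must be in (0, 1)")
        rates = (
            [self.missing_rate]
            if np.isscalar(self.missing_rate)
            else list(self.missing_rate)
        )
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("missing rates must be in [0, 1]")

    @property
    def unit_sizes(self) -> list[int]:
        if isinstance(self.collections_per_unit, int):
            return [self.collections_per_unit] * self.n_units
        sizes = list(self.collections_per_unit)
        if len(sizes) != self.n_units:
            raise ValueError("collections_per_unit length must equal n_units")
        return sizes

    @property
    def collection_names(self) -> dict[str, str]:
        out = {}
        for u, size in enumerate(self.unit_sizes, start=1):
            for c in range(1, size + 1):
                out[f"U{u:02d}C{c}"] = f"unit_{u:02d}"
        return out

    def unit_divergences(self) -> dict[str, float]:
        units = sorted(set(self.collection_names.values()))
        if np.isscalar(self.F_unit):
            return {u: float(self.F_unit) for u in units}
        fs = list(self.F_unit)
        if len(fs) != len(units):
            raise ValueError("one F_unit per unit required")
        return dict(zip(units, map(float, fs)))

    def missing_rates(self) -> dict[str, float]:
        colls = sorted(self.collection_names)
        if np.isscalar(self.missing_rate):
            return {c: float(self.missing_rate) for c in colls}
        rates = list(self.missing_rate)
        if len(rates) != len(colls):
            raise ValueError("one missing rate per collection required")
        return dict(zip(colls, map(float, rates)))


def _dirichlet(
    mean: np.ndarray, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from Dirichlet centered on ``mean`` with divergence parameter f
    (alpha = mean (1-f)/f)."""
    alpha = mean * (1.0 - f) / f
    if (alpha <= 0).any() or not np.isfinite(alpha).all():
        raise ValueError("degenerate Dirichlet parameters")
    draw = rng.dirichlet(alpha)
    # numerical floor: very small alphas can yield exact zeros
    draw = np.clip(draw, 1e-12, None)
    return draw / draw.sum()


def simulate_baseline(
    cfg: SimConfig,
) -> tuple[BaselineDataset, dict[str, dict[str, np.ndarray]]]:
    """Generate a baseline and return it with the true collection allele
    frequencies (collection -> locus -> frequency vector)."""
    rng = np.random.default_rng(cfg.seed)
    coll_to_unit = cfg.collection_names
    collections = sorted(coll_to_unit)
    units = sorted(set(coll_to_unit.values()))
    miss = cfg.missing_rates()

    # marker placement and allele sets
    chroms = list(cfg.map)
    lens = np.array([cfg.map[c] for c in chroms], dtype=float)
    chrom_p = lens / lens.sum()
    k_choices = sorted(cfg.alleles_per_locus)
    k_probs = np.array([cfg.alleles_per_locus[k] for k in k_choices], dtype=float)
    k_probs = k_probs / k_probs.sum()

    markers: list[MarkerDef] = []
    base_freqs: list[np.ndarray] = []
    for l in range(cfg.n_loci):
        k = int(rng.choice(k_choices, p=k_probs))
        alleles = tuple(
            _TRIPLETS[i] for i in sorted(rng.choice(64, size=k, replace=False))
        )
        ci = int(rng.choice(len(chroms), p=chrom_p))
        pos = int(rng.integers(1, cfg.map[chroms[ci]] + 1))
        markers.append(
            MarkerDef(
                locus_id=f"L{l:04d}",
                chromosome=chroms[ci],
                pos_bp=pos,
                category="mhap",
                alleles=alleles,
            )
        )
        p0 = rng.dirichlet(np.full(k, cfg.base_dirichlet_alpha))
        p0 = np.clip(p0, 0.02, None)
        base_freqs.append(p0 / p0.sum())

    # hierarchical frequencies
    f_by_unit = cfg.unit_divergences()
    unit_freqs = {
        u: [_dirichlet(p0, f_by_unit[u], rng) for p0 in base_freqs]
        for u in units
    }
    true_freqs = {
        c: {
            markers[l].locus_id: _dirichlet(
                unit_freqs[coll_to_unit[c]][l], cfg.F_coll, rng
            )
            for l in range(cfg.n_loci)
        }
        for c in collections
    }

    # genotypes
    frames = []
    n = cfg.n_per_collection
    for c in collections:
        inds = np.array([f"{c}_{i:04d}" for i in range(n)])
        for m in markers:
            p = true_freqs[c][m.locus_id]
            allele_arr = np.array(m.alleles)
            a = allele_arr[
                np.searchsorted(np.cumsum(p), rng.random(n)).clip(0, len(p) - 1)
            ]
            b = allele_arr[
                np.searchsorted(np.cumsum(p), rng.random(n)).clip(0, len(p) - 1)
            ]
            gone = rng.random(n) < miss[c]
            a = np.where(gone, "", a)
            b = np.where(gone, "", b)
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": inds,
                        "collection": c,
                        "locus_id": m.locus_id,
                        "allele_a": a,
                        "allele_b": b,
                    }
                )
            )
    genotypes = canonicalize_genotypes(pd.concat(frames, ignore_index=True))
    ds = BaselineDataset(
        markers=markers,
        genotypes=genotypes,
        collections=dict(coll_to_unit),
        metadata={"generator": "simulate_baseline", "seed": cfg.seed},
    )
    return ds, true_freqs


def simulate_read_counts(
    ds: BaselineDataset,
    depth_model: tuple[float, float] = (80.0, 5.0),
    balance_sd: float = 0.0,
    seed: int | None = None,
    background_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-haplotype read depths consistent with the dataset's genotypes.

    Total depth per (individual, locus) is negative binomial with the given
    mean and dispersion k; heterozygote reads split binomially around an
    allele balance of 0.5 perturbed by ``balance_sd``.  With probability
    ``background_rate`` a third haplotype is injected at 30%-45% of the
    total depth, to exercise the multi-haplotype QC path.
    """
    mean_depth, k_disp = depth_model
    rng = np.random.default_rng(seed)
    marker_map = ds.marker_map
    rows: list[tuple[str, str, str, int]] = []
    g = ds.genotypes
    typed = g[g["allele_a"] != ""]
    nb_p = k_disp / (k_disp + mean_depth)
    for row in typed.itertuples(index=False):
        depth = int(rng.negative_binomial(k_disp, nb_p))
        if depth <= 0:
            continue
        a, b = row.allele_a, row.allele_b
        if a == b:
            counts = {a: depth}
        else:
            q = 0.5
            if balance_sd > 0:
                q = float(np.clip(rng.normal(0.5, balance_sd), 0.05, 0.95))
            da = int(rng.binomial(depth, q))
            counts = {a: da, b: depth - da}
        if background_rate > 0 and rng.random() < background_rate:
            others = [
                al
                for al in marker_map[row.locus_id].alleles
                if al not in (a, b)
            ]
            if others:
                bg = others[int(rng.integers(len(others)))]
                frac = rng.uniform(0.30, 0.45)
                counts[bg] = counts.get(bg, 0) + max(1, int(round(frac * depth / (1 - frac))))
        for hap, d in counts.items():
            if d > 0:
                rows.append((row.individual_id, row.locus_id, hap, d))
    return pd.DataFrame(
        rows, columns=["individual_id", "locus_id", "haplotype", "depth"]
    )


def rosa_marker_defs(chromosome: str = "Chr28") -> tuple[list[MarkerDef], dict[str, tuple[str, str]]]:
    """Eight run-timing block markers with their (E-allele, L-allele) map."""
    markers, allele_map = [], {}
    for i in range(8):
        locus = f"ROSA{i+1}"
        markers.append(
            MarkerDef(
                locus_id=locus,
                chromosome=chromosome,
                pos_bp=9_660_000 + i * 80_000,
                category="rosa",
                alleles=("A", "G"),
            )
        )
        allele_map[locus] = ("A", "G")
    return markers, allele_map


def simulate_rosa_block(
    ds: BaselineDataset,
    E_freq: float | Mapping[str, float],
    recomb_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[MarkerDef], dict[str, tuple[str, str]]]:
    """Genotypes at the eight run-timing markers for every fish in ``ds``.

    Haplotypes are intact all-E or all-L blocks (E drawn with the
    per-collection frequency ``E_freq``); with probability ``recomb_rate`` a
    haplotype instead carries a single crossover splitting the block.
    Diplotypes are random unions of two haplotypes.
    """
    rng = np.random.default_rng(seed)
    markers, allele_map = rosa_marker_defs()
    e_alleles = np.array([allele_map[m.locus_id][0] for m in markers])
    l_alleles = np.array([allele_map[m.locus_id][1] for m in markers])

    def hap(coll: str) -> np.ndarray:
        f = E_freq if np.isscalar(E_freq) else E_freq[coll]
        lineage = rng.random() < f
        block = np.where(lineage, e_alleles, l_alleles)
        if recomb_rate > 0 and rng.random() < recomb_rate:
            cut = int(rng.integers(1, 8))
            other = np.where(lineage, l_alleles, e_alleles)
            block = np.concatenate([block[:cut], other[cut:]])
        return block

    rows = []
    for ind, coll in ds.individuals().itertuples(index=False):
        h1, h2 = hap(coll), hap(coll)
        for j, m in enumerate(markers):
            a, b = sorted((h1[j], h2[j]))
            rows.append((ind, coll, m.locus_id, a, b))
    geno = pd.DataFrame(
        rows,
        columns=["individual_id", "collection", "locus_id", "allele_a", "allele_b"],
    )
    return geno, markers, allele_map
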