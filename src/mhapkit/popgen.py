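"""Per-collection population-genetic summaries and pairwise Weir-Cockerham FST.

Summaries per collection (all means over loci):

* ``M``        — total fraction of missing genotypes;
* ``NA_ss``    — mean number of alleles per locus after subsampling every
  collection, at each locus, down to the smallest number of genotyped fish
  in any collection at that locus (without replacement, averaged over
  ``subsample_reps`` random draws);
* ``Ppoly_ss`` — fraction of polymorphic loci under the same subsampling;
* ``Hexp``     — expected heterozygosity, 1 - sum of squared allele
  frequencies, averaged over loci;
* ``Hobs``     — observed fraction of heterozygous genotypes, averaged over
  loci.

Pairwise FST is the Weir & Cockerham (1984) theta in its multiallelic form:
per locus and allele the among-population (a), among-individual (b) and
within-individual (c) variance components are computed from sample sizes,
allele frequencies, and observed heterozygote frequencies; theta is the
ratio of sums, sum(a) / sum(a+b+c), over all loci and alleles.  Negative
estimates are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    GSI_EXCLUDED_CATEGORIES,
    MISSING,
    BaselineDataset,
    genotyped_mask,
    logger,
)


@dataclass
class SummaryStats:
    collection: str
    M: float
    NA_ss: float
    Ppoly_ss: float
    Hexp: float
    Hobs: float


@dataclass
class FstMatrix:
    """Symmetric pairwise theta matrix (diagonal NaN)."""

    theta: pd.DataFrame
    loci_used: str

    def value(self, c1: str, c2: str) -> float:
        return float(self.theta.loc[c1, c2])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _locus_collection_arrays(
    ds: BaselineDataset,
) -> dict[tuple[str, str], np.ndarray]:
    """Genotyped allele-code pairs, shape (n, 2), per (locus, collection)."""
    out: dict[tuple[str, str], np.ndarray] = {}
    marker_map = ds.marker_map
    g = ds.genotypes[genotyped_mask(ds.genotypes)]
    for (locus, coll), sub in g.groupby(["locus_id", "collection"], sort=False):
        idx = {a: i for i, a in enumerate(marker_map[locus].alleles)}
        arr = np.array(
            [[idx[a], idx[b]] for a, b in zip(sub["allele_a"], sub["allele_b"])],
            dtype=np.int64,
        )
        out[(locus, coll)] = arr
    return out


def _distinct_allele_counts(
    arr: np.ndarray, m: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct alleles in each of ``reps`` subsamples of ``m`` individuals."""
    n = arr.shape[0]
    if m >= n:
        flat = np.sort(arr.reshape(-1))
        k = 1 + int((np.diff(flat) != 0).sum())
        return np.full(reps, k, dtype=np.int64)
    pick = np.argsort(rng.random((reps, n)), axis=1)[:, :m]
    chosen = arr[pick].reshape(reps, 2 * m)
    chosen.sort(axis=1)
    return 1 + (np.diff(chosen, axis=1) != 0).sum(axis=1)


def summarize_collections(
    ds: BaselineDataset,
    subsample_reps: int = 1000,
    seed: int | None = None,
) -> list[SummaryStats]:
    """Compute M, NA_ss, Ppoly_ss, Hexp and Hobs for every collection."""
    collections = sorted(ds.collections)
    loci = ds.locus_ids
    arrays = _locus_collection_arrays(ds)
    inds = ds.individuals().groupby("collection")["individual_id"].nunique()

    hexp: dict[str, list[float]] = {c: [] for c in collections}
    hobs: dict[str, list[float]] = {c: [] for c in collections}
    na_ss: dict[str, list[float]] = {c: [] for c in collections}
    poly_ss: dict[str, list[float]] = {c: [] for c in collections}

    for li, locus in enumerate(loci):
        per_coll = {c: arrays.get((locus, c)) for c in collections}
        counts = [0 if a is None else a.shape[0] for a in per_coll.values()]
        m = min(counts)
        rng = np.random.default_rng(None if seed is None else seed + li)
        for c in collections:
            arr = per_coll[c]
            if arr is None or arr.shape[0] == 0:
                continue
            k_alleles = len(ds.marker_map[locus].alleles)
            freqs = np.bincount(arr.reshape(-1), minlength=k_alleles) / (
                2 * arr.shape[0]
            )
            hexp[c].append(1.0 - float((freqs**2).sum()))
            hobs[c].append(float((arr[:, 0] != arr[:, 1]).mean()))
            if m > 0:
                k = _distinct_allele_counts(arr, m, subsample_reps, rng)
                na_ss[c].append(float(k.mean()))
                poly_ss[c].append(float((k > 1).mean()))

    out = []
    n_loci = len(loci)
    for c in collections:
        if c not in inds.index:
            raise ValueError(f"collection {c!r} has no individuals in dataset")
        n_cells = int(inds[c]) * n_loci
        n_typed = sum(
            arrays[(l, c)].shape[0] for l in loci if (l, c) in arrays
        )
        out.append(
            SummaryStats(
                collection=c,
                M=1.0 - n_typed / n_cells if n_cells else 0.0,
                NA_ss=float(np.mean(na_ss[c])) if na_ss[c] else float("nan"),
                Ppoly_ss=float(np.mean(poly_ss[c])) if poly_ss[c] else float("nan"),
                Hexp=float(np.mean(hexp[c])) if hexp[c] else float("nan"),
                Hobs=float(np.mean(hobs[c])) if hobs[c] else float("nan"),
            )
        )
    return out


def summaries_frame(stats: list[SummaryStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats]).set_index("collection")


def allele_frequency_table(
    ds: BaselineDataset,
    group_by: str = "collection",
    loci: set[str] | None = None,
) -> pd.DataFrame:
    """Allele frequencies per group x locus.

    ``N_gene_copies`` is twice the number of genotyped individuals; groups
    with no genotyped fish at a locus contribute no row.
    """
    if group_by not in {"collection", "reporting_unit"}:
        raise ValueError("group_by must be 'collection' or 'reporting_unit'")
    g = ds.genotypes[genotyped_mask(ds.genotypes)].copy()
    if loci is not None:
        unknown = set(loci) - set(ds.locus_ids)
        if unknown:
            raise ValueError(f"loci not in panel: {sorted(unknown)}")
        g = g[g["locus_id"].isin(loci)]
    if group_by == "reporting_unit":
        g["group"] = g["collection"].map(ds.collections)
    else:
        g["group"] = g["collection"]

    copies = pd.concat(
        [
            g[["group", "locus_id", "allele_a"]].rename(columns={"allele_a": "allele"}),
            g[["group", "locus_id", "allele_b"]].rename(columns={"allele_b": "allele"}),
        ]
    )
    tab = (
        copies.groupby(["group", "locus_id", "allele"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = tab.groupby(["group", "locus_id"])["count"].transform("sum")
    tab["freq"] = tab["count"] / totals
    tab["N_gene_copies"] = totals
    return tab[["group", "locus_id", "allele", "freq", "N_gene_copies"]]


# ---------------------------------------------------------------------------
# Weir-Cockerham pairwise FST
# ---------------------------------------------------------------------------

def _freq_het_stats(
    ds: BaselineDataset, loci: list[str]
) -> dict[tuple[str, str], tuple[int, np.ndarray, np.ndarray]]:
    """Per (locus, collection): (n, allele freqs, per-allele het frequency)."""
    out: dict[tuple[str, str], tuple[int, np.ndarray, np.ndarray]] = {}
    marker_map = ds.marker_map
    g = ds.genotypes[genotyped_mask(ds.genotypes)]
    g = g[g["locus_id"].isin(set(loci))]
    for (locus, coll), sub in g.groupby(["locus_id", "collection"], sort=False):
        alleles = marker_map[locus].alleles
        idx = {a: i for i, a in enumerate(alleles)}
        k = len(alleles)
        n = len(sub)
        ai = sub["allele_a"].map(idx).to_numpy()
        bi = sub["allele_b"].map(idx).to_numpy()
        p = (np.bincount(ai, minlength=k) + np.bincount(bi, minlength=k)) / (2 * n)
        het = ai != bi
        h = (
            np.bincount(ai[het], minlength=k) + np.bincount(bi[het], minlength=k)
        ) / n
        out[(locus, coll)] = (n, p, h)
    return out


def wc_pair_components(
    n1: int,
    p1: np.ndarray,
    h1: np.ndarray,
    n2: int,
    p2: np.ndarray,
    h2: np.ndarray,
) -> tuple[float, float]:
    """Weir-Cockerham (a, a+b+c) summed over alleles for a 2-population locus."""
    r = 2.0
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def pairwise_fst(
    ds: BaselineDataset,
    exclude: set[str] | None = None,
) -> FstMatrix:
    """Pairwise multiallelic Weir-Cockerham theta between all collections.

    ``exclude`` is a set of marker categories left out of the calculation
    (by default the run-timing, sex and species-diagnostic categories).
    Theta is the ratio of sums over loci and alleles; loci with fewer than
    two genotyped fish in either collection are skipped for that pair.
    """
    exclude = GSI_EXCLUDED_CATEGORIES if exclude is None else set(exclude)
    loci = [m.locus_id for m in ds.markers if m.category not in exclude]
    stats = _freq_het_stats(ds, loci)
    collections = sorted(ds.collections)
    theta = pd.DataFrame(np.nan, index=collections, columns=collections, dtype=float)
    for i, c1 in enumerate(collections):
        for c2 in collections[i + 1 :]:
            num = den = 0.0
            used = 0
            for locus in loci:
                s1 = stats.get((locus, c1))
                s2 = stats.get((locus, c2))
                if s1 is None or s2 is None or s1[0] < 2 or s2[0] < 2:
                    continue
                a, abc = wc_pair_components(*s1, *s2)
                num += a
                den += abc
                used += 1
            if used == 0 or den == 0.0:
                logger.warning("FST undefined for pair (%s, %s)", c1, c2)
                continue
            theta.loc[c1, c2] = theta.loc[c2, c1] = num / den
    desc = f"categories excluded: {sorted(exclude)}" if exclude else "all markers"
    return FstMatrix(theta=theta, loci_used=desc)
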