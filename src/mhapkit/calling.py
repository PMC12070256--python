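"""Microhaplotype genotype calling from amplicon read counts, plus locus QC.

Calling rule per (individual, locus): let ``D`` be the total read depth over
all haplotypes observed at the locus.

* ``D < min_depth`` (default 20)  -> genotype missing;
* otherwise rank haplotypes by depth (ties broken lexicographically).  If the
  third-ranked haplotype also carries at least ``min_ratio`` of the reads the
  call is suppressed (missing) and the individual is flagged as
  multi-haplotype; if the second-ranked haplotype carries at least
  ``min_ratio`` (default 0.30) of the reads the call is a heterozygote of the
  top two; otherwise a homozygote of the top haplotype.

Locus-level QC covers the fraction of multi-haplotype individuals, a
Monte-Carlo exact test of Hardy-Weinberg equilibrium per collection, and a
heterozygote-deficit null-allele statistic per collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import (
    MISSING,
    BaselineDataset,
    MarkerDef,
    _canonical_pair,
    genotyped_mask,
    logger,
)

NOT_TESTED = float("nan")


@dataclass
class CallingParams:
    """Depth/balance filters and QC thresholds for genotype calling.

    min_depth: minimum total read depth for a call.
    min_ratio: minimum fraction of reads on the minor haplotype of a
        heterozygote (must be <= 0.5).
    hwe_alpha / hwe_reps: significance level and Monte-Carlo replicates for
        the Hardy-Weinberg exact test.
    null_allele_threshold: heterozygote-deficit level above which a locus is
        flagged for a possible null allele.
    """

    min_depth: int = 20
    min_ratio: float = 0.30
    hwe_alpha: float = 0.01
    hwe_reps: int = 10000
    null_allele_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.min_ratio <= 0.5):
            raise ValueError("min_ratio must be in (0, 0.5]")


@dataclass
class LocusQC:
    """Per-locus quality-control summary."""

    locus_id: str
    frac_multi_haplotype: float = 0.0
    hwe_p: dict[str, float] = field(default_factory=dict)
    null_allele_stat: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)


def call_genotype(
    counts: Mapping[str, int], params: CallingParams | None = None
) -> tuple[tuple[str, str] | None, bool]:
    """Call one genotype from haplotype read depths.

    Returns ``(genotype, multi_hap_flag)`` where genotype is a
    lexicographically ordered allele pair or ``None`` (missing).
    """
    params = params or CallingParams()
    if any(d < 0 for d in counts.values()):
        raise ValueError("negative read depths")
    total = sum(counts.values())
    if not counts or total < params.min_depth:
        return None, False
    # sort by depth descending, lexicographic tiebreak
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) >= 3 and ranked[2][1] / total >= params.min_ratio:
        return None, True
    if len(ranked) >= 2 and ranked[1][1] / total >= params.min_ratio:
        return _canonical_pair(ranked[0][0], ranked[1][0]), False
    return (ranked[0][0], ranked[0][0]), False


def call_dataset(
    rc: pd.DataFrame,
    markers: Sequence[MarkerDef],
    params: CallingParams | None = None,
    collection_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, LocusQC]]:
    """Call genotypes for every (individual, locus) in a read-count table.

    ``rc`` has columns individual_id, locus_id, haplotype, depth.  Returns a
    genotype table (with a ``collection`` column filled from
    ``collection_map`` when given) and per-locus QC records carrying the
    multi-haplotype fraction.
    """
    params = params or CallingParams()
    known = {m.locus_id for m in markers}
    unknown = set(rc["locus_id"]) - known
    if unknown:
        raise ValueError(f"read counts at loci not in panel: {sorted(unknown)[:5]}")

    rows = []
    multi_counts: dict[str, int] = {m: 0 for m in known}
    seen_counts: dict[str, int] = {m: 0 for m in known}
    for (ind, locus), sub in rc.groupby(["individual_id", "locus_id"], sort=False):
        geno, multi = call_genotype(
            dict(zip(sub["haplotype"], sub["depth"])), params
        )
        seen_counts[locus] += 1
        if multi:
            multi_counts[locus] += 1
        a, b = geno if geno is not None else (MISSING, MISSING)
        coll = collection_map.get(ind, "") if collection_map else ""
        rows.append((ind, coll, locus, a, b))

    geno_df = pd.DataFrame(
        rows, columns=["individual_id", "collection", "locus_id", "allele_a", "allele_b"]
    )
    qc = {
        m: LocusQC(
            locus_id=m,
            frac_multi_haplotype=(multi_counts[m] / seen_counts[m])
            if seen_counts[m]
            else 0.0,
        )
        for m in known
    }
    return geno_df, qc


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo, multiallelic)
# ---------------------------------------------------------------------------

def _config_log_prob(
    het_count: int, genotype_counts: np.ndarray, allele_counts: np.ndarray
) -> float:
    """Log conditional probability of a genotype configuration given the
    allele pool under random pairing (Levene's distribution)."""
    n = int(genotype_counts.sum())
    two_n = int(allele_counts.sum())
    return float(
        gammaln(n + 1)
        + het_count * math.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(two_n + 1)
        - gammaln(genotype_counts + 1).sum()
    )


def hwe_exact_test(
    genotypes: Sequence[tuple[str, str]], reps: int = 10000, seed: int | None = None
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium (multiallelic).

    The test statistic is the conditional probability of the observed
    genotype-count configuration given the allele pool; the p-value is the
    fraction of random pairings of the pool with configuration probability
    at most the observed one (with the observed configuration counted once,
    so p is in (0, 1]).  Returns NaN when fewer than 5 genotypes are given.
    """
    genos = [g for g in genotypes if g[0] != MISSING]
    if len(genos) < 5:
        return NOT_TESTED
    alleles = sorted({a for g in genos for a in g})
    k = len(alleles)
    if k == 1:
        return 1.0
    idx = {a: i for i, a in enumerate(alleles)}
    pairs = np.array([[idx[a], idx[b]] for a, b in genos], dtype=np.int64)
    n = len(pairs)
    pool = pairs.reshape(-1)
    allele_counts = np.bincount(pool, minlength=k)

    def stat(p: np.ndarray) -> float:
        lo = np.minimum(p[:, 0], p[:, 1])
        hi = np.maximum(p[:, 0], p[:, 1])
        codes = lo * k + hi
        gcounts = np.bincount(codes, minlength=k * k).astype(np.float64)
        het = int((lo != hi).sum())
        return _config_log_prob(het, gcounts[gcounts > 0], allele_counts)

    obs = stat(pairs)
    rng = np.random.default_rng(seed)
    hits = 0
    work = pool.copy()
    tol = 1e-9
    for _ in range(reps):
        rng.shuffle(work)
        if stat(work.reshape(n, 2)) <= obs + tol:
            hits += 1
    return (1 + hits) / (1 + reps)


# ---------------------------------------------------------------------------
# null-allele screen (heterozygote deficit)
# ---------------------------------------------------------------------------

def _het_stats(sub: pd.DataFrame) -> tuple[float, float, int]:
    """(Hexp, Hobs, n_genotyped) for one locus x collection slice."""
    sub = sub[genotyped_mask(sub)]
    n = len(sub)
    if n == 0:
        return 0.0, 0.0, 0
    copies = pd.concat([sub["allele_a"], sub["allele_b"]])
    freqs = copies.value_counts(normalize=True).to_numpy()
    hexp = 1.0 - float((freqs**2).sum())
    hobs = float((sub["allele_a"] != sub["allele_b"]).mean())
    return hexp, hobs, n


def null_allele_scan(
    ds: BaselineDataset, params: CallingParams | None = None
) -> pd.DataFrame:
    """Heterozygote-deficit statistic per locus x collection.

    stat = max(0, 1 - Hobs/Hexp): the apparent proportion of heterozygotes
    miscalled as homozygotes, which a segregating null allele inflates.
    Returns columns locus_id, collection, stat, n, flagged — where ``flagged``
    marks loci whose stat exceeds the threshold in a collection with at
    least 20 genotyped fish.
    """
    params = params or CallingParams()
    rows = []
    for (locus, coll), sub in ds.genotypes.groupby(["locus_id", "collection"]):
        hexp, hobs, n = _het_stats(sub)
        stat = 0.0 if hexp == 0 else max(0.0, 1.0 - hobs / hexp)
        rows.append(
            {
                "locus_id": locus,
                "collection": coll,
                "stat": stat,
                "n": n,
                "flagged": bool(stat > params.null_allele_threshold and n >= 20),
            }
        )
    return pd.DataFrame(rows)


def locus_qc(
    ds: BaselineDataset,
    params: CallingParams | None = None,
    seed: int | None = None,
    qc: dict[str, LocusQC] | None = None,
    multi_hap_flag_frac: float = 0.05,
    hwe_fail_collections: int = 2,
) -> dict[str, LocusQC]:
    """Full locus QC: HWE per collection, null-allele scan, and flags.

    Flags: MULTI_HAP when the multi-haplotype fraction exceeds
    ``multi_hap_flag_frac``; HWE_FAIL when the exact-test p-value is below
    ``params.hwe_alpha`` in at least ``hwe_fail_collections`` collections;
    NULL_ALLELE when the heterozygote-deficit screen fires.
    """
    params = params or CallingParams()
    qc = qc or {m.locus_id: LocusQC(locus_id=m.locus_id) for m in ds.markers}
    rng = np.random.default_rng(seed)
    null_df = null_allele_scan(ds, params)
    for (locus, coll), sub in ds.genotypes.groupby(["locus_id", "collection"]):
        rec = qc.setdefault(locus, LocusQC(locus_id=locus))
        genos = list(
            zip(
                sub.loc[genotyped_mask(sub), "allele_a"],
                sub.loc[genotyped_mask(sub), "allele_b"],
            )
        )
        p = hwe_exact_test(genos, reps=params.hwe_reps,
                           seed=int(rng.integers(2**31)))
        if not math.isnan(p):
            rec.hwe_p[coll] = p
    for row in null_df.itertuples(index=False):
        qc.setdefault(row.locus_id, LocusQC(locus_id=row.locus_id))
        qc[row.locus_id].null_allele_stat[row.collection] = row.stat
        if row.flagged:
            qc[row.locus_id].flags.add("NULL_ALLELE")
    for rec in qc.values():
        if rec.frac_multi_haplotype > multi_hap_flag_frac:
            rec.flags.add("MULTI_HAP")
        n_fail = sum(1 for p in rec.hwe_p.values() if p < params.hwe_alpha)
        if n_fail >= hwe_fail_collections:
            rec.flags.add("HWE_FAIL")
    return qc
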