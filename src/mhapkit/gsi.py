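"""Leave-one-out genetic stock identification (self-assignment).

Each baseline fish is assigned to a collection by a per-locus
Dirichlet-compound-multinomial posterior-predictive likelihood: with allele
counts ``y_a`` in a candidate collection and Dirichlet prior ``lambda_a``,
the probability of an unordered genotype (i, j) is

    P = m * (y_i + l_i)/(Y + L) * (y_j + l_j + d_ij)/(Y + L + 1)

with m = 2 for heterozygotes, d_ij = 1 for homozygotes, Y and L the count
and prior totals.  The default prior is lambda_a = 1/K per allele (K the
number of alleles at the locus); a unit prior (lambda_a = 1) is available.

For a fish's own collection its two gene copies are removed from the counts
before evaluating the likelihood (leave-one-out), eliminating the upward
bias of self-assignment power estimates.  Per-fish log-likelihoods are
summed over non-missing loci, normalized across collections into scaled
likelihoods, summed within reporting units, and the fish is assigned to the
top reporting unit and to the top collection within it; a threshold on the
unit score (default 0.8) optionally withholds low-confidence assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import BaselineDataset, genotyped_mask, logger


@dataclass
class GsiPrior:
    """Per-locus Dirichlet parameters, one per allele (all > 0)."""

    lam: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for locus, d in self.lam.items():
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"non-positive prior at locus {locus}")

    @classmethod
    def from_scheme(cls, ds: BaselineDataset, scheme: str = "one_over_K") -> "GsiPrior":
        if scheme not in {"one_over_K", "unit"}:
            raise ValueError("prior scheme must be 'one_over_K' or 'unit'")
        lam = {}
        for m in ds.markers:
            k = len(m.alleles)
            v = 1.0 / k if scheme == "one_over_K" else 1.0
            lam[m.locus_id] = {a: v for a in m.alleles}
        return cls(lam=lam)


@dataclass
class AssignmentResult:
    individual_id: str
    true_collection: str
    scaled_likelihoods: dict[str, float]
    unit_scores: dict[str, float]
    assigned_unit: str
    assigned_collection: str
    passes_threshold: bool
    n_loci_used: int


def genotype_log_likelihood(
    genotype: tuple[str, str],
    allele_counts: Mapping[str, int],
    prior: Mapping[str, float],
) -> float:
    """Log posterior-predictive probability of one genotype.

    Alleles absent from ``allele_counts`` contribute prior mass only (count
    0), so no genotype has probability zero.
    """
    i, j = genotype
    y = {a: allele_counts.get(a, 0) for a in set(prior) | {i, j}}
    lam = dict(prior)
    lam.setdefault(i, min(prior.values()) if prior else 1.0)
    lam.setdefault(j, min(prior.values()) if prior else 1.0)
    Y = sum(y.values())
    L = sum(lam.values())
    if i == j:
        p = (y[i] + lam[i]) / (Y + L) * (y[i] + lam[i] + 1) / (Y + L + 1)
    else:
        p = 2.0 * (y[i] + lam[i]) / (Y + L) * (y[j] + lam[j]) / (Y + L + 1)
    return math.log(p)


def self_assign(
    ds: BaselineDataset,
    prior_scheme: str = "one_over_K",
    threshold: float = 0.8,
    leave_one_out: bool = True,
) -> list[AssignmentResult]:
    """Assign every baseline fish to a collection and reporting unit.

    GSI-excluded markers should already have been removed (see
    ``filter_markers``).  ``leave_one_out=False`` skips the removal of the
    fish's own gene copies and is provided only to quantify the resulting
    inflation of apparent accuracy.
    """
    collections = sorted(ds.collections)
    if len(collections) < 2:
        # degenerate but well-defined: everything assigns to the one collection
        pass
    coll_index = {c: i for i, c in enumerate(collections)}
    units = sorted(set(ds.collections.values()))
    prior = GsiPrior.from_scheme(ds, prior_scheme)

    fish = ds.individuals().sort_values("individual_id").to_records(index=False)
    fish_index = {ind: i for i, (ind, _) in enumerate(fish)}
    n_fish = len(fish)
    loglik = np.zeros((n_fish, len(collections)))
    n_loci_used = np.zeros(n_fish, dtype=int)

    g = ds.genotypes[genotyped_mask(ds.genotypes)]
    for locus, sub in g.groupby("locus_id", sort=False):
        alleles = ds.marker_map[locus].alleles
        aidx = {a: i for i, a in enumerate(alleles)}
        k = len(alleles)
        lam = np.array([prior.lam[locus][a] for a in alleles])
        L = lam.sum()

        ai = sub["allele_a"].map(aidx).to_numpy()
        bi = sub["allele_b"].map(aidx).to_numpy()
        ci = sub["collection"].map(coll_index).to_numpy()
        fi = sub["individual_id"].map(fish_index).to_numpy()

        # baseline allele counts per collection
        y = np.zeros((len(collections), k))
        np.add.at(y, (ci, ai), 1.0)
        np.add.at(y, (ci, bi), 1.0)
        Y = y.sum(axis=1)  # (C,)

        # per fish-with-data x collection counts, with leave-one-out applied
        yi = y[:, ai].T  # (F_l, C): count of fish's allele_a in each collection
        yj = y[:, bi].T
        Yf = np.broadcast_to(Y, (len(ai), len(collections))).copy()
        if leave_one_out:
            rows = np.arange(len(ai))
            # remove this fish's own two gene copies from its collection:
            # homozygotes carry 2 copies of allele_a, heterozygotes 1 of each
            yi[rows, ci] -= 1.0 + (ai == bi)
            yj[rows, ci] -= 1.0 + (ai == bi)
            Yf[rows, ci] -= 2.0

        lam_i = lam[ai][:, None]
        lam_j = lam[bi][:, None]
        hom = (ai == bi)[:, None]
        p = np.where(
            hom,
            (yi + lam_i) / (Yf + L) * (yi + lam_i + 1.0) / (Yf + L + 1.0),
            2.0 * (yi + lam_i) / (Yf + L) * (yj + lam_j) / (Yf + L + 1.0),
        )
        loglik[fi] += np.log(p)
        n_loci_used[fi] += 1

    results: list[AssignmentResult] = []
    for (ind, true_coll) in fish:
        i = fish_index[ind]
        if n_loci_used[i] == 0:
            logger.warning("fish %s has no non-missing loci; unassigned", ind)
            continue
        ll = loglik[i]
        w = np.exp(ll - ll.max())
        scaled = w / w.sum()
        scaled_map = dict(zip(collections, scaled))
        unit_scores = {u: 0.0 for u in units}
        for c, s in scaled_map.items():
            unit_scores[ds.collections[c]] += float(s)
        best_unit = max(sorted(unit_scores), key=lambda u: unit_scores[u])
        members = [c for c in collections if ds.collections[c] == best_unit]
        best_coll = max(sorted(members), key=lambda c: scaled_map[c])
        results.append(
            AssignmentResult(
                individual_id=str(ind),
                true_collection=str(true_coll),
                scaled_likelihoods={c: float(v) for c, v in scaled_map.items()},
                unit_scores=unit_scores,
                assigned_unit=best_unit,
                assigned_collection=best_coll,
                passes_threshold=bool(unit_scores[best_unit] > threshold),
                n_loci_used=int(n_loci_used[i]),
            )
        )
    return results


@dataclass
class AssignmentMatrix:
    counts: pd.DataFrame  # rows true group, columns assigned group
    accuracy: float
    n_assigned: int
    n_dropped: int


def assignment_matrix(
    results: Sequence[AssignmentResult],
    ds: BaselineDataset,
    level: str = "reporting_unit",
    apply_threshold: bool = False,
) -> AssignmentMatrix:
    """Cross-tabulate true vs assigned group; accuracy = trace / total."""
    if not results:
        raise ValueError("no assignment results")
    if level not in {"collection", "reporting_unit"}:
        raise ValueError("level must be 'collection' or 'reporting_unit'")
    kept = [r for r in results if r.passes_threshold or not apply_threshold]
    if level == "collection":
        groups = sorted(ds.collections)
        true = [r.true_collection for r in kept]
        assigned = [r.assigned_collection for r in kept]
    else:
        groups = sorted(set(ds.collections.values()))
        true = [ds.collections[r.true_collection] for r in kept]
        assigned = [r.assigned_unit for r in kept]
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, a in zip(true, assigned):
        counts.loc[t, a] += 1
    total = int(counts.to_numpy().sum())
    acc = float(np.trace(counts.to_numpy()) / total) if total else float("nan")
    return AssignmentMatrix(
        counts=counts,
        accuracy=acc,
        n_assigned=total,
        n_dropped=len(results) - len(kept),
    )


@dataclass
class RosaCrossTab:
    strata: dict[str, AssignmentMatrix]
    n_excluded: int  # NO_CALL or RECOMBINANT fish


def rosa_cross_tab(
    results: Sequence[AssignmentResult],
    rosa_calls: Mapping[str, str],
    ds: BaselineDataset,
    level: str = "reporting_unit",
) -> RosaCrossTab:
    """One assignment matrix per run-timing (RoSA) diplotype stratum.

    ``rosa_calls`` maps individual_id to a diplotype string; fish whose call
    is not EE/EL/LL (no-call or recombinant) are excluded and counted.
    """
    strata: dict[str, AssignmentMatrix] = {}
    excluded = 0
    by_dip: dict[str, list[AssignmentResult]] = {}
    for r in results:
        dip = rosa_calls.get(r.individual_id, "NO_CALL")
        if dip in {"EE", "EL", "LL"}:
            by_dip.setdefault(dip, []).append(r)
        else:
            excluded += 1
    for dip, rs in sorted(by_dip.items()):
        strata[dip] = assignment_matrix(rs, ds, level=level)
    return RosaCrossTab(strata=strata, n_excluded=excluded)
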