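"""Bespoke marker-level classification rules.

* RoSA diplotype calling: the run-timing region on chromosome 28 carries
  eight markers whose E (early) and L (late) haplotypes travel as intact
  blocks.  A fish is EE / EL / LL only when all eight markers are typed and
  concordant (all homozygous-E, all heterozygous, or all homozygous-L); any
  missing marker yields NO_CALL, and any other pattern marks a recombinant
  haplotype.
* LFAR candidate screen: selecting SNPs in the late-fall associated region
  from a precomputed association table, by association p-value rank within
  the peak plus allele-frequency-difference, near-fixation and functional-
  annotation clauses.
* Control-marker interpretation: a species-diagnostic marker (fixed for
  alternate alleles in coho vs Chinook) and the sdY sex marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .data import MISSING

ROSA_DIPLOTYPES = ("EE", "EL", "LL", "RECOMBINANT", "NO_CALL")
N_ROSA_MARKERS = 8


@dataclass
class RosaCall:
    individual_id: str
    diplotype: str
    n_markers_typed: int


@dataclass
class CandidateSNP:
    """One row of a precomputed case-control association table.

    ``d_est`` is the estimated allele-frequency difference between the
    late-fall and fall groups; ``d_ci_lower`` is the lower confidence bound
    of |d|; ``near_fixation`` marks SNPs nearly fixed in one group;
    ``annotation_impact`` is the functional-annotation class.
    """

    snp_id: str
    chromosome: str
    pos_bp: int
    assoc_p: float
    d_est: float
    d_ci_lower: float
    near_fixation: bool = False
    annotation_impact: str = "None"

    def __post_init__(self) -> None:
        if not (0.0 < self.assoc_p <= 1.0):
            raise ValueError(f"{self.snp_id}: assoc_p must be in (0, 1]")
        if abs(self.d_est) > 1.0:
            raise ValueError(f"{self.snp_id}: |d_est| must be <= 1")
        if self.d_ci_lower > abs(self.d_est) + 1e-12:
            raise ValueError(f"{self.snp_id}: d_ci_lower exceeds |d_est|")


@dataclass
class ControlCall:
    individual_id: str
    species: str  # chinook | coho | ambiguous
    sex: str  # male | female | no_call


def call_rosa(
    genotypes: Mapping[str, tuple[str, str] | None],
    allele_map: Mapping[str, tuple[str, str]],
    individual_id: str = "",
) -> RosaCall:
    """Classify one fish's run-timing diplotype from its eight RoSA markers.

    ``genotypes`` maps marker -> unordered allele pair (or None/missing);
    ``allele_map`` maps marker -> (E-allele, L-allele).  A definitive call
    requires all eight markers typed; concordance is strict.
    """
    if len(allele_map) != N_ROSA_MARKERS:
        raise ValueError(f"allele_map must cover {N_ROSA_MARKERS} markers")
    states = []
    typed = 0
    for marker, (e_allele, l_allele) in allele_map.items():
        g = genotypes.get(marker)
        if g is None or MISSING in g:
            continue
        bad = set(g) - {e_allele, l_allele}
        if bad:
            raise ValueError(f"{marker}: allele(s) {sorted(bad)} not in allele map")
        typed += 1
        n_e = sum(1 for a in g if a == e_allele)
        states.append({2: "E", 1: "H", 0: "L"}[n_e])
    if typed < N_ROSA_MARKERS:
        return RosaCall(individual_id, "NO_CALL", typed)
    uniq = set(states)
    if uniq == {"E"}:
        dip = "EE"
    elif uniq == {"L"}:
        dip = "LL"
    elif uniq == {"H"}:
        dip = "EL"
    else:
        dip = "RECOMBINANT"
    return RosaCall(individual_id, dip, typed)


def lfar_screen(
    candidates: Sequence[CandidateSNP],
    peak_interval: tuple[int, int],
    n_top: int = 10,
    d_high: float = 0.75,
    ci_high: float = 0.5,
    d_mid: float = 0.5,
    ci_mid: float = 0.25,
    d_adjacent: float = 0.48,
    adjacent_bp: int = 2_200_000,
) -> list[CandidateSNP]:
    """Select late-fall associated candidate SNPs.

    A SNP is selected if it is among the ``n_top`` lowest association
    p-values inside the peak interval, or satisfies any of:

    * |d| > 0.75 with lower confidence bound > 0.5;
    * |d| > 0.5 with lower bound > 0.25 and near fixation in one group;
    * functional annotation High or Moderate;
    * |d| > 0.48 with lower bound > 0.25 and position beyond 2.2 Mb
      (peak-adjacent SNPs informative about recombination in the region).
    """
    if not candidates:
        raise ValueError("no candidate SNPs")
    lo, hi = peak_interval
    in_peak = [c for c in candidates if lo <= c.pos_bp <= hi]
    top = set(
        c.snp_id
        for c in sorted(in_peak, key=lambda c: (c.assoc_p, c.snp_id))[:n_top]
    )
    out = []
    for c in candidates:
        keep = (
            c.snp_id in top
            or (abs(c.d_est) > d_high and c.d_ci_lower > ci_high)
            or (abs(c.d_est) > d_mid and c.d_ci_lower > ci_mid and c.near_fixation)
            or c.annotation_impact in {"High", "Moderate"}
            or (
                abs(c.d_est) > d_adjacent
                and c.d_ci_lower > ci_mid
                and c.pos_bp > adjacent_bp
            )
        )
        if keep:
            out.append(c)
    return out


def call_controls(
    coho_genotype: tuple[str, str] | None,
    sdy_genotype: tuple[str, str] | None,
    coho_alleles: tuple[str, str] = ("C", "T"),
    sdy_functional_allele: str = "A",
    individual_id: str = "",
) -> ControlCall:
    """Interpret the species-diagnostic and sex (sdY) control markers.

    ``coho_alleles`` is (chinook allele, coho allele).  Homozygotes for the
    coho allele are called coho; chinook-allele homozygotes chinook;
    heterozygous or missing is ambiguous.  Presence of the functional sdY
    allele means male, a successful call without it female.
    """
    chinook_allele, coho_allele = coho_alleles
    if coho_genotype is None or MISSING in coho_genotype:
        species = "ambiguous"
    elif set(coho_genotype) == {coho_allele}:
        species = "coho"
    elif set(coho_genotype) == {chinook_allele}:
        species = "chinook"
    else:
        species = "ambiguous"
    if sdy_genotype is None or MISSING in sdy_genotype:
        sex = "no_call"
    elif sdy_functional_allele in sdy_genotype:
        sex = "male"
    else:
        sex = "female"
    return ControlCall(individual_id=individual_id, species=species, sex=sex)
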