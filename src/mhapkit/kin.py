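"""Close-kin power analysis: pairwise relationship likelihood ratios,
false-positive/false-negative rate estimation by importance sampling and
Monte Carlo, and gene-dropping simulation of kin pairs under physical
linkage.

Relationships are parameterized by Cotterman kappa coefficients
(probabilities of sharing 0/1/2 alleles identical by descent at a locus):
U = (1,0,0), PO = (0,1,0), FS = (1/4,1/2,1/4), HS = AN = (1/2,1/2,0).
HS and AN differ only when loci are physically linked, which is why linked
simulation matters for separating them.

The per-locus joint probability of an observed genotype pair is

    P(O1, O2 | rel) = sum_{t1,t2} Perr(O1|t1) Perr(O2|t2) P(t1, t2 | kappa)

with P(t1,t2|kappa) = k0 P(t1)P(t2) + k1 P(t1) T(t2|t1) + k2 P(t1) 1[t2=t1],
where P is the HWE genotype probability and T(t2|t1) transmits one allele
drawn uniformly from t1 plus one population draw.  Genotyping error follows
the true-genotype-independent (TGIE) model: with probability epsilon the
recorded genotype is a fresh HWE draw.

The log-likelihood ratio for a pair is the sum over loci of
log P(O1,O2|num) - log P(O1,O2|den); unrelated-pair tail probabilities
(FPRs) far below Monte-Carlo reach are estimated by importance sampling
from the numerator relationship with weights exp(-LLR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import BaselineDataset, MarkerDef, genotyped_mask, logger

#: Cotterman kappa coefficients per relationship
KAPPAS: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "AN": (0.5, 0.5, 0.0),
}


@dataclass(frozen=True)
class RelationshipModel:
    name: str

    def __post_init__(self) -> None:
        if self.name not in KAPPAS:
            raise ValueError(f"unknown relationship {self.name!r}")

    @property
    def kappas(self) -> tuple[float, float, float]:
        return KAPPAS[self.name]


@dataclass(frozen=True)
class ErrorModel:
    """True-genotype-independent error: with probability epsilon the observed
    genotype is an HWE draw unrelated to the true genotype."""

    epsilon: float = 0.01
    kind: str = "TGIE"

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        if self.kind != "TGIE":
            raise ValueError("only the TGIE error model is implemented")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass
class GeneticMap:
    """Per-locus linkage group and genetic position (cM).

    Markers on different linkage groups recombine freely (r = 0.5); the
    default physical-to-genetic conversion is 1 cM per Mb.
    """

    locus_ids: list[str]
    linkage_group: list[str]
    pos_cM: np.ndarray

    @classmethod
    def from_markers(
        cls, markers: Sequence[MarkerDef], cm_per_mb: float = 1.0
    ) -> "GeneticMap":
        pos = np.array(
            [
                m.pos_cM if m.pos_cM is not None else m.pos_bp * 1e-6 * cm_per_mb
                for m in markers
            ]
        )
        return cls(
            locus_ids=[m.locus_id for m in markers],
            linkage_group=[m.chromosome for m in markers],
            pos_cM=pos,
        )

    def map_order(self) -> np.ndarray:
        """Locus indices sorted by (linkage group, position)."""
        keys = list(zip(self.linkage_group, self.pos_cM, self.locus_ids))
        return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))

    def recomb_fractions(self, order: np.ndarray) -> np.ndarray:
        """r between consecutive loci in map order; r[0] = 0.5 by convention."""
        r = np.full(len(order), 0.5)
        for k in range(1, len(order)):
            i, j = order[k - 1], order[k]
            if self.linkage_group[i] == self.linkage_group[j]:
                d = abs(self.pos_cM[j] - self.pos_cM[i])
                r[k] = float(haldane(d))
        return r


# ---------------------------------------------------------------------------
# per-locus probability tables
# ---------------------------------------------------------------------------

def _check_freqs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 1 or (p < 0).any():
        raise ValueError("allele frequencies must be a non-negative vector")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return p / p.sum()


def genotype_index(k: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Unordered genotype list [(i,j), i<=j] and a (k,k) -> index lookup."""
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    lut = np.zeros((k, k), dtype=np.int64)
    for g, (i, j) in enumerate(pairs):
        lut[i, j] = lut[j, i] = g
    return pairs, lut


def hwe_genotype_probs(p: np.ndarray) -> np.ndarray:
    """HWE probabilities of the unordered genotypes of ``genotype_index``."""
    k = len(p)
    pairs, _ = genotype_index(k)
    return np.array(
        [p[i] ** 2 if i == j else 2 * p[i] * p[j] for i, j in pairs]
    )


def _transmission_matrix(p: np.ndarray) -> np.ndarray:
    """T[t1, t2]: probability offspring genotype t2 arises from parent t1 by
    one transmitted allele (uniform over t1's two) plus one population draw."""
    k = len(p)
    pairs, lut = genotype_index(k)
    G = len(pairs)
    T = np.zeros((G, G))
    for g1, (a, b) in enumerate(pairs):
        for trans, w in ((a, 0.5), (b, 0.5)):
            for c in range(k):
                T[g1, lut[trans, c]] += w * p[c]
    return T


def _error_matrix(p: np.ndarray, eps: float) -> np.ndarray:
    """E[t, o] = P(observed o | true t) under TGIE."""
    phwe = hwe_genotype_probs(p)
    G = len(phwe)
    return (1.0 - eps) * np.eye(G) + eps * np.tile(phwe, (G, 1))


def joint_genotype_table(
    p: np.ndarray, rel: RelationshipModel | str, err: ErrorModel | None = None
) -> np.ndarray:
    """(G, G) matrix of P(O1=g1, O2=g2 | rel, eps) over unordered genotypes."""
    rel = RelationshipModel(rel) if isinstance(rel, str) else rel
    err = err or ErrorModel(epsilon=0.0)
    p = _check_freqs(p)
    k0, k1, k2 = rel.kappas
    phwe = hwe_genotype_probs(p)
    J = (
        k0 * np.outer(phwe, phwe)
        + k1 * phwe[:, None] * _transmission_matrix(p)
        + k2 * np.diag(phwe)
    )
    if err.epsilon > 0:
        E = _error_matrix(p, err.epsilon)
        J = E.T @ J @ E
    return J


def joint_genotype_prob(
    g1: tuple[str, str],
    g2: tuple[str, str],
    freqs: Mapping[str, float],
    rel: RelationshipModel | str,
    err: ErrorModel | None = None,
) -> float:
    """P(observed pair (g1, g2) | relationship) at one locus."""
    alleles = list(freqs)
    p = _check_freqs(np.array([freqs[a] for a in alleles]))
    aidx = {a: i for i, a in enumerate(alleles)}
    _, lut = genotype_index(len(alleles))
    J = joint_genotype_table(p, rel, err)
    i1 = lut[aidx[g1[0]], aidx[g1[1]]]
    i2 = lut[aidx[g2[0]], aidx[g2[1]]]
    return float(J[i1, i2])


def llr_table(
    p: np.ndarray,
    num_rel: RelationshipModel | str,
    den_rel: RelationshipModel | str,
    err: ErrorModel | None = None,
) -> np.ndarray:
    """(G, G) table of per-locus log-likelihood ratios num vs den."""
    Jn = joint_genotype_table(p, num_rel, err)
    Jd = joint_genotype_table(p, den_rel, err)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(Jn) - np.log(Jd)
    # impossible-under-both pairs (zero/zero) carry no information
    out[np.isnan(out)] = 0.0
    return out


def llr(
    pair_genotypes: Sequence[tuple[tuple[str, str] | None, tuple[str, str] | None]],
    freqs: Sequence[Mapping[str, float]],
    num_rel: RelationshipModel | str,
    den_rel: RelationshipModel | str,
    err: ErrorModel | None = None,
) -> float:
    """Sum of per-locus log-likelihood ratios over loci non-missing in both
    members; raises if every locus is missing."""
    total = 0.0
    used = 0
    for (pg, f) in zip(pair_genotypes, freqs):
        g1, g2 = pg
        if g1 is None or g2 is None:
            continue
        pn = joint_genotype_prob(g1, g2, f, num_rel, err)
        pd = joint_genotype_prob(g1, g2, f, den_rel, err)
        total += math.log(pn) - math.log(pd)
        used += 1
    if used == 0:
        raise ValueError("no locus is non-missing in both pair members")
    return total


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

@dataclass
class KinPanel:
    """Allele frequencies (one vector per locus) plus an optional map."""

    locus_ids: list[str]
    alleles: list[tuple[str, ...]]
    freqs: list[np.ndarray]
    gmap: GeneticMap | None = None

    def __post_init__(self) -> None:
        self.freqs = [_check_freqs(p) for p in self.freqs]


def panel_from_baseline(
    ds: BaselineDataset,
    collections: Sequence[str] | None = None,
    cm_per_mb: float = 1.0,
) -> KinPanel:
    """Pool allele frequencies over ``collections`` (default: all) and attach
    the physical map.  Loci with no genotyped fish in the group are dropped."""
    g = ds.genotypes[genotyped_mask(ds.genotypes)]
    if collections is not None:
        g = g[g["collection"].isin(set(collections))]
    markers, freqs = [], []
    for m in ds.markers:
        sub = g[g["locus_id"] == m.locus_id]
        if len(sub) == 0:
            logger.warning("locus %s has no genotypes in group; dropped", m.locus_id)
            continue
        idx = {a: i for i, a in enumerate(m.alleles)}
        counts = np.zeros(len(m.alleles))
        for col in ("allele_a", "allele_b"):
            np.add.at(counts, sub[col].map(idx).to_numpy(), 1.0)
        markers.append(m)
        freqs.append(counts / counts.sum())
    return KinPanel(
        locus_ids=[m.locus_id for m in markers],
        alleles=[m.alleles for m in markers],
        freqs=freqs,
        gmap=GeneticMap.from_markers(markers, cm_per_mb=cm_per_mb),
    )


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _sample_alleles(
    p: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    return np.searchsorted(np.cumsum(p), rng.random(n)).clip(0, len(p) - 1)


def _llr_tables(
    panel: KinPanel,
    num_rel: str,
    den_rel: str,
    err: ErrorModel,
) -> list[np.ndarray]:
    return [llr_table(p, num_rel, den_rel, err) for p in panel.freqs]


def simulate_pairs_unlinked(
    panel: KinPanel,
    rel: RelationshipModel | str,
    n_reps: int,
    err: ErrorModel | None = None,
    seed: int | None = None,
    num_rel: str | None = None,
    den_rel: str = "U",
) -> np.ndarray:
    """Log-likelihood ratios of simulated pairs, loci independent.

    Pairs are generated mechanically: a latent IBD state is drawn i.i.d.
    from the kappas at every locus, true genotypes are formed, TGIE error is
    applied, and the pair is scored with the analytic per-locus tables for
    ``num_rel`` vs ``den_rel`` (defaults: the simulated relationship vs U).
    """
    rel = rel.name if isinstance(rel, RelationshipModel) else rel
    err = err or ErrorModel()
    num_rel = num_rel or rel
    rng = np.random.default_rng(seed)
    kap = np.array(KAPPAS[rel])
    tables = _llr_tables(panel, num_rel, den_rel, err)
    lam = np.zeros(n_reps)
    for p, tab in zip(panel.freqs, tables):
        k = len(p)
        _, lut = genotype_index(k)
        a1 = _sample_alleles(p, n_reps, rng)
        b1 = _sample_alleles(p, n_reps, rng)
        s = np.searchsorted(np.cumsum(kap), rng.random(n_reps)).clip(0, 2)
        shared = np.where(rng.random(n_reps) < 0.5, a1, b1)
        popA = _sample_alleles(p, n_reps, rng)
        popB = _sample_alleles(p, n_reps, rng)
        a2 = np.select([s == 0, s == 1], [popA, shared], default=a1)
        b2 = np.select([s == 0, s == 1], [popB, popA], default=b1)
        if err.epsilon > 0:
            for pair in ((a1, b1), (a2, b2)):
                hit = rng.random(n_reps) < err.epsilon
                nh = int(hit.sum())
                if nh:
                    pair[0][hit] = _sample_alleles(p, nh, rng)
                    pair[1][hit] = _sample_alleles(p, nh, rng)
        lam += tab[lut[a1, b1], lut[a2, b2]]
    return lam


def _founder_factory(
    panel: KinPanel, n_reps: int, rng: np.random.Generator
) -> Callable[[], tuple[np.ndarray, np.ndarray]]:
    L = len(panel.freqs)

    def new_founder() -> tuple[np.ndarray, np.ndarray]:
        haps = []
        for _ in range(2):
            h = np.empty((n_reps, L), dtype=np.int64)
            for l, p in enumerate(panel.freqs):
                h[:, l] = _sample_alleles(p, n_reps, rng)
            haps.append(h)
        return haps[0], haps[1]

    return new_founder


def _meiosis_factory(
    r: np.ndarray, n_reps: int, rng: np.random.Generator
) -> Callable[[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    L = len(r)

    def meiosis(ind: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        switch = rng.random((n_reps, L)) < r  # col 0 uses r=0.5: random start
        inh = np.logical_xor.accumulate(switch, axis=1)
        return np.where(inh, ind[1], ind[0])

    return meiosis


def _pedigree_pair(
    rel: str,
    new_founder: Callable[[], tuple[np.ndarray, np.ndarray]],
    meiosis: Callable[[tuple[np.ndarray, np.ndarray]], np.ndarray],
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Gene-drop the pedigree recipe for ``rel`` and return the focal pair."""
    if rel == "U":
        return new_founder(), new_founder()
    if rel == "PO":
        parent, mate = new_founder(), new_founder()
        child = (meiosis(parent), meiosis(mate))
        return parent, child
    if rel == "FS":
        pa, pb = new_founder(), new_founder()
        return (meiosis(pa), meiosis(pb)), (meiosis(pa), meiosis(pb))
    if rel == "HS":
        shared, m1, m2 = new_founder(), new_founder(), new_founder()
        return (meiosis(shared), meiosis(m1)), (meiosis(shared), meiosis(m2))
    if rel == "AN":
        # three generations: grandparent couple -> two full sibs; one sib's
        # child (with an unrelated mate) is the niece/nephew of the other
        g1, g2 = new_founder(), new_founder()
        sib1 = (meiosis(g1), meiosis(g2))
        sib2 = (meiosis(g1), meiosis(g2))
        mate = new_founder()
        child = (meiosis(sib1), meiosis(mate))
        return sib2, child
    raise ValueError(f"unknown relationship {rel!r}")


def simulate_pairs_linked(
    panel: KinPanel,
    rel: RelationshipModel | str,
    n_reps: int,
    err: ErrorModel | None = None,
    seed: int | None = None,
    num_rel: str | None = None,
    den_rel: str = "U",
) -> np.ndarray:
    """Log-likelihood ratios of gene-dropped pairs with physical linkage.

    Founder haplotypes are assembled under linkage equilibrium; meioses
    recombine between map-adjacent loci with Haldane fractions.  The pair is
    scored with the same per-locus (linkage-free) likelihood tables used
    throughout, mirroring the estimation model.
    """
    rel = rel.name if isinstance(rel, RelationshipModel) else rel
    err = err or ErrorModel()
    num_rel = num_rel or rel
    if panel.gmap is None:
        raise ValueError("panel has no genetic map")
    rng = np.random.default_rng(seed)
    order = panel.gmap.map_order()
    r = panel.gmap.recomb_fractions(order)
    ordered = KinPanel(
        locus_ids=[panel.locus_ids[i] for i in order],
        alleles=[panel.alleles[i] for i in order],
        freqs=[panel.freqs[i] for i in order],
    )
    new_founder = _founder_factory(ordered, n_reps, rng)
    meiosis = _meiosis_factory(r, n_reps, rng)
    ind1, ind2 = _pedigree_pair(rel, new_founder, meiosis)

    tables = _llr_tables(ordered, num_rel, den_rel, err)
    lam = np.zeros(n_reps)
    for l, (p, tab) in enumerate(zip(ordered.freqs, tables)):
        _, lut = genotype_index(len(p))
        a1, b1 = ind1[0][:, l].copy(), ind1[1][:, l].copy()
        a2, b2 = ind2[0][:, l].copy(), ind2[1][:, l].copy()
        if err.epsilon > 0:
            for pair in ((a1, b1), (a2, b2)):
                hit = rng.random(n_reps) < err.epsilon
                nh = int(hit.sum())
                if nh:
                    pair[0][hit] = _sample_alleles(p, nh, rng)
                    pair[1][hit] = _sample_alleles(p, nh, rng)
        lam += tab[lut[a1, b1], lut[a2, b2]]
    return lam


def simulate_ibd_linked(
    gmap: GeneticMap,
    rel: RelationshipModel | str,
    n_reps: int,
    seed: int | None = None,
) -> np.ndarray:
    """(n_reps, L) matrix of IBD sharing counts (0/1/2) per locus in map
    order, from the same gene-dropping pedigrees as the genotype simulator."""
    rel = rel.name if isinstance(rel, RelationshipModel) else rel
    rng = np.random.default_rng(seed)
    order = gmap.map_order()
    r = gmap.recomb_fractions(order)
    L = len(order)
    counter = [0]

    def new_founder() -> tuple[np.ndarray, np.ndarray]:
        # each founder haplotype gets a unique label, constant along the genome
        h1 = np.full((n_reps, L), counter[0], dtype=np.int64)
        h2 = np.full((n_reps, L), counter[0] + 1, dtype=np.int64)
        counter[0] += 2
        return h1, h2

    meiosis = _meiosis_factory(r, n_reps, rng)
    ind1, ind2 = _pedigree_pair(rel, new_founder, meiosis)
    x1, x2 = ind1
    y1, y2 = ind2
    ibd = ((x1 == y1) | (x1 == y2)).astype(np.int64) + (
        (x2 == y1) | (x2 == y2)
    ).astype(np.int64)
    return ibd


# ---------------------------------------------------------------------------
# power estimation
# ---------------------------------------------------------------------------

@dataclass
class PowerResult:
    numerator_rel: str
    denominator_rel: str
    fnr_grid: list[float]
    fpr_estimates: list[tuple[float, float, int]]  # (estimate, MC SE, n_reps)
    method: str
    true_rel: str | None = None
    thresholds: list[float] = field(default_factory=list)


def _check_fnr_grid(fnr_grid: Sequence[float]) -> list[float]:
    grid = [float(f) for f in fnr_grid]
    if any(not (0.0 < f < 1.0) for f in grid):
        raise ValueError("FNR grid values must be in (0, 1)")
    return grid


def estimate_fpr_importance(
    panel: KinPanel,
    num_rel: str,
    fnr_grid: Sequence[float],
    n_reps: int = 100_000,
    err: ErrorModel | None = None,
    seed: int | None = None,
) -> PowerResult:
    """Unrelated-pair false-positive rates by importance sampling.

    The decision threshold eta(phi) is the phi-quantile of the LLR under the
    numerator relationship simulated *with* linkage; the U-pair tail
    probability P_U(LLR >= eta) is then estimated from unlinked draws of the
    numerator relationship with weights exp(-LLR) (exact for U pairs, whose
    loci are independent across individuals).
    """
    if num_rel not in {"PO", "FS", "HS"}:
        raise ValueError("importance sampling supports num_rel in {PO, FS, HS}")
    grid = _check_fnr_grid(fnr_grid)
    err = err or ErrorModel()
    rng = np.random.default_rng(seed)
    s1, s2 = (int(rng.integers(2**31)) for _ in range(2))
    lam_linked = simulate_pairs_linked(panel, num_rel, n_reps, err, s1, den_rel="U")
    lam_is = simulate_pairs_unlinked(panel, num_rel, n_reps, err, s2, den_rel="U")

    estimates, thresholds = [], []
    for phi in grid:
        eta = float(np.quantile(lam_linked, phi))
        w = np.zeros(n_reps)
        mask = lam_is >= eta
        w[mask] = np.exp(np.clip(-lam_is[mask], None, 700.0))
        fpr = float(w.mean())
        se = float(w.std(ddof=1) / math.sqrt(n_reps))
        estimates.append((fpr, se, n_reps))
        thresholds.append(eta)
    return PowerResult(
        numerator_rel=num_rel,
        denominator_rel="U",
        fnr_grid=grid,
        fpr_estimates=estimates,
        method="importance_sampling",
        thresholds=thresholds,
    )


def estimate_rates_mc(
    panel: KinPanel,
    true_rel: str,
    num_rel: str,
    den_rel: str,
    fnr_grid: Sequence[float],
    n_reps: int = 100_000,
    err: ErrorModel | None = None,
    seed: int | None = None,
) -> PowerResult:
    """Kin-vs-kin error rates by plain Monte Carlo with linked simulation.

    The threshold eta(phi) is the phi-quantile of the LLR (num vs den) under
    the numerator relationship; the reported rate is the fraction of linked
    ``true_rel`` draws at or above eta, with a binomial standard error.
    Rates much below 1e-3 are not reliably estimable at default n_reps.
    """
    if true_rel not in KAPPAS:
        raise ValueError(f"unknown relationship {true_rel!r}")
    grid = _check_fnr_grid(fnr_grid)
    err = err or ErrorModel()
    rng = np.random.default_rng(seed)
    s1, s2 = (int(rng.integers(2**31)) for _ in range(2))
    lam_num = simulate_pairs_linked(
        panel, num_rel, n_reps, err, s1, num_rel=num_rel, den_rel=den_rel
    )
    lam_true = simulate_pairs_linked(
        panel, true_rel, n_reps, err, s2, num_rel=num_rel, den_rel=den_rel
    )
    estimates, thresholds = [], []
    for phi in grid:
        eta = float(np.quantile(lam_num, phi))
        f = float((lam_true >= eta).mean())
        se = math.sqrt(f * (1.0 - f) / n_reps)
        estimates.append((f, se, n_reps))
        thresholds.append(eta)
    return PowerResult(
        numerator_rel=num_rel,
        denominator_rel=den_rel,
        fnr_grid=grid,
        fpr_estimates=estimates,
        method="monte_carlo",
        true_rel=true_rel,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# microhaplotype vs most-heterozygous-SNP projection
# ---------------------------------------------------------------------------

def reduce_to_top_snp(ds: BaselineDataset) -> BaselineDataset:
    """Project every microhaplotype locus down to its most heterozygous
    single variant site (expected heterozygosity pooled over all
    collections); genotypes are re-coded to the base at that site."""
    g = ds.genotypes
    typed = g[genotyped_mask(g)]
    new_markers: list[MarkerDef] = []
    projections: dict[str, dict[str, str]] = {}
    for m in ds.markers:
        length = len(m.alleles[0])
        sub = typed[typed["locus_id"] == m.locus_id]
        copies = list(sub["allele_a"]) + list(sub["allele_b"])
        best_pos, best_h = 0, -1.0
        for pos in range(length):
            bases = {a[pos] for a in m.alleles}
            if len(bases) < 2 and length > 1:
                continue
            if copies:
                vals, counts = np.unique([c[pos] for c in copies], return_counts=True)
                freqs = counts / counts.sum()
                h = 1.0 - float((freqs**2).sum())
            else:
                h = 0.0
            if h > best_h:
                best_pos, best_h = pos, h
        proj = {a: a[best_pos] for a in m.alleles}
        projections[m.locus_id] = proj
        new_alleles = tuple(sorted(set(proj.values())))
        new_markers.append(
            MarkerDef(
                locus_id=m.locus_id,
                chromosome=m.chromosome,
                pos_bp=m.pos_bp,
                pos_cM=m.pos_cM,
                category=m.category,
                alleles=new_alleles,
                excluded_from_gsi=m.excluded_from_gsi,
            )
        )
    new_g = g.copy()
    for locus, proj in projections.items():
        rows = new_g["locus_id"] == locus
        for col in ("allele_a", "allele_b"):
            new_g.loc[rows, col] = new_g.loc[rows, col].map(
                lambda a: proj.get(a, a) if a != "" else ""
            )
    # unordered pairs: restore canonical order after projection
    from .data import canonicalize_genotypes

    new_g = canonicalize_genotypes(new_g)
    return BaselineDataset(
        markers=new_markers,
        genotypes=new_g,
        collections=dict(ds.collections),
        metadata=dict(ds.metadata),
    )
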