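"""Core domain types and file I/O for microhaplotype baseline datasets.

A *baseline* (reference dataset) is a set of individuals, nested in
collections, nested in reporting units, genotyped at a shared panel of
amplicon markers.  Each marker is a microhaplotype: its alleles are short
strings over {A,C,G,T} giving the phased bases at the variant sites of one
amplicon (e.g. ``"ACG"`` for a 3-SNP amplicon).  Genotypes are unordered
pairs of alleles; a missing genotype has both alleles empty.

On disk a baseline is three CSV tables:

* ``genotypes.csv``   — individual_id, collection, locus_id, allele_a, allele_b
* ``markers.csv``     — locus_id, chromosome, pos_bp, pos_cM, category,
  alleles (semicolon-joined), excluded_from_gsi
* ``collections.csv`` — collection, reporting_unit

Missing genotypes are written as empty fields.  Genomic coordinates are
1-based.  Markers without a chromosome assignment use the chromosome string
``"unplaced:<locus_id>"`` so that linkage-aware code treats each as its own
linkage group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("mhapkit")

#: sentinel for a missing allele in genotype tables (empty string on disk too)
MISSING = ""

#: recognised marker categories
CATEGORIES = frozenset(
    {"mhap", "scon", "rosa", "wrap", "lfar", "sixx", "vgll", "sexy", "coho"}
)

#: categories routinely excluded from GSI likelihood calculations
GSI_EXCLUDED_CATEGORIES = frozenset({"rosa", "sexy", "coho"})

GENOTYPE_COLUMNS = ["individual_id", "collection", "locus_id", "allele_a", "allele_b"]
MARKER_COLUMNS = [
    "locus_id",
    "chromosome",
    "pos_bp",
    "pos_cM",
    "category",
    "alleles",
    "excluded_from_gsi",
]
COLLECTION_COLUMNS = ["collection", "reporting_unit"]
READCOUNT_COLUMNS = ["individual_id", "locus_id", "haplotype", "depth"]


class BaselineFormatError(ValueError):
    """A baseline file does not have the expected structure."""


class BaselineValidationError(ValueError):
    """A baseline violates a dataset invariant."""


@dataclass
class MarkerDef:
    """One amplicon locus.

    ``alleles`` is the ordered set of haplotype strings; all alleles at a
    locus have equal length (one character per variant site).  Markers in
    the run-timing, sex and species-diagnostic categories are always
    excluded from GSI likelihoods.
    """

    locus_id: str
    chromosome: str
    pos_bp: int
    pos_cM: float | None = None
    category: str = "mhap"
    alleles: tuple[str, ...] = ()
    excluded_from_gsi: bool = False

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)
        if not self.alleles:
            raise BaselineValidationError(f"{self.locus_id}: empty allele set")
        if len(set(self.alleles)) != len(self.alleles):
            raise BaselineValidationError(f"{self.locus_id}: duplicate alleles")
        lengths = {len(a) for a in self.alleles}
        if len(lengths) != 1:
            raise BaselineValidationError(
                f"{self.locus_id}: alleles of unequal length {sorted(self.alleles)}"
            )
        bad = [a for a in self.alleles if set(a) - set("ACGT")]
        if bad:
            raise BaselineValidationError(f"{self.locus_id}: non-ACGT alleles {bad}")
        if self.category not in CATEGORIES:
            raise BaselineValidationError(
                f"{self.locus_id}: unknown category {self.category!r}"
            )
        if int(self.pos_bp) < 1:
            raise BaselineValidationError(f"{self.locus_id}: pos_bp must be >= 1")
        self.pos_bp = int(self.pos_bp)
        if self.category in GSI_EXCLUDED_CATEGORIES:
            self.excluded_from_gsi = True

    def with_allele(self, allele: str) -> "MarkerDef":
        """Return a copy with ``allele`` appended to the allele set."""
        return replace(self, alleles=self.alleles + (allele,))


@dataclass
class BaselineDataset:
    """Markers, genotypes and the collection -> reporting-unit mapping."""

    markers: list[MarkerDef]
    genotypes: pd.DataFrame
    collections: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = self.genotypes.reset_index(drop=True)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def marker_map(self) -> dict[str, MarkerDef]:
        return {m.locus_id: m for m in self.markers}

    @property
    def locus_ids(self) -> list[str]:
        return [m.locus_id for m in self.markers]

    def reporting_unit(self, collection: str) -> str:
        return self.collections[collection]

    def individuals(self) -> pd.DataFrame:
        """Unique (individual_id, collection) pairs."""
        return self.genotypes[["individual_id", "collection"]].drop_duplicates()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        g = self.genotypes
        missing_cols = [c for c in GENOTYPE_COLUMNS if c not in g.columns]
        if missing_cols:
            raise BaselineFormatError(f"genotype table lacks columns {missing_cols}")
        known = set(self.marker_map)
        bad_loci = set(g["locus_id"]) - known
        if bad_loci:
            raise BaselineValidationError(
                f"genotypes refer to unknown loci: {sorted(bad_loci)[:5]}"
            )
        bad_coll = set(g["collection"]) - set(self.collections)
        if bad_coll:
            raise BaselineValidationError(
                f"collections without a reporting unit: {sorted(bad_coll)}"
            )
        dup = g.duplicated(subset=["individual_id", "locus_id"])
        if dup.any():
            rows = g.loc[dup, ["individual_id", "locus_id"]].head(5)
            raise BaselineValidationError(
                f"duplicated (individual, locus) rows, e.g.\n{rows}"
            )
        half = (g["allele_a"] == MISSING) ^ (g["allele_b"] == MISSING)
        if half.any():
            raise BaselineValidationError(
                "genotypes with exactly one missing allele are not allowed"
            )


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Genotypes are unordered: store alleles lexicographically."""
    return (a, b) if a <= b else (b, a)


def canonicalize_genotypes(g: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with allele_a <= allele_b on every row."""
    g = g.copy()
    swap = g["allele_a"] > g["allele_b"]
    if swap.any():
        a = g.loc[swap, "allele_a"].copy()
        g.loc[swap, "allele_a"] = g.loc[swap, "allele_b"]
        g.loc[swap, "allele_b"] = a
    return g


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise BaselineFormatError(f"{path}: missing column(s) {missing}")
    return df


def read_markers(path: Path | str) -> list[MarkerDef]:
    df = _read_csv(path, MARKER_COLUMNS)
    markers = []
    for row in df.itertuples(index=False):
        markers.append(
            MarkerDef(
                locus_id=row.locus_id,
                chromosome=row.chromosome,
                pos_bp=int(row.pos_bp),
                pos_cM=float(row.pos_cM) if row.pos_cM != "" else None,
                category=row.category,
                alleles=tuple(a for a in row.alleles.split(";") if a),
                excluded_from_gsi=str(row.excluded_from_gsi).strip().lower()
                in {"true", "1", "yes"},
            )
        )
    return markers


def read_baseline(
    genotype_path: Path | str,
    marker_path: Path | str,
    collection_path: Path | str,
) -> BaselineDataset:
    """Load and validate a baseline from its three CSV tables.

    Alleles observed in the genotype table but absent from the marker
    definition are appended to the marker's allele set with a warning.
    """
    markers = read_markers(marker_path)
    coll_df = _read_csv(collection_path, COLLECTION_COLUMNS)
    collections = dict(zip(coll_df["collection"], coll_df["reporting_unit"]))
    if any(u == "" for u in collections.values()):
        bad = [c for c, u in collections.items() if u == ""]
        raise BaselineValidationError(f"collections without reporting unit: {bad}")

    geno = _read_csv(genotype_path, GENOTYPE_COLUMNS)[GENOTYPE_COLUMNS]
    geno = canonicalize_genotypes(geno)

    # extend allele sets for novel alleles seen in the data
    marker_map = {m.locus_id: m for m in markers}
    nonmiss = geno[geno["allele_a"] != MISSING]
    for locus, sub in nonmiss.groupby("locus_id", sort=False):
        if locus not in marker_map:
            continue
        seen = set(sub["allele_a"]) | set(sub["allele_b"])
        novel = sorted(seen - set(marker_map[locus].alleles))
        for allele in novel:
            logger.warning("locus %s: allele %s not in marker definition; appending",
                           locus, allele)
            marker_map[locus] = marker_map[locus].with_allele(allele)
    markers = [marker_map[m.locus_id] for m in markers]

    return BaselineDataset(markers=markers, genotypes=geno, collections=collections)


def write_baseline(ds: BaselineDataset, out_dir: Path | str) -> dict[str, Path]:
    """Serialize a baseline to genotypes/markers/collections CSVs in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.csv",
        "markers": out / "markers.csv",
        "collections": out / "collections.csv",
    }
    ds.genotypes[GENOTYPE_COLUMNS].to_csv(paths["genotypes"], index=False)
    mrows = [
        {
            "locus_id": m.locus_id,
            "chromosome": m.chromosome,
            "pos_bp": m.pos_bp,
            "pos_cM": "" if m.pos_cM is None else m.pos_cM,
            "category": m.category,
            "alleles": ";".join(m.alleles),
            "excluded_from_gsi": m.excluded_from_gsi,
        }
        for m in ds.markers
    ]
    pd.DataFrame(mrows, columns=MARKER_COLUMNS).to_csv(paths["markers"], index=False)
    pd.DataFrame(
        sorted(ds.collections.items()), columns=COLLECTION_COLUMNS
    ).to_csv(paths["collections"], index=False)
    return paths


def read_read_counts(path: Path | str) -> pd.DataFrame:
    """Load a per-haplotype read count table (ReadCountTable)."""
    df = _read_csv(path, READCOUNT_COLUMNS)[READCOUNT_COLUMNS]
    df["depth"] = df["depth"].astype(int)
    if (df["depth"] < 0).any():
        raise BaselineValidationError("negative read depths")
    if df.duplicated(subset=["individual_id", "locus_id", "haplotype"]).any():
        raise BaselineValidationError("duplicate (individual, locus, haplotype) rows")
    return df


# ---------------------------------------------------------------------------
# marker filtering
# ---------------------------------------------------------------------------

def filter_markers(
    ds: BaselineDataset,
    exclude_gsi_flagged: bool = False,
    categories: Iterable[str] | None = None,
) -> BaselineDataset:
    """Subset the panel (and genotypes) by GSI-exclusion flag and/or category.

    Genotype records at retained loci are passed through unchanged.
    """
    cats = set(categories) if categories is not None else None
    keep = [
        m
        for m in ds.markers
        if not (exclude_gsi_flagged and m.excluded_from_gsi)
        and (cats is None or m.category in cats)
    ]
    keep_ids = {m.locus_id for m in keep}
    geno = ds.genotypes[ds.genotypes["locus_id"].isin(keep_ids)]
    return BaselineDataset(
        markers=keep,
        genotypes=geno,
        collections=dict(ds.collections),
        metadata=dict(ds.metadata),
    )


def genotyped_mask(g: pd.DataFrame) -> pd.Series:
    """Boolean mask of non-missing genotype rows."""
    return g["allele_a"] != MISSING
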