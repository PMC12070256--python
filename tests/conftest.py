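import numpy as np
import pandas as pd
import pytest

from mhapkit import BaselineDataset, MarkerDef, SimConfig, simulate_baseline


@pytest.fixture(scope="session")
def small_baseline():
    """A 2-unit x 2-collection baseline with moderate divergence."""
    cfg = SimConfig(
        seed=11,
        n_units=2,
        collections_per_unit=2,
        n_per_collection=30,
        n_loci=25,
        F_unit=0.10,
        F_coll=0.03,
        missing_rate=0.05,
    )
    ds, truth = simulate_baseline(cfg)
    return ds, truth


def make_baseline(rows, markers=None, collections=None):
    """Hand-build a tiny BaselineDataset from (ind, coll, locus, a, b) rows."""
    g = pd.DataFrame(
        rows, columns=["individual_id", "collection", "locus_id", "allele_a", "allele_b"]
    )
    if markers is None:
        markers = []
        for locus, sub in g.groupby("locus_id"):
            alleles = sorted(
                {a for a in list(sub["allele_a"]) + list(sub["allele_b"]) if a}
            )
            markers.append(
                MarkerDef(locus_id=locus, chromosome="Chr1", pos_bp=1000,
                          alleles=tuple(alleles))
            )
    if collections is None:
        collections = {c: f"unit_{c}" for c in g["collection"].unique()}
    return BaselineDataset(markers=markers, genotypes=g, collections=collections)
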