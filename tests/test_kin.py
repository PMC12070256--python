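"""Relationship likelihoods, simulators, and power estimation."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from mhapkit import (
    KAPPAS,
    ErrorModel,
    GeneticMap,
    KinPanel,
    MarkerDef,
    joint_genotype_prob,
    joint_genotype_table,
    estimate_fpr_importance,
    estimate_rates_mc,
    haldane,
    llr,
    llr_table,
    reduce_to_top_snp,
    simulate_ibd_linked,
    simulate_pairs_linked,
    simulate_pairs_unlinked,
)
from mhapkit.kin import genotype_index, hwe_genotype_probs
from conftest import make_baseline

E0 = ErrorModel(epsilon=0.0)
BIALLELIC = {"A": 0.5, "T": 0.5}


def _toy_panel(freq_list, same_chrom=False, spacing_cM=1e6):
    """Panel from frequency vectors, loci unlinked unless same_chrom."""
    n = len(freq_list)
    groups = ["Chr1"] * n if same_chrom else [f"Chr{i+1}" for i in range(n)]
    gmap = GeneticMap(
        locus_ids=[f"L{i}" for i in range(n)],
        linkage_group=groups,
        pos_cM=np.arange(n, dtype=float) * (spacing_cM if same_chrom else 0.0),
    )
    return KinPanel(
        locus_ids=gmap.locus_ids,
        alleles=[tuple("ACGT"[: len(p)]) for p in freq_list],
        freqs=[np.asarray(p, dtype=float) for p in freq_list],
        gmap=gmap,
    )


def test_joint_probability_worked_values():
    assert joint_genotype_prob(("A", "T"), ("A", "T"), BIALLELIC, "U", E0) == \
        pytest.approx(0.25)
    assert joint_genotype_prob(("A", "T"), ("A", "T"), BIALLELIC, "PO", E0) == \
        pytest.approx(0.25)
    assert joint_genotype_prob(("A", "T"), ("A", "T"), BIALLELIC, "FS", E0) == \
        pytest.approx(0.3125)


def test_joint_tables_sum_to_one_all_relationships():
    rng = np.random.default_rng(1)
    for k in (2, 4, 6):
        p = rng.dirichlet(np.ones(k))
        for rel in KAPPAS:
            for eps in (0.0, 0.01, 0.2):
                J = joint_genotype_table(p, rel, ErrorModel(epsilon=eps))
                assert J.sum() == pytest.approx(1.0, abs=1e-9)


def test_monomorphic_locus_prob_one():
    for rel in KAPPAS:
        assert joint_genotype_prob(
            ("A", "A"), ("A", "A"), {"A": 1.0}, rel, E0
        ) == pytest.approx(1.0)


def test_error_limit_erases_relationship_signal():
    """As epsilon -> 1 the joint probability factorizes into HWE marginals."""
    p = np.array([0.3, 0.7])
    err = ErrorModel(epsilon=1 - 1e-6)
    phwe = hwe_genotype_probs(p)
    for rel in ("PO", "FS"):
        J = joint_genotype_table(p, rel, err)
        assert np.allclose(J, np.outer(phwe, phwe), atol=1e-5)


def test_epsilon_one_rejected():
    with pytest.raises(ValueError):
        ErrorModel(epsilon=1.0)


def test_llr_identity_antisymmetry_and_value():
    pair = [((("A", "T")), (("A", "T")))]
    freqs = [BIALLELIC]
    assert llr(pair, freqs, "FS", "FS", E0) == 0.0
    fwd = llr(pair, freqs, "FS", "U", E0)
    assert fwd == pytest.approx(math.log(0.3125 / 0.25))
    assert llr(pair, freqs, "U", "FS", E0) == pytest.approx(-fwd)


def test_llr_skips_missing_and_requires_one_locus():
    pairs = [(None, ("A", "T")), (("A", "T"), ("A", "T"))]
    freqs = [BIALLELIC, BIALLELIC]
    assert llr(pairs, freqs, "FS", "U", E0) == pytest.approx(math.log(1.25))
    with pytest.raises(ValueError):
        llr([(None, None)], [BIALLELIC], "FS", "U", E0)


def test_simulator_reproducible_and_matches_analytic():
    """Fixed seeds reproduce; the mechanical pair simulator reproduces the
    analytic joint table; importance weights average to 1."""
    panel = _toy_panel([[0.5, 0.5]])
    err = ErrorModel(epsilon=0.01)
    lam1 = simulate_pairs_unlinked(panel, "FS", 5000, err, seed=5)
    lam2 = simulate_pairs_unlinked(panel, "FS", 5000, err, seed=5)
    assert np.array_equal(lam1, lam2)

    # single biallelic locus: P(het, het | FS) empirical vs analytic
    n = 100_000
    lam = simulate_pairs_unlinked(panel, "FS", n, err, seed=6)
    target = llr_table(panel.freqs[0], "FS", "U", err)[1, 1]
    p_analytic = joint_genotype_prob(("A", "C"), ("A", "C"),
                                     {"A": 0.5, "C": 0.5}, "FS", err)
    emp = (np.abs(lam - target) < 1e-12).mean()
    se = math.sqrt(p_analytic * (1 - p_analytic) / n)
    assert abs(emp - p_analytic) <= 3 * se

    # importance-weight identity E_rel[exp(-LLR_rel/U)] = 1
    panel2 = _toy_panel([[0.4, 0.6], [0.2, 0.3, 0.5], [0.25] * 4])
    lam = simulate_pairs_unlinked(panel2, "PO", 200_000, err, seed=7)
    w = np.exp(-lam)
    assert abs(w.mean() - 1.0) <= 3 * w.std() / math.sqrt(len(w))


def test_zero_cm_fs_loci_share_ibd_state():
    gmap = GeneticMap(["L0", "L1"], ["Chr1", "Chr1"], np.array([10.0, 10.0]))
    ibd = simulate_ibd_linked(gmap, "FS", 2000, seed=8)
    assert (ibd[:, 0] == ibd[:, 1]).all()
    # FS kappas recovered marginally
    counts = np.bincount(ibd[:, 0], minlength=3) / len(ibd)
    assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.04)


def test_po_ibd_constant_one():
    gmap = GeneticMap(["L0", "L1"], ["Chr1", "Chr1"], np.array([0.0, 50.0]))
    ibd = simulate_ibd_linked(gmap, "PO", 1000, seed=9)
    assert (ibd == 1).all()


def test_unlinked_limit_of_linked_simulator():
    """Loci on different linkage groups: linked and unlinked LLR samples are
    indistinguishable (KS)."""
    rng = np.random.default_rng(10)
    panel = _toy_panel([rng.dirichlet(np.ones(3)) for _ in range(12)])
    err = ErrorModel(epsilon=0.01)
    lam_link = simulate_pairs_linked(panel, "FS", 20_000, err, seed=11)
    lam_unlk = simulate_pairs_unlinked(panel, "FS", 20_000, err, seed=12)
    assert ks_2samp(lam_link, lam_unlk).pvalue > 0.001


def test_hs_an_identical_unlinked_but_not_linked():
    """HS and AN share kappas, so unlinked LLR distributions coincide; under
    tight linkage the extra meiosis shortens AN segments, shrinking the
    variance of the summed LLR."""
    rng = np.random.default_rng(13)
    tight = _toy_panel(
        [rng.dirichlet(np.ones(4)) for _ in range(30)],
        same_chrom=True, spacing_cM=1.0,
    )
    err = ErrorModel(epsilon=0.01)
    hs_u = simulate_pairs_unlinked(tight, "HS", 20_000, err, seed=14,
                                   num_rel="HS", den_rel="U")
    an_u = simulate_pairs_unlinked(tight, "AN", 20_000, err, seed=15,
                                   num_rel="HS", den_rel="U")
    assert ks_2samp(hs_u, an_u).pvalue > 0.001
    hs_l = simulate_pairs_linked(tight, "HS", 40_000, err, seed=16,
                                 num_rel="HS", den_rel="U")
    an_l = simulate_pairs_linked(tight, "AN", 40_000, err, seed=17,
                                 num_rel="HS", den_rel="U")
    assert np.var(an_l) < np.var(hs_l)
    assert ks_2samp(hs_l, an_l).pvalue < 0.001


def test_mean_llr_ordering():
    """E[LLR_FS/U] orders FS > HS > U on any polymorphic panel."""
    rng = np.random.default_rng(18)
    panel = _toy_panel([rng.dirichlet(np.ones(3)) for _ in range(20)])
    err = ErrorModel(epsilon=0.01)
    means = {
        rel: simulate_pairs_unlinked(
            panel, rel, 30_000, err, seed=19, num_rel="FS", den_rel="U"
        ).mean()
        for rel in ("FS", "HS", "U")
    }
    assert means["FS"] > means["HS"] > means["U"]


def test_fpr_grid_validation_and_monotonicity():
    rng = np.random.default_rng(20)
    panel = _toy_panel([rng.dirichlet(np.ones(3)) for _ in range(8)])
    with pytest.raises(ValueError):
        estimate_fpr_importance(panel, "PO", [0.0, 0.5], n_reps=100, seed=1)
    with pytest.raises(ValueError):
        estimate_fpr_importance(panel, "AN", [0.1], n_reps=100, seed=1)
    res = estimate_fpr_importance(
        panel, "FS", [0.05, 0.2, 0.5, 0.9], n_reps=40_000, seed=21
    )
    fprs = [e[0] for e in res.fpr_estimates]
    # a larger tolerated FNR means a higher threshold, so FPR can only fall
    assert fprs == sorted(fprs, reverse=True)
    assert all(f >= 0 and se >= 0 for f, se, _ in res.fpr_estimates)


def test_mc_self_consistency():
    """With true_rel = num_rel the rate at eta(phi) is 1 - phi within 3 SE."""
    rng = np.random.default_rng(22)
    panel = _toy_panel([rng.dirichlet(np.ones(3)) for _ in range(15)])
    res = estimate_rates_mc(
        panel, "FS", "FS", "U", [0.1, 0.3], n_reps=20_000, seed=23
    )
    for phi, (rate, se, _) in zip(res.fnr_grid, res.fpr_estimates):
        assert abs(rate - (1 - phi)) <= 3 * se + 0.01


# ---------------------------------------------------------------------------
# most-heterozygous-SNP projection
# ---------------------------------------------------------------------------

def test_reduce_single_variant_position_is_identity():
    rows = [("f1", "c1", "L1", "A", "T"), ("f2", "c1", "L1", "T", "T")]
    ds = make_baseline(rows)
    out = reduce_to_top_snp(ds)
    assert out.marker_map["L1"].alleles == ("A", "T")
    assert out.genotypes.equals(ds.genotypes)


def test_reduce_keeps_most_heterozygous_position():
    # alleles ACG/ACA/TCA: position 1 segregates A/T, position 3 G/A.
    # freq(ACG)=0.5 -> pos1 Hexp = 0.375 (A .75/T .25), pos3 Hexp = 0.5
    rows = [
        ("f1", "c1", "L1", "ACG", "ACG"),
        ("f2", "c1", "L1", "ACA", "TCA"),
    ]
    markers = [MarkerDef("L1", "Chr1", 5, alleles=("ACG", "ACA", "TCA"))]
    ds = make_baseline(rows, markers=markers)
    out = reduce_to_top_snp(ds)
    assert set(out.marker_map["L1"].alleles) == {"G", "A"}
    g = out.genotypes.set_index("individual_id")
    assert tuple(g.loc["f1", ["allele_a", "allele_b"]]) == ("G", "G")
    assert tuple(g.loc["f2", ["allele_a", "allele_b"]]) == ("A", "A")


def test_reduce_never_increases_heterozygosity(small_baseline):
    from mhapkit import summarize_collections

    ds, _ = small_baseline
    red = reduce_to_top_snp(ds)
    h_full = np.mean([s.Hexp for s in
                      summarize_collections(ds, subsample_reps=2, seed=1)])
    h_red = np.mean([s.Hexp for s in
                     summarize_collections(red, subsample_reps=2, seed=1)])
    assert h_red <= h_full + 1e-12


def test_haldane_bounds():
    assert haldane(0.0) == 0.0
    assert haldane(1e9) == pytest.approx(0.5)
    d = np.linspace(0, 500, 50)
    r = haldane(d)
    assert ((r >= 0) & (r <= 0.5)).all()
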