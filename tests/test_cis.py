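import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sbscreen as sb
from sbscreen.errors import ConfigError, DataError


def poisson_tail_oracle(k, lam):
    """Direct Poisson-mass summation of the upper tail, from k upward
    (no 1-CDF cancellation)."""
    if k == 0:
        return 1.0
    terms = []
    jmax = int(max(k + 600, lam + 60 * math.sqrt(lam + 1) + 600))
    for j in range(k, jmax):
        terms.append(math.exp(j * math.log(lam) - lam - math.lgamma(j + 1)))
    return math.fsum(terms)


def test_poisson_pvalue_closed_form_lambda_one():
    """lambda = 1 (N=100, w=10 kb, L=1 Mb), k=8: p equals the closed-form
    tail 1 - e^{-1} sum_{j<=7} 1/j!."""
    p = sb.poisson_cis_pvalue(8, 10_000, 100, 1_000_000)
    closed = 1 - math.exp(-1) * math.fsum(1 / math.factorial(j) for j in range(8))
    assert abs(p - closed) < 1e-12
    assert abs(p - poisson_tail_oracle(8, 1.0)) < 1e-12


@pytest.mark.parametrize("lam", [0.05, 0.5, 1.0, 5.0, 20.0, 50.0])
def test_poisson_pvalue_matches_direct_summation(lam):
    L = 1_000_000.0
    n_total = 1000
    w = lam * L / n_total
    for k in range(0, 201, 7):
        p = sb.poisson_cis_pvalue(k, w, n_total, L)
        assert abs(p - poisson_tail_oracle(k, lam)) < 1e-12


def test_poisson_pvalue_edge_cases():
    assert sb.poisson_cis_pvalue(0, 1000, 50, 1e6) == 1.0
    ps = [sb.poisson_cis_pvalue(k, 10_000, 100, 1e6) for k in range(1, 30)]
    assert all(a > b for a, b in zip(ps, ps[1:]))  # strictly decreasing in k
    with pytest.raises(ConfigError):
        sb.poisson_cis_pvalue(1, 2e6, 10, 1e6)  # window longer than genome
    with pytest.raises(ConfigError):
        sb.poisson_cis_pvalue(-1, 100, 10, 1e6)


def _insertion(chrom, pos, tumour, strain="12740", orient="+"):
    return {"chrom": chrom, "pos": pos, "transposon_orient": orient,
            "tumour_id": tumour, "strain": strain, "cre": "WAP", "support": 1}


def test_scan_region_is_gene_span_plus_3kb(mouse_catalog):
    gene = next(iter(mouse_catalog))
    ins = pd.DataFrame([_insertion(gene.chrom, gene.start, "T1")])
    scan = sb.gene_cis_scan(ins, mouse_catalog, alpha=1.1)
    row = scan[scan["gene_id"] == gene.gene_id].iloc[0]
    assert row["region_end"] - row["region_start"] + 1 == gene.length + 3000


def test_scan_zero_insertion_gene_absent(mouse_catalog):
    gene = next(iter(mouse_catalog))
    ins = pd.DataFrame([_insertion(gene.chrom, gene.start, "T1")])
    scan = sb.gene_cis_scan(ins, mouse_catalog)
    assert set(scan["gene_id"]) <= {gene.gene_id}
    empty = sb.gene_cis_scan(pd.DataFrame(), mouse_catalog)
    assert empty.empty


def test_site_counts_for_all_overlapping_gene_regions():
    """A site inside two genes' extended regions counts for both."""
    a = sb.GeneModel("a", "chr1", "+", 10_000, 20_000, ((10_000, 20_000),))
    b = sb.GeneModel("b", "chr1", "-", 21_000, 30_000, ((21_000, 30_000),))
    cat = sb.GeneCatalog(chrom_lengths={"chr1": 100_000})
    cat.add(a), cat.add(b)
    # pos 19_500 is in a's body and in b's 3' .. wait b is minus: extended (21000,33000)
    ins = pd.DataFrame([_insertion("chr1", 20_500, "T1")])
    scan = sb.gene_cis_scan(ins, cat, alpha=1.1)
    ks = dict(zip(scan["gene_id"], scan["k"]))
    # 20_500 is upstream of neither a (+, upstream left) nor b (-, upstream right)
    assert ks == {"a": 0, "b": 0}
    ins = pd.DataFrame([_insertion("chr1", 15_000, "T1")])
    c = sb.GeneModel("c", "chr1", "+", 16_000, 26_000, ((16_000, 26_000),))
    cat2 = sb.GeneCatalog(chrom_lengths={"chr1": 100_000})
    cat2.add(a), cat2.add(c)  # c's upstream window [13000,15999] overlaps a
    scan2 = sb.gene_cis_scan(ins, cat2, alpha=1.1)
    assert dict(zip(scan2["gene_id"], scan2["k"])) == {"a": 1, "c": 1}


def test_recurrence_filter_rules():
    df = pd.DataFrame({
        "gene_id": ["kept", "dropped", "boundary"],
        "f_12740": [0.06, 0.10, 0.05],
        "f_12775": [0.07, 0.03, 0.05],
        "frequency": [0.065, 0.065, 0.05],
    })
    cand = sb.recurrence_filter(df, theta=0.05)
    assert set(cand.genes) == {"kept", "boundary"}  # >= keeps the boundary


def test_recurrence_filter_undefined_fraction_errors():
    df = pd.DataFrame({"gene_id": ["g"], "f_12740": [0.2],
                       "f_12775": [np.nan], "frequency": [0.1]})
    with pytest.raises(DataError):
        sb.recurrence_filter(df)


def test_combine_groups_arithmetic():
    a = [f"g{i}" for i in range(119)]
    b = [f"g{i}" for i in range(79, 169)]  # overlap 40
    res = sb.combine_groups(a, b)
    assert len(res["union"]) == 169
    assert len(res["intersection"]) == 40
    assert len(res["only_a"]) + len(res["only_b"]) + len(res["intersection"]) == 169
    # disjoint and identical cases
    assert len(sb.combine_groups(["x"], ["y"])["union"]) == 2
    same = sb.combine_groups(a, a)
    assert same["union"] == same["intersection"] == sorted(a)


def test_oncoplot_matrix_properties(mouse_catalog):
    genes = [g.gene_id for g in list(mouse_catalog)[:3]]
    rows = []
    for ti in range(10):
        for gid in genes[: 1 + ti % 3]:
            g = mouse_catalog[gid]
            rows.append(_insertion(g.chrom, g.start, f"T{ti}"))
    ins = pd.DataFrame(rows)
    mat, freq = sb.oncoplot_matrix(genes, ins, mouse_catalog)
    assert mat.shape == (3, 10)
    assert (freq.sort_values(ascending=False).index == mat.index).all()
    # row sums equal per-gene tumour counts; shuffling tumours leaves freq unchanged
    for gid in genes:
        g = mouse_catalog[gid]
        lo, hi = g.extended_region()
        n = ins[(ins["chrom"] == g.chrom) & (ins["pos"] >= lo)
                & (ins["pos"] <= hi)]["tumour_id"].nunique()
        assert mat.loc[gid].sum() == n
    shuffled = ins.sample(frac=1, random_state=0).reset_index(drop=True)
    _, freq2 = sb.oncoplot_matrix(genes, shuffled, mouse_catalog)
    pd.testing.assert_series_equal(freq.sort_index(), freq2.sort_index())


def test_null_screen_calibration_and_recurrence_emptying(mouse_catalog):
    """On fully null screens the Monte-Carlo fraction of genes at p < 0.05
    matches the analytic size of the discrete Poisson test (within 3 s.e.),
    never exceeds alpha by construction, and the 5 percent-in-both-strains
    recurrence filter empties the candidate set in >= 95% of replicates."""
    n_reps = 25
    alpha = 0.05
    L = mouse_catalog.genome_length
    rejected = 0
    total = 0
    expected = 0.0
    var = 0.0
    empty_sets = 0
    for rep in range(n_reps):
        cfg = sb.ScreenConfig(
            n_tumours={("12740", "WAP"): 100, ("12775", "WAP"): 100},
            background_rate=50.0, seed=1000 + rep)
        ins, _ = sb.simulate_screen(mouse_catalog, cfg)
        scan_all = sb.gene_cis_scan(ins, mouse_catalog, alpha=1.1)
        rejected += int((scan_all["p"] < alpha).sum())
        total += len(scan_all)
        n_total = len(ins)
        for gene in mouse_catalog:
            lo, hi = gene.extended_region()
            lam = n_total * (hi - lo + 1) / L
            # analytic size: P(p < alpha) under Poisson(lam)
            k_crit = int(stats.poisson.isf(alpha, lam)) + 1
            size = stats.poisson.sf(k_crit - 1, lam)
            expected += size
            var += size * (1 - size)
        sig = sb.gene_cis_scan(ins, mouse_catalog, alpha=alpha)
        if len(sb.recurrence_filter(sig, theta=0.05)) == 0:
            empty_sets += 1
    se = np.sqrt(var)
    assert abs(rejected - expected) <= 3 * se + 1
    assert rejected / total <= alpha + 3 * np.sqrt(alpha / total)
    assert empty_sets >= 0.95 * n_reps


def test_planted_driver_recovery_single_screen(mouse_catalog):
    drivers = [
        sb.DriverSpec("gene005", "ONCOGENE", penetrance=0.3,
                      hotspot=(4, 7), sense_prob=0.9),
        sb.DriverSpec("gene030", "TSG", penetrance=0.3),
    ]
    cfg = sb.ScreenConfig(
        n_tumours={("12740", "WAP"): 100, ("12775", "WAP"): 100},
        background_rate=50.0, donor_chrom={"12740": "chr9", "12775": "chr12"},
        drivers=drivers, seed=77)
    ins, _ = sb.simulate_screen(mouse_catalog, cfg)
    cand = sb.recurrence_filter(sb.gene_cis_scan(ins, mouse_catalog),
                                group="BrWSB")
    assert set(cand.genes) == {"gene005", "gene030"}
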