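import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sbscreen as sb
from sbscreen.errors import ConfigError
from sbscreen.simulate import _ta_positions


def _screen_config(**kw):
    base = dict(
        n_tumours={("12740", "WAP"): 50, ("12775", "WAP"): 50},
        background_rate=20.0,
        seed=7,
    )
    base.update(kw)
    return sb.ScreenConfig(**base)


def test_seed_is_mandatory(mouse_catalog):
    cfg = _screen_config(seed=None)
    with pytest.raises(ConfigError):
        sb.simulate_screen(mouse_catalog, cfg)


def test_same_seed_gives_identical_tables(mouse_catalog):
    cfg = _screen_config()
    a, ta = sb.simulate_screen(mouse_catalog, cfg)
    b, tb = sb.simulate_screen(mouse_catalog, cfg)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ta, tb)


def test_oncogene_penetrance_within_binomial_interval(mouse_catalog):
    """With penetrance 0.3 over 100 tumours, the number of tumours carrying
    the driver insertion falls inside the central 99% binomial interval."""
    drv = sb.DriverSpec("gene001", "ONCOGENE", penetrance=0.3,
                        hotspot=(2, 5), sense_prob=0.9)
    cfg = _screen_config(
        n_tumours={("12740", "WAP"): 50, ("12775", "WAP"): 50},
        drivers=[drv], seed=42,
    )
    _, truth = sb.simulate_screen(mouse_catalog, cfg)
    carriers = truth["tumour_id"].nunique()
    lo, hi = stats.binom.interval(0.99, 100, 0.3)
    assert lo <= carriers <= hi


def test_uniform_insertions_match_chromosome_lengths(mouse_catalog):
    """At hopping_factor 1 the per-chromosome counts fit a length-
    proportional multinomial (chi-square goodness of fit, p > 0.01)."""
    cfg = _screen_config(background_rate=50.0, hopping_factor=1.0, seed=5)
    ins, _ = sb.simulate_screen(mouse_catalog, cfg)
    lengths = pd.Series(mouse_catalog.chrom_lengths)
    obs = ins["chrom"].value_counts().reindex(lengths.index, fill_value=0)
    expected = lengths / lengths.sum() * len(ins)
    chi2 = ((obs - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=len(lengths) - 1)
    assert p > 0.01


def test_donor_chromosome_hopping_excess(mouse_catalog):
    """hopping_factor 3 triples the donor chromosome's insertion density."""
    cfg = _screen_config(
        background_rate=50.0, hopping_factor=3.0,
        donor_chrom={"12740": "chr9", "12775": "chr12"}, seed=6,
    )
    ins, _ = sb.simulate_screen(mouse_catalog, cfg)
    sub = ins[ins["strain"] == "12740"]
    L = pd.Series(mouse_catalog.chrom_lengths)
    w = L.copy().astype(float)
    w["chr9"] *= 3
    expect = w["chr9"] / w.sum() * len(sub)
    n_donor = (sub["chrom"] == "chr9").sum()
    assert abs(n_donor - expect) < 4 * np.sqrt(expect)


def test_ta_mode_places_all_insertions_on_ta(small_genome, small_catalog):
    drv = sb.DriverSpec("gene001", "TSG", penetrance=0.5)
    cfg = _screen_config(n_tumours={("12740", "WAP"): 20}, background_rate=10,
                         drivers=[drv], seed=8)
    ins, _ = sb.simulate_screen(small_catalog, cfg, genome=small_genome)
    for row in ins.itertuples(index=False):
        assert small_genome[row.chrom][row.pos - 1 : row.pos + 1] == "TA"


def test_ta_index_positions():
    assert _ta_positions("GGTACCTA").tolist() == [3, 7]
    assert _ta_positions("GGGG").tolist() == []


def test_emit_reads_layout_and_errors(small_genome, small_catalog):
    """At zero error/contamination every read begins with one of the
    configured IRDR sequences and ends in linker chemistry."""
    cfg = _screen_config(n_tumours={("12740", "WAP"): 5}, background_rate=5, seed=9)
    ins, _ = sb.simulate_screen(small_catalog, cfg, genome=small_genome)
    rc = sb.ReadConfig(seed=10)
    reads = sb.emit_reads(ins, small_genome, rc)
    assert len(reads) == rc.reads_per_site * int(ins["support"].sum())
    for _, seq in reads:
        assert seq.startswith(rc.irdr_l) or seq.startswith(rc.irdr_r)
    # non-TA insertion is a model violation
    bad = ins.copy()
    chrom = bad.loc[0, "chrom"]
    seq = small_genome[chrom]
    pos = next(i + 1 for i in range(1000) if seq[i : i + 2] != "TA")
    bad.loc[0, "pos"] = pos
    with pytest.raises(sb.DataError):
        sb.emit_reads(bad, small_genome, rc)


def test_exon_counts_null_profiles_exchangeable():
    """At fold 1, trapped and control normalised profiles come from the same
    distribution: a Mann-Whitney test on the downstream/upstream log-ratio
    over repeated seeds rejects at most rarely at alpha 0.01."""
    lengths = [200] * 20
    stats_null = []
    for seed in range(40):
        counts, groups = sb.simulate_exon_counts(
            lengths, breakpoint_exon=10, fold=1.0, depth=0.5,
            n_trapped=3, n_control=3, seed=seed)
        norm = sb.normalize_exon_counts(counts)
        t = norm[[c for c in norm if groups[c] == "trapped"]].mean(axis=1)
        c = norm[[c for c in norm if groups[c] == "control"]].mean(axis=1)
        p = stats.mannwhitneyu(t, c).pvalue
        stats_null.append(p < 0.01)
    assert sum(stats_null) <= 3  # ~0.4 expected, allow slack


def test_exon_counts_step_visible_at_high_depth():
    counts, groups = sb.simulate_exon_counts(
        [300] * 30, breakpoint_exon=20, fold=8.0, depth=50.0,
        n_trapped=2, n_control=2, seed=3)
    # equal library sizes emulate genome-wide totals, of which one gene's
    # step is a negligible fraction
    samples = [c for c in counts.columns if c != "exon_length"]
    norm = sb.normalize_exon_counts(
        counts, lib_sizes=pd.Series(1e6, index=samples))
    t = norm[[c for c in norm if groups[c] == "trapped"]].mean(axis=1)
    c = norm[[c for c in norm if groups[c] == "control"]].mean(axis=1)
    ratio = (t / c).to_numpy()
    assert abs(ratio[19:].mean() - 8) < 0.5
    assert abs(ratio[:19].mean() - 1) < 0.1


def test_exon_counts_deterministic():
    a, _ = sb.simulate_exon_counts([100] * 5, 3, 4.0, 1.0, 2, 2, seed=1)
    b, _ = sb.simulate_exon_counts([100] * 5, 3, 4.0, 1.0, 2, 2, seed=1)
    pd.testing.assert_frame_equal(a, b)


def test_patient_cohort_tnbc_consistency():
    tab = sb.simulate_patient_cohort(500, {"NOTCH1": 2.0}, n_null_genes=3, seed=4)
    trip_neg = (tab[["er", "pr", "her2"]] == "neg").all(axis=1)
    assert (tab["tnbc"] == trip_neg).all()
    assert {"NOTCH1", "null0001", "null0002", "null0003"} <= set(tab.columns)


def test_patient_cohort_zero_base_rate_gives_no_tnbc():
    tab = sb.simulate_patient_cohort(200, {}, n_null_genes=2,
                                     base_tnbc_rate=0.0, seed=5)
    assert not tab["tnbc"].any()
    assign = sb.rank_and_bin(tab["null0001"], 10)
    pi = sb.cohort_incidence(assign, tab["tnbc"])
    assert (pi == 0).all()
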