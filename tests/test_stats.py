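import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from amped.quantify import AlignmentSet, count_alleles
from amped.align import AlignedRead
from amped.simulate import SimConfig, simulate_reads
from amped.quantify import quantify_sample, align_sample
from amped.stats import (
    bh_adjust,
    call_sites,
    fisher_site_test,
    pool_counts,
    read_precision,
    summarize_condition,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_enum(case, control, tie_tol=1e-7):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    a, b = case
    c, d = control
    n = a + b + c + d
    rv = hypergeom(n, a + c, a + b)
    support = np.arange(max(0, (a + c) - (c + d)), min(a + c, a + b) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(probs[probs <= p_obs * (1 + tie_tol)].sum(), 1.0))


def bh_stepup(p):
    """Direct step-up definition: q_(i) = min_{k>=i} p_(k) * m / k, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _tables_from_counts(ref, g_counts, depth, prefix):
    """Build SiteCountTables directly from per-site G counts."""
    tables = []
    for rep, gs in enumerate(g_counts):
        df = pd.DataFrame(
            {
                "label": [ref.site_label(p) for p in ref.adenosine_positions],
                "n_A": depth - np.asarray(gs),
                "n_G": np.asarray(gs),
                "n_other": 0,
                "n_masked": 0,
            },
            index=list(ref.adenosine_positions),
        )
        df["depth"] = depth
        df["rate"] = df["n_G"] / depth
        df.index.name = "position"
        from amped.quantify import SiteCountTable
        tables.append(SiteCountTable(sample_id=f"{prefix}{rep}", counts=df))
    return tables


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def test_pool_counts_sums_replicates(ref):
    m = len(ref.adenosine_positions)
    t1 = _tables_from_counts(ref, [np.full(m, 1)], 100, "a")
    t2 = _tables_from_counts(ref, [np.full(m, 3)], 100, "b")
    pooled = pool_counts(t1 + t2)
    assert (pooled["n_G"] == 4).all()
    assert (pooled["n_A"] == 196).all()
    assert pool_counts(t1)["n_G"].equals(t1[0].counts["n_G"])
    # pooled depth equals the sum of replicate depths at every site
    assert ((pooled["n_G"] + pooled["n_A"])
            == (t1[0].counts["depth"] + t2[0].counts["depth"])).all()


def test_pool_counts_rejects_mismatched_sites(ref, toy_ref):
    m = len(ref.adenosine_positions)
    k = len(toy_ref.adenosine_positions)
    with pytest.raises(ValueError, match="different sites"):
        pool_counts(
            _tables_from_counts(ref, [np.zeros(m, int)], 10, "a")
            + _tables_from_counts(toy_ref, [np.zeros(k, int)], 10, "b")
        )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def test_fisher_identical_tables_give_p_one():
    assert fisher_site_test((5, 95), (5, 95)) == 1.0


def test_fisher_matches_enumeration_oracle():
    assert fisher_site_test((5, 95), (0, 100)) == pytest.approx(
        fisher_enum((5, 95), (0, 100)), abs=1e-10
    )
    rng = np.random.default_rng(0)
    for _ in range(500):
        n = int(rng.integers(4, 61))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = int(rng.integers(0, n - a - b + 1))
        d = n - a - b - c
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        assert fisher_site_test((a, b), (c, d)) == pytest.approx(
            fisher_enum((a, b), (c, d)), abs=1e-10
        )


def test_fisher_symmetric_in_case_control():
    assert fisher_site_test((7, 93), (2, 98)) == pytest.approx(
        fisher_site_test((2, 98), (7, 93)), abs=1e-12
    )


def test_fisher_zero_margin_returns_one():
    assert fisher_site_test((0, 100), (0, 50)) == 1.0
    assert fisher_site_test((0, 0), (3, 50)) == 1.0
    with pytest.raises(ValueError, match="non-negative"):
        fisher_site_test((-1, 5), (1, 5))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_single_value_unchanged():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_example():
    # step-up on (0.01, 0.02, 0.03, 0.04): every q collapses to 0.04
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


@given(st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
                min_size=1, max_size=200))
def test_bh_matches_stepup_definition(pvals):
    got = bh_adjust(pvals)
    want = bh_stepup(pvals)
    assert np.allclose(got, want, atol=1e-12)
    assert (got >= np.asarray(pvals) - 1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError, match="p-values"):
        bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def test_null_model_rarely_flags_sites(ref):
    """Case == control generative model: ~no significant sites at q < 0.01."""
    rng = np.random.default_rng(10)
    m = len(ref.adenosine_positions)
    depth, p0 = 20000, 3.3e-4
    total_flagged = 0
    for _ in range(50):
        case = _tables_from_counts(ref, [rng.binomial(depth, p0, size=m)], depth, "c")
        ctrl = _tables_from_counts(ref, [rng.binomial(depth, p0, size=m)], depth, "k")
        calls = call_sites(pool_counts(case), pool_counts(ctrl),
                           target_index=ref.target_index)
        total_flagged += int(calls["significant"].sum())
    assert total_flagged < 1


def test_overwhelming_depth_flags_true_site(ref):
    rng = np.random.default_rng(11)
    m = len(ref.adenosine_positions)
    depth, p0 = 100000, 1e-3
    hot = 5  # index into adenosine list
    g_case = rng.binomial(depth, p0, size=m)
    g_case[hot] = rng.binomial(depth, 10 * p0)
    case = _tables_from_counts(ref, [g_case], depth, "c")
    ctrl = _tables_from_counts(ref, [rng.binomial(depth, p0, size=m)], depth, "k")
    calls = call_sites(pool_counts(case), pool_counts(ctrl),
                       target_index=ref.target_index)
    pos = ref.adenosine_positions[hot]
    assert bool(calls.loc[pos, "significant"])
    assert calls.loc[pos, "q"] < 0.01
    assert not calls.loc[pos, "is_target"]
    assert bool(calls.loc[ref.target_index, "is_target"])


def test_alpha_threshold_degeneracy(ref):
    rng = np.random.default_rng(12)
    m = len(ref.adenosine_positions)
    case = _tables_from_counts(ref, [rng.binomial(5000, 5e-3, size=m)], 5000, "c")
    ctrl = _tables_from_counts(ref, [rng.binomial(5000, 1e-4, size=m)], 5000, "k")
    calls = call_sites(pool_counts(case), pool_counts(ctrl), alpha=1.0)
    assert (calls.loc[calls["q"] < 1.0, "significant"]).all()
    assert calls["q"].ge(calls["p"] - 1e-15).all()


# ---------------------------------------------------------------------------
# condition summaries
# ---------------------------------------------------------------------------

def _summary_inputs(ref, on_rates, off_rate, sig_sites, depth=10000):
    m = len(ref.adenosine_positions)
    tidx = list(ref.adenosine_positions).index(ref.target_index)
    g = []
    for r in on_rates:
        row = np.zeros(m, int)
        row[tidx] = int(round(r * depth))
        for s in sig_sites:
            row[list(ref.adenosine_positions).index(s)] = int(round(off_rate * depth))
        g.append(row)
    tables = _tables_from_counts(ref, g, depth, "rep")
    calls = call_sites(pool_counts(tables),
                       _null_control(ref, depth * len(on_rates)),
                       target_index=ref.target_index)
    return tables, calls


def _null_control(ref, depth):
    df = pd.DataFrame(
        {
            "label": [ref.site_label(p) for p in ref.adenosine_positions],
            "n_G": 0,
            "n_A": depth,
        },
        index=list(ref.adenosine_positions),
    )
    return df


def test_summary_equal_replicates_have_zero_sem(ref):
    tables, calls = _summary_inputs(ref, [0.02, 0.02, 0.02], 0.0, [])
    s = summarize_condition(tables, calls, ref.target_index)
    assert s.on_target_mean == pytest.approx(0.02)
    assert s.on_target_sem == pytest.approx(0.0)


def test_summary_ratio_arithmetic(ref):
    sig = [p for p in ref.window_adenosines if p != ref.target_index][:4]
    tables, calls = _summary_inputs(ref, [0.0204] * 3, 0.0010, sig)
    s = summarize_condition(tables, calls, ref.target_index)
    assert set(sig).issubset(
        set(calls.index[calls["significant"] & ~calls["is_target"]])
    )
    assert s.off_target_mean == pytest.approx(0.0010)
    assert s.on_off_ratio == pytest.approx(20.4)
    assert s.off_target_sum_mean == pytest.approx(0.0010 * len(sig))


def test_summary_no_significant_off_targets_flagged(ref):
    tables, calls = _summary_inputs(ref, [0.02] * 3, 0.0, [])
    s = summarize_condition(tables, calls, ref.target_index)
    assert s.off_target_mean == 0.0
    assert np.isnan(s.on_off_ratio)
    assert "no_significant_off_target_sites" in s.flags


# ---------------------------------------------------------------------------
# per-read precision
# ---------------------------------------------------------------------------

def _aligned(ref, edits_list):
    out = []
    for k, edits in enumerate(edits_list):
        s = list(ref.sequence)
        for pos in edits:
            s[pos] = "G"
        out.append(AlignedRead(id=f"r{k}", bases="".join(s), orientation="+", identity=1.0))
    return AlignmentSet.from_aligned(out)

def test_precision_frozen_tally(ref):
    t = ref.target_index
    bys = next(p for p in ref.adenosine_positions if p != t)
    aln = _aligned(ref, [(t,), (t,), (t, bys), (), (bys,)])
    p = read_precision(aln, t, ref.adenosine_positions)
    assert (p.n_corrected, p.n_clean) == (3, 2)
    assert p.precision == pytest.approx(2 / 3)


def test_precision_without_bystanders_is_one(ref):
    cfg = SimConfig(n_reads=3000, engagement_prob=0.3, seq_error=0.0, seed=31)
    aln, _ = align_sample(simulate_reads(ref, cfg), ref)
    p = read_precision(aln, ref.target_index, ref.adenosine_positions)
    assert p.n_corrected > 0
    assert p.precision == 1.0


def test_precision_matches_independence_product(ref):
    """Two engaged bystander sites at q = 0.1 give P -> 0.9^2 = 0.81."""
    sites = [p for p in ref.window_adenosines if p != ref.target_index][:2]
    cfg = SimConfig(
        n_reads=20000, engagement_prob=0.5, on_target_prob_given_engaged=1.0,
        bystander_probs={s: 0.1 for s in sites}, seq_error=0.0, seed=32,
    )
    aln, _ = align_sample(simulate_reads(ref, cfg), ref)
    p = read_precision(aln, ref.target_index, ref.adenosine_positions)
    z99 = 2.576
    ci = z99 * np.sqrt(0.81 * 0.19 / p.n_corrected)
    assert abs(p.precision - 0.81) < ci


def test_precision_undefined_without_corrected_reads(ref):
    cfg = SimConfig(n_reads=200, engagement_prob=0.0, seq_error=0.0, seed=33)
    aln, _ = align_sample(simulate_reads(ref, cfg), ref)
    p = read_precision(aln, ref.target_index, ref.adenosine_positions)
    assert p.n_corrected == 0 and np.isnan(p.precision)
    assert "no_corrected_reads" in p.flags
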