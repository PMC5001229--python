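"""Ψ posterior, Bayes factor, effective sizes: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import beta

from splicedelta import quant
from splicedelta.events import EventType, SplicingEvent
from splicedelta.quant import (
    EffectiveSizes,
    EventCounts,
    bayes_factor,
    call_events,
    class_probabilities,
    effective_sizes,
    passes_thresholds,
    pool_replicates,
    psi_posterior,
)

SZ = EffectiveSizes(50, 50, 0)


def _counts(n_inc, n_exc, n_shared=0, sizes=SZ, cond="control"):
    return EventCounts("e1", cond, n_inc, n_exc, n_shared, sizes)


# ------------------------------------------------------------ effective sizes

def _token_oracle(event, read_length):
    """Independent enumeration: isoform mRNAs as tuples of genome positions;
    a read (tuple of positions) is compatible with an isoform iff it is a
    contiguous subsequence of that isoform's position sequence."""
    def tokens(chain, strand):
        t = [p for a, b in chain for p in range(a, b)]
        return t[::-1] if strand == "-" else t

    def windows(tok):
        return {tuple(tok[i:i + read_length]) for i in range(len(tok) - read_length + 1)}

    inc_t, exc_t = (tokens(c, event.strand) for c in
                    (event.inclusion_chain, event.exclusion_chain))
    inc_w, exc_w = windows(inc_t), windows(exc_t)
    # canonicalize footprint orientation
    canon = lambda ws: {tuple(sorted(w)) for w in ws}
    inc_c, exc_c = canon(inc_w), canon(exc_w)
    return (len(inc_c - exc_c), len(exc_c - inc_c), len(inc_c & exc_c))


def _mini_cassette(l_up=20, l_c=15, l_down=20, gap=30):
    a, b = 0, l_up
    c0, c1 = b + gap, b + gap + l_c
    d0, d1 = c1 + gap, c1 + gap + l_down
    return SplicingEvent(
        "mini", EventType.CASSETTE, "g", "t", "chr", "+",
        alt_segment=(c0, c1), upstream_exon=(a, b), downstream_exon=(d0, d1),
        inclusion_chain=((a, b), (c0, c1), (d0, d1)),
        exclusion_chain=((a, b), (d0, d1)),
    )


@pytest.mark.parametrize("l_c,read_length", [(15, 10), (10, 10), (30, 12), (7, 20)])
def test_effective_sizes_match_token_oracle(l_c, read_length):
    ev = _mini_cassette(l_c=l_c)
    sz = effective_sizes(ev, read_length, overhang=1)
    assert (sz.eff_inc, sz.eff_exc, sz.eff_shared) == _token_oracle(ev, read_length)


def test_effective_sizes_cassette_equal_to_read_length():
    # cassette of length L = read length: inclusion-specific positions are the
    # exon-internal starts plus the two junction-spanning windows
    ev = _mini_cassette(l_up=30, l_c=10, l_down=30)
    sz = effective_sizes(ev, 10, overhang=1)
    oracle = _token_oracle(ev, 10)
    assert (sz.eff_inc, sz.eff_exc, sz.eff_shared) == oracle
    # every read overlapping the cassette is inclusion-specific: 2*(L-1)+1
    assert sz.eff_inc == 2 * (10 - 1) + 1


def test_effective_sizes_symmetric_event():
    ev = _mini_cassette(l_up=25, l_c=20, l_down=25)
    sz = effective_sizes(ev, 12)
    # exclusion-specific reads span the single skipping junction
    assert sz.eff_exc == 12 - 1
    assert sz.testable


def test_effective_sizes_untestable_when_locus_too_short():
    ev = _mini_cassette(l_up=5, l_c=3, l_down=5)
    sz = effective_sizes(ev, 20)
    assert not sz.testable


def test_effective_sizes_overhang_filters_junction_reads():
    ev = _mini_cassette(l_up=30, l_c=30, l_down=30)
    loose = effective_sizes(ev, 10, overhang=1)
    strict = effective_sizes(ev, 10, overhang=5)
    assert strict.eff_exc < loose.eff_exc
    assert strict.eff_inc <= loose.eff_inc


# ------------------------------------------------------------------ posterior

def test_psi_posterior_symmetry_exact():
    post = psi_posterior(_counts(50, 50))
    assert post.mean == pytest.approx(0.5, abs=1e-12)
    assert abs(post.mass.sum() - 1.0) < 1e-9


def test_psi_posterior_beta_closed_form():
    """n_inc=0, n_exc=100, equal sizes, no shared: posterior is Beta(1, 101)."""
    post = psi_posterior(_counts(0, 100))
    assert post.mean == pytest.approx(1 / 102, abs=1e-3)
    lo, hi = beta.ppf([0.025, 0.975], 1, 101)
    assert post.ci_low == pytest.approx(lo, abs=2e-3)
    assert post.ci_high == pytest.approx(hi, abs=2e-3)


def test_psi_posterior_zero_counts_is_prior():
    post = psi_posterior(_counts(0, 0, 0))
    assert post.low_information
    assert post.mean == pytest.approx(0.5, abs=1e-9)
    assert post.ci_low == pytest.approx(0.025, abs=2e-3)
    assert post.ci_high == pytest.approx(0.975, abs=2e-3)


def test_class_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    for _ in range(20):
        sz = EffectiveSizes(*(int(x) for x in rng.integers(1, 200, 3)))
        p = np.array(class_probabilities(rng.random(), sz))
        assert np.isclose(p.sum(), 1.0)


def _oracle_mean_logm(c: EventCounts):
    """Adaptive-quadrature oracle; the likelihood is restated independently."""
    s = c.sizes

    def ll(p):
        z = p * (s.eff_inc + s.eff_shared) + (1 - p) * (s.eff_exc + s.eff_shared)
        v = -c.total * np.log(z)
        if c.n_inc:
            v += c.n_inc * np.log(p * s.eff_inc)
        if c.n_exc:
            v += c.n_exc * np.log((1 - p) * s.eff_exc)
        if c.n_shared:
            v += c.n_shared * np.log(s.eff_shared)
        return v

    gr = np.linspace(1e-9, 1 - 1e-9, 2001)
    vals = np.array([ll(p) for p in gr])
    lm, mle = vals.max(), gr[int(np.argmax(vals))]
    f = lambda p: np.exp(ll(p) - lm) if 0 < p < 1 else 0.0
    den, _ = quad(f, 0, 1, points=[mle], limit=200)
    num, _ = quad(lambda p: p * f(p), 0, 1, points=[mle], limit=200)
    return num / den, lm + np.log(den), ll


def test_grid_posterior_matches_quadrature_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        sz = EffectiveSizes(int(rng.integers(5, 200)), int(rng.integers(5, 200)),
                            int(rng.integers(0, 300)))
        n = rng.integers(0, 300, 3)
        c = _counts(int(n[0]), int(n[1]), int(n[2]) if sz.eff_shared else 0, sz)
        mean_o, _, _ = _oracle_mean_logm(c)
        assert psi_posterior(c).mean == pytest.approx(mean_o, abs=1e-3)


# --------------------------------------------------------------- Bayes factor

def test_log_bf_matches_quadrature_oracle():
    rng = np.random.default_rng(8)
    for _ in range(20):
        sz = EffectiveSizes(int(rng.integers(5, 200)), int(rng.integers(5, 200)),
                            int(rng.integers(0, 300)))
        def draw(cond):
            n = rng.integers(0, 300, 3)
            return _counts(int(n[0]), int(n[1]),
                           int(n[2]) if sz.eff_shared else 0, sz, cond)
        cc, ct = draw("control"), draw("treated")
        _, lm_c, ll_c = _oracle_mean_logm(cc)
        _, lm_t, ll_t = _oracle_mean_logm(ct)
        gr = np.linspace(1e-9, 1 - 1e-9, 2001)
        vals = np.array([ll_c(p) + ll_t(p) for p in gr])
        m, mle = vals.max(), gr[int(np.argmax(vals))]
        joint, _ = quad(lambda p: np.exp(ll_c(p) + ll_t(p) - m) if 0 < p < 1 else 0.0,
                        0, 1, points=[mle], limit=200)
        oracle = lm_c + lm_t - (m + np.log(joint))
        call = bayes_factor(cc, ct)
        assert call.log_bf == pytest.approx(oracle, abs=0.01)


def test_identical_counts_favor_shared_model():
    c = _counts(200, 200, 200, EffectiveSizes(50, 50, 50))
    t = _counts(200, 200, 200, EffectiveSizes(50, 50, 50), cond="treated")
    call = bayes_factor(c, t)
    assert call.bayes_factor < 5
    assert not call.passes


def test_label_symmetry_exact():
    cc = _counts(30, 120, 10, EffectiveSizes(40, 60, 20))
    ct = _counts(140, 25, 10, EffectiveSizes(40, 60, 20), cond="treated")
    fwd = bayes_factor(cc, ct)
    rev = bayes_factor(ct, cc)
    assert fwd.log_bf == pytest.approx(rev.log_bf, abs=1e-12)
    assert fwd.delta_psi == pytest.approx(-rev.delta_psi, abs=1e-12)


@given(st.integers(0, 200), st.integers(1, 200))
@settings(max_examples=60, deadline=None)
def test_posterior_mean_monotone_in_inclusion_reads(n_inc, total_extra):
    """Holding the informative total fixed, moving one read from the
    exclusion to the inclusion class never lowers the Ψ estimate."""
    total = n_inc + total_extra
    m1 = psi_posterior(_counts(n_inc, total - n_inc)).mean
    m2 = psi_posterior(_counts(n_inc + 1, total - n_inc - 1)).mean
    assert m2 >= m1 - 1e-12


def test_threshold_rule_boundaries():
    assert passes_thresholds(5.1, 0.06)
    assert not passes_thresholds(5.1, 0.04)
    assert not passes_thresholds(4.9, 0.30)
    assert not passes_thresholds(5.0, 0.06)   # strict inequality on BF
    assert not passes_thresholds(5.1, 0.05)   # strict inequality on dPsi


# ----------------------------------------------------------------- call_events

def test_pool_replicates_sums_counts():
    reps = [_counts(10, 5, 2), _counts(1, 2, 3), _counts(0, 0, 0)]
    pooled = pool_replicates(reps, "control")
    assert (pooled.n_inc, pooled.n_exc, pooled.n_shared) == (11, 7, 5)


def test_call_events_tallies_are_conserved():
    rng = np.random.default_rng(3)
    sz = EffectiveSizes(80, 80, 40)
    by_event = {}
    for i in range(12):
        psi_c, psi_t = (0.2, 0.8) if i % 3 == 0 else (0.5, 0.5)
        rec = {}
        for cond, psi in (("control", psi_c), ("treated", psi_t)):
            p = np.array(class_probabilities(psi, sz))
            n = rng.multinomial(800, p)
            rec[cond] = [EventCounts(f"e{i}", cond, *map(int, n), sz)]
        by_event[f"e{i}"] = rec
    calls, summary = call_events(by_event)
    assert summary.n_tested == 12
    assert summary.n_positive + summary.n_negative == summary.n_passing
    assert summary.n_passing >= 4  # the injected 0.2 -> 0.8 events


def test_call_events_empty_when_nothing_passes():
    sz = EffectiveSizes(80, 80, 0)
    by_event = {
        "e0": {
            "control": [_counts(100, 100, 0, sz)],
            "treated": [_counts(100, 100, 0, sz, "treated")],
        }
    }
    calls, summary = call_events(by_event)
    assert summary.n_passing == 0 and not calls[0].passes
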