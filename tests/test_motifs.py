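"""Regulatory-region geometry and exact-p-value PWM scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from splicedelta.events import interval_len
from splicedelta.motifs import (
    PWM,
    PWMScorer,
    estimate_background,
    extract_regions,
    motif_enrichment,
    scan_pwm,
)
from splicedelta.quant import DiffSplicingCall
from splicedelta.synthdata import (
    SimConfig,
    assign_truth,
    make_transcriptome,
    mirror_gene,
    planted_pwm,
    plant_motif,
)
from conftest import toy_cassette_gene


# ------------------------------------------------------------ region geometry

def test_region_lengths_long_introns():
    tx, ev, genome = toy_cassette_gene(
        cassette_len=72, e_lens=(200, 200, 200, 200), introns=(200, 1000, 1000, 200)
    )
    rs = extract_regions(ev, genome)
    assert [interval_len(r.interval) for r in rs.regions] == [
        150, 300, 300, 72, 300, 300, 150]
    assert [len(r.seq) for r in rs.regions] == [150, 300, 300, 72, 300, 300, 150]


def test_short_intron_midpoint_split():
    tx, ev, genome = toy_cassette_gene(introns=(200, 400, 401, 200))
    rs = extract_regions(ev, genome)
    r2, r3, r5, r6 = (rs.regions[i].interval for i in (1, 2, 4, 5))
    assert interval_len(r2) == 200 and interval_len(r3) == 200
    assert interval_len(r5) + interval_len(r6) == 401
    # non-overlapping, inside the intron
    assert r2[1] <= r3[0] or r3[1] <= r2[0]
    up_intron = (ev.upstream_exon[1], ev.alt_segment[0])
    assert r2[0] >= up_intron[0] and r3[1] <= up_intron[1]


def test_regions_truncate_to_short_exons():
    tx, ev, genome = toy_cassette_gene(e_lens=(200, 90, 80, 200))
    rs = extract_regions(ev, genome)
    assert len(rs.regions[0].seq) == 90
    assert len(rs.regions[6].seq) == 80


def test_strand_mirror_regions_identical_sequences():
    tx, ev, genome = toy_cassette_gene(cassette_len=72)
    txm, evm, seqm = mirror_gene(tx, ev, genome["chr_toy"])
    fwd = extract_regions(ev, genome)
    rev = extract_regions(evm, {"chr_toy": seqm})
    assert [r.seq for r in fwd.regions] == [r.seq for r in rev.regions]
    assert [r.label for r in fwd.regions] == [r.label for r in rev.regions]


def test_non_cassette_rejected():
    from dataclasses import replace
    from splicedelta.events import EventType
    tx, ev, genome = toy_cassette_gene()
    with pytest.raises(ValueError):
        extract_regions(replace(ev, event_type=EventType.ALT5), genome)


# ------------------------------------------------------------------ PWM maths

def _random_pwm(rng, w):
    return PWM("m", "rbp", rng.dirichlet(np.ones(4), size=w))


@pytest.mark.parametrize("w", [3, 4, 6])
def test_dp_distribution_equals_enumeration(w):
    """Exact check: the DP null distribution and tail p-values equal
    brute-force enumeration over all 4^w words."""
    rng = np.random.default_rng(41)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    scorer = PWMScorer(_random_pwm(rng, w), background=bg)
    probs, scores = {}, {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(scorer.iscores[j, b] for j, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    dist = np.zeros_like(scorer.null_dist)
    for s, p in probs.items():
        dist[s - scorer.null_lo] += p
    assert np.max(np.abs(dist - scorer.null_dist)) < 1e-12
    for s in probs:
        brute_tail = sum(p for t, p in probs.items() if t >= s)
        assert abs(scorer.p_value(s) - min(1.0, brute_tail)) < 1e-12
    assert abs(scorer.null_dist.sum() - 1.0) < 1e-9


def test_uniform_pwm_scores_zero():
    pwm = PWM("u", "u", np.full((5, 4), 0.25))
    scorer = PWMScorer(pwm, background=np.full(4, 0.25))
    offsets, scores, pvals = scorer.scan("ACGTACGTACGT")
    assert np.allclose(scores, 0.0)
    assert np.allclose(pvals, 1.0)


def test_planted_consensus_is_top_hit():
    pwm = planted_pwm()
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    seq = seq[:10] + pwm.consensus + seq[10 + pwm.width:]
    hits = scan_pwm(seq, pwm, background=np.full(4, 0.25))
    best = max(hits, key=lambda h: h.score_bits)
    assert best.offset == 10
    assert best.p_value < 1e-4


def test_consensus_achieves_max_score():
    rng = np.random.default_rng(6)
    pwm = _random_pwm(rng, 7)
    scorer = PWMScorer(pwm, background=np.full(4, 0.25))
    offsets, scores, _ = scorer.scan(pwm.consensus)
    assert len(scores) == 1
    assert int(round(scores[0] / scorer.bin_bits)) == scorer.max_int_score


def test_scan_shorter_than_motif_is_empty():
    pwm = planted_pwm()
    assert scan_pwm("ACGT", pwm) == []


def test_rna_and_dna_alphabets_equivalent():
    pwm = planted_pwm()
    scorer = PWMScorer(pwm)
    seq = "ACGUACGUACGUACGU"
    o1, s1, p1 = scorer.scan(seq)
    o2, s2, p2 = scorer.scan(seq.replace("U", "T"))
    assert np.array_equal(s1, s2) and np.array_equal(p1, p2)


def test_background_hit_rate_matches_binomial():
    """On i.i.d. background sequence, the number of p < 1e-3 hits is within
    3 standard errors of its expectation (exact-p calibration)."""
    rng = np.random.default_rng(47)
    n_offsets, hits, exp = 0, 0, 0.0
    for i in range(20):
        pwm = _random_pwm(rng, int(rng.integers(5, 8)))
        scorer = PWMScorer(pwm, background=np.full(4, 0.25))
        seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 2000))
        offsets, scores, pvals = scorer.scan(seq)
        # the achievable p closest below the cutoff, from the exact null
        tail = scorer.null_tail
        pv_levels = np.unique(tail)
        alpha = pv_levels[pv_levels < 1e-3].max() if (pv_levels < 1e-3).any() else 0.0
        hits += int((pvals < 1e-3).sum())
        n_offsets += len(offsets)
        exp += alpha * len(offsets)
    se = np.sqrt(exp)  # Poisson-binomial approximation
    assert abs(hits - exp) <= 3 * se + 3


# ---------------------------------------------------------------- enrichment

def _calls_for(events, truth):
    calls = []
    for ev in events:
        t = truth[ev.event_id]
        d = t.true_psi_treated - t.true_psi_control
        calls.append(DiffSplicingCall(ev.event_id, t.true_psi_control,
                                      t.true_psi_treated, d, 100.0, np.log(100.0),
                                      passes=t.is_differential))
    return calls


def test_plant_and_recover_region3_up():
    cfg = SimConfig(n_genes=60, seed=51, frac_affected=0.6,
                    delta_psi_effects=(0.3, -0.3))
    txome = make_transcriptome(cfg)
    truth = assign_truth(txome.events, cfg)
    pwm = planted_pwm()
    planted = plant_motif(txome, truth, pwm, region_index=3, direction="up")
    calls = _calls_for(planted.events, truth)
    region_sets = {
        c.event_id: extract_regions(e, planted.genome)
        for c, e in zip(calls, planted.events)
        if c.passes and e.event_type.value == "cassette"
    }
    res = motif_enrichment(calls, region_sets, [pwm])
    assert not res.hits.empty
    up = res.hits[res.hits.direction == "up"]
    down = res.hits[res.hits.direction == "down"]
    assert (up.region == 3).all()
    assert down.empty
    assert "PLANTED" in res.up_only
    # every up-regulated cassette event carries the planted hit
    n_up_cassette = sum(
        1 for c, e in zip(calls, planted.events)
        if c.passes and c.delta_psi > 0 and e.event_type.value == "cassette")
    assert up.event_id.nunique() == n_up_cassette


def test_enrichment_empty_without_passing_calls():
    res = motif_enrichment([], {}, [planted_pwm()])
    assert res.hits.empty and res.table.empty


def test_bh_q_monotone_in_p_within_stratum():
    cfg = SimConfig(n_genes=30, seed=53, frac_affected=0.5,
                    delta_psi_effects=(0.3,))
    txome = make_transcriptome(cfg)
    truth = assign_truth(txome.events, cfg)
    pwm = planted_pwm()
    planted = plant_motif(txome, truth, pwm, region_index=2, direction="up")
    calls = _calls_for(planted.events, truth)
    region_sets = {
        c.event_id: extract_regions(e, planted.genome)
        for c, e in zip(calls, planted.events)
        if c.passes and e.event_type.value == "cassette"
    }
    res = motif_enrichment(calls, region_sets, [pwm], p_cut=1e-2, fdr_cut=0.5)
    for _, grp in res.hits.groupby(["direction", "motif_id"]):
        g = grp.sort_values("p_value")
        assert g.q_value.is_monotonic_increasing
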