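"""Consensus merging: routing, deduplication and the optimised modes."""

from __future__ import annotations

import numpy as np
import pytest

from svmeld import (
    CONSENSUS_ID,
    CallSet,
    ErrorModel,
    GenomeModel,
    LengthBins,
    MergeConfig,
    SVRecord,
    SVType,
    compute_metrics,
    corrupt,
    dedupe,
    generate_truth,
    match_callset,
    merge_by_profile,
    metrics_from_counts,
    optimize_precision,
    optimize_recall,
    records_match,
    train_profile,
)
from svmeld.profiles import DEFAULT_TIERS, CallerProfile

from conftest import make_del, random_callset


def _profile_all(winner: str, bins=LengthBins(), runner_up: str | None = None):
    row = metrics_from_counts(1, 0, 0)
    entries = [(winner, row)] + ([(runner_up, row)] if runner_up else [])
    return CallerProfile(
        organism="toy",
        tier=DEFAULT_TIERS[3],
        svtype=SVType.DEL,
        bins=bins,
        bin_winners={b: list(entries) for b in range(bins.n_bins)},
    )


def _key(r: SVRecord):
    return (r.chrom, r.pos, r.end, r.svtype, r.svlen)


# ---------------------------------------------------------------------------
# dedupe
# ---------------------------------------------------------------------------


def test_identical_duplicates_collapse():
    r = make_del("chr1", 100, 300, caller="a")
    s = make_del("chr1", 100, 300, caller="b")
    out = dedupe(CallSet(caller_id="m", records=(r, s)), 100)
    assert len(out) == 1


def test_separated_records_both_survive():
    cs = CallSet(
        caller_id="m",
        records=(make_del("chr1", 100, 300), make_del("chr1", 150, 350)),
    )
    out = dedupe(cs, 10)
    assert len(out) == 2


def test_dedupe_recovers_event_count_from_jittered_duplicates():
    # 50 well-separated truth events, 4 jittered copies each (|jitter| <= 50):
    # at tau=100 every copy pair is within tau, so exactly 50 survive
    rng = np.random.default_rng(30)
    base = [(int(p), 500) for p in range(10_000, 10_000 + 50 * 30_000, 30_000)]
    records = []
    for k, (pos, ln) in enumerate(base):
        for c in range(4):
            dp, de = rng.integers(-50, 51), rng.integers(-50, 51)
            records.append(
                make_del("chr1", pos + int(dp), pos + ln + int(de), caller=f"c{c}")
            )
    cs = CallSet(caller_id="m", records=tuple(records))
    out = dedupe(cs, 100)
    assert len(out) == 50


def _check_against_quadratic_oracle(original: CallSet, out: CallSet, tau: int):
    kept = list(out.records)
    # no retained pair violates separation
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert not (
                a.chrom == b.chrom
                and a.svtype == b.svtype
                and abs(a.pos - b.pos) <= tau
                and abs(a.end - b.end) <= tau
            )
    # every dropped record is tau-equivalent to some retained record
    kept_keys = {_key(r) for r in kept}
    for r in original.records:
        if _key(r) not in kept_keys:
            assert any(
                r.chrom == k.chrom
                and r.svtype == k.svtype
                and abs(r.pos - k.pos) <= tau
                and abs(r.end - k.end) <= tau
                for k in kept
            )


@pytest.mark.parametrize("seed", range(4))
def test_dedupe_satisfies_separation_and_coverage(seed):
    rng = np.random.default_rng(seed)
    cs = random_callset(rng, 120, span=30_000)
    for tau in (0, 100, 1000):
        out = dedupe(cs, tau)
        _check_against_quadratic_oracle(cs, out, tau)


def test_dedupe_idempotent():
    rng = np.random.default_rng(31)
    cs = random_callset(rng, 150, span=40_000)
    once = dedupe(cs, 100)
    assert dedupe(once, 100) == once


def test_dedupe_prefers_higher_ranked_caller():
    a = make_del("chr1", 100, 300, caller="low_rank")
    b = make_del("chr1", 105, 305, caller="top")
    cs = CallSet(caller_id="m", records=(a, b))
    rank = {"top": 0, "low_rank": 1}
    out = dedupe(cs, 100, rank=lambda r: rank[r.caller_id])
    assert [r.caller_id for r in out.records] == ["top"]
    # without ranks, sort order decides
    out2 = dedupe(cs, 100)
    assert [r.caller_id for r in out2.records] == ["low_rank"]


# ---------------------------------------------------------------------------
# profile-routed merge
# ---------------------------------------------------------------------------


def test_single_winner_merge_is_dedupe_identity():
    rng = np.random.default_rng(32)
    a = random_callset(rng, 60, caller="a", span=10_000_000)
    merged = merge_by_profile(_profile_all("a"), [a])
    assert merged.caller_id == CONSENSUS_ID
    assert [_key(r) for r in merged.records] == [_key(r) for r in dedupe(a, 100).records]


def test_bin_routing_discards_out_of_bin_records(bins):
    # A wins bin 0 only; its 150 bp call must be discarded, B's 150 bp kept
    row = metrics_from_counts(1, 0, 0)
    prof = CallerProfile(
        organism="toy", tier=DEFAULT_TIERS[3], svtype=SVType.DEL, bins=bins,
        bin_winners={0: [("a", row)], 1: [("b", row)], 2: [("b", row)], 3: [("b", row)]},
    )
    a = CallSet(caller_id="a", records=(
        make_del("chr1", 1000, 1150, caller="a"),      # 150 bp -> bin 1, not a's bin
        make_del("chr1", 50_000, 50_060, caller="a"),  # 60 bp -> bin 0, kept
    ))
    b = CallSet(caller_id="b", records=(
        make_del("chr1", 90_000, 90_150, caller="b"),  # 150 bp -> bin 1, kept
        make_del("chr1", 120_000, 120_070, caller="b"),  # bin 0: b not the winner
    ))
    merged = merge_by_profile(prof, [a, b])
    assert {(r.caller_id, r.svlen) for r in merged.records} == {("a", 60), ("b", 150)}


def test_provenance_reproduces_routing_table(genome, bins):
    truth = generate_truth(genome, 80, bins, seed=33)
    a = corrupt(truth, ErrorModel((0.9, 0.2, 0.2, 0.2), fp_rate=0.5, jitter_sd=5, seed=34), genome, "a")
    b = corrupt(truth, ErrorModel((0.2, 0.9, 0.9, 0.9), fp_rate=0.5, jitter_sd=5, seed=35), genome, "b")
    prof = train_profile([a, b], truth, bins=bins)
    merged = merge_by_profile(prof, [a, b])
    for r in merged.records:
        assert r.caller_id == prof.winner(bins.assign(r.svlen))
    assert len(merged) <= len(a) + len(b)


def test_missing_winner_callset_fatal():
    with pytest.raises(ValueError, match="a"):
        merge_by_profile(_profile_all("a"), [CallSet(caller_id="b")])


def test_merged_consensus_beats_individual_callers(genome, bins):
    """Bin-disjoint caller strengths: the routed merge outperforms both
    inputs on truth it was trained against."""
    truth = generate_truth(genome, 120, bins, seed=36)
    a = corrupt(truth, ErrorModel((0.9, 0.3, 0.3, 0.3), fp_rate=1.0, jitter_sd=10, seed=37), genome, "a")
    b = corrupt(truth, ErrorModel((0.3, 0.9, 0.9, 0.9), fp_rate=1.0, jitter_sd=10, seed=38), genome, "b")
    prof = train_profile([a, b], truth, bins=bins)
    merged = merge_by_profile(prof, [a, b])
    f = lambda cs: compute_metrics(match_callset(cs, truth, 100)).fscore
    assert f(merged) > max(f(a), f(b))


# ---------------------------------------------------------------------------
# optimised modes
# ---------------------------------------------------------------------------


def test_recall_union_of_disjoint_sets():
    a = CallSet(caller_id="a", records=(make_del("chr1", 1000, 1200, caller="a"),))
    b = CallSet(caller_id="b", records=(make_del("chr1", 50_000, 50_200, caller="b"),))
    out = optimize_recall([a, b])
    assert len(out) == 2


def test_recall_subset_absorbed():
    rng = np.random.default_rng(39)
    b = random_callset(rng, 40, caller="b", span=10_000_000)
    a = CallSet(caller_id="a", records=b.records[:10])
    out = optimize_recall([a, b])
    assert [_key(r) for r in out.records] == [_key(r) for r in dedupe(b, 100).records]


def test_recall_sensitivity_dominates_inputs(genome, bins):
    truth = generate_truth(genome, 100, bins, seed=40)
    sets = [
        corrupt(truth, ErrorModel((s,) * 4, fp_rate=1.0, jitter_sd=10, seed=41 + i), genome, f"c{i}")
        for i, s in enumerate((0.5, 0.7))
    ]
    out = optimize_recall(sets)
    sens = lambda cs: compute_metrics(match_callset(cs, truth, 100)).sensitivity
    assert sens(out) >= max(sens(cs) for cs in sets)


def test_precision_support_filtering():
    shared_a = make_del("chr1", 1000, 1200, caller="a")
    shared_b = make_del("chr1", 1010, 1210, caller="b")  # within tau of shared_a
    private = make_del("chr1", 80_000, 80_200, caller="a")
    a = CallSet(caller_id="a", records=(shared_a, private))
    b = CallSet(caller_id="b", records=(shared_b,))
    out = optimize_precision([a, b], MergeConfig(mode="precision", min_support=2))
    assert [_key(r) for r in out.records] == [_key(shared_a)]
    assert out.records[0].support == 2


def test_precision_min_support_one_degenerates_to_recall():
    rng = np.random.default_rng(42)
    a = random_callset(rng, 30, caller="a", span=100_000)
    b = random_callset(rng, 30, caller="b", span=100_000)
    rec = optimize_recall([a, b])
    prec = optimize_precision([a, b], MergeConfig(mode="precision", min_support=1))
    assert [_key(r) for r in prec.records] == [_key(r) for r in rec.records]


def test_precision_min_support_exceeding_callers_fatal():
    a = CallSet(caller_id="a", records=(make_del("chr1", 100, 300, caller="a"),))
    with pytest.raises(ValueError, match="min_support"):
        optimize_precision([a], MergeConfig(mode="precision", min_support=2))


def test_own_duplicates_do_not_self_confirm():
    # one noisy caller emitting the same event twice must not reach support 2
    r1 = make_del("chr1", 1000, 1200, caller="a")
    r2 = make_del("chr1", 1005, 1205, caller="a")
    a = CallSet(caller_id="a", records=(r1, r2))
    b = CallSet(caller_id="b", records=(make_del("chr1", 90_000, 90_100, caller="b"),))
    out = optimize_precision([a, b], MergeConfig(mode="precision", min_support=2))
    assert len(out) == 0


def _tau_contained(inner: CallSet, outer: CallSet, tau: int) -> bool:
    return all(
        any(records_match(r, o, tau) for o in outer.records) for r in inner.records
    )


@pytest.mark.parametrize("seed", range(4))
def test_containment_chain_precision_recall(seed):
    rng = np.random.default_rng(seed)
    sets = [
        random_callset(rng, int(rng.integers(10, 40)), caller=f"c{i}", span=50_000)
        for i in range(3)
    ]
    tau = 100
    rec = optimize_recall(sets, MergeConfig(dedupe_tau=tau, mode="recall"))
    prev = rec
    for k in (1, 2, 3):
        pk = optimize_precision(sets, MergeConfig(dedupe_tau=tau, mode="precision", min_support=k))
        assert _tau_contained(pk, rec, tau)
        assert _tau_contained(pk, prev, tau)  # support k+1 subset of support k
        assert len(pk) <= len(prev)
        prev = pk


def test_precision_beats_inputs_when_fps_are_independent(genome, bins):
    truth = generate_truth(genome, 100, bins, seed=50)
    sets = [
        corrupt(truth, ErrorModel((0.85,) * 4, fp_rate=3.0, jitter_sd=10, seed=51 + i), genome, f"c{i}")
        for i in range(3)
    ]
    out = optimize_precision(sets, MergeConfig(mode="precision", min_support=2))
    rec = optimize_recall(sets)
    prec = lambda cs: compute_metrics(match_callset(cs, truth, 100)).precision
    sens = lambda cs: compute_metrics(match_callset(cs, truth, 100)).sensitivity
    assert prec(out) > max(prec(cs) for cs in sets)
    assert sens(out) < sens(rec)
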