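"""Pre-training: pick the top-performing caller per length bin.

Given call sets from several upstream callers and a gold-standard truth set,
each caller is benchmarked per length bin (module :mod:`svmeld.benchmark`)
and the callers are ranked within each bin by a chosen metric — F-score by
default, since the standard consensus mode targets overall accuracy. The
ranked table is frozen into a :class:`~svmeld.profiles.CallerProfile` that
discovery mode later applies to samples without a truth set.
"""

from __future__ import annotations

import datetime
import logging
from typing import Iterable, Sequence

from .benchmark import (
    HEADLINE_TAU,
    MetricsRow,
    compute_metrics,
    match_callset,
    stratified_metrics,
)
from .profiles import (
    DEFAULT_TIERS,
    CallerProfile,
    CoverageTier,
    LengthBins,
    tier_for_coverage,
)
from .sv_model import CallSet, SVType

__all__ = ["train_profile", "train_test_split"]

log = logging.getLogger(__name__)

_METRIC_FIELDS = {"fscore", "precision", "sensitivity"}


def _rank_key(metric: str):
    # higher metric wins; ties broken by higher precision, then caller_id —
    # FP inflation is the field's chronic failure mode, so precision breaks ties
    def key(entry: tuple[str, MetricsRow]):
        caller, row = entry
        return (-getattr(row, metric), -row.precision, caller)

    return key


def train_profile(
    callsets: Sequence[CallSet],
    truth: CallSet,
    bins: LengthBins = LengthBins(),
    tau: int = HEADLINE_TAU,
    metric: str = "fscore",
    organism: str = "unknown",
    coverage: float | None = None,
    tiers: Sequence[CoverageTier] = DEFAULT_TIERS,
    dataset: str = "",
) -> CallerProfile:
    """Benchmark every caller per length bin and rank them into a profile.

    All call sets and the truth must share one SV type (deletions and
    insertions are trained separately — they have different winning
    combinations). The full per-caller, per-bin metrics table is retained in
    the profile so the ranking is auditable. A bin with no truth events
    cannot be ranked on its own evidence; its winner falls back to the
    best caller by unstratified metrics and the bin is flagged
    ``untrained_bins`` in the metadata.

    Winner selection is invariant to the order callsets are passed in: ties
    break on higher precision, then lexicographic caller_id.
    """
    if not callsets:
        raise ValueError("at least one callset required")
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_FIELDS)}")
    svtypes = {t for cs in callsets for t in cs.svtypes()} | set(truth.svtypes())
    if len(svtypes) > 1:
        raise ValueError(f"train one svtype at a time, got {sorted(t.value for t in svtypes)}")
    svtype = svtypes.pop() if svtypes else SVType.DEL
    ids = [cs.caller_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate caller_id among callsets: {ids}")

    per_caller_rows = {
        cs.caller_id: stratified_metrics(cs, truth, tau, bins) for cs in callsets
    }
    global_rows = {
        cs.caller_id: compute_metrics(match_callset(cs, truth, tau), caller=cs.caller_id)
        for cs in callsets
    }

    truth_bin_counts = [0] * bins.n_bins
    for r in truth.records:
        if r.svlen >= bins.edges[0]:
            truth_bin_counts[bins.assign(r.svlen)] += 1

    bin_winners: dict[int, list[tuple[str, MetricsRow]]] = {}
    untrained: list[int] = []
    for b in range(bins.n_bins):
        if truth_bin_counts[b] == 0:
            untrained.append(b)
            entries = sorted(global_rows.items(), key=_rank_key(metric))
        else:
            entries = sorted(
                ((cid, rows[b]) for cid, rows in per_caller_rows.items()),
                key=_rank_key(metric),
            )
        bin_winners[b] = list(entries)
    if untrained:
        log.warning(
            "no truth events in bin(s) %s; winners chosen by global metrics",
            ", ".join(bins.label(b) for b in untrained),
        )

    if coverage is None:
        coverage = truth.coverage
    tier = (
        tier_for_coverage(coverage, tiers)
        if coverage is not None
        else tiers[-1]  # unknown depth: assume full-coverage data
    )
    metadata = {
        "dataset": dataset or (truth.caller_id or "truth"),
        "tau": tau,
        "metric": metric,
        "date": datetime.date.today().isoformat(),
        "n_truth_per_bin": truth_bin_counts,
    }
    if untrained:
        metadata["untrained_bins"] = untrained
    return CallerProfile(
        organism=organism,
        tier=tier,
        svtype=svtype,
        bins=bins,
        bin_winners=bin_winners,
        metadata=metadata,
    )


def train_test_split(
    truth: CallSet, train_chroms: Iterable[str], test_chroms: Iterable[str]
) -> tuple[CallSet, CallSet]:
    """Partition a call set by chromosome into train and test subsets.

    The chromosome sets must be disjoint; records on chromosomes in neither
    set are dropped with a logged count. An empty side is allowed (with a
    warning) so single-chromosome experiments remain expressible.
    """
    train_set = set(train_chroms)
    test_set = set(test_chroms)
    overlap = train_set & test_set
    if overlap:
        raise ValueError(f"train/test chromosome sets overlap: {sorted(overlap)}")
    train = truth.replace_records(r for r in truth.records if r.chrom in train_set)
    test = truth.replace_records(r for r in truth.records if r.chrom in test_set)
    dropped = len(truth) - len(train) - len(test)
    if dropped:
        log.info("train_test_split: %d record(s) on unlisted chromosomes dropped", dropped)
    if not len(test):
        log.warning("train_test_split: empty test set")
    if not len(train):
        log.warning("train_test_split: empty training set")
    return train, test
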