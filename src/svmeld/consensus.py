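"""Consensus merging of caller outputs.

Discovery mode routes each length bin to the caller a trained profile
declares best there, concatenates the routed records and removes cross-
caller duplicates of the same event. Two optimised modes trade the balance
point: recall mode takes the deduplicated union of every caller's records
(its sensitivity dominates each input's by set containment), and precision
mode keeps only events corroborated by at least ``min_support`` distinct
callers.

"Same event" is decided with the same two-breakpoint tau rule used for
benchmarking (default 100 bp), so the merge and its evaluation agree on
what a duplicate is.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .profiles import CallerProfile
from .sv_model import CallSet, SVRecord, SVType

__all__ = [
    "CONSENSUS_ID",
    "MergeConfig",
    "dedupe",
    "merge_by_profile",
    "optimize_recall",
    "optimize_precision",
]

log = logging.getLogger(__name__)

#: caller_id attached to consensus output call sets.
CONSENSUS_ID = "svmeld"


@dataclass(frozen=True)
class MergeConfig:
    """Tunables of the merge step.

    dedupe_tau
        Two records of the same type on the same chromosome closer than
        this (both breakpoints) are one event; default 100 bp, matching the
        headline evaluation threshold.
    mode
        "standard" (profile routing), "precision" or "recall".
    min_support
        Distinct-caller agreement required in precision mode. The default
        of 2 is the weakest corroboration requirement that can remove
        caller-private false positives.
    """

    dedupe_tau: int = 100
    mode: str = "standard"
    min_support: int = 2

    def __post_init__(self) -> None:
        if self.dedupe_tau < 0:
            raise ValueError("dedupe_tau must be >= 0")
        if self.mode not in ("standard", "precision", "recall"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


class _SeparationIndex:
    """Kept records per (chrom, svtype), queryable by breakpoint proximity."""

    def __init__(self, tau: int):
        self.tau = tau
        self._pos: dict[tuple[str, SVType], list[tuple[int, int]]] = {}

    def conflicts(self, r: SVRecord) -> bool:
        kept = self._pos.get((r.chrom, r.svtype))
        if not kept:
            return False
        lo = bisect_left(kept, (r.pos - self.tau, -1))
        hi = bisect_right(kept, (r.pos + self.tau, 1 << 62))
        return any(abs(kept[j][1] - r.end) <= self.tau for j in range(lo, hi))

    def add(self, r: SVRecord) -> None:
        insort(self._pos.setdefault((r.chrom, r.svtype), []), (r.pos, r.end))


def dedupe(
    calls: CallSet,
    tau: int,
    rank: Callable[[SVRecord], int] | None = None,
) -> CallSet:
    """Collapse tau-duplicates, keeping one representative per event.

    Records are visited in (caller rank, sort key) order and kept greedily
    unless an already-kept record of the same chromosome and type lies
    within ``tau`` on both breakpoints. Among duplicates the record from the
    higher-ranked caller therefore survives, falling back to sort order when
    ranks tie (or no ranking is given). No two kept records violate the
    separation predicate, and the operation is idempotent.
    """
    rank = rank or (lambda r: 0)
    index = _SeparationIndex(tau)
    kept: list[SVRecord] = []
    for r in sorted(calls.records, key=lambda r: (rank(r), r.sort_key)):
        if not index.conflicts(r):
            index.add(r)
            kept.append(r)
    return calls.replace_records(kept)


def _callsets_by_id(callsets: Sequence[CallSet]) -> dict[str, CallSet]:
    by_id: dict[str, CallSet] = {}
    for cs in callsets:
        if cs.caller_id in by_id:
            raise ValueError(f"duplicate caller_id {cs.caller_id!r}")
        by_id[cs.caller_id] = cs
    return by_id


def _consensus_meta(callsets: Sequence[CallSet]) -> dict:
    organisms = {cs.organism for cs in callsets if cs.organism is not None}
    coverages = {cs.coverage for cs in callsets if cs.coverage is not None}
    return {
        "organism": organisms.pop() if len(organisms) == 1 else None,
        "coverage": coverages.pop() if len(coverages) == 1 else None,
    }


def merge_by_profile(
    profile: CallerProfile,
    callsets: Sequence[CallSet],
    cfg: MergeConfig = MergeConfig(),
) -> CallSet:
    """Standard discovery-mode merge.

    For each length bin, take the records of that bin's winning caller whose
    own svlen falls in the bin (records of other lengths are the remit of
    other bins' winners), concatenate across bins and deduplicate. Every
    output record keeps its source caller in ``caller_id``, so provenance
    survives into the written VCF (INFO/SRC).
    """
    by_id = _callsets_by_id(callsets)
    missing = [c for c in profile.winners() if c not in by_id]
    if missing:
        raise ValueError(
            f"no callset provided for profile winner(s): {sorted(set(missing))}"
        )
    routed: list[SVRecord] = []
    for b in range(profile.bins.n_bins):
        winner = profile.winner(b)
        for r in by_id[winner].records:
            if r.svtype != profile.svtype or r.svlen < profile.bins.edges[0]:
                continue
            if profile.bins.assign(r.svlen) == b:
                routed.append(r)
    merged = CallSet(
        caller_id=CONSENSUS_ID, records=tuple(routed), **_consensus_meta(callsets)
    )
    return dedupe(merged, cfg.dedupe_tau, rank=lambda r: profile.caller_rank(r.caller_id))


def optimize_recall(
    callsets: Sequence[CallSet], cfg: MergeConfig = MergeConfig(mode="recall")
) -> CallSet:
    """Recall-optimised consensus: the deduplicated union of all callers.

    The output contains (a tau-representative of) every input record, so on
    any truth set its sensitivity is at least that of each input.
    """
    if not callsets:
        raise ValueError("at least one callset required")
    _callsets_by_id(callsets)  # reject duplicate ids
    pooled = [r for cs in callsets for r in cs.records]
    merged = CallSet(
        caller_id=CONSENSUS_ID, records=tuple(pooled), **_consensus_meta(callsets)
    )
    return dedupe(merged, cfg.dedupe_tau)


def optimize_precision(
    callsets: Sequence[CallSet], cfg: MergeConfig = MergeConfig(mode="precision")
) -> CallSet:
    """Precision-optimised consensus: keep only multi-caller events.

    A record survives iff records within ``dedupe_tau`` of it (both
    breakpoints, same type) exist in at least ``min_support`` distinct
    callers — a caller's own duplicates count once, so a noisy caller cannot
    corroborate itself. Survivors are deduplicated; each carries its
    supporting-caller count in ``support`` (INFO/SUPP on write). With
    ``min_support=1`` this degenerates to :func:`optimize_recall`.
    """
    by_id = _callsets_by_id(callsets)
    if cfg.min_support > len(by_id):
        raise ValueError(
            f"min_support={cfg.min_support} exceeds number of callers ({len(by_id)})"
        )
    # per (caller, chrom, svtype): sorted (pos, end) pairs for window queries
    per_caller: dict[str, dict[tuple[str, SVType], list[tuple[int, int]]]] = {}
    for cid, cs in by_id.items():
        idx: dict[tuple[str, SVType], list[tuple[int, int]]] = {}
        for r in cs.records:
            idx.setdefault((r.chrom, r.svtype), []).append((r.pos, r.end))
        per_caller[cid] = idx  # lists are sorted: records come pre-sorted

    tau = cfg.dedupe_tau

    def support_of(r: SVRecord) -> int:
        n = 0
        for cid, idx in per_caller.items():
            pairs = idx.get((r.chrom, r.svtype))
            if not pairs:
                continue
            lo = bisect_left(pairs, (r.pos - tau, -1))
            hi = bisect_right(pairs, (r.pos + tau, 1 << 62))
            if any(abs(pairs[j][1] - r.end) <= tau for j in range(lo, hi)):
                n += 1
        return n

    supported: list[SVRecord] = []
    for cs in by_id.values():
        for r in cs.records:
            s = support_of(r)
            if s >= cfg.min_support:
                supported.append(replace(r, support=s))
    merged = CallSet(
        caller_id=CONSENSUS_ID, records=tuple(supported), **_consensus_meta(callsets)
    )
    return dedupe(merged, tau)
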