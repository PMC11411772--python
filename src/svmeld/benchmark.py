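"""Breakpoint-resolution benchmarking of SV call sets against a truth set.

A predicted event matches a truth event when both of its breakpoints fall
within a resolution threshold tau (bp) of the truth breakpoints — a dynamic
distance criterion rather than a fixed reciprocal-overlap percentage.
Matching is one-to-one: each truth event can absorb at most one prediction
and vice versa, with ties resolved greedily and deterministically by the
call sets' total sort order. From the resulting TP/FP/FN partition the three
standard accuracy metrics are computed:

    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F-score     = 2 * sensitivity * precision / (sensitivity + precision)

The default threshold sweep is tau in {0, 10, 100, 1000, 10000} bp, with
100 bp as the single-threshold headline value.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Sequence

from .sv_model import CallSet, SVRecord, SVType

__all__ = [
    "DEFAULT_TAUS",
    "HEADLINE_TAU",
    "MatchResult",
    "MetricsRow",
    "records_match",
    "match_callset",
    "fscore",
    "metrics_from_counts",
    "compute_metrics",
    "threshold_sweep",
    "stratified_metrics",
]

#: Default resolution-threshold sweep, in bp.
DEFAULT_TAUS: tuple[int, ...] = (0, 10, 100, 1000, 10000)

#: Threshold used when a single headline number is reported.
HEADLINE_TAU: int = 100


def records_match(
    inferred: SVRecord, truth: SVRecord, tau: int, length_gate: bool = False
) -> bool:
    """True iff both breakpoints agree within ``tau`` bp (inclusive).

    Requires the same chromosome and the same SV type; deletions never match
    insertions. For insertions both coordinates equal POS, so the rule
    degenerates to a single position comparison; ``length_gate`` additionally
    requires ``|svlen difference| <= tau`` (off by default — mainly useful
    for insertions, whose length is not encoded in coordinates).
    """
    return (
        inferred.chrom == truth.chrom
        and inferred.svtype == truth.svtype
        and abs(inferred.pos - truth.pos) <= tau
        and abs(inferred.end - truth.end) <= tau
        and (not length_gate or abs(inferred.svlen - truth.svlen) <= tau)
    )


@dataclass
class MatchResult:
    """One-to-one TP pairing plus the FP/FN remainders at one tau."""

    tau: int
    tp_pairs: list[tuple[SVRecord, SVRecord]]  # (inferred, truth)
    fp: list[SVRecord]
    fn: list[SVRecord]

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


def match_callset(
    inferred: CallSet, truth: CallSet, tau: int, length_gate: bool = False
) -> MatchResult:
    """Greedy deterministic one-to-one matching of calls against truth.

    Truth records are visited in sorted order; each is paired with the first
    (in sort order) not-yet-paired inferred record satisfying
    :func:`records_match`. A paired record is never reused, so
    ``|TP| + |FP| == |inferred|`` and ``|TP| + |FN| == |truth|`` always hold.
    Candidate lookup is restricted with a binary search on start positions,
    which preserves the first-in-sort-order rule because a match requires
    ``|dpos| <= tau``.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    # index inferred records by (chrom, svtype); within a group the global
    # sort order is ascending (pos, end, ...)
    groups: dict[tuple[str, SVType], list[int]] = {}
    for idx, r in enumerate(inferred.records):
        groups.setdefault((r.chrom, r.svtype), []).append(idx)
    group_pos = {
        key: [inferred.records[i].pos for i in idxs] for key, idxs in groups.items()
    }

    used = [False] * len(inferred.records)
    tp_pairs: list[tuple[SVRecord, SVRecord]] = []
    fn: list[SVRecord] = []
    for t in truth.records:
        idxs = groups.get((t.chrom, t.svtype))
        matched = False
        if idxs:
            positions = group_pos[(t.chrom, t.svtype)]
            lo = bisect_left(positions, t.pos - tau)
            hi = bisect_right(positions, t.pos + tau)
            for j in range(lo, hi):
                i = idxs[j]
                cand = inferred.records[i]
                if (
                    not used[i]
                    and abs(cand.end - t.end) <= tau
                    and (not length_gate or abs(cand.svlen - t.svlen) <= tau)
                ):
                    used[i] = True
                    tp_pairs.append((inferred.records[i], t))
                    matched = True
                    break
        if not matched:
            fn.append(t)
    fp = [r for i, r in enumerate(inferred.records) if not used[i]]
    return MatchResult(tau=tau, tp_pairs=tp_pairs, fp=fp, fn=fn)


@dataclass
class MetricsRow:
    """Accuracy metrics for one (caller, tau, length-bin) cell."""

    tau: int
    n_tp: int
    n_fp: int
    n_fn: int
    sensitivity: float
    precision: float
    fscore: float
    caller: str = ""
    bin_label: str = "all"

    def as_dict(self) -> dict:
        return {
            "caller": self.caller,
            "tau": self.tau,
            "bin": self.bin_label,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "n_fn": self.n_fn,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "fscore": self.fscore,
        }


def fscore(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both are 0."""
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def metrics_from_counts(
    n_tp: int, n_fp: int, n_fn: int, tau: int = HEADLINE_TAU, **kw
) -> MetricsRow:
    """Build a :class:`MetricsRow` from raw TP/FP/FN counts.

    Zero-denominator cases return 0 rather than NaN so that empty call sets
    still yield comparable report rows.
    """
    sens = n_tp / (n_tp + n_fn) if n_tp + n_fn else 0.0
    prec = n_tp / (n_tp + n_fp) if n_tp + n_fp else 0.0
    return MetricsRow(
        tau=tau,
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        sensitivity=sens,
        precision=prec,
        fscore=fscore(sens, prec),
        **kw,
    )


def compute_metrics(m: MatchResult, **kw) -> MetricsRow:
    """Sensitivity, precision and F-score of a :class:`MatchResult`."""
    return metrics_from_counts(m.n_tp, m.n_fp, m.n_fn, tau=m.tau, **kw)


def threshold_sweep(
    inferred: CallSet,
    truth: CallSet,
    taus: Sequence[int] = DEFAULT_TAUS,
    caller: str | None = None,
) -> list[MetricsRow]:
    """One :class:`MetricsRow` per resolution threshold.

    Because the match predicate only relaxes as tau grows, TP counts (hence
    sensitivity and precision) are non-decreasing across the sweep.
    """
    if not taus:
        raise ValueError("taus must be non-empty")
    name = caller if caller is not None else inferred.caller_id
    return [
        compute_metrics(match_callset(inferred, truth, tau), caller=name)
        for tau in taus
    ]


def stratified_metrics(
    inferred: CallSet,
    truth: CallSet,
    tau: int,
    bins: "LengthBins",
    caller: str | None = None,
) -> list[MetricsRow]:
    """Per-length-bin metrics at one tau.

    Records are stratified by their own svlen (truth records by truth length
    — the ground-truth quantity) and matching is redone independently within
    each stratum. Records below the first bin edge are ignored; the standard
    pipeline filters them out beforehand.
    """
    from .profiles import LengthBins  # local import to avoid a cycle

    assert isinstance(bins, LengthBins)
    name = caller if caller is not None else inferred.caller_id
    rows: list[MetricsRow] = []
    for b in range(bins.n_bins):
        t_sub = truth.replace_records(
            r for r in truth.records if r.svlen >= bins.edges[0] and bins.assign(r.svlen) == b
        )
        i_sub = inferred.replace_records(
            r for r in inferred.records if r.svlen >= bins.edges[0] and bins.assign(r.svlen) == b
        )
        m = match_callset(i_sub, t_sub, tau)
        rows.append(compute_metrics(m, caller=name, bin_label=bins.label(b)))
    return rows
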