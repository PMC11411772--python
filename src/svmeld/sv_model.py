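"""Domain model for structural-variant call sets.

Structural variants (SVs) are genomic rearrangements of at least 50 bp:
deletions, insertions, duplications, inversions and complex events. This
module defines the in-memory representation used throughout the package —
:class:`SVRecord` (one event), :class:`CallSet` (a sorted collection from one
caller) and :class:`RegionSet` (high-confidence genomic intervals) — plus VCF
reading/writing and the two standard pre-filters applied before any
benchmarking or merging: the >=50 bp size filter and restriction to
high-confidence regions.

Coordinate conventions
----------------------
Records mirror VCF: 1-based, inclusive ``pos``/``end``. For deletions,
duplications and inversions the event spans ``[pos, end]`` and for deletions
``svlen == end - pos`` always holds. Insertions are point events
(``end == pos``) whose ``svlen`` is the inserted-sequence length. BED
intervals are 0-based half-open; the conversion happens only at the
:func:`filter_regions` boundary.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "MIN_SV_LENGTH",
    "SVType",
    "SVRecord",
    "CallSet",
    "RegionSet",
    "VCFParseError",
    "parse_vcf",
    "write_vcf",
    "filter_min_length",
    "filter_regions",
]

log = logging.getLogger(__name__)

#: Events shorter than this are not structural variants by definition.
MIN_SV_LENGTH = 50


class SVType(str, Enum):
    """Structural variant class."""

    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    INV = "INV"
    OTHER = "OTHER"


class VCFParseError(RuntimeError):
    """Raised when a VCF file cannot be opened or its header is malformed."""


def _parse_svtype(raw: str | None) -> SVType | None:
    if raw is None:
        return None
    raw = raw.upper()
    if raw.startswith("DUP"):  # DUP:TANDEM and friends
        return SVType.DUP
    try:
        return SVType(raw)
    except ValueError:
        return None


@dataclass(frozen=True)
class SVRecord:
    """A single structural variant event.

    Parameters
    ----------
    chrom, pos, end
        1-based inclusive breakpoint coordinates. ``end == pos`` for
        insertions.
    svtype
        Event class.
    svlen
        Event length magnitude in bp (>= 1). Deletions store
        ``end - pos``; insertions store the inserted-sequence length.
    caller_id
        Label of the caller that produced the record.
    qual, id
        Optional VCF QUAL and ID pass-throughs.
    support
        Number of distinct callers supporting the event (set by the
        precision-optimised consensus mode).
    """

    chrom: str
    pos: int
    end: int
    svtype: SVType
    svlen: int
    caller_id: str = ""
    qual: float | None = None
    id: str | None = None
    support: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.svlen < 1:
            raise ValueError(f"svlen must be >= 1, got {self.svlen}")
        if self.svtype is SVType.INS:
            if self.end != self.pos:
                raise ValueError("insertions are point events: end must equal pos")
        elif self.end < self.pos:
            raise ValueError(f"end ({self.end}) < pos ({self.pos})")
        if self.svtype is SVType.DEL and self.svlen != self.end - self.pos:
            raise ValueError(
                f"deletion svlen ({self.svlen}) != end - pos ({self.end - self.pos})"
            )

    @property
    def sort_key(self) -> tuple:
        """Total, deterministic ordering: (chrom, pos, end, svtype, ...)."""
        return (
            self.chrom,
            self.pos,
            self.end,
            self.svtype.value,
            self.svlen,
            self.caller_id,
            self.id or "",
        )

    def interval0(self) -> tuple[int, int]:
        """The record's footprint as a 0-based half-open interval."""
        return (self.pos - 1, max(self.end, self.pos))


@dataclass
class CallSet:
    """A sorted collection of :class:`SVRecord` from one caller.

    Records are re-sorted on construction so the sortedness invariant can
    never be violated by hand-built inputs.
    """

    caller_id: str
    records: tuple[SVRecord, ...] = ()
    organism: str | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        self.records = tuple(sorted(self.records, key=lambda r: r.sort_key))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def replace_records(self, records: Iterable[SVRecord]) -> "CallSet":
        """A copy of this call set with different records (re-sorted)."""
        return CallSet(
            caller_id=self.caller_id,
            records=tuple(records),
            organism=self.organism,
            coverage=self.coverage,
        )

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted({r.chrom for r in self.records}))

    def svtypes(self) -> tuple[SVType, ...]:
        return tuple(sorted({r.svtype for r in self.records}, key=lambda t: t.value))


class RegionSet:
    """Per-chromosome genomic intervals, 0-based half-open, merged on load.

    Used for high-confidence region filtering: the truth set is considered
    complete only inside these intervals, so benchmarking is restricted to
    them.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._ivals: dict[str, list[tuple[int, int]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, ivs in intervals.items():
            merged = self._merge(ivs)
            if merged:
                self._ivals[chrom] = merged
                self._starts[chrom] = [s for s, _ in merged]

    @staticmethod
    def _merge(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in sorted((int(s), int(e)) for s, e in ivs):
            if e <= s:
                continue
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        """Load a BED3 file (extra columns ignored)."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    fields = line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: not a BED3 line: {line!r}")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                intervals.setdefault(chrom, []).append((start, end))
        return cls(intervals)

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._ivals))

    def intervals(self, chrom: str) -> tuple[tuple[int, int], ...]:
        return tuple(self._ivals.get(chrom, ()))

    def _candidate(self, chrom: str, start: int) -> tuple[int, int] | None:
        """Last interval starting at or before ``start`` on ``chrom``."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, start) - 1
        if i < 0:
            return None
        return self._ivals[chrom][i]

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies fully inside one interval."""
        iv = self._candidate(chrom, start)
        return iv is not None and end <= iv[1]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, start) - 1
        if i >= 0 and self._ivals[chrom][i][1] > start:
            return True
        # next interval may begin inside [start, end)
        j = i + 1
        return j < len(starts) and starts[j] < end


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_HEADER_META = ("caller_id", "organism", "coverage")


def parse_vcf(path: str | Path, caller_id: str | None = None) -> CallSet:
    """Read SV records from a VCF 4.x file into a sorted :class:`CallSet`.

    Both symbolic (``<DEL>``) and sequence-resolved ALTs are accepted;
    multi-allelic records are split into one record per ALT. Records missing
    both SVLEN and END, or with an unknown SVTYPE, are counted and skipped
    with a log message, never fatal. For deletions the END coordinate is
    authoritative and ``svlen`` is recomputed as ``end - pos``; for
    insertions SVLEN is authoritative.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    caller_id
        Label for the records' source. Defaults to a ``##caller_id=`` header
        line if present, else the file stem. A per-record ``SRC`` INFO key
        (written by the consensus merger) overrides it record by record.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError, NotImplementedError) as exc:
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc

    meta: dict[str, str] = {}
    for hrec in vf.header.records:
        if hrec.key in _HEADER_META and hrec.value is not None:
            meta[hrec.key] = hrec.value
    default_caller = caller_id or meta.get("caller_id") or Path(str(path)).stem
    organism = meta.get("organism")
    coverage = float(meta["coverage"]) if "coverage" in meta else None

    declared = set(vf.header.info)  # pysam raises on undeclared INFO lookups

    def info_get(rec, key):
        return rec.info.get(key) if key in declared else None

    records: list[SVRecord] = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or (None,)
        svtype_raw = info_get(rec, "SVTYPE")
        svlen_raw = info_get(rec, "SVLEN")
        src = info_get(rec, "SRC")
        supp = info_get(rec, "SUPP")
        for i, alt in enumerate(alts):
            svtype = _parse_svtype(_per_alt(svtype_raw, i, len(alts)))
            if svtype is None:
                n_skipped += 1
                continue
            svlen_i = _per_alt(svlen_raw, i, len(alts))
            svlen = abs(int(svlen_i)) if svlen_i is not None else None
            # one stop cannot describe several ALTs: per-ALT SVLEN wins then
            per_alt_svlen = (
                len(alts) > 1
                and isinstance(svlen_raw, tuple)
                and len(svlen_raw) == len(alts)
            )
            try:
                fields = _resolve_coords(rec, alt, svtype, svlen, per_alt_svlen)
            except ValueError:
                n_skipped += 1
                continue
            if fields is None:
                n_skipped += 1
                continue
            pos, end, svlen = fields
            try:
                records.append(
                    SVRecord(
                        chrom=rec.chrom,
                        pos=pos,
                        end=end,
                        svtype=svtype,
                        svlen=svlen,
                        caller_id=str(src) if src is not None else default_caller,
                        qual=rec.qual,
                        id=rec.id,
                        support=int(supp) if supp is not None else None,
                    )
                )
            except ValueError:
                n_skipped += 1
    if n_skipped:
        log.warning("%s: skipped %d unusable record(s)", path, n_skipped)
    return CallSet(
        caller_id=default_caller,
        records=tuple(records),
        organism=organism,
        coverage=coverage,
    )


def _per_alt(value, i: int, n_alts: int):
    """INFO values declared Number=A/./1 — pick the i-th when per-ALT."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[i]
        return value[0] if value else None
    return value


def _resolve_coords(
    rec, alt: str | None, svtype: SVType, svlen: int | None, per_alt_svlen: bool = False
) -> tuple[int, int, int] | None:
    """Derive (pos, end, svlen) from a VCF record, or None if undecidable."""
    pos = rec.pos
    has_end = rec.stop > rec.pos and not per_alt_svlen  # pysam folds END into .stop
    if svtype is SVType.INS:
        if svlen is None:
            if alt and not alt.startswith("<"):
                svlen = len(alt) - len(rec.ref)
            else:
                return None
        if svlen < 1:
            return None
        return pos, pos, svlen
    if svtype is SVType.DEL:
        if has_end:
            end = rec.stop
        elif svlen is not None:
            end = pos + svlen
        else:
            return None
        return pos, end, end - pos  # coordinates are authoritative
    # DUP / INV / OTHER
    if has_end:
        end = rec.stop
        return pos, end, svlen if svlen is not None else end - pos
    if svlen is not None:
        return pos, pos + svlen, svlen
    return None


def write_vcf(calls: CallSet, path: str | Path) -> None:
    """Write a :class:`CallSet` as a minimal, sorted VCF 4.2 file.

    Records are emitted symbolically (``<DEL>``, ``<INS>``, ...) with
    SVTYPE, SVLEN and END in INFO; deletions carry negative SVLEN per VCF
    convention. Per-record provenance goes into ``SRC`` (source caller) and
    ``SUPP`` (supporting-caller count, when set). The call set's caller,
    organism and coverage metadata are stored as header lines so that
    ``parse_vcf(write_vcf(c)) == c``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=svmeld",
        f"##caller_id={calls.caller_id}",
    ]
    if calls.organism is not None:
        lines.append(f"##organism={calls.organism}")
    if calls.coverage is not None:
        lines.append(f"##coverage={calls.coverage:g}")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Length of the variant (negative for deletions)">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SRC,Number=1,Type=String,Description="Caller that produced this record">',
        '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of distinct callers supporting this record">',
    ]
    for chrom in calls.chromosomes():
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in calls.records:
        svlen_out = -r.svlen if r.svtype is SVType.DEL else r.svlen
        info = [
            f"SVTYPE={r.svtype.value}",
            f"SVLEN={svlen_out}",
            f"END={r.end}",
            f"SRC={r.caller_id}",
        ]
        if r.support is not None:
            info.append(f"SUPP={r.support}")
        qual = "." if r.qual is None else f"{r.qual:g}"
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    r.id or ".",
                    "N",
                    f"<{r.svtype.value}>",
                    qual,
                    ".",
                    ";".join(info),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pre-filters
# ---------------------------------------------------------------------------


def filter_min_length(calls: CallSet, min_len: int = MIN_SV_LENGTH) -> CallSet:
    """Drop records shorter than ``min_len`` bp.

    "Smaller than" is strict: a record with ``svlen == min_len`` is kept.
    Events under 50 bp fall below the defining size of a structural variant
    and are removed before any training or benchmarking.
    """
    return calls.replace_records(r for r in calls.records if r.svlen >= min_len)


def filter_regions(
    calls: CallSet, regions: RegionSet, mode: str = "containment"
) -> CallSet:
    """Restrict a call set to high-confidence regions.

    ``mode="containment"`` (default) keeps records fully contained in one
    interval, matching the usual high-confidence benchmarking convention;
    ``mode="overlap"`` keeps any record overlapping an interval by >= 1 bp.
    Chromosomes present in the calls but absent from the BED are reported as
    a warning (typically a naming-scheme mismatch, chr1 vs 1).
    """
    if mode not in ("containment", "overlap"):
        raise ValueError(f"unknown region-filter mode: {mode!r}")
    missing = set(calls.chromosomes()) - set(regions.chromosomes())
    if missing:
        log.warning(
            "chromosomes absent from region file (all their records drop): %s",
            ", ".join(sorted(missing)),
        )
    test = regions.contains if mode == "containment" else regions.overlaps
    kept = [r for r in calls.records if test(r.chrom, *r.interval0())]
    return calls.replace_records(kept)
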