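"""Length bins, coverage tiers and trained caller profiles.

Caller performance varies strongly with event length and sequencing depth,
so the consensus framework stratifies both. Events are grouped into
half-open length bins — by default [50,100), [100,500), [500,1000) and
[1000,inf) bp — and samples into coverage tiers. A trained
:class:`CallerProfile` records, per bin, the ranked list of callers with
their training metrics; discovery mode looks the profile up by organism and
coverage and routes each bin to its winning caller.

Profiles serialise to a small YAML document so they can be inspected,
versioned and edited by hand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .benchmark import MetricsRow
from .sv_model import SVType

__all__ = [
    "DEFAULT_BIN_EDGES",
    "DEFAULT_TIERS",
    "LengthBins",
    "CoverageTier",
    "CallerProfile",
    "ProfileStore",
    "ProfileError",
    "assign_bin",
    "tier_for_coverage",
    "resolve_profile",
    "save_profile",
    "load_profile",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_EDGES: tuple[int, ...] = (50, 100, 500, 1000)


class ProfileError(RuntimeError):
    """Raised on profile schema violations or an empty profile store."""


@dataclass(frozen=True)
class LengthBins:
    """Ascending edges defining half-open length bins; the last is open-ended.

    ``edges=(50, 100, 500, 1000)`` gives four bins: [50,100), [100,500),
    [500,1000) and [1000,inf). A boundary value belongs to the upper bin.
    """

    edges: tuple[int, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(int(e) for e in self.edges))
        if len(self.edges) < 1:
            raise ValueError("at least one bin edge required")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError(f"edges must be strictly ascending: {self.edges}")
        if self.edges[0] < 50:
            raise ValueError("first edge must be >= 50 bp (SV size definition)")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def assign(self, svlen: int) -> int:
        """Index of the unique bin containing ``svlen``."""
        if svlen < self.edges[0]:
            raise ValueError(
                f"svlen {svlen} below first bin edge {self.edges[0]}; "
                "filter short events before binning"
            )
        for i in range(self.n_bins - 1, -1, -1):
            if svlen >= self.edges[i]:
                return i
        raise AssertionError("unreachable")

    def label(self, i: int) -> str:
        if i < 0 or i >= self.n_bins:
            raise IndexError(f"bin index {i} out of range")
        if i == self.n_bins - 1:
            return f"[{self.edges[i]},inf)"
        return f"[{self.edges[i]},{self.edges[i + 1]})"

    def upper(self, i: int) -> float:
        """Exclusive upper bound of bin ``i`` (inf for the last)."""
        return float(self.edges[i + 1]) if i < self.n_bins - 1 else math.inf


def assign_bin(svlen: int, bins: LengthBins) -> int:
    """Functional alias for :meth:`LengthBins.assign`."""
    return bins.assign(svlen)


@dataclass(frozen=True)
class CoverageTier:
    """A labelled half-open depth interval [lo, hi), in x coverage."""

    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"tier {self.label}: lo must be < hi")

    def contains(self, coverage: float) -> bool:
        return self.lo <= coverage < self.hi

    @property
    def midpoint(self) -> float:
        # open-ended top tier: use its lower edge as the representative depth
        return self.lo if math.isinf(self.hi) else (self.lo + self.hi) / 2.0


#: Default depth tiers, chosen to separate the regimes of interest:
#: ultra-low (<0.5x), low (0.5-8x), mid (8-20x) and full depth (>=20x).
DEFAULT_TIERS: tuple[CoverageTier, ...] = (
    CoverageTier("ultra-low", 0.0, 0.5),
    CoverageTier("low", 0.5, 8.0),
    CoverageTier("mid", 8.0, 20.0),
    CoverageTier("high", 20.0, math.inf),
)


def tier_for_coverage(
    coverage: float, tiers: Sequence[CoverageTier] = DEFAULT_TIERS
) -> CoverageTier:
    for t in tiers:
        if t.contains(coverage):
            return t
    raise ValueError(f"no tier contains coverage {coverage}x")


@dataclass
class CallerProfile:
    """The trained artifact: ranked winning callers per length bin.

    ``bin_winners`` maps bin index to a ranked list of (caller_id, training
    MetricsRow), best first. Rank 0 is the caller used by the standard
    merge; the runners-up support the optimised modes and auditing.
    """

    organism: str
    tier: CoverageTier
    svtype: SVType
    bins: LengthBins
    bin_winners: dict[int, list[tuple[str, MetricsRow]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b in range(self.bins.n_bins):
            if not self.bin_winners.get(b):
                raise ProfileError(f"bin {b} ({self.bins.label(b)}) has no winner")

    def winner(self, bin_index: int, rank: int = 0) -> str:
        return self.bin_winners[bin_index][rank][0]

    def winners(self) -> tuple[str, ...]:
        """Rank-0 caller per bin, in bin order."""
        return tuple(self.winner(b) for b in range(self.bins.n_bins))

    def callers(self) -> tuple[str, ...]:
        out: set[str] = set()
        for entries in self.bin_winners.values():
            out.update(c for c, _ in entries)
        return tuple(sorted(out))

    def caller_rank(self, caller_id: str) -> int:
        """Best (lowest) rank the caller achieves in any bin; inf if absent."""
        best = math.inf
        for entries in self.bin_winners.values():
            for rank, (c, _) in enumerate(entries):
                if c == caller_id:
                    best = min(best, rank)
        return int(best) if math.isfinite(best) else 10**9


@dataclass
class ProfileStore:
    """A collection of trained profiles with an optional designated default."""

    profiles: list[CallerProfile] = field(default_factory=list)
    default_organism: str | None = None


def resolve_profile(
    organism: str, coverage: float, store: ProfileStore, svtype: SVType | None = None
) -> CallerProfile:
    """Pick the closest trained profile for a sample.

    Preference order: exact organism with the tier containing ``coverage``;
    same organism, nearest tier by depth midpoint; the store's default
    organism (falling back to the first profile) with a warning. Organism
    closeness is exact-tag matching only — no phylogenetic guessing.
    """
    pool = store.profiles
    if svtype is not None:
        pool = [p for p in pool if p.svtype == svtype] or store.profiles
    if not pool:
        raise ProfileError("profile store is empty")
    same_org = [p for p in pool if p.organism == organism]
    if same_org:
        exact = [p for p in same_org if p.tier.contains(coverage)]
        if exact:
            log.info("profile: exact match %s/%s", organism, exact[0].tier.label)
            return exact[0]
        nearest = min(same_org, key=lambda p: (abs(p.tier.midpoint - coverage), p.tier.lo))
        log.info(
            "profile: no tier for %.3gx, using nearest tier %s", coverage, nearest.tier.label
        )
        return nearest
    fallback_org = store.default_organism or pool[0].organism
    fallback = [p for p in pool if p.organism == fallback_org] or pool
    log.warning(
        "profile: organism %r not in store, falling back to %r", organism, fallback_org
    )
    exact = [p for p in fallback if p.tier.contains(coverage)]
    if exact:
        return exact[0]
    return min(fallback, key=lambda p: (abs(p.tier.midpoint - coverage), p.tier.lo))


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

_SCHEMA = "svmeld-profile/1"


def _row_to_dict(row: MetricsRow) -> dict:
    return row.as_dict()


def _row_from_dict(d: dict) -> MetricsRow:
    return MetricsRow(
        tau=int(d["tau"]),
        n_tp=int(d["n_tp"]),
        n_fp=int(d["n_fp"]),
        n_fn=int(d["n_fn"]),
        sensitivity=float(d["sensitivity"]),
        precision=float(d["precision"]),
        fscore=float(d["fscore"]),
        caller=str(d.get("caller", "")),
        bin_label=str(d.get("bin", "all")),
    )


def save_profile(profile: CallerProfile, path: str | Path) -> None:
    """Serialise a profile to a human-readable YAML file."""
    doc = {
        "schema": _SCHEMA,
        "organism": profile.organism,
        "svtype": profile.svtype.value,
        "coverage_tier": {
            "label": profile.tier.label,
            "lo": float(profile.tier.lo),
            "hi": float(profile.tier.hi),
        },
        "bin_edges": list(profile.bins.edges),
        "bin_winners": {
            int(b): [
                {"caller": c, "metrics": _row_to_dict(row)} for c, row in entries
            ]
            for b, entries in sorted(profile.bin_winners.items())
        },
        "metadata": profile.metadata,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_profile(path: str | Path) -> CallerProfile:
    """Load and validate a YAML profile; schema violations name the field."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ProfileError(f"{path}: not a mapping")
    for key in ("organism", "svtype", "coverage_tier", "bin_edges", "bin_winners"):
        if key not in doc:
            raise ProfileError(f"{path}: missing required field {key!r}")
    tier_doc = doc["coverage_tier"]
    for key in ("label", "lo", "hi"):
        if key not in tier_doc:
            raise ProfileError(f"{path}: coverage_tier missing field {key!r}")
    bins = LengthBins(tuple(doc["bin_edges"]))
    winners: dict[int, list[tuple[str, MetricsRow]]] = {}
    raw = doc["bin_winners"]
    for b in range(bins.n_bins):
        entries = raw.get(b, raw.get(str(b)))
        if not entries:
            raise ProfileError(f"{path}: bin_winners missing bin {b} ({bins.label(b)})")
        parsed = []
        for e in entries:
            if "caller" not in e:
                raise ProfileError(f"{path}: bin {b} entry missing field 'caller'")
            parsed.append((str(e["caller"]), _row_from_dict(e.get("metrics", _EMPTY_ROW))))
        winners[b] = parsed
    return CallerProfile(
        organism=str(doc["organism"]),
        tier=CoverageTier(
            label=str(tier_doc["label"]),
            lo=float(tier_doc["lo"]),
            hi=float(tier_doc["hi"]),
        ),
        svtype=SVType(doc["svtype"]),
        bins=bins,
        bin_winners=winners,
        metadata=dict(doc.get("metadata") or {}),
    )


_EMPTY_ROW = {
    "tau": 0,
    "n_tp": 0,
    "n_fp": 0,
    "n_fn": 0,
    "sensitivity": 0.0,
    "precision": 0.0,
    "fscore": 0.0,
}
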