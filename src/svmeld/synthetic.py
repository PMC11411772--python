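"""Synthetic truth sets and imperfect caller call sets.

Real SV callers are strong in some length regimes and weak in others, miss
events, emit false positives, and report breakpoints with noise. This
module generates call-level fixtures with all of those behaviours under
explicit control, so training, merging and evaluation can be exercised
end-to-end without any external data:

* :func:`generate_truth` places non-overlapping events on a toy genome with
  a prescribed number of events per length bin (lengths log-uniform within
  each bin, positions uniform). Events are spaced far apart relative to the
  largest event, so fixture matching is never ambiguous.
* :func:`corrupt` passes a truth set through an :class:`ErrorModel`: each
  event is reported with its bin's sensitivity probability, surviving
  breakpoints are jittered by rounded zero-mean Gaussian noise, and false
  positives arrive as a Poisson process along the genome with lengths drawn
  from the truth length distribution (so every bin sees false calls).

Everything is deterministic per seed. No read-level data is simulated —
fixtures are call sets, not FASTQ/BAM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import LengthBins
from .sv_model import MIN_SV_LENGTH, CallSet, SVRecord, SVType

__all__ = ["GenomeModel", "ErrorModel", "generate_truth", "corrupt"]

#: Cap on event length in the open-ended top bin, as a multiple of its edge.
_TOP_BIN_SPAN = 10


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths of a toy genome."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("genome needs at least one chromosome")
        if any(length <= 0 for _, length in self.chroms):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeModel":
        return cls(tuple(d.items()))

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chroms)

    @property
    def total_mb(self) -> float:
        return self.total_bp / 1e6


@dataclass(frozen=True)
class ErrorModel:
    """Behaviour of one simulated caller.

    sensitivity
        Per-bin detection probability, one value per length bin.
    fp_rate
        Expected false calls per Mb of genome.
    jitter_sd
        SD (bp) of the rounded Gaussian noise added to each reported
        breakpoint independently (deletions; insertions jitter position
        only).
    length_noise_sd
        Extra length noise for insertions, whose length is not encoded in
        coordinates.
    seed
        Seed of this caller's private RNG stream.
    """

    sensitivity: tuple[float, ...]
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    length_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= s <= 1.0 for s in self.sensitivity):
            raise ValueError("sensitivities must lie in [0, 1]")
        if self.jitter_sd < 0 or self.length_noise_sd < 0 or self.fp_rate < 0:
            raise ValueError("noise parameters must be non-negative")


def _length_cap(bins: LengthBins, b: int) -> int:
    hi = bins.upper(b)
    return int(hi) - 1 if np.isfinite(hi) else bins.edges[b] * _TOP_BIN_SPAN


def _draw_length(rng: np.random.Generator, bins: LengthBins, b: int) -> int:
    lo = bins.edges[b]
    hi = _length_cap(bins, b) + 1
    return int(np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def generate_truth(
    genome: GenomeModel,
    n_per_bin: int,
    bins: LengthBins = LengthBins(),
    svtype: SVType = SVType.DEL,
    seed: int = 0,
) -> CallSet:
    """Place ``n_per_bin`` non-overlapping events per length bin.

    Consecutive events are separated by at least twice the largest possible
    event length, so no simulated call can sit within matching distance of
    two truth events at any sensible tau. Raises if the genome is too small
    to hold the requested events at that spacing.
    """
    if n_per_bin < 0:
        raise ValueError("n_per_bin must be >= 0")
    rng = np.random.default_rng(seed)
    max_len = max(_length_cap(bins, b) for b in range(bins.n_bins))
    spacing = 2 * max_len

    events: list[tuple[int, int]] = []  # (bin, length)
    for b in range(bins.n_bins):
        events.extend((b, _draw_length(rng, bins, b)) for _ in range(n_per_bin))
    rng.shuffle(events)

    records: list[SVRecord] = []
    chrom_iter = iter(genome.chroms)
    chrom, chrom_len = next(chrom_iter)
    cursor = 1
    for i, (b, length) in enumerate(events):
        gap = int(rng.integers(spacing, 2 * spacing))
        cursor += gap
        while cursor + length >= chrom_len:
            try:
                chrom, chrom_len = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    f"genome too small: placed {i} of {len(events)} events "
                    f"at spacing >= {spacing} bp"
                ) from None
            cursor = 1 + int(rng.integers(spacing, 2 * spacing))
        pos = cursor
        if svtype is SVType.INS:
            rec = SVRecord(chrom, pos, pos, svtype, length, caller_id="truth",
                           id=f"truth_{i:05d}")
            cursor = pos
        else:
            rec = SVRecord(chrom, pos, pos + length, svtype, length,
                           caller_id="truth", id=f"truth_{i:05d}")
            cursor = pos + length
        records.append(rec)
    return CallSet(caller_id="truth", records=tuple(records))


def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(np.rint(rng.normal(0.0, sd))) if sd > 0 else 0


def corrupt(
    truth: CallSet,
    model: ErrorModel,
    genome: GenomeModel,
    caller_id: str,
    bins: LengthBins = LengthBins(),
) -> CallSet:
    """Simulate one caller's output from a truth set.

    Each truth event is emitted with its bin's sensitivity probability and
    jittered breakpoints; false positives are added as Poisson(fp_rate x
    genome Mb) random events with lengths resampled from the truth set. All
    output records respect the 50 bp minimum length. With sensitivities of
    1 and no noise, the output equals the truth.
    """
    if len(model.sensitivity) != bins.n_bins:
        raise ValueError(
            f"error model has {len(model.sensitivity)} sensitivities "
            f"for {bins.n_bins} bins"
        )
    rng = np.random.default_rng(model.seed)
    out: list[SVRecord] = []
    counter = itertools.count()

    for r in truth.records:
        b = bins.assign(r.svlen)
        if rng.random() >= model.sensitivity[b]:
            continue
        pos = max(1, r.pos + _jitter(rng, model.jitter_sd))
        if r.svtype is SVType.INS:
            svlen = max(
                MIN_SV_LENGTH, r.svlen + _jitter(rng, model.length_noise_sd)
            )
            out.append(
                SVRecord(r.chrom, pos, pos, r.svtype, svlen, caller_id=caller_id,
                         id=f"{caller_id}_{next(counter):05d}")
            )
        else:
            end = max(pos + MIN_SV_LENGTH, r.end + _jitter(rng, model.jitter_sd))
            svlen = end - pos if r.svtype is SVType.DEL else r.svlen
            out.append(
                SVRecord(r.chrom, pos, end, r.svtype, svlen, caller_id=caller_id,
                         id=f"{caller_id}_{next(counter):05d}")
            )

    # false positives: Poisson along the genome, truth-like lengths
    n_fp = int(rng.poisson(model.fp_rate * genome.total_mb))
    truth_lengths = [r.svlen for r in truth.records]
    if n_fp and truth_lengths:
        chrom_names = [c for c, _ in genome.chroms]
        chrom_lens = np.array([l for _, l in genome.chroms], dtype=float)
        weights = chrom_lens / chrom_lens.sum()
        svtype = truth.records[0].svtype
        for _ in range(n_fp):
            ci = int(rng.choice(len(chrom_names), p=weights))
            length = int(truth_lengths[int(rng.integers(len(truth_lengths)))])
            pos = int(rng.integers(1, max(2, int(chrom_lens[ci]) - length)))
            if svtype is SVType.INS:
                rec = SVRecord(chrom_names[ci], pos, pos, svtype, length,
                               caller_id=caller_id,
                               id=f"{caller_id}_fp{next(counter):05d}")
            else:
                rec = SVRecord(chrom_names[ci], pos, pos + length, svtype, length,
                               caller_id=caller_id,
                               id=f"{caller_id}_fp{next(counter):05d}")
            out.append(rec)
    return CallSet(
        caller_id=caller_id,
        records=tuple(out),
        organism=truth.organism,
        coverage=truth.coverage,
    )
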