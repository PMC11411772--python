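"""Read-pair-aware downsampling of SAM/BAM alignments.

Naive per-read subsampling breaks read pairs apart and leaves singleton
mates in the output, which distorts the discordant-pair signal SV callers
depend on. Here the keep/drop decision is made once per read *name* (the
template), so both mates — and any secondary or supplementary alignments of
the same template — share one fate, no matter how far apart they appear in
the file and without buffering it.

The decision is a seeded hash of the read name rather than a streaming RNG:
``keep(name) = blake2b(name, salt=seed) / 2^64 < p``. This makes the
selection deterministic for a given (input, fraction, seed), consistent for
mates, and independent across seeds.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pysam

__all__ = ["keep_read_name", "downsample_pairs", "fraction_for_target"]

log = logging.getLogger(__name__)

_PG_ID = "svmeld-downsample"


def keep_read_name(name: str, fraction: float, seed: int) -> bool:
    """Deterministic per-template keep decision.

    Maps the read name to a uniform 64-bit hash salted with the seed and
    keeps the template iff the hash falls below ``fraction`` of the range.
    """
    if fraction >= 1.0:
        return True
    if fraction <= 0.0:
        return False
    salt = int(seed).to_bytes(8, "little", signed=True)
    h = hashlib.blake2b(name.encode(), digest_size=8, salt=salt).digest()
    return int.from_bytes(h, "big") < fraction * 2.0**64


def downsample_pairs(
    in_path: str | Path,
    out_path: str | Path,
    fraction: float,
    seed: int = 0,
) -> tuple[int, int]:
    """Subsample an alignment file to ``fraction`` of its templates.

    All records sharing a read name are kept or dropped together, so the
    output contains no singleton mates. The header is passed through with a
    @PG record appended. SAM and BAM are both accepted (by extension) for
    input and output.

    Returns
    -------
    (n_kept, n_total)
        Record counts (not template counts) after and before sampling.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    in_path, out_path = Path(in_path), Path(out_path)
    with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as fin:
        header = fin.header.to_dict()
        if not header.get("SQ") and not header.get("HD"):
            raise ValueError(f"{in_path}: alignment file has no header")
        header.setdefault("PG", []).append(
            {
                "ID": _PG_ID,
                "PN": "svmeld",
                "CL": f"downsample --fraction {fraction} --seed {seed}",
            }
        )
        out_mode = "wb" if str(out_path).endswith(".bam") else "wh"
        n_kept = n_total = 0
        with pysam.AlignmentFile(str(out_path), out_mode, header=header) as fout:
            for rec in fin:
                n_total += 1
                if keep_read_name(rec.query_name, fraction, seed):
                    fout.write(rec)
                    n_kept += 1
    log.info(
        "downsample: kept %d/%d records (target fraction %.4g, seed %d)",
        n_kept,
        n_total,
        fraction,
        seed,
    )
    return n_kept, n_total


def fraction_for_target(current_coverage: float, target_coverage: float) -> float:
    """Sampling fraction that brings ``current_coverage`` down to target.

    E.g. 32x down to 0.5x requires keeping 0.5/32 = 0.015625 of templates.
    """
    if target_coverage <= 0:
        raise ValueError("target coverage must be > 0")
    if target_coverage > current_coverage:
        raise ValueError(
            f"target coverage ({target_coverage}x) exceeds current "
            f"({current_coverage}x); cannot upsample"
        )
    return min(1.0, target_coverage / current_coverage)
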