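"""Shared fixtures: random call sets, toy genomes, and a SAM-file builder."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from svmeld import CallSet, GenomeModel, LengthBins, SVRecord, SVType


@pytest.fixture
def bins() -> LengthBins:
    return LengthBins()


@pytest.fixture
def genome() -> GenomeModel:
    return GenomeModel.from_dict({"chr1": 60_000_000, "chr2": 40_000_000})


def make_del(chrom: str, pos: int, end: int, caller: str = "x", **kw) -> SVRecord:
    return SVRecord(chrom, pos, end, SVType.DEL, end - pos, caller_id=caller, **kw)


def make_ins(chrom: str, pos: int, svlen: int, caller: str = "x", **kw) -> SVRecord:
    return SVRecord(chrom, pos, pos, SVType.INS, svlen, caller_id=caller, **kw)


def random_callset(
    rng: np.random.Generator,
    n: int,
    caller: str = "x",
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    span: int = 1_000_000,
    svtypes: tuple[SVType, ...] = (SVType.DEL,),
) -> CallSet:
    """Random events with lengths in [50, 5000] — no spacing guarantees."""
    records = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        svtype = svtypes[int(rng.integers(len(svtypes)))]
        pos = int(rng.integers(1, span))
        svlen = int(rng.integers(50, 5001))
        if svtype is SVType.INS:
            records.append(SVRecord(chrom, pos, pos, svtype, svlen, caller_id=caller))
        else:
            records.append(
                SVRecord(chrom, pos, pos + svlen, svtype, svlen, caller_id=caller)
            )
    return CallSet(caller_id=caller, records=tuple(records))


def write_sam_pairs(
    path: Path, n_pairs: int, n_unpaired: int = 0, seed: int = 0
) -> None:
    """Write a coordinate-plausible SAM file with n_pairs proper pairs."""
    rng = np.random.default_rng(seed)
    ref_len = 1_000_000
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:chr1\tLN:{ref_len}"]
    seq, qual = "ACGTACGTAC", "IIIIIIIIII"
    for i in range(n_pairs):
        p1 = int(rng.integers(1, ref_len - 500))
        p2 = p1 + int(rng.integers(100, 400))
        name = f"pair{i:06d}"
        lines.append(
            f"{name}\t99\tchr1\t{p1}\t60\t10M\t=\t{p2}\t{p2 - p1 + 10}\t{seq}\t{qual}"
        )
        lines.append(
            f"{name}\t147\tchr1\t{p2}\t60\t10M\t=\t{p1}\t{-(p2 - p1 + 10)}\t{seq}\t{qual}"
        )
    for i in range(n_unpaired):
        p = int(rng.integers(1, ref_len - 500))
        lines.append(f"solo{i:06d}\t0\tchr1\t{p}\t60\t10M\t*\t0\t0\t{seq}\t{qual}")
    path.write_text("\n".join(lines) + "\n")
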