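"""Fragment-level I/O: reading, filtering, downsampling and interval assignment.

All coordinates are BED-style 0-based half-open; a fragment's length is
``end - start`` and its genomic position, whenever a single point is needed,
is its midpoint ``(start + end) // 2``. Strand is ignored throughout:
records are DNA fragments, not reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FragmentSet",
    "read_fragments",
    "write_fragments",
    "downsample",
    "assign_intervals",
    "merge_fragment_sets",
]

_COLS = ["chrom", "start", "end"]


@dataclass
class FragmentSet:
    """One sample's cfDNA fragments plus provenance metadata.

    ``records`` is a DataFrame with columns chrom/start/end, sorted by
    (chrom, start). ``metadata`` records where the fragments came from and
    which filters were applied (counts of read / kept / dropped records).
    """

    sample_id: str
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns[:3]) != _COLS:
            df = df.iloc[:, :3].set_axis(_COLS, axis=1)
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if len(df) and not (df["end"].to_numpy() > df["start"].to_numpy()).all():
            raise ValueError("all fragments must satisfy end > start")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> np.ndarray:
        """Fragment lengths in bp (end - start)."""
        return (self.records["end"] - self.records["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.records["start"] + self.records["end"]) // 2).to_numpy()


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(
    path: str | Path,
    length_range: tuple[int, int] = (100, 220),
    sample_id: str | None = None,
) -> FragmentSet:
    """Read a BED3+ file into a FragmentSet, keeping fragments with
    ``lo <= length <= hi`` (both bounds inclusive).

    Records with ``end <= start`` are rejected and counted, malformed lines
    raise with their line number. Extra BED columns are ignored. Gzip input
    is detected by the ``.gz`` suffix.
    """
    path = Path(path)
    lo, hi = length_range
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_read = n_bad = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            n_read += 1
            if end <= start:
                n_bad += 1
                continue
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    if len(df):
        keep = (df["end"] - df["start"]).between(lo, hi)
        n_dropped = int((~keep).sum())
        df = df[keep]
    else:
        n_dropped = 0
    return FragmentSet(
        sample_id=sample_id or path.name.split(".")[0],
        records=df,
        metadata={
            "source": str(path),
            "length_range": [lo, hi],
            "n_read": n_read,
            "n_invalid": n_bad,
            "n_length_filtered": n_dropped,
            "n_kept": len(df),
        },
    )


def read_fragments_bam(
    path: str | Path,
    length_range: tuple[int, int] = (100, 220),
    sample_id: str | None = None,
    min_mapq: int = 30,
) -> FragmentSet:
    """Read properly paired reads from a coordinate-sorted BAM/SAM into
    outer-coordinate fragments (optional; requires pysam)."""
    import pysam  # deferred: BAM support is optional

    path = Path(path)
    lo, hi = length_range
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_read = 0
    with pysam.AlignmentFile(str(path)) as bam:
        for aln in bam:
            if (
                not aln.is_proper_pair
                or aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.mapping_quality < min_mapq
                or aln.template_length <= 0  # count each pair once, from the leftmost mate
            ):
                continue
            n_read += 1
            start = aln.reference_start
            end = start + aln.template_length
            if lo <= end - start <= hi:
                chroms.append(aln.reference_name)
                starts.append(start)
                ends.append(end)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentSet(
        sample_id=sample_id or path.name.split(".")[0],
        records=df,
        metadata={
            "source": str(path),
            "length_range": [lo, hi],
            "min_mapq": min_mapq,
            "n_read": n_read,
            "n_kept": len(df),
        },
    )


def write_fragments(fragset: FragmentSet, path: str | Path) -> Path:
    """Write a FragmentSet as BED3 (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for chrom, start, end in fragset.records.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path


def downsample(
    fragset: FragmentSet,
    target_count: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> FragmentSet:
    """Simple random sample of fragments without replacement, re-sorted.

    Exactly one of ``target_count`` / ``fraction`` must be given; the result
    is deterministic given ``seed``.
    """
    n = len(fragset)
    if (target_count is None) == (fraction is None):
        raise ValueError("specify exactly one of target_count or fraction")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        target_count = int(round(fraction * n))
    if target_count > n:
        raise ValueError(f"target_count {target_count} exceeds available {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=target_count, replace=False)
    sub = fragset.records.iloc[np.sort(idx)]
    meta = dict(fragset.metadata)
    meta.update({"downsampled_from": n, "downsample_seed": seed, "n_kept": target_count})
    return FragmentSet(sample_id=fragset.sample_id, records=sub, metadata=meta)


def merge_fragment_sets(fragsets: Sequence[FragmentSet], sample_id: str) -> FragmentSet:
    """Union of several samples' fragments, merged and re-sorted."""
    if not fragsets:
        raise ValueError("no fragment sets to merge")
    df = pd.concat([f.records for f in fragsets], ignore_index=True)
    return FragmentSet(
        sample_id=sample_id,
        records=df,
        metadata={"merged_from": [f.sample_id for f in fragsets], "n_kept": len(df)},
    )


def assign_intervals(
    fragset: FragmentSet,
    intervals: Sequence[tuple[str, str, int, int]],
) -> np.ndarray:
    """Assign each fragment to an interval by midpoint containment.

    ``intervals`` is a sequence of (name, chrom, start, end), half-open and
    non-overlapping within each chromosome (overlap raises). Returns an
    object array of interval names, with ``"unassigned"`` for fragments whose
    midpoint falls outside every interval.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for name, chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end), name))
    lookup: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs])
        ends = np.array([e for _, e, _ in ivs])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping intervals on {chrom}")
        lookup[chrom] = (starts, ends, [n for _, _, n in ivs])

    out = np.full(len(fragset), "unassigned", dtype=object)
    mids = fragset.midpoints
    chrom_arr = fragset.records["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        if chrom not in lookup:
            continue
        starts, ends, names = lookup[chrom]
        mask = chrom_arr == chrom
        pos = mids[mask]
        # half-open: midpoint exactly at an interval end belongs to the next one
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        assigned = np.full(mask.sum(), "unassigned", dtype=object)
        name_arr = np.array(names, dtype=object)
        assigned[ok] = name_arr[j[ok]]
        out[mask] = assigned
    return out
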