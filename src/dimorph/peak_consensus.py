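"""m-of-n consensus peak definition over replicate interval sets.

A consensus ("true") peak is a maximal genomic run where calls from at
least m of the n replicate samples simultaneously overlap, computed
base-wise by a boundary sweep, with any candidate that intersects an
input-control interval by >= 1 bp moved to the excluded set.  The study
default is m = 14 of n = 18 replicates.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakCollection",
    "ConsensusSet",
    "normalize_intervals",
    "support_profile",
    "call_consensus",
    "annotate_genes",
    "read_bed",
    "write_bed",
]

BED3 = ["contig", "start", "end"]


def normalize_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent-overlapping intervals per
    contig (touching intervals stay separate; only >=1 bp overlaps merge)."""
    if df.empty:
        return pd.DataFrame(columns=BED3)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")
    out = []
    for contig, grp in df.sort_values(["contig", "start", "end"]).groupby("contig"):
        cur_s = cur_e = None
        for s, e in grp[["start", "end"]].itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # >=1 bp overlap
                cur_e = max(cur_e, e)
            else:
                out.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((contig, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED3)


@dataclass
class PeakCollection:
    """One replicate's peak calls: named, normalized, half-open intervals."""

    sample_id: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        self.intervals = normalize_intervals(
            self.intervals[BED3] if len(self.intervals) else self.intervals
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class ConsensusSet:
    """Consensus regions with per-region support, plus input-excluded ones."""

    m: int
    n: int
    regions: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        reg = self.regions.assign(status="consensus")
        exc = self.excluded.assign(status="excluded") if len(self.excluded) else None
        out = pd.concat([reg, exc]) if exc is not None else reg
        return out.sort_values(["contig", "start"]).reset_index(drop=True)


def support_profile(collections: list[PeakCollection]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-base support as a step function, by boundary sweep.

    Returns {contig: (breaks, counts)} where counts[i] samples cover
    every base in [breaks[i], breaks[i+1]); counts has len(breaks)-1.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for col in collections:
        for contig, s, e in col.intervals.itertuples(index=False):
            events.setdefault(contig, []).append((s, 1))
            events[contig].append((e, -1))
    out = {}
    for contig, ev in events.items():
        arr = np.array(sorted(ev), dtype=np.int64)
        breaks, inverse = np.unique(arr[:, 0], return_inverse=True)
        deltas = np.zeros(len(breaks), dtype=np.int64)
        np.add.at(deltas, inverse, arr[:, 1])
        counts = np.cumsum(deltas)[:-1]
        out[contig] = (breaks, counts)
    return out


def _runs_at_least(breaks: np.ndarray, counts: np.ndarray, m: int):
    """Maximal runs where the step function is >= m, with min/max support."""
    hot = counts >= m
    runs = []
    i = 0
    while i < len(counts):
        if hot[i]:
            j = i
            while j + 1 < len(counts) and hot[j + 1]:
                j += 1
            seg = counts[i : j + 1]
            runs.append((int(breaks[i]), int(breaks[j + 1]),
                         int(seg.min()), int(seg.max())))
            i = j + 1
        i += 1
    return runs


def _overlaps_any(contig: str, start: int, end: int, track: pd.DataFrame) -> bool:
    if track.empty:
        return False
    sel = track[track["contig"] == contig]
    return bool(((sel["start"] < end) & (sel["end"] > start)).any())


def call_consensus(
    collections: list[PeakCollection],
    input_collection: PeakCollection | None = None,
    m: int = 14,
    merge_gap: int = 0,
) -> ConsensusSet:
    """Call consensus regions supported by >= m of the replicate samples
    at every base, excluding any candidate overlapping an input-control
    interval by >= 1 bp.

    ``merge_gap`` (default 0: never merge) joins consensus runs
    separated by at most that many bases before the input exclusion.
    """
    if not collections:
        raise ValueError("need at least one peak collection")
    if m < 1 or m > len(collections):
        raise ValueError(f"m must lie in [1, {len(collections)}]")
    profile = support_profile(collections)
    rows = []
    for contig, (breaks, counts) in profile.items():
        rows += [(contig, *run) for run in _runs_at_least(breaks, counts, m)]
    cand = pd.DataFrame(rows, columns=["contig", "start", "end",
                                       "support_min", "support_max"])
    if merge_gap > 0 and len(cand) > 1:
        merged = []
        for contig, grp in cand.sort_values(["contig", "start"]).groupby("contig"):
            cur = None
            for row in grp.itertuples(index=False):
                if cur is not None and row.start - cur[2] <= merge_gap:
                    cur = (contig, cur[1], row.end,
                           min(cur[3], row.support_min), max(cur[4], row.support_max))
                else:
                    if cur is not None:
                        merged.append(cur)
                    cur = (contig, row.start, row.end, row.support_min, row.support_max)
            merged.append(cur)
        cand = pd.DataFrame(merged, columns=cand.columns)

    input_track = (input_collection.intervals if input_collection is not None
                   else pd.DataFrame(columns=BED3))
    if len(cand):
        excl_mask = cand.apply(
            lambda r: _overlaps_any(r["contig"], r["start"], r["end"], input_track),
            axis=1,
        ).to_numpy(dtype=bool)
    else:
        excl_mask = np.zeros(0, dtype=bool)
    regions = cand[~excl_mask].reset_index(drop=True)
    excluded = cand[excl_mask].reset_index(drop=True)
    return ConsensusSet(m=m, n=len(collections), regions=regions, excluded=excluded)


def annotate_genes(consensus: ConsensusSet, gene_regions: pd.DataFrame) -> pd.DataFrame:
    """Per-gene consensus-peak presence (>=1 bp intersection with the
    supplied gene/promoter interval); excluded regions do not count."""
    rows = []
    for g in gene_regions.itertuples(index=False):
        has = _overlaps_any(g.contig, g.start, g.end, consensus.regions)
        rows.append({"gene": g.name, "has_consensus_peak": has})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path, names: bool = False) -> pd.DataFrame:
    """Read BED3 (or BED4 with ``names=True``: contig,start,end,name)."""
    cols = BED3 + (["name"] if names else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(len(cols)), names=cols)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
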