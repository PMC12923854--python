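"""Imputation target regions around the markers.

Reference-panel imputation needs a dense flanking-marker context, so each
marker position is slopped by 2.5 Mb in both directions, overlapping (or
book-ended) intervals are merged, and any merged window still shorter than
5 Mb — markers near telomeres or centromeres get clipped — is extended in
the opposite direction until it reaches the minimum or exhausts the
chromosome.  Coordinates are 1-based internally (marker positions) and
0-based half-open externally (BED), with the conversion at this module's
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import ChromLengths, normalize_chrom

__all__ = ["WindowSet", "WindowError", "build_windows", "write_bed", "read_bed"]

DEFAULT_SLOP = 2_500_000
DEFAULT_MIN_LEN = 5_000_000


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSet:
    """Sorted, disjoint (chrom, start, end) intervals, 0-based half-open."""

    intervals: tuple
    slop: int = DEFAULT_SLOP
    min_len: int = DEFAULT_MIN_LEN

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_span(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def containing(self, chrom: str, pos: int):
        """Windows containing a 1-based position (empty/one entry when disjoint)."""
        chrom = normalize_chrom(chrom)
        return [
            (c, s, e) for c, s, e in self.intervals
            if c == chrom and s <= pos - 1 < e
        ]


def _merge(intervals):
    """Union of intervals on one chromosome; book-ended intervals merge too."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return merged


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def build_windows(markers, lengths: ChromLengths, slop: int = DEFAULT_SLOP,
                  min_len: int = DEFAULT_MIN_LEN) -> WindowSet:
    """Slop each marker, merge, then enforce the minimum window length.

    Sub-minimum windows extend away from the clipped chromosome end, or
    symmetrically when no end was hit; a chromosome shorter than *min_len*
    yields the whole chromosome.  Extension can create new overlaps, so
    merge + extend iterates to a fixed point.
    """
    by_chrom = {}
    for m in markers:
        if m.chrom not in lengths:
            raise WindowError(
                f"marker {m.rsid}: chromosome {m.chrom!r} missing from length table"
            )
        length = lengths[m.chrom]
        start = max(0, m.pos - 1 - slop)
        end = min(length, m.pos + slop)
        by_chrom.setdefault(m.chrom, []).append((start, end))

    out = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        length = lengths[chrom]
        intervals = [tuple(iv) for iv in _merge(by_chrom[chrom])]
        target = min(min_len, length)
        while any(e - s < target for s, e in intervals):
            extended = []
            for start, end in intervals:
                deficit = min_len - (end - start)
                if deficit > 0:
                    if length <= min_len:
                        start, end = 0, length
                    elif start == 0:
                        end = min(length, min_len)
                    elif end == length:
                        start = max(0, length - min_len)
                    else:
                        # unclipped: split the deficit symmetrically, then push
                        # any clipped remainder to the opposite side
                        start2 = start - deficit // 2
                        end2 = end + (deficit - deficit // 2)
                        if start2 < 0:
                            end2 += -start2
                            start2 = 0
                        if end2 > length:
                            start2 -= end2 - length
                            end2 = length
                        start, end = max(0, start2), min(length, end2)
                extended.append((start, end))
            intervals = [tuple(iv) for iv in _merge(extended)]
        out.extend((chrom, int(s), int(e)) for s, e in intervals)

    ws = WindowSet(tuple(out), slop=slop, min_len=min_len)
    _validate(ws, markers, lengths)
    return ws


def _validate(ws: WindowSet, markers, lengths) -> None:
    seen = {}
    for chrom, start, end in ws:
        if end <= start:
            raise WindowError(f"empty window {chrom}:{start}-{end}")
        if end - start < ws.min_len and end - start < lengths[chrom]:
            raise WindowError(f"window {chrom}:{start}-{end} below minimum length")
        seen.setdefault(chrom, []).append((start, end))
    for chrom, ivs in seen.items():
        ordered = sorted(ivs)
        if ordered != ivs:
            raise WindowError(f"windows on {chrom} not sorted")
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise WindowError(f"overlapping windows on {chrom}")
    for m in markers:
        hits = ws.containing(m.chrom, m.pos)
        if len(hits) != 1:
            raise WindowError(
                f"marker {m.rsid} at {m.chrom}:{m.pos} covered by {len(hits)} windows"
            )


def write_bed(ws: WindowSet, path) -> None:
    """Standard 3-column BED, sorted, no header; empty set -> empty file."""
    with open(path, "w") as fh:
        for chrom, start, end in ws:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path, slop: int = DEFAULT_SLOP, min_len: int = DEFAULT_MIN_LEN) -> WindowSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": int, "end": int})
    except pd.errors.EmptyDataError:
        return WindowSet((), slop=slop, min_len=min_len)
    intervals = tuple(
        (normalize_chrom(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()
    )
    return WindowSet(intervals, slop=slop, min_len=min_len)
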