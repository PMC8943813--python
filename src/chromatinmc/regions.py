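"""Nucleosome position sets, occupancy tracks and repeat-length statistics.

Nucleosome positions are non-overlapping 147-bp footprints (the canonical
core-particle length) on a genomic interval, each carrying an occupancy
score.  Coordinates follow the BED convention: 0-based, half-open.  The
module reads/writes BED-like position files and bedGraph-like occupancy
tracks, computes linker lengths and sliding-window nucleosome repeat
lengths (NRL), ranks nucleosomes by occupancy signal, and produces
"nucleosome removal" variants in which the lowest-occupancy nucleosomes
are replaced by naked DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CORE_FOOTPRINT_BP = 147

__all__ = [
    "CORE_FOOTPRINT_BP",
    "GenomicInterval",
    "NucleosomeSet",
    "OccupancyTrack",
    "read_positions",
    "write_positions",
    "read_occupancy",
    "write_occupancy",
    "linker_lengths",
    "nrl_sliding_window",
    "rank_by_occupancy",
    "remove_lowest",
]


class PositionsError(ValueError):
    """Invalid nucleosome position input (overlap, bounds, parse)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class NucleosomeSet:
    """Ordered non-overlapping nucleosome footprints with occupancy scores.

    ``starts[i]`` is the first bp of footprint *i* (the "dyad_start"
    convention: footprint start, since the underlying positioning data do
    not fix a dyad convention); footprints span
    ``[starts[i], starts[i] + footprints[i])``.
    """

    interval: GenomicInterval
    starts: np.ndarray
    footprints: np.ndarray = None  # type: ignore[assignment]
    scores: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.footprints is None:
            self.footprints = np.full(self.starts.size, CORE_FOOTPRINT_BP, np.int64)
        self.footprints = np.asarray(self.footprints, dtype=np.int64)
        if self.scores is None:
            self.scores = np.ones(self.starts.size, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.footprints

    def validate(self) -> None:
        s, e = self.starts, self.ends
        if s.size != self.footprints.size or s.size != self.scores.size:
            raise PositionsError("starts/footprints/scores length mismatch")
        if np.any(self.footprints < 1):
            raise PositionsError("footprint must be >= 1 bp")
        if np.any(self.scores < 0):
            raise PositionsError("occupancy scores must be >= 0")
        if s.size == 0:
            return
        if np.any(np.diff(s) < 0):
            raise PositionsError("nucleosome starts must be sorted")
        if s[0] < self.interval.start or e[-1] > self.interval.end:
            raise PositionsError(
                f"footprints extend outside interval {self.interval}"
            )
        overlap = np.nonzero(s[1:] < e[:-1])[0]
        if overlap.size:
            i = int(overlap[0])
            raise PositionsError(
                "overlapping nucleosomes: "
                f"[{s[i]}, {e[i]}) and [{s[i + 1]}, {e[i + 1]})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.interval.chrom,
                "start": self.starts,
                "end": self.ends,
                "name": [f"nuc_{i}" for i in range(len(self))],
                "score": self.scores,
            }
        )


@dataclass
class OccupancyTrack:
    """Per-bp occupancy signal (MNase-like) over a genomic interval."""

    interval: GenomicInterval
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.interval.length:
            raise ValueError("track length must equal interval length")
        if np.any(self.values < 0):
            raise ValueError("occupancy values must be >= 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_positions(path, interval: GenomicInterval | None = None) -> NucleosomeSet:
    """Read a BED-like nucleosome position file into a :class:`NucleosomeSet`.

    Columns: chrom, start, end, [name, [score]].  Records are sorted by
    start; overlapping records are rejected.  If *interval* is omitted it is
    taken as the span of the records.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise PositionsError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                score = float(parts[4]) if len(parts) >= 5 else 1.0
            except ValueError as exc:
                raise PositionsError(f"{path}:{lineno}: {exc}") from exc
            rows.append((chrom, start, end, score))
    if not rows:
        raise PositionsError(f"{path}: no records")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise PositionsError(f"{path}: multiple chromosomes {sorted(chroms)}")
    rows.sort(key=lambda r: r[1])
    starts = np.array([r[1] for r in rows], np.int64)
    ends = np.array([r[2] for r in rows], np.int64)
    scores = np.array([r[3] for r in rows], float)
    if interval is None:
        interval = GenomicInterval(rows[0][0], int(starts[0]), int(ends[-1]))
    return NucleosomeSet(interval, starts, ends - starts, scores)


def write_positions(ns: NucleosomeSet, path) -> None:
    """Write a NucleosomeSet as 5-column BED (chrom start end name score)."""
    ns.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_occupancy(path, interval: GenomicInterval | None = None) -> OccupancyTrack:
    """Read a 4-column bedGraph-like file (chrom start end value) into a track."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if df.empty:
        raise ValueError(f"{path}: no records")
    if interval is None:
        interval = GenomicInterval(
            str(df.chrom.iloc[0]), int(df.start.min()), int(df.end.max())
        )
    values = np.zeros(interval.length)
    for _, row in df.iterrows():
        a = max(int(row.start), interval.start) - interval.start
        b = min(int(row.end), interval.end) - interval.start
        if b > a:
            values[a:b] = row.value
    return OccupancyTrack(interval, values)


def write_occupancy(track: OccupancyTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal value."""
    v = track.values
    change = np.nonzero(np.diff(v))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [v.size]))
    off = track.interval.start
    with open(path, "w") as fh:
        for a, b in zip(starts, ends):
            fh.write(f"{track.interval.chrom}\t{a + off}\t{b + off}\t{v[a]:g}\n")


# ---------------------------------------------------------------------------
# Linker / NRL statistics
# ---------------------------------------------------------------------------

def linker_lengths(ns: NucleosomeSet) -> np.ndarray:
    """Linker DNA lengths (bp) between successive footprints; N−1 values."""
    if len(ns) < 2:
        return np.zeros(0, dtype=np.int64)
    return ns.starts[1:] - ns.ends[:-1]


def nrl_sliding_window(
    ns: NucleosomeSet,
    window: int = 30_000,
    step: int | None = None,
    max_nrl: int = 300,
    min_nucleosomes: int = 3,
) -> pd.DataFrame:
    """Sliding-window mean nucleosome repeat length.

    NRL is the start-to-start distance of successive nucleosomes.  Within
    each window, individual NRL values above *max_nrl* bp are discarded and
    windows containing fewer than *min_nucleosomes* nucleosomes emit no
    value.  Returns a DataFrame with columns ``midpoint`` and ``mean_nrl``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if step is None:
        step = window // 2
    out_mid, out_nrl = [], []
    if len(ns) > 0:
        starts = ns.starts
        w0 = ns.interval.start
        while w0 < ns.interval.end:
            w1 = w0 + window
            sel = (starts >= w0) & (starts < w1)
            if int(sel.sum()) >= min_nucleosomes:
                nrl = np.diff(starts[sel])
                nrl = nrl[nrl <= max_nrl]
                if nrl.size:
                    out_mid.append(w0 + window // 2)
                    out_nrl.append(float(nrl.mean()))
            w0 += step
    return pd.DataFrame({"midpoint": out_mid, "mean_nrl": out_nrl})


# ---------------------------------------------------------------------------
# Occupancy ranking and nucleosome removal
# ---------------------------------------------------------------------------

def rank_by_occupancy(ns: NucleosomeSet, track: OccupancyTrack | None = None) -> np.ndarray:
    """Indices of nucleosomes in ascending occupancy-signal order.

    The signal is the mean per-bp track value over the footprint; with no
    track the stored occupancy scores are used.  Ties are broken by
    ascending genomic position (stable sort), so the result is a
    deterministic permutation of ``range(len(ns))``.
    """
    if track is not None:
        if (
            track.interval.chrom != ns.interval.chrom
            or (len(ns) and ns.starts[0] < track.interval.start)
            or (len(ns) and ns.ends[-1] > track.interval.end)
        ):
            raise ValueError("track does not cover all footprints")
        off = track.interval.start
        signal = np.array(
            [track.values[s - off : e - off].mean() for s, e in zip(ns.starts, ns.ends)]
        )
    else:
        signal = ns.scores
    return np.argsort(signal, kind="stable")


def remove_lowest(
    ns: NucleosomeSet,
    k: int,
    track: OccupancyTrack | None = None,
    ranking: np.ndarray | None = None,
) -> NucleosomeSet:
    """Replace the *k* lowest-occupancy nucleosomes by naked DNA.

    The removed footprints' wrapped DNA becomes linker (adjacent linkers
    merge); the genomic interval is unchanged, so total DNA length is
    conserved.
    """
    n = len(ns)
    if not 0 <= k < max(n, 1):
        raise ValueError(f"k must satisfy 0 <= k < {n}, got {k}")
    if k == 0:
        return replace(
            ns,
            starts=ns.starts.copy(),
            footprints=ns.footprints.copy(),
            scores=ns.scores.copy(),
        )
    if ranking is None:
        ranking = rank_by_occupancy(ns, track)
    keep = np.setdiff1d(np.arange(n), ranking[:k])
    return NucleosomeSet(
        ns.interval, ns.starts[keep], ns.footprints[keep], ns.scores[keep]
    )
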