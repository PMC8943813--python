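"""Marker-pair distance distributions and mixture deconvolution.

Distances between two genomic markers (FISH probe-set midpoints) are
measured either from simulated chain configurations or from measured
single-cell tables (one distance per cell, nm).  Distances above the
maximum extension of a beads-on-a-string fiber — genomic length in bp
times 0.34 nm/bp divided by 7 — are physically implausible and cut off.
Measured histograms are deconvolved into non-negative, sum-to-one
mixtures of simulated component histograms by constrained least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .chain import NM_PER_BP, ChainTopology, Configuration

__all__ = [
    "MarkerPair",
    "DistanceDataset",
    "Histogram",
    "MixtureFit",
    "marker_distance",
    "max_extension",
    "apply_cutoff",
    "project_omit_z",
    "random_projection_2d",
    "histogram",
    "fit_mixture",
    "rmse_hist",
    "summary_stats",
    "rank_sum_compare",
    "read_distance_table",
    "write_distance_table",
]

BEADS_ON_A_STRING_DIVISOR = 7.0


@dataclass(frozen=True)
class MarkerPair:
    """Two probe-set midpoints (bp) bounding a genomic interval of interest."""

    anchor_a: int
    anchor_b: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.anchor_a < self.anchor_b:
            raise ValueError("anchor_a must be < anchor_b")

    @property
    def span(self) -> int:
        return self.anchor_b - self.anchor_a


@dataclass
class DistanceDataset:
    """Single-observation marker distances in nm."""

    distances: np.ndarray
    dimensionality: str = "3D"      # "2D" | "3D"
    source: str = "simulated"       # simulated | measured | synthetic
    span_bp: int | None = None
    labels: np.ndarray | None = None  # optional ground-truth component ids

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        if self.dimensionality not in ("2D", "3D"):
            raise ValueError("dimensionality must be '2D' or '3D'")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass
class Histogram:
    """Density-normalized histogram with its binning carried structurally."""

    edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.density = np.asarray(self.density, float)
        if self.edges.size != self.density.size + 1:
            raise ValueError("edges must have len(density) + 1 entries")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def integral(self) -> float:
        return float(np.sum(self.density * self.widths))

    def same_binning(self, other: "Histogram") -> bool:
        return self.edges.size == other.edges.size and bool(
            np.allclose(self.edges, other.edges)
        )


@dataclass
class MixtureFit:
    """Non-negative sum-to-one component weights and fit quality."""

    weights: np.ndarray
    rmse: float
    edges: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def marker_distance(
    config: Configuration, topology: ChainTopology, pair: MarkerPair
) -> float:
    """Euclidean 3D distance (nm) between the chain points of the two anchors.

    Each anchor maps to the nearest segment boundary of the genomic-anchor
    track carried by the topology.
    """
    ja = topology.joint_index_for_bp(pair.anchor_a)
    jb = topology.joint_index_for_bp(pair.anchor_b)
    return float(np.linalg.norm(config.pos[jb] - config.pos[ja]))


def max_extension(span_bp: float) -> float:
    """Maximum length (nm) of a beads-on-a-string fiber of *span_bp* bases.

    genomic length [bp] * 0.34 nm / 7; e.g. 5 kb -> ~243 nm.
    """
    if span_bp <= 0:
        raise ValueError("genomic span must be > 0 bp")
    return span_bp * NM_PER_BP / BEADS_ON_A_STRING_DIVISOR


def apply_cutoff(
    ds: DistanceDataset, threshold: float | None = None
) -> tuple[DistanceDataset, int]:
    """Remove distances above the cutoff; returns (filtered, n_excluded).

    The default threshold is the beads-on-a-string maximum extension of
    the dataset's genomic span.
    """
    if threshold is None:
        if ds.span_bp is None:
            raise ValueError("no threshold given and dataset has no genomic span")
        threshold = max_extension(ds.span_bp)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    keep = ds.distances <= threshold
    out = DistanceDataset(
        ds.distances[keep], ds.dimensionality, ds.source, ds.span_bp,
        None if ds.labels is None else np.asarray(ds.labels)[keep],
    )
    return out, int((~keep).sum())


def project_omit_z(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """2D pair distances from 3D coordinates by omitting the z coordinate.

    Arrays of shape (n, 3) ordered (z, y, x) or (x, y, z) — only the last
    two axes are used, so pass coordinates with z first (image convention).
    """
    a = np.atleast_2d(np.asarray(coords_a, float))
    b = np.atleast_2d(np.asarray(coords_b, float))
    return np.linalg.norm(a[:, 1:] - b[:, 1:], axis=1)


def random_projection_2d(ds: DistanceDataset, seed=None) -> DistanceDataset:
    """Isotropic random projection of 3D distances to 2D.

    Each 3D distance is multiplied by sin(theta) with theta drawn from the
    uniform-sphere polar density (cos(theta) uniform on [-1, 1]); use this
    to compare 3D simulated distances with 2D measured data.
    """
    if ds.dimensionality != "3D":
        raise ValueError("random projection applies to 3D datasets")
    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(-1.0, 1.0, size=len(ds))
    return DistanceDataset(
        ds.distances * np.sqrt(1.0 - cos_t**2), "2D",
        ds.source, ds.span_bp, ds.labels,
    )


# ---------------------------------------------------------------------------
# Histograms and mixture fitting
# ---------------------------------------------------------------------------

def histogram(
    ds: DistanceDataset,
    bin_width: float = 10.0,
    range_nm: tuple[float, float] | None = None,
    edges: np.ndarray | None = None,
) -> Histogram:
    """Density-normalized distance histogram.

    Either pass explicit *edges* (to reuse a binning structurally) or a
    bin width plus optional range; the default range is [0, the dataset's
    beads-on-a-string maximum extension] (or the data maximum).
    """
    if edges is None:
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if range_nm is None:
            hi = (
                max_extension(ds.span_bp)
                if ds.span_bp is not None
                else (float(ds.distances.max()) if len(ds) else bin_width)
            )
            range_nm = (0.0, hi)
        lo, hi = range_nm
        n_bins = max(int(math.ceil((hi - lo) / bin_width)), 1)
        edges = lo + bin_width * np.arange(n_bins + 1)
    edges = np.asarray(edges, float)
    dens, _ = np.histogram(ds.distances, bins=edges, density=True)
    return Histogram(edges, dens)


def _check_binning(hists: list[Histogram]) -> None:
    for h in hists[1:]:
        if not hists[0].same_binning(h):
            raise ValueError("histograms do not share a common binning")


def rmse_hist(hist_a: Histogram, hist_b: Histogram) -> float:
    """Root-mean-square difference of the bin values of two histograms."""
    _check_binning([hist_a, hist_b])
    d = hist_a.density - hist_b.density
    return float(np.sqrt(np.mean(d * d)))


def fit_mixture(
    target: Histogram, components: list[Histogram], sum_weight: float = 1e6
) -> MixtureFit:
    """Least-squares mixture weights: min ||target - sum_k w_k comp_k||^2
    subject to w >= 0 and sum w = 1.

    Solved as a non-negative least squares problem (Lawson-Hanson) with
    the equality constraint enforced through a heavily weighted extra row;
    the result is renormalized, making the sum constraint exact.
    """
    if not components:
        raise ValueError("need at least one component histogram")
    _check_binning([target, *components])
    A = np.stack([c.density for c in components], axis=1)
    if np.any(np.all(A == 0, axis=0)):
        raise ValueError("degenerate all-zero component histogram")
    scale = max(float(np.abs(target.density).max()), 1e-12)
    A_aug = np.vstack([A / scale, np.full((1, A.shape[1]), sum_weight)])
    b_aug = np.concatenate([target.density / scale, [sum_weight]])
    w, _ = nnls(A_aug, b_aug)
    total = w.sum()
    if total <= 0:
        raise ValueError("mixture fit degenerate: all weights zero")
    w = w / total
    mix = Histogram(target.edges, A @ w)
    return MixtureFit(w, rmse_hist(target, mix), edges=target.edges)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summary_stats(ds: DistanceDataset) -> dict:
    """Median, mean, sd (ddof=1) and n, all in nm."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    d = ds.distances
    return {
        "median": float(np.median(d)),
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        "n": int(d.size),
    }


def rank_sum_compare(ds_a: DistanceDataset, ds_b: DistanceDataset) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Normal approximation with midrank tie correction; returns
    (statistic, p-value).
    """
    if len(ds_a) == 0 or len(ds_b) == 0:
        raise ValueError("both datasets must be non-empty")
    res = stats.mannwhitneyu(
        ds_a.distances, ds_b.distances, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_distance_table(path) -> DistanceDataset:
    """Read a TSV of single-cell distances.

    Columns: cell_id, distance_nm, and optionally dimensionality and
    pair_label; extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    if "distance_nm" not in df.columns:
        raise ValueError(f"{path}: missing required column 'distance_nm'")
    dim = "3D"
    if "dimensionality" in df.columns and len(df):
        dim = str(df["dimensionality"].iloc[0])
    return DistanceDataset(df["distance_nm"].to_numpy(float), dim, source="measured")


def write_distance_table(ds: DistanceDataset, path, pair_label: str = "") -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(len(ds)),
            "distance_nm": ds.distances,
            "dimensionality": ds.dimensionality,
            "pair_label": pair_label,
        }
    ).to_csv(path, sep="\t", index=False)
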