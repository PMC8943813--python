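"""Synthetic inputs for every pipeline stage — no downloads required.

Generators emulate the field's data types with stated, realistic
statistics and always return their ground truth alongside the data:

* nucleosome position sets with controlled repeat-length statistics
  (truncated-normal spacings, mean NRL ~183 bp as in bulk chromatin);
* MNase-like per-bp occupancy tracks (smoothed, jittered footprint
  coverage with Poisson sampling noise);
* right-tailed single-cell distance datasets (lognormal mixtures with
  ~7.5 nm pairwise localization noise, emulating two-color STED FISH);
* two-channel 3D image stacks of Gaussian-PSF spot pairs with Poisson
  photon noise.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .distances import DistanceDataset
from .regions import CORE_FOOTPRINT_BP, GenomicInterval, NucleosomeSet, OccupancyTrack
from .spots import ImageStack

__all__ = [
    "SyntheticSpec",
    "gen_positions",
    "gen_occupancy_track",
    "gen_distance_dataset",
    "gen_image_stack",
]


@dataclass
class SyntheticSpec:
    """Stated world for the synthetic generators.

    Defaults: 30-kb region at mean NRL 183 bp (sd 25 bp), MNase-like
    fuzziness of 20 bp, a two-component lognormal distance mixture
    spanning the <50-250 nm range typical of 5-kb two-color FISH
    measurements, 7.5 nm pairwise localization noise, and a 3D-STED-like
    PSF (sigma 100/40/40 nm) sampled at 50/30/30-nm voxels — the regime
    in which two-spot distances reach ~7.5 nm pairwise 3D precision.
    """

    region_length_bp: int = 30_000
    chrom: str = "chrSyn"
    nrl_mean_bp: float = 183.0
    nrl_sd_bp: float = 25.0
    occupancy_fuzziness_bp: float = 20.0
    occupancy_depth: float = 50.0
    # (median nm, lognormal sigma, weight) per component; right-tailed
    distance_components: tuple = ((60.0, 0.45, 0.6), (140.0, 0.30, 0.4))
    localization_noise_nm: float = 7.5
    psf_sigma_nm: tuple = (100.0, 40.0, 40.0)   # 3D-STED-like PSF widths
    photons: float = 500.0
    background: float = 1.0
    voxel_nm: tuple = (50.0, 30.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([c[2] for c in self.distance_components], float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be >= 0 and sum to 1")
        if self.nrl_mean_bp <= CORE_FOOTPRINT_BP:
            raise ValueError("NRL mean must exceed the 147-bp footprint")


def gen_positions(
    spec: SyntheticSpec | None = None,
    seed=None,
    score_shape: float = 4.0,
    **overrides,
) -> NucleosomeSet:
    """Sequentially placed non-overlapping nucleosomes with NRL statistics.

    Spacings are drawn from a normal(NRL mean, NRL sd) truncated below at
    footprint + 1 bp; occupancy scores are Gamma distributed (shape
    *score_shape*, mean 1).  ``nrl_sd_bp=0`` gives perfectly periodic
    positions.
    """
    spec = _resolve(spec, seed, overrides)
    rng = np.random.default_rng(spec.seed)
    interval = GenomicInterval(spec.chrom, 0, spec.region_length_bp)
    min_spacing = CORE_FOOTPRINT_BP + 1
    if spec.region_length_bp < CORE_FOOTPRINT_BP:
        raise ValueError("region too short for a single nucleosome")
    starts = []
    pos = 0
    while pos + CORE_FOOTPRINT_BP <= spec.region_length_bp:
        starts.append(pos)
        if spec.nrl_sd_bp == 0:
            spacing = spec.nrl_mean_bp
        else:
            spacing = rng.normal(spec.nrl_mean_bp, spec.nrl_sd_bp)
        pos += int(round(max(spacing, min_spacing)))
    starts = np.array(starts, np.int64)
    scores = rng.gamma(score_shape, 1.0 / score_shape, size=starts.size)
    return NucleosomeSet(interval, starts, None, scores)


def gen_occupancy_track(
    ns: NucleosomeSet,
    fuzziness_bp: float = 20.0,
    depth: float = 50.0,
    seed=0,
    background: float = 0.02,
) -> OccupancyTrack:
    """MNase-like occupancy track from a nucleosome set.

    Each nucleosome contributes ``Poisson(depth * score / mean score)``
    fragment footprints whose centers are jittered by a normal of sd
    *fuzziness_bp*; the per-bp coverage is smoothed with a 10-bp Gaussian
    and carries a small uniform background.  Track maxima sit at
    footprint centers for zero fuzziness, and the mean track value over a
    footprint correlates with the generating score.
    """
    rng = np.random.default_rng(seed)
    L = ns.interval.length
    cov = np.zeros(L)
    if len(ns):
        mean_score = float(ns.scores.mean()) or 1.0
        half = CORE_FOOTPRINT_BP // 2
        for s, fp, sc in zip(ns.starts, ns.footprints, ns.scores):
            center = s - ns.interval.start + fp // 2
            n_frag = rng.poisson(depth * sc / mean_score)
            if fuzziness_bp > 0:
                centers = np.round(
                    center + rng.normal(0, fuzziness_bp, n_frag)
                ).astype(int)
            else:
                centers = np.full(n_frag, center)
            for c in centers:
                a, b = max(c - half, 0), min(c + half + 1, L)
                if b > a:
                    cov[a:b] += 1.0
    cov = ndimage.gaussian_filter1d(cov, 10.0)
    cov += background * max(depth, 1.0)
    return OccupancyTrack(ns.interval, cov)


def gen_distance_dataset(
    spec: SyntheticSpec | None = None,
    n: int = 1000,
    seed=None,
    **overrides,
) -> DistanceDataset:
    """Right-tailed single-cell distance sample from a lognormal mixture.

    True distances are drawn per component; isotropic 3D localization
    error is added to the pair separation vector with total RMS equal to
    the spec's pairwise localization noise.  Ground-truth component
    labels are kept on the dataset for recovery tests.
    """
    spec = _resolve(spec, seed, overrides)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    comps = spec.distance_components
    weights = np.array([c[2] for c in comps])
    labels = rng.choice(len(comps), size=n, p=weights)
    true = np.empty(n)
    for k, (median, sigma, _) in enumerate(comps):
        m = labels == k
        if sigma == 0:
            true[m] = median
        else:
            true[m] = rng.lognormal(np.log(median), sigma, size=int(m.sum()))
    noise = spec.localization_noise_nm
    if noise > 0:
        # separation vector along a random direction plus isotropic error
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        err = rng.normal(0.0, noise / np.sqrt(3.0), size=(n, 3))
        obs = np.linalg.norm(true[:, None] * u + err, axis=1)
    else:
        obs = true
    return DistanceDataset(
        obs, "3D", source="synthetic", span_bp=None, labels=labels
    )


def gen_image_stack(
    centers_nm,
    spec: SyntheticSpec | None = None,
    shape=(20, 48, 48),
    seed=None,
    channels=("ch1", "ch2"),
    **overrides,
) -> tuple[list[ImageStack], np.ndarray]:
    """Two-channel 3D stacks of Gaussian-PSF spots with Poisson noise.

    *centers_nm* is a sequence of (z, y, x) spot centers in nm, one per
    channel.  Each spot integrates to ``spec.photons`` photons on top of
    a constant ``spec.background`` (counts/voxel); ``photons=0`` yields a
    pure-background stack.  Returns the stacks and the ground-truth
    centers as an array.
    """
    spec = _resolve(spec, seed, overrides)
    rng = np.random.default_rng(spec.seed)
    voxel = np.asarray(spec.voxel_nm, float)
    sig_vox = np.asarray(spec.psf_sigma_nm, float) / voxel
    centers = np.atleast_2d(np.asarray(centers_nm, float))
    if centers.shape[0] != len(channels):
        raise ValueError("one center per channel required")
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    stacks = []
    for c, name in zip(centers, channels):
        cv = c / voxel
        if np.any(cv < 0) or np.any(cv > np.array(shape) - 1):
            raise ValueError(f"center {c} outside stack")
        if spec.photons > 0:
            g = np.exp(
                -0.5 * sum(((grids[d] - cv[d]) / sig_vox[d]) ** 2 for d in range(3))
            )
            g *= spec.photons / g.sum()
        else:
            g = np.zeros(shape)
        lam = g + spec.background
        stacks.append(
            ImageStack(rng.poisson(lam).astype(float), tuple(voxel), channel=name)
        )
    return stacks, centers


def _resolve(spec, seed, overrides) -> SyntheticSpec:
    if spec is None:
        spec = SyntheticSpec(**overrides)
    elif overrides:
        spec = SyntheticSpec(**{**spec.__dict__, **overrides})
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    return spec
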