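"""Pairwise r-squared and LD-decay summaries.

r^2 here is the composite (Rogers-Huff) form: the squared Pearson
correlation of alt-allele dosages over jointly called samples.  Genotypes
are unphased, so this phase-free surrogate replaces haplotype r^2; under
Hardy-Weinberg the two are monotonically related.  Decay is summarised by
pooling all intra-contig pairs up to a maximum separation into distance
bins and reporting the mean r^2 and pair count per bin, plus the distance
at which the mean first falls to half its maximum.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap

DEFAULT_MAX_DIST = 100_000
DEFAULT_BIN = 1_000


def genotype_r2(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """Composite LD r^2 between two sites from genotype dosages.

    Uses only jointly non-missing samples; returns NaN when fewer than two
    remain or either site is monomorphic among them.
    """
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_decay(
    G: GenotypeMatrix,
    pop: str,
    popmap: PopulationMap,
    max_dist: int = DEFAULT_MAX_DIST,
    bin_size: int = DEFAULT_BIN,
) -> pd.DataFrame:
    """Mean composite r^2 by inter-SNP distance bin for one population.

    All intra-contig site pairs separated by at most ``max_dist`` bp are
    pooled genome-wide into contiguous bins ``[0, bin), [bin, 2*bin), ...``.
    Pairs whose r^2 is undefined (monomorphic among jointly called
    samples) are skipped.  Returns a DataFrame with columns
    ``bin_lo, bin_hi, midpoint, mean_r2, n_pairs``.
    """
    idx = G.sample_index(popmap.samples(pop))
    calls = G.calls[idx, :].astype(float)
    called = calls != MISSING

    n_bins = math.ceil(max_dist / bin_size)
    sum_r2 = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=int)

    contigs = G.sites["contig"].to_numpy()
    pos = G.sites["pos"].to_numpy()
    boundaries = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(contigs)]))

    for s, e in zip(starts, ends):
        block_pos = pos[s:e]
        block = calls[:, s:e]
        block_called = called[:, s:e]
        for i in range(e - s):
            j_hi = np.searchsorted(block_pos, block_pos[i] + max_dist, side="right")
            if j_hi <= i + 1:
                continue
            js = np.arange(i + 1, j_hi)
            dist = block_pos[js] - block_pos[i]
            ok = block_called[:, i][:, None] & block_called[:, js]
            n = ok.sum(axis=0).astype(float)
            x = np.where(ok, block[:, i][:, None], 0.0)
            y = np.where(ok, block[:, js], 0.0)
            sx, sy = x.sum(axis=0), y.sum(axis=0)
            sxx, syy = (x * x).sum(axis=0), (y * y).sum(axis=0)
            sxy = (x * y).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                vx = sxx / n - (sx / n) ** 2
                vy = syy / n - (sy / n) ** 2
                cov = sxy / n - (sx / n) * (sy / n)
                r2 = cov * cov / (vx * vy)
            valid = (n >= 2) & (vx > 0) & (vy > 0) & np.isfinite(r2)
            if not valid.any():
                continue
            b = ((dist[valid] - 1) // bin_size).astype(int)
            np.add.at(sum_r2, b, r2[valid])
            np.add.at(n_pairs, b, 1)

    if n_pairs.sum() == 0:
        raise ValueError("no valid site pairs within max_dist")

    lo = np.arange(n_bins) * bin_size
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r2 = np.where(n_pairs > 0, sum_r2 / np.maximum(n_pairs, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": lo,
            "bin_hi": lo + bin_size,
            "midpoint": lo + bin_size / 2.0,
            "mean_r2": mean_r2,
            "n_pairs": n_pairs,
        }
    )


def half_decay_distance(bins: pd.DataFrame) -> float:
    """Distance (bp) at which mean r^2 first falls to half its maximum.

    Linear interpolation between the flanking bin midpoints; ``inf`` when
    half-maximum is never reached within the binned range.
    """
    sub = bins.dropna(subset=["mean_r2"])
    if len(sub) < 2:
        raise ValueError("need at least two populated bins")
    mid = sub["midpoint"].to_numpy()
    r2 = sub["mean_r2"].to_numpy()
    half = r2.max() / 2.0
    below = np.flatnonzero(r2 <= half)
    if below.size == 0:
        return float("inf")
    k = below[0]
    if k == 0:
        return float(mid[0])
    x0, x1 = mid[k - 1], mid[k]
    y0, y1 = r2[k - 1], r2[k]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
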