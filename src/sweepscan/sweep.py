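"""Sliding-window selective-sweep scan and genome-wide differentiation.

The scan contrasts a focal population against a high-diversity reference
population in overlapping windows (default 100 kb window, 10 kb step):

* window F_ST — Weir & Cockerham (1984) variance-components estimator for
  the two-population diploid case, combined across the sites of a window
  by summing numerator (a) and denominator (a + b + c) separately
  ("ratio of sums");
* window pi — per-bp nucleotide diversity from the unbiased pairwise-
  difference form, summed over usable sites and divided by window length;
* pi ln-ratio — ln(pi_reference / pi_focal), positive when the focal
  population has lost diversity (the sweep signature);
* selection — a window is selected when BOTH statistics lie at or above
  their empirical 95%-quantile over unmasked windows (top-5% intersection
  rule); selected windows are merged into candidate regions and
  intersected with gene models.

A Hudson-type estimator is available as an independent cross-check
(``estimator="hudson"``); it is never used to compute the reported scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PopulationMap
from .popstats import SiteFreq, site_frequencies

log = logging.getLogger("sweepscan")

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000
DEFAULT_QUANTILE = 0.95
DEFAULT_MIN_SNPS = 10


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def enumerate_windows(
    contig_lengths: dict[str, int],
    size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    drop_tails: bool = False,
) -> pd.DataFrame:
    """Enumerate sliding windows over contigs.

    Windows start at 1, 1+step, 1+2*step, ... while the start lies within
    the contig; the final windows are truncated at the contig end (or
    dropped entirely with ``drop_tails=True``).  Coordinates are 1-based
    inclusive.
    """
    if not contig_lengths:
        raise ValueError("empty contig set")
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    rows = []
    for contig, length in contig_lengths.items():
        start = 1
        while start <= length:
            end = min(start + size - 1, length)
            if not (drop_tails and end - start + 1 < size):
                rows.append((contig, start, end))
            start += step
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


# ---------------------------------------------------------------------------
# Per-site estimator kernels
# ---------------------------------------------------------------------------


def site_fst_components(
    freqA: SiteFreq, freqB: SiteFreq
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components (a, b, c) per site, two diploid pops.

    ``a`` is the among-population component, ``b`` among-individual within
    population, ``c`` within-individual; the F_ST estimate for any set of
    sites is sum(a) / sum(a + b + c).  Sites unusable in either population
    (fewer than 2 called diploids) yield NaN components.
    """
    n1 = freqA.n_called.astype(float)
    n2 = freqB.n_called.astype(float)
    usable = freqA.usable & freqB.usable
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = freqA.p_alt
        p2 = freqB.p_alt
        h1 = np.where(n1 > 0, freqA.n_het / n1, np.nan)
        h2 = np.where(n2 > 0, freqB.n_het / n2, np.nan)

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    nan = np.full_like(nbar, np.nan)
    return (
        np.where(usable, a, nan),
        np.where(usable, b, nan),
        np.where(usable, c, nan),
    )


def site_hudson_components(
    freqA: SiteFreq, freqB: SiteFreq
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson-type F_ST numerator/denominator per site (cross-check estimator).

    num = (p1-p2)^2 - p1(1-p1)/(nh1-1) - p2(1-p2)/(nh2-1),
    den = p1(1-p2) + p2(1-p1), with nh the called haplotype counts;
    windowed value is the ratio of sums.
    """
    usable = freqA.usable & freqB.usable
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = freqA.p_alt, freqB.p_alt
        nh1 = freqA.n_haplotypes.astype(float)
        nh2 = freqB.n_haplotypes.astype(float)
        num = (
            (p1 - p2) ** 2
            - p1 * (1.0 - p1) / (nh1 - 1.0)
            - p2 * (1.0 - p2) / (nh2 - 1.0)
        )
        den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    nan = np.full_like(num, np.nan)
    return np.where(usable, num, nan), np.where(usable, den, nan)


def site_pi(freq: SiteFreq) -> np.ndarray:
    """Unbiased per-site nucleotide diversity within one population.

    Computed from integer allele counts as the exact mean pairwise
    difference over the 2n called haplotypes: k(2n-k) / C(2n, 2), which
    equals (2n/(2n-1)) * 2p(1-p).  NaN where the site is unusable.
    """
    nh = freq.n_haplotypes.astype(float)
    k = freq.alt_count.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pairs = nh * (nh - 1.0) / 2.0
        pi = k * (nh - k) / pairs
    return np.where(freq.usable, pi, np.nan)


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------


def _window_site_ranges(
    sites: pd.DataFrame, windows: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open site-index range [lo, hi) covered by each window."""
    lo = np.zeros(len(windows), dtype=int)
    hi = np.zeros(len(windows), dtype=int)
    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy()
    # site table is sorted by (contig, pos); locate each contig block once
    offsets: dict[str, tuple[int, int]] = {}
    if len(sites):
        change = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(sites)]))
        offsets = {contigs[s]: (s, e) for s, e in zip(starts, ends)}
    for w_contig, grp in windows.groupby("contig", sort=False):
        if w_contig not in offsets:
            continue
        s, e = offsets[w_contig]
        block = pos[s:e]
        idx = grp.index.to_numpy()
        lo[idx] = s + np.searchsorted(block, grp["start"].to_numpy(), side="left")
        hi[idx] = s + np.searchsorted(block, grp["end"].to_numpy(), side="right")
    return lo, hi


def _window_sums(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sum of ``values`` (NaN treated as 0) over each [lo, hi) site range."""
    filled = np.nan_to_num(values, nan=0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    return csum[hi] - csum[lo]


def _window_counts(usable: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    csum = np.concatenate(([0], np.cumsum(usable.astype(int))))
    return csum[hi] - csum[lo]


def windowed_fst(
    G: GenotypeMatrix,
    popA: str,
    popB: str,
    windows: pd.DataFrame,
    popmap: PopulationMap,
    min_snps: int = DEFAULT_MIN_SNPS,
    estimator: str = "wc",
) -> np.ndarray:
    """Window F_ST between two populations (ratio of sums); NaN where masked."""
    fA = site_frequencies(G, popA, popmap)
    fB = site_frequencies(G, popB, popmap)
    if estimator == "wc":
        a, b, c = site_fst_components(fA, fB)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = site_hudson_components(fA, fB)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    lo, hi = _window_site_ranges(G.sites, windows)
    usable = fA.usable & fB.usable
    n_snps = _window_counts(usable, lo, hi)
    num_w = _window_sums(num, lo, hi)
    den_w = _window_sums(den, lo, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = num_w / den_w
    fst[(n_snps < min_snps) | (den_w == 0)] = np.nan
    if np.all(np.isnan(fst)):
        log.warning("windowed_fst: all %d windows masked", len(windows))
    return fst


def windowed_pi(
    G: GenotypeMatrix,
    pop: str,
    windows: pd.DataFrame,
    popmap: PopulationMap,
    min_snps: int = 0,
) -> np.ndarray:
    """Per-bp nucleotide diversity per window for one population."""
    f = site_frequencies(G, pop, popmap)
    pi = site_pi(f)
    lo, hi = _window_site_ranges(G.sites, windows)
    length = (windows["end"] - windows["start"] + 1).to_numpy().astype(float)
    out = _window_sums(pi, lo, hi) / length
    if min_snps > 0:
        n = _window_counts(f.usable, lo, hi)
        out[n < min_snps] = np.nan
    return out


def pi_lnratio(pi_ref: np.ndarray, pi_focal: np.ndarray) -> np.ndarray:
    """ln(pi_reference / pi_focal); NaN where either pi is 0 or missing."""
    pi_ref = np.asarray(pi_ref, dtype=float)
    pi_focal = np.asarray(pi_focal, dtype=float)
    ok = (pi_ref > 0) & (pi_focal > 0)
    out = np.full(pi_ref.shape, np.nan)
    out[ok] = np.log(pi_ref[ok] / pi_focal[ok])
    return out


def select_sweep_windows(
    fst: np.ndarray,
    lnratio: np.ndarray,
    q: float = DEFAULT_QUANTILE,
) -> tuple[np.ndarray, float, float]:
    """Flag windows in the top (1-q) tail of BOTH statistics.

    Thresholds are empirical order-statistic quantiles (linear/type-7
    interpolation) over windows unmasked in both statistics; ties at a
    threshold are selected.  Returns (selected flags, fst threshold,
    ln-ratio threshold).
    """
    fst = np.asarray(fst, dtype=float)
    lnratio = np.asarray(lnratio, dtype=float)
    unmasked = ~np.isnan(fst) & ~np.isnan(lnratio)
    if unmasked.sum() < 20:
        raise ValueError(
            f"only {int(unmasked.sum())} unmasked windows; quantile unstable"
        )
    t_fst = float(np.quantile(fst[unmasked], q))
    t_lnr = float(np.quantile(lnratio[unmasked], q))
    selected = unmasked & (fst >= t_fst) & (lnratio >= t_lnr)
    return selected, t_fst, t_lnr


# ---------------------------------------------------------------------------
# Regions and genes
# ---------------------------------------------------------------------------


def merge_regions(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended selected windows into regions.

    ``windows`` needs columns ``contig, start, end`` (and is typically the
    selected subset of the scan table).  Output regions are disjoint,
    sorted, and carry the member window count.  Idempotent.
    """
    if len(windows) == 0:
        return pd.DataFrame(columns=["contig", "start", "end", "n_windows"])
    wins = windows.sort_values(["contig", "start"], kind="stable")
    rows = []
    cur = None  # [contig, start, end, n]
    for w in wins.itertuples(index=False):
        if cur is not None and w.contig == cur[0] and w.start <= cur[2] + 1:
            cur[2] = max(cur[2], w.end)
            cur[3] += 1
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [w.contig, int(w.start), int(w.end), 1]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_windows"])


def genes_in_regions(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> tuple[list[set[str]], set[str]]:
    """Gene IDs overlapping each region (>= 1 shared bp, 1-based inclusive).

    Returns the per-region gene sets (in region order) and their union.
    """
    per_region: list[set[str]] = []
    for reg in regions.itertuples(index=False):
        sub = genes[genes["contig"] == reg.contig]
        hit = sub[(sub["start"] <= reg.end) & (sub["end"] >= reg.start)]
        per_region.append(set(hit["gene_id"]))
    union: set[str] = set().union(*per_region) if per_region else set()
    return per_region, union


def shared_genes(
    gene_sets: dict[str, set[str]],
) -> tuple[set[str], dict[str, int]]:
    """All-way intersection and full Venn partition counts.

    The Venn keys are "&"-joined comparison names; each counts the genes
    belonging to exactly that subset of comparisons.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets")
    names = list(gene_sets)
    inter = set.intersection(*gene_sets.values())
    venn: dict[str, int] = {}
    universe = set().union(*gene_sets.values())
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            exactly = set(universe)
            for n in combo:
                exactly &= gene_sets[n]
            for n in names:
                if n not in combo:
                    exactly -= gene_sets[n]
            venn["&".join(combo)] = len(exactly)
    return inter, venn


# ---------------------------------------------------------------------------
# Genome-wide pairwise F_ST
# ---------------------------------------------------------------------------

HIGH_DIFFERENTIATION = 0.15  # conventional cutoff for "high" F_ST


@dataclass
class FstMatrix:
    """Genome-wide pairwise Weir-Cockerham F_ST between populations."""

    populations: list[str]
    values: pd.DataFrame  # symmetric, zero diagonal

    @property
    def mean_per_population(self) -> pd.Series:
        """Mean F_ST of each population against all others."""
        n = len(self.populations)
        return self.values.sum(axis=1) / (n - 1)

    @property
    def differentiation_class(self) -> pd.Series:
        """"high" where mean pairwise F_ST exceeds 0.15, else "low"."""
        return self.mean_per_population.map(
            lambda v: "high" if v > HIGH_DIFFERENTIATION else "low"
        )


def genomewide_fst(
    G: GenotypeMatrix,
    popA: str,
    popB: str,
    popmap: PopulationMap,
    estimator: str = "wc",
) -> float:
    """Single ratio-of-sums F_ST over all usable sites of the genome."""
    fA = site_frequencies(G, popA, popmap)
    fB = site_frequencies(G, popB, popmap)
    if estimator == "wc":
        a, b, c = site_fst_components(fA, fB)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = site_hudson_components(fA, fB)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    ok = ~np.isnan(den)
    if not ok.any():
        raise ValueError(f"no usable sites between {popA} and {popB}")
    return float(np.nansum(num[ok]) / np.nansum(den[ok]))


def pairwise_fst_matrix(
    G: GenotypeMatrix, popmap: PopulationMap, estimator: str = "wc"
) -> FstMatrix:
    """Genome-wide pairwise F_ST for every pair of populations."""
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = {p: site_frequencies(G, p, popmap) for p in pops}
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        if not freqs[pa].usable.any():
            raise ValueError(f"population {pa!r} has no usable sites")
        for pb in pops[i + 1 :]:
            val = genomewide_fst(G, pa, pb, popmap, estimator=estimator)
            mat.loc[pa, pb] = mat.loc[pb, pa] = val
    return FstMatrix(populations=pops, values=mat)


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------


@dataclass
class SweepScanResult:
    """Everything one reference-vs-focal scan produces."""

    windows: pd.DataFrame  # contig,start,end,n_snps,fst,pi_ref,pi_focal,pi_lnratio,selected
    regions: pd.DataFrame  # merged candidate regions
    region_genes: list[set[str]] = field(default_factory=list)
    gene_ids: set[str] = field(default_factory=set)
    fst_threshold: float = float("nan")
    lnratio_threshold: float = float("nan")


def sweep_scan(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    ref_pop: str,
    focal_pop: str,
    genes: pd.DataFrame | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    quantile: float = DEFAULT_QUANTILE,
    min_snps: int = DEFAULT_MIN_SNPS,
    drop_tails: bool = False,
    merge: bool = True,
    per_contig_quantile: bool = False,
    contig_lengths: dict[str, int] | None = None,
) -> SweepScanResult:
    """Run the full windowed F_ST + pi ln-ratio scan of focal vs reference.

    Windows are enumerated over the contigs of the genotype matrix (or an
    explicit ``contig_lengths`` map), both statistics are computed per
    window, the top-(1-quantile) intersection rule flags selected windows,
    flagged windows are merged into regions (unless ``merge=False``), and
    gene models are intersected with the regions when provided.
    """
    lengths = contig_lengths or G.contig_lengths
    wins = enumerate_windows(lengths, size=window, step=step, drop_tails=drop_tails)
    fst = windowed_fst(G, ref_pop, focal_pop, wins, popmap, min_snps=min_snps)
    pi_ref = windowed_pi(G, ref_pop, wins, popmap)
    pi_foc = windowed_pi(G, focal_pop, wins, popmap)
    lnr = pi_lnratio(pi_ref, pi_foc)

    if per_contig_quantile:
        selected = np.zeros(len(wins), dtype=bool)
        t_fst = t_lnr = float("nan")
        for contig in wins["contig"].unique():
            m = (wins["contig"] == contig).to_numpy()
            sel_c, t_fst, t_lnr = select_sweep_windows(fst[m], lnr[m], q=quantile)
            selected[m] = sel_c
    else:
        selected, t_fst, t_lnr = select_sweep_windows(fst, lnr, q=quantile)

    table = wins.copy()
    lo, hi = _window_site_ranges(G.sites, wins)
    fref = site_frequencies(G, ref_pop, popmap)
    ffoc = site_frequencies(G, focal_pop, popmap)
    table["n_snps"] = _window_counts(fref.usable & ffoc.usable, lo, hi)
    table["fst"] = fst
    table["pi_ref"] = pi_ref
    table["pi_focal"] = pi_foc
    table["pi_lnratio"] = lnr
    table["selected"] = selected

    sel = table[table["selected"]][["contig", "start", "end"]]
    if merge:
        regions = merge_regions(sel)
    else:
        regions = sel.assign(n_windows=1).reset_index(drop=True)

    result = SweepScanResult(
        windows=table,
        regions=regions,
        fst_threshold=t_fst,
        lnratio_threshold=t_lnr,
    )
    if genes is not None:
        result.region_genes, result.gene_ids = genes_in_regions(regions, genes)
    return result
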