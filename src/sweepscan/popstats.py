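"""Site filters and per-population diversity statistics.

The filter reproduces the two hard site filters applied to the global SNP
set before any per-population analysis: missing ratio strictly below 20%
and pooled minor-allele frequency strictly above 5% (both thresholds
strict, as printed; MAF is computed over all samples pooled).

Per-population diversity is summarised as observed heterozygosity (Ho),
expected heterozygosity (He = 2p(1-p)) and polymorphism information
content in the biallelic Botstein closed form
PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, each averaged (unweighted) over the
sites usable in that population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap

log = logging.getLogger("sweepscan")


@dataclass
class SiteFreq:
    """Per-site allele-frequency summaries within one population.

    ``p_alt`` is computed from non-missing calls only; sites with fewer
    than two called diploids are flagged unusable (their ``p_alt`` is NaN).
    """

    n_called: np.ndarray  # int, diploid individuals with a call
    p_alt: np.ndarray  # float in [0, 1], NaN where unusable
    n_het: np.ndarray  # int, heterozygote count
    usable: np.ndarray  # bool, n_called >= 2

    @property
    def n_haplotypes(self) -> np.ndarray:
        return 2 * self.n_called

    @property
    def alt_count(self) -> np.ndarray:
        """Integer alt-allele count among called haplotypes."""
        return self._alt_count

    def __post_init__(self) -> None:
        self._alt_count = np.rint(
            np.where(self.usable, self.p_alt, 0.0) * self.n_haplotypes
        ).astype(int)


def site_frequencies(
    G: GenotypeMatrix, pop: str, popmap: PopulationMap
) -> SiteFreq:
    """Allele-frequency summaries for one population at every site."""
    idx = G.sample_index(popmap.samples(pop))
    calls = G.calls[idx, :]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    usable = n_called >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    p_alt = np.where(usable, p_alt, np.nan)
    return SiteFreq(
        n_called=n_called.astype(int),
        p_alt=p_alt,
        n_het=n_het.astype(int),
        usable=usable,
    )


def filter_sites(
    G: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the missingness and pooled-MAF site filters.

    A site is kept iff its missing fraction over all samples is strictly
    below ``max_missing`` AND its pooled minor-allele frequency is strictly
    above ``min_maf``.  Returns the filtered matrix and removal counts per
    filter (a site failing both rules is counted under both).
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    calls = G.calls
    missing_frac = (calls == MISSING).mean(axis=0)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1.0 - p)

    pass_missing = missing_frac < max_missing
    pass_maf = maf > min_maf
    keep = pass_missing & pass_maf
    counts = {
        "removed_missing": int((~pass_missing).sum()),
        "removed_maf": int((~pass_maf).sum()),
        "kept": int(keep.sum()),
    }
    if counts["kept"] == 0:
        log.warning("filter_sites: all %d sites removed", G.n_sites)
    return G.take_sites(np.flatnonzero(keep)), counts


def he_site(p: np.ndarray) -> np.ndarray:
    """Expected heterozygosity 2p(1-p) under Hardy-Weinberg."""
    return 2.0 * p * (1.0 - p)


def pic_site(p: np.ndarray) -> np.ndarray:
    """Biallelic polymorphism information content (Botstein form)."""
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def diversity_report(G: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population mean Ho, He and PIC, plus an overall Mean row.

    Values are unweighted means over the sites usable (>= 2 called
    diploids) in each population; rows are sorted by PIC ascending so the
    most selection-eroded populations come first.
    """
    rows = []
    for pop in popmap.populations:
        f = site_frequencies(G, pop, popmap)
        if not f.usable.any():
            raise ValueError(f"population {pop!r} has no usable sites")
        u = f.usable
        ho = f.n_het[u] / f.n_called[u]
        p = f.p_alt[u]
        rows.append(
            {
                "population": pop,
                "n_sites": int(u.sum()),
                "Ho": float(ho.mean()),
                "He": float(he_site(p).mean()),
                "PIC": float(pic_site(p).mean()),
            }
        )
    report = pd.DataFrame(rows).sort_values("PIC", kind="stable").reset_index(drop=True)
    mean_row = {
        "population": "Mean",
        "n_sites": int(report["n_sites"].mean()),
        "Ho": float(report["Ho"].mean()),
        "He": float(report["He"].mean()),
        "PIC": float(report["PIC"].mean()),
    }
    return pd.concat([report, pd.DataFrame([mean_row])], ignore_index=True)
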