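"""Synthetic structured-population genotype fixtures with known truth.

Background differentiation follows the Balding-Nichols model: each site
has an ancestral allele frequency p ~ Uniform(0.05, 0.95), and every
population draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F),
giving an expected pairwise F_ST of approximately F.  Diploid genotypes
are Binomial(2, p_pop) and calls are masked missing independently at a
configurable rate.  Inside each planted sweep interval, the focal
population's frequency is replaced by a draw within ``fixation_bias`` of
the nearer of 0 or 1, which simultaneously collapses its diversity and
inflates differentiation — the two signatures the windowed scan detects.

Sites that come out monomorphic in the realized sample are retained (real
call sets contain them) and must be removed by the MAF filter downstream.

The model has no linkage, so LD-decay analyses use a separate
copying-chain generator (:func:`simulate_ld_panel`): haplotype alleles
follow a two-state Markov chain along the contig whose autocorrelation
falls off exponentially with distance, with a tunable correlation length
per population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap
from .sweep import genes_in_regions, site_pi
from .popstats import site_frequencies

log = logging.getLogger("sweepscan")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, diploid count, drift parameter F."""

    label: str
    n_diploids: int
    F: float

    def __post_init__(self) -> None:
        if not (0 < self.F < 1):
            raise ValueError("F must be in (0, 1)")
        if self.n_diploids < 1:
            raise ValueError("need at least one diploid")


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: interval where the focal population is near-fixed.

    ``fixation_bias`` is the ceiling on the focal minor-allele frequency
    inside the interval (default 0.02).
    """

    pop: str
    contig: str
    start: int
    end: int
    fixation_bias: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.fixation_bias < 0.5):
            raise ValueError("fixation_bias must be in (0, 0.5)")
        if self.start > self.end:
            raise ValueError("sweep start > end")


@dataclass
class SimConfig:
    """Full description of a synthetic study.

    Defaults emulate a two-population contrast at resequencing-like SNP
    density: one 2 Mb contig, 20,000 SNPs, a reference and a focal
    population of 20 diploids each with weak background structure
    (F = 0.05), 5% random missingness, and three planted 100-kb sweeps in
    the focal population.  Genes are tiled deterministically (2 kb gene
    every 10 kb) so every region has an unambiguous truth gene set.
    """

    seed: int = 42
    contigs: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000)]
    )
    n_sites: int = 20_000
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("SZ", 20, 0.05),
            PopulationSpec("JL", 20, 0.05),
        ]
    )
    missing_rate: float = 0.05
    sweeps: list[SweepSpec] = field(
        default_factory=lambda: [
            SweepSpec("JL", "chr1", 200_001, 300_000),
            SweepSpec("JL", "chr1", 900_001, 1_000_000),
            SweepSpec("JL", "chr1", 1_600_001, 1_700_000),
        ]
    )
    gene_length: int = 2_000
    gene_spacing: int = 8_000

    def __post_init__(self) -> None:
        if sum(p.n_diploids for p in self.populations) < 4:
            raise ValueError("need at least 4 diploids in total")
        labels = {p.label for p in self.populations}
        contig_len = dict(self.contigs)
        for sw in self.sweeps:
            if sw.pop not in labels:
                raise ValueError(f"sweep references unknown population {sw.pop!r}")
            if sw.contig not in contig_len:
                raise ValueError(f"sweep references unknown contig {sw.contig!r}")
            if not (1 <= sw.start and sw.end <= contig_len[sw.contig]):
                raise ValueError(f"sweep outside contig bounds: {sw}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated fixture."""

    regions: list[tuple[str, int, int]]
    gene_ids: set[str]
    realized_F: dict[str, float]
    region_pi_ratio: list[float]  # mean pi(ref-like pops) / pi(focal) per region


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def _tile_genes(config: SimConfig) -> pd.DataFrame:
    rows = []
    pitch = config.gene_length + config.gene_spacing
    for contig, length in config.contigs:
        k = 0
        start = 1
        while start + config.gene_length - 1 <= length:
            rows.append(
                (
                    f"gene_{contig}_{k:04d}",
                    contig,
                    start,
                    start + config.gene_length - 1,
                    "+" if k % 2 == 0 else "-",
                )
            )
            k += 1
            start += pitch
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def simulate(
    config: SimConfig,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame, SimTruth]:
    """Generate a genotype matrix, popmap, gene models, and truth record.

    Identical configs (including the seed) produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    total_len = sum(length for _, length in config.contigs)

    # site positions: allocated to contigs proportionally to length,
    # uniform without replacement within a contig
    site_rows = []
    remaining = config.n_sites
    for i, (contig, length) in enumerate(config.contigs):
        n_here = (
            remaining
            if i == len(config.contigs) - 1
            else int(round(config.n_sites * length / total_len))
        )
        n_here = min(n_here, length, remaining)
        pos = np.sort(rng.choice(length, size=n_here, replace=False)) + 1
        site_rows.append(pd.DataFrame({"contig": contig, "pos": pos}))
        remaining -= n_here
    sites = pd.concat(site_rows, ignore_index=True)
    n_sites = len(sites)
    sites["ref"] = "A"
    sites["alt"] = "G"

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)

    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    calls_blocks = []
    realized_F: dict[str, float] = {}

    sweep_masks: dict[str, np.ndarray] = {}  # focal pop -> site mask
    contig_arr = sites["contig"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for sw in config.sweeps:
        m = (contig_arr == sw.contig) & (pos_arr >= sw.start) & (pos_arr <= sw.end)
        sweep_masks[sw.pop] = sweep_masks.get(sw.pop, np.zeros(n_sites, bool)) | m

    any_sweep = (
        np.logical_or.reduce(list(sweep_masks.values()))
        if sweep_masks
        else np.zeros(n_sites, bool)
    )

    for spec in config.populations:
        F = spec.F
        p_pop = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        # realized drift estimate from non-sweep sites (method of moments)
        bg = ~any_sweep
        realized_F[spec.label] = float(
            np.mean(
                (p_pop[bg] - p_anc[bg]) ** 2 / (p_anc[bg] * (1 - p_anc[bg]))
            )
        )
        swm = sweep_masks.get(spec.label)
        if swm is not None and swm.any():
            eps = max(sw.fixation_bias for sw in config.sweeps if sw.pop == spec.label)
            n_sw = int(swm.sum())
            near_one = p_pop[swm] >= 0.5
            draw = rng.uniform(0.0, eps, size=n_sw)
            p_pop[swm] = np.where(near_one, 1.0 - draw, draw)
        geno = rng.binomial(2, p_pop, size=(spec.n_diploids, n_sites)).astype(np.int8)
        if config.missing_rate > 0:
            mask = rng.random((spec.n_diploids, n_sites)) < config.missing_rate
            geno[mask] = MISSING
        calls_blocks.append(geno)
        ids = [f"{spec.label}_{i:03d}" for i in range(spec.n_diploids)]
        sample_ids.extend(ids)
        for s in ids:
            assignment[s] = spec.label

    G = GenotypeMatrix(
        sample_ids=sample_ids,
        sites=sites,
        calls=np.vstack(calls_blocks),
        contig_lengths=dict(config.contigs),
    )
    popmap = PopulationMap(assignment)
    genes = _tile_genes(config)

    truth_regions = [(sw.contig, sw.start, sw.end) for sw in config.sweeps]
    regions_df = pd.DataFrame(truth_regions, columns=["contig", "start", "end"])
    _, truth_genes = genes_in_regions(regions_df, genes)

    # realized diversity contrast inside each planted region
    region_pi_ratio = []
    focal_labels = {sw.pop for sw in config.sweeps}
    pis = {p.label: site_pi(site_frequencies(G, p.label, popmap)) for p in config.populations}
    for sw in config.sweeps:
        m = (contig_arr == sw.contig) & (pos_arr >= sw.start) & (pos_arr <= sw.end)
        pi_focal = float(np.nansum(pis[sw.pop][m]))
        others = [
            float(np.nansum(pis[p.label][m]))
            for p in config.populations
            if p.label not in focal_labels
        ]
        pi_other = float(np.mean(others)) if others else float("nan")
        region_pi_ratio.append(pi_other / pi_focal if pi_focal > 0 else float("inf"))

    truth = SimTruth(
        regions=truth_regions,
        gene_ids=truth_genes,
        realized_F=realized_F,
        region_pi_ratio=region_pi_ratio,
    )
    return G, popmap, genes, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def _as_interval_list(regions) -> list[tuple[str, int, int]]:
    if isinstance(regions, pd.DataFrame):
        return [
            (r.contig, int(r.start), int(r.end)) for r in regions.itertuples(index=False)
        ]
    return [(c, int(s), int(e)) for c, s, e, *_ in regions]


def _overlap_bp(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> int:
    total = 0
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca == cb:
                total += max(0, min(ea, eb) - max(sa, sb) + 1)
    return total


def evaluate_recovery(called, truth) -> tuple[float, float]:
    """Base-pair recall and precision of called regions against truth.

    recall = truth bp overlapped by calls / total truth bp;
    precision = called bp overlapping truth / total called bp (0, with a
    warning, when nothing was called).  Truth regions must not overlap
    each other; called regions are assumed disjoint (merged).
    """
    truth_regions = truth.regions if isinstance(truth, SimTruth) else _as_interval_list(truth)
    if not truth_regions:
        raise ValueError("empty truth region set")
    called_regions = _as_interval_list(called)
    truth_bp = sum(e - s + 1 for _, s, e in truth_regions)
    if not called_regions:
        log.warning("evaluate_recovery: no called regions; precision reported as 0")
        return 0.0, 0.0
    called_bp = sum(e - s + 1 for _, s, e in called_regions)
    hit = _overlap_bp(truth_regions, called_regions)
    return hit / truth_bp, hit / called_bp


# ---------------------------------------------------------------------------
# LD fixture generator (copying chain)
# ---------------------------------------------------------------------------


def simulate_ld_panel(
    seed: int,
    populations: list[tuple[str, int, float]],
    n_sites: int = 2_000,
    contig: str = "chr1",
    contig_length: int = 1_000_000,
    coding_noise: float = 0.05,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Generate unlinked-background haplotypes with exponential LD decay.

    ``populations`` is a list of ``(label, n_diploids, corr_length_bp)``:
    each haplotype's alleles follow a symmetric two-state Markov chain
    whose autocorrelation between sites d bp apart is exp(-d / corr_length),
    thinned by ``coding_noise`` (each allele independently re-randomised
    with that probability).  Shorter correlation lengths model populations
    whose LD decays faster.  Allele frequencies sit near 0.5 by design;
    the fixture targets LD structure, not the site-frequency spectrum.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(contig_length, size=n_sites, replace=False)) + 1
    gaps = np.diff(pos).astype(float)

    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    blocks = []
    for label, n_dip, corr_len in populations:
        flip_p = 0.5 * (1.0 - np.exp(-gaps / corr_len))
        n_hap = 2 * n_dip
        hap = np.empty((n_hap, n_sites), dtype=np.int8)
        hap[:, 0] = rng.integers(0, 2, size=n_hap)
        flips = rng.random((n_hap, n_sites - 1)) < flip_p[None, :]
        state = hap[:, 0].copy()
        for j in range(1, n_sites):
            state = np.where(flips[:, j - 1], 1 - state, state)
            hap[:, j] = state
        if coding_noise > 0:
            noisy = rng.random((n_hap, n_sites)) < coding_noise
            hap[noisy] = rng.integers(0, 2, size=int(noisy.sum()))
        geno = (hap[0::2, :] + hap[1::2, :]).astype(np.int8)
        blocks.append(geno)
        ids = [f"{label}_{i:03d}" for i in range(n_dip)]
        sample_ids.extend(ids)
        for s in ids:
            assignment[s] = label

    sites = pd.DataFrame(
        {"contig": contig, "pos": pos, "ref": "A", "alt": "G"}
    )
    G = GenotypeMatrix(
        sample_ids=sample_ids,
        sites=sites,
        calls=np.vstack(blocks),
        contig_lengths={contig: contig_length},
    )
    return G, PopulationMap(assignment)
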