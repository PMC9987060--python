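"""Readers and writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* Coordinates are 1-based inclusive everywhere (the VCF/GFF convention);
  conversion to 0-based half-open happens only at the BED boundary.
* Genotypes are stored as alt-allele dosage: 0, 1, 2, or :data:`MISSING`
  (-1).  Half-calls such as ``0/.`` are conservatively treated as missing,
  and phase separators ``/`` and ``|`` are equivalent (all downstream
  statistics are dosage-based).
* Only biallelic SNP records are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("sweepscan")

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for samples x biallelic SNP sites.

    Attributes
    ----------
    sample_ids
        Ordered sample labels.
    sites
        DataFrame with columns ``contig, pos, ref, alt``; sorted by
        (contig, pos), positions unique within a contig, 1-based.
    calls
        ``(n_samples, n_sites)`` int8 array of {0, 1, 2, MISSING}
        alt-allele dosages.
    contig_lengths
        Mapping contig name -> length in bp.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        for contig, sub in self.sites.groupby("contig", sort=False):
            if sub["pos"].duplicated().any():
                raise ValueError(f"duplicate positions on contig {contig}")
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"sites not sorted by position on {contig}")
            length = self.contig_lengths.get(contig)
            if length is not None and (
                (sub["pos"] < 1).any() or (sub["pos"] > length).any()
            ):
                raise ValueError(f"position outside [1, {length}] on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            contig_lengths=dict(self.contig_lengths),
        )

    def sample_index(self, labels: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in labels if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([pos[s] for s in labels], dtype=int)


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of each sample to exactly one population."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("population map is empty")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)

    def samples(self, pop: str) -> list[str]:
        out = [s for s, p in self.assignment.items() if p == pop]
        if not out:
            raise KeyError(f"population {pop!r} has no samples")
        return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str, keep_samples: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT genotypes) into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count logged).  Missing
    and half-called genotypes become :data:`MISSING`.  Contig lengths come
    from ``##contig`` header lines when present, else the max position seen
    per contig.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib reports its own line context
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if keep_samples is not None:
        absent = [s for s in keep_samples if s not in samples]
        if absent:
            raise FormatError(f"samples absent from VCF {path}: {absent}")
        col_idx = [samples.index(s) for s in keep_samples]
        samples = list(keep_samples)
    else:
        col_idx = list(range(len(samples)))

    header_lengths: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        if length:
            header_lengths[name] = int(length)

    rows = []
    cols = []
    n_dropped = 0
    try:
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_dropped += 1
                continue
            gts = v.genotypes  # [[a1, a2, phased], ...]
            dosage = np.empty(len(col_idx), dtype=np.int8)
            for out_i, i in enumerate(col_idx):
                a1, a2 = gts[i][0], gts[i][1]
                dosage[out_i] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
            cols.append(dosage)
    except Exception as exc:
        raise FormatError(f"parse error in VCF {path}: {exc}") from exc
    if n_dropped:
        log.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)

    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    calls = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["contig"].to_numpy())) if len(sites) else np.array([], dtype=int)
    sites = sites.iloc[order].reset_index(drop=True)
    calls = calls[:, order]

    contig_lengths = dict(header_lengths)
    for contig, sub in sites.groupby("contig", sort=False):
        contig_lengths.setdefault(contig, int(sub["pos"].max()))

    return GenotypeMatrix(samples, sites, calls, contig_lengths)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF v4.2 (deterministic byte output)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for contig, length in G.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        contigs = G.sites["contig"].to_numpy()
        poss = G.sites["pos"].to_numpy()
        refs = G.sites["ref"].to_numpy()
        alts = G.sites["alt"].to_numpy()
        for j in range(G.n_sites):
            gts = "\t".join(_GT_STR[int(d)] for d in G.calls[:, j])
            fh.write(
                f"{contigs[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Population map (two-column TSV)
# ---------------------------------------------------------------------------


def read_popmap(path: str) -> PopulationMap:
    """Read a headerless two-column sample<TAB>population TSV."""
    assignment: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            sample, pop = fields[0].strip(), fields[1].strip()
            if sample in assignment:
                raise FormatError(
                    f"{path}:{lineno}: sample {sample!r} listed more than once"
                )
            assignment[sample] = pop
    if n_lines == 0:
        raise FormatError(f"{path}: empty population map")
    return PopulationMap(assignment)


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignment.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gff(path: str) -> pd.DataFrame:
    """Read gene records from a GFF3 file.

    Returns a DataFrame with columns ``gene_id, contig, start, end, strand``
    (1-based inclusive, sorted by contig then start).  Only features of type
    ``gene`` are used; a gene without an ``ID`` attribute is an error.
    """
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"gene record at {feat.seqid}:{feat.start} lacks ID")
        rows.append((ids[0], feat.seqid, int(feat.start), int(feat.end), feat.strand or "."))
    genes = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])
    return genes.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)


def write_gff(genes: pd.DataFrame, path: str) -> None:
    """Write gene models as minimal GFF3 (inverse of :func:`read_gff`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.contig}\tsweepscan\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(regions: list[tuple], path: str) -> None:
    """Write regions given in 1-based inclusive coordinates as BED.

    BED is 0-based half-open, so a region ``(contig, start, end[, name])``
    is emitted as ``contig  start-1  end``.
    """
    with open(path, "w") as fh:
        for region in regions:
            contig, start, end = region[0], region[1], region[2]
            name = region[3] if len(region) > 3 else None
            line = f"{contig}\t{start - 1}\t{end}"
            if name is not None:
                line += f"\t{name}"
            fh.write(line + "\n")


def read_bed(path: str) -> list[tuple]:
    """Read a BED file back into 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start0, end = fields[0], int(fields[1]), int(fields[2])
            if len(fields) > 3:
                out.append((contig, start0 + 1, end, fields[3]))
            else:
                out.append((contig, start0 + 1, end))
    return out
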