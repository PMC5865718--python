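"""Fixed-width genomic binning and rDNA contact quantification.

The genome is partitioned into non-overlapping bins of a fixed width
(1 Mb by default); the final bin of each chromosome is the remainder,
so a chromosome of length L yields ceil(L / width) bins.  Contacts are
read pairs with exactly one end anchored in an rDNA array; each contact
increments the bin containing the 5'-most mapped base of its genomic
mate.  Raw counts are normalized to contacts per million (CPM) using
the total number of rDNA-genome contacts of the same dataset and array
as the library size.

All coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRCH37_AUTOSOMES",
    "BinScheme",
    "RateEstimate",
    "bin_genome",
    "count_contacts",
    "cpm_normalize",
    "estimate_rates",
    "replicate_correlation",
]

# GRCh37/hg19 autosome lengths (bp), chr1..chr22, UCSC chromInfo.
GRCH37_AUTOSOMES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
}


@dataclass(frozen=True)
class BinScheme:
    """A tiling of the genome into fixed-width bins.

    ``bins`` has columns ``bin_id`` (0..n-1 in chromosome order then
    coordinate order), ``chrom``, ``start``, ``end``.  The last bin of
    each chromosome may be partial; its end equals the chromosome
    length.
    """

    width: int
    bins: pd.DataFrame
    chrom_sizes: dict[str, int]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_index(self, chrom: np.ndarray | list, pos: np.ndarray | list) -> np.ndarray:
        """Map (chromosome, position) pairs to bin ids (vectorized)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        offsets = {}
        cursor = 0
        for name, size in self.chrom_sizes.items():
            offsets[name] = cursor
            cursor += -(-size // self.width)
        out = np.empty(len(pos), dtype=np.int64)
        for name in np.unique(chrom):
            m = chrom == name
            if name not in offsets:
                raise KeyError(f"chromosome {name!r} not in bin scheme")
            size = self.chrom_sizes[name]
            p = pos[m]
            bad = (p < 0) | (p >= size)
            if bad.any():
                i = int(np.argmax(bad))
                raise ValueError(
                    f"record position {name}:{p[i]} outside the bin scheme "
                    f"(chromosome length {size})"
                )
            out[m] = offsets[name] + p // self.width
        return out

    def to_bed(self, path) -> None:
        self.bins[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def bin_genome(chrom_sizes: dict[str, int], width: int = 1_000_000) -> BinScheme:
    """Tile chromosomes into ``width``-bp bins with a ceiling final bin.

    GRCh37 autosomes at 1 Mb give 2897 bins.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    bin_id = 0
    for name, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {size}")
        for start in range(0, size, width):
            rows.append((bin_id, name, start, min(start + width, size)))
            bin_id += 1
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])
    return BinScheme(width=width, bins=bins, chrom_sizes=dict(chrom_sizes))


def count_contacts(
    records: pd.DataFrame,
    scheme: BinScheme,
    mask=None,
) -> pd.DataFrame:
    """Count rDNA-genome contacts per (dataset, array, bin).

    ``records`` needs columns ``dataset``, ``array``, ``chrom``, ``pos``
    and ``category``; only ``rdna_genome`` records are counted.  Masked
    bins keep their counts but are flagged ``masked`` so statistics can
    exclude them.  Returns a long-format table with one row per
    (dataset, array) x bin, including zero bins.
    """
    rec = records[records["category"] == "rdna_genome"]
    frames = []
    for (dataset, array), grp in rec.groupby(["dataset", "array"], sort=True):
        idx = scheme.bin_index(grp["chrom"].to_numpy(), grp["pos"].to_numpy())
        counts = np.bincount(idx, minlength=scheme.n_bins)
        tab = scheme.bins.copy()
        tab.insert(0, "array", array)
        tab.insert(0, "dataset", dataset)
        tab["count"] = counts
        frames.append(tab)
    if not frames:
        tab = scheme.bins.copy()
        tab.insert(0, "array", None)
        tab.insert(0, "dataset", None)
        tab["count"] = np.zeros(scheme.n_bins, dtype=np.int64)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["masked"] = False
    if mask is not None:
        for array, excluded in mask.excluded_bins.items():
            if excluded:
                sel = (out["array"] == array) & out["bin_id"].isin(excluded)
                out.loc[sel, "masked"] = True
    return out


def cpm_normalize(
    table: pd.DataFrame, library_sizes: dict | None = None
) -> pd.DataFrame:
    """Add a CPM column: count * 1e6 / library size of the dataset-array.

    By default the library size is the total number of binned
    rDNA-genome contacts of that dataset and array (both-end-rDNA and
    excluded categories are not in the denominator).  Raw counts are
    left untouched.
    """
    out = table.copy()
    out["cpm"] = np.nan
    for (dataset, array), grp in out.groupby(["dataset", "array"], sort=False):
        if library_sizes is not None:
            lib = library_sizes[(dataset, array)]
        else:
            lib = int(grp["count"].sum())
        if lib <= 0:
            warnings.warn(
                f"zero library size for ({dataset}, {array}); CPM set to NA",
                stacklevel=2,
            )
            continue
        out.loc[grp.index, "cpm"] = grp["count"] * 1e6 / lib
    return out


@dataclass(frozen=True)
class RateEstimate:
    """Per-nucleotide contact rates for one dataset-array.

    Three estimators: contacts per bp over the whole genome, over
    unmasked 1 Mb bins only, and over retained gene spans only.
    """

    rate_genomewide: float
    rate_masked_bins: float
    rate_genic: float


def estimate_rates(
    records: pd.DataFrame,
    scheme: BinScheme,
    mask=None,
    gene_models: pd.DataFrame | None = None,
    genome_length: int | None = None,
) -> RateEstimate:
    """Estimate per-bp contact rates three ways for one record set.

    ``records`` should be the ``rdna_genome`` records of a single
    dataset-array.  ``gene_models`` needs ``gene_id``, ``chrom``,
    ``start``, ``end``; genes excluded by ``mask`` are dropped from the
    genic estimator.
    """
    rec = records[records["category"] == "rdna_genome"]
    if genome_length is None:
        genome_length = sum(scheme.chrom_sizes.values())
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    total = len(rec)
    rate_gw = total / genome_length

    idx = scheme.bin_index(rec["chrom"].to_numpy(), rec["pos"].to_numpy()) if total else np.empty(0, int)
    excluded: set[int] = set()
    excluded_genes: set[str] = set()
    if mask is not None:
        for s in mask.excluded_bins.values():
            excluded |= set(s)
        for s in mask.excluded_genes.values():
            excluded_genes |= set(s)
    keep_bins = ~scheme.bins["bin_id"].isin(excluded)
    unmasked_len = int((scheme.bins.loc[keep_bins, "end"] - scheme.bins.loc[keep_bins, "start"]).sum())
    if unmasked_len <= 0:
        raise ValueError("no unmasked bin length")
    in_unmasked = int(np.sum(~np.isin(idx, np.fromiter(excluded, dtype=np.int64, count=len(excluded))))) if total else 0
    rate_masked = in_unmasked / unmasked_len

    rate_genic = 0.0
    if gene_models is not None and len(gene_models):
        # one row per gene span (gene tables may carry one row per exon);
        # spans from the generator are non-overlapping
        genes = gene_models.drop_duplicates("gene_id")
        genes = genes[~genes["gene_id"].isin(excluded_genes)]
        glen = int((genes["end"] - genes["start"]).sum())
        if glen <= 0:
            raise ValueError("no retained gene length")
        n_genic = 0
        for chrom, grp in genes.groupby("chrom"):
            starts = np.sort(grp["start"].to_numpy())
            ends = grp["end"].to_numpy()[np.argsort(grp["start"].to_numpy())]
            pos = rec.loc[rec["chrom"] == chrom, "pos"].to_numpy()
            if len(pos) == 0:
                continue
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            n_genic += int(ok.sum())
        rate_genic = n_genic / glen
    return RateEstimate(rate_gw, rate_masked, rate_genic)


def replicate_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame, value: str = "count"
):
    """Spearman rank correlation of bin values between two replicates.

    Bins masked in either table are dropped.  Both tables must derive
    from the same bin scheme.  Returns (rho, two-sided p).
    """
    a = table_a.set_index("bin_id")
    b = table_b.set_index("bin_id")
    shared = a.index.intersection(b.index)
    keep = shared[~(a.loc[shared, "masked"] | b.loc[shared, "masked"])]
    if len(keep) < 3:
        raise ValueError("fewer than 3 shared unmasked bins")
    rho, p = stats.spearmanr(a.loc[keep, value], b.loc[keep, value])
    return float(rho), float(p)
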