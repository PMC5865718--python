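"""Synthetic genomes, rDNA references and Hi-C read pairs with ground truth.

The generator builds a toy multi-chromosome genome, distinct 5S/45S
rDNA reference units, a small repeat library, optional planted rDNA
pseudogene copies, non-overlapping gene models, and bin-level
annotation tracks.  From these it simulates Hi-C read pairs whose
ground-truth category (rDNA-genome contact, both-end rDNA, repeat
mate, non-rDNA) and source bin are recorded, so every downstream stage
of the pipeline can be tested against known truth without downloading
any real corpus.

Default unit sizes follow the real repeats where desk scale permits:
the 5S unit is 2121 bp (the chr1 repeat unit including flanks); the
45S unit defaults to a 5 kb stand-in for the 45,337 bp unit so exact
mapping and masking run in seconds.  rDNA references and repeat units
are rejection-sampled so they share no 21-mer with the non-planted
genome: at toy scale an accidental shared k-mer would corrupt the
ground truth of the exact-mapping stage.

Randomness is fully determined by the seeds in the spec/model objects:
identical seeds give byte-identical FASTA/FASTQ/GTF/BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contactmap import BinScheme, bin_genome

__all__ = [
    "PseudogenePlant",
    "SyntheticGenomeSpec",
    "ToyGenome",
    "ContactPropensityModel",
    "ReadPairSet",
    "make_toy_genome",
    "simulate_contact_pairs",
    "simulate_contact_records",
    "make_gene_models",
    "make_annotation_track",
    "write_fasta",
    "write_gtf",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length).tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ints(seq: str, k: int) -> np.ndarray:
    """2-bit packed k-mer integers at every position (k <= 31)."""
    codes = _encode(seq).astype(np.uint64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n]
    return out


@dataclass(frozen=True)
class PseudogenePlant:
    """A planted rDNA pseudogene: a (possibly degraded) copy of a source array."""

    chrom: str
    start: int
    source_array: str  # "5S" or "45S"
    length: int
    identity: float = 1.0
    source_start: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the toy genome.

    ``chromosomes`` is a list of (name, length-bp).  Pseudogene plants
    must not overlap each other and must lie within their chromosome.
    """

    chromosomes: list[tuple[str, int]]
    rdna_5s_length: int = 2121
    rdna_45s_length: int = 5000
    pseudogene_plants: list[PseudogenePlant] = field(default_factory=list)
    n_repeat_units: int = 3
    repeat_unit_length: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        sizes = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.rdna_5s_length <= 0 or self.rdna_45s_length <= 0:
            raise ValueError("rDNA unit lengths must be positive")
        by_chrom: dict[str, list[PseudogenePlant]] = {}
        for p in self.pseudogene_plants:
            if p.source_array not in ("5S", "45S"):
                raise ValueError(f"unknown source array {p.source_array!r}")
            if not 0 < p.identity <= 1:
                raise ValueError("plant identity must be in (0, 1]")
            if p.chrom not in sizes:
                raise ValueError(f"plant chromosome {p.chrom!r} not in genome")
            if p.start < 0 or p.end > sizes[p.chrom]:
                raise ValueError(f"plant {p} lies outside {p.chrom}")
            src_len = self.rdna_5s_length if p.source_array == "5S" else self.rdna_45s_length
            if p.source_start < 0 or p.source_start + p.length > src_len:
                raise ValueError(f"plant {p} exceeds its source unit")
            by_chrom.setdefault(p.chrom, []).append(p)
        for plants in by_chrom.values():
            plants = sorted(plants, key=lambda p: p.start)
            for a, b in zip(plants, plants[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping pseudogene plants: {a} and {b}")


@dataclass
class ToyGenome:
    """Generated sequences plus the plant truth table."""

    chromosomes: dict[str, str]
    rdna: dict[str, str]  # {"5S": seq, "45S": seq}
    repeats: dict[str, str]
    plants: list[PseudogenePlant]
    spec: SyntheticGenomeSpec

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def sizes_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": list(self.chromosomes), "length": [len(s) for s in self.chromosomes.values()]}
        )

    def plant_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.chrom, p.start, p.end, p.source_array, p.length, p.identity)
                for p in self.plants
            ],
            columns=["chrom", "start", "end", "array", "length", "identity"],
        )


_REJECT_K = 21


def make_toy_genome(spec: SyntheticGenomeSpec) -> ToyGenome:
    """Generate the toy genome, rDNA references and repeat library.

    rDNA references and repeat units are re-drawn until they share no
    21-mer with the random genome or with each other; pseudogene plants
    are copied in afterwards, so plants are the only rDNA-like sequence
    in the genome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chromosomes = {name: _random_seq(rng, length) for name, length in spec.chromosomes}

    genome_kmers = np.sort(
        np.concatenate(
            [_kmer_ints(seq, _REJECT_K) for seq in chromosomes.values()]
            or [np.empty(0, dtype=np.uint64)]
        )
    )

    def _member(sorted_arr: np.ndarray, query: np.ndarray) -> bool:
        if len(sorted_arr) == 0 or len(query) == 0:
            return False
        idx = np.clip(np.searchsorted(sorted_arr, query), 0, len(sorted_arr) - 1)
        return bool((sorted_arr[idx] == query).any())

    def draw_distinct(length: int, taken: np.ndarray) -> str:
        for _ in range(50):
            cand = _random_seq(rng, length)
            km = _kmer_ints(cand, _REJECT_K)
            if not _member(genome_kmers, km) and not _member(taken, km):
                return cand
        raise RuntimeError("could not draw a k-mer-distinct reference sequence")

    taken = np.empty(0, dtype=np.uint64)
    rdna = {}
    for label, length in (("5S", spec.rdna_5s_length), ("45S", spec.rdna_45s_length)):
        seq = draw_distinct(length, taken)
        taken = np.sort(np.concatenate([taken, _kmer_ints(seq, _REJECT_K)]))
        rdna[label] = seq
    repeats = {}
    for i in range(spec.n_repeat_units):
        name = f"repeat_{i}"
        seq = draw_distinct(spec.repeat_unit_length, taken)
        taken = np.sort(np.concatenate([taken, _kmer_ints(seq, _REJECT_K)]))
        repeats[name] = seq

    # plant pseudogene copies with per-base identity
    for p in spec.pseudogene_plants:
        source = rdna[p.source_array][p.source_start : p.source_start + p.length]
        copy = list(source)
        if p.identity < 1.0:
            mutate = rng.random(p.length) < (1.0 - p.identity)
            for i in np.flatnonzero(mutate):
                alternatives = [b for b in "ACGT" if b != copy[i]]
                copy[i] = alternatives[rng.integers(3)]
        chrom = chromosomes[p.chrom]
        chromosomes[p.chrom] = chrom[: p.start] + "".join(copy) + chrom[p.end :]

    return ToyGenome(
        chromosomes=chromosomes,
        rdna=rdna,
        repeats=repeats,
        plants=list(spec.pseudogene_plants),
        spec=spec,
    )


@dataclass
class ContactPropensityModel:
    """Bin-level contact propensities and read-pair category mix.

    The genomic mate of an rDNA-genome pair falls in bin *i* with
    probability proportional to ``bin_weights[i]`` times the product of
    the multipliers of every annotation label covering bin *i*.
    ``bin_weights=None`` draws log-normal(0, sigma=0.5) weights from
    the seed.  Category fractions: ``frac_rdna_pairs`` of all pairs
    have at least one rDNA end; of those, ``frac_both_end_rdna`` have
    both ends in the array and ``frac_repeat_mate`` have a repeat-library
    mate (the remainder are informative rDNA-genome contacts).
    """

    bin_weights: np.ndarray | None = None
    annotation_multipliers: dict[str, float] = field(default_factory=dict)
    annotation_bins: dict[str, set[int]] = field(default_factory=dict)
    frac_rdna_pairs: float = 0.8
    frac_both_end_rdna: float = 0.29
    frac_repeat_mate: float = 0.1
    frac_5s: float = 0.5
    bin_width: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        for f in (self.frac_rdna_pairs, self.frac_both_end_rdna, self.frac_repeat_mate, self.frac_5s):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_both_end_rdna + self.frac_repeat_mate > 1:
            raise ValueError("frac_both_end_rdna + frac_repeat_mate must be <= 1")
        if self.bin_weights is not None:
            w = np.asarray(self.bin_weights, dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("bin weights must be nonnegative with at least one positive")

    def effective_weights(self, scheme: BinScheme, rng: np.random.Generator) -> np.ndarray:
        if self.bin_weights is None:
            w = rng.lognormal(mean=0.0, sigma=0.5, size=scheme.n_bins)
        else:
            w = np.asarray(self.bin_weights, dtype=float).copy()
            if len(w) != scheme.n_bins:
                raise ValueError(
                    f"bin_weights has {len(w)} entries but the scheme has {scheme.n_bins} bins"
                )
        for label, bins in self.annotation_bins.items():
            mult = self.annotation_multipliers.get(label, 1.0)
            idx = np.fromiter(bins, dtype=np.int64, count=len(bins))
            w[idx] *= mult
        if w.sum() <= 0:
            raise ValueError("all effective bin weights are zero")
        return w


@dataclass
class ReadPairSet:
    """Simulated paired reads plus the per-pair ground truth."""

    pairs: list[tuple[str, str, str, str, str]]  # (name, seq1, qual1, seq2, qual2)
    truth: pd.DataFrame  # pair_id, category, array, chrom, pos, bin_id

    def to_fastq(self, path1, path2) -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for name, s1, q1, s2, q2 in self.pairs:
                f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")


def _sample_genome_position(
    rng: np.random.Generator,
    scheme: BinScheme,
    probs: np.ndarray,
    read_len: int,
    plants_by_chrom: dict[str, list[tuple[int, int]]],
    n: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n (chrom, pos, bin_id) with bin ∝ probs, position uniform in bin.

    Positions overlapping a planted pseudogene are resampled within the
    bin so read-level ground truth stays exact.
    """
    bin_ids = rng.choice(scheme.n_bins, size=n, p=probs)
    bins = scheme.bins
    chroms = bins["chrom"].to_numpy()[bin_ids]
    starts = bins["start"].to_numpy()[bin_ids]
    ends = bins["end"].to_numpy()[bin_ids]
    hi = np.maximum(ends - read_len, starts + 1)
    pos = rng.integers(starts, hi)
    for i in range(n):
        intervals = plants_by_chrom.get(chroms[i], [])
        for _ in range(200):
            p = pos[i]
            if not any(s - read_len < p < e for s, e in intervals):
                break
            pos[i] = rng.integers(starts[i], hi[i])
        else:  # pragma: no cover - pathological spec
            raise RuntimeError("bin too crowded with plants to place a clean read")
    return chroms, pos, bin_ids


_CATEGORIES = ("rdna_genome", "rdna_both", "repeat_excluded", "non_rdna")


def simulate_contact_pairs(
    genome: ToyGenome,
    model: ContactPropensityModel,
    n_pairs: int,
    read_len: int = 80,
    frac_low_quality_tail: float = 0.1,
    max_tail: int = 20,
) -> ReadPairSet:
    """Simulate Hi-C read pairs with recorded ground truth.

    Reads are error-free substrings of their source (either strand); a
    ``frac_low_quality_tail`` fraction of reads get their final 5-20
    bases replaced with random sequence at Phred quality 2, so that
    3'-quality trimming restores the mappable prefix.
    """
    model.validate()
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    refs = list(genome.rdna.values()) + list(genome.repeats.values()) + list(
        genome.chromosomes.values()
    )
    if read_len > min(len(s) for s in refs):
        raise ValueError("read_len exceeds the shortest reference")
    if read_len - max_tail <= 0:
        raise ValueError("max_tail must be smaller than read_len")
    rng = np.random.default_rng(model.seed)
    scheme = bin_genome(genome.chrom_sizes, model.bin_width)
    weights = model.effective_weights(scheme, rng)
    probs = weights / weights.sum()
    plants_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in genome.plants:
        plants_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))

    p_r = model.frac_rdna_pairs
    p_cat = np.array(
        [
            p_r * (1 - model.frac_both_end_rdna - model.frac_repeat_mate),
            p_r * model.frac_both_end_rdna,
            p_r * model.frac_repeat_mate,
            1 - p_r,
        ]
    )
    cat_idx = rng.choice(4, size=n_pairs, p=p_cat)
    arrays = np.where(rng.random(n_pairs) < model.frac_5s, "5S", "45S")

    n_rg = int(np.sum(cat_idx == 0))
    n_non = int(np.sum(cat_idx == 3))
    rg_loc = _sample_genome_position(rng, scheme, probs, read_len, plants_by_chrom, n_rg)
    uniform = np.ones(scheme.n_bins) / scheme.n_bins
    non_loc1 = _sample_genome_position(rng, scheme, uniform, read_len, plants_by_chrom, n_non)
    non_loc2 = _sample_genome_position(rng, scheme, uniform, read_len, plants_by_chrom, n_non)

    def rdna_read(array: str) -> str:
        ref = genome.rdna[array]
        start = rng.integers(0, len(ref) - read_len + 1)
        return ref[start : start + read_len]

    def finalize(seq: str) -> tuple[str, str]:
        if rng.random() < 0.5:
            seq = revcomp(seq)
        qual = "".join(chr(33 + q) for q in rng.integers(35, 41, size=len(seq)))
        if rng.random() < frac_low_quality_tail:
            t = int(rng.integers(5, max_tail + 1))
            seq = seq[:-t] + _random_seq(rng, t)
            qual = qual[:-t] + chr(33 + 2) * t
        return seq, qual

    pairs = []
    truth_rows = []
    i_rg = i_non = 0
    for i in range(n_pairs):
        cat = _CATEGORIES[cat_idx[i]]
        array = str(arrays[i])
        if cat == "rdna_genome":
            chrom, pos, bin_id = (
                rg_loc[0][i_rg],
                int(rg_loc[1][i_rg]),
                int(rg_loc[2][i_rg]),
            )
            i_rg += 1
            r1 = rdna_read(array)
            r2 = genome.chromosomes[chrom][pos : pos + read_len]
            truth_rows.append((i, cat, array, chrom, pos, bin_id))
        elif cat == "rdna_both":
            r1, r2 = rdna_read(array), rdna_read(array)
            truth_rows.append((i, cat, array, None, -1, -1))
        elif cat == "repeat_excluded":
            r1 = rdna_read(array)
            unit = genome.repeats[rng.choice(list(genome.repeats))]
            start = rng.integers(0, len(unit) - read_len + 1)
            r2 = unit[start : start + read_len]
            truth_rows.append((i, cat, array, None, -1, -1))
        else:  # non_rdna
            c1, p1 = non_loc1[0][i_non], int(non_loc1[1][i_non])
            c2, p2 = non_loc2[0][i_non], int(non_loc2[1][i_non])
            i_non += 1
            r1 = genome.chromosomes[c1][p1 : p1 + read_len]
            r2 = genome.chromosomes[c2][p2 : p2 + read_len]
            truth_rows.append((i, cat, None, None, -1, -1))
        if rng.random() < 0.5:
            r1, r2 = r2, r1
        s1, q1 = finalize(r1)
        s2, q2 = finalize(r2)
        pairs.append((f"pair_{i:07d}", s1, q1, s2, q2))

    truth = pd.DataFrame(
        truth_rows, columns=["pair_id", "category", "array", "chrom", "pos", "bin_id"]
    )
    return ReadPairSet(pairs=pairs, truth=truth)


def simulate_contact_records(
    genome_or_sizes,
    model: ContactPropensityModel,
    n_records: int,
    dataset: str = "sim",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate classified rDNA-genome contact records directly.

    A fast path that skips read synthesis and mapping: every record is
    an ``rdna_genome`` contact whose genomic-mate bin is drawn from the
    model's effective bin weights and whose position is uniform within
    the bin.  Used to exercise the counting, gene-assignment,
    differential and enrichment stages at scale.
    """
    model.validate()
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    sizes = (
        genome_or_sizes.chrom_sizes
        if isinstance(genome_or_sizes, ToyGenome)
        else dict(genome_or_sizes)
    )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    scheme = bin_genome(sizes, model.bin_width)
    weights = model.effective_weights(scheme, rng)
    probs = weights / weights.sum()
    bin_ids = rng.choice(scheme.n_bins, size=n_records, p=probs)
    bins = scheme.bins
    starts = bins["start"].to_numpy()[bin_ids]
    ends = bins["end"].to_numpy()[bin_ids]
    pos = rng.integers(starts, ends)
    arrays = np.where(rng.random(n_records) < model.frac_5s, "5S", "45S")
    return pd.DataFrame(
        {
            "dataset": dataset,
            "array": arrays,
            "chrom": bins["chrom"].to_numpy()[bin_ids],
            "pos": pos,
            "category": "rdna_genome",
            "bin_id": bin_ids,
        }
    )


def make_annotation_track(
    scheme: BinScheme, label: str, bin_ids, state: str | None = None
) -> pd.DataFrame:
    """BED-style intervals (0-based half-open) covering the given bins."""
    bins = scheme.bins.set_index("bin_id")
    rows = [
        (bins.at[b, "chrom"], bins.at[b, "start"], bins.at[b, "end"], state or label)
        for b in sorted(bin_ids)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def make_gene_models(
    genome_or_sizes,
    n_genes: int,
    length_range: tuple[int, int] = (2_000, 20_000),
    max_exons: int = 4,
    min_gap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Place non-overlapping gene models with exons on the toy genome.

    Returns a table with one row per exon: ``gene_id``, ``chrom``,
    ``start``, ``end`` (gene span, 0-based half-open), ``exon_start``,
    ``exon_end``.  The gene span runs from the first exon start to the
    last exon end.  Raises if the genes cannot be packed.
    """
    sizes = (
        genome_or_sizes.chrom_sizes
        if isinstance(genome_or_sizes, ToyGenome)
        else dict(genome_or_sizes)
    )
    if n_genes == 0:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "exon_start", "exon_end"]
        )
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError("invalid length range")
    chrom_names = list(sizes)
    cursors = {c: 0 for c in chrom_names}
    rows = []
    placed = 0
    ci = 0
    while placed < n_genes:
        # round-robin over chromosomes so genes spread across the genome
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            ci += 1
            length = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(min_gap, 2 * min_gap + 1))
            start = cursors[chrom] + gap
            if start + length <= sizes[chrom]:
                break
        else:
            raise ValueError(
                f"cannot pack {n_genes} genes of {lo}-{hi} bp into the genome "
                f"(placed {placed})"
            )
        cursors[chrom] = start + length
        gene_id = f"G{placed:05d}"
        n_exons = int(rng.integers(1, max_exons + 1))
        # cut the span into 2*n_exons-1 alternating exon/intron blocks
        if n_exons == 1:
            bounds = [(start, start + length)]
        else:
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
            edges = np.concatenate([[0], cuts, [length]])
            bounds = [
                (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                for k in range(n_exons)
            ]
        for es, ee in bounds:
            rows.append((gene_id, chrom, start, start + length, es, ee))
        placed += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "exon_start", "exon_end"]
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write sequences as 70-column FASTA (deterministic byte layout)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gtf(gene_models: pd.DataFrame, path) -> None:
    """Write exon rows as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gene_id, grp in gene_models.groupby("gene_id", sort=True):
            first = grp.iloc[0]
            attrs = f'gene_id "{gene_id}"; gene_name "{gene_id}";'
            fh.write(
                f"{first.chrom}\tsynthio\tgene\t{first.start + 1}\t{first.end}\t.\t+\t.\t{attrs}\n"
            )
            for _, row in grp.sort_values("exon_start").iterrows():
                fh.write(
                    f"{row.chrom}\tsynthio\texon\t{row.exon_start + 1}\t{row.exon_end}\t.\t+\t.\t{attrs}\n"
                )
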