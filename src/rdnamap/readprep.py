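"""Read trimming, independent dual-end mapping and contact classification.

Hi-C pairs informative about rDNA contacts are mined by mapping the
two mates *independently* (no insert-size constraint — the mates of a
Hi-C pair may lie megabases or chromosomes apart) against the 5S and
45S rDNA reference units, the genome, and a repeat library.  A pair is
an rDNA-genome contact when exactly one end maps to an rDNA unit and
the mate maps uniquely to the genome; pairs whose mate hits the repeat
library are excluded, and both-end-rDNA pairs are tallied separately.

Mapping here is exact unique full-length substring matching over a
k-mer seed index.  Synthetic reads are error-free once their low
quality 3' tail is trimmed, so the classification logic — the part
that matters — is exercised without aligner heuristics.  Real-mode
users can plug in an external aligner and feed its per-end loci to
:func:`classify_pair` via :class:`MappedEnd`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TrimPolicy",
    "MappedEnd",
    "ReferenceIndex",
    "quality_trim",
    "map_end",
    "classify_pair",
    "mine_pairs",
    "read_fastq_pairs",
    "summarize_mining",
]


@dataclass(frozen=True)
class TrimPolicy:
    """3'-quality trimming thresholds: keep quality > 20 and length > 50 bp."""

    min_quality: int = 20
    min_length: int = 50

    def __post_init__(self):
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def quality_trim(
    sequence: str, qualities: Iterable[int], policy: TrimPolicy = TrimPolicy()
) -> tuple[str, list[int]] | None:
    """Trim low-quality 3' bases; return None when the read is discarded.

    Trailing bases with Phred quality <= ``min_quality`` are removed
    from the 3' end; the read is discarded if the remainder is <=
    ``min_length`` bp.  Sequence content is otherwise unchanged, so the
    operation is idempotent.  ``qualities`` may be Phred integers or a
    Phred+33 ASCII string.
    """
    if isinstance(qualities, str):
        qualities = [ord(c) - 33 for c in qualities]
    qualities = list(qualities)
    if len(qualities) != len(sequence):
        raise ValueError(
            f"malformed record: {len(sequence)} bases but {len(qualities)} quality values"
        )
    keep = len(sequence)
    while keep > 0 and qualities[keep - 1] <= policy.min_quality:
        keep -= 1
    if keep <= policy.min_length:
        return None
    return sequence[:keep], qualities[:keep]


@dataclass(frozen=True)
class MappedEnd:
    """One mate's mapping call.

    ``target`` is one of 5S/45S/genome/repeat/unmapped.  Genome targets
    carry chromosome coordinates (0-based, forward strand of the match
    start); rDNA targets carry unit-relative coordinates.  ``unique``
    is False for ambiguous placements (multiple loci, or hits both in
    an rDNA unit and elsewhere).
    """

    target: str
    chrom: str | None = None
    start: int = -1
    strand: str = "+"
    unique: bool = False


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


_ENC_LUT = np.zeros(128, dtype=np.uint8)
_ENC_LUT[ord("C")] = 1
_ENC_LUT[ord("G")] = 2
_ENC_LUT[ord("T")] = 3


def _pack_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit packed k-mer integer at every start position (k <= 31)."""
    codes = _ENC_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.uint64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n]
    return out


class ReferenceIndex:
    """Seed k-mer index over rDNA units, genome chromosomes and repeats.

    Reads are located by looking up their first ``seed_len`` bases (and
    those of the reverse complement) in a sorted packed-k-mer array and
    verifying a full-length exact match.  ``seed_len`` must not exceed
    the post-trim minimum read length.
    """

    def __init__(
        self,
        rdna: dict[str, str],
        genome: dict[str, str],
        repeats: dict[str, str] | None = None,
        seed_len: int = 24,
    ):
        if not 1 <= seed_len <= 31:
            raise ValueError("seed_len must be in 1..31")
        self.seed_len = seed_len
        # role: "5S"/"45S" for rDNA units, "genome" per chromosome, "repeat"
        self._refs: list[tuple[str, str, str]] = []  # (role, name, seq)
        for label, seq in rdna.items():
            if label not in ("5S", "45S"):
                raise ValueError(f"rDNA labels must be 5S/45S, got {label!r}")
            self._refs.append((label, label, seq))
        for name, seq in genome.items():
            self._refs.append(("genome", name, seq))
        for name, seq in (repeats or {}).items():
            self._refs.append(("repeat", name, seq))

        kmer_blocks, pos_blocks, ref_blocks = [], [], []
        for ref_i, (_, _, seq) in enumerate(self._refs):
            km = _pack_kmers(seq, seed_len)
            kmer_blocks.append(km)
            pos_blocks.append(np.arange(len(km), dtype=np.int64))
            ref_blocks.append(np.full(len(km), ref_i, dtype=np.int32))
        kmers = np.concatenate(kmer_blocks)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = np.concatenate(pos_blocks)[order]
        self._ref_i = np.concatenate(ref_blocks)[order]

    def occurrences(self, read: str) -> list[tuple[str, str, int, str]]:
        """All full-length exact occurrences: (role, name, start, strand)."""
        hits = []
        seen = set()
        for strand, seq in (("+", read), ("-", _revcomp(read))):
            if any(b not in "ACGT" for b in seq[: self.seed_len]):
                continue  # non-ACGT seed cannot match our references
            key = _pack_kmers(seq[: self.seed_len], self.seed_len)[0]
            lo = np.searchsorted(self._kmers, key, side="left")
            hi = np.searchsorted(self._kmers, key, side="right")
            for idx in range(lo, hi):
                ref_i, pos = int(self._ref_i[idx]), int(self._pos[idx])
                role, name, ref = self._refs[ref_i]
                if ref[pos : pos + len(seq)] == seq and (name, pos) not in seen:
                    seen.add((name, pos))
                    hits.append((role, name, pos, strand))
        return hits


def map_end(sequence: str, index: ReferenceIndex) -> MappedEnd:
    """Map one mate by exact unique substring occurrence.

    Repeat-library hits win outright (the mate is to be excluded either
    way).  Otherwise a single occurrence across all references gives a
    unique call; none gives unmapped; several give an ambiguous call.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(sequence) < index.seed_len:
        return MappedEnd(target="unmapped")
    hits = index.occurrences(sequence)
    if any(role == "repeat" for role, *_ in hits):
        return MappedEnd(target="repeat", unique=False)
    if not hits:
        return MappedEnd(target="unmapped")
    if len(hits) > 1:
        role = hits[0][0]
        return MappedEnd(target=role if role in ("5S", "45S") else "genome", unique=False)
    role, name, pos, strand = hits[0]
    if role in ("5S", "45S"):
        return MappedEnd(target=role, chrom=name, start=pos, strand=strand, unique=True)
    return MappedEnd(target="genome", chrom=name, start=pos, strand=strand, unique=True)


@dataclass(frozen=True)
class ContactRecord:
    """A classified pair: rDNA anchor, genomic mate locus and category."""

    array: str | None
    chrom: str | None
    pos: int
    category: str  # rdna_genome | rdna_both | repeat_excluded | non_rdna | ambiguous


def classify_pair(end1: MappedEnd, end2: MappedEnd) -> ContactRecord:
    """Assign a pair to its contact category from the two independent calls.

    (rDNA, unique genome) -> rdna_genome; (rDNA, rDNA) -> rdna_both;
    (rDNA, repeat) -> repeat_excluded; (rDNA, ambiguous or unmapped) ->
    ambiguous; no rDNA end -> non_rdna.
    """
    def is_rdna(e: MappedEnd) -> bool:
        return e.target in ("5S", "45S") and e.unique

    r1, r2 = is_rdna(end1), is_rdna(end2)
    if r1 and r2:
        array = end1.target if end1.target == end2.target else f"{end1.target}|{end2.target}"
        return ContactRecord(array=array, chrom=None, pos=-1, category="rdna_both")
    if r1 or r2:
        anchor, mate = (end1, end2) if r1 else (end2, end1)
        if mate.target == "repeat":
            return ContactRecord(array=anchor.target, chrom=None, pos=-1, category="repeat_excluded")
        if mate.target == "genome" and mate.unique:
            return ContactRecord(
                array=anchor.target, chrom=mate.chrom, pos=mate.start, category="rdna_genome"
            )
        return ContactRecord(array=anchor.target, chrom=None, pos=-1, category="ambiguous")
    return ContactRecord(array=None, chrom=None, pos=-1, category="non_rdna")


def read_fastq_pairs(path1, path2):
    """Yield (name, seq1, quals1, seq2, quals2) from two FASTQ files."""
    from Bio import SeqIO

    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        yield (
            rec1.id.rsplit("/", 1)[0],
            str(rec1.seq),
            rec1.letter_annotations["phred_quality"],
            str(rec2.seq),
            rec2.letter_annotations["phred_quality"],
        )


def mine_pairs(
    pairs: Iterable[tuple[str, str, Iterable[int], str, Iterable[int]]],
    index: ReferenceIndex,
    policy: TrimPolicy = TrimPolicy(),
    dataset: str = "sim",
) -> pd.DataFrame:
    """Trim, map and classify read pairs.

    ``pairs`` yields (name, seq1, quals1, seq2, quals2).  Pairs with a
    discarded mate are recorded as ``qc_failed``.  Returns one row per
    input pair: ``pair``, ``dataset``, ``array``, ``chrom``, ``pos``,
    ``category``.
    """
    rows = []
    for name, s1, q1, s2, q2 in pairs:
        t1 = quality_trim(s1, q1, policy)
        t2 = quality_trim(s2, q2, policy)
        if t1 is None or t2 is None:
            rows.append((name, dataset, None, None, -1, "qc_failed"))
            continue
        rec = classify_pair(map_end(t1[0], index), map_end(t2[0], index))
        rows.append((name, dataset, rec.array, rec.chrom, rec.pos, rec.category))
    return pd.DataFrame(
        rows, columns=["pair", "dataset", "array", "chrom", "pos", "category"]
    )


def summarize_mining(counts: pd.DataFrame, with_sum: bool = True) -> pd.DataFrame:
    """Per-dataset mining bookkeeping with recomputed percentages.

    ``counts`` needs columns ``dataset``, ``total_reads``, ``qc_reads``,
    ``reads_45s``, ``reads_5s`` (see
    :func:`rdnamap.datasets.published_read_counts` for the published
    seven-corpus table).  Derived columns: ``pct_qc`` = 100*qc/total
    (2 decimals), ``pct_45s`` = 100*45S/qc (2 decimals), ``pct_5s`` =
    100*5S/qc (4 decimals).  Zero qc reads give NA percentages.  A SUM
    row aggregates the counts and recomputes its percentages from the
    summed counts.
    """
    df = counts.copy()
    if with_sum:
        total = df[["total_reads", "qc_reads", "reads_45s", "reads_5s"]].sum()
        df = pd.concat(
            [df, pd.DataFrame([{"dataset": "SUM", **total.to_dict()}])],
            ignore_index=True,
        )

    def pct(num, den, digits):
        if den == 0:
            return np.nan
        return round(100.0 * num / den, digits)

    df["pct_qc"] = [pct(q, t, 2) for q, t in zip(df["qc_reads"], df["total_reads"])]
    df["pct_45s"] = [pct(a, q, 2) for a, q in zip(df["reads_45s"], df["qc_reads"])]
    df["pct_5s"] = [pct(a, q, 4) for a, q in zip(df["reads_5s"], df["qc_reads"])]
    return df


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Category tallies per dataset for mined synthetic records."""
    out = (
        records.groupby(["dataset", "category"]).size().unstack(fill_value=0).reset_index()
    )
    out.columns.name = None
    return out
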