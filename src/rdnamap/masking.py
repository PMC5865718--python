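"""rDNA pseudogene detection and bin/gene exclusion.

Reads that map to an rDNA reference could instead derive from an rDNA
pseudogene elsewhere in the genome, so any 1 Mb bin or gene containing
rDNA-similar sequence must be excluded before contact statistics.

Detection is an ungapped seed-and-extend scan: exact 11-mer seeds
between the rDNA unit (both strands) and the genome are extended with
match +1 / mismatch -2 scoring and an X-drop of 10; a hit is reported
when its Karlin-Altschul E-value against the full search space falls
below 1e-4.  Lambda is solved exactly for the scoring scheme under
uniform base composition; K uses the standard ungapped BLASTN value
for +1/-2 (0.621).  Overlapping hits are merged per array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize

from .contactmap import BinScheme

__all__ = [
    "MaskSet",
    "karlin_altschul_lambda",
    "scan_pseudogenes",
    "build_mask",
]

_MATCH = 1
_MISMATCH = -2
_XDROP = 10
_WORD = 11
_K_UNGAPPED = 0.621


@lru_cache(maxsize=None)
def karlin_altschul_lambda(match: int = _MATCH, mismatch: int = _MISMATCH) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform bases.

    With uniform composition the equation is
    0.25*exp(lambda*match) + 0.75*exp(lambda*mismatch) = 1; for +1/-2
    the root is ~1.33.
    """
    f = lambda lam: 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0
    return float(optimize.brentq(f, 1e-6, 10.0))


_ENC = np.zeros(128, dtype=np.int8)
_ENC[ord("C")] = 1
_ENC[ord("G")] = 2
_ENC[ord("T")] = 3


def _codes(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _pack(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | c[j : j + n]
    return out


def _extend(g: np.ndarray, r: np.ndarray, gpos: int, rpos: int) -> tuple[int, int, int]:
    """X-drop ungapped extension of a word match on one diagonal.

    Returns (score, genome_start, genome_end) of the best-scoring
    segment containing the seed.
    """
    score = _WORD * _MATCH
    # right extension
    best = 0
    cur = 0
    gi, ri = gpos + _WORD, rpos + _WORD
    right = 0
    while gi < len(g) and ri < len(r):
        cur += _MATCH if g[gi] == r[ri] else _MISMATCH
        if cur > best:
            best = cur
            right = gi - (gpos + _WORD) + 1
        if best - cur > _XDROP:
            break
        gi += 1
        ri += 1
    score += best
    # left extension
    best = 0
    cur = 0
    gi, ri = gpos - 1, rpos - 1
    left = 0
    while gi >= 0 and ri >= 0:
        cur += _MATCH if g[gi] == r[ri] else _MISMATCH
        if cur > best:
            best = cur
            left = gpos - gi
        if best - cur > _XDROP:
            break
        gi -= 1
        ri -= 1
    score += best
    return score, gpos - left, gpos + _WORD + right


def scan_pseudogenes(
    genome: dict[str, str],
    rdna_ref: str,
    array: str,
    evalue_max: float = 1e-4,
) -> pd.DataFrame:
    """Scan the genome for local rDNA similarity above the E-value cutoff.

    Returns merged, pairwise non-overlapping hits with columns
    ``chrom``, ``start``, ``end`` (0-based half-open), ``array``,
    ``score`` (best segment score within the merged interval) and
    ``evalue``.  Both strands of the rDNA reference are searched.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        return pd.DataFrame(columns=["chrom", "start", "end", "array", "score", "evalue"])
    lam = karlin_altschul_lambda()
    m = sum(len(s) for s in genome.values())
    n = len(rdna_ref)
    search_space = 2.0 * m * n  # both strands
    from .synthio import revcomp

    raw_hits: list[tuple[str, int, int, int]] = []
    for strand_seq in (rdna_ref, revcomp(rdna_ref)):
        r = _codes(strand_seq)
        ref_kmers = _pack(r, _WORD)
        # map word -> ref positions (reference is small)
        order = np.argsort(ref_kmers, kind="stable")
        sorted_ref = ref_kmers[order]
        for chrom, seq in genome.items():
            g = _codes(seq)
            gk = _pack(g, _WORD)
            if len(gk) == 0:
                continue
            cand = np.flatnonzero(np.isin(gk, sorted_ref))
            covered: dict[int, list[tuple[int, int]]] = {}
            for gpos in cand:
                lo = np.searchsorted(sorted_ref, gk[gpos], side="left")
                hi = np.searchsorted(sorted_ref, gk[gpos], side="right")
                for ref_idx in order[lo:hi]:
                    diag = int(gpos) - int(ref_idx)
                    spans = covered.get(diag)
                    if spans and any(s <= gpos < e for s, e in spans):
                        continue
                    score, gstart, gend = _extend(g, r, int(gpos), int(ref_idx))
                    covered.setdefault(diag, []).append((gstart, gend))
                    evalue = _K_UNGAPPED * search_space * np.exp(-lam * score)
                    if evalue < evalue_max:
                        raw_hits.append((chrom, gstart, gend, score))

    if not raw_hits:
        return pd.DataFrame(columns=["chrom", "start", "end", "array", "score", "evalue"])
    hits = pd.DataFrame(raw_hits, columns=["chrom", "start", "end", "score"])
    merged_rows = []
    for chrom, grp in hits.groupby("chrom"):
        grp = grp.sort_values(["start", "end"])
        cur_s, cur_e, cur_score = None, None, 0
        for _, row in grp.iterrows():
            if cur_s is None or row.start > cur_e:
                if cur_s is not None:
                    merged_rows.append((chrom, cur_s, cur_e, cur_score))
                cur_s, cur_e, cur_score = int(row.start), int(row.end), int(row.score)
            else:
                cur_e = max(cur_e, int(row.end))
                cur_score = max(cur_score, int(row.score))
        merged_rows.append((chrom, cur_s, cur_e, cur_score))
    out = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "score"])
    out["array"] = array
    out["evalue"] = _K_UNGAPPED * search_space * np.exp(-lam * out["score"])
    return out[["chrom", "start", "end", "array", "score", "evalue"]].sort_values(
        ["chrom", "start"], ignore_index=True
    )


@dataclass
class MaskSet:
    """Bins and genes excluded per rDNA array."""

    excluded_bins: dict[str, set[int]] = field(default_factory=dict)
    excluded_genes: dict[str, set[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("bin", array, str(b))
            for array, bins in self.excluded_bins.items()
            for b in sorted(bins)
        ] + [
            ("gene", array, g)
            for array, genes in self.excluded_genes.items()
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["feature_type", "array", "feature_id"])


def build_mask(
    hits: pd.DataFrame,
    scheme: BinScheme | None = None,
    genes: pd.DataFrame | None = None,
) -> MaskSet:
    """Exclude every bin/gene overlapping a pseudogene hit by >= 1 bp.

    ``genes`` needs ``gene_id``, ``chrom``, ``start``, ``end`` (gene
    spans; introns count, so a hit anywhere inside the span excludes
    the gene).
    """
    mask = MaskSet()
    if hits is None or len(hits) == 0:
        return mask
    for array, grp in hits.groupby("array"):
        excluded_bins: set[int] = set()
        excluded_genes: set[str] = set()
        if scheme is not None:
            bins = scheme.bins
            for _, h in grp.iterrows():
                sel = (
                    (bins["chrom"] == h.chrom)
                    & (bins["start"] < h.end)
                    & (bins["end"] > h.start)
                )
                excluded_bins.update(bins.loc[sel, "bin_id"].tolist())
        if genes is not None and len(genes):
            spans = genes.drop_duplicates("gene_id")
            for _, h in grp.iterrows():
                sel = (
                    (spans["chrom"] == h.chrom)
                    & (spans["start"] < h.end)
                    & (spans["end"] > h.start)
                )
                excluded_genes.update(spans.loc[sel, "gene_id"].tolist())
        mask.excluded_bins[array] = excluded_bins
        mask.excluded_genes[array] = excluded_genes
    return mask
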