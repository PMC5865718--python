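"""Observed vs expected rDNA contacts in annotated genomic segments.

Annotation tracks (A/B compartments, ChromHMM chromatin states,
replication timing classes, CTCF binding segments) are BED-style
interval sets with a state label.  For each state the observed number
of rDNA-genome contacts whose genomic mate falls inside the state's
(merged) intervals is compared with the expectation from a uniform
per-nucleotide contact rate: expected = rate x merged state length.
Significance comes from a chi-square goodness-of-fit on the in/out
split and a one-proportion test (exact binomial for modest totals,
normal approximation with continuity correction for large ones).
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import stats

from .contactmap import RateEstimate

__all__ = [
    "read_track",
    "merge_intervals",
    "observed_in_track",
    "expected_in_track",
    "enrichment_test",
    "enrich_track",
]

_ONE_PROP_EXACT_MAX = 10_000


def read_track(bed_path, label: str | None = None) -> pd.DataFrame:
    """Load a BED track; 4th column (or ``label``) is the state."""
    df = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "state"]
    else:
        df = df.iloc[:, :3]
        df.columns = ["chrom", "start", "end"]
        df["state"] = label or "track"
    return df


def merge_intervals(track: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals within each (state, chrom)."""
    rows = []
    for (state, chrom), grp in track.groupby(["state", "chrom"]):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if e <= s:
                raise ValueError(f"interval with end <= start in state {state!r}")
            if cur_s is None or s > cur_e:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, state))
                cur_s, cur_e = int(s), int(e)
            else:
                cur_e = max(cur_e, int(e))
        rows.append((chrom, cur_s, cur_e, state))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def _state_lengths(merged: pd.DataFrame) -> pd.Series:
    return (merged["end"] - merged["start"]).groupby(merged["state"]).sum()


def observed_in_track(records: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Count records whose mate position lies inside each state.

    Intervals are merged per state first so overlapping records of the
    same state are not double counted.  Half-open convention: a record
    at the exact end coordinate of an interval is outside it.  Returns
    per-state ``observed`` plus ``fraction`` of all records.
    """
    rec = records[records["category"] == "rdna_genome"]
    merged = merge_intervals(track)
    n_total = len(rec)
    rows = []
    for state, grp in merged.groupby("state"):
        n_in = 0
        for chrom, ivals in grp.groupby("chrom"):
            pos = rec.loc[rec["chrom"] == chrom, "pos"].to_numpy()
            if len(pos) == 0:
                continue
            starts = np.sort(ivals["start"].to_numpy())
            ends = ivals.sort_values("start")["end"].to_numpy()
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            n_in += int(inside.sum())
        rows.append((state, n_in, n_in / n_total if n_total else np.nan))
    return pd.DataFrame(rows, columns=["state", "observed", "fraction"])


def expected_in_track(rate: RateEstimate | float, track: pd.DataFrame,
                      rate_source: str = "genomewide") -> pd.DataFrame:
    """Expected contacts per state from a per-nucleotide rate.

    ``rate_source`` selects which estimator feeds the expectation:
    ``genomewide`` (default) or ``masked_bins``.  Zero-length states
    get expected 0 and are excluded from testing downstream.
    """
    if isinstance(rate, RateEstimate):
        r = rate.rate_genomewide if rate_source == "genomewide" else rate.rate_masked_bins
    else:
        r = float(rate)
    merged = merge_intervals(track)
    lengths = _state_lengths(merged)
    return pd.DataFrame(
        {"state": lengths.index, "length": lengths.to_numpy(),
         "expected": r * lengths.to_numpy()}
    ).reset_index(drop=True)


def enrichment_test(observed: int, expected: float, n_total: int) -> tuple[float, float]:
    """Chi-square GOF p and one-proportion p for one state.

    The in/out-of-state split of ``n_total`` records is compared with
    the expected proportion ``expected / n_total``.  The one-proportion
    test is the exact two-sided binomial for n_total <= 10,000, else a
    normal approximation with continuity correction.
    """
    if n_total < observed:
        raise ValueError("n_total must be >= observed")
    p0 = expected / n_total
    if not 0 < p0 < 1:
        raise ValueError("expected proportion must lie strictly in (0, 1)")
    chi_p = float(
        stats.chisquare(
            [observed, n_total - observed],
            f_exp=[expected, n_total - expected],
        ).pvalue
    )
    if n_total <= _ONE_PROP_EXACT_MAX:
        prop_p = float(stats.binomtest(observed, n_total, p0).pvalue)
    else:
        sd = np.sqrt(n_total * p0 * (1 - p0))
        z = (abs(observed - n_total * p0) - 0.5) / sd
        prop_p = float(2.0 * stats.norm.sf(max(z, 0.0)))
    return chi_p, min(prop_p, 1.0)


def enrich_track(
    records: pd.DataFrame,
    track: pd.DataFrame,
    rate: RateEstimate | float,
    rate_source: str = "genomewide",
) -> pd.DataFrame:
    """Observed/expected table with enrichment tests per state.

    Combines :func:`observed_in_track`, :func:`expected_in_track` and
    :func:`enrichment_test`; states with zero expected counts are kept
    in the table but carry NA p-values.
    """
    obs = observed_in_track(records, track)
    exp = expected_in_track(rate, track, rate_source=rate_source)
    out = obs.merge(exp, on="state")
    n_total = int((records["category"] == "rdna_genome").sum())
    ratios, chi_ps, prop_ps = [], [], []
    for _, row in out.iterrows():
        ratios.append(row.observed / row.expected if row.expected > 0 else np.nan)
        if row.expected <= 0 or row.expected >= n_total:
            chi_ps.append(np.nan)
            prop_ps.append(np.nan)
        else:
            c, p = enrichment_test(int(row.observed), float(row.expected), n_total)
            chi_ps.append(c)
            prop_ps.append(p)
    out["ratio"] = ratios
    out["chi2_p"] = chi_ps
    out["one_prop_p"] = prop_ps
    return out
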