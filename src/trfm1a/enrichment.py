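"""RIP-vs-input enrichment statistics and the two-antibody m1A call.

Enrichment of a small-RNA group in an immunoprecipitated library over its
input is scored by a two-sided binomial test of the RIP count against the
combined count, with the null proportion set by relative library sizes,
followed by Benjamini-Hochberg adjustment.  This is a deliberate
simplification appropriate for Poisson-like counts without biological
overdispersion; candidate thresholds default to padj < 0.1 with at least
10 combined reads.

A group is called an m1A candidate only when it is significantly enriched
in EVERY antibody arm, not in the IgG control arm, and shows independent
misincorporation evidence (a defined mismatch index above background at
at least one annotated site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_COUNT = 10
DEFAULT_PADJ_CUT = 0.1
#: stricter cut used for volcano-style colored calls
STRICT_PADJ_CUT = 1e-5
#: mismatch% a site must exceed to count as misincorporation evidence
MISMATCH_EVIDENCE_PCT = 10.0


@dataclass
class EnrichmentRecord:
    key: str
    input_count: float
    rip_count: float
    input_rpm: float
    rip_rpm: float
    log2fe: float
    p: Optional[float] = None
    padj: Optional[float] = None
    meets_min_count: bool = True


def log2_fold_enrichment(input_count: float, rip_count: float,
                         input_lib_size: float, rip_lib_size: float,
                         pseudocount: float = 0.5) -> float:
    """log2((RIP RPM + psi) / (input RPM + psi)), psi in RPM units.

    When counts are already spike-in normalized frequencies, pass the
    spike-in totals as the library sizes; the ratio is then on the
    spike-in scale instead of RPM.
    """
    if input_lib_size <= 0 or rip_lib_size <= 0:
        raise ValueError("library sizes must be positive")
    input_rpm = 1e6 * input_count / input_lib_size
    rip_rpm = 1e6 * rip_count / rip_lib_size
    return float(np.log2((rip_rpm + pseudocount) / (input_rpm + pseudocount)))


def enrichment_test(input_count: float, rip_count: float,
                    input_lib_size: float, rip_lib_size: float,
                    min_count: int = MIN_COUNT) -> Optional[float]:
    """Two-sided binomial test of the RIP count against library proportion.

    Tests k = round(rip) successes of n = round(rip + input) trials at
    p0 = rip_lib / (rip_lib + input_lib).  Returns None (excluded) when
    the combined count is below ``min_count``.
    """
    k = int(round(rip_count))
    n = int(round(rip_count + input_count))
    if n < min_count:
        return None
    p0 = rip_lib_size / (rip_lib_size + input_lib_size)
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone), NaN-tolerant."""
    p = np.asarray(p_values, float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def enrichment_table(input_counts: Mapping[str, float],
                     rip_counts: Mapping[str, float],
                     input_lib_size: Optional[float] = None,
                     rip_lib_size: Optional[float] = None,
                     pseudocount: float = 0.5,
                     min_count: int = MIN_COUNT) -> pd.DataFrame:
    """Per-group enrichment records with BH-adjusted binomial p-values."""
    keys = sorted(set(input_counts) | set(rip_counts))
    in_lib = input_lib_size or sum(input_counts.values())
    rip_lib = rip_lib_size or sum(rip_counts.values())
    rows = []
    for key in keys:
        ic = float(input_counts.get(key, 0.0))
        rc = float(rip_counts.get(key, 0.0))
        p = enrichment_test(ic, rc, in_lib, rip_lib, min_count)
        rows.append(dict(
            key=key, input_count=ic, rip_count=rc,
            input_rpm=1e6 * ic / in_lib, rip_rpm=1e6 * rc / rip_lib,
            log2fe=log2_fold_enrichment(ic, rc, in_lib, rip_lib, pseudocount),
            p=p, meets_min_count=p is not None))
    df = pd.DataFrame(rows)
    df["padj"] = adjust_bh(df["p"].to_numpy(float))
    return df


def class_enrichment_comparison(log2fe_by_class: Mapping[str, Sequence[float]],
                                reference_class: str = "miR",
                                min_members: int = 3) -> pd.DataFrame:
    """Two-sided rank-sum p for each class's log2FE against the miRNA class.

    Uses the Mann-Whitney U statistic with exact small-sample p where
    possible and the tie-corrected normal approximation otherwise.
    Classes with fewer than ``min_members`` values are skipped with a note.
    """
    ref_vals = np.asarray(log2fe_by_class.get(reference_class, []), float)
    rows = []
    for cls in sorted(log2fe_by_class):
        if cls == reference_class:
            continue
        vals = np.asarray(log2fe_by_class[cls], float)
        if len(vals) < min_members or len(ref_vals) < min_members:
            rows.append(dict(trf_class=cls, n=len(vals), median_log2fe=np.nan,
                             p=np.nan, note=f"fewer than {min_members} members"))
            continue
        res = stats.mannwhitneyu(vals, ref_vals, alternative="two-sided",
                                 method="auto")
        rows.append(dict(trf_class=cls, n=len(vals),
                         median_log2fe=float(np.median(vals)),
                         p=float(res.pvalue), note=""))
    return pd.DataFrame(rows)


@dataclass
class CandidateCall:
    key: str
    enriched_by_antibody: dict[str, bool]
    enriched_by_igg: bool
    has_site_mismatch: bool
    verdict: str  # candidate | antibody-only | mismatch-only | negative


def call_m1a_candidates(antibody_tables: Mapping[str, pd.DataFrame],
                        igg_table: Optional[pd.DataFrame],
                        site_mismatch: Mapping[str, float],
                        padj_cut: float = DEFAULT_PADJ_CUT,
                        mismatch_cut: float = MISMATCH_EVIDENCE_PCT
                        ) -> list[CandidateCall]:
    """Intersection call over antibody arms, IgG control and mismatch evidence.

    ``antibody_tables`` maps antibody name -> enrichment table (from
    :func:`enrichment_table`); ``site_mismatch`` maps group key -> best
    defined mismatch index (percent) over that group's annotated sites
    (missing/undefined keys count as no evidence).

    verdict == candidate requires padj < cut AND log2FE > 0 in every
    antibody arm, no significant IgG enrichment, and site mismatch above
    ``mismatch_cut``.
    """
    if not antibody_tables:
        raise ValueError("at least one antibody arm is required")

    def enriched(df: pd.DataFrame, key: str) -> bool:
        row = df.loc[df.key == key]
        if row.empty:
            return False
        r = row.iloc[0]
        return bool(r.padj is not None and np.isfinite(r.padj)
                    and r.padj < padj_cut and r.log2fe > 0)

    keys = sorted(set().union(*(set(t.key) for t in antibody_tables.values())))
    calls = []
    for key in keys:
        by_ab = {ab: enriched(t, key) for ab, t in antibody_tables.items()}
        by_igg = enriched(igg_table, key) if igg_table is not None else False
        mm = site_mismatch.get(key)
        has_mm = mm is not None and mm > mismatch_cut
        all_ab = all(by_ab.values())
        if all_ab and not by_igg and has_mm:
            verdict = "candidate"
        elif all_ab and not by_igg:
            verdict = "antibody-only"
        elif has_mm and not all_ab:
            verdict = "mismatch-only"
        else:
            verdict = "negative"
        calls.append(CandidateCall(key, by_ab, by_igg, has_mm, verdict))
    return calls


def calls_to_frame(calls: Sequence[CandidateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = dict(key=c.key, enriched_by_igg=c.enriched_by_igg,
                   has_site_mismatch=c.has_site_mismatch, verdict=c.verdict)
        for ab, flag in c.enriched_by_antibody.items():
            row[f"enriched_{ab}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
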