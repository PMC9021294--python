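"""Seed families, 3' UTR target-site scanning, and repression analysis.

The seed of a guide RNA is its nucleotides 2-8 (7 nt).  Target sites on
an mRNA 3' UTR follow the canonical microRNA-target taxonomy: with
``core7`` the reverse complement of guide positions 2-8 and ``core6``
that of positions 2-7, a site is

* 8mer-A1 — core7 immediately followed by an A (the adenosine opposite
  guide position 1),
* 7mer-m8 — core7 not followed by an A,
* 7mer-A1 — core6 followed by an A, not part of a core7 match,
* 6mer — core6 alone, qualifying for no higher type.

Each occurrence resolves to its single highest type; a gene is labeled by
the highest-rank type over its occurrences.  Repression of target classes
relative to non-targets is scored on non-target-median-centered log2
fold changes by a one-sided two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

SITE_TYPE_RANK = ["8mer-A1", "7mer-m8", "7mer-A1", "6mer"]
_RANK = {t: i for i, t in enumerate(SITE_TYPE_RANK)}

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_seed(guide_sequence: str) -> str:
    """Guide positions 2-8 (7 nt), DNA alphabet."""
    if len(guide_sequence) < 8:
        raise ValueError(
            f"guide of length {len(guide_sequence)} has no 2-8 seed")
    return guide_sequence[1:8]


@dataclass
class SeedFamily:
    seed: str
    members: dict[str, float]      # guide sequence -> Ago-bound read count
    coverage_share: float
    m1a_response: Optional[float] = None  # log2FC of member mismatch on knockdown


def cluster_seeds(ago_bound_counts: Mapping[str, float],
                  coverage_threshold: float = 0.90
                  ) -> tuple[list[SeedFamily], int]:
    """Group guides by identical 2-8 seed; share of Ago-bound reads each.

    Returns families sorted by descending coverage share, plus the minimal
    number of seeds whose cumulative share exceeds ``coverage_threshold``
    (0 for an empty input).
    """
    total = sum(ago_bound_counts.values())
    if total <= 0:
        return [], 0
    groups: dict[str, dict[str, float]] = {}
    for guide, n in ago_bound_counts.items():
        groups.setdefault(extract_seed(guide), {})[guide] = n
    families = [SeedFamily(seed, members, sum(members.values()) / total)
                for seed, members in groups.items()]
    families.sort(key=lambda f: (-f.coverage_share, f.seed))
    cum, k = 0.0, 0
    for f in families:
        k += 1
        cum += f.coverage_share
        if cum >= coverage_threshold - 1e-12:
            break
    return families, k


@dataclass(frozen=True)
class TargetSite:
    gene: str
    utr_position: int  # 1-based start of the site on the UTR
    site_type: str
    seed: str


def scan_utr(seed: str, utr: str, gene: str = "") -> list[TargetSite]:
    """All seed-match sites in a 3' UTR, each at its highest type.

    The UTR alphabet is A/C/G/T/N; N never matches.  A core6 occurrence
    preceded by the complement of guide position 8 is part of a core7
    match and is typed at the core7 locus (8mer-A1 or 7mer-m8); otherwise
    it is typed at its own locus (7mer-A1 or 6mer) by the presence of the
    A1-opposite adenosine.
    """
    if len(seed) != 7:
        raise ValueError("seed must be 7 nt (guide positions 2-8)")
    core7 = _revcomp(seed)
    core6 = _revcomp(seed[:6])
    m8_base = core7[0]
    sites = []
    for j in range(len(utr) - 6 + 1):
        if utr[j:j + 6] != core6:
            continue
        in_core7 = j >= 1 and utr[j - 1] == m8_base
        a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if in_core7:
            site_type = "8mer-A1" if a1 else "7mer-m8"
            start = j  # core7 begins one base 5' of core6; 1-based = j
        else:
            site_type = "7mer-A1" if a1 else "6mer"
            start = j + 1
        sites.append(TargetSite(gene, start, site_type, seed))
    return sites


@dataclass(frozen=True)
class TargetGene:
    gene: str
    best_type: str
    site_count: int

    @property
    def multi_site(self) -> bool:
        return self.site_count > 1


def classify_gene_targets(sites_by_gene: Mapping[str, Sequence[TargetSite]],
                          expression: pd.DataFrame,
                          genes_with_utr: Optional[set] = None,
                          min_expr: float = 100.0
                          ) -> tuple[list[TargetGene], list[str]]:
    """Label expressed genes by their best site type; return non-targets too.

    Genes without a 3' UTR sequence or with baseMean <= ``min_expr``
    (strictly higher than the cutoff is required) are excluded entirely
    — they are neither targets nor non-targets.
    """
    if expression["gene"].duplicated().any():
        dupes = expression.loc[expression["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids in expression table: {dupes[:5]}")
    if genes_with_utr is None:
        genes_with_utr = set(sites_by_gene)
    targets, non_targets = [], []
    for _, row in expression.iterrows():
        g = row["gene"]
        if g not in genes_with_utr or row["baseMean"] <= min_expr:
            continue
        sites = sites_by_gene.get(g, [])
        if sites:
            best = min(sites, key=lambda s: _RANK[s.site_type]).site_type
            targets.append(TargetGene(g, best, len(sites)))
        else:
            non_targets.append(g)
    return targets, non_targets


@dataclass
class RepressionResult:
    direction: str
    center: float                                # non-target median log2FC
    classes: pd.DataFrame                        # class, n, ks_stat, p
    centered_values: dict[str, np.ndarray] = field(default_factory=dict)

    def ecdf_table(self, cls: str) -> pd.DataFrame:
        v = np.sort(self.centered_values[cls])
        return pd.DataFrame({"log2FC_centered": v,
                             "ecdf": np.arange(1, len(v) + 1) / len(v)})


def repression_analysis(target_genes: Sequence[TargetGene],
                        non_targets: Sequence[str],
                        log2fc: Union[Mapping[str, float], pd.DataFrame],
                        direction: str = "repressed",
                        min_n: int = 10) -> RepressionResult:
    """Centered-CDF comparison of each target class against non-targets.

    All log2FC values are shifted by minus the non-target median (so the
    non-target centered median is exactly 0).  Each class with at least
    ``min_n`` genes is compared to non-targets by a one-sided two-sample
    Kolmogorov-Smirnov test with the alternative that the class is
    shifted in ``direction`` (``repressed`` = toward lower log2FC,
    ``derepressed`` = toward higher); smaller classes report p = NA.
    """
    if direction not in ("repressed", "derepressed"):
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(log2fc, pd.DataFrame):
        log2fc = dict(zip(log2fc["gene"], log2fc["log2FC"]))
    nt_vals = np.asarray([log2fc[g] for g in non_targets], float)
    if len(nt_vals) < min_n:
        raise ValueError(f"need at least {min_n} non-target genes")
    center = float(np.median(nt_vals))
    nt_centered = nt_vals - center
    by_class: dict[str, list[float]] = {t: [] for t in SITE_TYPE_RANK}
    for tg in target_genes:
        by_class[tg.best_type].append(log2fc[tg.gene] - center)
    # a class shifted to smaller values has the stochastically greater ECDF
    alternative = "greater" if direction == "repressed" else "less"
    rows = []
    values = {"non-target": nt_centered}
    for cls in SITE_TYPE_RANK:
        vals = np.asarray(by_class[cls], float)
        values[cls] = vals
        if len(vals) < min_n:
            rows.append(dict(site_type=cls, n=len(vals), ks_stat=np.nan, p=np.nan))
            continue
        res = stats.ks_2samp(vals, nt_centered, alternative=alternative)
        rows.append(dict(site_type=cls, n=len(vals),
                         ks_stat=float(res.statistic), p=float(res.pvalue)))
    rows.append(dict(site_type="non-target", n=len(nt_centered),
                     ks_stat=np.nan, p=np.nan))
    return RepressionResult(direction, center, pd.DataFrame(rows), values)


def seed_overlap_with_mirnas(seed: str,
                             mirna_counts: Mapping[str, tuple[str, float]],
                             min_count: float = 10.0) -> bool:
    """True iff the seed equals the 2-8 seed of an expressed miRNA.

    ``mirna_counts`` maps miRNA name -> (sequence, read count); only
    miRNAs with count strictly above ``min_count`` qualify.
    """
    for _, (mir_seq, count) in mirna_counts.items():
        if count > min_count and len(mir_seq) >= 8 and extract_seed(mir_seq) == seed:
            return True
    return False
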