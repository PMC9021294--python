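"""Per-position mismatch pileups and the mismatch index.

The mismatch index at a position is the percentage of reads carrying any
non-reference base there, defined only when fractional coverage exceeds a
minimum read count (default 50; strictly greater).  Fractional
multi-mapping weights flow into pileups, consistent with the counting
rule.  Soft-clipped (non-templated tail) bases are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from trfm1a.core import frag_to_mature_coord  # noqa: F401  (re-exported frame math)
from trfm1a.annotate import AlignedRead

#: coverage must strictly exceed this for an index to be defined
MIN_READS = 50


@dataclass
class MismatchProfile:
    """Weighted per-position coverage and substitution counts for a group."""

    group: str
    frame: str  # "fragment" | "mature"
    coverage: dict[int, float] = field(default_factory=dict)
    subs: dict[int, dict[str, float]] = field(default_factory=dict)
    subs_from_a: dict[int, float] = field(default_factory=dict)

    def positions(self) -> list[int]:
        return sorted(self.coverage)

    def total_subs(self, position: int) -> float:
        return sum(self.subs.get(position, {}).values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions():
            cov = self.coverage[pos]
            s = self.subs.get(pos, {})
            idx = mismatch_index(self, pos)
            rows.append(dict(group=self.group, frame=self.frame, position=pos,
                             coverage=cov, subA=s.get("A", 0.0), subC=s.get("C", 0.0),
                             subG=s.get("G", 0.0), subT=s.get("T", 0.0),
                             mismatch_index=idx.value))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MismatchIndex:
    position: int
    value: Optional[float]  # percent in [0, 100]; None when coverage too low
    coverage: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def _matches_group(hit, group_key: Union[str, Mapping[str, Optional[str]]]) -> bool:
    if isinstance(group_key, str):
        return hit.reference == group_key
    a = hit.annotation
    if a is None:
        return False
    for field_name, want in group_key.items():
        if want is not None and getattr(a, field_name) != want:
            return False
    return True


def pileup(aligned: list[AlignedRead],
           group_key: Union[str, Mapping[str, Optional[str]]],
           frame: str = "fragment") -> MismatchProfile:
    """Build a weighted per-position pileup for one fragment group.

    ``group_key`` is either a reference name or a mapping over
    :class:`~trfm1a.core.FragmentAnnotation` fields (``parent``,
    ``trf_class``, ``size_isoform``); ``None`` values are wildcards, so
    ``{"parent": None, "trf_class": "tRF-3", "size_isoform": "3b"}`` pools
    tRF-3b reads across all parental tRNAs.

    In the ``fragment`` frame positions are 1-based on the fragment; in
    the ``mature`` frame they are mapped onto the parental reference
    (position = hit start + read offset).  Multi-hit reads contribute
    their per-hit fractional weight to each hit's profile.
    """
    if frame not in ("fragment", "mature"):
        raise ValueError(f"unknown frame {frame!r}")
    name = group_key if isinstance(group_key, str) else "/".join(
        str(v) for v in group_key.values() if v is not None)
    prof = MismatchProfile(name, frame)
    for ar in aligned:
        if ar.status != "mapped":
            continue
        for h in ar.hits:
            if not _matches_group(h, group_key):
                continue
            w = h.weight * ar.count
            alen = len(ar.sequence) - h.clip
            off = h.start - 1 if frame == "mature" else 0
            for rp in range(1, alen + 1):
                prof.coverage[off + rp] = prof.coverage.get(off + rp, 0.0) + w
            for rp, ref_base, read_base in h.substitutions:
                pos = off + rp
                prof.subs.setdefault(pos, {})
                prof.subs[pos][read_base] = prof.subs[pos].get(read_base, 0.0) + w
                if ref_base == "A":
                    prof.subs_from_a[pos] = prof.subs_from_a.get(pos, 0.0) + w
    return prof


def mismatch_index(profile: MismatchProfile, position: int,
                   min_reads: float = MIN_READS) -> MismatchIndex:
    """Percent of reads with a non-reference base at ``position``.

    Undefined (``value=None``), not zero, when coverage <= ``min_reads``.
    """
    cov = profile.coverage.get(position, 0.0)
    if cov <= min_reads:
        return MismatchIndex(position, None, cov)
    return MismatchIndex(position, 100.0 * profile.total_subs(position) / cov, cov)


def index_profile(profile: MismatchProfile,
                  min_reads: float = MIN_READS) -> dict[int, MismatchIndex]:
    return {pos: mismatch_index(profile, pos, min_reads) for pos in profile.positions()}


def peak_position(profile: MismatchProfile,
                  min_reads: float = MIN_READS) -> Optional[int]:
    """Position of the maximal defined mismatch index (ties -> smallest)."""
    best, best_val = None, -1.0
    for pos, idx in sorted(index_profile(profile, min_reads).items()):
        if idx.defined and idx.value > best_val:
            best, best_val = pos, idx.value
    return best


@dataclass(frozen=True)
class Spectrum:
    to_c: float
    to_g: float
    to_t: float
    empty: bool


def substitution_spectrum(profile: MismatchProfile, position: int) -> Spectrum:
    """Fractions of substitutions to C/G/T at a position (sum to 1 if any)."""
    s = profile.subs.get(position, {})
    total = s.get("C", 0.0) + s.get("G", 0.0) + s.get("T", 0.0)
    if total == 0:
        return Spectrum(0.0, 0.0, 0.0, True)
    return Spectrum(s.get("C", 0.0) / total, s.get("G", 0.0) / total,
                    s.get("T", 0.0) / total, False)


def a_site_share(profile: MismatchProfile) -> float:
    """Share of all mismatches that occur at reference-A positions."""
    total = sum(profile.total_subs(p) for p in profile.subs)
    if total == 0:
        return float("nan")
    return sum(profile.subs_from_a.values()) / total


def normalized_mismatch_index(value: float) -> float:
    """Mismatch% over non-mismatch%: ``value / (100 - value)``."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"mismatch percent {value} outside [0, 100]")
    if value == 100.0:
        return math.inf
    return value / (100.0 - value)


@dataclass(frozen=True)
class MismatchComparison:
    delta: Optional[float]     # percentage-point difference A - B
    log2fc: Optional[float]    # log2 fold change of the mismatch rate
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.delta is not None


def compare_mismatch(profile_a: MismatchProfile, profile_b: MismatchProfile,
                     position: int, pseudocount: float = 0.1,
                     min_reads: float = MIN_READS) -> MismatchComparison:
    """Difference and log2 fold change of mismatch rates between conditions.

    ``log2fc = log2((mA + psi) / (mB + psi))`` on the percent scale, with
    ``psi`` in percentage points.  Undefined coverage in either profile
    propagates an undefined result with the reason named.
    """
    ia = mismatch_index(profile_a, position, min_reads)
    ib = mismatch_index(profile_b, position, min_reads)
    if not ia.defined or not ib.defined:
        which = []
        if not ia.defined:
            which.append(f"A (coverage {ia.coverage:.1f})")
        if not ib.defined:
            which.append(f"B (coverage {ib.coverage:.1f})")
        return MismatchComparison(None, None,
                                  "coverage <= min_reads in " + " and ".join(which))
    log2fc = float(np.log2((ia.value + pseudocount) / (ib.value + pseudocount)))
    return MismatchComparison(ia.value - ib.value, log2fc)


def site_report(profiles: Mapping[str, MismatchProfile], sites,
                min_reads: float = MIN_READS) -> pd.DataFrame:
    """Mismatch indices at annotated modification sites (mature frame)."""
    rows = []
    for site in sites:
        prof = profiles.get(site.reference)
        if prof is None:
            continue
        idx = mismatch_index(prof, site.position, min_reads)
        rows.append(dict(reference=site.reference, position=site.position,
                         modification=site.modification, coverage=idx.coverage,
                         mismatch_index=idx.value, defined=idx.defined))
    return pd.DataFrame(rows)
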