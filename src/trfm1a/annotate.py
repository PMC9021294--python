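"""Hierarchical mismatch-tolerant read mapping and tRF classification.

Reads are searched against reference categories in priority order —
miRNAs first, then tRNA space (mature tRNAs + precursor trailers), then
spike-ins — and a read with any hit in an earlier category is never
searched in later ones.  miRNA mapping tolerates up to 2 non-templated
3' nucleotides plus 1 internal mismatch; tRNA-space and spike-in mapping
tolerate 1 mismatch and no indels.  Multi-mapping reads are counted as
equal fractions over their surviving hits to avoid duplicate counts.

The reference space is tiny (a few kb), so alignment uses a transparent
in-memory k-mer index with pigeonhole candidate generation rather than a
genome aligner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from trfm1a.core import (
    HALVES_CUTOFF,
    TRF3A_LENGTH,
    TRF3B_LENGTH,
    FragmentAnnotation,
    ReferenceSet,
)


class ClassificationError(ValueError):
    """Raised when a hit cannot be classified in tRNA space."""


@dataclass(frozen=True)
class MappingPolicy:
    """Category priority and mismatch budgets for hierarchical mapping."""

    order: tuple[str, ...] = ("miRNA", "tRNA", "spikeIn")
    mir_max_internal_mismatch: int = 1
    mir_max_nontemplated_3p: int = 2
    trf_max_mismatch: int = 1
    min_read_len: int = 15
    max_read_len: int = 50

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("category order must be non-empty")
        if min(self.mir_max_internal_mismatch, self.mir_max_nontemplated_3p,
               self.trf_max_mismatch) < 0:
            raise ValueError("mismatch/tail limits must be non-negative")


@dataclass
class Hit:
    """One alignment of a read to a reference, 1-based start."""

    reference: str
    start: int
    mismatch_positions: list[int]            # 1-based read coordinates
    substitutions: list[tuple[int, str, str]]  # (read pos, ref base, read base)
    clip: int = 0                            # non-templated 3' tail length
    weight: float = 1.0
    annotation: Optional[FragmentAnnotation] = None


@dataclass
class AlignedRead:
    sequence: str
    count: int = 1
    category: Optional[str] = None           # None = unmapped or length-filtered
    hits: list[Hit] = field(default_factory=list)
    status: str = "mapped"                   # mapped | unmapped | length_filtered


class SubstringIndex:
    """Exact-occurrence k-mer index over all references.

    ``lookup(pattern)`` returns every (reference, 0-based offset) where the
    pattern occurs exactly, in O(len + occurrences) via a fixed-k seed
    table plus verification.
    """

    def __init__(self, ref: ReferenceSet, k0: int = 6):
        names = ref.all_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate reference names")
        self.ref = ref
        self.k0 = k0
        self.names: list[str] = []
        self.seqs: list[str] = []
        self.search_category: list[str] = []
        for name in names:
            cat = ref.category(name)
            self.names.append(name)
            self.seqs.append(ref.sequence(name))
            # trailers belong to the tRNA search space
            self.search_category.append("tRNA" if cat in ("tRNA", "trailer") else cat)
        self._table: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(self.seqs):
            for i in range(len(seq) - k0 + 1):
                self._table.setdefault(seq[i:i + k0], []).append((idx, i))

    def lookup(self, pattern: str) -> list[tuple[int, int]]:
        if len(pattern) < self.k0:
            raise ValueError(f"pattern shorter than index k ({self.k0})")
        out = []
        for idx, i in self._table.get(pattern[:self.k0], ()):
            if self.seqs[idx][i:i + len(pattern)] == pattern:
                out.append((idx, i))
        return out

    def lookup_names(self, pattern: str) -> list[tuple[str, int]]:
        return [(self.names[i], pos) for i, pos in self.lookup(pattern)]


def build_index(ref: ReferenceSet, k0: int = 6) -> SubstringIndex:
    return SubstringIndex(ref, k0)


def _hamming_hits(index: SubstringIndex, s: str, category: str, max_mm: int
                  ) -> list[tuple[int, int, list[int]]]:
    """All (ref idx, 0-based start, 0-based mismatch offsets) with <= max_mm.

    Pigeonhole: with at most one mismatch budget per half, at least one
    half of the read matches exactly, so exact lookups of both halves
    enumerate every candidate placement.
    """
    m = len(s) // 2
    cands = set()
    for idx, pos in index.lookup(s[:m]):
        cands.add((idx, pos))
    for idx, pos in index.lookup(s[m:]):
        cands.add((idx, pos - m))
    out = []
    for idx, start in sorted(cands):
        if index.search_category[idx] != category:
            continue
        refseq = index.seqs[idx]
        if start < 0 or start + len(s) > len(refseq):
            continue
        mm = []
        ok = True
        for i, (a, b) in enumerate(zip(s, refseq[start:start + len(s)])):
            if a != b:
                mm.append(i)
                if len(mm) > max_mm:
                    ok = False
                    break
        if ok:
            out.append((idx, start, mm))
    return out


def align_read(sequence: str, index: SubstringIndex, policy: MappingPolicy,
               count: int = 1) -> AlignedRead:
    """Align one (collapsed) read following the category priority order.

    Hits are all placements within the category's mismatch budget; for the
    miRNA category up to ``mir_max_nontemplated_3p`` terminal 3' bases may
    be soft-clipped (the minimal sufficient clip is reported, and clipped
    bases never count as mismatches).  Fractional weight is split equally
    over surviving hits.  Reads outside the length window are tallied as
    ``length_filtered``; reads with no hit anywhere as ``unmapped``.
    """
    L = len(sequence)
    if not policy.min_read_len <= L <= policy.max_read_len:
        return AlignedRead(sequence, count, None, [], "length_filtered")
    for category in policy.order:
        if category == "miRNA":
            max_mm, max_clip = policy.mir_max_internal_mismatch, policy.mir_max_nontemplated_3p
        else:
            max_mm, max_clip = policy.trf_max_mismatch, 0
        found: dict[tuple[int, int], Hit] = {}
        for clip in range(0, max_clip + 1):
            s = sequence[:L - clip] if clip else sequence
            if len(s) < 2 * index.k0:
                break
            for idx, start, mm in _hamming_hits(index, s, category, max_mm):
                key = (idx, start)
                if key in found:
                    continue  # minimal clip wins
                refseq = index.seqs[idx]
                subs = [(i + 1, refseq[start + i], s[i]) for i in mm]
                found[key] = Hit(index.names[idx], start + 1,
                                 [i + 1 for i in mm], subs, clip)
        if found:
            hits = list(found.values())
            w = 1.0 / len(hits)
            for h in hits:
                h.weight = w
            return AlignedRead(sequence, count, category, hits, "mapped")
    return AlignedRead(sequence, count, None, [], "unmapped")


def classify_trf(reference: str, start: int, aligned_length: int,
                 ref: ReferenceSet) -> FragmentAnnotation:
    """tRF taxonomy of a tRNA-space hit from its placement alone.

    tRF-3 requires the full CCA terminus (alignment end = mature 3' end);
    CC-ended fragments classify as ``other``.  Fragments of
    >= 30 nt anchored at either terminus are halves rather than tRFs.
    """
    cat = ref.category(reference)
    end = start + aligned_length - 1
    if cat == "trailer":
        cls = "tRF-1" if start == 1 else "other"
        return FragmentAnnotation(reference, cls, "none", start, end)
    if cat != "tRNA":
        raise ClassificationError(f"{reference} is not in tRNA space ({cat})")
    L = len(ref.sequence(reference))
    if end == L:
        if aligned_length >= HALVES_CUTOFF:
            return FragmentAnnotation(reference, "3'half", "none", start, end)
        iso = {TRF3B_LENGTH: "3b", TRF3A_LENGTH: "3a"}.get(aligned_length, "none")
        return FragmentAnnotation(reference, "tRF-3", iso, start, end)
    if start == 1:
        cls = "5'half" if aligned_length >= HALVES_CUTOFF else "tRF-5"
        return FragmentAnnotation(reference, cls, "none", start, end)
    return FragmentAnnotation(reference, "other", "none", start, end)


def annotate_reads(reads: Union[Counter, Mapping[str, int], Iterable[str]],
                   index: SubstringIndex, policy: Optional[MappingPolicy] = None
                   ) -> tuple[list[AlignedRead], dict]:
    """Collapse, align and classify a read multiset.

    Returns the aligned reads (with per-hit :class:`FragmentAnnotation`)
    and a tally dict (mapped / unmapped / length_filtered, in
    collapsed-count-weighted reads).
    """
    policy = policy or MappingPolicy()
    if not isinstance(reads, (Counter, dict)):
        reads = Counter(reads)
    aligned = []
    tally = {"mapped": 0, "unmapped": 0, "length_filtered": 0}
    for seq in sorted(reads):
        ar = align_read(seq, index, policy, count=reads[seq])
        tally[ar.status] += ar.count
        for h in ar.hits:
            alen = len(seq) - h.clip
            if index.ref.category(h.reference) in ("tRNA", "trailer"):
                h.annotation = classify_trf(h.reference, h.start, alen, index.ref)
            else:
                cls = "miR" if ar.category == "miRNA" else "spikeIn"
                h.annotation = FragmentAnnotation(
                    h.reference, cls, "none", h.start, h.start + alen - 1)
        aligned.append(ar)
    return aligned, tally


def make_count_table(aligned: list[AlignedRead], min_count: int = 10) -> pd.DataFrame:
    """Fractional, collapsed-count-weighted counts per (parent, class, isoform).

    RPM is per million mapped reads; groups below ``min_count`` raw counts
    are flagged ``tested=False`` (excluded from differential testing).
    The fractional counts sum exactly to the number of mapped reads.
    """
    counts: dict[tuple[str, str, str], float] = {}
    total_mapped = 0.0
    for ar in aligned:
        if ar.status != "mapped":
            continue
        total_mapped += ar.count
        for h in ar.hits:
            a = h.annotation
            key = (a.parent, a.trf_class, a.size_isoform)
            counts[key] = counts.get(key, 0.0) + h.weight * ar.count
    rows = [dict(parent=p, trf_class=c, size_isoform=i, count=n,
                 rpm=1e6 * n / total_mapped if total_mapped else 0.0,
                 tested=n >= min_count)
            for (p, c, i), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["parent", "trf_class", "size_isoform",
                                       "count", "rpm", "tested"])


def write_annotation_tsv(aligned: list[AlignedRead], path: str) -> None:
    rows = []
    for ar in aligned:
        if not ar.hits:
            rows.append(dict(sequence=ar.sequence, count=ar.count, category="",
                             parent="", trf_class="", size_isoform="", start="",
                             end="", mismatch_positions="", status=ar.status))
        for h in ar.hits:
            a = h.annotation
            rows.append(dict(sequence=ar.sequence, count=ar.count,
                             category=ar.category, parent=h.reference,
                             trf_class=a.trf_class if a else "",
                             size_isoform=a.size_isoform if a else "",
                             start=h.start, end=a.mature_end if a else "",
                             mismatch_positions=",".join(map(str, h.mismatch_positions)),
                             status=ar.status))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
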