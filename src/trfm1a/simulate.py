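"""Synthetic benchmark data: references, molecule pools, RT reads, RIP arms.

The generator emulates the experimental design of ligation-first small-RNA
sequencing of tRNA fragments: m1A on a molecule either stalls the reverse
transcriptase (the molecule is then never cloned, because the 5' adaptor
was ligated before RT and a truncated cDNA cannot be amplified) or reads
through with a misincorporation at the modified base.  Background
sequencing/RT error is applied independently per base.

Every stochastic operation takes an explicit integer seed (or a numpy
Generator) and is deterministic under it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from trfm1a.core import (
    HALVES_CUTOFF,
    TRF3A_LENGTH,
    TRF3B_LENGTH,
    FragmentAnnotation,
    MatureTRNA,
    ModificationSite,
    ReferenceSet,
    TrailerSeq,
    mature_to_frag_coord,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
SITE_TYPE_RANK = ["8mer-A1", "7mer-m8", "7mer-A1", "6mer"]

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# RT error models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTModel:
    """Per-molecule behavior of a reverse transcriptase at an m1A base.

    Parameters
    ----------
    p_mis : probability of misincorporation at a modified base on a
        read-through molecule.
    mis_spectrum : distribution of the substituted base over C/G/T.
    p_stall : probability of truncation at a modified base; a stalled
        molecule is discarded entirely (ligation-first design).
    eps_bg : per-base background substitution probability.
    """

    name: str
    p_mis: float
    p_stall: float
    eps_bg: float
    mis_spectrum: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # C, G, T

    def __post_init__(self) -> None:
        for p in (self.p_mis, self.p_stall, self.eps_bg):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probability {p} outside [0,1]")
        if self.p_mis + self.p_stall > 1.0 + 1e-12:
            raise ValueError(f"{self.name}: p_mis + p_stall > 1")
        if abs(sum(self.mis_spectrum) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mis_spectrum must sum to 1")


# Defaults are qualitative presets: TGIRT reads through m1A with high
# misincorporation and ~0.2% background; ProtoScriptII mostly stalls
# (under-representing modified molecules); RT-1306 is intermediate.
TGIRT = RTModel("TGIRT", p_mis=0.85, p_stall=0.05, eps_bg=0.002)
PSII = RTModel("PSII", p_mis=0.05, p_stall=0.90, eps_bg=0.005)
RT1306 = RTModel("RT1306", p_mis=0.70, p_stall=0.10, eps_bg=0.005)
RT_PRESETS = {"TGIRT": TGIRT, "PSII": PSII, "RT1306": RT1306}


@dataclass(frozen=True)
class RIPConfig:
    """Antibody-pulldown model: fold preference for modified molecules."""

    enrichment_factor: float = 8.0
    igg_capture: float = 1.0
    lib_depth: int = 100_000

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not 0.0 <= self.igg_capture <= 1.0:
            raise ValueError("igg_capture must be in [0,1]")


# ---------------------------------------------------------------------------
# Molecule pools
# ---------------------------------------------------------------------------

@dataclass
class PoolEntry:
    """A group of identical molecules sharing sequence and site status."""

    sequence: str
    annotation: FragmentAnnotation
    copies: int
    mod_status: dict[int, bool] = field(default_factory=dict)  # frag pos -> modified

    @property
    def modified_positions(self) -> list[int]:
        return sorted(p for p, m in self.mod_status.items() if m)


@dataclass
class MoleculePool:
    entries: list[PoolEntry] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return sum(e.copies for e in self.entries)

    @property
    def n_modified(self) -> int:
        return sum(e.copies for e in self.entries if e.modified_positions)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def _shares_window(seq: str, hosts: Sequence[str], k: int = 15,
                   max_mismatch: int = 1) -> bool:
    """True if any k-window of ``seq`` matches a host with <= max_mismatch."""
    for host in hosts:
        for i in range(len(seq) - k + 1):
            win = seq[i:i + k]
            for j in range(len(host) - k + 1):
                mm = 0
                for a, b in zip(win, host[j:j + k]):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    return True
    return False


def build_reference(seed: Union[int, np.random.Generator], n_trna: int = 10,
                    n_mir: int = 20, n_spike: int = 2, n_control: int = 1,
                    n_mito: int = 0) -> ReferenceSet:
    """Generate a random reference space with annotated m1A sites.

    Every mature tRNA (length 72-90, CCA-terminal) carries an m1A site at
    mature position L-18 — the T-loop position that falls at fragment
    position 4 of its 22-nt 3' fragment.  The first ``n_mito`` tRNAs are
    mitochondrial and additionally carry m1A at position 9.  Spike-ins are
    regenerated until no 15-nt window of theirs maps (within 1 mismatch)
    to any tRNA/miRNA reference; ``n_control`` of them are synthetic m1A
    control oligos (with an annotated site), the rest QC spike-ins used
    for normalization.
    """
    if min(n_trna, n_mir) < 1 or n_spike + n_control < 1:
        raise ValueError("reference counts must be >= 1")
    rng = _as_rng(seed)
    trnas: list[MatureTRNA] = []
    sites: list[ModificationSite] = []
    for i in range(n_trna):
        length = int(rng.integers(72, 91))
        seq = list(_random_seq(rng, length - 3)) + list("CCA")
        seq[length - 19] = "A"  # mature position L-18, 1-based
        mito = i < n_mito
        if mito:
            seq[8] = "A"
        name = (f"mt_tRNA{i:02d}" if mito else f"tRNA{i:02d}")
        anticodon = _random_seq(rng, 3)
        trnas.append(MatureTRNA(name, anticodon,
                                "mitochondrial" if mito else "nuclear",
                                "".join(seq)))
        sites.append(ModificationSite(name, length - 18, "m1A", "TRMT6/61A"))
        if mito:
            sites.append(ModificationSite(name, 9, "m1A", "TRMT10C"))
    trailers = []
    for t in trnas:
        tail_len = int(rng.integers(16, 25))
        trailers.append(TrailerSeq(f"{t.name}_trailer", t.name,
                                   _random_seq(rng, tail_len - 4) + "TTTT"))
    mirnas = [(f"miR{i:03d}", _random_seq(rng, int(rng.integers(21, 24))))
              for i in range(n_mir)]

    hosts = [t.sequence for t in trnas] + [s for _, s in mirnas]
    spikes: list[tuple[str, str, bool]] = []
    for i in range(n_spike + n_control):
        is_control = i >= n_spike
        name = f"m1A_control{i - n_spike:02d}" if is_control else f"qc_spike{i:02d}"
        for attempt in range(100):
            seq = _random_seq(rng, int(rng.integers(22, 31)))
            pos = int(rng.integers(8, 16)) if is_control else None
            if is_control:
                seq = seq[:pos - 1] + "A" + seq[pos:]
            if not _shares_window(seq, hosts):
                break
            logger.info("spike-in %s attempt %d mapped to a reference; retrying",
                        name, attempt + 1)
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not generate unmappable spike-in {name}")
        if is_control:
            sites.append(ModificationSite(name, pos, "m1A"))
        spikes.append((name, seq, not is_control))

    return ReferenceSet(trnas, trailers, mirnas, spikes, sites)


# ---------------------------------------------------------------------------
# Fragment pools
# ---------------------------------------------------------------------------

#: fragment length sampled per class, inclusive ranges
DEFAULT_LENGTH_RANGES = {
    "tRF-5": (16, 29),
    "5'half": (HALVES_CUTOFF, 34),
    "3'half": (HALVES_CUTOFF, 34),
    "tRF-1": (15, 20),
}

DEFAULT_PROFILE = {
    "tRF-3b": 0.30, "tRF-3a": 0.15, "tRF-5": 0.15, "tRF-1": 0.10,
    "5'half": 0.05, "miR": 0.20, "spikeIn": 0.05,
}


def _fragment_of(ref: ReferenceSet, cls: str, parent: str, length: int
                 ) -> tuple[str, FragmentAnnotation]:
    seq = ref.sequence(parent)
    L = len(seq)
    if cls in ("tRF-3b", "tRF-3a", "3'half"):
        trf_class = "3'half" if cls == "3'half" else "tRF-3"
        iso = {"tRF-3b": "3b", "tRF-3a": "3a"}.get(cls, "none")
        ann = FragmentAnnotation(parent, trf_class, iso, L - length + 1, L)
        return seq[L - length:], ann
    if cls in ("tRF-5", "5'half"):
        trf_class = "5'half" if cls == "5'half" else "tRF-5"
        ann = FragmentAnnotation(parent, trf_class, "none", 1, length)
        return seq[:length], ann
    if cls == "tRF-1":
        ann = FragmentAnnotation(parent, "tRF-1", "none", 1, length)
        return seq[:length], ann
    if cls == "miR":
        return seq, FragmentAnnotation(parent, "miR", "none", 1, L)
    if cls == "spikeIn":
        return seq, FragmentAnnotation(parent, "spikeIn", "none", 1, L)
    raise ValueError(f"unknown fragment class {cls!r}")


def _eligible_parents(ref: ReferenceSet, cls: str) -> list[str]:
    if cls in ("tRF-3b", "tRF-3a", "tRF-5", "5'half", "3'half"):
        return [t.name for t in ref.tRNAs]
    if cls == "tRF-1":
        return [t.name for t in ref.trailers]
    if cls == "miR":
        return [n for n, _ in ref.miRNAs]
    if cls == "spikeIn":
        return [n for n, _, _ in ref.spike_ins]
    raise ValueError(f"unknown fragment class {cls!r}")


def _site_stoichiometry(stoich, parent: str, mature_pos: int) -> float:
    if isinstance(stoich, Mapping):
        return float(stoich.get((parent, mature_pos), 0.0))
    return float(stoich)


def simulate_fragment_pool(ref: ReferenceSet, profile: Mapping[str, float],
                           stoich, n_molecules: int = 10_000,
                           seed: Union[int, np.random.Generator] = 0,
                           length_ranges: Optional[Mapping[str, tuple[int, int]]] = None,
                           ) -> tuple[MoleculePool, pd.DataFrame]:
    """Draw a molecule pool with per-molecule Bernoulli modification status.

    ``profile`` weights fragment classes (tRF-3b, tRF-3a, tRF-5, tRF-1,
    5'half, 3'half, miR, spikeIn); class counts are multinomial, parents
    uniform among eligible references.  ``stoich`` is either a scalar
    stoichiometry applied at every annotated site or a map
    ``(reference, mature position) -> p``.

    Returns the pool and a truth table (one row per entry group) with the
    planted stoichiometry and copy numbers.
    """
    if not profile or sum(profile.values()) <= 0:
        raise ValueError("fragment-class profile is empty")
    rng = _as_rng(seed)
    ranges = dict(DEFAULT_LENGTH_RANGES)
    if length_ranges:
        ranges.update(length_ranges)
    classes = [c for c, w in profile.items() if w > 0]
    weights = np.array([profile[c] for c in classes], float)
    class_counts = rng.multinomial(n_molecules, weights / weights.sum())

    entries: list[PoolEntry] = []
    truth_rows = []
    for cls, total in zip(classes, class_counts):
        if total == 0:
            continue
        parents = _eligible_parents(ref, cls)
        per_parent = rng.multinomial(total, np.full(len(parents), 1 / len(parents)))
        for parent, n_par in zip(parents, per_parent):
            if n_par == 0:
                continue
            if cls in ranges:
                lo, hi = ranges[cls]
                hi = min(hi, len(ref.sequence(parent)))
                lo = min(lo, hi)  # short trailers: fall back to full length
                lengths = np.arange(lo, hi + 1)
                per_len = rng.multinomial(n_par, np.full(len(lengths), 1 / len(lengths)))
                length_counts = list(zip(lengths, per_len))
            else:
                fixed = {"tRF-3b": TRF3B_LENGTH, "tRF-3a": TRF3A_LENGTH}.get(
                    cls, len(ref.sequence(parent)))
                length_counts = [(fixed, n_par)]
            for length, n_frag in length_counts:
                if n_frag == 0:
                    continue
                seq, ann = _fragment_of(ref, cls, parent, int(length))
                # sites covered by this fragment, in fragment coordinates
                frag_sites = []
                for site in ref.sites_on(parent):
                    fp = mature_to_frag_coord(len(ref.sequence(parent)), ann.frag_length,
                                              ann.anchor, site.position)
                    if fp is not None:
                        p = _site_stoichiometry(stoich, parent, site.position)
                        frag_sites.append((fp, site.position, p))
                if not frag_sites:
                    entries.append(PoolEntry(seq, ann, int(n_frag), {}))
                    truth_rows.append(dict(parent=parent, trf_class=ann.trf_class,
                                           size_isoform=ann.size_isoform,
                                           frag_length=ann.frag_length, site_frag_pos=None,
                                           site_mature_pos=None, stoichiometry=0.0,
                                           copies=int(n_frag)))
                    continue
                # partition copies over the 2^k site-status combinations
                k = len(frag_sites)
                combos = []
                probs = []
                for mask in range(1 << k):
                    pr = 1.0
                    status = {}
                    for b, (fp, _, p) in enumerate(frag_sites):
                        mod = bool(mask >> b & 1)
                        status[fp] = mod
                        pr *= p if mod else (1 - p)
                    combos.append(status)
                    probs.append(pr)
                counts = rng.multinomial(n_frag, np.array(probs) / sum(probs))
                for status, n_combo in zip(combos, counts):
                    if n_combo:
                        entries.append(PoolEntry(seq, ann, int(n_combo), dict(status)))
                for fp, mp, p in frag_sites:
                    truth_rows.append(dict(parent=parent, trf_class=ann.trf_class,
                                           size_isoform=ann.size_isoform,
                                           frag_length=ann.frag_length, site_frag_pos=fp,
                                           site_mature_pos=mp, stoichiometry=p,
                                           copies=int(n_frag)))
    return MoleculePool(entries), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# RT processing
# ---------------------------------------------------------------------------

def apply_rt_model(pool: MoleculePool, rt: RTModel,
                   seed: Union[int, np.random.Generator]) -> tuple[Counter, dict]:
    """Reverse-transcribe a pool into a read multiset.

    At each modified site a molecule stalls with probability ``p_stall``
    (and is discarded — ligation-first cloning never amplifies truncated
    cDNA), otherwise misincorporates with probability ``p_mis`` drawing
    the substituted base from the spectrum.  Every position is further
    substituted with probability ``eps_bg`` (uniform over the three
    non-reference bases).  Reads carry no indels.

    Returns ``(reads, stats)`` with ``stats['molecules']``,
    ``stats['stalled']`` and ``stats['emitted']`` conserving
    ``emitted = molecules - stalled``.
    """
    rng = _as_rng(seed)
    reads: Counter = Counter()
    molecules = stalled = 0
    spectrum = np.array(rt.mis_spectrum)
    for entry in pool.entries:
        seq = entry.sequence
        L = len(seq)
        c = entry.copies
        molecules += c
        mod_pos = entry.modified_positions  # 1-based fragment positions
        k = len(mod_pos)
        surv = int(rng.binomial(c, (1 - rt.p_stall) ** k)) if k else c
        stalled += c - surv
        if surv == 0:
            continue
        # sparse event collection: molecule index -> {0-based pos: base}
        events: dict[int, dict[int, str]] = {}
        for fp in mod_pos:
            hit_idx = np.nonzero(rng.random(surv) < rt.p_mis)[0]
            if hit_idx.size:
                subs = rng.choice(3, size=hit_idx.size, p=spectrum)
                for mol, s in zip(hit_idx, subs):
                    events.setdefault(int(mol), {})[fp - 1] = "CGT"[s]
        if rt.eps_bg > 0:
            n_bg = int(rng.binomial(surv * L, rt.eps_bg))
            if n_bg:
                flat = rng.integers(0, surv * L, n_bg)
                for f in flat:
                    mol, pos = int(f // L), int(f % L)
                    mol_events = events.setdefault(mol, {})
                    if pos in mol_events:
                        continue  # m1A misincorporation already placed here
                    alts = [b for b in BASES if b != seq[pos]]
                    mol_events[pos] = alts[int(rng.integers(0, 3))]
        n_clean = surv - len(events)
        if n_clean:
            reads[seq] += n_clean
        for mol_events in events.values():
            mut = list(seq)
            for pos, base in mol_events.items():
                mut[pos] = base
            reads["".join(mut)] += 1
    emitted = sum(reads.values())
    return reads, {"molecules": molecules, "stalled": stalled, "emitted": emitted}


def expected_site_mismatch_rate(p: float, rt: RTModel) -> float:
    """Closed-form expected mismatch fraction at a modified site.

    Among emitted (non-stalled) molecules, a fraction
    ``p (1 - p_stall) / (1 - p p_stall)`` carried the modification; those
    mismatch with probability ``p_mis + (1 - p_mis) eps_bg`` while
    unmodified molecules mismatch at the background rate.
    """
    surv_mod = p * (1 - rt.p_stall)
    denom = 1 - p * rt.p_stall
    f_mod = surv_mod / denom
    return f_mod * (rt.p_mis + (1 - rt.p_mis) * rt.eps_bg) + (1 - f_mod) * rt.eps_bg


def simulate_rip(pool: MoleculePool, rip: RIPConfig, rt: RTModel,
                 seed: Union[int, np.random.Generator]) -> dict[str, Counter]:
    """Sample input / m1A-RIP / IgG-RIP libraries and reverse-transcribe them.

    The RIP arm multiplies a molecule's sampling weight by the enrichment
    factor iff it carries at least one modified site; the IgG arm captures
    nonspecifically at ``igg_capture``-scaled depth.
    """
    rng = _as_rng(seed)
    copies = np.array([e.copies for e in pool.entries], float)
    if copies.sum() == 0:
        raise ValueError("empty molecule pool")
    rip_w = np.array([e.copies * (rip.enrichment_factor if e.modified_positions else 1.0)
                      for e in pool.entries])
    arms = {
        "input": (copies, rip.lib_depth),
        "m1A_RIP": (rip_w, rip.lib_depth),
        "IgG_RIP": (copies, int(round(rip.igg_capture * rip.lib_depth))),
    }
    out = {}
    for arm, (w, depth) in arms.items():
        sampled = rng.multinomial(depth, w / w.sum())
        sub = MoleculePool([
            PoolEntry(e.sequence, e.annotation, int(n), dict(e.mod_status))
            for e, n in zip(pool.entries, sampled) if n
        ])
        out[arm], _ = apply_rt_model(sub, rt, rng)
    return out


# ---------------------------------------------------------------------------
# Expression tables and synthetic 3' UTRs
# ---------------------------------------------------------------------------

def simulate_expression_table(genes: Sequence[str],
                              targets_by_type: Mapping[str, Sequence[str]],
                              shifts: Mapping[str, float], sigma: float = 0.4,
                              seed: Union[int, np.random.Generator] = 0,
                              frac_low_expr: float = 0.2,
                              min_expr: float = 100.0) -> pd.DataFrame:
    """Gene-level log2FC table with planted per-site-type repression shifts.

    Non-targets draw log2FC ~ Normal(0, sigma); targets of site type t
    draw Normal(delta_t, sigma).  Genes in several target sets take the
    strongest (highest-rank) site type.  baseMean is log-uniform, with a
    ``frac_low_expr`` fraction planted below the expression filter.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = _as_rng(seed)
    best: dict[str, str] = {}
    for t in reversed(SITE_TYPE_RANK):  # strongest type wins, applied last
        for g in targets_by_type.get(t, []):
            best[g] = t
    rows = []
    for g in genes:
        t = best.get(g)
        delta = float(shifts.get(t, 0.0)) if t else 0.0
        lfc = rng.normal(delta, sigma)
        if rng.random() < frac_low_expr:
            base = 10 ** rng.uniform(0, np.log10(min_expr))
        else:
            base = 10 ** rng.uniform(np.log10(min_expr * 1.01), 5)
        rows.append(dict(gene=g, log2FC=lfc, baseMean=base,
                         true_type=t or "non-target"))
    return pd.DataFrame(rows)


def site_motif(seed7: str, site_type: str,
               rng: Optional[np.random.Generator] = None) -> str:
    """The mRNA-sense motif (5'->3') realizing a site type for a 7-nt seed.

    Includes one flanking 5' base for the 6mer/7mer-A1 types so that the
    planted occurrence cannot accidentally extend to a core-7 match.
    """
    rng = rng or np.random.default_rng(0)
    core7 = revcomp(seed7)
    core6 = revcomp(seed7[:6])
    m8_base = core7[0]  # complement of guide position 8
    non_m8 = [b for b in BASES if b != m8_base]
    non_a = [b for b in BASES if b != "A"]
    if site_type == "8mer-A1":
        return core7 + "A"
    if site_type == "7mer-m8":
        return core7 + non_a[int(rng.integers(0, 3))]
    if site_type == "7mer-A1":
        return non_m8[int(rng.integers(0, 3))] + core6 + "A"
    if site_type == "6mer":
        return (non_m8[int(rng.integers(0, 3))] + core6
                + non_a[int(rng.integers(0, 3))])
    raise ValueError(f"unknown site type {site_type!r}")


def build_utrs(genes: Sequence[str],
               planted: Mapping[str, Sequence[tuple[str, str]]],
               seed: Union[int, np.random.Generator] = 0,
               utr_length: int = 500) -> dict[str, str]:
    """Random 3' UTRs with planted seed-match sites.

    ``planted`` maps gene -> list of (seed7, site_type); each site motif is
    written at a random non-overlapping offset.  Background sequence is
    uniform random, so rare accidental matches can occur — score target
    status with the scanner (or its brute-force oracle), not from the
    planting list alone.
    """
    rng = _as_rng(seed)
    utrs = {}
    for g in genes:
        utr = list(_random_seq(rng, utr_length))
        offset = 10
        for seed7, site_type in planted.get(g, []):
            motif = site_motif(seed7, site_type, rng)
            start = offset + int(rng.integers(0, 20))
            utr[start:start + len(motif)] = list(motif)
            offset = start + len(motif) + 10
        utrs[g] = "".join(utr[:utr_length])
    return utrs


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fastq(reads: Union[Counter, Mapping[str, int]], path: str,
                prefix: str = "read") -> int:
    """Expand a read multiset to FASTQ (constant quality 'I'); returns count."""
    i = 0
    with open(path, "w") as fh:
        for seq in sorted(reads):
            for _ in range(reads[seq]):
                fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1
    return i
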