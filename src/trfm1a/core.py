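"""Domain types and coordinate conventions for tRNA-fragment analysis.

All coordinates are 1-based and inclusive, expressed on the mature tRNA
*including* the 3' CCA tail.  For a canonical 76-nt cytoplasmic tRNA the
T-loop m1A site sits at mature position 58, which is fragment position 4
of the 22-nt 3' fragment (tRF-3b).  Sequences are stored in the DNA
alphabet (U -> T), matching sequencing output.

tRNAs of non-canonical length keep their own length L; "position 58" is a
property of specific annotated tRNAs, never hard-coded downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

Anchor = Literal["3prime", "5prime"]
TrfClass = Literal["tRF-5", "tRF-3", "tRF-1", "5'half", "3'half", "miR", "spikeIn", "other"]
SizeIsoform = Literal["3a", "3b", "none"]

#: length (nt) at which a 5'/3'-anchored fragment is called a tRNA half
HALVES_CUTOFF = 30
#: size isoform lengths for 3' fragments
TRF3A_LENGTH = 18
TRF3B_LENGTH = 22


class CoordinateError(ValueError):
    """Raised when a fragment/mature coordinate falls outside its frame."""


def frag_to_mature_coord(parent_length: int, frag_length: int, anchor: Anchor,
                         frag_pos: int) -> int:
    """Map a 1-based fragment position to its 1-based mature-tRNA position.

    A 3'-anchored fragment of length ``f`` occupies mature positions
    ``L - f + 1 .. L``; a 5'-anchored fragment occupies ``1 .. f``.

    Parameters
    ----------
    parent_length : length L of the mature tRNA (including CCA).
    frag_length : fragment length f, ``f <= L``.
    anchor : which terminus of the parent the fragment is anchored to.
    frag_pos : 1-based position on the fragment.

    Returns
    -------
    The 1-based position on the mature tRNA.

    Examples
    --------
    >>> frag_to_mature_coord(76, 22, "3prime", 4)
    58
    """
    if not 1 <= frag_length <= parent_length:
        raise CoordinateError(
            f"fragment length {frag_length} outside parent length {parent_length}")
    if not 1 <= frag_pos <= frag_length:
        raise CoordinateError(
            f"fragment position {frag_pos} outside fragment of length {frag_length}")
    if anchor == "3prime":
        return parent_length - frag_length + frag_pos
    if anchor == "5prime":
        return frag_pos
    raise CoordinateError(f"unknown anchor {anchor!r}")


def mature_to_frag_coord(parent_length: int, frag_length: int, anchor: Anchor,
                         mature_pos: int) -> Optional[int]:
    """Inverse of :func:`frag_to_mature_coord`.

    Returns the 1-based fragment position covering ``mature_pos``, or
    ``None`` when the fragment does not cover that mature position.
    """
    if not 1 <= frag_length <= parent_length:
        raise CoordinateError(
            f"fragment length {frag_length} outside parent length {parent_length}")
    if not 1 <= mature_pos <= parent_length:
        raise CoordinateError(
            f"mature position {mature_pos} outside parent length {parent_length}")
    if anchor == "3prime":
        pos = mature_pos - (parent_length - frag_length)
    elif anchor == "5prime":
        pos = mature_pos
    else:
        raise CoordinateError(f"unknown anchor {anchor!r}")
    if 1 <= pos <= frag_length:
        return pos
    return None


@dataclass(frozen=True)
class MatureTRNA:
    """A mature tRNA sequence with CCA tail, in DNA alphabet."""

    name: str
    anticodon: str
    compartment: Literal["nuclear", "mitochondrial"]
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"{self.name}: mature tRNA must end in CCA")
        if not 60 <= len(self.sequence) <= 100:
            raise ValueError(f"{self.name}: implausible tRNA length {len(self.sequence)}")
        if not set(self.sequence) <= DNA_ALPHABET:
            raise ValueError(f"{self.name}: sequence contains non-ACGT characters")
        if len(self.anticodon) != 3:
            raise ValueError(f"{self.name}: anticodon must be 3 nt")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrailerSeq:
    """3' trailer of a precursor tRNA (source of tRF-1s)."""

    name: str
    parent: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty trailer sequence")
        if not set(self.sequence) <= DNA_ALPHABET:
            raise ValueError(f"{self.name}: sequence contains non-ACGT characters")


@dataclass(frozen=True)
class ModificationSite:
    """An annotated modification on a reference, 1-based position."""

    reference: str
    position: int
    modification: str = "m1A"
    writer: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.reference}: position must be >= 1")


@dataclass
class ReferenceSet:
    """The full small-RNA reference space and its modification annotations.

    Categories mirror the mapping priority used downstream: miRNAs first,
    then tRNA space (mature tRNAs + precursor trailers), then spike-ins.
    """

    tRNAs: list[MatureTRNA] = field(default_factory=list)
    trailers: list[TrailerSeq] = field(default_factory=list)
    miRNAs: list[tuple[str, str]] = field(default_factory=list)
    spike_ins: list[tuple[str, str, bool]] = field(default_factory=list)
    mod_sites: list[ModificationSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -------------------------------------------------------

    def all_names(self) -> list[str]:
        return ([t.name for t in self.tRNAs] + [t.name for t in self.trailers]
                + [n for n, _ in self.miRNAs] + [n for n, _, _ in self.spike_ins])

    def sequence(self, name: str) -> str:
        for t in self.tRNAs:
            if t.name == name:
                return t.sequence
        for t in self.trailers:
            if t.name == name:
                return t.sequence
        for n, s in self.miRNAs:
            if n == name:
                return s
        for n, s, _ in self.spike_ins:
            if n == name:
                return s
        raise KeyError(name)

    def category(self, name: str) -> str:
        if any(t.name == name for t in self.tRNAs):
            return "tRNA"
        if any(t.name == name for t in self.trailers):
            return "trailer"
        if any(n == name for n, _ in self.miRNAs):
            return "miRNA"
        if any(n == name for n, _, _ in self.spike_ins):
            return "spikeIn"
        raise KeyError(name)

    def trna(self, name: str) -> MatureTRNA:
        for t in self.tRNAs:
            if t.name == name:
                return t
        raise KeyError(name)

    def sites_on(self, name: str) -> list[ModificationSite]:
        return [s for s in self.mod_sites if s.reference == name]

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        names = self.all_names()
        if len(names) != len(set(names)):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate reference names: {sorted(dupes)}")
        trailer_parents = {t.parent for t in self.trailers}
        known = {t.name for t in self.tRNAs}
        orphans = trailer_parents - known
        if orphans:
            raise ValueError(f"trailers with unknown parent tRNA: {sorted(orphans)}")
        host_seqs = ([t.sequence for t in self.tRNAs] + [s for _, s in self.miRNAs])
        for n, s, _ in self.spike_ins:
            if any(s in h for h in host_seqs):
                raise ValueError(f"spike-in {n} occurs inside a tRNA/miRNA reference")
        for site in self.mod_sites:
            seq = self.sequence(site.reference)
            if site.position > len(seq):
                raise ValueError(
                    f"site {site.reference}:{site.position} beyond reference length")
            if site.modification == "m1A" and seq[site.position - 1] != "A":
                raise ValueError(
                    f"m1A site {site.reference}:{site.position} is not on an A")

    # -- file I/O ------------------------------------------------------

    def to_dir(self, path: str) -> None:
        """Write one FASTA per category plus a modification-site TSV."""
        os.makedirs(path, exist_ok=True)

        def _write(fname: str, records: list[SeqRecord]) -> None:
            with open(os.path.join(path, fname), "w") as fh:
                SeqIO.write(records, fh, "fasta")

        _write("trnas.fa", [
            SeqRecord(Seq(t.sequence), id=t.name, description=
                      f"anticodon={t.anticodon} compartment={t.compartment}")
            for t in self.tRNAs])
        _write("trailers.fa", [
            SeqRecord(Seq(t.sequence), id=t.name, description=f"parent={t.parent}")
            for t in self.trailers])
        _write("mirnas.fa", [SeqRecord(Seq(s), id=n, description="")
                             for n, s in self.miRNAs])
        _write("spikeins.fa", [
            SeqRecord(Seq(s), id=n, description=f"qc={int(qc)}")
            for n, s, qc in self.spike_ins])
        with open(os.path.join(path, "mod_sites.tsv"), "w") as fh:
            fh.write("reference\tposition\tmodification\twriter\n")
            for s in self.mod_sites:
                fh.write(f"{s.reference}\t{s.position}\t{s.modification}\t"
                         f"{s.writer or ''}\n")

    @classmethod
    def from_dir(cls, path: str) -> "ReferenceSet":
        def _meta(desc: str) -> dict[str, str]:
            out = {}
            for tok in desc.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    out[k] = v
            return out

        trnas = []
        for rec in SeqIO.parse(os.path.join(path, "trnas.fa"), "fasta"):
            m = _meta(rec.description)
            trnas.append(MatureTRNA(rec.id, m.get("anticodon", "NNN"),
                                    m.get("compartment", "nuclear"), str(rec.seq)))
        trailers = []
        for rec in SeqIO.parse(os.path.join(path, "trailers.fa"), "fasta"):
            m = _meta(rec.description)
            trailers.append(TrailerSeq(rec.id, m["parent"], str(rec.seq)))
        mirnas = [(rec.id, str(rec.seq))
                  for rec in SeqIO.parse(os.path.join(path, "mirnas.fa"), "fasta")]
        spikes = []
        for rec in SeqIO.parse(os.path.join(path, "spikeins.fa"), "fasta"):
            m = _meta(rec.description)
            spikes.append((rec.id, str(rec.seq), m.get("qc", "0") == "1"))
        sites = []
        with open(os.path.join(path, "mod_sites.tsv")) as fh:
            next(fh)
            for line in fh:
                ref, pos, mod, writer = line.rstrip("\n").split("\t")
                sites.append(ModificationSite(ref, int(pos), mod, writer or None))
        return cls(trnas, trailers, mirnas, spikes, sites)


@dataclass(frozen=True)
class FragmentAnnotation:
    """Placement and taxonomy of one fragment on its parental reference."""

    parent: str
    trf_class: TrfClass
    size_isoform: SizeIsoform
    mature_start: int
    mature_end: int

    def __post_init__(self) -> None:
        if self.mature_end < self.mature_start:
            raise ValueError("mature_end before mature_start")
        if self.size_isoform == "3b" and not (
                self.trf_class == "tRF-3" and self.frag_length == TRF3B_LENGTH):
            raise ValueError("isoform 3b requires a 22-nt tRF-3")
        if self.size_isoform == "3a" and not (
                self.trf_class == "tRF-3" and self.frag_length == TRF3A_LENGTH):
            raise ValueError("isoform 3a requires an 18-nt tRF-3")

    @property
    def frag_length(self) -> int:
        return self.mature_end - self.mature_start + 1

    @property
    def anchor(self) -> Anchor:
        return "3prime" if self.trf_class in ("tRF-3", "3'half") else "5prime"
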