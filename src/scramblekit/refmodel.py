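"""Segment model of a loxPsym-annotated synthetic chromosome.

A SCRaMbLE-competent chromosome is partitioned by its loxPsym sites into
*segments*: the intervals between consecutive sites.  Segments are the atomic
units of rearrangement — Cre-mediated recombination between two loxPsym sites
deletes, inverts or duplicates whole blocks of segments and never creates
breakpoints inside a segment.  Everything downstream (the recombination
simulator, the split-read junction caller, the structure reconstructor)
operates on this segment model.

Coordinates are 0-based half-open throughout; on disk the annotation uses the
BED dialect.  For circular chromosomes the sequence is held in a canonical
rotation that places the first loxPsym site at coordinate 0, so segment
coordinates never wrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical 34-bp symmetric loxPsym site (13-bp arm / 8-bp spacer / 13-bp arm).
#: The spacer of loxPsym is itself palindromic, which is what lets Cre
#: recombine any two sites in either relative orientation.
LOXPSYM_SITE = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMP)[::-1]


class AnnotationError(ValueError):
    """Reference annotation violates the segment-model invariants."""


class ConfigError(ValueError):
    """A configuration value is out of its allowed range."""


@dataclass(frozen=True)
class LoxPsymAnnotation:
    """Positions of the loxPsym sites on one chromosome.

    ``sites`` is a sorted list of 0-based half-open ``(start, end)`` intervals,
    each exactly ``len(site_seq)`` long; the annotated sequence must match
    ``site_seq``, and ``site_seq`` must equal its own reverse complement.
    """

    chrom_id: str
    sites: tuple[tuple[int, int], ...]
    site_seq: str = LOXPSYM_SITE

    def __post_init__(self) -> None:
        if revcomp(self.site_seq) != self.site_seq:
            raise AnnotationError("loxPsym site sequence must be palindromic "
                                  "(equal to its own reverse complement)")
        prev_end = -1
        for start, end in self.sites:
            if end - start != len(self.site_seq):
                raise AnnotationError(
                    f"site interval [{start},{end}) is not "
                    f"{len(self.site_seq)} bp")
            if start <= prev_end:
                raise AnnotationError(
                    f"loxPsym intervals unsorted or overlapping at {start}")
            prev_end = end

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class Segment:
    """One loxPsym-flanked interval of the reference chromosome."""

    seg_id: int                     # 1..N in reference order
    start: int                      # 0-based half-open, site-exclusive
    end: int
    contains_essential: bool = False
    contains_centromere: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"segment {self.seg_id}: end {self.end} <= start {self.start}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentedReference:
    """A chromosome sequence together with its segment partition.

    Linear chromosomes with N sites have N+1 segments (two telomeric terminal
    segments without a distal site); circular chromosomes have N segments and
    are stored rotated so that site 1 begins at coordinate 0.
    """

    chrom_id: str
    sequence: str
    segments: tuple[Segment, ...]
    topology: str                   # "linear" | "circular"
    loxp: LoxPsymAnnotation

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        n = self.loxp.n_sites
        expect = n + 1 if self.topology == "linear" else n
        if len(self.segments) != expect:
            raise AnnotationError(
                f"{self.topology} chromosome with {n} loxPsym sites must have "
                f"{expect} segments, got {len(self.segments)}")
        if self.topology == "circular" and n and self.loxp.sites[0][0] != 0:
            raise AnnotationError(
                "circular reference must be rotated so site 1 starts at 0")
        # segments + sites tile the sequence exactly
        pieces = sorted(
            [(s.start, s.end, "seg") for s in self.segments]
            + [(a, b, "site") for a, b in self.loxp.sites])
        pos = 0
        for start, end, _kind in pieces:
            if start != pos:
                raise AnnotationError(
                    f"gap/overlap in segment tiling at {pos}..{start}")
            pos = end
        if pos != len(self.sequence):
            raise AnnotationError(
                f"segments+sites cover {pos} bp of a "
                f"{len(self.sequence)} bp sequence")
        if sum(s.contains_centromere for s in self.segments) != 1:
            raise AnnotationError("exactly one segment must carry the "
                                  "centromere")
        for a, b in self.loxp.sites:
            if self.sequence[a:b] != self.loxp.site_seq:
                raise AnnotationError(
                    f"sequence at loxPsym interval [{a},{b}) does not match "
                    "the annotated site sequence")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.loxp.n_sites

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def site_seq(self) -> str:
        return self.loxp.site_seq

    def segment(self, seg_id: int) -> Segment:
        return self.segments[seg_id - 1]

    def segment_seq(self, seg_id: int) -> str:
        s = self.segment(abs(seg_id))
        seq = self.sequence[s.start:s.end]
        return revcomp(seq) if seg_id < 0 else seq

    def site_position(self, site_index: int) -> int:
        """Midpoint (bp) of a 1-based loxPsym site, for genomic binning."""
        a, b = self.loxp.sites[site_index - 1]
        return (a + b) // 2

    # -- segment-end / site adjacency --------------------------------------
    # Linear layout:   seg1 site1 seg2 site2 ... siteN seg(N+1)
    # Circular layout: site1 seg1 site2 seg2 ... siteN segN (wraps to site1)
    def site_left_of(self, seg_id: int) -> int | None:
        """1-based site index immediately left of a segment (None at a
        linear chromosome start)."""
        if self.topology == "linear":
            return seg_id - 1 if seg_id > 1 else None
        return seg_id

    def site_right_of(self, seg_id: int) -> int | None:
        if self.topology == "linear":
            return seg_id if seg_id <= self.n_sites else None
        return seg_id + 1 if seg_id < self.n_segments else 1

    def site_of_end(self, seg_id: int, end: str) -> int | None:
        """Site adjacent to a segment end ('L' or 'R'); None for telomeric
        ends of a linear chromosome."""
        return (self.site_left_of(seg_id) if end == "L"
                else self.site_right_of(seg_id))

    def parental_junctions(self) -> set[tuple[tuple[int, str], tuple[int, str]]]:
        """The segment-end pairs joined across each site in the reference."""
        out = set()
        k = self.n_segments
        for i in range(1, k):
            out.add(canonical_junction((i, "R"), (i + 1, "L")))
        if self.topology == "circular":
            out.add(canonical_junction((k, "R"), (1, "L")))
        return out

    def essential_ids(self) -> tuple[int, ...]:
        return tuple(s.seg_id for s in self.segments if s.contains_essential)

    def centromere_id(self) -> int:
        return next(s.seg_id for s in self.segments if s.contains_centromere)


def canonical_junction(end_a: tuple[int, str],
                       end_b: tuple[int, str]) -> tuple[tuple[int, str], tuple[int, str]]:
    """Order-free canonical form of a loxPsym junction between two segment
    ends.  Because the site is palindromic, a junction read and its reverse
    complement describe the same unordered end pair."""
    return (end_a, end_b) if end_a <= end_b else (end_b, end_a)


# ---------------------------------------------------------------------------
# construction / IO
# ---------------------------------------------------------------------------

def _read_bed(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[1, 2], names=["start", "end"],
                     dtype={"start": int, "end": int})
    return list(df.itertuples(index=False, name=None))


def _segment_from_sites(seq_len: int, sites: list[tuple[int, int]],
                        topology: str) -> list[tuple[int, int]]:
    bounds = []
    if topology == "linear":
        pos = 0
        for a, b in sites:
            bounds.append((pos, a))
            pos = b
        bounds.append((pos, seq_len))
    else:
        for i, (_a, b) in enumerate(sites):
            nxt = sites[i + 1][0] if i + 1 < len(sites) else seq_len
            bounds.append((b, nxt))
    return bounds


def build_reference(chrom_id: str, sequence: str,
                    site_intervals: list[tuple[int, int]],
                    essential_intervals: list[tuple[int, int]],
                    centromere_interval: tuple[int, int],
                    topology: str = "linear",
                    site_seq: str = LOXPSYM_SITE) -> SegmentedReference:
    """Assemble and validate a SegmentedReference from raw intervals.

    For circular topology the sequence and all intervals are rotated so the
    first loxPsym site starts at coordinate 0.
    """
    sequence = sequence.upper()
    site_intervals = sorted(site_intervals)
    if topology == "circular" and site_intervals and site_intervals[0][0] != 0:
        shift = site_intervals[0][0]
        L = len(sequence)
        sequence = sequence[shift:] + sequence[:shift]

        def rot(iv):
            a, b = (iv[0] - shift) % L, (iv[1] - shift) % L or L
            if a < b:
                return [(a, b)]
            return [(a, L), (0, b)]        # interval split by the new origin

        site_intervals = sorted(x for iv in site_intervals for x in rot(iv))
        essential_intervals = sorted(
            x for iv in essential_intervals for x in rot(iv))
        cen = rot(centromere_interval)
        if len(cen) != 1:
            raise AnnotationError("centromere interval spans the rotation "
                                  "origin (inside a loxPsym site?)")
        centromere_interval = cen[0]

    loxp = LoxPsymAnnotation(chrom_id, tuple(site_intervals), site_seq)
    for a, b in site_intervals:
        if b > len(sequence):
            raise AnnotationError(f"site interval [{a},{b}) outside sequence")
        if sequence[a:b] != site_seq:
            raise AnnotationError(
                f"sequence at loxPsym interval [{a},{b}) != site sequence")

    def overlaps(iv, ivs):
        return any(iv[0] < b and a < iv[1] for a, b in ivs)

    seg_bounds = _segment_from_sites(len(sequence), site_intervals, topology)
    segments = []
    n_cen = 0
    for i, (a, b) in enumerate(seg_bounds, start=1):
        ess = overlaps((a, b), essential_intervals)
        cen = overlaps((a, b), [centromere_interval])
        n_cen += cen
        segments.append(Segment(i, a, b, ess, cen))
    if n_cen != 1:
        raise AnnotationError(
            f"centromere interval {centromere_interval} overlaps {n_cen} "
            "segments; must overlap exactly one")
    return SegmentedReference(chrom_id, sequence, tuple(segments),
                              topology, loxp)


def load_reference(fasta_path, loxp_bed_path, essential_bed_path,
                   centromere_interval: tuple[int, int],
                   topology: str = "linear",
                   site_seq: str = LOXPSYM_SITE) -> SegmentedReference:
    """Load a loxPsym-annotated reference chromosome from FASTA + BED files."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"expected exactly one FASTA sequence, found {len(records)}")
    rec = records[0]
    essential = _read_bed(essential_bed_path) if essential_bed_path else []
    return build_reference(rec.id, str(rec.seq), _read_bed(loxp_bed_path),
                           essential, tuple(centromere_interval),
                           topology, site_seq)


def write_reference(ref: SegmentedReference, fasta_path, loxp_bed_path,
                    essential_bed_path) -> None:
    """Write the reference back to FASTA + BED (round-trips with
    :func:`load_reference`)."""
    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.chrom_id,
                           description="")], str(fasta_path), "fasta")
    with open(loxp_bed_path, "w") as fh:
        for i, (a, b) in enumerate(ref.loxp.sites, start=1):
            fh.write(f"{ref.chrom_id}\t{a}\t{b}\tloxPsym_{i}\n")
    with open(essential_bed_path, "w") as fh:
        for s in ref.segments:
            if s.contains_essential:
                fh.write(f"{ref.chrom_id}\t{s.start}\t{s.end}\tessential\n")


# ---------------------------------------------------------------------------
# flank library
# ---------------------------------------------------------------------------

def segment_flank_library(ref: SegmentedReference,
                          flank_len: int) -> dict[tuple[int, str], str]:
    """Reference sequence immediately flanking each loxPsym site.

    Returns two entries per site, keyed ``(site_index, side)`` with side in
    {"left", "right"}: the left entry is the ``flank_len`` bases ending at the
    site start (read toward the site), the right entry the ``flank_len`` bases
    starting at the site end (read away from it).  Both are exact substrings
    of the reference and are what a loxPsym-spanning read must carry on either
    side of the site.
    """
    if flank_len < 15:
        raise ConfigError("flank_len must be >= 15")
    shortest = min(s.length_bp for s in ref.segments)
    if flank_len > shortest:
        bad = min(ref.segments, key=lambda s: s.length_bp)
        raise ConfigError(
            f"flank_len {flank_len} exceeds the length of segment "
            f"{bad.seg_id} ({bad.length_bp} bp)")
    lib: dict[tuple[int, str], str] = {}
    L = len(ref.sequence)
    for i, (a, b) in enumerate(ref.loxp.sites, start=1):
        left = ref.sequence[a - flank_len:a] if a >= flank_len else \
            ref.sequence[(a - flank_len) % L:] + ref.sequence[:a]
        right = ref.sequence[b:b + flank_len]
        if len(right) < flank_len:                       # circular wrap
            right += ref.sequence[:flank_len - len(right)]
        lib[(i, "left")] = left
        lib[(i, "right")] = right
    return lib


def end_flank_index(ref: SegmentedReference,
                    flank_len: int) -> dict[tuple[int, str], str]:
    """Per segment-end flank sequences used for split-read assignment.

    For each site-adjacent segment end ``(seg_id, 'L'|'R')`` this gives the
    sequence that appears immediately *after* a loxPsym site in a chromosome
    where that end follows the site: the segment prefix for an L end, the
    reverse complement of the segment suffix for an R end.  The sequence that
    appears *before* a site when that end precedes it is the reverse
    complement of this entry (palindromic-site symmetry).
    """
    segment_flank_library(ref, flank_len)      # validates flank_len
    idx: dict[tuple[int, str], str] = {}
    for s in ref.segments:
        if ref.site_of_end(s.seg_id, "L") is not None:
            idx[(s.seg_id, "L")] = ref.segment_seq(s.seg_id)[:flank_len]
        if ref.site_of_end(s.seg_id, "R") is not None:
            idx[(s.seg_id, "R")] = revcomp(
                ref.segment_seq(s.seg_id)[-flank_len:])
    return idx


# ---------------------------------------------------------------------------
# synthetic references for simulation studies
# ---------------------------------------------------------------------------

def random_reference(n_segments: int = 12,
                     mean_segment_len: int = 1500,
                     topology: str = "linear",
                     essential_segments: tuple[int, ...] | None = None,
                     centromere_segment: int | None = None,
                     seed: int = 0,
                     site_seq: str = LOXPSYM_SITE,
                     chrom_id: str = "synthchr") -> SegmentedReference:
    """Generate a random loxPsym-partitioned chromosome for simulations.

    Segment lengths are drawn uniformly in [0.5, 1.5] x ``mean_segment_len``
    so depth estimates see realistic length heterogeneity.  By default every
    third interior segment is flagged essential (mimicking the interleaving of
    essential genes along Sc2.0 chromosomes) and the centromere sits near the
    middle.
    """
    if n_segments < 3:
        raise ConfigError("need at least 3 segments")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(mean_segment_len // 2,
                           3 * mean_segment_len // 2 + 1, size=n_segments)
    if centromere_segment is None:
        centromere_segment = n_segments // 2
    if essential_segments is None:
        essential_segments = tuple(
            i for i in range(2, n_segments) if i % 3 == 0
            and i != centromere_segment)
    bases = np.array(list("ACGT"))
    site = site_seq

    def draw(n):
        # rejection-free random DNA; loxPsym arms are AT-rich enough that a
        # chance 34-bp collision is effectively impossible at these sizes
        return "".join(rng.choice(bases, size=n))

    parts = []
    site_iv = []
    seg_iv = []
    pos = 0
    for k in range(n_segments):
        parts_len = int(lengths[k])
        if topology == "circular" or k > 0:
            site_iv.append((pos, pos + len(site)))
            parts.append(site)
            pos += len(site)
        seg_iv.append((pos, pos + parts_len))
        parts.append(draw(parts_len))
        pos += parts_len
    sequence = "".join(parts)
    essential_iv = [seg_iv[i - 1] for i in essential_segments]
    cen_a, cen_b = seg_iv[centromere_segment - 1]
    mid = (cen_a + cen_b) // 2
    centromere = (mid - 60, mid + 60)   # ~120 bp point centromere, as in yeast
    return build_reference(chrom_id, sequence, site_iv, essential_iv,
                           centromere, topology, site)
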