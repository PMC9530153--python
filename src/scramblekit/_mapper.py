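"""Minimal seed-and-vote read placement against small references.

This is deliberately not a general aligner: SCRaMbLEd-strain reads are short
(100 bp), substitution-dominated and drawn from references of tens to
hundreds of kilobases, so exact k-mer seeding at a few offsets followed by a
Hamming check recovers the unique best end-to-end placement.  It backs two
consumers: mapped-read exclusion in the junction caller (a read that places
end-to-end on the reference cannot span a novel junction) and per-segment
depth for copy-number estimation.  A SAM ingestion path exists alongside for
externally aligned real data.
"""

from __future__ import annotations

import numpy as np

from .refmodel import revcomp


class Placement:
    __slots__ = ("seq_idx", "pos", "strand", "mismatches")

    def __init__(self, seq_idx: int, pos: int, strand: str, mismatches: int):
        self.seq_idx = seq_idx
        self.pos = pos
        self.strand = strand
        self.mismatches = mismatches


def hamming(a: str, b: str, limit: int = 10 ** 9) -> int:
    if a == b:
        return 0
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


class KmerMapper:
    """Exact-seed mapper over one or more reference sequences.

    Seeds of length ``k`` are looked up at ``seed_offsets`` within the read;
    every seed hit proposes a start, proposals are verified by bounded
    Hamming comparison and the unique best placement (margin >= 1 mismatch)
    is returned.
    """

    def __init__(self, sequences: list[str], k: int = 31,
                 seed_offsets: tuple[int, ...] = (0, 23, 46, 69),
                 max_mismatch: int = 3):
        self.sequences = sequences
        self.k = k
        self.seed_offsets = seed_offsets
        self.max_mismatch = max_mismatch
        self.index: dict[str, list[tuple[int, int]]] = {}
        for si, seq in enumerate(sequences):
            for p in range(len(seq) - k + 1):
                kmer = seq[p:p + k]
                hits = self.index.setdefault(kmer, [])
                if len(hits) < 8:          # cap repeats; enough to vote
                    hits.append((si, p))

    def _candidates(self, seq: str):
        k = self.k
        n = len(seq)
        cands = set()
        for off in self.seed_offsets:
            if off + k > n:
                break
            for si, p in self.index.get(seq[off:off + k], ()):
                start = p - off
                if 0 <= start <= len(self.sequences[si]) - n:
                    cands.add((si, start))
        return cands

    def map_read(self, seq: str) -> Placement | None:
        """Unique best end-to-end placement of a read (either strand)."""
        best: Placement | None = None
        second = 10 ** 9
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for si, start in self._candidates(s):
                ref = self.sequences[si]
                d = hamming(s, ref[start:start + len(s)],
                            limit=self.max_mismatch + 1)
                if best is None or d < best.mismatches:
                    if best is not None:
                        second = best.mismatches
                    best = Placement(si, start, strand, d)
                elif d < second:
                    second = d
        if best is None or best.mismatches > self.max_mismatch:
            return None
        if second <= best.mismatches:
            return None                    # ambiguous placement
        return best

    def maps_end_to_end(self, seq: str, max_mismatch: int | None = None) -> bool:
        """True when the read has any end-to-end placement within the
        mismatch budget (used for excluding reference-consistent reads)."""
        mm = self.max_mismatch if max_mismatch is None else max_mismatch
        for s in (seq, revcomp(seq)):
            for si, start in self._candidates(s):
                ref = self.sequences[si]
                if hamming(s, ref[start:start + len(s)], limit=mm) <= mm:
                    return True
        return False


def coverage_from_placements(placements, length: int,
                             read_len: int) -> np.ndarray:
    """Per-base coverage array from (pos, weight) placements on one
    sequence."""
    diff = np.zeros(length + 1)
    for pos, weight in placements:
        diff[pos] += weight
        diff[min(pos + read_len, length)] -= weight
    return np.cumsum(diff)[:length]
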