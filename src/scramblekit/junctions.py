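"""Split-read detection of loxPsym junctions.

The detection procedure mirrors standard SCRaMbLE genotyping: reads that fail
to place end-to-end on the reference but contain a loxPsym site with at least
``min_flank`` bases on *both* sides are trisected into left flank / site /
right flank; each flank is assigned to a unique segment end by comparison
against a reference flank library; the resulting segment-end pair is a
junction observation.  Observations are grouped into canonical junctions
(order-free, reverse-complement-invariant thanks to the palindromic site),
junctions below the read-support threshold are discarded, and survivors are
labelled *parental* (present in the unrearranged reference) or *novel*
(evidence of recombination).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from ._mapper import KmerMapper, hamming
from .refmodel import (SegmentedReference, canonical_junction,
                       end_flank_index, revcomp)

End = tuple[int, str]
JunctionKey = tuple[End, End]


@dataclass
class CallerConfig:
    """Thresholds of the junction caller.

    ``min_flank`` — minimum bases required on each side of the site for a
    read to be usable (both flanks must be assignable).
    ``min_support`` — minimum distinct read pairs per reported junction.
    ``flank_index_len`` — length of the reference flank entries compared
    against read flanks.
    ``max_mismatch_per_flank`` — mismatch budget per flank assignment; the
    best hit must also beat the runner-up by at least one mismatch.
    """

    min_flank: int = 15
    min_support: int = 5
    flank_index_len: int = 30
    max_mismatch_per_flank: int = 1
    site_max_mismatch: int = 1
    map_max_mismatch: int = 3

    def __post_init__(self) -> None:
        if self.min_flank > self.flank_index_len:
            raise ValueError("min_flank must not exceed flank_index_len")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class Candidate:
    """A read containing a loxPsym site with two usable flanks."""

    read_id: str
    seq: str
    site_pos: int                   # 0-based start of the site in the read


@dataclass(frozen=True)
class JunctionObservation:
    """One trisected read resolved to a canonical segment-end pair."""

    read_id: str
    junction: JunctionKey
    mismatches: tuple[int, int]


def _find_site(seq: str, site: str, max_mm: int) -> list[int]:
    """All start positions of the (palindromic) site in a read, exact first,
    then Hamming-tolerant anchored on exact 10-mer chunks."""
    hits = []
    start = seq.find(site)
    while start != -1:
        hits.append(start)
        start = seq.find(site, start + 1)
    if hits or max_mm == 0:
        return hits
    n, m = len(seq), len(site)
    seen = set()
    for chunk_off in (0, m // 2 - 5, m - 10):
        chunk = site[chunk_off:chunk_off + 10]
        p = seq.find(chunk)
        while p != -1:
            s = p - chunk_off
            if 0 <= s <= n - m and s not in seen:
                seen.add(s)
                if hamming(seq[s:s + m], site, limit=max_mm) <= max_mm:
                    hits.append(s)
            p = seq.find(chunk, p + 1)
    return sorted(hits)


def reference_mapper(ref: SegmentedReference,
                     extra_seqs: Iterable[str] = (),
                     max_mismatch: int = 3,
                     overhang: int = 99) -> KmerMapper:
    """Seed mapper over the reference (plus e.g. a diploid native homolog).

    Circular references are extended by ``overhang`` bases past the origin so
    reads spanning the origin still place end-to-end; ``overhang`` must stay
    below the read length to keep placements unique.
    """
    seq = ref.sequence
    if ref.topology == "circular":
        seq = seq + seq[:overhang]
    return KmerMapper([seq, *extra_seqs], max_mismatch=max_mismatch)


def find_loxp_reads(reads: Iterable[tuple[str, str]], site_seq: str,
                    cfg: CallerConfig,
                    mapper: KmerMapper | None = None
                    ) -> tuple[list[Candidate], list[Candidate], dict]:
    """Select candidate split reads.

    ``reads`` yields ``(read_id, sequence)``.  A candidate contains the site
    (within ``site_max_mismatch``) with >= ``min_flank`` bases on both sides
    and — when a mapper over the reference (plus, for diploids, the native
    homolog) is supplied — does not place end-to-end on any reference
    sequence.  Because the site is palindromic a single forward scan covers
    both read strands.

    Returns ``(candidates, mapped_site_reads, stats)``: the second list
    holds site-spanning reads that *did* map end-to-end — direct evidence
    for parental junctions retained in the strain.
    """
    stats = {"reads_in": 0, "site_containing": 0, "short_flank": 0,
             "mapped_excluded": 0, "candidates": 0}
    out: list[Candidate] = []
    mapped: list[Candidate] = []
    m = len(site_seq)
    for read_id, seq in reads:
        stats["reads_in"] += 1
        positions = _find_site(seq, site_seq, cfg.site_max_mismatch)
        if not positions:
            continue
        stats["site_containing"] += 1
        usable = [p for p in positions
                  if p >= cfg.min_flank and len(seq) - p - m >= cfg.min_flank]
        if not usable:
            stats["short_flank"] += 1
            continue
        if mapper is not None and mapper.maps_end_to_end(
                seq, cfg.map_max_mismatch):
            stats["mapped_excluded"] += 1
            mapped.append(Candidate(read_id, seq, usable[0]))
            continue
        out.append(Candidate(read_id, seq, usable[0]))
        stats["candidates"] += 1
    return out, mapped, stats


def _assign_flank(flank: str, entries: dict[End, str], anchored: str,
                  cfg: CallerConfig) -> tuple[End | None, int]:
    """Unique best segment-end for one flank.

    ``anchored`` is 'right' when the flank starts at the site (compare
    prefixes against the index entries) and 'left' when it ends at the site
    (compare suffixes against the reverse complement of the entries).
    Returns (end, mismatches) or (None, reason-agnostic sentinel) when no
    unique within-budget hit exists.
    """
    best_end: End | None = None
    best = second = 10 ** 9
    for end, entry in entries.items():
        m = min(len(flank), len(entry))
        if anchored == "right":
            d = hamming(flank[:m], entry[:m],
                        limit=cfg.max_mismatch_per_flank + 1)
        else:
            rc = revcomp(entry)
            d = hamming(flank[-m:], rc[-m:],
                        limit=cfg.max_mismatch_per_flank + 1)
        if d < best:
            second = best
            best, best_end = d, end
        elif d < second:
            second = d
    if best > cfg.max_mismatch_per_flank or second - best < 1:
        return None, best
    return best_end, best


def trisect_and_assign(candidate: Candidate, flank_index: dict[End, str],
                       cfg: CallerConfig, site_len: int = 34
                       ) -> tuple[JunctionObservation | None, str]:
    """Trisect a candidate read and resolve both flanks.

    Returns ``(observation, "ok")`` or ``(None, reason)`` with reason in
    {"short_flank", "ambiguous_left", "ambiguous_right"}.
    """
    pos = candidate.site_pos
    seq = candidate.seq
    left = seq[:pos][-cfg.flank_index_len:]
    right = seq[pos + site_len:][:cfg.flank_index_len]
    if len(left) < cfg.min_flank or len(right) < cfg.min_flank:
        return None, "short_flank"
    left_end, d_left = _assign_flank(left, flank_index, "left", cfg)
    if left_end is None:
        return None, "ambiguous_left"
    right_end, d_right = _assign_flank(right, flank_index, "right", cfg)
    if right_end is None:
        return None, "ambiguous_right"
    junction = canonical_junction(left_end, right_end)
    return JunctionObservation(candidate.read_id, junction,
                               (d_left, d_right)), "ok"


def call_junctions(observations: Iterable[JunctionObservation],
                   ref: SegmentedReference,
                   cfg: CallerConfig) -> pd.DataFrame:
    """Group observations into supported junctions.

    Support counts distinct read *pairs* (mate suffixes ``/1``/``/2`` are
    collapsed), junctions below ``min_support`` are dropped, and each kept
    junction is labelled parental or novel.  Output order is deterministic:
    sorted by segment ids then ends.
    """
    groups: dict[JunctionKey, set[str]] = {}
    for obs in observations:
        base = obs.read_id.rsplit("/", 1)[0]
        groups.setdefault(obs.junction, set()).add(base)
    parental = ref.parental_junctions()
    rows = []
    for junction, readset in groups.items():
        support = len(readset)
        if support < cfg.min_support:
            continue
        (sa, ea), (sb, eb) = junction
        rows.append({"chrom": ref.chrom_id, "segA": sa, "endA": ea,
                     "segB": sb, "endB": eb, "support": support,
                     "label": "parental" if junction in parental
                     else "novel"})
    df = pd.DataFrame(rows, columns=["chrom", "segA", "endA", "segB",
                                     "endB", "support", "label"])
    return df.sort_values(["segA", "endA", "segB", "endB"],
                          ignore_index=True)


def junction_keys(df: pd.DataFrame) -> set[JunctionKey]:
    return {canonical_junction((int(r.segA), r.endA), (int(r.segB), r.endB))
            for r in df.itertuples()}


def novel_junction_keys(df: pd.DataFrame) -> set[JunctionKey]:
    return junction_keys(df[df["label"] == "novel"])


def _site_lookup(ref: SegmentedReference, overhang: int) -> dict[int, int]:
    """Map reference start coordinate -> 1-based site index, including the
    origin-extension images of a circular reference."""
    lut = {a: i for i, (a, _b) in enumerate(ref.loxp.sites, start=1)}
    if ref.topology == "circular":
        L = len(ref.sequence)
        for i, (a, b) in enumerate(ref.loxp.sites, start=1):
            if b <= overhang:
                lut[a + L] = i
    return lut


def _parental_junction_of_site(ref: SegmentedReference,
                               site_index: int) -> JunctionKey:
    if ref.topology == "linear":
        left, right = site_index, site_index + 1
    else:
        left = site_index - 1 if site_index > 1 else ref.n_segments
        right = site_index
    return canonical_junction((left, "R"), (right, "L"))


def parental_observations(mapped: list[Candidate], ref: SegmentedReference,
                          cfg: CallerConfig, mapper: KmerMapper,
                          overhang: int = 99) -> list[JunctionObservation]:
    """Turn mapped site-spanning reads into parental-junction observations.

    A read that places end-to-end on the reference and covers a loxPsym site
    with >= ``min_flank`` bases on both sides attests that the reference
    adjacency across that site is retained in the strain."""
    lut = _site_lookup(ref, overhang)
    out = []
    for cand in mapped:
        pl = mapper.map_read(cand.seq)
        if pl is None or pl.seq_idx != 0:
            continue                         # ambiguous or native-homolog read
        if pl.strand == "+":
            site_start = pl.pos + cand.site_pos
        else:
            site_start = pl.pos + len(cand.seq) - cand.site_pos \
                - len(ref.site_seq)
        site = lut.get(site_start)
        if site is None:
            continue
        junction = _parental_junction_of_site(ref, site)
        out.append(JunctionObservation(cand.read_id, junction, (0, 0)))
    return out


def call_pipeline(pairs, ref: SegmentedReference, cfg: CallerConfig,
                  extra_ref_seqs: list[str] = (),
                  mapper: KmerMapper | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Full caller on in-memory read pairs.

    Candidate selection (unmapped site-spanning reads), trisection and flank
    assignment give novel-junction observations; mapped site-spanning reads
    give parental-junction observations; both are grouped, support-filtered
    and labelled.  ``extra_ref_seqs`` typically holds the diploid native
    homolog so homolog-consistent reads are excluded."""
    if mapper is None:
        mapper = reference_mapper(ref, extra_ref_seqs,
                                  max_mismatch=cfg.map_max_mismatch)
    flank_index = end_flank_index(ref, cfg.flank_index_len)
    reads = ((r.name, r.seq) for pair in pairs for r in pair)
    candidates, mapped, stats = find_loxp_reads(reads, ref.site_seq, cfg,
                                                mapper)
    observations = parental_observations(mapped, ref, cfg, mapper)
    stats["parental_observations"] = len(observations)
    discards = {"short_flank": 0, "ambiguous_left": 0, "ambiguous_right": 0}
    site_len = len(ref.site_seq)
    for cand in candidates:
        obs, reason = trisect_and_assign(cand, flank_index, cfg, site_len)
        if obs is None:
            discards[reason] += 1
        else:
            observations.append(obs)
    stats.update({f"discard_{k}": v for k, v in discards.items()})
    stats["observations"] = len(observations)
    df = call_junctions(observations, ref, cfg)
    return df, stats


def candidates_from_sam(sam_path, site_seq: str, cfg: CallerConfig
                        ) -> tuple[list[Candidate], dict]:
    """Candidate split reads from an externally aligned SAM: unmapped
    records are scanned for the site, mapped records are excluded."""
    import pysam

    stats = {"reads_in": 0, "site_containing": 0, "short_flank": 0,
             "mapped_excluded": 0, "candidates": 0}
    out: list[Candidate] = []
    m = len(site_seq)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence \
                    is None:
                continue
            stats["reads_in"] += 1
            seq = rec.query_sequence
            positions = _find_site(seq, site_seq, cfg.site_max_mismatch)
            if not positions:
                continue
            stats["site_containing"] += 1
            if not rec.is_unmapped:
                stats["mapped_excluded"] += 1
                continue
            usable = [p for p in positions if p >= cfg.min_flank
                      and len(seq) - p - m >= cfg.min_flank]
            if not usable:
                stats["short_flank"] += 1
                continue
            name = rec.query_name + ("/1" if rec.is_read1 else
                                     "/2" if rec.is_read2 else "")
            out.append(Candidate(name, seq, usable[0]))
            stats["candidates"] += 1
    return out, stats
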