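"""Copy-number estimation, structure reconstruction and event typing.

Given the junction table and per-segment sequencing depth of a SCRaMbLEd
strain, this module (i) converts depth into integer segment copy numbers,
(ii) rebuilds candidate chromosome structures as walks through the segment
graph — each segment traversed exactly its copy number of times, consecutive
segments joined only across observed loxPsym junctions — and (iii) types the
rearrangement events: a deletion is a maximal run of copy-0 reference
segments, a duplication a maximal run of copy >= 2, and an inversion a
maximal run of orientation-flipped segments bounded by its two tell-tale
novel junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._mapper import KmerMapper
from .junctions import junction_keys
from .refmodel import SegmentedReference, canonical_junction
from .scramble import RearrangementEvent, SignedStructure


class ReconstructionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def segment_depth(pairs, ref: SegmentedReference,
                  native_seq: str | None = None,
                  mapper: KmerMapper | None = None,
                  native_mapper: KmerMapper | None = None) -> np.ndarray:
    """Mean per-base depth over each segment from in-memory read pairs.

    Reads are placed with the built-in seed-and-vote mapper (unique best
    end-to-end position).  With a diploid ``native_seq`` the read is assigned
    to the homolog it matches with fewer mismatches; ties (reads covering no
    distinguishing substitution) contribute half a read to the synthetic
    chromosome, so an unrearranged synthetic segment reports roughly half the
    total locus depth.  loxPsym intervals are outside all segments and are
    never counted.
    """
    from .junctions import reference_mapper

    circular = ref.topology == "circular"
    if mapper is None:
        mapper = reference_mapper(ref)
    if native_seq is not None and native_mapper is None:
        ext = native_seq + native_seq[:99] if circular else native_seq
        native_mapper = KmerMapper([ext])
    placements = []
    read_len = None
    for pair in pairs:
        for read in pair:
            read_len = read_len or len(read.seq)
            p_syn = mapper.map_read(read.seq)
            if p_syn is not None and p_syn.seq_idx != 0:
                p_syn = None
            if native_seq is None:
                if p_syn is not None:
                    placements.append((p_syn.pos, 1.0))
                continue
            p_nat = native_mapper.map_read(read.seq)
            if p_syn is None:
                continue
            if p_nat is None or p_syn.mismatches < p_nat.mismatches:
                placements.append((p_syn.pos, 1.0))
            elif p_syn.mismatches == p_nat.mismatches:
                placements.append((p_syn.pos, 0.5))
    if not placements:
        raise ReconstructionError("no reads placed on the reference")
    L = len(ref.sequence)
    diff = np.zeros(L + 1)
    for pos, w in placements:
        end = pos + read_len
        if end <= L:
            diff[pos] += w
            diff[end] -= w
        else:                               # read spans the circular origin
            diff[pos] += w
            diff[L] -= w
            diff[0] += w
            diff[end - L] -= w
    cov = np.cumsum(diff)[:L]
    return np.array([cov[s.start:s.end].mean() for s in ref.segments])


def depth_from_sam(sam_path, ref: SegmentedReference) -> np.ndarray:
    """Per-segment mean depth from an externally aligned SAM file."""
    import pysam

    cov = np.zeros(len(ref.sequence))
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            a, b = rec.reference_start, rec.reference_end
            cov[a:min(b, len(cov))] += 1
    if cov.sum() == 0:
        raise ReconstructionError("no reads placed on the reference")
    return np.array([cov[s.start:s.end].mean() for s in ref.segments])


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberProfile:
    """Raw per-segment depth, the per-copy baseline, rounded integer copies
    and a mosaic flag for segments whose depth sits far from any integer
    multiple (possible mixed colony)."""

    depth: np.ndarray
    copies: np.ndarray
    baseline: float
    mosaic: np.ndarray

    def retained_mask(self) -> np.ndarray:
        return self.copies >= 1


def novel_segments(junction_df: pd.DataFrame) -> set[int]:
    nov = junction_df[junction_df["label"] == "novel"]
    return set(nov["segA"].astype(int)) | set(nov["segB"].astype(int))


def baseline_exclusions(ref: SegmentedReference,
                        junction_df: pd.DataFrame) -> set[int]:
    """Segments unusable for the depth baseline: anything named by a novel
    junction, plus the terminal segments of a linear chromosome, whose mean
    depth is depressed by the fragment-start coverage ramp at the ends."""
    out = novel_segments(junction_df)
    if ref.topology == "linear":
        out |= {1, ref.n_segments}
    return out


def estimate_copy_number(depths: np.ndarray,
                         exclude: set[int] = frozenset(),
                         anchor_index: int | None = None,
                         mosaic_tol: float = 0.3) -> CopyNumberProfile:
    """Integer copy numbers from per-segment depth.

    The per-copy baseline starts from the centromeric segment when
    ``anchor_index`` is given — viability pins its copy number at exactly
    one — and is refined as the median over segments not named by any novel
    junction (``exclude``) whose depth lies within a band of the anchor, so
    deleted or duplicated segments never drag the baseline.  Without an
    anchor the global median serves as the starting point.  Copies are the
    nearest integer (ties to even).  For diploids pass homolog-resolved
    depth of the synthetic chromosome.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 3:
        raise ReconstructionError("need >= 3 segments for a depth baseline")
    b0 = float(np.median(depths))
    if anchor_index is not None and depths[anchor_index] > 0:
        b0 = float(depths[anchor_index])
    if b0 <= 0:
        raise ReconstructionError("depth baseline is zero: chromosome lost?")
    band = [d for i, d in enumerate(depths)
            if i + 1 not in exclude and 0.66 * b0 <= d <= 1.5 * b0]
    baseline = float(np.median(band)) if band else b0
    ratio = depths / baseline
    copies = np.rint(ratio).astype(int)
    copies[copies < 0] = 0
    mosaic = np.abs(ratio - copies) > mosaic_tol
    return CopyNumberProfile(depths, copies, baseline, mosaic)


# ---------------------------------------------------------------------------
# segment graph + structure search
# ---------------------------------------------------------------------------

def build_segment_graph(junction_df: pd.DataFrame,
                        copies: np.ndarray) -> nx.MultiGraph:
    """Multigraph over segment ends: one internal edge per retained copy of
    each segment, one edge per observed junction.  A chromosome is a walk
    using each internal edge exactly once."""
    g = nx.MultiGraph()
    for seg0, c in enumerate(copies):
        seg = seg0 + 1
        if c >= 1:
            g.add_node((seg, "L"))
            g.add_node((seg, "R"))
            for _ in range(int(c)):
                g.add_edge((seg, "L"), (seg, "R"), kind="segment")
    for r in junction_df.itertuples():
        g.add_edge((int(r.segA), r.endA), (int(r.segB), r.endB),
                   kind="junction", support=int(r.support), label=r.label)
    return g


def _tail_end(signed_seg: int) -> tuple[int, str]:
    return (signed_seg, "R") if signed_seg > 0 else (-signed_seg, "L")


def _adjacency(junctions: set) -> dict:
    adj: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for a, b in junctions:
        adj.setdefault(a, []).append(b)
        if a != b:
            adj.setdefault(b, []).append(a)
    for k in adj:
        adj[k] = sorted(set(adj[k]))
    return adj


def reconstruct_structure(junction_df: pd.DataFrame, copies: np.ndarray,
                          ref: SegmentedReference, cap: int = 16,
                          max_steps: int = 500_000
                          ) -> tuple[list[SignedStructure], str, dict]:
    """Enumerate chromosome structures consistent with junctions + copies.

    Linear chromosomes are anchored at the two telomeric segments (the first
    and last reference segments, which Cre cannot detach); circular ones are
    closed walks reported in canonical rotation/reflection.  Every observed
    junction must be used at least once and each segment exactly its copy
    number of times.  Enumeration is depth-first with deterministic
    tie-breaking (smallest segment id, '+' orientation first) and stops at
    ``cap`` distinct structures.  Returns (structures, status, diagnostics)
    with status in {"unique", "ambiguous", "inconsistent"}.
    """
    juncs = junction_keys(junction_df)
    adj = _adjacency(juncs)
    remaining = [int(c) for c in copies]
    n = ref.n_segments
    diagnostics: dict = {}
    if ref.topology == "linear":
        if remaining[0] < 1 or remaining[-1] < 1:
            return [], "inconsistent", {"reason": "telomeric segment lost"}
        start_opts = [1]
        end_seg = n
    else:
        present = [i + 1 for i in range(n) if remaining[i] >= 1]
        if not present:
            return [], "inconsistent", {"reason": "no segments retained"}
        start_opts = [present[0]]
        end_seg = None

    results: list[SignedStructure] = []
    seen: set[tuple[int, ...]] = set()
    steps = 0

    def dfs(path: list[int], used: set) -> None:
        nonlocal steps
        if len(results) >= cap or steps > max_steps:
            return
        steps += 1
        if sum(remaining) == 0:
            if ref.topology == "linear":
                if path[-1] != end_seg:
                    return
                if not juncs <= used:
                    return
                results.append(SignedStructure(tuple(path), "linear"))
            else:
                closing = canonical_junction(_tail_end(path[-1]),
                                             (path[0], "L"))
                if closing not in juncs or not juncs <= (used | {closing}):
                    return
                cand = SignedStructure(tuple(path), "circular").canonical()
                if cand.order not in seen:
                    seen.add(cand.order)
                    results.append(cand)
            return
        tail = _tail_end(path[-1])
        for nxt_end in adj.get(tail, ()):
            seg, side = nxt_end
            if remaining[seg - 1] <= 0:
                continue
            signed = seg if side == "L" else -seg
            if ref.topology == "linear" and seg == end_seg and side == "R":
                continue                     # telomeric end cannot be internal
            j = canonical_junction(tail, nxt_end)
            remaining[seg - 1] -= 1
            path.append(signed)
            dfs(path, used | {j})
            path.pop()
            remaining[seg - 1] += 1

    for start in start_opts:
        remaining[start - 1] -= 1
        dfs([start], set())
        remaining[start - 1] += 1

    if not results:
        # degree diagnostics: junction degree vs copy demand per segment end
        bad = []
        for seg0, c in enumerate(copies):
            seg = seg0 + 1
            for side in ("L", "R"):
                deg = len(adj.get((seg, side), ()))
                telo = ref.topology == "linear" and (
                    (seg == 1 and side == "L") or (seg == n and side == "R"))
                if c >= 1 and deg == 0 and not telo:
                    bad.append((seg, side))
        diagnostics["unconnected_ends"] = bad
        return [], "inconsistent", diagnostics
    status = "unique" if len(results) == 1 else "ambiguous"
    diagnostics["n_structures"] = len(results)
    diagnostics["search_steps"] = steps
    return results, status, diagnostics


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) 1-based inclusive segment ids,
    wrapping across the origin for circular references."""
    n = mask.size
    if not mask.any():
        return []
    if mask.all():
        return [(1, n)]
    runs = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    if circular and len(runs) >= 2 and runs[0][0] == 1 and runs[-1][1] == n:
        first, last = runs.pop(0), runs.pop()
        runs.append((last[0], first[1]))      # wrap-around run
    return runs


def _structure_junctions(structure: SignedStructure) -> set:
    out = set()
    order = structure.order
    k = len(order)
    upto = k if structure.topology == "circular" else k - 1
    for i in range(upto):
        u, v = order[i], order[(i + 1) % k]
        left = (u, "R") if u > 0 else (-u, "L")
        right = (v, "L") if v > 0 else (-v, "R")
        out.add(canonical_junction(left, right))
    return out


def _run_loci(ref: SegmentedReference, first: int, last: int
              ) -> tuple[int, int]:
    return ref.site_left_of(first), ref.site_right_of(last)


def _neighbors(ref: SegmentedReference, seg: int) -> tuple[int | None,
                                                           int | None]:
    n = ref.n_segments
    circular = ref.topology == "circular"
    prev = seg - 1 if seg > 1 else (n if circular else None)
    nxt = seg + 1 if seg < n else (1 if circular else None)
    return prev, nxt


def classify_signature(ref: SegmentedReference, novel: set,
                       copies: np.ndarray) -> list[RearrangementEvent]:
    """Type rearrangements from the (novel-junction set, copy-number)
    signature — the representation that is invariant across all chromosome
    walks consistent with the data, hence what cohort statistics are built
    on.

    Rules: a deletion is a maximal run of copy-0 reference segments, a
    duplication a maximal run of copy >= 2, an inversion a block bounded by
    its two tell-tale novel junctions {(i-1)R, jR} and {iL, (j+1)L}.  Novel
    junctions explained by none of these signatures are reported as
    ``complex`` events rather than silently dropped.
    """
    circular = ref.topology == "circular"
    n = ref.n_segments
    copies = np.asarray(copies, dtype=int)
    events: list[RearrangementEvent] = []
    explained: set = set()

    for first, last in _runs(copies == 0, circular):
        events.append(RearrangementEvent(
            "deletion", _block(first, last, n), _run_loci(ref, first, last)))
        prev, _ = _neighbors(ref, first)
        _, nxt = _neighbors(ref, last)
        if prev is not None and nxt is not None:
            explained.add(canonical_junction((prev, "R"), (nxt, "L")))

    for first, last in _runs(copies >= 2, circular):
        events.append(RearrangementEvent(
            "duplication", _block(first, last, n),
            _run_loci(ref, first, last)))
        # tandem head-to-tail junction of the duplicated block
        explained.add(canonical_junction((last, "R"), (first, "L")))

    for j1 in sorted(novel):
        (a, ea), (b, eb) = j1
        if not (ea == "R" and eb == "R"):
            continue
        lo, hi = min(a, b), max(a, b)
        _, first = _neighbors(ref, lo)
        _, nxt = _neighbors(ref, hi)
        if first is None or nxt is None:
            continue
        j2 = canonical_junction((first, "L"), (nxt, "L"))
        block = _block(first, hi, n)
        if j2 in novel and all(copies[s - 1] >= 1 for s in block):
            events.append(RearrangementEvent(
                "inversion", block, _run_loci(ref, first, hi)))
            explained |= {j1, j2}

    for j in sorted(novel - explained):
        (sa, ea), (sb, eb) = j
        loci = (ref.site_of_end(sa, ea), ref.site_of_end(sb, eb))
        events.append(RearrangementEvent(
            "complex", tuple(sorted({sa, sb})), loci))
    return sorted(events, key=lambda e: (e.segments[0], e.type, e.loci))


def classify_events(ref: SegmentedReference,
                    structure: SignedStructure | None = None,
                    junction_df: pd.DataFrame | None = None,
                    copies: np.ndarray | None = None
                    ) -> list[RearrangementEvent]:
    """Type the rearrangement events of a strain.

    The classification operates on the walk-invariant signature (novel
    junction set + copy numbers); a ``structure`` input — a simulated or
    reconstructed chromosome — is first reduced to its signature, so a
    ground-truth structure and a correct reconstruction always classify
    identically even when several walks explain the same data.
    """
    if structure is not None:
        cps = structure.copy_numbers(ref.n_segments)
        novel = _structure_junctions(structure) - ref.parental_junctions()
    else:
        if junction_df is None or copies is None:
            raise ValueError("need a structure or (junction_df, copies)")
        cps = np.asarray(copies, dtype=int)
        novel = junction_keys(junction_df) - ref.parental_junctions()
    return classify_signature(ref, novel, cps)


def _block(first: int, last: int, n: int) -> tuple[int, ...]:
    if first <= last:
        return tuple(range(first, last + 1))
    return tuple(range(first, n + 1)) + tuple(range(1, last + 1))


def _inversion_junctions(ref: SegmentedReference, first: int,
                         last: int) -> set | None:
    """The two novel junctions an inversion of block [first..last] creates:
    {(first-1)R, lastR} and {firstL, (last+1)L} (neighbours wrap on circular
    references; None when a boundary is a telomere)."""
    n = ref.n_segments
    circular = ref.topology == "circular"
    prev = first - 1 if first > 1 else (n if circular else None)
    nxt = last + 1 if last < n else (1 if circular else None)
    if prev is None or nxt is None:
        return None
    return {canonical_junction((prev, "R"), (last, "R")),
            canonical_junction((first, "L"), (nxt, "L"))}


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

def retention_rate(copies: np.ndarray, ref: SegmentedReference) -> float:
    """Percent of loxPsym-flanked segment base pairs retained (copy >= 1),
    to two decimals."""
    lengths = np.array([s.length_bp for s in ref.segments], dtype=float)
    retained = lengths[np.asarray(copies) >= 1].sum()
    return round(100.0 * retained / lengths.sum(), 2)


def reconstructed_bp(copies: np.ndarray, ref: SegmentedReference) -> int:
    lengths = np.array([s.length_bp for s in ref.segments], dtype=int)
    return int((np.asarray(copies) * lengths).sum())
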