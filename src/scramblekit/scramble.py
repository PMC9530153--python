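"""Cre/loxPsym recombination simulator with ground-truth event logging.

Simulates SCRaMbLE on a segmented chromosome: each event picks a pair of
loxPsym loci in the *current* structure (uniformly, or biased by a 3D contact
matrix) and applies a deletion, inversion or tandem duplication of the block
between them.  Because Cre-lox recombination regenerates intact sites, every
inter-segment boundary remains a usable locus after each event, so later
events can hit junctions created by earlier ones.

Viability is enforced after every event: haploid cells die when an
essential-gene-bearing segment drops to copy number zero or the centromere
copy number leaves one; heterozygous diploids (synthetic chromosome mated to
a loxPsym-free native homolog) tolerate essential-segment loss and only
require a single centromere on the synthetic chromosome.  Non-viable
intermediates are resampled, modelling death during induction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refmodel import SegmentedReference

EVENT_TYPES = ("deletion", "inversion", "duplication")


class SimulationError(RuntimeError):
    """Raised when the sampler cannot produce a viable event."""


@dataclass(frozen=True)
class SignedStructure:
    """Ordered, oriented segment list of a (possibly SCRaMbLEd) chromosome.

    ``order`` holds signed seg_ids; a negative id is an inverted segment.
    Circular structures compare equal up to rotation and whole-molecule
    reversal; :meth:`canonical` returns the lexicographically smallest
    representative.
    """

    order: tuple[int, ...]
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not self.order:
            raise ValueError("empty structure")

    @classmethod
    def reference(cls, ref: SegmentedReference) -> "SignedStructure":
        return cls(tuple(range(1, ref.n_segments + 1)), ref.topology)

    def __len__(self) -> int:
        return len(self.order)

    def copy_numbers(self, n_segments: int) -> np.ndarray:
        cn = np.zeros(n_segments, dtype=int)
        for s in self.order:
            cn[abs(s) - 1] += 1
        return cn

    def canonical(self) -> "SignedStructure":
        if self.topology == "linear":
            return self
        variants = []
        for orient in (self.order, tuple(-s for s in reversed(self.order))):
            for r in range(len(orient)):
                variants.append(orient[r:] + orient[:r])
        return SignedStructure(min(variants), "circular")

    def orientation_normalized(self) -> "SignedStructure":
        """Deterministic representative of a circular molecule's two
        orientations: the one with fewer inverted segments (a ring has no
        intrinsic strand, so inversion is defined against the majority
        orientation); ties break toward the lexicographically smaller
        canonical rotation.  Linear structures are returned unchanged."""
        if self.topology == "linear":
            return self
        flipped = SignedStructure(
            tuple(-s for s in reversed(self.order)), "circular")
        neg_self = sum(s < 0 for s in self.order)
        neg_flip = len(self.order) - neg_self
        if neg_self < neg_flip:
            chosen = self.order
        elif neg_flip < neg_self:
            chosen = flipped.order
        else:
            chosen = self.order \
                if min(self._rotations(self.order)) <= \
                min(self._rotations(flipped.order)) else flipped.order
        return SignedStructure(chosen, "circular")

    @staticmethod
    def _rotations(order: tuple[int, ...]) -> list[tuple[int, ...]]:
        return [order[r:] + order[:r] for r in range(len(order))]

    def equivalent(self, other: "SignedStructure") -> bool:
        if self.topology != other.topology:
            return False
        return self.canonical().order == other.canonical().order

    def n_loci(self) -> int:
        """Number of loxPsym loci (inter-segment boundaries) available for
        recombination in this structure."""
        return len(self.order) - 1 if self.topology == "linear" \
            else len(self.order)

    def boundary_ends(self, locus: int) -> tuple[tuple[int, str], tuple[int, str]]:
        """Oriented segment ends meeting at a boundary locus.

        Linear loci are numbered 1..k-1 (locus i sits between position i-1
        and i of ``order``); circular loci 0..k-1 with locus 0 between the
        last and first entries.
        """
        k = len(self.order)
        if self.topology == "linear":
            if not 1 <= locus <= k - 1:
                raise ValueError(f"locus {locus} out of range for k={k}")
            u, v = self.order[locus - 1], self.order[locus]
        else:
            u, v = self.order[locus - 1], self.order[locus % k]
        left = (u, "R") if u > 0 else (-u, "L")
        right = (v, "L") if v > 0 else (-v, "R")
        return left, right

    def sequence(self, ref: SegmentedReference) -> str:
        """Chromosome sequence implied by the structure: oriented segment
        sequences joined by intact loxPsym sites (circular: a site precedes
        every segment, matching the canonical rotation of the reference)."""
        site = ref.site_seq
        segs = [ref.segment_seq(s) for s in self.order]
        if self.topology == "linear":
            return site.join(segs)
        return "".join(site + s for s in segs)


@dataclass(frozen=True)
class RearrangementEvent:
    """One recombination outcome: typed block of reference segments plus the
    1-based loxPsym site indices adjacent to the block's two boundary
    flanks.  ``structure_loci`` (simulator ground truth only) are the
    boundary positions in the structure the event was applied to, allowing
    exact replay of a strain's history."""

    type: str
    segments: tuple[int, ...]
    loci: tuple[int, int]
    order: int = 0                  # 1-based position in a strain's history
    structure_loci: tuple[int, int] | None = None


@dataclass
class SimConfig:
    """Study conditions for one simulated strain.

    ``n_events`` is either a fixed count or a Poisson mean (``poisson=True``;
    SCRaMbLEd strains carrying at least one event typically show about four
    events, hence the default mean of 4.0).
    """

    n_events: float = 4.0
    poisson: bool = True
    type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ploidy: str = "haploid"
    contact_bias: "object | None" = None      # ContactMatrix, optional
    contact_bin_size: int = 10_000
    max_resample: int = 200
    viability_each_event: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_probs) - 1.0) > 1e-9:
            raise ValueError("type_probs must sum to 1")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")


@dataclass
class GroundTruth:
    """Everything the detection pipeline is later asked to recover."""

    structure: SignedStructure
    events: list[RearrangementEvent]
    copy_numbers: np.ndarray
    n_resamples: int = 0


# ---------------------------------------------------------------------------
# event mechanics
# ---------------------------------------------------------------------------

def _block_indices(structure: SignedStructure, locus_a: int,
                   locus_b: int) -> tuple[int, int]:
    """Positions [i, j) of the block between two loci (forward arc for
    circular structures)."""
    k = len(structure.order)
    if locus_a == locus_b:
        raise ValueError("recombination needs two distinct loxPsym loci")
    if structure.topology == "linear":
        a, b = sorted((locus_a, locus_b))
        if not (1 <= a and b <= k - 1):
            raise ValueError(f"loci ({locus_a},{locus_b}) out of range")
        return a, b
    if not (0 <= locus_a < k and 0 <= locus_b < k):
        raise ValueError(f"loci ({locus_a},{locus_b}) out of range")
    return locus_a, locus_b


def apply_event(structure: SignedStructure, locus_a: int, locus_b: int,
                event_type: str) -> SignedStructure:
    """Apply one Cre recombination outcome to a structure.

    The block runs from ``locus_a`` to ``locus_b`` (for circular structures:
    the forward arc, so the caller chooses which arc by ordering the loci).
    Deletion excises the block, inversion reverses it and flips every sign,
    duplication tandem-duplicates it in place with unchanged orientation.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    i, j = _block_indices(structure, locus_a, locus_b)
    order = structure.order
    k = len(order)
    if structure.topology == "linear" or i < j:
        block = order[i:j]
        rest_left, rest_right = order[:i], order[j:]
    else:                                       # circular wrap-around arc
        block = order[i:] + order[:j]
        rest_left, rest_right = (), order[j:i]
    if not block:
        raise ValueError("empty block between loci")
    if event_type == "deletion":
        if len(block) == k:
            raise ValueError("cannot delete the entire circular chromosome")
        new = rest_left + rest_right
    elif event_type == "inversion":
        new = rest_left + tuple(-s for s in reversed(block)) + rest_right
    else:
        new = rest_left + block + block + rest_right
    return SignedStructure(new, structure.topology)


def event_block_segments(structure: SignedStructure, locus_a: int,
                         locus_b: int) -> tuple[int, ...]:
    i, j = _block_indices(structure, locus_a, locus_b)
    if structure.topology == "linear" or i < j:
        block = structure.order[i:j]
    else:
        block = structure.order[i:] + structure.order[:j]
    return tuple(sorted({abs(s) for s in block}))


def event_reference_loci(structure: SignedStructure, ref: SegmentedReference,
                         locus_a: int, locus_b: int) -> tuple[int, int]:
    """Reference loxPsym site indices recombined by an event, identified via
    the block's inner boundary flanks (the only sequence evidence a
    split-read caller ever sees)."""
    i, j = _block_indices(structure, locus_a, locus_b)
    k = len(structure.order)
    first = structure.order[i % k]
    last = structure.order[(j - 1) % k]
    head = ref.site_of_end(first, "L") if first > 0 \
        else ref.site_of_end(-first, "R")
    tail = ref.site_of_end(last, "R") if last > 0 \
        else ref.site_of_end(-last, "L")
    return head, tail


def viability_check(structure: SignedStructure, ref: SegmentedReference,
                    ploidy: str) -> bool:
    """Cell-survival rule after rearrangement.

    Haploids require every essential segment at copy >= 1 and exactly one
    centromere; diploids keep a native homolog carrying all essentials, so
    only the single-centromere constraint applies to the synthetic
    chromosome.
    """
    cn = structure.copy_numbers(ref.n_segments)
    if cn[ref.centromere_id() - 1] != 1:
        return False
    if ploidy == "haploid":
        for seg_id in ref.essential_ids():
            if cn[seg_id - 1] == 0:
                return False
    return True


# ---------------------------------------------------------------------------
# strain simulation
# ---------------------------------------------------------------------------

def _locus_weights(structure: SignedStructure, ref: SegmentedReference,
                   cfg: SimConfig) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Candidate (ordered) locus pairs and their sampling weights."""
    loci = list(range(1, len(structure.order))) if structure.topology == \
        "linear" else list(range(len(structure.order)))
    pairs = [(a, b) for a in loci for b in loci if a != b]
    if cfg.contact_bias is None:
        return pairs, np.ones(len(pairs))
    mat = cfg.contact_bias.matrix
    bsz = cfg.contact_bias.bin_size
    # a locus inherits the genomic bin of the reference site adjacent to its
    # left-hand flank — the best observable proxy after rearrangement
    bins = {}
    for locus in loci:
        (seg, end), _ = structure.boundary_ends(locus)
        site = ref.site_of_end(seg, end)
        bins[locus] = min(ref.site_position(site) // bsz, mat.shape[0] - 1)
    w = np.array([mat[bins[a], bins[b]] for a, b in pairs], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(pairs))
    return pairs, w


def simulate_strain(ref: SegmentedReference, cfg: SimConfig) -> GroundTruth:
    """Simulate one SCRaMbLEd strain and log its ground truth.

    Events are applied sequentially to the evolving structure; after each
    event the viability filter rejects dead intermediates and the event is
    resampled (up to ``cfg.max_resample`` attempts across the strain).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.poisson(cfg.n_events)) if cfg.poisson else int(cfg.n_events)
    structure = SignedStructure.reference(ref)
    events: list[RearrangementEvent] = []
    resamples = 0
    for step in range(n):
        pairs, weights = _locus_weights(structure, ref, cfg)
        if not pairs:
            break                       # structure shrunk to a single segment
        p = weights / weights.sum()
        ok = False
        # the event type is drawn once and kept while loci are resampled, so
        # viability rejection reshapes *where* events land, not the realized
        # type frequencies; the remaining types are tried only if the drawn
        # type admits no viable locus pair at all
        first = EVENT_TYPES[rng.choice(3, p=np.asarray(cfg.type_probs))]
        fallback = [t for t in EVENT_TYPES if t != first]
        for etype in (first, *fallback):
            for _attempt in range(cfg.max_resample + 1):
                idx = rng.choice(len(pairs), p=p)
                a, b = pairs[idx]
                try:
                    candidate = apply_event(structure, a, b, etype)
                except ValueError:
                    resamples += 1
                    continue
                if cfg.viability_each_event and not viability_check(
                        candidate, ref, cfg.ploidy):
                    resamples += 1
                    continue
                ok = True
                break
            if ok:
                break
        if not ok:
            raise SimulationError(
                f"no viable {cfg.ploidy} event found after "
                f"{cfg.max_resample} resamples at step {step + 1}")
        loci = event_reference_loci(structure, ref, a, b)
        segs = event_block_segments(structure, a, b)
        events.append(RearrangementEvent(etype, segs, loci, order=step + 1,
                                         structure_loci=(a, b)))
        structure = candidate
    if not cfg.viability_each_event and not viability_check(
            structure, ref, cfg.ploidy):
        raise SimulationError("final structure is not viable "
                              "(end-state filtering mode)")
    return GroundTruth(structure, events,
                       structure.copy_numbers(ref.n_segments), resamples)


# ---------------------------------------------------------------------------
# diploid genomes
# ---------------------------------------------------------------------------

def diploid_genome(ref: SegmentedReference, structure: SignedStructure,
                   snp_density: float = 0.01, seed: int = 0,
                   flank_exclusion: int = 40) -> tuple[str, str, list[int]]:
    """Build the two homologs of a heterozygous SCRaMbLEd diploid.

    Returns ``(synthetic_seq, native_seq, snp_positions)``: the rearranged
    synthetic homolog implied by ``structure`` and a loxPsym-free native
    homolog (the wild-type parent) carrying random substitutions at
    ``snp_density`` per base.  Substitutions are kept out of the
    ``flank_exclusion`` bp windows homologous to loxPsym flanks so flank-based
    homolog assignment stays exact.
    """
    if not 0 < snp_density <= 0.05:
        raise ValueError("snp_density must be in (0, 0.05]; identical "
                         "homologs cannot be resolved")
    rng = np.random.default_rng(seed)
    syn = structure.sequence(ref)
    # native homolog: reference with the engineered loxPsym insertions absent
    parts = []
    pos = 0
    excluded_points = []
    for a, b in ref.loxp.sites:
        parts.append(ref.sequence[pos:a])
        pos = b
        excluded_points.append(sum(len(x) for x in parts))
    parts.append(ref.sequence[pos:])
    native = "".join(parts)
    mask = np.ones(len(native), dtype=bool)
    for p in excluded_points:
        mask[max(0, p - flank_exclusion):p + flank_exclusion] = False
    hits = np.nonzero((rng.random(len(native)) < snp_density) & mask)[0]
    seq = list(native)
    bases = "ACGT"
    for p in hits:
        choices = [b for b in bases if b != seq[p]]
        seq[p] = choices[rng.integers(3)]
    return syn, "".join(seq), hits.tolist()


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------

def structure_string(structure: SignedStructure) -> str:
    return ",".join(str(s) for s in structure.order)


def parse_structure(text: str, topology: str = "linear") -> SignedStructure:
    return SignedStructure(tuple(int(x) for x in text.split(",")), topology)


def ground_truth_table(strain_id: str, events: list[RearrangementEvent]):
    """One-row-per-event TSV-ready records for a strain's ground truth."""
    rows = []
    for ev in events:
        rows.append({
            "strain_id": strain_id,
            "order": ev.order,
            "type": ev.type,
            "loxp_loci": f"{ev.loci[0]},{ev.loci[1]}",
            "segments": ",".join(str(s) for s in ev.segments),
        })
    return rows
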