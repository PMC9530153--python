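"""Paired-end short-read simulator and read-quality filter.

Emits 100 bp paired-end reads (the sequencing configuration used for
SCRaMbLEd-strain genotyping) from one or more genome sequences — e.g. the two
homologs of a diploid — with fragment sizes matching a 200-400 bp library,
a uniform substitution error model and Phred+33 qualities.  The companion QC
filter drops read pairs whose N-base plus low-quality-base fraction exceeds
a configurable threshold, mirroring standard pre-alignment read cleaning.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .refmodel import revcomp


class Read(NamedTuple):
    name: str
    seq: str
    qual: str                       # Phred+33


class ReadPair(NamedTuple):
    r1: Read
    r2: Read


@dataclass
class ReadSimConfig:
    """Sequencing-run parameters.

    Defaults model a 100 bp paired-end run over a 200-400 bp insert library:
    insert sizes are normal(300, 30) truncated to [read_len, 2*insert_mean].
    ``error_rate`` is the per-base substitution probability; erroneous bases
    are emitted with a reduced quality symbol (``error_qual``).
    """

    read_len: int = 100
    mean_depth: float = 100.0
    insert_mean: int = 300
    insert_sd: float = 30.0
    error_rate: float = 0.001
    base_qual: int = 38
    error_qual: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")


@dataclass
class QCConfig:
    """Read-pair quality filter: drop a pair when either mate's
    (N bases + bases below ``phred_floor``) / length is strictly greater
    than ``max_bad_fraction``."""

    max_bad_fraction: float = 0.05
    phred_floor: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.max_bad_fraction < 1:
            raise ValueError("max_bad_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GenomeSource:
    """One haplotype to sequence: name, sequence, relative abundance (copy
    number in the cell) and topology."""

    name: str
    sequence: str
    abundance: float = 1.0
    circular: bool = False


def emit_reads(genomes: Iterable[GenomeSource],
               cfg: ReadSimConfig) -> list[ReadPair]:
    """Simulate paired-end reads over one or more genomes.

    Fragments are placed uniformly along each genome with expected counts
    proportional to ``length x abundance``; circular genomes are sampled
    across the origin.  Mate 1 reads the fragment 5'->3' from its left end,
    mate 2 is the reverse complement of its right end.
    """
    genomes = list(genomes)
    rng = np.random.default_rng(cfg.seed)
    weights = np.array([len(g.sequence) * g.abundance for g in genomes],
                       dtype=float)
    total_pairs = int(round(cfg.mean_depth * weights.sum()
                            / (2 * cfg.read_len)))
    counts = rng.multinomial(total_pairs, weights / weights.sum())
    pairs: list[ReadPair] = []
    rl = cfg.read_len
    serial = 0
    for g, n in zip(genomes, counts):
        if n == 0:
            continue
        L = len(g.sequence)
        if L <= cfg.insert_mean + 6 * cfg.insert_sd and not g.circular:
            raise ValueError(
                f"genome {g.name} too short for the insert distribution")
        inserts = np.clip(
            np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)),
            rl, 2 * cfg.insert_mean).astype(int)
        if g.circular:
            starts = rng.integers(0, L, size=n)
            doubled = g.sequence + g.sequence[:2 * cfg.insert_mean + 1]
        else:
            starts = (rng.random(n) * (L - inserts + 1)).astype(int)
            doubled = g.sequence
        for s, ins in zip(starts, inserts):
            frag = doubled[s:s + ins]
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            name = f"{g.name}_{serial}"
            pairs.append(ReadPair(Read(name + "/1", r1, ""),
                                  Read(name + "/2", r2, "")))
            serial += 1
    # inject substitution errors; sampling (read, position) with replacement
    # approximates per-base Bernoulli draws (collisions are negligible)
    base_q = chr(cfg.base_qual + 33) * rl
    err_q = chr(cfg.error_qual + 33)
    n_reads = 2 * len(pairs)
    n_err = rng.binomial(n_reads * rl, cfg.error_rate) if cfg.error_rate \
        else 0
    err_map: dict[int, list[int]] = {}
    if n_err:
        ridx = rng.integers(0, n_reads, size=n_err)
        pidx = rng.integers(0, rl, size=n_err)
        for r, p in zip(ridx.tolist(), pidx.tolist()):
            err_map.setdefault(r, []).append(p)
    out: list[ReadPair] = []
    alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i, pair in enumerate(pairs):
        mates = []
        for m, read in enumerate(pair):
            j = 2 * i + m
            if j in err_map:
                seq = list(read.seq)
                qual = list(base_q)
                for p in err_map[j]:
                    draws = alt.get(seq[p], "ACG")
                    seq[p] = draws[rng.integers(3)]
                    qual[p] = err_q
                mates.append(Read(read.name, "".join(seq), "".join(qual)))
            else:
                mates.append(Read(read.name, read.seq, base_q))
        out.append(ReadPair(*mates))
    return out


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def _bad_fraction(read: Read, phred_floor: int) -> float:
    floor_chr = chr(phred_floor + 33)
    bad = sum(1 for b, q in zip(read.seq, read.qual)
              if b == "N" or q < floor_chr)
    return bad / len(read.seq)


def qc_filter(pairs: Iterable[ReadPair],
              cfg: QCConfig | None = None) -> tuple[list[ReadPair], dict]:
    """Drop read pairs failing the bad-base-fraction rule.

    A read is bad when (N bases + bases with Phred < ``phred_floor``) exceeds
    ``max_bad_fraction`` of its length — *strictly* greater, so a 100 bp read
    with exactly 5 offending bases is retained.  Mates are kept or dropped
    together.  Returns the surviving pairs and a counts summary.
    """
    cfg = cfg or QCConfig()
    kept: list[ReadPair] = []
    dropped = 0
    for pair in pairs:
        if any(_bad_fraction(r, cfg.phred_floor) > cfg.max_bad_fraction
               for r in pair):
            dropped += 1
        else:
            kept.append(pair)
    return kept, {"pairs_in": dropped + len(kept),
                  "pairs_kept": len(kept), "pairs_dropped": dropped}


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------

def write_fastq(pairs: Iterable[ReadPair], path1, path2) -> None:
    """Write mates to a pair of (optionally gzipped) FASTQ files."""
    def opener(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with opener(path1) as f1, opener(path2) as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.name}\n{r1.seq}\n+\n{r1.qual}\n")
            f2.write(f"@{r2.name}\n{r2.seq}\n+\n{r2.qual}\n")


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Parse two mate FASTQ files back into read pairs."""
    from Bio import SeqIO

    def opener(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with opener(path1) as f1, opener(path2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            yield ReadPair(
                Read(rec1.id, str(rec1.seq),
                     "".join(chr(q + 33)
                             for q in rec1.letter_annotations["phred_quality"])),
                Read(rec2.id, str(rec2.seq),
                     "".join(chr(q + 33)
                             for q in rec2.letter_annotations["phred_quality"])))
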