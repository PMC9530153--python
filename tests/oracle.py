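"""Brute-force junction oracle: naive sliding-window / substring-search
re-derivation of the junction table, sharing no code path with the caller
(no k-mer index, no flank library)."""

from collections import defaultdict

import pandas as pd

from scramblekit.refmodel import SegmentedReference, canonical_junction, \
    revcomp


def _site_positions_naive(seq: str, site: str) -> list[int]:
    return [p for p in range(len(seq) - len(site) + 1)
            if seq[p:p + len(site)] == site]


def oracle_junctions(pairs, ref: SegmentedReference, min_flank: int = 15,
                     min_support: int = 5,
                     flank_cmp: int = 30) -> pd.DataFrame:
    """Recompute the junction table for error-free reads by exhaustive
    search.  Mapped-read exclusion uses Python substring search against the
    reference (extended past the origin for circular references); flank
    lookup compares the read flanks directly against every segment's
    prefix/suffix (both orientations)."""
    site = ref.site_seq
    ext = ref.sequence + (ref.sequence[:99]
                          if ref.topology == "circular" else "")
    ext_rc = revcomp(ext)

    # independent per-end flank sequences straight from segment slices
    left_options = {}        # sequence left of a site -> segment end
    right_options = {}       # sequence right of a site -> segment end
    for s in ref.segments:
        seq = ref.sequence[s.start:s.end]
        left_options[(s.seg_id, "R")] = seq[-flank_cmp:]
        left_options[(s.seg_id, "L")] = revcomp(seq[:flank_cmp])
        right_options[(s.seg_id, "L")] = seq[:flank_cmp]
        right_options[(s.seg_id, "R")] = revcomp(seq[-flank_cmp:])
    if ref.topology == "linear":
        # telomeric ends never touch a site
        left_options.pop((1, "L"))
        right_options.pop((1, "L"))
        left_options.pop((ref.n_segments, "R"))
        right_options.pop((ref.n_segments, "R"))

    site_starts = {a for a, _b in ref.loxp.sites}
    if ref.topology == "circular":
        L = len(ref.sequence)
        site_starts |= {a + L for a, b in ref.loxp.sites if b <= 99}

    def parental_of_site_start(start):
        idx = sorted(a for a, _ in ref.loxp.sites)
        a = start % len(ref.sequence)
        k = idx.index(a) + 1
        if ref.topology == "linear":
            return canonical_junction((k, "R"), (k + 1, "L"))
        left = k - 1 if k > 1 else ref.n_segments
        return canonical_junction((left, "R"), (k, "L"))

    support = defaultdict(set)
    for pair in pairs:
        for read in pair:
            seq = read.seq
            hits = [p for p in _site_positions_naive(seq, site)
                    if p >= min_flank
                    and len(seq) - p - len(site) >= min_flank]
            if not hits:
                continue
            p = hits[0]
            base = read.name.rsplit("/", 1)[0]
            mapped_at = ext.find(seq)
            if mapped_at == -1:
                rc_at = ext_rc.find(seq)
                mapped_at = None if rc_at == -1 else \
                    len(ext) - rc_at - len(seq)
                strand = "-"
            else:
                strand = "+"
            if mapped_at is not None:
                if strand == "+":
                    start = mapped_at + p
                else:
                    start = mapped_at + len(seq) - p - len(site)
                if start in site_starts:
                    support[parental_of_site_start(start)].add(base)
                continue
            left = seq[:p][-flank_cmp:]
            right = seq[p + len(site):][:flank_cmp]
            lhits = [e for e, opt in left_options.items()
                     if left[-min(len(left), len(opt)):]
                     == opt[-min(len(left), len(opt)):]]
            rhits = [e for e, opt in right_options.items()
                     if right[:min(len(right), len(opt))]
                     == opt[:min(len(right), len(opt))]]
            if len(lhits) != 1 or len(rhits) != 1:
                continue
            support[canonical_junction(lhits[0], rhits[0])].add(base)

    parental = ref.parental_junctions()
    rows = []
    for junction, reads in support.items():
        if len(reads) < min_support:
            continue
        (sa, ea), (sb, eb) = junction
        rows.append({"chrom": ref.chrom_id, "segA": sa, "endA": ea,
                     "segB": sb, "endB": eb, "support": len(reads),
                     "label": "parental" if junction in parental
                     else "novel"})
    df = pd.DataFrame(rows, columns=["chrom", "segA", "endA", "segB",
                                     "endB", "support", "label"])
    return df.sort_values(["segA", "endA", "segB", "endB"],
                          ignore_index=True)
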