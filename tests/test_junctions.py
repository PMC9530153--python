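import numpy as np
import pytest

from scramblekit.junctions import (CallerConfig,
                                   call_pipeline, find_loxp_reads,
                                   reference_mapper, trisect_and_assign)
from scramblekit.reads import GenomeSource, Read, ReadPair, ReadSimConfig, \
    emit_reads
from scramblekit.refmodel import (LOXPSYM_SITE, build_reference,
                                  canonical_junction, end_flank_index,
                                  revcomp)
from scramblekit.scramble import SignedStructure, SimConfig, simulate_strain


def _junction_read(ref, end_left, end_right, flank=20):
    """Sequence of a read spanning the junction between two segment ends."""
    seg_l, side_l = end_left
    seg_r, side_r = end_right
    left = ref.segment_seq(seg_l)[-flank:] if side_l == "R" \
        else revcomp(ref.segment_seq(seg_l)[:flank])
    right = ref.segment_seq(seg_r)[:flank] if side_r == "L" \
        else revcomp(ref.segment_seq(seg_r)[-flank:])
    return left + ref.site_seq + right


def _pairs_of(seqs):
    filler = "A" * 60
    return [ReadPair(Read(f"r{i}/1", s, "I" * len(s)),
                     Read(f"r{i}/2", filler, "I" * len(filler)))
            for i, s in enumerate(seqs)]


def test_candidate_selection_flank_thresholds(small_ref):
    cfg = CallerConfig()
    good = _junction_read(small_ref, (1, "R"), (3, "L"), flank=20)
    short = _junction_read(small_ref, (1, "R"), (3, "L"), flank=40)[26:]
    assert len(short) - short.find(LOXPSYM_SITE) - 34 == 40
    assert short.find(LOXPSYM_SITE) == 14          # 14 bp left flank
    cands, mapped, stats = find_loxp_reads(
        [("good", good), ("short", short), ("plain", "ACGT" * 30)],
        small_ref.site_seq, cfg)
    assert [c.read_id for c in cands] == ["good"]
    assert stats["short_flank"] == 1
    assert stats["site_containing"] == 2


def test_mapped_parental_read_excluded_from_novel_path(small_ref):
    cfg = CallerConfig()
    a, b = small_ref.loxp.sites[0]
    parental = small_ref.sequence[a - 30:b + 30]
    mapper = reference_mapper(small_ref)
    cands, mapped, stats = find_loxp_reads([("p", parental)],
                                           small_ref.site_seq, cfg, mapper)
    assert cands == []
    assert stats["mapped_excluded"] == 1
    assert [m.read_id for m in mapped] == ["p"]


def test_trisection_assigns_expected_ends(small_ref):
    cfg = CallerConfig()
    idx = end_flank_index(small_ref, cfg.flank_index_len)
    from scramblekit.junctions import Candidate
    seq = _junction_read(small_ref, (1, "R"), (3, "L"))
    obs, reason = trisect_and_assign(Candidate("r/1", seq, 20), idx, cfg)
    assert reason == "ok"
    assert obs.junction == canonical_junction((1, "R"), (3, "L"))
    # inverted-block junction: right side is an R end
    seq2 = _junction_read(small_ref, (2, "R"), (5, "R"))
    obs2, _ = trisect_and_assign(Candidate("q/1", seq2, 20), idx, cfg)
    assert obs2.junction == canonical_junction((2, "R"), (5, "R"))


def test_reverse_complement_read_gives_same_canonical_junction(small_ref):
    cfg = CallerConfig()
    idx = end_flank_index(small_ref, cfg.flank_index_len)
    from scramblekit.junctions import Candidate
    seq = _junction_read(small_ref, (4, "R"), (9, "L"), flank=22)
    rc = revcomp(seq)
    obs_f, _ = trisect_and_assign(Candidate("f/1", seq, 22), idx, cfg)
    obs_r, _ = trisect_and_assign(
        Candidate("r/1", rc, rc.find(LOXPSYM_SITE)), idx, cfg)
    assert obs_f.junction == obs_r.junction


def test_repeated_segment_flank_is_discarded_as_ambiguous():
    rng = np.random.default_rng(21)
    segs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(3)]
    segs.append(segs[1])                    # segment 4 repeats segment 2
    site = LOXPSYM_SITE
    seq_parts, ivs, pos = [], [], 0
    for k, s in enumerate(segs):
        if k:
            ivs.append((pos, pos + 34))
            seq_parts.append(site)
            pos += 34
        seq_parts.append(s)
        pos += len(s)
    ref = build_reference("rep", "".join(seq_parts), ivs, [], (50, 80),
                          "linear")
    cfg = CallerConfig()
    idx = end_flank_index(ref, cfg.flank_index_len)
    from scramblekit.junctions import Candidate
    read = segs[0][-20:] + site + segs[1][:20]      # matches seg2 and seg4
    obs, reason = trisect_and_assign(Candidate("r/1", read, 20), idx, cfg)
    assert obs is None and reason == "ambiguous_right"


@pytest.mark.parametrize("support,present", [(4, False), (5, True)])
def test_support_threshold_boundary(small_ref, support, present):
    """A junction backed by 4 read pairs is never reported; 5 always is."""
    cfg = CallerConfig()
    seq = _junction_read(small_ref, (1, "R"), (3, "L"))
    pairs = _pairs_of([seq] * support)
    df, _stats = call_pipeline(pairs, small_ref, cfg)
    novel = df[df["label"] == "novel"]
    assert (len(novel) == 1) is present
    if present:
        assert novel.iloc[0]["support"] == support


def test_both_mates_spanning_count_once(small_ref):
    cfg = CallerConfig(min_support=1)
    seq = _junction_read(small_ref, (1, "R"), (3, "L"))
    pairs = [ReadPair(Read("x/1", seq, "I" * len(seq)),
                      Read("x/2", revcomp(seq), "I" * len(seq)))]
    df, _ = call_pipeline(pairs, small_ref, cfg)
    novel = df[df["label"] == "novel"]
    assert len(novel) == 1 and novel.iloc[0]["support"] == 1


def test_unrearranged_strain_yields_only_parental_junctions(small_ref):
    genome = SignedStructure.reference(small_ref).sequence(small_ref)
    assert genome == small_ref.sequence
    pairs = emit_reads([GenomeSource("wt", genome)],
                       ReadSimConfig(mean_depth=60, error_rate=0.0, seed=6))
    df, _ = call_pipeline(pairs, small_ref, CallerConfig())
    assert (df["label"] == "parental").all()
    assert len(df) == small_ref.n_sites


def test_junction_ends_are_always_site_adjacent(small_ref):
    """No reported junction may name a telomeric (non-site-adjacent)
    segment end."""
    for seed in range(5):
        truth = simulate_strain(small_ref,
                                SimConfig(n_events=4, poisson=False,
                                          seed=300 + seed))
        pairs = emit_reads(
            [GenomeSource("syn", truth.structure.sequence(small_ref))],
            ReadSimConfig(mean_depth=60, error_rate=0.001,
                          seed=400 + seed))
        df, _ = call_pipeline(pairs, small_ref, CallerConfig())
        for r in df.itertuples():
            assert small_ref.site_of_end(int(r.segA), r.endA) is not None
            assert small_ref.site_of_end(int(r.segB), r.endB) is not None
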