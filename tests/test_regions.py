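"""Occupancy counting, peak enrichment, chromatin-state segmentation analyses."""

import numpy as np
import pytest

from cishex.association import results_to_frame
from cishex.hexamers import canonicalize, scan_sequence
from cishex.io import DatasetDEG, GeneSets, PromoterRecord
from cishex.regions import (
    IntervalSet,
    enrichment_test,
    merge_intervals,
    occupancy,
    peak_enrichment,
    read_bed,
    state_association,
    state_hexamer_enrichment,
    state_presence,
    state_segments,
    write_bed,
)
from cishex.simulate import PeakConfig, PlantedMotif, SimConfig, StateConfig, simulate


def test_occupancy_examples():
    assert occupancy(["AAAAAAA"], "AAAAAA") == (2, 2)
    assert occupancy(["TGTCTCT", "CCCCCCC"], "GAGACA") == (1, 4)
    assert occupancy([], "AAAAAA") == (0, 0)
    # canonical collapse: querying either strand's spelling is equivalent
    assert occupancy(["TGTCTCT"], "TGTCTC") == occupancy(["TGTCTCT"], "GAGACA")


def test_occupancy_agrees_with_scan_sequence(rng):
    seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)]) for _ in range(5)]
    occ, total = occupancy(seqs, "CACGTG")
    manual = sum(scan_sequence(s).position_counts.get("CACGTG", 0) for s in seqs)
    assert occ == manual
    assert total == sum(scan_sequence(s).total_positions for s in seqs)


def test_enrichment_test_examples():
    assert enrichment_test((2, 2), (0, 2)) == pytest.approx(1 / 6, abs=1e-15)
    assert enrichment_test((0, 10), (3, 10)) == 1.0
    assert enrichment_test((5, 10), (5, 10)) >= 0.5  # no enrichment signal
    with pytest.raises(ValueError):
        enrichment_test((0, 0), (1, 2))


def test_enrichment_test_swap_property(rng):
    """For non-degenerate tables at most one direction looks enriched."""
    for _ in range(50):
        fo, bo = rng.integers(0, 20, 2)
        ft, bt = fo + rng.integers(1, 20), bo + rng.integers(1, 20)
        p1 = enrichment_test((int(fo), int(ft)), (int(bo), int(bt)))
        p2 = enrichment_test((int(bo), int(bt)), (int(fo), int(ft)))
        assert not (p1 < 0.5 and p2 < 0.5)


def test_merge_intervals_unions_overlaps():
    ivs = IntervalSet(
        [("c1", 0, 10, "a"), ("c1", 5, 15, "b"), ("c1", 20, 30, "c"), ("c2", 0, 5, "d")],
        name="x",
    )
    merged = merge_intervals(ivs)
    assert [(c, s, e) for c, s, e, _ in merged.intervals] == [
        ("c1", 0, 15), ("c1", 20, 30), ("c2", 0, 5)
    ]


def test_bed_roundtrip(tmp_path):
    ivs = IntervalSet([("c1", 0, 10, "4"), ("c1", 10, 25, "2")], name="states")
    write_bed(ivs, tmp_path / "x.bed")
    back = read_bed(tmp_path / "x.bed", name="states")
    assert back.intervals == ivs.intervals


# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def peak_sim():
    cfg = SimConfig(
        n_genes=300, window_len=400, seed=9,
        planted_motifs=(PlantedMotif("TGTCTC", "up", p_fg=0.9, p_bg=0.05),),
        peak_cfg=PeakConfig(n_peaks=60, width=60, frac_centered=1.0),
    )
    return simulate(cfg)


def test_peak_enrichment_recovers_planted_hexamer(peak_sim):
    res = peak_enrichment(peak_sim.peaks, peak_sim.genome, peak_sim.promoters)
    planted = canonicalize("TGTCTC").seq
    by_feat = {r.feature: r for r in res}
    assert by_feat[planted].significant
    assert by_feat[planted].fwer_p < 0.05
    # occupancy bookkeeping: occupied never exceeds total
    for r in res:
        assert r.occupied_fg <= r.total_fg and r.occupied_bg <= r.total_bg


def test_peak_enrichment_single_exact_peak():
    genome = {"c1": "TGTCTC" + "A" * 50}
    peaks = IntervalSet([("c1", 0, 6, "peak")], name="peaks")
    bg = [PromoterRecord(gene_id="g1", seq="ACGT" * 20)]
    res = peak_enrichment(peaks, genome, bg, hexamer_list=["TGTCTC"])
    (r,) = res
    assert (r.occupied_fg, r.total_fg) == (1, 1)
    assert r.feature == "GAGACA"


def test_peak_beyond_chromosome_end_is_truncated(caplog):
    genome = {"c1": "A" * 20}
    peaks = IntervalSet([("c1", 10, 50, "peak")], name="peaks")
    bg = [PromoterRecord(gene_id="g1", seq="C" * 30)]
    res = peak_enrichment(peaks, genome, bg, hexamer_list=["AAAAAA"])
    (r,) = res
    assert r.total_fg == 5  # 10 clipped bases -> 5 windows


# ---------------------------------------------------------------------------


def _promoter(gene, seq, chrom, start, strand):
    return PromoterRecord(gene_id=gene, seq=seq, chrom=chrom, strand=strand,
                          start=start, end=start + len(seq))


def test_state_segments_partition_and_orientation():
    states = IntervalSet([("c1", 0, 100, "1"), ("c1", 100, 400, "2")], name="st")
    # plus-strand promoter fully inside state 2
    p1 = _promoter("g1", "ACGT" * 10, "c1", 150, "+")
    segs = state_segments([p1], states)
    assert set(segs) == {("g1", "2")}
    assert segs[("g1", "2")] == [p1.seq]

    # straddling the boundary: lengths sum to the window length
    p2 = _promoter("g2", "ACGTACGTAC" * 4, "c1", 80, "+")
    segs = state_segments([p2], states)
    assert len(segs[("g2", "1")][0]) + len(segs[("g2", "2")][0]) == 40
    assert segs[("g2", "1")][0] == p2.seq[:20]  # genomic [80,100)

    # minus strand: sub-sequence is the reverse-complemented slice
    from cishex.hexamers import reverse_complement

    fwd = "AACCGGTTAACCGGTTAACC"
    p3 = _promoter("g3", reverse_complement(fwd), "c1", 90, "-")
    segs = state_segments([p3], states)
    # genomic [90,100) is state 1 = last 10 promoter bases reversed
    assert segs[("g3", "1")] == [reverse_complement(fwd[:10])]
    assert segs[("g3", "2")] == [reverse_complement(fwd[10:])]


def test_state_segments_uncovered_promoter_and_missing_coords():
    states = IntervalSet([("c1", 0, 10, "1")], name="st")
    p = _promoter("g1", "ACGTACGTAC", "c2", 0, "+")
    assert state_segments([p], states) == {}
    with pytest.raises(ValueError):
        state_segments([PromoterRecord(gene_id="g2", seq="ACGTAC")], states)


def test_state_presence_from_segments():
    segs = {("g1", "1"): ["ACGT"], ("g1", "4"): ["A"], ("g2", "2"): []}
    pres = state_presence(segs)
    assert pres == {"g1": {"1", "4"}}


@pytest.fixture(scope="module")
def state_sim():
    cfg = SimConfig(
        n_genes=400, window_len=400, seed=21, frac_up=0.15, frac_down=0.1,
        state_cfg=StateConfig(mean_block_len=120, comp_bias={"4": 0.08}),
    )
    return simulate(cfg)


def test_state_association_detects_planted_state_bias():
    """Genes carrying state 4 are preferentially up-regulated -> state 4 selected."""
    rng = np.random.default_rng(4)
    n = 500
    genes = [f"g{i}" for i in range(n)]
    has4 = rng.random(n) < 0.4
    pres = {g: ({"4", "1"} if has4[i] else {"1", "2"}) for i, g in enumerate(genes)}
    datasets = []
    for d in range(3):
        up = (has4 & (rng.random(n) < 0.5)) | (~has4 & (rng.random(n) < 0.05))
        datasets.append(
            DatasetDEG(f"d{d}", {g: "up" for g, u in zip(genes, up) if u}, set(genes))
        )
    meta, perm = state_association(datasets, pres, M=200, seed=1)
    df = results_to_frame(meta)
    hit = df[(df.feature == "4") & (df.status == "up")].iloc[0]
    assert hit.selected and hit.meta_p < 1e-8


def test_state_association_degenerate_single_state():
    genes = [f"g{i}" for i in range(40)]
    pres = {g: {"1"} for g in genes}
    ds = DatasetDEG("d", {"g0": "up", "g1": "down"}, set(genes))
    meta, perm = state_association([ds], pres, M=20, seed=0)
    assert all(r.meta_p == 1.0 for r in meta)  # no contrast: presence everywhere


def test_state_hexamer_enrichment_genomewide(state_sim):
    segs = state_segments(state_sim.promoters, state_sim.states)
    res = state_hexamer_enrichment("AAAAAA", "4", segs, state_sim.promoters,
                                   mode="genomewide")
    assert res.significant and res.fwer_p < 0.05  # A/T-rich state-4 composition
    gc_hex = state_hexamer_enrichment("GGCCGG", "4", segs, state_sim.promoters,
                                      mode="genomewide")
    assert not gc_hex.significant


def test_state_hexamer_enrichment_responsive_mode_and_degenerate(state_sim):
    segs = state_segments(state_sim.promoters, state_sim.states)
    genes = [p.gene_id for p in state_sim.promoters]
    sets = GeneSets(control=set(genes[: len(genes) // 2]),
                    positive=set(genes[len(genes) // 2 :]))
    res = state_hexamer_enrichment("AAAAAA", "4", segs, state_sim.promoters,
                                   mode="responsive_vs_control", sets=sets)
    # halves drawn from the same generator: no systematic difference
    assert not res.significant

    empty = state_hexamer_enrichment("AAAAAA", "9", {}, state_sim.promoters,
                                     mode="genomewide")
    assert empty.degenerate and empty.p == 1.0
    with pytest.raises(ValueError):
        state_hexamer_enrichment("AAAAAA", "4", segs, state_sim.promoters,
                                 mode="responsive_vs_control")


def test_state_segment_lengths_conserve_coverage(state_sim):
    """Per gene, segment lengths sum exactly to the promoter bases covered by the map."""
    segs = state_segments(state_sim.promoters, state_sim.states)
    by_gene = {}
    for (g, lab), parts in segs.items():
        by_gene[g] = by_gene.get(g, 0) + sum(len(s) for s in parts)
    for p in state_sim.promoters[:50]:
        covered = 0
        for chrom, s, e, _ in state_sim.states.intervals:
            if chrom == p.chrom:
                covered += max(0, min(e, p.end) - max(s, p.start))
        assert by_gene.get(p.gene_id, 0) == covered == len(p.seq)
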