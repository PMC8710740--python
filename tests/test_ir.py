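"""Quadripartite detection against construction and a brute-force oracle."""

import numpy as np
import pytest

from plastevo import AnnotatedPlastome, GeneFeature, detect_quadripartite, junction_report
from plastevo.ir import NoQuadripartiteError, ir_size_table, revcomp

from _oracles import oracle_best_quadripartite

BASES = np.array(list("ACGT"))


def _rand_seq(rng, n):
    return "".join(rng.choice(BASES, size=n))


def _planted_genome(rng, lsc, ir, ssc):
    """LSC + IRb + SSC + revcomp(IRb), with extension-blocking junction bases."""
    s_lsc = list(_rand_seq(rng, lsc))
    s_ir = _rand_seq(rng, ir)
    s_ssc = list(_rand_seq(rng, ssc))
    comp = dict(zip("ACGT", "TGCA"))
    if s_lsc[-1] == comp[s_lsc[0]]:
        s_lsc[-1] = "A" if s_lsc[-1] != "A" and comp[s_lsc[0]] != "A" else "C"
    if s_ssc[0] == comp[s_ssc[-1]]:
        s_ssc[0] = "A" if s_ssc[0] != "A" and comp[s_ssc[-1]] != "A" else "C"
    return "".join(s_lsc) + s_ir + "".join(s_ssc) + revcomp(s_ir)


def test_planted_toy_recovered_exactly(rng):
    seq = _planted_genome(rng, lsc=600, ir=200, ssc=100)
    p = AnnotatedPlastome("toy", seq)
    q = detect_quadripartite(p, min_ir_len=100)
    assert (q.lsc, q.irb, q.ssc, q.ira) == (
        (0, 600), (600, 800), (800, 900), (900, 1100)
    )
    assert q.rotation == 0


def test_revcomp_invariant_of_detected_copies(rng):
    seq = _planted_genome(rng, lsc=600, ir=200, ssc=100)
    p = AnnotatedPlastome("toy", seq)
    q = detect_quadripartite(p, min_ir_len=100)
    r = p.rotated(q.rotation)
    assert r.sequence[slice(*q.irb)] == revcomp(r.sequence[slice(*q.ira)])


def test_partition_property_and_rotation_invariance(rng):
    seq = _planted_genome(rng, lsc=900, ir=250, ssc=180)
    p = AnnotatedPlastome("toy", seq)
    q0 = detect_quadripartite(p, min_ir_len=100)
    assert q0.lsc_len + 2 * q0.ir_len + q0.ssc_len == p.length
    for offset in (1, 500, 1000, p.length - 3):
        q = detect_quadripartite(p.rotated(offset), min_ir_len=100)
        assert (q.lsc_len, q.ir_len, q.ssc_len) == (
            q0.lsc_len, q0.ir_len, q0.ssc_len
        )


def test_no_repeat_raises(rng):
    # a random 1 kb sequence has no 100 bp inverted repeat
    p = AnnotatedPlastome("bare", _rand_seq(rng, 1000))
    with pytest.raises(NoQuadripartiteError):
        detect_quadripartite(p, min_ir_len=100)


def test_detection_matches_bruteforce_oracle_on_random_planted_genomes():
    """50 random ~2 kb genomes with planted IRs: region sizes equal the
    exhaustive all-pairs maximal-inverted-repeat oracle."""
    rng = np.random.default_rng(17)
    for _ in range(50):
        lsc = int(rng.integers(700, 1100))
        ir = int(rng.integers(150, 401))
        ssc = int(rng.integers(120, min(400, lsc - 1)))
        seq = _planted_genome(rng, lsc, ir, ssc)
        q = detect_quadripartite(AnnotatedPlastome("r", seq), min_ir_len=100)
        expected = oracle_best_quadripartite(seq, 100)
        assert expected is not None
        assert (q.ir_len, q.lsc_len, q.ssc_len) == expected


def test_junction_distances_and_spanning_gene(rng):
    seq = _planted_genome(rng, lsc=600, ir=200, ssc=100)
    feats = [
        # ends exactly at JLB (position 600): distance 0, not spanning
        GeneFeature("rps19", "protein_cds", "-", [(510, 600)]),
        # rps19-like geometry: a gene 36 bp before JLB on the other side
        GeneFeature("rpl22", "protein_cds", "-", [(400, 464)]),
        # ndhH-like gene crossing JSA (position 900) with 40 bp in SSC
        GeneFeature("ndhH", "protein_cds", "+", [(860, 1060)]),
    ]
    p = AnnotatedPlastome("toy", seq, feats)
    q = detect_quadripartite(p, min_ir_len=100)
    rep = junction_report(p, q)

    jlb = rep["JLB"]
    assert jlb.upstream.name == "rps19" and jlb.upstream.distance == 0
    assert jlb.spanning is None

    jsa = rep["JSA"]
    assert jsa.spanning is not None
    assert jsa.spanning.name == "ndhH"
    assert jsa.spanning.left_bp == 40    # SSC side
    assert jsa.spanning.right_bp == 160  # IRa side

    # nearest-edge convention: rpl22 is 600-464=136 bp before JLB
    assert jlb.upstream.distance <= 136


def test_junction_report_with_empty_annotation(rng):
    seq = _planted_genome(rng, lsc=600, ir=200, ssc=100)
    p = AnnotatedPlastome("toy", seq)
    rep = junction_report(p, detect_quadripartite(p, min_ir_len=100))
    assert all(r.upstream is None and r.spanning is None for r in rep.values())


def test_preset_fixture_rps19_sits_36bp_before_jlb(clean_preset_result):
    label = "Hordeum_vulgare"
    p = clean_preset_result.plastomes[label]
    q = detect_quadripartite(p, min_ir_len=300)
    rep = junction_report(p, q)
    assert rep["JLB"].upstream.name == "rps19"
    assert rep["JLB"].upstream.distance == 36


def test_ir_size_table_skips_genomes_without_ir(rng, caplog):
    good = AnnotatedPlastome("good", _planted_genome(rng, 600, 200, 100))
    good2 = AnnotatedPlastome("good2", _planted_genome(rng, 650, 210, 120))
    bad = AnnotatedPlastome("bad", _rand_seq(rng, 1000))
    import logging

    with caplog.at_level(logging.WARNING, logger="plastevo.ir"):
        table = ir_size_table([good, bad, good2], min_ir_len=100)
    assert list(table.id) == ["good", "good2"]
    assert list(table.ir_len) == [200, 210]
    assert any("bad" in r.message for r in caplog.records)


def test_planted_ir_deletion_shrinks_ir_by_planted_amount(clean_preset_result):
    res = clean_preset_result
    table = ir_size_table(
        [res.plastomes["Thinopyrum_bessarabicum"], res.plastomes["Hordeum_vulgare"]],
        min_ir_len=300,
    )
    by_id = dict(zip(table.id, table.ir_len))
    assert (
        by_id["Hordeum_vulgare"] - by_id["Thinopyrum_bessarabicum"] == 800
    )
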