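"""Synthetic-data generator: determinism, truth bookkeeping, event statistics."""

import dataclasses
import filecmp

import numpy as np
import pytest

from plastevo import detect_quadripartite
from plastevo.simulate import (
    SimulationConfig,
    simulate,
    simulate_bm,
    triticeae_preset,
    triticeae_tree,
)


def test_zero_rates_give_identical_tips(mini_template):
    cfg = SimulationConfig(
        seed=1,
        newick="(((A:1,B:1)ab:1,(C:1,D:1)cd:1)in:1,O:3)root;",
        template=mini_template,
        indel_rate=0.0,
        subst_rate=0.0,
    )
    res = simulate(cfg)
    seqs = {p.sequence for p in res.plastomes.values()}
    assert len(seqs) == 1
    assert "-" not in "".join(res.alignment.rows)
    assert len(set(res.truth.tip_sizes.values())) == 1
    assert res.truth.events == []


def test_identical_seed_reproduces_outputs_byte_identical(tmp_path, mini_config):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate(mini_config, out_dir=d1)
    simulate(dataclasses.replace(mini_config), out_dir=d2)
    for rel in ["alignment.fasta", "tree.nwk", "sizes.tsv", "true_events.tsv"]:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
    for gb in sorted((d1 / "genbank").glob("*.gb")):
        assert gb.read_bytes() == (d2 / "genbank" / gb.name).read_bytes()


def test_different_seed_changes_outputs(mini_config):
    r1 = simulate(mini_config)
    r2 = simulate(dataclasses.replace(mini_config, seed=12))
    assert r1.alignment.rows != r2.alignment.rows


def test_true_quadripartite_recovered_by_detection(clean_preset_result):
    res = clean_preset_result
    for label in ("Hordeum_vulgare", "Thinopyrum_bessarabicum", "Agropyron_cristatum"):
        q_true = res.truth.quadripartite[label]
        q = detect_quadripartite(res.plastomes[label], min_ir_len=300)
        assert (q.lsc, q.irb, q.ssc, q.ira) == (
            q_true.lsc, q_true.irb, q_true.ssc, q_true.ira
        )
        assert q.rotation == 0


def test_size_bookkeeping_matches_event_ledger(mini_config):
    res = simulate(mini_config)
    root_len = None
    for label, size in res.truth.tip_sizes.items():
        # signed sum of this lineage's events (IR events count twice: both copies)
        node = res.tree.node(label)
        path = set()
        while node is not None:
            path.add(node.id)
            node = node.parent
        delta = 0
        for e in res.truth.events:
            if e.branch in path:
                mult = 2 if e.region == "irb" else 1
                delta += mult * (e.length if e.kind == "insertion" else -e.length)
        ancestral = res.plastomes[label].length - delta
        if root_len is None:
            root_len = ancestral
        assert ancestral == root_len


def test_planted_event_clade_signature(clean_preset_result):
    res = clean_preset_result
    sizes = {r.species: r.total_bp for r in res.sizes}
    clades = {r.species: r.clade for r in res.sizes}
    base = sizes["Hordeum_vulgare"]  # clade IV: no planted events
    for sp, clade in clades.items():
        expected = {
            "I": base - 172,
            "II": base - 529 - 2 * 800,
            "III": base - 438,
            "IV": base,
            "outgroup": base,
        }[clade]
        assert sizes[sp] == expected


def test_stochastic_event_count_matches_poisson_mean(mini_config):
    """Mean event count over replicates ~ rate x total tree length."""
    rate = mini_config.indel_rate
    tree = simulate(mini_config).tree
    total_len = sum(
        n.edge_length for n in tree.preorder() if n.parent is not None
    )
    counts = []
    for rep in range(200):
        cfg = dataclasses.replace(mini_config, seed=1000 + rep, subst_rate=0.0)
        counts.append(len(simulate(cfg).truth.events))
    mean = np.mean(counts)
    expected = rate * total_len
    se = np.sqrt(expected / len(counts))
    assert abs(mean - expected) < 3 * se


def test_ir_indels_are_mirrored_into_both_copies(mini_template):
    # high indel rate confined by seed; IRa must stay revcomp of IRb
    from plastevo.ir import revcomp

    cfg = SimulationConfig(
        seed=5,
        newick="(((A:1,B:1)ab:1,(C:1,D:1)cd:1)in:1,O:3)root;",
        template=mini_template,
        indel_rate=3.0,
        subst_rate=0.01,
    )
    res = simulate(cfg)
    for label, q in res.truth.quadripartite.items():
        seq = res.plastomes[label].sequence
        assert seq[slice(*q.irb)] == revcomp(seq[slice(*q.ira)])


def test_alignment_consistent_with_tip_sequences(mini_config):
    res = simulate(mini_config)
    for label, p in res.plastomes.items():
        row = res.alignment.row(label).replace("-", "")
        assert row == p.sequence


def test_preset_tree_shape_and_ages():
    tree = triticeae_tree()
    assert len(tree.tip_labels) == 34  # 33 ingroup + outgroup
    assert tree.root.age == pytest.approx(27.63)
    assert tree.node("cladeI").age == pytest.approx(12.71)
    assert tree.node("cladeII").age == pytest.approx(12.62)
    assert tree.node("cladeIII").age == pytest.approx(17.16)
    assert tree.node("cladeIV").age == pytest.approx(15.09)
    # ultrametric: branch lengths reproduce ages
    tree2 = triticeae_tree()
    tree2.assign_ages_from_lengths()
    for n in tree.preorder():
        assert tree2.node(n.id).age == pytest.approx(n.age, abs=1e-9)


def test_planted_event_too_long_for_spacer_rejected(mini_template):
    from plastevo.simulate import PlantedEvent

    cfg = SimulationConfig(
        seed=1,
        newick="(((A:1,B:1)ab:1,(C:1,D:1)cd:1)in:1,O:3)root;",
        template=mini_template,
        indel_rate=0.0,
        subst_rate=0.0,
        planted_events=[PlantedEvent("ab", "igs", "petN", "trnC", 10_000)],
    )
    with pytest.raises(ValueError, match="exceeds"):
        simulate(cfg)


def test_unknown_planted_branch_rejected(mini_template):
    from plastevo.simulate import PlantedEvent

    cfg = SimulationConfig(
        seed=1,
        newick="(((A:1,B:1)ab:1,(C:1,D:1)cd:1)in:1,O:3)root;",
        template=mini_template,
        planted_events=[PlantedEvent("nope", "igs", "petN", "trnC", 10)],
    )
    with pytest.raises(ValueError, match="unknown branch"):
        simulate(cfg)


def test_bm_simulation_zero_rate_is_constant():
    tree = triticeae_tree()
    vals = simulate_bm(tree, 1000.0, 0.0, seed=3)
    assert set(vals.values()) == {1000.0}


def test_bm_variance_scales_with_depth():
    tree = triticeae_tree()
    rng = np.random.default_rng(6)
    tips = []
    for _ in range(300):
        vals = simulate_bm(tree, 0.0, 1.0, rng)
        tips.append(vals["Hordeum_vulgare"])
    # tip depth = root age 27.63 MY; variance ~ sigma2 * depth
    assert np.var(tips) == pytest.approx(27.63, rel=0.25)
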