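"""Synthetic Triticeae-like plastome evolution with full ground truth.

The generator builds an ancestral quadripartite genome from a gene-layout
template, evolves it down a time-calibrated tree (uniform point
substitutions, Poisson indels with geometric lengths, plus deterministic
"planted" events on named branches), and emits everything the analysis
modules consume — per-tip annotated genomes, the true multiple alignment
(homology is known, so no aligner runs in the test path), the tree, and
size tables — together with a truth object recording exactly what happened
on every branch.

Two structural invariants are maintained by construction: the two IR copies
stay mutually reverse-complementary (IRa is derived from the evolved IRb,
emulating gene-conversion homogenization of real plastome IRs), and an
event planted inside the IR shrinks both copies.

The default template is a roughly 10x scaled-down plastome (12.1 kb LSC /
2.3 kb IR / 1.35 kb SSC) carrying a Triticeae-style gene layout; the ``triticeae``
preset adds the four clade-diagnostic deletions (529 bp petN-trnC, 438 bp
psbE-petL, 172 bp trnT-trnE, 800 bp in the IR) on the corresponding clade
stem branches of a 33-ingroup-taxon, 27.63-MY-crown phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .ir import Quadripartite, revcomp
from .indels import Alignment
from .plastome import (
    AnnotatedPlastome,
    GeneFeature,
    SizeRecord,
    size_partition,
    write_genbank,
)
from .tables import CROWN_AGE_MYA, OUTGROUP_SPECIES, triticeae_size_table
from .trees import Node, PhyloTree

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Template: gene layout of the ancestral genome

@dataclass
class LayoutGene:
    name: str
    kind: str
    strand: str
    length: int
    igs_after: int
    filler: bool = False  # receives the leftover bp needed to hit the target


@dataclass
class Template:
    lsc_len: int = 12100
    ir_len: int = 2300
    ssc_len: int = 1350
    lsc_genes: list[LayoutGene] = field(default_factory=list)
    ir_genes: list[LayoutGene] = field(default_factory=list)
    ssc_genes: list[LayoutGene] = field(default_factory=list)
    # gene crossing the SSC/IRa junction: (name, bp in SSC, bp in IRa)
    jsa_spanner: tuple[str, int, int] = ("ndhH", 40, 260)

    @property
    def genome_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


def _g(name, kind, strand, length, igs, filler=False) -> LayoutGene:
    return LayoutGene(name, kind, strand, length, igs, filler)


def default_template() -> Template:
    """Scaled-down Triticeae-style layout (regions 10x smaller than real)."""
    lsc = [
        _g("psbA", "protein_cds", "-", 300, 80),
        _g("matK", "protein_cds", "+", 320, 60),
        _g("rps16", "protein_cds", "-", 180, 70),
        _g("psbK", "protein_cds", "+", 90, 50),
        _g("atpA", "protein_cds", "-", 300, 60),
        _g("atpF", "protein_cds", "-", 150, 40),
        _g("rpoC2", "protein_cds", "-", 500, 50),
        _g("rpoC1", "protein_cds", "-", 300, 50),
        _g("rpoB", "protein_cds", "-", 400, 200),
        _g("petN", "protein_cds", "-", 90, 650),   # petN-trnC spacer
        _g("trnC", "trna", "+", 70, 60),
        _g("psbM", "protein_cds", "-", 100, 80),
        _g("psbD", "protein_cds", "+", 250, 30),
        _g("psbC", "protein_cds", "+", 300, 60),
        _g("psaB", "protein_cds", "-", 350, 30),
        _g("psaA", "protein_cds", "-", 350, 70),
        _g("ycf3", "protein_cds", "-", 160, 60),
        _g("rps4", "protein_cds", "-", 180, 60),
        _g("trnT", "trna", "+", 70, 260),          # trnT-trnE spacer
        _g("trnE", "trna", "+", 70, 60),
        _g("ndhJ", "protein_cds", "-", 140, 50),
        _g("atpB", "protein_cds", "-", 300, 70),
        _g("rbcL", "protein_cds", "+", 350, 120, filler=True),
        _g("psaI", "protein_cds", "+", 80, 60),
        _g("accD", "pseudogene", "+", 200, 60),
        _g("petA", "protein_cds", "+", 200, 80),
        _g("psbE", "protein_cds", "-", 90, 560),   # psbE-petL spacer
        _g("petL", "protein_cds", "+", 80, 50),
        _g("petG", "protein_cds", "+", 80, 60),
        _g("rpl33", "protein_cds", "+", 90, 40),
        _g("rps18", "protein_cds", "+", 90, 50),
        _g("clpP", "protein_cds", "-", 180, 60),
        _g("psbB", "protein_cds", "+", 300, 40),
        _g("petB", "protein_cds", "+", 150, 50),
        _g("petD", "protein_cds", "+", 140, 50),
        _g("rpoA", "protein_cds", "-", 250, 40),
        _g("rps11", "protein_cds", "-", 100, 30),
        _g("rpl36", "protein_cds", "+", 60, 40),
        _g("infA", "protein_cds", "+", 70, 40),
        _g("rps8", "protein_cds", "-", 100, 40),
        _g("rpl14", "protein_cds", "-", 100, 40),
        _g("rpl16", "protein_cds", "-", 120, 40),
        _g("rps3", "protein_cds", "-", 150, 40),
        _g("rpl22", "protein_cds", "-", 110, 30),
        _g("rps19", "protein_cds", "-", 90, 36),   # 36 bp short of JLB
    ]
    ir = [
        _g("rpl2", "protein_cds", "-", 150, 40),
        _g("rpl23", "pseudogene", "-", 90, 40),
        _g("trnI", "trna", "-", 70, 30),
        _g("ycf2", "pseudogene", "+", 250, 30),
        _g("ycf15", "pseudogene", "+", 100, 830),  # ycf15-trnL spacer (IR)
        _g("trnL", "trna", "+", 70, 40),
        _g("ndhB", "protein_cds", "-", 250, 40),
        _g("rps7", "protein_cds", "-", 120, 50, filler=True),
    ]
    ssc = [
        _g("ndhF", "protein_cds", "-", 350, 60),
        _g("rpl32", "protein_cds", "+", 90, 60),
        _g("ccsA", "protein_cds", "+", 200, 50),
        _g("ndhD", "protein_cds", "-", 250, 40),
        _g("rps15", "protein_cds", "+", 90, 70, filler=True),
    ]
    return Template(lsc_genes=lsc, ir_genes=ir, ssc_genes=ssc)


def _place_region(
    genes: list[LayoutGene], offset: int, target: int, reserve_tail: int = 0
) -> list[GeneFeature]:
    """Lay genes head-to-tail, stretching the filler spacer to hit target."""
    used = sum(g.length + g.igs_after for g in genes) + reserve_tail
    extra = target - used
    if extra < 0:
        raise ValueError(f"gene layout exceeds region target by {-extra} bp")
    feats = []
    pos = offset
    for g in genes:
        feats.append(GeneFeature(g.name, g.kind, g.strand, [(pos, pos + g.length)]))
        pos += g.length + g.igs_after
        if g.filler:
            pos += extra
    return feats


def build_ancestor(
    template: Template, rng: np.random.Generator
) -> tuple[str, list[GeneFeature], Quadripartite]:
    """Random core sequence + annotation for LSC/IRb/SSC, IRa derived.

    Returns (full sequence, full-genome features, true quadripartite).
    Boundary bases are adjusted so the exact inverted-repeat pair cannot
    extend past the true junctions by chance.
    """
    t = template
    lsc_end = t.lsc_len
    irb_end = lsc_end + t.ir_len
    ssc_end = irb_end + t.ssc_len
    span_name, span_ssc, span_ira = t.jsa_spanner

    feats = []
    feats += _place_region(t.lsc_genes, 0, t.lsc_len)
    feats += _place_region(t.ir_genes, lsc_end, t.ir_len)
    feats += _place_region(t.ssc_genes, irb_end, t.ssc_len, reserve_tail=span_ssc)
    feats.append(
        GeneFeature(span_name, "protein_cds", "+", [(ssc_end - span_ssc, ssc_end + span_ira)])
    )

    core = list(rng.choice(list(_BASES), size=ssc_end))
    # block chance extension of the IR pair beyond the true junctions:
    # outer: LSC's last base vs (circularly) LSC's first base
    if core[lsc_end - 1] == _COMP[core[0]]:
        core[lsc_end - 1] = _BASES[(_BASES.index(core[lsc_end - 1]) + 1) % 4]
        if core[lsc_end - 1] == _COMP[core[0]]:
            core[lsc_end - 1] = _BASES[(_BASES.index(core[lsc_end - 1]) + 1) % 4]
    # inner: SSC's first base vs SSC's last base
    if core[irb_end] == _COMP[core[ssc_end - 1]]:
        core[irb_end] = _BASES[(_BASES.index(core[irb_end]) + 1) % 4]
        if core[irb_end] == _COMP[core[ssc_end - 1]]:
            core[irb_end] = _BASES[(_BASES.index(core[irb_end]) + 1) % 4]
    seq_core = "".join(core)
    full = seq_core + revcomp(seq_core[lsc_end:irb_end])

    # mirror IR annotation into IRa
    n = len(full)
    for f in [f for f in feats if f.intervals[0][0] >= lsc_end and f.intervals[0][1] <= irb_end]:
        s, e = f.intervals[0]
        ms = ssc_end + (irb_end - e)
        me = ssc_end + (irb_end - s)
        feats.append(
            GeneFeature(f.name, f.kind, "-" if f.strand == "+" else "+", [(ms, me)])
        )

    q = Quadripartite(
        lsc=(0, lsc_end),
        irb=(lsc_end, irb_end),
        ssc=(irb_end, ssc_end),
        ira=(ssc_end, n),
    )
    return full, feats, q


# ---------------------------------------------------------------------------
# Config and truth

@dataclass
class PlantedEvent:
    branch: str           # child-node id of the target branch
    region: str           # "igs" (single copy) or "ir"
    left_flank: str
    right_flank: str
    length: int
    kind: str = "deletion"


@dataclass
class SimulationConfig:
    seed: int
    newick: Optional[str] = None        # explicit tree; else generated preset tree
    n_clade_tips: tuple[int, ...] = (18, 5, 6, 4)
    crown_age: float = CROWN_AGE_MYA
    bm_sigma2: float = 1.0e4            # bp^2 / MYA, genome-size Brownian motion
    indel_rate: float = 2.0             # stochastic events per branch per MYA
    indel_length_p: float = 0.2         # geometric(p): mean length 1/p = 5 bp
    subst_rate: float = 0.001           # substitutions / site / MYA
    template: Template = field(default_factory=default_template)
    planted_events: list[PlantedEvent] = field(default_factory=list)


@dataclass
class TrueEvent:
    branch: str
    kind: str              # insertion | deletion
    length: int
    region: str            # lsc | irb | ssc (ancestral region of the locus)
    col_ids: tuple[int, int]   # ancestral/insert column-id range [start, end)
    flanks: Optional[tuple[str, str]] = None
    planted: bool = False


@dataclass
class SimulationTruth:
    tree: PhyloTree
    events: list[TrueEvent]
    tip_sizes: dict[str, int]
    quadripartite: dict[str, Quadripartite]
    node_ages: dict[str, float]


@dataclass
class SimulationResult:
    plastomes: dict[str, AnnotatedPlastome]
    alignment: Alignment
    tree: PhyloTree
    truth: SimulationTruth
    sizes: list[SizeRecord]


# ---------------------------------------------------------------------------
# Preset phylogeny

def _ladder(labels: list[str], crown: float, prefix: str) -> Node:
    """Pectinate clade with evenly spaced internal-node ages below crown."""
    k = len(labels)
    if k == 1:
        return Node(id=labels[0], age=0.0)
    ages = [crown * i / (k - 1) for i in range(1, k)]
    node = Node(id=labels[0], age=0.0)
    for i in range(1, k):
        tip = Node(id=labels[i], age=0.0)
        nid = f"{prefix}" if i == k - 1 else f"{prefix}_{i}"
        parent = Node(id=nid, age=ages[i - 1], children=[node, tip])
        node.parent = parent
        tip.parent = parent
        node = parent
    return node


def triticeae_tree(
    clade_tips: Optional[dict[str, list[str]]] = None,
    crown_age: float = CROWN_AGE_MYA,
) -> PhyloTree:
    """Preset maternal phylogeny: four clades + outgroup, empirical crown ages.

    Clade stems are named cladeI..cladeIV so branch-specific events can be
    planted on them; deeper nodes get descriptive ids. Branch lengths are in
    MY (ultrametric).
    """
    if clade_tips is None:
        by_clade: dict[str, list[str]] = {}
        for r in triticeae_size_table():
            by_clade.setdefault(r.clade, []).append(r.species)
        clade_tips = by_clade
    crown_ages = {"I": 12.71, "II": 12.62, "III": 17.16, "IV": 15.09}
    clades = {
        roman: _ladder(clade_tips[roman], crown_ages[roman], f"clade{roman}")
        for roman in ("I", "II", "III", "IV")
    }
    n12 = Node(id="cladeI_II", age=20.49, children=[clades["I"], clades["II"]])
    n123 = Node(id="cladeI_II_III", age=21.18, children=[n12, clades["III"]])
    ingroup = Node(id="ingroup", age=27.03, children=[n123, clades["IV"]])
    outg = Node(id=OUTGROUP_SPECIES, age=0.0)
    root = Node(id="root", age=crown_age, children=[ingroup, outg])
    for node in (n12, n123, ingroup, outg, *clades.values()):
        pass
    # wire parents and branch lengths from ages
    def wire(node: Node, parent: Optional[Node]):
        node.parent = parent
        if parent is not None:
            node.edge_length = parent.age - node.age
        for c in node.children:
            wire(c, node)

    wire(root, None)
    return PhyloTree(root)


def triticeae_planted_events() -> list[PlantedEvent]:
    """The four clade-diagnostic deletions, on the clade stem branches."""
    return [
        PlantedEvent("cladeII", "igs", "petN", "trnC", 529),
        PlantedEvent("cladeIII", "igs", "psbE", "petL", 438),
        PlantedEvent("cladeI", "igs", "trnT", "trnE", 172),
        PlantedEvent("cladeII", "ir", "ycf15", "trnL", 800),
    ]


def triticeae_preset(
    seed: int,
    indel_rate: float = 2.0,
    subst_rate: float = 0.001,
    bm_sigma2: float = 1.0e4,
) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        indel_rate=indel_rate,
        subst_rate=subst_rate,
        bm_sigma2=bm_sigma2,
        planted_events=triticeae_planted_events(),
    )


# ---------------------------------------------------------------------------
# Sequence evolution with known homology

def _igs_interval(
    feats: list[GeneFeature], left: str, right: str, region: tuple[int, int]
) -> tuple[int, int]:
    """[end of left gene, start of right gene) inside one region."""
    s = e = None
    for f in feats:
        fs, fe = f.intervals[0]
        if not (region[0] <= fs and fe <= region[1]):
            continue
        if f.name == left:
            s = fe
        elif f.name == right and e is None:
            e = fs
    if s is None or e is None or e <= s:
        raise ValueError(f"no spacer between {left!r} and {right!r} in region {region}")
    return s, e


def simulate(cfg: SimulationConfig, out_dir: str | Path | None = None) -> SimulationResult:
    """Evolve the template genome down the tree; emit data + ground truth.

    When ``out_dir`` is given, per-tip GenBank files, the true alignment
    (FASTA), the tree (Newick), and size/event/age TSVs are written there.
    Identical config and seed give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = (
        PhyloTree.from_newick(cfg.newick)
        if cfg.newick is not None
        else triticeae_tree(crown_age=cfg.crown_age)
    )
    if cfg.newick is not None and tree.root.age is None:
        tree.assign_ages_from_lengths()

    t = cfg.template
    full_seq, full_feats, q0 = build_ancestor(t, rng)
    lsc_end, irb_end, ssc_end = q0.lsc[1], q0.irb[1], q0.ssc[1]
    core_len = ssc_end

    # column-id machinery: ancestral core columns 0..core_len-1
    col_region = {}
    for i in range(core_len):
        col_region[i] = "lsc" if i < lsc_end else ("irb" if i < irb_end else "ssc")
    master: list[int] = list(range(core_len))
    next_id = [core_len]

    # resolve planted loci to ancestral column ranges (centered in spacer)
    planted_by_branch: dict[str, list[tuple[PlantedEvent, int, int]]] = {}
    for pe in cfg.planted_events:
        if pe.branch not in tree:
            raise ValueError(f"planted event on unknown branch {pe.branch!r}")
        region = (lsc_end, irb_end) if pe.region == "ir" else (0, lsc_end)
        try:
            s, e = _igs_interval(full_feats, pe.left_flank, pe.right_flank, region)
        except ValueError:
            s, e = _igs_interval(full_feats, pe.left_flank, pe.right_flank, (irb_end, ssc_end))
        if e - s < pe.length:
            raise ValueError(
                f"planted {pe.length} bp event exceeds the {pe.left_flank}-"
                f"{pe.right_flank} spacer ({e - s} bp)"
            )
        ds = s + (e - s - pe.length) // 2
        planted_by_branch.setdefault(pe.branch, []).append((pe, ds, ds + pe.length))

    # stochastic indels keep clear of the planted spacers so the diagnostic
    # events stay recoverable as single clean gap patterns
    protected: set[int] = set()
    for lst in planted_by_branch.values():
        for _, ds, de in lst:
            protected.update(range(ds, de))

    truth_events: list[TrueEvent] = []
    tip_cols: dict[str, list[tuple[int, str]]] = {}

    root_cols = [(i, full_seq[i]) for i in range(core_len)]

    def evolve(node, cols: list[tuple[int, str]]):
        if node.parent is not None:
            bt = node.edge_length or 0.0
            # planted events first (deterministic)
            for pe, ds, de in planted_by_branch.get(node.id, ()):
                keep = [c for c in cols if not (ds <= c[0] < de)]
                removed = len(cols) - len(keep)
                if removed != de - ds:
                    raise ValueError(
                        f"planted locus {pe.left_flank}-{pe.right_flank} already "
                        f"modified upstream of branch {node.id}"
                    )
                cols = keep
                truth_events.append(
                    TrueEvent(
                        branch=node.id,
                        kind="deletion",
                        length=pe.length,
                        region=col_region[ds],
                        col_ids=(ds, de),
                        flanks=(pe.left_flank, pe.right_flank),
                        planted=True,
                    )
                )
            # stochastic indels
            n_ev = rng.poisson(cfg.indel_rate * bt) if cfg.indel_rate > 0 else 0
            for _ in range(n_ev):
                length = int(rng.geometric(cfg.indel_length_p))
                if rng.random() < 0.5 and len(cols) > length + 2:
                    pos = -1
                    for _ in range(30):
                        cand = int(rng.integers(0, len(cols) - length))
                        if all(
                            c[0] not in protected
                            for c in cols[cand : cand + length]
                        ):
                            pos = cand
                            break
                    if pos < 0:
                        continue
                    removed = cols[pos : pos + length]
                    cols = cols[:pos] + cols[pos + length :]
                    truth_events.append(
                        TrueEvent(
                            branch=node.id,
                            kind="deletion",
                            length=length,
                            region=col_region[removed[0][0]],
                            col_ids=(removed[0][0], removed[-1][0] + 1),
                        )
                    )
                else:
                    pos = int(rng.integers(1, len(cols)))
                    for _ in range(30):
                        if cols[pos - 1][0] not in protected:
                            break
                        pos = int(rng.integers(1, len(cols)))
                    else:
                        continue
                    anchor = cols[pos - 1][0]
                    new_ids = list(range(next_id[0], next_id[0] + length))
                    next_id[0] += length
                    reg = col_region[anchor]
                    for nid in new_ids:
                        col_region[nid] = reg
                    mi = master.index(anchor)
                    master[mi + 1 : mi + 1] = new_ids
                    new_cols = [
                        (nid, _BASES[int(rng.integers(0, 4))]) for nid in new_ids
                    ]
                    cols = cols[:pos] + new_cols + cols[pos:]
                    truth_events.append(
                        TrueEvent(
                            branch=node.id,
                            kind="insertion",
                            length=length,
                            region=reg,
                            col_ids=(new_ids[0], new_ids[-1] + 1),
                        )
                    )
            # substitutions
            if cfg.subst_rate > 0 and bt > 0:
                p_mut = min(1.0, cfg.subst_rate * bt)
                n_mut = rng.binomial(len(cols), p_mut)
                if n_mut:
                    sites = rng.choice(len(cols), size=n_mut, replace=False)
                    for s_i in sites:
                        cid, base = cols[s_i]
                        alt = _BASES[int(rng.integers(0, 4))]
                        while alt == base:
                            alt = _BASES[int(rng.integers(0, 4))]
                        cols[s_i] = (cid, alt)
        if node.is_tip:
            tip_cols[node.id] = cols
        else:
            for child in node.children:
                evolve(child, list(cols))

    evolve(tree.root, root_cols)

    # assemble tips: sequence, annotation, quadripartite truth
    plastomes: dict[str, AnnotatedPlastome] = {}
    quads: dict[str, Quadripartite] = {}
    tip_sizes: dict[str, int] = {}
    span_name, span_ssc, span_ira = t.jsa_spanner

    for label, cols in tip_cols.items():
        pos_of = {cid: i for i, (cid, _) in enumerate(cols)}
        regions = [col_region[cid] for cid, _ in cols]
        n_lsc = sum(1 for r in regions if r == "lsc")
        n_irb = sum(1 for r in regions if r == "irb")
        n_ssc = len(cols) - n_lsc - n_irb
        core = "".join(b for _, b in cols)
        irb_seq = core[n_lsc : n_lsc + n_irb]
        full = core + revcomp(irb_seq)
        n = len(full)

        feats: list[GeneFeature] = []
        for f in full_feats:
            fs, fe = f.intervals[0]
            if fs >= ssc_end:  # ancestral IRa mirror; re-derived per tip below
                continue
            if f.name == span_name:
                continue
            ids = [pos_of[c] for c in range(fs, fe) if c in pos_of]
            if not ids:
                continue
            feats.append(GeneFeature(f.name, f.kind, f.strand, [(min(ids), max(ids) + 1)]))
        # mirror IR genes into IRa (tip frame)
        irb_lo, irb_hi = n_lsc, n_lsc + n_irb
        for f in list(feats):
            s, e = f.intervals[0]
            if irb_lo <= s and e <= irb_hi:
                ms = len(core) + (irb_hi - e)
                me = len(core) + (irb_hi - s)
                feats.append(
                    GeneFeature(f.name, f.kind, "-" if f.strand == "+" else "+", [(ms, me)])
                )
        # SSC/IRa spanner
        if span_ssc <= len(core) and span_ira <= n_irb:
            feats.append(
                GeneFeature(
                    span_name, "protein_cds", "+",
                    [(len(core) - span_ssc, len(core) + span_ira)],
                )
            )

        p = AnnotatedPlastome(label, full, feats)
        plastomes[label] = p
        tip_sizes[label] = n
        quads[label] = Quadripartite(
            lsc=(0, n_lsc),
            irb=(n_lsc, n_lsc + n_irb),
            ssc=(n_lsc + n_irb, len(core)),
            ira=(len(core), n),
        )

    # true alignment: core columns in master order + mirrored IRa block
    taxa = tree.tip_labels
    irb_master = [cid for cid in master if col_region[cid] == "irb"]
    aln_rows = []
    for label in taxa:
        base_of = {cid: b for cid, b in tip_cols[label]}
        core_row = "".join(base_of.get(cid, "-") for cid in master)
        ira_row = "".join(
            _COMP[base_of[cid]] if cid in base_of else "-"
            for cid in reversed(irb_master)
        )
        aln_rows.append(core_row + ira_row)
    alignment = Alignment(list(taxa), aln_rows)

    ages = {node.id: node.age for node in tree.preorder()}
    clade_of = {r.species: r.clade for r in triticeae_size_table()}
    sizes = [
        size_partition(plastomes[label], clade_of.get(label, "outgroup"))
        for label in taxa
    ]
    truth = SimulationTruth(
        tree=tree,
        events=truth_events,
        tip_sizes=tip_sizes,
        quadripartite=quads,
        node_ages=ages,
    )
    result = SimulationResult(plastomes, alignment, tree, truth, sizes)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: SimulationResult, out: Path) -> None:
    from .plastome import write_size_table
    from .indels import events_table

    out.mkdir(parents=True, exist_ok=True)
    gb = out / "genbank"
    gb.mkdir(exist_ok=True)
    for label, p in res.plastomes.items():
        write_genbank(p, gb / f"{label}.gb")
    res.alignment.to_fasta(out / "alignment.fasta")
    (out / "tree.nwk").write_text(res.tree.to_newick() + "\n")
    write_size_table(res.sizes, out / "sizes.tsv")
    import pandas as pd

    pd.DataFrame(
        [
            {
                "branch": e.branch,
                "kind": e.kind,
                "length": e.length,
                "region": e.region,
                "flanks": "-".join(e.flanks) if e.flanks else "",
                "planted": e.planted,
            }
            for e in res.truth.events
        ]
    ).to_csv(out / "true_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"node": k, "age": v} for k, v in res.truth.node_ages.items()]
    ).to_csv(out / "node_ages.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Brownian-motion trait simulation

def simulate_bm(
    tree: PhyloTree,
    root_value: float,
    sigma2: float,
    seed: int | np.random.Generator,
) -> dict[str, float]:
    """Brownian motion along branches: child ~ Normal(parent, sigma2 * t).

    Returns a value for every node id (root included). sigma2 is in squared
    trait units per MY; branch lengths must be in MY.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {tree.root.id: float(root_value)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        b = node.edge_length
        if b is None or b < 0:
            raise ValueError(f"node {node.id} lacks a usable branch length")
        step = rng.normal(0.0, np.sqrt(sigma2 * b)) if sigma2 > 0 else 0.0
        values[node.id] = values[node.parent.id] + step
    return values
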