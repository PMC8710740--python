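"""Indel-event calling from a multiple alignment, parsimony placement on a
rooted phylogeny, region classification, and a sliding-window divergence
scan.

An indel *event* is a maximal run of contiguous alignment columns sharing an
identical taxon gap-presence pattern, collapsed into one record. Counting
events (rather than columns or bp) matches how discrete deletions are
described in comparative plastome work ("a 529-bp deletion between petN and
trnC") and makes counts invariant to alignment length.

Placement treats gap presence as a binary character and maps the minimum
number of state changes onto branches with Fitch parsimony. Polarity
(insertion vs deletion) is read off the outgroup-anchored ancestral state:
if the ancestral state at the root is "base present" and the derived state
is "gap", the event is a deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .ir import Quadripartite
from .plastome import AnnotatedPlastome
from .trees import Node, PhyloTree

logger = logging.getLogger(__name__)

GAP = ord("-")


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Equal-length gapped sequences over {A,C,G,T,N,-} with unique taxa."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa / rows length mismatch")
        if len(self.taxa) < 3:
            raise AlignmentError("alignment needs at least 3 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"rows of unequal length: {sorted(lengths)}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa, rows)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        """(taxa x columns) byte matrix."""
        return np.frombuffer(
            "".join(self.rows).encode(), dtype=np.uint8
        ).reshape(len(self.rows), -1)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class IndelEvent:
    """A collapsed gap pattern: one candidate insertion/deletion event."""

    columns: tuple[int, int]  # [start, end) in alignment coordinates
    gap_taxa: frozenset[str]
    polarity: str = "unset"  # insertion | deletion | ambiguous | unset
    region_class: str = "unset"
    flanks: Optional[tuple[str, str]] = None  # flanking genes for IGS events
    branch: Optional[str] = None  # primary branch (child-node id)
    branches: tuple[str, ...] = ()  # all equally parsimonious placements

    @property
    def length_bp(self) -> int:
        return self.columns[1] - self.columns[0]


# ---------------------------------------------------------------------------
# Gap-pattern calling


def call_gap_patterns(a: Alignment) -> list[IndelEvent]:
    """Collapse maximal identical gap-pattern column runs into events.

    Columns where no taxon or every taxon has a gap yield no event; two
    adjacent runs with different taxon sets stay separate events.
    """
    m = a.matrix() == GAP  # True where gap
    n_taxa, n_cols = m.shape
    if n_cols == 0:
        return []
    # pattern id per column: group identical boolean columns
    _, col_ids = np.unique(m, axis=1, return_inverse=True)
    events: list[IndelEvent] = []
    start = 0
    for c in range(1, n_cols + 1):
        if c == n_cols or col_ids[c] != col_ids[start]:
            pat = m[:, start]
            k = int(pat.sum())
            if 0 < k < n_taxa:
                taxa = frozenset(a.taxa[i] for i in np.nonzero(pat)[0])
                events.append(IndelEvent(columns=(start, c), gap_taxa=taxa))
            start = c
    return events


# ---------------------------------------------------------------------------
# Fitch parsimony placement and polarity

# binary states: 1 = gap present, 0 = base present
_STATE_SETS = {0: frozenset({0}), 1: frozenset({1}), 2: frozenset({0, 1})}


def _fitch(
    tree: PhyloTree, tip_state: dict[str, int], root_prefer: Optional[int]
) -> tuple[dict[str, int], bool]:
    """One most-parsimonious reconstruction of a binary character.

    Down-pass computes Fitch state sets; the root picks ``root_prefer``
    when its set is ambiguous; the up-pass propagates parental choices.
    Returns (final state per node id, whether the root set was ambiguous).
    """
    sets: dict[str, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[node.id] = frozenset({tip_state[node.id]})
        else:
            inter = frozenset({0, 1})
            for c in node.children:
                inter = inter & sets[c.id]
            if inter:
                sets[node.id] = inter
            else:
                union: frozenset[int] = frozenset()
                for c in node.children:
                    union = union | sets[c.id]
                sets[node.id] = union

    final: dict[str, int] = {}
    root_set = sets[tree.root.id]
    root_ambiguous = len(root_set) > 1
    if root_ambiguous and root_prefer is not None and root_prefer in root_set:
        final[tree.root.id] = root_prefer
    else:
        final[tree.root.id] = min(root_set)
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = final[node.parent.id]
        s = sets[node.id]
        final[node.id] = parent_state if parent_state in s else min(s)
    return final, root_ambiguous


def polarize_and_place(
    event: IndelEvent, tree: PhyloTree, outgroup: str
) -> IndelEvent:
    """Assign an event to tree branch(es) and call insertion vs deletion.

    Gap presence is a binary character; Fitch parsimony yields the branches
    requiring a state change. An ambiguous root state is resolved to the
    outgroup's observed state. Polarity is deletion when the derived state
    relative to that ancestral anchor is "gap", insertion otherwise; if the
    root remains unresolvable the event is marked ambiguous and assigned to
    the branch subtending the smaller taxon set. With several equally
    parsimonious change branches, all are listed and the preorder-first is
    primary.
    """
    tips = set(tree.tip_labels)
    missing = event.gap_taxa - tips
    if missing:
        raise AlignmentError(f"event taxa not in tree: {sorted(missing)}")
    if outgroup not in tips:
        raise AlignmentError(f"outgroup {outgroup!r} is not a tip")

    tip_state = {t: (1 if t in event.gap_taxa else 0) for t in tips}
    out_state = tip_state[outgroup]
    final, root_ambiguous = _fitch(tree, tip_state, root_prefer=out_state)

    change_nodes = [
        n.id
        for n in tree.preorder()
        if n.parent is not None and final[n.id] != final[n.parent.id]
    ]
    root_state = final[tree.root.id]
    if root_state == 0:
        polarity = "deletion"
    else:
        polarity = "insertion"

    if root_ambiguous and out_state not in (0, 1):
        polarity = "ambiguous"  # defensive; tip states are always 0/1

    if not change_nodes:
        # all tips share the state yet the pattern was a proper subset —
        # cannot happen for binary patterns from call_gap_patterns
        polarity = "ambiguous"
        smaller = (
            event.gap_taxa
            if len(event.gap_taxa) <= len(tips - event.gap_taxa)
            else tips - event.gap_taxa
        )
        change_nodes = [tree.mrca(smaller).id]

    if len(change_nodes) > 1:
        logger.info(
            "event %s: %d equally parsimonious placements %s",
            event.columns,
            len(change_nodes),
            change_nodes,
        )
    return IndelEvent(
        columns=event.columns,
        gap_taxa=event.gap_taxa,
        polarity=polarity,
        region_class=event.region_class,
        flanks=event.flanks,
        branch=change_nodes[0],
        branches=tuple(change_nodes),
    )


# ---------------------------------------------------------------------------
# Region classification


def alignment_column_map(a: Alignment, reference: str) -> np.ndarray:
    """Map alignment columns to ungapped reference coordinates.

    Columns where the reference row has a gap get the coordinate of the
    nearest mapped column to the left (or the first mapped coordinate for
    leading gaps).
    """
    row = np.frombuffer(a.row(reference).encode(), dtype=np.uint8)
    ungapped = row != GAP
    coord = np.cumsum(ungapped) - 1
    coord[coord < 0] = 0
    return coord


def classify_region(
    event: IndelEvent,
    ref: AnnotatedPlastome,
    q: Quadripartite,
    colmap: np.ndarray,
    reference: str | None = None,
) -> IndelEvent:
    """Set the event's genomic region class from the reference annotation.

    Events inside either IR copy are classed ``ir``; elsewhere a feature
    overlap decides (protein_cds > intron > pseudogene > trna/rrna treated
    as their own gene body -> the event is still "in a gene", reported under
    the feature kind); intergenic events are ``igs`` with the flanking gene
    pair named. ``colmap`` must come from :func:`alignment_column_map` on
    the reference row, and ``ref`` must be in the quadripartite frame
    (LSC at 0).
    """
    s = int(colmap[event.columns[0]])
    e = int(colmap[event.columns[1] - 1]) + 1
    if e <= s:
        e = s + 1
        logger.warning(
            "event %s maps inside a reference gap; using nearest column",
            event.columns,
        )
    region = q.region_of(s)
    if region in ("irb", "ira"):
        return _with_class(event, "ir", None)

    overlaps: list = []
    for f in ref.features:
        for fs, fe in f.intervals:
            if fs < e and s < fe:
                overlaps.append(f)
                break
    for kind in ("protein_cds", "intron", "pseudogene", "trna", "rrna"):
        for f in overlaps:
            if f.kind == kind:
                cls = kind if kind in ("protein_cds", "intron", "pseudogene") else "igs"
                # tRNA/rRNA bodies fall in the non-protein-coding bucket;
                # report them as igs flanked by the gene itself
                if cls == "igs":
                    return _with_class(event, "igs", (f.name, f.name))
                return _with_class(event, cls, None)

    # intergenic: name the nearest gene on each side
    left_name, left_edge = None, -1
    right_name, right_edge = None, ref.length + 1
    for f in ref.features:
        fs, fe = f.span
        if fe <= s and fe > left_edge:
            left_name, left_edge = f.name, fe
        if fs >= e and fs < right_edge:
            right_name, right_edge = f.name, fs
    if left_name is None and right_name is None:
        return _with_class(event, region, None)  # unannotated genome: lsc/ssc
    return _with_class(event, "igs", (left_name or "?", right_name or "?"))


def _with_class(
    event: IndelEvent, cls: str, flanks: Optional[tuple[str, str]]
) -> IndelEvent:
    return IndelEvent(
        columns=event.columns,
        gap_taxa=event.gap_taxa,
        polarity=event.polarity,
        region_class=cls,
        flanks=flanks,
        branch=event.branch,
        branches=event.branches,
    )


# ---------------------------------------------------------------------------
# Per-node event counts (clade-cumulative)


def node_counts(
    events: Sequence[IndelEvent],
    tree: PhyloTree,
    ages: Optional[dict[str, float]] = None,
    sizes: Optional[dict[str, float]] = None,
):
    """Clade-cumulative indel counts per internal node as a DataFrame.

    A node's count is the number of events whose primary branch lies inside
    the clade it subtends (any branch at or below the node's children), so
    counts increase monotonically toward the root and the root carries the
    total. Optional per-node ages (MYA) and genome sizes are passed through.
    """
    import pandas as pd

    unplaced = [e for e in events if e.branch is None]
    if unplaced:
        raise AlignmentError(f"{len(unplaced)} events lack a branch assignment")

    # events on the branch *above* node b count for every strict ancestor of b
    per_branch: dict[str, int] = {}
    for e in events:
        per_branch[e.branch] = per_branch.get(e.branch, 0) + 1

    cum: dict[str, int] = {}
    for node in tree.postorder():
        total = 0
        for c in node.children:
            total += cum[c.id] + per_branch.get(c.id, 0)
        cum[node.id] = total

    rows = []
    for node in tree.internal_nodes:
        rows.append(
            {
                "node": node.id,
                "divergence_time": (
                    ages.get(node.id) if ages else node.age
                ),
                "indel_count": cum[node.id],
                "cp_size": sizes.get(node.id) if sizes else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sliding-window divergence scan


def windowed_divergence(
    a: Alignment,
    window: int = 600,
    step: int = 200,
    max_gap_frac: float = 0.5,
):
    """Mean pairwise identity per alignment window.

    Identity is averaged over all taxon pairs and all columns where both
    sequences have a base; N never matches anything; columns with more than
    ``max_gap_frac`` gaps are excluded. Returns a DataFrame with window
    start/end (alignment coordinates) and mean identity (NaN when a window
    has no comparable pair).
    """
    import pandas as pd

    if window < 1 or step < 1:
        raise AlignmentError("window and step must be >= 1")
    m = a.matrix()
    n_taxa, n_cols = m.shape
    is_gap = m == GAP
    is_n = m == ord("N")
    col_ok = is_gap.mean(axis=0) <= max_gap_frac

    starts = list(range(0, max(n_cols - window, 0) + 1, step))
    if not starts:
        starts = [0]
    rows = []
    for s in starts:
        e = min(s + window, n_cols)
        sel = col_ok[s:e]
        sub = m[:, s:e][:, sel]
        g = is_gap[:, s:e][:, sel]
        nn = is_n[:, s:e][:, sel]
        matches = 0
        comps = 0
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                both = ~(g[i] | g[j])
                comparable = int(both.sum())
                eq = (sub[i] == sub[j]) & both & ~nn[i] & ~nn[j]
                matches += int(eq.sum())
                comps += comparable
        ident = matches / comps if comps else float("nan")
        rows.append({"start": s, "end": e, "identity": ident})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular export


def events_table(events: Sequence[IndelEvent]):
    """Events as a DataFrame (one row per event, stable order)."""
    import pandas as pd

    rows = []
    for i, e in enumerate(events):
        rows.append(
            {
                "event_id": i,
                "aln_start": e.columns[0],
                "aln_end": e.columns[1],
                "length_bp": e.length_bp,
                "taxa": ",".join(sorted(e.gap_taxa)),
                "polarity": e.polarity,
                "branch": e.branch,
                "all_branches": ",".join(e.branches),
                "region": e.region_class,
                "flanks": "-".join(e.flanks) if e.flanks else "",
            }
        )
    return pd.DataFrame(rows)
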