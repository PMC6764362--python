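"""Gene-tree conflict mapping against a reference phylogeny.

Each gene tree is compared to every internal node of a reference tree
using the bipartition method: a reference split (restricted to the taxa
the gene actually samples) is either contained in the gene tree
(concordant), contradicted by a supported gene-tree split (conflict), or
neither (uninformative — low support, a polytomy, or a missing taxon
that collapses the node).  Per-node tallies identify the dominant
alternative topology; per-gene tallies feed the concordance regression;
node ages bin the signal into time slices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .trees import Bipartition, PhyloTree, TreeError, restricted_splits

__all__ = [
    "CONCORDANT",
    "CONFLICT",
    "UNINFORMATIVE",
    "NodeClassification",
    "ConflictSummary",
    "ClassificationMatrix",
    "TimeSliceProfile",
    "GeneConcordanceScore",
    "reference_nodes",
    "classify_node",
    "map_all",
    "time_slice",
    "score_genes",
    "region_summary",
    "PAPER_BINS",
]

CONCORDANT = "concordant"
CONFLICT = "conflict"
UNINFORMATIVE = "uninformative"

#: reason codes for UNINFORMATIVE
MISSING_TAXA = "missing_taxa"
LOW_SUPPORT = "low_support"

#: The five 30-Ma angiosperm time intervals: (name, upper, lower printed edge).
PAPER_BINS = [
    ("150-121", 150.0, 121.0),
    ("120-91", 120.0, 91.0),
    ("90-61", 90.0, 61.0),
    ("60-31", 60.0, 31.0),
    ("30-0", 30.0, 0.0),
]


@dataclass(frozen=True)
class NodeClassification:
    category: str
    conflicting: Optional[Bipartition] = None
    reason: Optional[str] = None

    def __post_init__(self):
        if self.category == CONFLICT and self.conflicting is None:
            raise ValueError("CONFLICT classification must carry the observed split")

    @property
    def evaluable(self) -> bool:
        """False when the node was voided by missing taxa."""
        return self.reason != MISSING_TAXA

    def __str__(self) -> str:
        if self.category == UNINFORMATIVE and self.reason:
            return f"{self.category}:{self.reason}"
        return self.category


@dataclass
class ConflictSummary:
    node_id: str
    n_concordant: int
    n_dominant_alt: int
    n_other_conflict: int
    n_uninformative: int
    dominant_alt: Optional[Bipartition]

    @property
    def n_total(self) -> int:
        return (
            self.n_concordant
            + self.n_dominant_alt
            + self.n_other_conflict
            + self.n_uninformative
        )


# ----------------------------------------------------------------------


def reference_nodes(reference: PhyloTree) -> list[tuple[str, Bipartition, frozenset]]:
    """Internal reference nodes usable for conflict mapping.

    Returns ``(node_id, split, clade)`` triples in postorder.  Nodes whose
    split is trivial on the full taxon set (e.g. the ingroup node when a
    single outgroup subtends it) are excluded.  Ids are ``N<k>`` by
    postorder position and stable across runs.
    """
    taxa = reference.leaf_labels()
    out = []
    below: dict[int, frozenset] = {}
    k = 0
    seen_splits = set()
    for node in reference.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node is reference.root:
            continue
        if len(clade) < 2 or len(taxa - clade) < 2:
            continue
        split = Bipartition.make(clade, taxa)
        if split in seen_splits:  # the two children of a bifurcating root
            continue
        seen_splits.add(split)
        out.append((f"N{k}", split, clade))
        k += 1
    return out


def classify_node(
    gene_tree: PhyloTree,
    ref_split: Bipartition,
    support_cutoff: Optional[float] = None,
) -> NodeClassification:
    """Classify one gene tree against one reference split.

    The reference split is restricted to the gene's leaf set first: if a
    side collapses below two taxa the gene cannot address the node
    (uninformative, missing taxa).  Otherwise the gene is concordant if a
    qualifying edge induces exactly the restricted split, conflicting if
    a qualifying edge induces an incompatible split (the first such split
    in postorder is recorded), and uninformative otherwise.  With a
    support cutoff, edges below the cutoff (or without support) never
    qualify.
    """
    gene_taxa = gene_tree.leaf_labels()
    common = gene_taxa & ref_split.taxon_set
    if not common:
        raise TreeError("gene tree and reference split share no taxa")
    restricted = ref_split.restrict(common)
    if restricted is None:
        return NodeClassification(UNINFORMATIVE, reason=MISSING_TAXA)
    gene_splits = restricted_splits(gene_tree, common, min_support=support_cutoff)
    if restricted in gene_splits:
        return NodeClassification(CONCORDANT)
    for gs in gene_splits:
        if gs.conflicts_with(restricted):
            return NodeClassification(CONFLICT, conflicting=gs)
    return NodeClassification(UNINFORMATIVE, reason=LOW_SUPPORT)


@dataclass
class ClassificationMatrix:
    """Gene x reference-node grid of :class:`NodeClassification`."""

    genes: list[str]
    node_ids: list[str]
    cells: dict[tuple[str, str], NodeClassification]
    support_cutoff: Optional[float]

    def get(self, gene: str, node_id: str) -> NodeClassification:
        return self.cells[(gene, node_id)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            nid: [str(self.cells[(g, nid)]) for g in self.genes] for nid in self.node_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, support_cutoff=None) -> "ClassificationMatrix":
        cells = {}
        for gene in frame.index:
            for nid in frame.columns:
                raw = frame.loc[gene, nid]
                if ":" in raw:
                    cat, reason = raw.split(":", 1)
                else:
                    cat, reason = raw, None
                if cat == CONFLICT:
                    # the observed split is not serialized in the frame
                    cells[(gene, nid)] = NodeClassification(
                        CONFLICT, conflicting=Bipartition.make({"_a", "_b"}, {"_a", "_b", "_c", "_d"})
                    )
                else:
                    cells[(gene, nid)] = NodeClassification(cat, reason=reason)
        return cls(list(frame.index), list(frame.columns), cells, support_cutoff)


def map_all(
    gene_trees: Sequence[tuple[str, PhyloTree]],
    reference: PhyloTree,
    support_cutoff: Optional[float] = None,
) -> tuple[dict[str, ConflictSummary], ClassificationMatrix]:
    """Classify every gene tree at every reference node.

    Returns per-node conflict summaries (with the dominant alternative
    split) and the full gene-by-node classification matrix.  Genes that
    cannot be evaluated at a node (for instance no shared taxa) are
    recorded as uninformative for that node rather than aborting the run.
    """
    nodes = reference_nodes(reference)
    names = [n for n, _ in gene_trees]
    if len(set(names)) != len(names):
        raise TreeError("duplicate gene names")
    ref_taxa = reference.leaf_labels()
    # Every reference split carries the full reference taxon set, so the
    # comparison taxon set is the same for all nodes of one gene: cache
    # each gene's qualifying splits once instead of per node.
    gene_cache: dict[str, tuple[frozenset, set, list]] = {}
    for gene, tree in gene_trees:
        common = tree.leaf_labels() & ref_taxa
        try:
            splits = restricted_splits(tree, common, min_support=support_cutoff)
        except TreeError:
            splits = []
        gene_cache[gene] = (common, set(splits), splits)

    def fast_classify(gene: str, split: Bipartition) -> NodeClassification:
        common, split_set, ordered = gene_cache[gene]
        if not common:
            return NodeClassification(UNINFORMATIVE, reason=MISSING_TAXA)
        restricted = split.restrict(common)
        if restricted is None:
            return NodeClassification(UNINFORMATIVE, reason=MISSING_TAXA)
        if restricted in split_set:
            return NodeClassification(CONCORDANT)
        for gs in ordered:
            if gs.conflicts_with(restricted):
                return NodeClassification(CONFLICT, conflicting=gs)
        return NodeClassification(UNINFORMATIVE, reason=LOW_SUPPORT)

    cells: dict[tuple[str, str], NodeClassification] = {}
    summaries: dict[str, ConflictSummary] = {}
    for node_id, split, _clade in nodes:
        tally = Counter()
        alt_counts: Counter[Bipartition] = Counter()
        for gene, tree in gene_trees:
            cls = fast_classify(gene, split)
            cells[(gene, node_id)] = cls
            tally[cls.category] += 1
            if cls.category == CONFLICT:
                alt_counts[cls.conflicting] += 1
        dominant: Optional[Bipartition] = None
        n_dom = 0
        if alt_counts:
            best = max(alt_counts.values())
            candidates = sorted(
                (bp for bp, c in alt_counts.items() if c == best),
                key=Bipartition.sort_key,
            )
            dominant = candidates[0]
            n_dom = best
        summaries[node_id] = ConflictSummary(
            node_id=node_id,
            n_concordant=tally[CONCORDANT],
            n_dominant_alt=n_dom,
            n_other_conflict=tally[CONFLICT] - n_dom,
            n_uninformative=tally[UNINFORMATIVE],
            dominant_alt=dominant,
        )
    matrix = ClassificationMatrix(names, [n for n, _, _ in nodes], cells, support_cutoff)
    return summaries, matrix


# ----------------------------------------------------------------------
# Time slices


def assign_bin(age: float, bins: Sequence[tuple[str, float, float]]) -> str:
    """Bin an age (Ma): the bin with the largest lower printed edge <= age.

    With the standard five 30-Ma intervals this sends 95 to "120-91",
    121 to "150-121" and 30 to "30-0"; ages above the oldest bin's upper
    edge are errors.
    """
    ordered = sorted(bins, key=lambda b: -b[1])
    if age > ordered[0][1] or age < 0:
        raise ValueError(f"age {age} outside all bins")
    for name, _upper, lower in ordered:
        if age >= lower:
            return name
    raise ValueError(f"age {age} outside all bins")


@dataclass
class TimeSliceProfile:
    """Per gene x per time bin concordance proportions."""

    table: pd.DataFrame  # columns: gene, bin, n_concordant, n_evaluable, proportion
    bins: list[tuple[str, float, float]]

    def pivot(self, value: str = "proportion") -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="bin", values=value)[
            [b[0] for b in self.bins]
        ]


def time_slice(
    matrix: ClassificationMatrix,
    node_ages: Mapping[str, float],
    bins: Sequence[tuple[str, float, float]] = PAPER_BINS,
) -> TimeSliceProfile:
    """Bin per-gene concordance into age intervals.

    ``node_ages`` maps reference node ids to ages in Ma; every node of
    the matrix must be aged.  The denominator per gene/bin counts only
    evaluable nodes (not voided by missing taxa); the proportion is NaN
    where no node is evaluable.
    """
    missing = [n for n in matrix.node_ids if n not in node_ages]
    if missing:
        raise ValueError(f"nodes without ages: {missing}")
    node_bin = {n: assign_bin(node_ages[n], bins) for n in matrix.node_ids}
    rows = []
    for gene in matrix.genes:
        conc = Counter()
        ev = Counter()
        for nid in matrix.node_ids:
            cls = matrix.get(gene, nid)
            b = node_bin[nid]
            if cls.evaluable:
                ev[b] += 1
                if cls.category == CONCORDANT:
                    conc[b] += 1
        for name, _u, _l in bins:
            n_ev = ev[name]
            rows.append(
                {
                    "gene": gene,
                    "bin": name,
                    "n_concordant": conc[name],
                    "n_evaluable": n_ev,
                    "proportion": conc[name] / n_ev if n_ev else float("nan"),
                }
            )
    return TimeSliceProfile(pd.DataFrame(rows), list(bins))


# ----------------------------------------------------------------------
# Per-gene scores and genomic regions


@dataclass
class GeneConcordanceScore:
    gene: str
    n_concordant_nosupport: int
    n_concordant_support: int
    n_available: int

    def __post_init__(self):
        if not (
            self.n_concordant_support
            <= self.n_concordant_nosupport
            <= self.n_available
        ):
            raise ValueError(
                f"inconsistent counts for {self.gene}: "
                f"{self.n_concordant_support} <= {self.n_concordant_nosupport} "
                f"<= {self.n_available} violated"
            )


def score_genes(
    matrix_nosupport: ClassificationMatrix,
    matrix_support: ClassificationMatrix,
) -> list[GeneConcordanceScore]:
    """Per-gene concordant-node counts with and without the support cutoff.

    ``n_available`` counts reference nodes not voided by missing taxa
    (identical in both matrices by construction).  The returned list is
    sorted by gene name, so rankings that tie on counts break ties
    alphabetically.
    """
    if set(matrix_nosupport.genes) != set(matrix_support.genes) or set(
        matrix_nosupport.node_ids
    ) != set(matrix_support.node_ids):
        raise ValueError("matrices cover different gene or node sets")
    out = []
    for gene in sorted(matrix_nosupport.genes):
        avail = 0
        c_ns = 0
        c_s = 0
        for nid in matrix_nosupport.node_ids:
            ns = matrix_nosupport.get(gene, nid)
            s = matrix_support.get(gene, nid)
            if ns.evaluable:
                avail += 1
            if ns.category == CONCORDANT:
                c_ns += 1
            if s.category == CONCORDANT:
                c_s += 1
        out.append(GeneConcordanceScore(gene, c_ns, c_s, avail))
    return out


def region_summary(
    scores: Sequence[GeneConcordanceScore],
    region_map: Mapping[str, str],
    alignment_lengths: Optional[Mapping[str, int]] = None,
    tree_lengths: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Aggregate concordance by genomic region (LSC / SSC / IR).

    Sums per-gene concordant-node counts per region; when provided, also
    totals the concatenated alignment length (sum of gene alignment
    lengths) and the summed gene tree lengths as the region's rate proxy.
    """
    unlabeled = [s.gene for s in scores if s.gene not in region_map]
    if unlabeled:
        raise ValueError(f"genes without region label: {unlabeled}")
    rows = []
    for s in scores:
        rows.append(
            {
                "region": region_map[s.gene],
                "gene": s.gene,
                "n_concordant_nosupport": s.n_concordant_nosupport,
                "n_concordant_support": s.n_concordant_support,
                "n_available": s.n_available,
                "alignment_length": (alignment_lengths or {}).get(s.gene, 0),
                "tree_length": (tree_lengths or {}).get(s.gene, 0.0),
            }
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("region").agg(
        n_genes=("gene", "count"),
        n_concordant_nosupport=("n_concordant_nosupport", "sum"),
        n_concordant_support=("n_concordant_support", "sum"),
        n_available=("n_available", "sum"),
        alignment_length=("alignment_length", "sum"),
        tree_length=("tree_length", "sum"),
    )
    return agg.sort_index()
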