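"""End-to-end pipeline stages over files: conflict mapping, the edge
test, and the RF network, with reproducible TSV/JSON reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .alignments import Alignment, read_fasta
from .conflict import (
    PAPER_BINS,
    ClassificationMatrix,
    map_all,
    reference_nodes,
    region_summary,
    score_genes,
    time_slice,
)
from .likelihood import ConstraintHypothesis, SubstModel, edge_test
from .trees import PhyloTree, TreeError, parse_newick, rf_distance, root_ranked, tree_stats

log = logging.getLogger("phyloconflict")


def _report_meta(config: Mapping) -> dict:
    return {"software": "phyloconflict", "version": __version__, "config": dict(config)}


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def load_gene_trees(
    directory: Path, outgroups: Optional[Sequence[str]] = None
) -> list[tuple[str, PhyloTree]]:
    """Read every ``*.tre`` / ``*.nwk`` in a directory, rooting if asked."""
    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix in (".tre", ".nwk", ".newick")
    )
    if not paths:
        raise TreeError(f"no gene trees in {directory}")
    out = []
    for p in paths:
        tree = parse_newick(p.read_text())
        if outgroups:
            try:
                tree = root_ranked(tree, outgroups)
            except TreeError as exc:
                log.warning("could not root %s (%s); using as-is", p.name, exc)
        out.append((p.stem, tree))
    return out


def read_age_table(path: Path) -> pd.DataFrame:
    ages = pd.read_csv(path, sep="\t")
    required = {"node_id", "age"}
    if not required <= set(ages.columns):
        raise ValueError(f"age table needs columns {sorted(required)}")
    return ages


def match_ages_to_reference(reference: PhyloTree, ages: pd.DataFrame) -> dict[str, float]:
    """Map ages onto this run's node ids, matching by clade when present."""
    nodes = reference_nodes(reference)
    if "clade" in ages.columns:
        by_clade = {
            frozenset(str(c).split(";")): a for c, a in zip(ages["clade"], ages["age"])
        }
        out = {}
        for nid, _split, clade in nodes:
            if clade in by_clade:
                out[nid] = float(by_clade[clade])
        return out
    return {str(n): float(a) for n, a in zip(ages["node_id"], ages["age"])}


def run_conflict(
    gene_trees: Sequence[tuple[str, PhyloTree]],
    reference: PhyloTree,
    out_dir: Path,
    support_cutoff: float = 70.0,
    outgroups: Optional[Sequence[str]] = None,
    node_ages: Optional[Mapping[str, float]] = None,
    bins=PAPER_BINS,
    region_map: Optional[Mapping[str, str]] = None,
    gene_stats: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> dict:
    """Full conflict-mapping stage; writes TSV/JSON reports to ``out_dir``.

    Runs the bipartition mapping at no cutoff and at ``support_cutoff``,
    tabulates per-node pies with dominant alternatives, per-gene scores,
    time slices (when ages are given) and region summaries (when a
    region map is given).  Per-gene failures are logged and degrade to
    uninformative rather than aborting the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if outgroups:
        rooted = []
        for name, t in gene_trees:
            try:
                rooted.append((name, root_ranked(t, outgroups)))
            except TreeError as exc:
                log.warning("gene %s: %s; left unrooted", name, exc)
                rooted.append((name, t))
        gene_trees = rooted
    summaries_ns, matrix_ns = map_all(gene_trees, reference, None)
    summaries_s, matrix_s = map_all(gene_trees, reference, support_cutoff)

    pies = pd.DataFrame(
        [
            {
                "node_id": s.node_id,
                "n_concordant": s.n_concordant,
                "n_dominant_alt": s.n_dominant_alt,
                "n_other_conflict": s.n_other_conflict,
                "n_uninformative": s.n_uninformative,
                "dominant_alt": str(s.dominant_alt) if s.dominant_alt else "",
            }
            for s in summaries_s.values()
        ]
    )
    pies.to_csv(out_dir / "node_pies.tsv", sep="\t", index=False)
    matrix_s.to_frame().to_csv(out_dir / "classification_support.tsv", sep="\t")
    matrix_ns.to_frame().to_csv(out_dir / "classification_nosupport.tsv", sep="\t")

    scores = score_genes(matrix_ns, matrix_s)
    scores_df = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "n_concordant_nosupport": s.n_concordant_nosupport,
                "n_concordant_support": s.n_concordant_support,
                "n_available": s.n_available,
            }
            for s in scores
        ]
    )
    scores_df.to_csv(out_dir / "gene_scores.tsv", sep="\t", index=False)

    outputs = {"node_pies": pies, "gene_scores": scores_df}
    if node_ages is not None:
        profile = time_slice(matrix_s, node_ages, bins)
        profile.table.to_csv(out_dir / "time_slices.tsv", sep="\t", index=False)
        outputs["time_slices"] = profile.table
    if region_map is not None:
        al = tl = None
        if gene_stats is not None:
            al = dict(zip(gene_stats["gene"], gene_stats["alignment_length"]))
            tl = dict(zip(gene_stats["gene"], gene_stats["tree_length"]))
        regions = region_summary(scores, region_map, al, tl)
        regions.to_csv(out_dir / "region_summary.tsv", sep="\t")
        outputs["region_summary"] = regions
    meta = _report_meta(
        {
            "support_cutoff": support_cutoff,
            "outgroups": list(outgroups or []),
            "n_genes": len(gene_trees),
            "seed": seed,
        }
    )
    _write_json(out_dir / "conflict_report.json", meta)
    return outputs


def run_edgetest(
    genes: Sequence[tuple[str, Alignment]],
    hypotheses: Sequence[ConstraintHypothesis],
    out_dir: Path,
    model: Optional[SubstModel] = None,
    gene_trees: Optional[Mapping[str, PhyloTree]] = None,
    support_cutoff: float = 70.0,
    keep_trees: bool = False,
    seed: Optional[int] = None,
) -> dict:
    """Edge test over constraint hypotheses; writes per-gene and summary tables.

    When ``gene_trees`` (e.g. the genes' inferred trees with bootstrap
    supports) are supplied, a listing of the genes whose own tree
    supports each hypothesis's focal split at ``support_cutoff`` is also
    written, complementing the likelihood totals.  With ``keep_trees``
    the best constrained topology per gene and hypothesis is exported as
    newick.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(hypotheses) == 1:
        log.warning("only one hypothesis: the 'winner' is degenerate")
        hypotheses = list(hypotheses) * 2
        result = edge_test(genes, [hypotheses[0],
                                   ConstraintHypothesis(hypotheses[0].name + "_dup",
                                                        hypotheses[0].constraint_tree)],
                           model=model, keep_trees=keep_trees)
        result.table = result.table.iloc[:, :1]
    else:
        result = edge_test(genes, hypotheses, model=model, keep_trees=keep_trees)
    result.table.to_csv(out_dir / "edgetest_per_gene.tsv", sep="\t")
    if keep_trees and result.trees:
        tree_dir = out_dir / "constrained_trees"
        tree_dir.mkdir(exist_ok=True)
        for (gene, hyp), tree in sorted(result.trees.items()):
            (tree_dir / f"{gene}__{hyp}.tre").write_text(tree.to_newick() + "\n")
    if gene_trees is not None:
        support = gene_support_listing(gene_trees, hypotheses, support_cutoff)
        support.to_csv(out_dir / "gene_support.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        {
            "total_loglik": result.totals,
            "total_rounded": result.totals.round(0).astype(int),
            "n_genes_best": result.per_gene_best.value_counts().reindex(
                result.table.columns, fill_value=0
            ),
        }
    )
    summary.index.name = "hypothesis"
    summary.to_csv(out_dir / "edgetest_summary.tsv", sep="\t")
    meta = _report_meta(
        {
            "hypotheses": [h.name for h in hypotheses],
            "best_hypothesis": result.best_hypothesis,
            "flagged_genes": result.flagged_genes,
            "seed": seed,
        }
    )
    _write_json(out_dir / "edgetest_report.json", meta)
    return {"result": result, "summary": summary}


def gene_support_listing(
    gene_trees: Mapping[str, PhyloTree],
    hypotheses: Sequence[ConstraintHypothesis],
    support_cutoff: float = 70.0,
) -> pd.DataFrame:
    """Which genes' own trees support each hypothesis's focal split.

    Every resolved split of each constraint is classified against every
    gene tree at the support cutoff; the table lists one row per
    (hypothesis, gene) with the classification, so "genes supporting
    hypothesis H at >= cutoff" is the concordant subset.
    """
    from .conflict import classify_node

    rows = []
    for h in hypotheses:
        for split in sorted(h.splits(), key=lambda b: b.sort_key()):
            for gene in sorted(gene_trees):
                try:
                    cls = classify_node(gene_trees[gene], split, support_cutoff)
                    cat = cls.category
                except TreeError:
                    cat = "uninformative"
                rows.append(
                    {
                        "hypothesis": h.name,
                        "split": str(split),
                        "gene": gene,
                        "classification": cat,
                    }
                )
    return pd.DataFrame(rows)


def run_rf_network(
    trees: Sequence[tuple[str, PhyloTree]],
    out_dir: Path,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """All-pairs RF network: nodes are trees, weights are inverse RF.

    Identical-topology pairs (RF = 0) are flagged and given twice the
    largest finite inverse weight; pairs with insufficient leaf overlap
    are skipped with a log entry.
    """
    if len(trees) < 2:
        raise TreeError("need at least 2 trees")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            n1, t1 = trees[i]
            n2, t2 = trees[j]
            try:
                rf = rf_distance(t1, t2)
            except TreeError as exc:
                log.warning("skipping pair (%s, %s): %s", n1, n2, exc)
                continue
            rows.append({"tree_1": n1, "tree_2": n2, "rf": rf})
    edges = pd.DataFrame(rows)
    finite = edges.loc[edges["rf"] > 0, "rf"]
    max_inv = (1.0 / finite).max() if len(finite) else 1.0
    edges["weight"] = edges["rf"].apply(lambda r: 2 * max_inv if r == 0 else 1.0 / r)
    edges["flagged_zero_rf"] = edges["rf"] == 0
    edges.to_csv(out_dir / "rf_edges.tsv", sep="\t", index=False)
    nodes = pd.DataFrame({"tree": [n for n, _ in trees]})
    nodes.to_csv(out_dir / "rf_nodes.tsv", sep="\t", index=False)
    _write_json(out_dir / "rfnet_report.json", _report_meta({"n_trees": len(trees), "seed": seed}))
    return edges
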