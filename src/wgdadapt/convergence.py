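"""Cross-species convergence tests on a shared gene namespace.

Candidates from two independently polyploidized species are mapped to a common
reference-species namespace via an orthogroup/reciprocal-best-hit cascade and
compared at three levels: identical orthologs (Fisher exact overlap), shared
biological processes (topology-aware GO enrichment with the elim algorithm),
and interacting proteins (permutation test on interaction-network overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom


@dataclass(frozen=True)
class OrthologAssignment:
    gene: str
    reference_id: str | None
    rule: int  # 1-5, or 0 for unassigned
    orthogroup: str | None = None
    rbh: bool = False
    evalue: float | None = None


def assign_reference_ids(
    orthogroups: pd.DataFrame,
    rbh: dict[str, str] | pd.DataFrame,
    evalues: pd.DataFrame,
    source_species: str,
    reference_species: str,
) -> pd.DataFrame:
    """Assign each source-species gene one reference-species ID by cascade.

    orthogroups: columns og, species, gene.  rbh: source gene -> reference gene
    (dict or 2-column frame).  evalues: columns gene, reference_gene, evalue
    (best alignment hits).  The cascade:

    1. the gene's orthogroup holds exactly one reference gene -> that gene;
    2. more than one, and the gene's RBH is among them -> the RBH;
    3. more than one, RBH absent from the orthogroup -> the lowest-E-value
       orthogroup member;
    4. orthogroup holds no reference genes -> the RBH;
    5. otherwise -> the lowest-E-value hit overall; no hit -> unassigned (rule 0).

    Every input gene gets exactly one rule.  A gene in several orthogroups is
    an input error.
    """
    if isinstance(rbh, pd.DataFrame):
        rbh = dict(zip(rbh.iloc[:, 0], rbh.iloc[:, 1]))
    src = orthogroups[orthogroups["species"] == source_species]
    dup = src["gene"].duplicated()
    if dup.any():
        raise ValueError(f"gene(s) in multiple orthogroups: {sorted(src.loc[dup, 'gene'])}")
    gene_og = dict(zip(src["gene"], src["og"]))
    ref = orthogroups[orthogroups["species"] == reference_species]
    og_refs = ref.groupby("og")["gene"].apply(list).to_dict()

    ev = evalues.set_index(["gene", "reference_gene"])["evalue"]
    best_hit = (
        evalues.sort_values("evalue", kind="stable").drop_duplicates("gene").set_index("gene")
    )

    rows = []
    for gene in src["gene"]:
        og = gene_og[gene]
        members = og_refs.get(og, [])
        gene_rbh = rbh.get(gene)
        assignment = None
        if len(members) == 1:
            assignment = (members[0], 1)
        elif len(members) > 1:
            if gene_rbh in members:
                assignment = (gene_rbh, 2)
            else:
                scored = [
                    (ev.get((gene, m), np.inf), m) for m in members
                ]
                scored.sort()
                assignment = (scored[0][1], 3)
        elif gene_rbh is not None:
            assignment = (gene_rbh, 4)
        elif gene in best_hit.index:
            assignment = (best_hit.loc[gene, "reference_gene"], 5)
        if assignment is None:
            rows.append((gene, None, 0, og, False, None))
        else:
            target, rule = assignment
            rows.append(
                (
                    gene,
                    target,
                    rule,
                    og,
                    target == gene_rbh,
                    float(ev.get((gene, target), np.nan)),
                )
            )
    return pd.DataFrame(
        rows, columns=["gene", "reference_id", "rule", "orthogroup", "rbh", "evalue"]
    )


def overlap_test(
    candidates_a: set[str], candidates_b: set[str], universe: set[str]
) -> tuple[int, float]:
    """Two-sided Fisher exact test for candidate-list overlap within a universe.

    The 2x2 table counts genes in both lists, in each alone, and in neither;
    two-sidedness follows the exact probability-mass rule (all tables with
    probability <= the observed one).
    """
    a, b, universe = set(candidates_a), set(candidates_b), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not a <= universe or not b <= universe:
        raise ValueError("candidate sets must be subsets of the universe")
    both = len(a & b)
    table = [
        [both, len(a - b)],
        [len(b - a), len(universe) - len(a | b)],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    return both, float(p)


def _term_depths(dag: nx.DiGraph) -> dict[str, int]:
    """Longest path (in edges) from each term to a root, edges child -> parent."""
    depths: dict[str, int] = {}
    for node in reversed(list(nx.topological_sort(dag))):
        parents = list(dag.successors(node))
        depths[node] = 1 + max((depths[p] for p in parents), default=-1)
    return depths


def go_enrichment_elim(
    candidates: set[str],
    universe: set[str],
    annotations: dict[str, set[str]],
    dag: nx.DiGraph,
    min_node_size: int = 150,
    elim_cutoff: float = 0.01,
    method: str = "elim",
) -> pd.DataFrame:
    """Topology-aware one-sided Fisher GO enrichment (elim algorithm).

    ``annotations`` maps term -> annotated genes and must be closed under DAG
    ancestry (edges point child -> parent).  Terms annotated to fewer than
    ``min_node_size`` universe genes are skipped.  Terms are tested
    most-specific-first (decreasing depth); when a term's p-value falls below
    ``elim_cutoff`` its candidate genes are eliminated from all ancestor
    terms' tallies before those are tested.  ``method="classic"`` (or
    ``elim_cutoff=0``) disables elimination.

    Returns term, annotated, candidate, expected, p, fold (observed/expected),
    ordered by increasing p.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("GO DAG contains a cycle")
    if method not in ("elim", "classic"):
        raise ValueError("method must be 'elim' or 'classic'")
    universe = set(universe)
    candidates = set(candidates) & universe
    n_universe = len(universe)
    n_cand = len(candidates)

    depths = _term_depths(dag)
    order = sorted(dag.nodes, key=lambda t: (-depths[t], t))
    eliminated: dict[str, set[str]] = {t: set() for t in dag.nodes}
    rows = []
    for term in order:
        ann = annotations.get(term, set()) & universe
        if len(ann) < min_node_size:
            continue
        current = ann - eliminated[term]
        k = len(current & candidates)
        n_term = len(current)
        p = float(hypergeom.sf(k - 1, n_universe, n_cand, n_term)) if n_term else 1.0
        expected = n_cand * n_term / n_universe if n_universe else 0.0
        fold = k / expected if expected > 0 else 0.0
        rows.append((term, len(ann), k, expected, p, fold))
        if method == "elim" and elim_cutoff > 0 and p < elim_cutoff:
            removed = current & candidates
            for anc in nx.descendants(dag, term):  # ancestors along child->parent
                eliminated[anc] |= removed
    out = pd.DataFrame(
        rows, columns=["term", "annotated", "candidate", "expected", "p", "fold"]
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def shared_enrichment(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    universe_terms: set[str],
    alpha: float = 0.05,
) -> tuple[list[str], float]:
    """Terms significant in both species, and a Fisher test for excess sharing.

    The sharing test treats the tested-term universe as the sampling frame and
    asks whether the two species' significant term sets overlap more than
    chance would allow.
    """
    sig_a = set(results_a.loc[results_a["p"] < alpha, "term"]) & set(universe_terms)
    sig_b = set(results_b.loc[results_b["p"] < alpha, "term"]) & set(universe_terms)
    shared = sorted(sig_a & sig_b)
    _, p = overlap_test(sig_a, sig_b, set(universe_terms))
    return shared, p


def interaction_overlap_perm(
    candidates_a: list[str],
    candidates_b: list[str],
    edges: pd.DataFrame,
    universe: list[str],
    min_confidence: int = 400,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test for interaction-network overlap between candidate lists.

    Observed statistics: the number of A-candidates with >= 1 direct ("first
    shell") edge to a B-candidate, and the number with > 1.  The null draws
    ``n_perm`` A-sized gene sets uniformly from the universe; the p-value uses
    the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm), so its floor
    at n_perm = 1000 is 1/1001.  Only edges with confidence >= min_confidence
    count.
    """
    universe = list(dict.fromkeys(universe))
    idx = {g: i for i, g in enumerate(universe)}
    if len(universe) < len(set(candidates_a)):
        raise ValueError("universe smaller than candidate list A")
    set_a = [g for g in dict.fromkeys(candidates_a) if g in idx]
    set_b = {g for g in candidates_b if g in idx}

    kept = edges[edges["score"] >= min_confidence]
    n_b_neighbors = np.zeros(len(universe), dtype=np.int64)
    counts: dict[int, set[str]] = {}
    for ga, gb in zip(kept["geneA"], kept["geneB"]):
        for x, y in ((ga, gb), (gb, ga)):
            if x in idx and y in set_b and x != y:
                counts.setdefault(idx[x], set()).add(y)
    for i, nbrs in counts.items():
        n_b_neighbors[i] = len(nbrs)

    ind1 = (n_b_neighbors >= 1).astype(np.int64)
    ind2 = (n_b_neighbors > 1).astype(np.int64)
    a_idx = np.array([idx[g] for g in set_a], dtype=np.int64)
    obs1 = int(ind1[a_idx].sum())
    obs2 = int(ind2[a_idx].sum())

    rng = np.random.default_rng(seed)
    null1 = np.empty(n_perm, dtype=np.int64)
    null2 = np.empty(n_perm, dtype=np.int64)
    n = len(universe)
    k = len(set_a)
    for t in range(n_perm):
        pick = rng.choice(n, size=k, replace=False)
        null1[t] = ind1[pick].sum()
        null2[t] = ind2[pick].sum()
    return {
        "observed_ge1": obs1,
        "observed_gt1": obs2,
        "p_ge1": float((1 + (null1 >= obs1).sum()) / (1 + n_perm)),
        "p_gt1": float((1 + (null2 >= obs2).sum()) / (1 + n_perm)),
        "n_perm": n_perm,
        "n_candidates_a": len(set_a),
        "n_candidates_b": len(set_b),
    }
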