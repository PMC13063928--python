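"""Variant-to-gene assignment and ontology term selection.

A variant is assigned to a gene if it lies in the gene body (start..end,
1-based inclusive), within the 500 bp flanks covering promoter and
termination regions, or inside an enhancer interval linked to that gene
(enhancers may sit anywhere on the chromosome).  A variant may map to
several genes — e.g. a variant inside one gene's body and another gene's
enhancer belongs to both marker sets.  Overlapping or book-ended
enhancers of the same gene are fused before assignment.

Ontology terms are organised by level: depth 1 is the root, and a term's
depth is the length of its shortest child -> ... -> root path, matching
the conventional level numbering of the Human Phenotype Ontology.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .panel import CohortPanel

__all__ = ["GeneModel", "EnhancerInterval", "GeneAssignment",
           "fuse_enhancers", "assign_variants", "term_depths", "select_terms"]

#: assignment reasons in priority order
REASONS = ("body", "flank", "enhancer")


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    start: int          # 1-based inclusive
    end: int
    strand: str = "unknown"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start > end")


@dataclass(frozen=True)
class EnhancerInterval:
    chrom: str
    start: int          # 1-based inclusive
    end: int
    gene: str
    source: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("enhancer start > end")
        if not self.gene:
            raise ValueError("enhancer must name a linked gene")


@dataclass
class GeneAssignment:
    """variant id -> list of (gene symbol, reason)."""
    mapping: dict

    def genes_of(self, variant_id: str) -> list:
        return [g for g, _ in self.mapping.get(variant_id, [])]

    def variants_of(self, gene: str) -> list:
        return [v for v, pairs in self.mapping.items()
                if any(g == gene for g, _ in pairs)]

    def gene_sets(self) -> dict:
        """gene symbol -> sorted list of variant ids."""
        out: dict = {}
        for v, pairs in self.mapping.items():
            for g, _ in pairs:
                out.setdefault(g, set()).add(v)
        return {g: sorted(vs) for g, vs in out.items()}

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.mapping.values())


def fuse_enhancers(enhancers: list) -> list:
    """Merge overlapping or book-ended enhancer intervals per linked gene.

    Sources of merged intervals are concatenated with ';'.  Output sorted
    by (chrom, start).
    """
    by_gene: dict = {}
    for e in enhancers:
        by_gene.setdefault((e.gene, e.chrom), []).append(e)
    fused = []
    for (gene, chrom), ivs in by_gene.items():
        ivs.sort(key=lambda e: (e.start, e.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_sources = [ivs[0].source] if ivs[0].source else []
        for e in ivs[1:]:
            if e.start <= cur_end + 1:          # overlap or book-ended
                cur_end = max(cur_end, e.end)
                if e.source:
                    cur_sources.append(e.source)
            else:
                fused.append(EnhancerInterval(chrom, cur_start, cur_end,
                                              gene, ";".join(cur_sources)))
                cur_start, cur_end = e.start, e.end
                cur_sources = [e.source] if e.source else []
        fused.append(EnhancerInterval(chrom, cur_start, cur_end, gene,
                                      ";".join(cur_sources)))
    fused.sort(key=lambda e: (e.chrom, e.start, e.end, e.gene))
    return fused


def assign_variants(panel: CohortPanel, genes: list, enhancers: list,
                    flank_bp: int = 500) -> GeneAssignment:
    """Assign every panel variant to genes by body, flank or enhancer.

    Flank boundaries are inclusive at exactly ``flank_bp``.  When several
    reasons hold for the same (variant, gene) pair, the strongest
    (body > flank > enhancer) is reported.  Enhancers must already be
    fused.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    genes_by_chrom: dict = {}
    for g in genes:
        genes_by_chrom.setdefault(str(g.chrom), []).append(g)
    enh_by_chrom: dict = {}
    for e in enhancers:
        enh_by_chrom.setdefault(str(e.chrom), []).append(e)

    mapping: dict = {}
    v = panel.variants
    for vid, chrom, pos in zip(v["id"], v["chrom"].astype(str), v["pos"]):
        hits: dict = {}
        for g in genes_by_chrom.get(chrom, []):
            if g.start <= pos <= g.end:
                hits[g.symbol] = "body"
            elif (g.start - flank_bp <= pos < g.start
                  or g.end < pos <= g.end + flank_bp):
                hits.setdefault(g.symbol, "flank")
        for e in enh_by_chrom.get(chrom, []):
            if e.start <= pos <= e.end:
                hits.setdefault(e.gene, "enhancer")
        if hits:
            mapping[vid] = sorted(hits.items())
    return GeneAssignment(mapping=mapping)


def term_depths(edges: list, root: str) -> tuple[dict, list]:
    """Shortest-path depth of every ontology term, root at depth 1.

    ``edges`` are (child, parent) pairs forming a rooted DAG.  Returns
    (depths, unreachable) where ``unreachable`` lists terms with no path
    to the root.  A cycle anywhere in the graph is fatal.
    """
    children: dict = {}
    nodes = {root}
    indeg: dict = {}
    parents: dict = {}
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
        parents.setdefault(child, []).append(parent)
        nodes.update((child, parent))
    # cycle check by Kahn's algorithm on child->parent direction
    indeg = {n: 0 for n in nodes}
    for child, parent in edges:
        indeg[parent] += 1
    queue = deque(n for n in nodes if indeg[n] == 0)
    seen = 0
    while queue:
        n = queue.popleft()
        seen += 1
        for p in parents.get(n, []):
            indeg[p] -= 1
            if indeg[p] == 0:
                queue.append(p)
    if seen != len(nodes):
        raise ValueError("cycle detected in ontology edges")

    depths = {root: 1}
    queue = deque([root])
    while queue:
        n = queue.popleft()
        for c in children.get(n, []):
            if c not in depths:          # BFS: first visit = shortest path
                depths[c] = depths[n] + 1
                queue.append(c)
    unreachable = sorted(nodes - set(depths))
    return depths, unreachable


def select_terms(depths: dict, lo: int = 2, hi: int = 6) -> list:
    """Terms whose level satisfies lo <= depth <= hi, sorted by (depth, id)."""
    if lo > hi:
        raise ValueError("lo > hi")
    return sorted((t for t, d in depths.items() if lo <= d <= hi),
                  key=lambda t: (depths[t], t))
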