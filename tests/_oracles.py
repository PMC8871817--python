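"""Independent reference implementations used only by the tests.

These deliberately avoid the package's code paths: the local-alignment
oracle is a plain-Python Gotoh dynamic program over lists, tree splits
are recovered by deleting edges of a networkx graph and reading off
connected components, and tiling counts come from brute-force start
enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, 2.0, 1.0

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


def oracle_sw(a: str, b: str):
    """Best local alignment (score, n_columns, n_matches) with the
    toolkit's scoring and tie-break conventions, forward strand only.

    Tie-breaks: within a cell prefer diagonal, then vertical gap, then
    horizontal gap (strict inequality needed to displace); the best
    cell is the first maximal-score cell in row-major order; E/F prefer
    opening a fresh gap over extending on ties.
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop 1 diag 2 up 3 left
    e_open = [[False] * (m + 1) for _ in range(n + 1)]
    f_open = [[False] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo, ee = H[i][j - 1] - GAP_OPEN, E[i][j - 1] - GAP_EXTEND
            if eo >= ee:
                E[i][j], e_open[i][j] = eo, True
            else:
                E[i][j] = ee
            fo, fe = H[i - 1][j] - GAP_OPEN, F[i - 1][j] - GAP_EXTEND
            if fo >= fe:
                F[i][j], f_open[i][j] = fo, True
            else:
                F[i][j] = fe
            match = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            diag = H[i - 1][j - 1] + (MATCH if match else MISMATCH)
            h, p = 0.0, 0
            if diag > 0.0:
                h, p = diag, 1
            if F[i][j] > h:
                h, p = F[i][j], 2
            if E[i][j] > h:
                h, p = E[i][j], 3
            H[i][j], ptr[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return 0.0, 0, 0
    i, j, state = bi, bj, "H"
    ncols = nmatch = 0
    while i > 0 and j > 0:
        if state == "H":
            p = ptr[i][j]
            if p == 0:
                break
            if p == 1:
                ncols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT":
                    nmatch += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            ncols += 1
            if e_open[i][j]:
                state = "H"
            j -= 1
        else:
            ncols += 1
            if f_open[i][j]:
                state = "H"
            i -= 1
    return best, ncols, nmatch


def oracle_sw_both_strands(a: str, b: str):
    """(score, ncols, nmatch, strand); forward preferred on score ties."""
    fwd = oracle_sw(a, b)
    rev = oracle_sw(oracle_revcomp(a), b)
    if rev[0] > fwd[0]:
        return (*rev, "-")
    return (*fwd, "+")


def oracle_meets(a: str, b: str, min_identity: float, min_overlap: int) -> bool:
    score, ncols, nmatch = oracle_sw_both_strands(a, b)[:3]
    return ncols >= min_overlap and ncols > 0 and nmatch / ncols >= min_identity


# ---------------------------------------------------------------------------
# trees


def newick_to_graph(newick: str) -> tuple[nx.Graph, list[str]]:
    """Parse via dendropy, rebuild as an undirected graph."""
    import dendropy

    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=dendropy.TaxonNamespace(),
        suppress_internal_node_taxa=True,
    )
    g = nx.Graph()
    leaves = []
    counter = itertools.count()
    names = {}

    def node_name(node):
        if node not in names:
            if node.is_leaf():
                names[node] = node.taxon.label
            else:
                names[node] = f"__internal_{next(counter)}"
        return names[node]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(node_name(edge.tail_node), node_name(edge.head_node))
    for leaf in tree.leaf_node_iter():
        leaves.append(leaf.taxon.label)
    # suppress the artificial degree-2 root of rooted newick strings
    for node in [n for n in g.nodes if str(n).startswith("__") and g.degree[n] == 2]:
        u, v = list(g.neighbors(node))
        g.remove_node(node)
        g.add_edge(u, v)
    return g, leaves


def oracle_splits(newick: str) -> set[frozenset]:
    """Informative splits by edge deletion + connected components."""
    g, leaves = newick_to_graph(newick)
    taxa = frozenset(leaves)
    out = set()
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(x for x in comp if not str(x).startswith("__"))
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(frozenset({side, taxa - side}))
    return out


def oracle_classify(
    species_split: frozenset, gene_newick: str
) -> tuple[str, frozenset | None]:
    """Classify one gene tree against one species split (a frozenset of
    two frozen taxon sets) by exhaustive set arithmetic."""
    g, leaves = newick_to_graph(gene_newick)
    gene_taxa = frozenset(leaves)
    s1, s2 = tuple(species_split)
    shared = (s1 | s2) & gene_taxa
    r1, r2 = s1 & shared, s2 & shared
    if len(r1) < 2 or len(r2) < 2:
        return "uninformative", None
    restricted = frozenset({r1, r2})
    observed = set()
    for split in oracle_splits(gene_newick):
        a, b = tuple(split)
        ra, rb = a & shared, b & shared
        if len(ra) >= 2 and len(rb) >= 2:
            observed.add(frozenset({ra, rb}))
    if restricted in observed:
        return "concordant", None
    conflicting = []
    for split in observed:
        a, b = tuple(split)
        if (r1 & a) and (r1 & b) and (r2 & a) and (r2 & b):
            conflicting.append(split)
    if conflicting:
        key = lambda s: tuple(sorted(tuple(sorted(side)) for side in s))
        return "conflict", min(conflicting, key=key)
    return "uninformative", None


def random_binary_newick(rng, taxa: list[str]) -> str:
    """Random binary tree by sequential joining."""
    nodes = list(taxa)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
        rng.shuffle(nodes)
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# tiling


def brute_force_tile_count(L: int, probe_length: int, step: int, end_anchor: bool) -> int:
    """Enumerate candidate start positions directly."""
    if L < probe_length:
        return 0
    regular = [s for s in range(0, L) if s % step == 0 and s + probe_length <= L]
    starts = set(regular)
    if end_anchor and regular and regular[-1] + probe_length < L:
        starts.add(L - probe_length)
    return len(starts)
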