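"""Independent brute-force oracle for 5-taxon neighbour-joining checks.

Enumerates all 15 unrooted binary 5-taxon topologies, builds additive
path-distance matrices from explicit branch lengths, and compares trees by
their nontrivial bipartitions — no NJ code involved.
"""

import pandas as pd

TAXA = ["t0", "t1", "t2", "t3", "t4"]


def five_taxon_topologies():
    """All 15 unrooted binary shapes: a middle leaf plus two cherries
    partitioning the remaining four taxa."""
    out = []
    seen = set()
    for middle in TAXA:
        rest = [t for t in TAXA if t != middle]
        a = rest[0]
        for partner in rest[1:]:
            cherry1 = frozenset({a, partner})
            cherry2 = frozenset(set(rest) - cherry1)
            key = frozenset({cherry1, cherry2, frozenset({middle})})
            if key not in seen:
                seen.add(key)
                out.append((cherry1, cherry2))
    return out


def additive_matrix(cherry1, cherry2, lengths):
    """Path distances of the tree (cherry1)-u-w(-middle), (cherry2)-v-w,
    with the 7 branch lengths given as (la, lb, lc, ld, lmiddle, luw, lvw)."""
    (a, b), (c, d) = sorted(cherry1), sorted(cherry2)
    (middle,) = set(TAXA) - cherry1 - cherry2
    la, lb, lc, ld, lm, luw, lvw = lengths
    path = {
        (a, b): la + lb,
        (c, d): lc + ld,
        (a, c): la + luw + lvw + lc,
        (a, d): la + luw + lvw + ld,
        (b, c): lb + luw + lvw + lc,
        (b, d): lb + luw + lvw + ld,
        (a, middle): la + luw + lm,
        (b, middle): lb + luw + lm,
        (c, middle): lc + lvw + lm,
        (d, middle): ld + lvw + lm,
    }
    m = pd.DataFrame(0.0, index=TAXA, columns=TAXA)
    for (x, y), v in path.items():
        m.loc[x, y] = m.loc[y, x] = v
    return m


def tree_splits(tree, taxa=TAXA):
    """Nontrivial bipartitions of an unrooted skbio tree, each normalized
    to the side not containing the first taxon."""
    full = set(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 2 <= len(side) <= len(full) - 2:
            if taxa[0] in side:
                side = full - side
            splits.add(frozenset(side))
    return splits


def true_splits(cherry1, cherry2, taxa=TAXA):
    full = set(taxa)
    out = set()
    for cherry in (cherry1, cherry2):
        side = set(cherry)
        if taxa[0] in side:
            side = full - side
        out.add(frozenset(side))
    return out
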