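"""Statistical-parsimony haplotype networks with locality annotations.

Haplotypes are connected in order of increasing mutational distance up to
a parsimony connection limit; multi-step connections pass through
inferred unobserved intermediates (the "missing haplotypes" drawn as
black dots in published networks), and alternative equal-length
connections are retained as reticulations.  The construction is
deterministic: ties at equal distance are resolved toward the
higher-frequency pair, then lexicographically by node id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diversity import HaplotypeTable, collapse_haplotypes, jukes_cantor


def parsimony_limit(seq_len: int, alpha: float = 0.95) -> int:
    """Largest number of steps with non-homoplasy probability above alpha.

    For j observed differences over ``seq_len`` sites, the per-site
    Jukes-Cantor divergence d(j) implies L*d(j) - j expected superimposed
    (hidden) changes; treating those as Poisson, the probability that the
    j-step connection involves no homoplasy is exp(-(L*d(j) - j)).  The
    limit is the largest j keeping that probability at or above ``alpha``
    (at least 1: single-step connections are always accepted).
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if not 0.5 < alpha < 1.0:
        raise ValueError("alpha must lie in (0.5, 1)")
    j = 0
    while True:
        nxt = j + 1
        p = nxt / seq_len
        if p >= 0.75:
            break
        hidden = seq_len * jukes_cantor(p) - nxt
        if math.exp(-hidden) < alpha:
            break
        j = nxt
    return max(j, 1)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _locality_string(counts: dict[str, int]) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(counts.items()))


def build_network(table: HaplotypeTable, limit: int | None = None,
                  alpha: float = 0.95) -> nx.Graph:
    """TCS-style agglomerative network over a collapsed haplotype table.

    Observed haplotypes become nodes H1..Hk (input order).  Pairs are
    examined in order of increasing Hamming distance; a pair is connected
    when its distance is within the parsimony ``limit`` and the two nodes
    were in different components at the start of that distance class (so
    equal-distance alternative connections create reticulations).  A
    d-step connection inserts d-1 inferred intermediates with count 0.
    """
    haps = table.haplotypes
    if not haps:
        raise ValueError("empty haplotype table")
    if limit is None:
        limit = parsimony_limit(len(haps[0]), alpha)
    width = len(str(len(haps)))
    ids = [f"H{i + 1:0{width}d}" for i in range(len(haps))]
    g = nx.Graph()
    for hid, seq, count, locs in zip(ids, haps, table.counts,
                                     table.locality_counts):
        g.add_node(hid, haplotype=seq, count=count, inferred=False,
                   localities=_locality_string(locs))

    pairs = []
    for i in range(len(haps) - 1):
        for j in range(i + 1, len(haps)):
            d = _hamming(haps[i], haps[j])
            if 0 < d <= limit:
                pairs.append((d, -(table.counts[i] + table.counts[j]),
                              ids[i], ids[j], i, j))
    pairs.sort()

    at = 0
    inferred_n = 0
    while at < len(pairs):
        d = pairs[at][0]
        # snapshot components at the start of this distance class
        comp = {node: k for k, cc in enumerate(nx.connected_components(g))
                for node in cc}
        while at < len(pairs) and pairs[at][0] == d:
            _, _, u, v, i, j = pairs[at]
            at += 1
            if comp[u] == comp[v]:
                continue
            # orient the path from the higher-frequency end (ties: lower id)
            if (-table.counts[i], u) <= (-table.counts[j], v):
                src, dst, s_seq, d_seq = u, v, haps[i], haps[j]
            else:
                src, dst, s_seq, d_seq = v, u, haps[j], haps[i]
            prev = src
            cur = list(s_seq)
            for col in [c for c in range(len(s_seq)) if s_seq[c] != d_seq[c]][:-1]:
                cur[col] = d_seq[col]
                inferred_n += 1
                mid = f"X{inferred_n}"
                g.add_node(mid, haplotype="".join(cur), count=0,
                           inferred=True, localities="")
                g.add_edge(prev, mid, step=1)
                prev = mid
            g.add_edge(prev, dst, step=1)
    return g


def network_from_population(pop, limit: int | None = None,
                            alpha: float = 0.95) -> nx.Graph:
    table = collapse_haplotypes(pop)
    if limit is None:
        limit = parsimony_limit(len(table.haplotypes[0]), alpha)
    return build_network(table, limit=limit)


# ---------------------------------------------------------------------------
# Locality sharing


@dataclass
class SharingReport:
    shared: list[dict]          # haplotypes seen at >= 2 localities
    chi2: float | None = None
    p_value: float | None = None
    n_permutations: int = 0


def locality_sharing(table: HaplotypeTable, reps: int = 1000,
                     seed: int | None = None) -> SharingReport:
    """Haplotypes shared across localities plus a permutation association test.

    The statistic is the chi-square of the haplotype x locality contingency
    table; the null redistributes locality labels over sequences.
    """
    shared = [
        {"haplotype_index": i, "counts": dict(locs)}
        for i, locs in enumerate(table.locality_counts)
        if len(locs) >= 2
    ]
    localities = sorted({loc for lc in table.locality_counts for loc in lc})
    if len(localities) < 2:
        return SharingReport(shared=[])

    hap_of, loc_of = [], []
    for i, locs in enumerate(table.locality_counts):
        for loc, c in locs.items():
            hap_of.extend([i] * c)
            loc_of.extend([localities.index(loc)] * c)
    hap_of = np.array(hap_of)
    loc_of = np.array(loc_of)

    def chi2(h, l) -> float:
        obs = np.zeros((table.n_hap, len(localities)))
        np.add.at(obs, (h, l), 1.0)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            cells = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        return float(cells.sum())

    observed = chi2(hap_of, loc_of)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        if chi2(hap_of, rng.permutation(loc_of)) >= observed:
            hits += 1
    return SharingReport(
        shared=shared, chi2=observed,
        p_value=(hits + 1) / (reps + 1), n_permutations=reps,
    )


# ---------------------------------------------------------------------------
# Export


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    rows = [
        {
            "haplotype": f"H{i + 1}", "count": table.counts[i],
            "localities": _locality_string(table.locality_counts[i]),
            "members": ",".join(table.members[i]),
            "sequence": table.haplotypes[i],
        }
        for i in range(table.n_hap)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dot(g: nx.Graph, path: str | Path) -> None:
    """Minimal DOT export (observed nodes labelled, inferred as points)."""
    lines = ["graph haplonet {"]
    for node, data in g.nodes(data=True):
        if data.get("inferred"):
            lines.append(f'  "{node}" [shape=point];')
        else:
            lines.append(f'  "{node}" [label="{node} ({data["count"]})"];')
    for u, v in g.edges():
        lines.append(f'  "{u}" -- "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
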