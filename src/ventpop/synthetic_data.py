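"""Coalescent generator of mtCOI-like population samples.

Downstream modules are exercised on synthetic samples that mimic the
statistical structure of vent-copepod mtCOI data: small haploid samples
(4-83 sequences) of ~600-675 bp coding sequence with high haplotype
diversity, nucleotide diversity of order 0.003-0.015, an excess of
singleton variants under population growth, and strong purifying
selection (pi_a/pi_s << 1).

The machinery is a neutral Kingman coalescent (optionally with
exponential growth, which produces star-like genealogies and the
negative-Tajima's-D regime) with a finite-sites Jukes-Cantor mutation
overlay.  Purifying selection is emulated by acceptance sampling: a
candidate mutation that would change the encoded amino acid is kept with
probability ``omega``; mutations creating stop codons can be suppressed
entirely so that every simulated alignment passes the ORF screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codons
from .io_align import CodonAlignment, SequenceRecord

# ---------------------------------------------------------------------------
# Genealogies


@dataclass
class Genealogy:
    """Binary coalescent tree: nodes 0..n-1 are leaves, 2n-2 is the root.

    Branch lengths are in coalescent units (2N generations for a haploid
    effective size of 2N gene copies; pairwise coalescence rate 1).
    """

    n: int
    parent: np.ndarray  # (2n-1,), -1 for the root
    time: np.ndarray    # (2n-1,), node ages; leaves at 0

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        bl = np.zeros(2 * self.n - 1)
        idx = np.arange(2 * self.n - 2)
        bl[idx] = self.time[self.parent[idx]] - self.time[idx]
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def external_fraction(self) -> float:
        """Fraction of total tree length in branches above leaves."""
        bl = self.branch_lengths()
        return float(bl[: self.n].sum() / bl.sum())

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for v in range(2 * self.n - 2):
            kids[self.parent[v]].append(v)
        return kids

    def leaf_sets(self) -> list[np.ndarray]:
        """Boolean leaf-membership mask below each node."""
        masks = [np.zeros(self.n, dtype=bool) for _ in range(2 * self.n - 1)]
        for leaf in range(self.n):
            masks[leaf][leaf] = True
        # accumulate bottom-up: nodes are created in increasing time order,
        # so child indices are always smaller than their parent's index
        for v in range(2 * self.n - 2):
            masks[self.parent[v]] |= masks[v]
        return masks


def simulate_genealogy(n: int, growth: float = 0.0,
                       seed: int | np.random.Generator | None = None) -> Genealogy:
    """Sample a neutral coalescent genealogy for ``n`` haploid sequences.

    ``growth`` is the exponential growth rate in coalescent units: looking
    back in time the pairwise coalescence hazard scales as exp(growth * t),
    so large values compress internal branches into a star-like tree.
    Under growth 0, E[T_MRCA] = 2(1 - 1/n).
    """
    if n < 2:
        raise ValueError("need at least 2 sequences to coalesce")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0
        e = rng.exponential()
        if growth == 0.0:
            t += e / rate
        else:
            # inverse of the integrated hazard rate * exp(growth t)
            t += np.log1p(growth * e * np.exp(-growth * t) / rate) / growth
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n=n, parent=parent, time=time)


def simulate_infinite_sites(n: int, theta: float,
                            seed: int | np.random.Generator | None = None,
                            growth: float = 0.0) -> np.ndarray:
    """0/1 haplotype matrix (n x S) under the infinite-sites coalescent.

    ``theta`` is the population-scaled mutation rate per locus; each branch
    receives Poisson(theta/2 * length) mutations, each its own column.
    Used for the coalescent null distributions of the demography tests.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tree = simulate_genealogy(n, growth=growth, seed=rng)
    bl = tree.branch_lengths()[: 2 * n - 2]
    counts = rng.poisson(theta / 2.0 * bl)
    if counts.sum() == 0:
        return np.zeros((n, 0), dtype=np.int8)
    masks = tree.leaf_sets()
    cols = []
    for node, c in enumerate(counts):
        cols.extend([masks[node]] * int(c))
    return np.array(cols, dtype=np.int8).T


# ---------------------------------------------------------------------------
# Finite-sites codon-constrained mutation overlay


@dataclass
class SynthConfig:
    """Parameters of one synthetic population sample."""

    n: int = 20
    L: int = 657
    theta: float = 5.0          # per-locus, coalescent scaling
    growth: float = 0.0
    omega: float = 1.0          # acceptance probability of amino-acid changes
    suppress_stops: bool = True
    seed: int = 0
    genetic_code: int = codons.INVERTEBRATE_MITO_ID
    species: str = "Synthopontius exemplaris"
    region: str = "SIM"
    site: str = "sim-site"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must lie in (0, 1]")
        if (self.omega < 1.0 or self.suppress_stops) and self.L % 3:
            raise ValueError("L must be a multiple of 3 under codon constraints")


def _random_coding_sequence(n_codons: int, rng: np.random.Generator,
                            code_id: int) -> list[str]:
    sense = codons.sense_codons(code_id)
    return [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]


def drop_mutations(tree: Genealogy, config: SynthConfig) -> CodonAlignment:
    """Overlay Jukes-Cantor mutations on a genealogy, returning sequences.

    Mutations arrive as Poisson(theta/2 * branch length) per branch and hit
    uniform sites; a candidate that changes the amino acid (under the
    configured code, frame 0) is retained with probability ``omega``, a
    synonymous one always, and one creating a stop codon never when
    ``suppress_stops`` is on.
    """
    rng = np.random.default_rng(config.seed)
    code_id = config.genetic_code
    codon_mode = config.L % 3 == 0
    if codon_mode:
        root = list("".join(_random_coding_sequence(config.L // 3, rng, code_id)))
    else:
        root = [("ACGT")[i] for i in rng.integers(0, 4, size=config.L)]

    kids = tree.children()
    bl = tree.branch_lengths()
    seqs: dict[int, list[str]] = {}

    stack = [(tree.root, root)]
    while stack:
        node, seq = stack.pop()
        if node < tree.n:
            seqs[node] = seq
            continue
        for child in kids[node]:
            child_seq = seq.copy()
            for _ in range(rng.poisson(config.theta / 2.0 * bl[child])):
                site = int(rng.integers(config.L))
                old = child_seq[site]
                new = "ACGT".replace(old, "")[rng.integers(3)]
                if codon_mode:
                    c0 = 3 * (site // 3)
                    codon = "".join(child_seq[c0 : c0 + 3])
                    pos = site - c0
                    mutant = codon[:pos] + new + codon[pos + 1 :]
                    if config.suppress_stops and codons.is_stop(mutant, code_id):
                        continue
                    if not codons.is_synonymous(codon, pos, new, code_id):
                        if rng.random() >= config.omega:
                            continue
                child_seq[site] = new
            stack.append((child, child_seq))

    width = len(str(tree.n))
    records = [
        SequenceRecord(
            id=f"s{i + 1:0{width}d}",
            seq="".join(seqs[i]),
            species=config.species,
            region=config.region,
            site=config.site,
        )
        for i in range(tree.n)
    ]
    return CodonAlignment(records, frame_offset=0, genetic_code=code_id)


def simulate_alignment(config: SynthConfig) -> CodonAlignment:
    """Genealogy plus mutation overlay in one call (single seeded stream)."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_genealogy(config.n, growth=config.growth, seed=rng)
    # drop_mutations reseeds from config.seed; derive a distinct child seed
    sub = SynthConfig(**{**config.__dict__,
                         "seed": int(rng.integers(2**31 - 1))})
    return drop_mutations(tree, sub)


# ---------------------------------------------------------------------------
# Hand-constructed fixtures with enumerated expected statistics


def _aln(seqs: dict[str, str], sites: dict[str, str] | None = None,
         species: str = "fixture") -> CodonAlignment:
    records = [
        SequenceRecord(id=k, seq=v, species=species,
                       site=(sites or {}).get(k, "fix-site"))
        for k, v in seqs.items()
    ]
    return CodonAlignment(records)


def make_fixture(name: str) -> tuple[CodonAlignment, dict[str, float]]:
    """Tiny alignments whose statistics were enumerated by hand.

    "tajima_toy": 4 sequences, 10 sites, two singleton variant columns.
        All 6 pairwise difference counts: 2,1,1,1,1,0 -> k = 1.0; S = 2;
        haplotype counts {2,1,1} -> Hd = (4/3)(1 - 6/16) = 5/6;
        Tajima's constants at n=4 give D = (1 - 2/a1)/sqrt(e1*2 + e2*2)
        = -0.7099; singleton loads U = (1,1,0,0) -> R2 = 0.25.
    "fst_fixed": two demes of 5, each fixed for a private haplotype
        (theta_WC = 1).
    "mono": 5 identical sequences (Hd = pi = S = 0).
    """
    base = "ACGTACGTAC"
    if name == "tajima_toy":
        s1 = base[:2] + "T" + base[3:]   # singleton at column 3 (1-based)
        s2 = base[:5] + "A" + base[6:]   # singleton at column 6
        aln = _aln({"a": s1, "b": s2, "c": base, "d": base})
        expected = {
            "n": 4, "S": 2, "k": 1.0, "n_hap": 3,
            "Hd": 5.0 / 6.0, "pi": 0.10,
            "tajima_d": -0.70990,
            "r2": 0.25,
        }
        return aln, expected
    if name == "fst_fixed":
        hap_a, hap_b = "AAACCCGGG", "TTTCCCGGG"
        seqs = {f"p1_{i}": hap_a for i in range(1, 6)}
        seqs.update({f"p2_{i}": hap_b for i in range(1, 6)})
        sites = {k: ("SiteA" if k.startswith("p1") else "SiteB") for k in seqs}
        aln = _aln(seqs, sites)
        expected = {"n": 10, "fst": 1.0, "n_hap": 2}
        return aln, expected
    if name == "mono":
        aln = _aln({f"m{i}": "ACGACGACG" for i in range(1, 6)})
        expected = {"n": 5, "S": 0, "k": 0.0, "n_hap": 1, "Hd": 0.0, "pi": 0.0}
        return aln, expected
    raise ValueError(f"unknown fixture: {name!r}")
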