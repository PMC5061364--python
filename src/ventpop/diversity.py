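"""Per-population diversity statistics and p-distance summaries.

Implements the classical single-marker diversity battery for haploid
sequence samples: haplotype counts and Nei's unbiased haplotype
diversity, segregating sites, Jukes-Cantor-corrected nucleotide
diversity (overall and split into nonsynonymous/synonymous components by
the Nei-Gojobori pathway method), and within/between-group uncorrected
p-distance summaries with a site-resampling bootstrap standard error.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codons
from .io_align import PopulationSample


def _as_sample(pop) -> tuple[list[str], PopulationSample | None]:
    """Accept a PopulationSample or a bare list of equal-length strings."""
    if isinstance(pop, PopulationSample):
        return pop.masked_seqs(), pop
    seqs = list(pop)
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences have unequal lengths")
    return seqs, None


def seq_matrix(seqs: list[str]) -> np.ndarray:
    """(n, L) uint8 view of a list of equal-length sequences."""
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def pairwise_differences(seqs: list[str]) -> np.ndarray:
    """Condensed vector of pairwise difference counts (i<j order)."""
    m = seq_matrix(seqs)
    n = len(seqs)
    out = []
    for i in range(n - 1):
        out.append((m[i] != m[i + 1 :]).sum(axis=1))
    return np.concatenate(out) if out else np.zeros(0, dtype=int)


# ---------------------------------------------------------------------------
# Haplotypes


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with total and per-locality counts."""

    haplotypes: list[str]                 # distinct masked sequences
    counts: list[int]                     # total count per haplotype
    locality_counts: list[dict[str, int]]  # per-locality breakdown
    members: list[list[str]]              # sequence ids per haplotype

    @property
    def n_hap(self) -> int:
        return len(self.haplotypes)

    @property
    def n_seq(self) -> int:
        return sum(self.counts)


def collapse_haplotypes(pop) -> HaplotypeTable:
    """Group identical masked sequences, keeping locality frequencies."""
    seqs, sample = _as_sample(pop)
    if sample is not None:
        ids = sample.alignment.ids()
        sites = [r.site for r in sample.alignment.records]
    else:
        ids = [f"s{i + 1}" for i in range(len(seqs))]
        sites = [""] * len(seqs)
    order: dict[str, int] = {}
    table = HaplotypeTable([], [], [], [])
    for seq, sid, loc in zip(seqs, ids, sites):
        if seq not in order:
            order[seq] = len(table.haplotypes)
            table.haplotypes.append(seq)
            table.counts.append(0)
            table.locality_counts.append(Counter())
            table.members.append([])
        k = order[seq]
        table.counts[k] += 1
        table.locality_counts[k][loc] += 1
        table.members[k].append(sid)
    table.locality_counts = [dict(c) for c in table.locality_counts]
    return table


def haplotype_diversity(pop) -> float:
    """Nei's unbiased haplotype diversity Hd = n(1 - sum p_i^2)/(n-1)."""
    seqs, _ = _as_sample(pop)
    n = len(seqs)
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    freqs = np.array(list(Counter(seqs).values())) / n
    return float(n * (1.0 - np.sum(freqs**2)) / (n - 1))


def segregating_sites(pop) -> int:
    """Number of columns carrying at least two distinct bases."""
    seqs, _ = _as_sample(pop)
    m = seq_matrix(seqs)
    return int(np.sum((m != m[0]).any(axis=0)))


# ---------------------------------------------------------------------------
# Nucleotide diversity


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); defined for p < 3/4."""
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor undefined at p = {p:.4f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def nucleotide_diversity(pop, correction: str = "JC") -> float:
    """Mean pairwise per-site difference, optionally JC-corrected per pair."""
    seqs, _ = _as_sample(pop)
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    if correction not in ("JC", "none"):
        raise ValueError(f"unknown correction: {correction!r}")
    L = len(seqs[0])
    diffs = pairwise_differences(seqs)
    ps = diffs / L
    if correction == "none":
        return float(ps.mean())
    out = []
    pairs = [(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    for (i, j), p in zip(pairs, ps):
        if p >= 0.75:
            raise ValueError(
                f"Jukes-Cantor undefined for pair ({i}, {j}): p = {p:.4f}"
            )
        out.append(jukes_cantor(float(p)))
    return float(np.mean(out))


def pi_syn_nonsyn(pop, code_id: int | None = None) -> tuple[float, float, float | None]:
    """Nonsynonymous and synonymous nucleotide diversity (Nei-Gojobori).

    Per pair of sequences, differences and mutational-opportunity sites are
    split into synonymous and nonsynonymous classes by averaging over all
    single-step pathways between differing codons; the per-pair proportions
    are JC-corrected and then averaged over pairs.

    Returns ``(pi_a, pi_s, ratio)``; ratio is None when both diversities
    vanish (reported "-"), 0.0 when only pi_a vanishes, and inf when only
    pi_s vanishes.
    """
    seqs_masked, sample = _as_sample(pop)
    if sample is None:
        raise ValueError("pi_syn_nonsyn requires a PopulationSample with a mask")
    if code_id is None:
        code_id = sample.alignment.genetic_code
    triples = sample.mask.codon_triples(sample.alignment.frame_offset)
    if not triples:
        raise ValueError("mask is not codon-aligned: no complete in-frame codons")
    raw = [r.seq for r in sample.alignment.records]
    n = len(raw)
    if n < 2:
        raise ValueError("pi_syn_nonsyn needs at least 2 sequences")
    pa_vals, ps_vals = [], []
    for i in range(n - 1):
        for j in range(i + 1, n):
            s_sites = n_sites = sd = nd = 0.0
            for (a, b, c) in triples:
                c1 = raw[i][a] + raw[i][b] + raw[i][c]
                c2 = raw[j][a] + raw[j][b] + raw[j][c]
                s1 = codons.syn_sites(c1, code_id)
                s2 = codons.syn_sites(c2, code_id)
                s_sites += 0.5 * (s1 + s2)
                n_sites += 3.0 - 0.5 * (s1 + s2)
                if c1 != c2:
                    dsd, dnd = codons.pathway_differences(c1, c2, code_id)
                    sd += dsd
                    nd += dnd
            ps_vals.append(jukes_cantor(sd / s_sites) if s_sites else 0.0)
            pa_vals.append(jukes_cantor(nd / n_sites) if n_sites else 0.0)
    pi_a = float(np.mean(pa_vals))
    pi_s = float(np.mean(ps_vals))
    if pi_s == 0.0 and pi_a == 0.0:
        ratio: float | None = None
    elif pi_s == 0.0:
        ratio = math.inf
    else:
        ratio = pi_a / pi_s
    return pi_a, pi_s, ratio


# ---------------------------------------------------------------------------
# Per-population summary (diversity-table layout)


@dataclass
class DiversitySummary:
    species: str
    region: str
    site: str
    n_seq: int
    sites_used: int
    sites_alignment: int
    n_hap: int | None = None
    hd: float | None = None
    s: int | None = None
    pi: float | None = None
    pi_a: float | None = None
    pi_s: float | None = None
    pi_ratio: float | None = None


def diversity_summary(pop: PopulationSample) -> DiversitySummary:
    """All per-population diversity statistics; '-' fields stay None when
    the population is below the 4-specimen estimation gate."""
    table = collapse_haplotypes(pop)
    out = DiversitySummary(
        species=pop.species, region=pop.region, site=pop.site,
        n_seq=pop.n, sites_used=pop.sites_used,
        sites_alignment=pop.sites_alignment, n_hap=table.n_hap,
    )
    if pop.excluded:
        return out
    out.hd = haplotype_diversity(pop)
    out.s = segregating_sites(pop)
    out.pi = nucleotide_diversity(pop, correction="JC")
    try:
        out.pi_a, out.pi_s, out.pi_ratio = pi_syn_nonsyn(pop)
    except ValueError:
        pass  # mask without whole codons: ratio stays unreported
    return out


def _fmt(v, digits=5):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "-"
    if isinstance(v, float):
        return f"{round(v, digits):g}"
    return str(v)


def diversity_table(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """One row per population, in the standard diversity-table layout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "Species": s.species, "Region": s.region, "Site": s.site,
                "N_Seq": s.n_seq,
                "Sites_used/Sites_alignment": f"{s.sites_used}/{s.sites_alignment}",
                "N_Hap": _fmt(s.n_hap), "Hd": _fmt(s.hd), "S": _fmt(s.s),
                "pi": _fmt(s.pi), "pi_a/pi_s": _fmt(s.pi_ratio),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Uncorrected p-distances (within/between groups)


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Uncorrected p-distance with pairwise deletion of non-ACGT positions."""
    valid = np.isin(a, _ACGT_CODES) & np.isin(b, _ACGT_CODES)
    nv = int(valid.sum())
    if nv == 0:
        raise ValueError("no comparable sites in pair")
    return float((a[valid] != b[valid]).sum() / nv)


_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def p_distance_summary(groups: dict[str, list[str]],
                       bootstrap_reps: int = 500,
                       seed: int | None = None) -> pd.DataFrame:
    """Within/between-group p-distance table with bootstrap SE.

    ``groups`` maps a label to equal-length aligned sequences.  Within-group
    SE is the standard deviation of the mean pairwise p-distance over
    ``bootstrap_reps`` site-resampling replicates (the convention of
    distance bootstrapping); between-group values are means of cross-group
    pairwise distances, min/max taken over partner groups.
    """
    if not groups:
        raise ValueError("no groups given")
    rng = np.random.default_rng(seed)
    mats = {g: seq_matrix(list(seqs)) for g, seqs in groups.items()}
    L = {m.shape[1] for m in mats.values()}
    if len(L) > 1:
        raise ValueError("groups must come from one alignment (equal lengths)")
    L = L.pop()

    def within_mean(m: np.ndarray, cols: np.ndarray | None) -> float:
        sub = m if cols is None else m[:, cols]
        vals = [
            _p_distance(sub[i], sub[j])
            for i in range(sub.shape[0] - 1)
            for j in range(i + 1, sub.shape[0])
        ]
        return float(np.mean(vals))

    rows = []
    labels = list(groups)
    for g in labels:
        m = mats[g]
        row: dict[str, object] = {"group": g, "n": m.shape[0]}
        if m.shape[0] >= 2:
            vals = [
                _p_distance(m[i], m[j])
                for i in range(m.shape[0] - 1)
                for j in range(i + 1, m.shape[0])
            ]
            boots = [
                within_mean(m, rng.integers(0, L, size=L))
                for _ in range(bootstrap_reps)
            ]
            row.update(
                within_min=float(np.min(vals)), within_max=float(np.max(vals)),
                within_mean=float(np.mean(vals)),
                within_SE=float(np.std(boots, ddof=1)) if bootstrap_reps > 1 else 0.0,
            )
        else:
            row.update(within_min=np.nan, within_max=np.nan,
                       within_mean=np.nan, within_SE=np.nan)
        between = []
        for h in labels:
            if h == g:
                continue
            mh = mats[h]
            cross = [
                _p_distance(a, b) for a in m for b in mh
            ]
            between.append(float(np.mean(cross)))
        row.update(
            between_min=float(np.min(between)) if between else np.nan,
            between_max=float(np.max(between)) if between else np.nan,
            bootstrap_reps=bootstrap_reps,
        )
        rows.append(row)
    return pd.DataFrame(rows)
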