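"""AMOVA-style F_ST between site populations of haploid sequences.

The default estimator is the Weir & Cockerham (1984) variance-components
theta adapted to haploid data (mtDNA sequences are single alleles, so the
individuals-within-population layer drops out), computed over haplotype
frequencies and summed over alleles.  A distance-weighted Phi_ST variant
(AMOVA on pairwise difference counts) is available as an option.
Significance comes from permuting sequences among populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import seq_matrix
from .io_align import MIN_SAMPLE, PopulationSample


@dataclass
class FstResult:
    fst: float
    p_value: float | None = None
    n_permutations: int = 0
    populations: list[tuple[str, int]] = field(default_factory=list)
    method: str = "weir-cockerham"
    low_reps: bool = False


def fst_from_haplotype_counts(counts: np.ndarray) -> float:
    """Weir-Cockerham theta from a populations x alleles count table.

    Haploid variance-components estimator: per allele,
    a = (MSP - MSG) / n_c and b = MSG, with theta = sum(a) / sum(a + b)
    over alleles.  Negative estimates are possible and not truncated.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 populations")
    sizes = counts.sum(axis=1)
    if np.any(sizes == 0):
        raise ValueError("empty population in count table")
    r = counts.shape[0]
    total = sizes.sum()
    n_c = (total - np.sum(sizes**2) / total) / (r - 1)
    freqs = counts / sizes[:, None]
    pbar = counts.sum(axis=0) / total
    msp = (sizes[:, None] * (freqs - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (sizes[:, None] * freqs * (1.0 - freqs)).sum(axis=0) / (total - r)
    a = (msp - msg) / n_c
    b = msg
    denom = float((a + b).sum())
    if denom == 0.0:
        return 0.0  # monomorphic data: no variance to apportion
    return float(a.sum() / denom)


def _haplotype_counts(seq_groups: list[list[str]]) -> np.ndarray:
    alleles: dict[str, int] = {}
    for grp in seq_groups:
        for s in grp:
            alleles.setdefault(s, len(alleles))
    table = np.zeros((len(seq_groups), len(alleles)))
    for gi, grp in enumerate(seq_groups):
        for s in grp:
            table[gi, alleles[s]] += 1
    return table


def phi_st(seq_groups: list[list[str]]) -> float:
    """Distance-weighted Phi_ST: AMOVA on pairwise difference counts."""
    all_seqs = [s for grp in seq_groups for s in grp]
    n = len(all_seqs)
    r = len(seq_groups)
    m = seq_matrix(all_seqs)
    d2 = np.zeros((n, n))
    for i in range(n - 1):
        d2[i, i + 1 :] = (m[i] != m[i + 1 :]).sum(axis=1)
    d2 = d2 + d2.T
    sizes = np.array([len(g) for g in seq_groups], dtype=float)
    bounds = np.cumsum([0] + [len(g) for g in seq_groups])
    ssd_total = d2[np.triu_indices(n, 1)].sum() / n
    ssd_within = sum(
        d2[bounds[i]: bounds[i + 1], bounds[i]: bounds[i + 1]][
            np.triu_indices(int(sizes[i]), 1)
        ].sum() / sizes[i]
        for i in range(r)
    )
    ssd_among = ssd_total - ssd_within
    total = sizes.sum()
    sigma_w = ssd_within / (total - r)
    n_c = (total - np.sum(sizes**2) / total) / (r - 1)
    sigma_a = (ssd_among / (r - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def _check_gate(pops: list[PopulationSample]) -> None:
    small = [p.site or p.species for p in pops if p.n < MIN_SAMPLE]
    if small:
        raise ValueError(
            f"populations below the {MIN_SAMPLE}-specimen gate: {small}"
        )


def _groups_from(pops) -> tuple[list[list[str]], list[tuple[str, int]]]:
    if pops and isinstance(pops[0], PopulationSample):
        _check_gate(pops)
        lengths = {p.sites_used for p in pops}
        if len(lengths) > 1:
            raise ValueError(
                "populations must share one complete-site mask; "
                f"got masked lengths {sorted(lengths)}"
            )
        groups = [p.masked_seqs() for p in pops]
        labels = [(p.site or p.species, p.n) for p in pops]
    else:
        groups = [list(g) for g in pops]
        labels = [(f"pop{i + 1}", len(g)) for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("need at least 2 populations")
    return groups, labels


def amova_fst(pops, method: str = "weir-cockerham") -> FstResult:
    """Point estimate of F_ST between two or more populations.

    ``pops`` is a list of PopulationSample (sharing a site mask) or bare
    lists of equal-length sequences.  ``method`` selects the haplotype-
    frequency Weir-Cockerham theta (default) or the distance-based
    ``"phi"`` variant.
    """
    groups, labels = _groups_from(pops)
    if method == "weir-cockerham":
        val = fst_from_haplotype_counts(_haplotype_counts(groups))
    elif method == "phi":
        val = phi_st(groups)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return FstResult(fst=val, populations=labels, method=method)


def permutation_test(pops, reps: int = 1000, seed: int | None = None,
                     method: str = "weir-cockerham") -> FstResult:
    """Permute sequences among populations (sizes preserved) for a P-value.

    P = (1 + #{theta_perm >= theta_obs}) / (reps + 1).
    """
    groups, labels = _groups_from(pops)
    result = amova_fst(groups, method=method)
    result.populations = labels
    rng = np.random.default_rng(seed)
    pooled = [s for g in groups for s in g]
    sizes = [len(g) for g in groups]
    hits = 0
    for _ in range(reps):
        perm = [pooled[i] for i in rng.permutation(len(pooled))]
        split, at = [], 0
        for s in sizes:
            split.append(perm[at: at + s])
            at += s
        if amova_fst(split, method=method).fst >= result.fst:
            hits += 1
    result.p_value = (hits + 1) / (reps + 1)
    result.n_permutations = reps
    result.low_reps = reps < 99
    return result
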