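"""Demographic statistics and their coalescent significance tests.

Four classic single-locus signals of population expansion are computed
for each population sample: Tajima's D (skew of the frequency spectrum),
Fu's Fs (haplotype excess under the Ewens sampling formula), the
Ramos-Onsins & Rozas R2 (singleton load relative to pairwise diversity),
and Harpending-style raggedness of the mismatch distribution.  P-values
come from neutral constant-size coalescent replicates simulated at
Watterson's theta fitted to the observed number of segregating sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .diversity import collapse_haplotypes, pairwise_differences, seq_matrix
from .io_align import PopulationSample
from .synthetic_data import simulate_infinite_sites

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Sufficient statistics of one sample


@dataclass
class SampleStats:
    """Everything the demography statistics need, format-agnostic."""

    n: int
    S: int
    k: float                 # mean pairwise difference count
    u: np.ndarray            # per-sequence singleton (minor-allele) load
    pair_diffs: np.ndarray   # condensed pairwise difference counts
    n_hap: int

    @classmethod
    def from_seqs(cls, seqs: list[str]) -> "SampleStats":
        m = seq_matrix(seqs)
        n, L = m.shape
        base_counts = np.stack([(m == b).sum(axis=0) for b in _ACGT])
        seg = (base_counts > 0).sum(axis=0) >= 2
        u = np.zeros(n, dtype=int)
        for bi, b in enumerate(_ACGT):
            cols = np.flatnonzero(seg & (base_counts[bi] == 1))
            if cols.size:
                u += (m[:, cols] == b).sum(axis=1)
        pd_ = pairwise_differences(seqs)
        return cls(
            n=n, S=int(seg.sum()),
            k=float(pd_.mean()) if pd_.size else 0.0,
            u=u, pair_diffs=pd_,
            n_hap=len(set(seqs)),
        )

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "SampleStats":
        """From a 0/1 haplotype matrix (infinite-sites simulation output)."""
        n = mat.shape[0]
        if mat.shape[1] == 0:
            return cls(n=n, S=0, k=0.0, u=np.zeros(n, dtype=int),
                       pair_diffs=np.zeros(n * (n - 1) // 2, dtype=int),
                       n_hap=1)
        mat = mat.astype(np.int64)
        g = mat @ mat.T
        rs = mat.sum(axis=1)
        dmat = rs[:, None] + rs[None, :] - 2 * g
        iu = np.triu_indices(n, k=1)
        pd_ = dmat[iu]
        cs = mat.sum(axis=0)
        u = np.zeros(n, dtype=int)
        ones = np.flatnonzero(cs == 1)
        if ones.size:
            u += mat[:, ones].sum(axis=1)
        filled = np.flatnonzero(cs == n - 1)
        if filled.size:
            u += (1 - mat[:, filled]).sum(axis=1)
        return cls(
            n=n, S=mat.shape[1], k=float(pd_.mean()), u=u, pair_diffs=pd_,
            n_hap=int(np.unique(mat, axis=0).shape[0]),
        )


def _as_stats(pop) -> SampleStats:
    if isinstance(pop, SampleStats):
        return pop
    if isinstance(pop, PopulationSample):
        stats = SampleStats.from_seqs(pop.masked_seqs())
        stats.n_hap = collapse_haplotypes(pop).n_hap
        return stats
    return SampleStats.from_seqs(list(pop))


# ---------------------------------------------------------------------------
# Tajima's D


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's (1989) variance normalisation."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


def watterson_theta(S: int, n: int) -> float:
    """Per-locus Watterson estimator theta_W = S / a1."""
    return S / tajima_constants(n)["a1"]


def tajima_d(pop) -> float:
    """D = (k - S/a1) / sqrt(e1 S + e2 S(S-1)); negative under singleton excess."""
    st = _as_stats(pop)
    if st.S == 0:
        raise ValueError("Tajima's D undefined: no segregating sites")
    c = tajima_constants(st.n)
    var = c["e1"] * st.S + c["e2"] * st.S * (st.S - 1)
    return float((st.k - st.S / c["a1"]) / math.sqrt(var))


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling formula


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, j)| for j = 0..n (unsigned Stirling numbers, 1st kind).

    Computed with exact big-integer recurrence s(n+1,j) = s(n,j-1) + n s(n,j)
    and converted to logs only at the end, so no overflow for any n used here.
    """
    row = [1]  # s(0,0)
    for m in range(n):
        nxt = [0] * (len(row) + 1)
        for j, v in enumerate(row):
            nxt[j] += m * v
            nxt[j + 1] += v
        row = nxt
    return np.array(
        [math.log(v) if v else -math.inf for v in row], dtype=float
    )


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = j) for j = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_row(n)
    j = np.arange(n + 1)
    logp = logs + j * math.log(theta) - sum(
        math.log(theta + i) for i in range(n)
    )
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


FS_CLAMP = 1e-4  # keeps Fs finite when S' saturates (flagged)


@dataclass
class FsResult:
    value: float
    s_prime: float
    clamped: bool


def fu_fs_detail(pop) -> FsResult:
    """Fu's Fs: S' = P(K >= K_obs | theta = k), Fs = ln(S'/(1-S')).

    K_obs is the observed number of haplotypes and theta is estimated by
    the mean pairwise difference count.  S' is clamped away from {0, 1}
    (flagged) so that Fs stays finite.
    """
    st = _as_stats(pop)
    if st.k <= 0:
        raise ValueError("Fu's Fs undefined: no pairwise differences")
    p = ewens_k_distribution(st.n, st.k)
    s_prime = float(p[st.n_hap :].sum())
    clamped = not (FS_CLAMP < s_prime < 1.0 - FS_CLAMP)
    s_clamped = min(max(s_prime, FS_CLAMP), 1.0 - FS_CLAMP)
    return FsResult(
        value=float(math.log(s_clamped / (1.0 - s_clamped))),
        s_prime=s_prime, clamped=clamped,
    )


def fu_fs(pop) -> float:
    return fu_fs_detail(pop).value


# ---------------------------------------------------------------------------
# R2 and the mismatch distribution


def r2_statistic(pop) -> float:
    """Ramos-Onsins & Rozas R2 = sqrt(mean((U_i - k/2)^2)) / S."""
    st = _as_stats(pop)
    if st.S == 0:
        raise ValueError("R2 undefined: no segregating sites")
    dev = st.u - st.k / 2.0
    return float(math.sqrt(np.mean(dev**2)) / st.S)


@dataclass
class MismatchDistribution:
    counts: np.ndarray  # frequency of each pairwise-difference value 0..d
    n_pairs: int

    @property
    def relative(self) -> np.ndarray:
        return self.counts / self.n_pairs


def mismatch_and_raggedness(pop) -> tuple[MismatchDistribution, float]:
    """Mismatch distribution and its raggedness rg = sum of squared steps.

    Both boundary steps (from 0 into the first class and from the last
    class back to 0) are included, so a point mass gives rg = 2 and the
    two-class distribution {0.5, 0.5} gives 0.5.
    """
    st = _as_stats(pop)
    counts = np.bincount(st.pair_diffs)
    mismatch = MismatchDistribution(counts=counts, n_pairs=st.pair_diffs.size)
    x = np.concatenate([[0.0], mismatch.relative, [0.0]])
    rg = float(np.sum(np.diff(x) ** 2))
    return mismatch, rg


def raggedness(pop) -> float:
    return mismatch_and_raggedness(pop)[1]


# ---------------------------------------------------------------------------
# Coalescent null distributions


STAT_NAMES = ("tajima_d", "fu_fs", "r2", "raggedness")
LOWER_TAIL_DEFAULT = {"tajima_d": True, "fu_fs": True, "r2": True,
                      "raggedness": False}


def _all_stats(st: SampleStats) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    try:
        out["tajima_d"] = tajima_d(st)
    except ValueError:
        out["tajima_d"] = None
    try:
        out["fu_fs"] = fu_fs(st)
    except ValueError:
        out["fu_fs"] = None
    try:
        out["r2"] = r2_statistic(st)
    except ValueError:
        out["r2"] = None
    out["raggedness"] = raggedness(st) if st.pair_diffs.size else None
    return out


def coalescent_pvalues(pop, reps: int = 1000,
                       seed: int | None = None,
                       theta: float | None = None,
                       lower_tail: dict[str, bool] | None = None,
                       ) -> dict[str, float | None]:
    """Empirical P-values from neutral constant-size coalescent replicates.

    Replicates are simulated at Watterson's theta fitted to the observed S
    (no recombination, infinite sites); each statistic is recomputed and
    compared to the observed value with +1/(reps+1) smoothing.  By default
    D, Fs and R2 are tested on the lower (expansion) tail and raggedness on
    the upper-or-equal tail; orientations are configurable.
    """
    st = _as_stats(pop)
    obs = _all_stats(st)
    tails = {**LOWER_TAIL_DEFAULT, **(lower_tail or {})}
    if theta is None:
        if st.S == 0:
            return {name: None for name in STAT_NAMES}
        theta = watterson_theta(st.S, st.n)
    rng = np.random.default_rng(seed)
    extreme = {name: 0 for name in STAT_NAMES}
    defined = {name: 0 for name in STAT_NAMES}
    for _ in range(reps):
        mat = simulate_infinite_sites(st.n, theta, seed=rng)
        sim = _all_stats(SampleStats.from_matrix(mat))
        for name in STAT_NAMES:
            if obs[name] is None or sim[name] is None:
                continue
            defined[name] += 1
            if tails[name]:
                extreme[name] += sim[name] <= obs[name]
            else:
                extreme[name] += sim[name] >= obs[name]
    pvals: dict[str, float | None] = {}
    for name in STAT_NAMES:
        if obs[name] is None or defined[name] == 0:
            pvals[name] = None
        else:
            pvals[name] = (extreme[name] + 1) / (defined[name] + 1)
    return pvals


# ---------------------------------------------------------------------------
# Per-population summary (demography-table layout)


@dataclass
class DemographySummary:
    species: str
    region: str
    site: str
    n_seq: int
    n_hap: int | None = None
    tajima_d: float | None = None
    fu_fs: float | None = None
    fs_clamped: bool = False
    r2: float | None = None
    raggedness: float | None = None
    p_d: float | None = None
    p_fs: float | None = None
    p_r2: float | None = None
    p_rg: float | None = None
    n_replicates: int = 1000


def demography_summary(pop: PopulationSample, reps: int = 1000,
                       seed: int | None = None) -> DemographySummary:
    out = DemographySummary(
        species=pop.species, region=pop.region, site=pop.site, n_seq=pop.n,
        n_hap=collapse_haplotypes(pop).n_hap, n_replicates=reps,
    )
    if pop.excluded:
        return out
    st = _as_stats(pop)
    obs = _all_stats(st)
    out.tajima_d = obs["tajima_d"]
    out.fu_fs = obs["fu_fs"]
    if obs["fu_fs"] is not None:
        out.fs_clamped = fu_fs_detail(st).clamped
    out.r2 = obs["r2"]
    out.raggedness = obs["raggedness"]
    if st.S > 0:
        p = coalescent_pvalues(st, reps=reps, seed=seed)
        out.p_d, out.p_fs = p["tajima_d"], p["fu_fs"]
        out.p_r2, out.p_rg = p["r2"], p["raggedness"]
    return out


def demography_table(summaries: list[DemographySummary]):
    """One row per population, statistics with P-values in parentheses."""
    import pandas as pd

    def cell(v, p):
        if v is None:
            return "-"
        return f"{v:.4f} (P = {p:.4f})" if p is not None else f"{v:.4f}"

    rows = []
    for s in summaries:
        rows.append(
            {
                "Species": s.species, "Region": s.region, "Site": s.site,
                "N_Seq": s.n_seq,
                "N_Hap": s.n_hap if s.n_hap is not None else "-",
                "Tajima D": cell(s.tajima_d, s.p_d),
                "Fu Fs": cell(s.fu_fs, s.p_fs),
                "R2": cell(s.r2, s.p_r2),
                "rg": cell(s.raggedness, s.p_rg),
            }
        )
    return pd.DataFrame(rows)
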