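"""Two-deme isolation-with-migration coalescent and joint-SFS estimation.

The demographic model: two demes of constant diploid size N exchange
migrants at per-generation rates m12/m21 and merge into a single
ancestral deme (size N_anc) T_div generations in the past.  Datasets are
collections of unlinked fragments (600 bp by default), each evolving
under the infinite-sites model within the fragment.

Scaling.  The genealogy law depends on the scaled parameters only:
time in units of 2N generations, tau = T_div / 2N, and per-lineage
scaled migration rates M = 2N m.  Absolute N enters the expected joint
site-frequency spectrum purely as a linear scale factor through the
per-fragment mutation intensity mu * L * 2N, which is what makes the
profile-likelihood trick in :func:`estimate_params` possible.

Estimation maximises a Poisson composite likelihood over the cells of
the (folded) joint SFS.  The multinomial shape likelihood of
:func:`composite_loglik` is also provided, but by itself it cannot
identify N once monomorphic cells are excluded: SFS *proportions* are
invariant to rescaling (N, T, m) -> (cN, cT, m/c).  The Poisson form
adds the observed total number of variable sites, which pins N down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize


@dataclass
class IMConfig:
    """Parameters of the isolation-with-migration simulation."""

    N: float = 10000.0          # diploid deme size
    N_anc: float | None = None  # ancestral diploid size (default: N)
    T_div: float = 100000.0     # divergence time in generations
    m12: float = 1e-4           # backward per-generation migration rates
    m21: float = 1e-4
    n_frag: int = 100           # unlinked fragments per dataset
    L: int = 600                # fragment length, bp
    mu: float = 1e-8            # mutation rate per bp per generation
    rec: float = 0.0            # within-fragment recombination (off: unlinked
                                # fragments, fully linked sites inside one)
    n_ind: int = 20             # diploid individuals sampled per deme
    seed: int = 0
    folded: bool = True

    def __post_init__(self) -> None:
        if self.N_anc is None:
            self.N_anc = self.N
        for name in ("N", "N_anc", "T_div", "m12", "m21", "mu", "L", "n_frag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_ind < 1:
            raise ValueError("n_ind must be >= 1")

    @property
    def n_hap(self) -> int:
        """Gene copies sampled per deme (2 per diploid individual)."""
        return 2 * self.n_ind

    @property
    def theta_frag(self) -> float:
        """Per-fragment scaled mutation rate 4 N mu L."""
        return 4.0 * self.N * self.mu * self.L

    @property
    def migrants_per_generation(self) -> float:
        """N*m, the expected number of migrant individuals per generation."""
        return self.N * max(self.m12, self.m21)

    @classmethod
    def symmetric(cls, **kw) -> "IMConfig":
        return cls(**kw)

    @classmethod
    def asymmetric(cls, m: float = 1e-4, **kw) -> "IMConfig":
        """One-directional migration at rate m; the other direction 0."""
        return cls(m12=m, m21=0.0, **kw)

    #: accepted aliases in config files (simulation-table shorthand)
    ALIASES = {
        "tau": "T_div", "Ne": "N", "bp": "L",
        "migration_rate": "m12", "n_fragments": "n_frag",
    }

    @classmethod
    def from_file(cls, path) -> "IMConfig":
        """Read a JSON or YAML config; simulation-table aliases accepted
        (tau -> T_div, Ne -> N, bp -> L); ``migration_type`` of
        "symmetric"/"asymmetric" sets m12/m21 from ``migration_rate``."""
        import json as _json
        from pathlib import Path as _Path

        import yaml as _yaml

        text = _Path(path).read_text()
        data = (_json.loads(text) if str(path).endswith(".json")
                else _yaml.safe_load(text))
        mig_type = data.pop("migration_type", "symmetric")
        kw = {cls.ALIASES.get(k, k): v for k, v in data.items()}
        if "m12" in kw and "m21" not in kw:
            kw["m21"] = kw["m12"] if mig_type == "symmetric" else 0.0
        return cls(**kw)


@dataclass
class JointSFS:
    """Joint site-frequency spectrum of two demes.

    ``counts[i, j]`` is the number of variable sites whose allele is
    carried by i copies in deme 1 and j in deme 2 (minor allele when
    folded).  The monomorphic corners carry no information and are
    excluded from likelihoods.
    """

    counts: np.ndarray
    folded: bool = False

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def fold(self) -> "JointSFS":
        if self.folded:
            return self
        return JointSFS(fold_matrix(self.counts), folded=True)


def fold_matrix(counts: np.ndarray) -> np.ndarray:
    """Fold a joint SFS onto minor-allele coordinates.

    Cell (i, j) pools with its mirror (K1-i, K2-j); mass goes to whichever
    of the two has the smaller total count (ties pool into the
    lexicographically smaller index pair), preserving the total.
    """
    k1 = counts.shape[0] - 1
    k2 = counts.shape[1] - 1
    out = np.zeros_like(counts, dtype=float)
    for i in range(k1 + 1):
        for j in range(k2 + 1):
            mi, mj = k1 - i, k2 - j
            tot, mtot = i + j, mi + mj
            if tot < mtot or (tot == mtot and (i, j) <= (mi, mj)):
                out[i, j] += counts[i, j]
                if (mi, mj) != (i, j):
                    out[i, j] += counts[mi, mj]
    return out


def polymorphic_mask(shape: tuple[int, int]) -> np.ndarray:
    mask = np.ones(shape, dtype=bool)
    mask[0, 0] = False
    mask[-1, -1] = False
    return mask


# ---------------------------------------------------------------------------
# Structured-coalescent core (scaled units)


def _simulate_fragment(rng: np.random.Generator, n1: int, n2: int,
                       tau: float, M1: float, M2: float,
                       anc_ratio: float = 1.0,
                       theta: float | None = None):
    """One two-deme coalescent genealogy in units of 2N generations.

    Returns ``(cells, columns)``: ``cells`` maps (i, j) descendant
    configurations to total branch length carrying them; ``columns`` is a
    list of boolean carrier vectors, one per mutation, drawn as
    Poisson(theta/2 * length) on each lineage interval (only when
    ``theta`` is given).
    """
    n = n1 + n2
    members = [np.zeros(n, dtype=bool) for _ in range(n)]
    for s in range(n):
        members[s][s] = True
    conf = [(1, 0)] * n1 + [(0, 1)] * n2
    birth = [0.0] * n
    deme = [0] * n1 + [1] * n2
    active = list(range(n))
    cells: dict[tuple[int, int], float] = {}
    columns: list[np.ndarray] = []
    t = 0.0
    merged = tau == 0.0
    if merged:
        deme = [0] * n

    def close_episode(li: int, now: float) -> None:
        # a lineage's descendant set is constant from its creation to its
        # coalescence, so one Poisson draw per episode suffices
        length = now - birth[li]
        if length <= 0.0:
            return
        key = conf[li]
        cells[key] = cells.get(key, 0.0) + length
        if theta is not None:
            for _ in range(rng.poisson(theta / 2.0 * length)):
                columns.append(members[li].copy())

    while len(active) > 1:
        k1 = sum(1 for li in active if deme[li] == 0)
        k2 = len(active) - k1
        if merged:
            rates = (k1 * (k1 - 1) / 2.0 / anc_ratio, 0.0, 0.0, 0.0)
        else:
            rates = (k1 * (k1 - 1) / 2.0, k2 * (k2 - 1) / 2.0,
                     k1 * M1, k2 * M2)
        total = sum(rates)
        if total == 0.0:
            # isolated singletons before the merge: jump to tau
            t = tau
            merged = True
            for li in active:
                deme[li] = 0
            continue
        dt = rng.exponential() / total
        if not merged and t + dt > tau:
            t = tau
            merged = True
            for li in active:
                deme[li] = 0
            continue
        t += dt
        u = rng.random() * total
        if u < rates[0] + rates[1]:
            ev = 0 if u < rates[0] else 1
            pool = [li for li in active if deme[li] == ev]
            a, b = rng.choice(len(pool), size=2, replace=False)
            la, lb = pool[a], pool[b]
            close_episode(la, t)
            close_episode(lb, t)
            conf[la] = (conf[la][0] + conf[lb][0], conf[la][1] + conf[lb][1])
            members[la] = members[la] | members[lb]
            birth[la] = t
            active.remove(lb)
        else:
            src = 0 if u < rates[0] + rates[1] + rates[2] else 1
            pool = [li for li in active if deme[li] == src]
            li = pool[rng.integers(len(pool))]
            deme[li] = 1 - src
    return cells, columns


@dataclass
class IMSimResult:
    """Pseudo-observed dataset: per-fragment haplotypes plus joint SFS."""

    config: IMConfig
    fragments: list[np.ndarray]   # (n1+n2) x S_f 0/1 matrices
    sfs: JointSFS

    @property
    def n_sites(self) -> int:
        return self.sfs.n_sites


def simulate_im(config: IMConfig) -> IMSimResult:
    """Simulate a pseudo-observed dataset under the IM model."""
    rng = np.random.default_rng(config.seed)
    n1 = n2 = config.n_hap
    tau = config.T_div / (2.0 * config.N)
    m1 = 2.0 * config.N * config.m12
    m2 = 2.0 * config.N * config.m21
    anc_ratio = config.N_anc / config.N
    counts = np.zeros((n1 + 1, n2 + 1))
    fragments = []
    for _ in range(config.n_frag):
        _, cols = _simulate_fragment(rng, n1, n2, tau, m1, m2, anc_ratio,
                                     theta=config.theta_frag)
        if cols:
            mat = np.array(cols, dtype=np.int8).T
        else:
            mat = np.zeros((n1 + n2, 0), dtype=np.int8)
        fragments.append(mat)
        for col in cols:
            counts[int(col[:n1].sum()), int(col[n1:].sum())] += 1
    sfs = JointSFS(counts, folded=False)
    if config.folded:
        sfs = sfs.fold()
    return IMSimResult(config=config, fragments=fragments, sfs=sfs)


# ---------------------------------------------------------------------------
# Expected SFS (Monte-Carlo over genealogies) and composite likelihoods


_CELLS_CACHE: dict[tuple, np.ndarray] = {}


def expected_branch_cells(n1: int, n2: int, tau: float, M1: float, M2: float,
                          n_mc: int, seed: int,
                          anc_ratio: float = 1.0) -> np.ndarray:
    """Mean branch length (units of 2N generations) per joint-SFS cell.

    Monte-Carlo average over ``n_mc`` genealogies; results are cached by
    parameter value so repeated likelihood evaluations (e.g. a shared
    grid across pseudo-observed datasets) are free.
    """
    key = (n1, n2, round(float(tau), 12), round(float(M1), 12),
           round(float(M2), 12), n_mc, seed, round(float(anc_ratio), 12))
    if key in _CELLS_CACHE:
        return _CELLS_CACHE[key]
    rng = np.random.default_rng(seed)
    acc = np.zeros((n1 + 1, n2 + 1))
    for _ in range(n_mc):
        cells, _ = _simulate_fragment(rng, n1, n2, tau, M1, M2, anc_ratio)
        for (i, j), length in cells.items():
            acc[i, j] += length
    acc /= n_mc
    _CELLS_CACHE[key] = acc
    return acc


def expected_sfs(config: IMConfig, n_mc: int = 1000,
                 seed: int = 0) -> np.ndarray:
    """Expected joint-SFS proportions over polymorphic cells.

    Proportions sum to 1 over the polymorphic cells; zero cells are
    floored at a small pseudo-count for likelihood stability.
    """
    n1 = n2 = config.n_hap
    cells = expected_branch_cells(
        n1, n2, config.T_div / (2 * config.N),
        2 * config.N * config.m12, 2 * config.N * config.m21,
        n_mc, seed, config.N_anc / config.N,
    )
    if config.folded:
        cells = fold_matrix(cells)
    mask = polymorphic_mask(cells.shape)
    if cells[mask].sum() == 0:
        raise ValueError("theta too small: Monte-Carlo output is monomorphic")
    floor = 0.05 / n_mc
    prop = np.where(cells > floor, cells, floor)
    prop[~mask] = 0.0
    return prop / prop[mask].sum()


def composite_loglik(obs: JointSFS, exp_prop: np.ndarray) -> float:
    """Multinomial composite log-likelihood sum(obs * ln(expected proportion))."""
    if obs.counts.shape != exp_prop.shape:
        raise ValueError(
            f"dimension mismatch: obs {obs.counts.shape} vs exp {exp_prop.shape}"
        )
    mask = polymorphic_mask(obs.counts.shape) & (obs.counts > 0)
    if np.any(exp_prop[mask] <= 0):
        raise ValueError("expected proportions must be positive where observed")
    return float(np.sum(obs.counts[mask] * np.log(exp_prop[mask])))


@dataclass
class EstimationResult:
    N_hat: float
    T_hat: float
    m_hat: float
    m21_hat: float | None
    logCL: float
    trace: list[dict] = field(default_factory=list)
    at_bound: bool = False


DEFAULT_BOUNDS = {"N": (1e2, 1e6), "T": (1e2, 1e7), "m": (1e-6, 1e-2)}


def estimate_params(obs: JointSFS, model: str = "symmetric",
                    n_frag: int = 100, mu: float = 1e-8, L: int = 600,
                    bounds: dict | None = None, seed: int = 0,
                    n_mc_grid: int = 150, n_mc_refine: int = 400,
                    grid_size: int = 6, maxiter: int = 60) -> EstimationResult:
    """Maximum composite-likelihood estimates of (N, T_div, m).

    A coarse log-grid over the scaled shape parameters (tau = T/2N,
    M = 2Nm) is refined by Nelder-Mead on log coordinates; for every shape
    the diploid size N has a closed-form optimum (the Poisson composite
    likelihood is concave in N), so the numeric search is 2-D.  Common
    random numbers (the ``seed``) make the Monte-Carlo likelihood surface
    deterministic.
    """
    if model not in ("symmetric", "asymmetric"):
        raise ValueError(f"unknown model: {model!r}")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    if not obs.folded:
        obs = obs.fold()
    n1 = obs.shape[0] - 1
    n2 = obs.shape[1] - 1
    mask = polymorphic_mask(obs.shape)
    o = obs.counts[mask]
    s_total = o.sum()
    if s_total == 0:
        raise ValueError("flat likelihood: no polymorphic sites observed")
    c_scale = n_frag * mu * L * 2.0  # lambda = c_scale * N * E[length]
    floor = 0.02
    trace: list[dict] = []

    def evaluate(log_tau: float, log_m: float, n_mc: int) -> tuple[float, float]:
        tau = math.exp(log_tau)
        mm = math.exp(log_m)
        cells = expected_branch_cells(
            n1, n2, tau, mm, mm if model == "symmetric" else 0.0, n_mc, seed
        )
        e = fold_matrix(cells)[mask]
        e = np.where(e > floor / n_mc, e, floor / n_mc)
        n_hat = s_total / (c_scale * e.sum())
        n_hat = min(max(n_hat, bounds["N"][0]), bounds["N"][1])
        lam = c_scale * n_hat * e
        ll = float(np.sum(o * np.log(lam)) - lam.sum())
        trace.append({"tau": tau, "M": mm, "N": n_hat, "logCL": ll,
                      "n_mc": n_mc})
        return ll, n_hat

    # scaled bounds implied by the natural-parameter search box
    lt_lo, lt_hi = math.log(0.02), math.log(80.0)
    lm_lo, lm_hi = math.log(0.02), math.log(80.0)
    grid_t = np.linspace(lt_lo, lt_hi, grid_size)
    grid_m = np.linspace(lm_lo, lm_hi, grid_size)
    best = None
    for lt in grid_t:
        for lm in grid_m:
            ll, _ = evaluate(lt, lm, n_mc_grid)
            if best is None or ll > best[0]:
                best = (ll, lt, lm)

    def neg(x: np.ndarray) -> float:
        lt = min(max(x[0], lt_lo), lt_hi)
        lm = min(max(x[1], lm_lo), lm_hi)
        return -evaluate(lt, lm, n_mc_refine)[0]

    res = minimize(neg, x0=np.array(best[1:]), method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 0.02, "fatol": 0.05})
    lt = min(max(res.x[0], lt_lo), lt_hi)
    lm = min(max(res.x[1], lm_lo), lm_hi)
    ll, n_hat = evaluate(lt, lm, n_mc_refine)
    tau, mm = math.exp(lt), math.exp(lm)
    t_hat = min(max(tau * 2 * n_hat, bounds["T"][0]), bounds["T"][1])
    m_hat = min(max(mm / (2 * n_hat), bounds["m"][0]), bounds["m"][1])
    at_bound = (
        n_hat in bounds["N"] or t_hat in bounds["T"] or m_hat in bounds["m"]
        or lt in (lt_lo, lt_hi) or lm in (lm_lo, lm_hi)
    )
    return EstimationResult(
        N_hat=float(n_hat), T_hat=float(t_hat), m_hat=float(m_hat),
        m21_hat=(float(m_hat) if model == "symmetric" else 0.0),
        logCL=ll, trace=trace, at_bound=at_bound,
    )


# ---------------------------------------------------------------------------
# Performance study (the boxplot experiment)


def run_performance_study(models: list[str] = ("symmetric",),
                          t_divs: list[float] = (100000.0,),
                          fragment_counts: list[int] = (10, 100),
                          n_pseudo: int = 20,
                          seed: int = 0,
                          config_kw: dict | None = None,
                          estimate_kw: dict | None = None) -> pd.DataFrame:
    """Simulate pseudo-observed datasets and re-estimate (N, T, m).

    Returns one row per model x T_div x fragment count x pseudo-dataset
    with the re-estimated parameters and the per-dataset seed, ready for
    boxplot-style summaries of estimator performance.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        for t_div in t_divs:
            for n_frag in fragment_counts:
                for rep in range(n_pseudo):
                    ds_seed = int(rng.integers(2**31 - 1))
                    kw = dict(config_kw or {})
                    if model == "symmetric":
                        cfg = IMConfig.symmetric(
                            T_div=t_div, n_frag=n_frag, seed=ds_seed, **kw
                        )
                    else:
                        cfg = IMConfig.asymmetric(
                            T_div=t_div, n_frag=n_frag, seed=ds_seed, **kw
                        )
                    sim = simulate_im(cfg)
                    est = estimate_params(
                        sim.sfs, model=model, n_frag=n_frag,
                        mu=cfg.mu, L=cfg.L, seed=seed,
                        **(estimate_kw or {}),
                    )
                    rows.append({
                        "model": model, "T_div": t_div, "n_frag": n_frag,
                        "pseudo": rep, "seed": ds_seed,
                        "N_hat": est.N_hat, "T_hat": est.T_hat,
                        "m_hat": est.m_hat, "logCL": est.logCL,
                        "n_sites": sim.n_sites, "at_bound": est.at_bound,
                    })
    return pd.DataFrame(rows)


def summarize_performance(report: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each estimate per study cell."""
    def iqr(x):
        return np.subtract(*np.percentile(x, [75, 25]))

    return (
        report.groupby(["model", "T_div", "n_frag"])
        .agg(
            N_median=("N_hat", "median"), N_iqr=("N_hat", iqr),
            T_median=("T_hat", "median"), T_iqr=("T_hat", iqr),
            m_median=("m_hat", "median"), m_iqr=("m_hat", iqr),
            n_pseudo=("pseudo", "count"),
        )
        .reset_index()
    )
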