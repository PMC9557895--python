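"""Distribution-matched negative-control experiments.

A significant G-by-E interaction can be an artefact of the two exposure
groups simply having different outcome distributions (higher mean *and* SD
in cases), rather than of genuine effect modification.  The negative-control
experiment breaks any true exposure effect while preserving the
distributional difference: individuals are repeatedly sampled at random —
regardless of their real exposure — into two disjoint pseudo-groups whose
sizes, BMI means and BMI SDs match the real cases and controls, and the
interaction model is refitted each time with pseudo-exposure = group
membership.  The empirical P is the proportion of replicates whose
interaction P falls below the observed one (strict inequality, plain
proportion); small values support a real interaction, values near the
nominal level indicate a distribution-driven artefact.

Group selection is a seeded swap-descent optimizer: starting from a
density-tilted random assignment it repeatedly proposes swapping members
between groups (or with the unused pool) and accepts proposals that reduce

    L = sum over groups of (mean - target_mean)^2 + (sd - target_sd)^2,

stopping once every |achieved - target| is below the tolerance (default
0.05, i.e. agreement to one decimal place).  When the two group sizes
exhaust the pool — the usual situation when targets come from the real
cases and controls of the same sample — the two groups are optimized
jointly as a partition, since selecting one group then fixes the other.
Targets that cannot be met within the iteration budget raise
``InfeasibleTargetsError`` carrying the best-achieved moments, reproducing
the real failure mode of moment-matching on very large groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    EmptyGroupError,
    InfeasibleTargetsError,
    InvalidInputError,
    InvalidSpecError,
)
from .models import ModelSpec, build_design, _fit_interaction_arrays, fit_interaction_model

__all__ = [
    "GroupTargets",
    "NegativeControlRun",
    "NegativeControlSummary",
    "select_matched_group",
    "select_matched_pair",
    "run_negative_experiments",
    "empirical_p",
    "median_replicate",
    "simulate_groups_from_summary",
]


@dataclass(frozen=True)
class GroupTargets:
    """Sizes and BMI moments the two pseudo-groups must reproduce."""

    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    tolerance: float = 0.05

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidInputError("group sizes must be >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise InvalidInputError("target SDs must be positive")
        if self.tolerance <= 0:
            raise InvalidInputError("tolerance must be positive")

    @classmethod
    def from_groups(
        cls, outcome: pd.Series, exposure: pd.Series, tolerance: float = 0.05
    ) -> "GroupTargets":
        """Targets from the real groups: group 1 = exposure 0, group 2 = exposure 1."""
        df = pd.DataFrame({"y": outcome, "e": exposure}).dropna()
        g1 = df.loc[df["e"] == 0, "y"].to_numpy(float)
        g2 = df.loc[df["e"] == 1, "y"].to_numpy(float)
        if len(g1) < 2 or len(g2) < 2:
            raise EmptyGroupError("both exposure levels need >= 2 observations")
        return cls(
            n1=len(g1),
            n2=len(g2),
            mean1=float(g1.mean()),
            sd1=float(g1.std(ddof=1)),
            mean2=float(g2.mean()),
            sd2=float(g2.std(ddof=1)),
            tolerance=tolerance,
        )


@dataclass
class NegativeControlRun:
    replicate: int
    group1_ids: np.ndarray
    group2_ids: np.ndarray
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    beta_int: float
    se_int: float
    p_int: float
    iterations: int
    converged: bool


@dataclass
class NegativeControlSummary:
    """Replicate interaction P-values and the empirical P against the observed one."""

    R: int
    observed_p: float
    count_below: int
    empirical_p: float
    median_p: float
    median_replicate: int
    replicate_ps: np.ndarray
    failure_count: int = 0
    runs: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "replicate": r.replicate,
                "mean1": r.mean1,
                "sd1": r.sd1,
                "mean2": r.mean2,
                "sd2": r.sd2,
                "beta_int": r.beta_int,
                "se_int": r.se_int,
                "p_int": r.p_int,
                "iterations": r.iterations,
                "converged": r.converged,
            }
            for r in self.runs
        ]
        return pd.DataFrame(rows)

    def histogram(self, bins: int = 30) -> dict:
        """-log10(P) histogram data plus observed/median annotations."""
        logp = -np.log10(np.clip(self.replicate_ps, 1e-300, None))
        counts, edges = np.histogram(logp, bins=bins)
        return {
            "bin_edges": edges,
            "counts": counts,
            "observed_neglog10p": float(-np.log10(max(self.observed_p, 1e-300)))
            if np.isfinite(self.observed_p)
            else float("nan"),
            "median_neglog10p": float(-np.log10(max(self.median_p, 1e-300))),
        }


# ---------------------------------------------------------------------------
# swap-descent group selection


def _sd_from(s: float, q: float, n: int) -> float:
    var = (q - s * s / n) / (n - 1)
    return math.sqrt(var) if var > 0 else 0.0


class _GroupState:
    __slots__ = ("positions", "s", "q", "n", "tmean", "tsd")

    def __init__(self, x, positions, tmean, tsd):
        self.positions = np.asarray(positions, dtype=np.int64)
        v = x[self.positions]
        self.s = float(v.sum())
        self.q = float((v * v).sum())
        self.n = len(self.positions)
        self.tmean = tmean
        self.tsd = tsd

    def mean(self):
        return self.s / self.n

    def sd(self):
        return _sd_from(self.s, self.q, self.n)

    def loss(self):
        return (self.mean() - self.tmean) ** 2 + (self.sd() - self.tsd) ** 2

    def within(self, tol):
        return abs(self.mean() - self.tmean) < tol and abs(self.sd() - self.tsd) < tol


def _batch_group_loss(s, q, n, u, v, tmean, tsd):
    """Vectorized loss of a group after replacing value u by value v."""
    sn = s - u + v
    qn = q - u * u + v * v
    mn = sn / n
    var = (qn - sn * sn / n) / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return (mn - tmean) ** 2 + (sd - tsd) ** 2


def _tilted_split(x, n1, n2, t: GroupTargets, rng):
    """Density-ratio-tilted random start: near-target groups before descent."""
    npool = len(x)
    w1 = n1 * norm.pdf(x, t.mean1, max(t.sd1, 1e-6)) + 1e-12
    w2 = n2 * norm.pdf(x, t.mean2, max(t.sd2, 1e-6)) + 1e-12
    if n1 + n2 == npool:
        p = w1 / (w1 + w2)
        keys = rng.random(npool) ** (1.0 / p)  # weighted sampling without replacement
        order = np.argsort(-keys, kind="stable")
        g1 = order[:n1]
        g2 = order[n1:]
    else:
        p = w1 / w1.sum()
        g1 = rng.choice(npool, size=n1, replace=False, p=p)
        rest = np.setdiff1d(np.arange(npool), g1, assume_unique=False)
        pr = w2[rest]
        pr = pr / pr.sum()
        g2 = rest[rng.choice(len(rest), size=n2, replace=False, p=pr)]
    return g1, g2


def _swap_descent_pair(
    x: np.ndarray,
    targets: GroupTargets,
    rng: np.random.Generator,
    max_iter: int = 200_000,
    batch: int = 64,
    stall_limit: int = 400,
):
    """Optimize both groups at once; returns (g1, g2, iterations, converged)."""
    npool = len(x)
    n1, n2 = targets.n1, targets.n2
    tol = targets.tolerance
    partition = n1 + n2 == npool
    free = npool - n1 - n2

    best = None
    it = 0
    while it < max_iter:
        g1pos, g2pos = _tilted_split(x, n1, n2, targets, rng)
        G1 = _GroupState(x, g1pos, targets.mean1, targets.sd1)
        G2 = _GroupState(x, g2pos, targets.mean2, targets.sd2)
        used = np.zeros(npool, dtype=bool)
        used[G1.positions] = True
        used[G2.positions] = True
        unused = np.flatnonzero(~used)
        L = G1.loss() + G2.loss()
        stall = 0
        moves = [(G1, G2)]
        if free > 0:
            moves += [(G1, None), (G2, None)]
        while it < max_iter and stall <= stall_limit:
            if G1.within(tol) and G2.within(tol):
                return G1.positions.copy(), G2.positions.copy(), it, True
            A, B = moves[rng.integers(0, len(moves))] if len(moves) > 1 else moves[0]
            it += batch
            ai = rng.integers(0, A.n, batch)
            u = x[A.positions[ai]]
            if B is None:
                bj = rng.integers(0, len(unused), batch)
                v = x[unused[bj]]
                other = G2 if A is G1 else G1
                lossA = _batch_group_loss(A.s, A.q, A.n, u, v, A.tmean, A.tsd)
                newL = lossA + other.loss()
            else:
                bj = rng.integers(0, B.n, batch)
                v = x[B.positions[bj]]
                lossA = _batch_group_loss(A.s, A.q, A.n, u, v, A.tmean, A.tsd)
                lossB = _batch_group_loss(B.s, B.q, B.n, v, u, B.tmean, B.tsd)
                newL = lossA + lossB
            k = int(np.argmin(newL))
            if newL[k] < L - 1e-15:
                uu, vv = float(u[k]), float(v[k])
                pa = int(A.positions[ai[k]])
                if B is None:
                    pb = int(unused[bj[k]])
                    A.positions[ai[k]] = pb
                    unused[bj[k]] = pa
                else:
                    pb = int(B.positions[bj[k]])
                    A.positions[ai[k]] = pb
                    B.positions[bj[k]] = pa
                    B.s += uu - vv
                    B.q += uu * uu - vv * vv
                A.s += vv - uu
                A.q += vv * vv - uu * uu
                L = float(newL[k])
                stall = 0
            else:
                stall += 1
        if G1.within(tol) and G2.within(tol):
            return G1.positions.copy(), G2.positions.copy(), it, True
        cand = (G1, G2, L)
        if best is None or L < best[2]:
            best = cand
        # stalled before the budget ran out: restart from a fresh tilt
    G1, G2, _ = best
    raise InfeasibleTargetsError(
        "could not match target moments within the iteration budget "
        f"(best achieved: group1 {G1.mean():.3f} ({G1.sd():.3f}), "
        f"group2 {G2.mean():.3f} ({G2.sd():.3f}); "
        f"targets: {targets.mean1:.3f} ({targets.sd1:.3f}), "
        f"{targets.mean2:.3f} ({targets.sd2:.3f}))",
        achieved={
            "mean1": G1.mean(),
            "sd1": G1.sd(),
            "mean2": G2.mean(),
            "sd2": G2.sd(),
        },
        iterations=max_iter,
    )


def select_matched_pair(
    pool_values: pd.Series,
    targets: GroupTargets,
    seed: int = 0,
    max_iter: int = 200_000,
) -> tuple[pd.Index, pd.Index, int]:
    """Two disjoint groups matching the targets; returns (ids1, ids2, iterations)."""
    x = pool_values.to_numpy(float)
    if targets.n1 + targets.n2 > len(x):
        raise InvalidInputError(
            f"group sizes {targets.n1}+{targets.n2} exceed pool of {len(x)}"
        )
    _feasibility_precheck(x, targets)
    rng = np.random.default_rng(seed)
    g1, g2, iters, _ = _swap_descent_pair(x, targets, rng, max_iter=max_iter)
    return pool_values.index[g1], pool_values.index[g2], iters


def _feasibility_precheck(x: np.ndarray, targets: GroupTargets) -> None:
    lo, hi = float(np.min(x)), float(np.max(x))
    for m, s in ((targets.mean1, targets.sd1), (targets.mean2, targets.sd2)):
        if m < lo - targets.tolerance or m > hi + targets.tolerance:
            raise InfeasibleTargetsError(
                f"target mean {m:.3f} outside the pool range [{lo:.3f}, {hi:.3f}]",
                achieved=None,
                iterations=0,
            )


def select_matched_group(
    pool_bmi: pd.Series,
    n: int,
    target_mean: float,
    target_sd: float,
    tolerance: float = 0.05,
    excluded_ids=(),
    seed: int = 0,
    max_iter: int = 200_000,
) -> pd.Index:
    """Select one group of exactly ``n`` matching (mean, sd) within tolerance.

    Seeded swap descent from a density-tilted start; swaps members with
    non-members of the remaining pool.  Raises ``InfeasibleTargetsError``
    (with best-achieved moments) if the targets cannot be hit.
    """
    pool = pool_bmi.drop(index=list(excluded_ids), errors="ignore").dropna()
    if n > len(pool):
        raise InvalidInputError(f"n = {n} exceeds available pool of {len(pool)}")
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    x = pool.to_numpy(float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if target_mean < lo - tolerance or target_mean > hi + tolerance:
        raise InfeasibleTargetsError(
            f"target mean {target_mean:.3f} outside pool range [{lo:.3f}, {hi:.3f}]",
            achieved=None,
            iterations=0,
        )
    rng = np.random.default_rng(seed)
    npool = len(x)
    w = norm.pdf(x, target_mean, max(target_sd, 1e-6)) + 1e-12
    best = None
    it = 0
    batch, stall_limit = 64, 400
    while it < max_iter:
        gpos = rng.choice(npool, size=n, replace=False, p=w / w.sum())
        G = _GroupState(x, gpos, target_mean, target_sd)
        used = np.zeros(npool, dtype=bool)
        used[G.positions] = True
        unused = np.flatnonzero(~used)
        L = G.loss()
        stall = 0
        while it < max_iter and stall <= stall_limit:
            if G.within(tolerance):
                return pool.index[np.sort(G.positions)]
            it += batch
            ai = rng.integers(0, n, batch)
            bj = rng.integers(0, len(unused), batch)
            u = x[G.positions[ai]]
            v = x[unused[bj]]
            newL = _batch_group_loss(G.s, G.q, n, u, v, target_mean, target_sd)
            k = int(np.argmin(newL))
            if newL[k] < L - 1e-15:
                pa = int(G.positions[ai[k]])
                G.positions[ai[k]] = int(unused[bj[k]])
                unused[bj[k]] = pa
                uu, vv = float(u[k]), float(v[k])
                G.s += vv - uu
                G.q += vv * vv - uu * uu
                L = float(newL[k])
                stall = 0
            else:
                stall += 1
        if G.within(tolerance):
            return pool.index[np.sort(G.positions)]
        if best is None or L < best[1]:
            best = (G, L)
    G, _ = best
    raise InfeasibleTargetsError(
        "could not match target moments within the iteration budget "
        f"(best achieved {G.mean():.3f} ({G.sd():.3f}), "
        f"target {target_mean:.3f} ({target_sd:.3f}))",
        achieved={"mean": G.mean(), "sd": G.sd()},
        iterations=max_iter,
    )


# ---------------------------------------------------------------------------
# replicate engine


def empirical_p(count_below: int, R: int) -> float:
    """Plain proportion of replicates with interaction P below the observed.

    Strict inequality upstream and no (+1)/(R+1) correction: 67 of 1000
    replicates below the observed P reads as empirical P = 0.067.
    """
    if R < 1:
        raise InvalidInputError("R must be >= 1")
    if not 0 <= count_below <= R:
        raise InvalidInputError(f"count_below must lie in [0, {R}], got {count_below}")
    return count_below / R


def median_replicate(replicate_ps) -> tuple[int, float]:
    """Index and P of the median replicate (lower-middle rule for even counts)."""
    ps = np.asarray(replicate_ps, dtype=float)
    if ps.size == 0:
        raise InvalidInputError("no converged replicates")
    order = np.argsort(ps, kind="stable")
    idx = int(order[(ps.size - 1) // 2])
    return idx, float(ps[idx])


def run_negative_experiments(
    data: pd.DataFrame,
    spec: ModelSpec,
    targets: GroupTargets,
    R: int = 1000,
    seed: int = 0,
    grs: pd.Series | None = None,
    observed_p: float | None = None,
    include_covariates: bool = True,
    strict_R: bool = True,
    max_iter: int = 200_000,
    keep_members: bool = True,
) -> NegativeControlSummary:
    """R distribution-matched pseudo-exposure replicates of the interaction fit.

    The sampling pool is the full analysis sample regardless of true
    exposure.  Per replicate, two disjoint groups matching ``targets`` are
    selected (jointly, as a partition, when their sizes exhaust the pool;
    sequentially otherwise) and the interaction model is refitted with
    pseudo-exposure = membership of group 2 (the "case-target" group).
    Replicate models reuse the real model's covariates unless
    ``include_covariates`` is off.

    ``strict_R``: failed (non-converged) selections are redrawn until R
    converged replicates exist, up to a 2R attempt budget; otherwise
    failures are logged and excluded from the denominator.  More than 50%
    failures aborts with an infeasibility error either way.
    """
    from .models import _apply_stratum

    df = data
    if grs is not None:
        df = df.copy()
        df[spec.genetic] = grs.reindex(df.index)
    df = _apply_stratum(df, spec.stratum)
    needed = [spec.outcome, spec.genetic, spec.exposure, *spec.covariates, "bmi_raw"]
    needed = list(dict.fromkeys(c for c in needed if c in df.columns))
    df = df.dropna(subset=needed)
    if df.empty:
        raise EmptyGroupError("analysis sample is empty")

    if observed_p is None:
        observed_p = fit_interaction_model(df, spec, with_strata=False).p_int

    pool = df["bmi_raw"] if "bmi_raw" in df.columns else df[spec.outcome]
    x = pool.to_numpy(float)
    if targets.n1 + targets.n2 > len(x):
        raise InvalidInputError(
            f"group sizes {targets.n1}+{targets.n2} exceed pool of {len(x)}"
        )
    _feasibility_precheck(x, targets)

    y = df[spec.outcome].to_numpy(float)
    g = df[spec.genetic].to_numpy(float)
    covs = spec.covariates if include_covariates else ()
    C_df = build_design(df, covs)
    C = C_df.to_numpy(float)
    cnames = list(C_df.columns)

    runs: list[NegativeControlRun] = []
    failures = 0
    attempts = 0
    max_attempts = 2 * R if strict_R else R
    partition = targets.n1 + targets.n2 == len(x)
    while len(runs) < R and attempts < max_attempts:
        rng = np.random.default_rng([int(seed), attempts])
        attempts += 1
        try:
            g1, g2, iters, _ = _swap_descent_pair(x, targets, rng, max_iter=max_iter)
        except InfeasibleTargetsError:
            failures += 1
            if attempts >= 20 and failures > 0.5 * attempts:
                raise InfeasibleTargetsError(
                    f"{failures}/{attempts} replicate selections failed to converge; "
                    "targets appear infeasible for this pool",
                    iterations=attempts,
                ) from None
            continue
        e = np.zeros(len(x))
        e[g2] = 1.0
        if partition:
            sel = slice(None)
        else:
            sel = np.concatenate([g1, g2])
        beta, se, p = _fit_interaction_arrays(
            y[sel], g[sel], e[sel], C[sel], cnames, keller=spec.keller
        )
        v1, v2 = x[g1], x[g2]
        runs.append(
            NegativeControlRun(
                replicate=len(runs),
                group1_ids=pool.index[g1].to_numpy() if keep_members else np.array([]),
                group2_ids=pool.index[g2].to_numpy() if keep_members else np.array([]),
                mean1=float(v1.mean()),
                sd1=float(v1.std(ddof=1)),
                mean2=float(v2.mean()),
                sd2=float(v2.std(ddof=1)),
                beta_int=beta,
                se_int=se,
                p_int=p,
                iterations=iters,
                converged=True,
            )
        )
    if not runs:
        raise InfeasibleTargetsError(
            f"no replicate converged in {attempts} attempts", iterations=attempts
        )
    if failures > 0.5 * attempts:
        raise InfeasibleTargetsError(
            f"{failures}/{attempts} replicate selections failed to converge",
            iterations=attempts,
        )
    ps = np.array([r.p_int for r in runs])
    count_below = int((ps < observed_p).sum())
    med_idx, med_p = median_replicate(ps)
    return NegativeControlSummary(
        R=len(runs),
        observed_p=float(observed_p),
        count_below=count_below,
        empirical_p=empirical_p(count_below, len(runs)),
        median_p=med_p,
        median_replicate=med_idx,
        replicate_ps=ps,
        failure_count=failures,
        runs=runs,
        meta={
            "targets": targets,
            "strict_R": strict_R,
            "attempts": attempts,
            "partition": partition,
            "include_covariates": include_covariates,
        },
    )


def simulate_groups_from_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    weights: pd.DataFrame,
    spec: ModelSpec | None = None,
    R: int = 1000,
    seed: int = 0,
    observed_p: float | None = None,
) -> NegativeControlSummary:
    """Summary-statistics mode: negative experiments without individual data.

    When only another study's group sizes and BMI moments are available, each
    replicate draws BMI for the two groups from Normal(mean, sd), draws
    genotypes under Hardy-Weinberg from the weight table's frequencies —
    independent of group, i.e. under the interaction null — computes the
    GRS and fits the interaction model (no covariates; the outcome is
    inverse-normalized unless the spec says raw).
    """
    if min(n1, n2) < 2:
        raise InvalidInputError("group sizes must be >= 2")
    if sd1 <= 0 or sd2 <= 0 or not np.isfinite([mean1, mean2]).all():
        raise InvalidInputError("invalid group moments")
    from .grs import compute_weighted_grs, recode_to_increasing_allele
    from .phenotypes import inverse_normal_transform

    spec = spec or ModelSpec(covariates=())
    eaf = weights["eaf"].to_numpy(float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise InvalidInputError("weight-table frequencies must lie in (0, 1)")
    n = n1 + n2
    e = np.concatenate([np.zeros(n1), np.ones(n2)])
    runs = []
    ps = np.empty(R)
    for r in range(R):
        rng = np.random.default_rng([int(seed), r])
        bmi = np.concatenate(
            [rng.normal(mean1, sd1, n1), rng.normal(mean2, sd2, n2)]
        )
        dos = pd.DataFrame(
            rng.binomial(2, eaf, size=(n, len(eaf))).astype(float),
            columns=weights["variant_id"],
        )
        w2, d2 = recode_to_increasing_allele(weights, dos)
        grs = compute_weighted_grs(d2, w2).scores.to_numpy()
        y = (
            inverse_normal_transform(bmi)
            if spec.outcome == "bmi_int"
            else bmi
        )
        beta, se, p = _fit_interaction_arrays(
            np.asarray(y, float), grs, e, np.empty((n, 0)), [], keller=False
        )
        ps[r] = p
        runs.append(
            NegativeControlRun(
                replicate=r,
                group1_ids=np.arange(n1),
                group2_ids=np.arange(n1, n),
                mean1=float(bmi[:n1].mean()),
                sd1=float(bmi[:n1].std(ddof=1)),
                mean2=float(bmi[n1:].mean()),
                sd2=float(bmi[n1:].std(ddof=1)),
                beta_int=beta,
                se_int=se,
                p_int=p,
                iterations=0,
                converged=True,
            )
        )
    med_idx, med_p = median_replicate(ps)
    obs = float(observed_p) if observed_p is not None else float("nan")
    count_below = int((ps < obs).sum()) if np.isfinite(obs) else 0
    return NegativeControlSummary(
        R=R,
        observed_p=obs,
        count_below=count_below,
        empirical_p=empirical_p(count_below, R) if np.isfinite(obs) else float("nan"),
        median_p=med_p,
        median_replicate=med_idx,
        replicate_ps=ps,
        runs=runs,
        meta={"mode": "summary", "n1": n1, "n2": n2},
    )
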