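"""Permutation and bootstrap tests for quantile-step information loss.

Stepping the removal quantile from q_k to q_{k+1} discards the next band of
low-degree taxa and increases the information loss by Δ_{k+1} = Λ_{k+1} − Λ_k.
The question is whether that increase reflects real shared information or
just the baseline Frobenius mass any taxa carry.  Two one-sided tests of
H0: Λ_k = Λ_{k+1} are provided.

Permutation test
    The null model destroys all between-taxon association: each taxon's
    counts are independently shuffled across samples, the adjusted-MI
    network, weighted degrees and the same quantile step are recomputed, and
    the resampled Δ* collected.  On association-free data a removal step
    costs only the near-diagonal mass of the matrix, so steps that discard
    genuinely connected taxa produce Δ far in the upper tail.  Because the
    shuffle operates on whole columns, the test is exact under taxon
    independence (exchangeability), which gives type-I control on null data.

Bootstrap test
    The studentised statistic t_k of Δ_{k+1} (normalised by covariance-matrix
    norms of the two retained column sets) is compared against its bootstrap
    distribution under resampling columns with replacement from the pooled
    retained sets, recentred at the observed difference.

Both use the (count + 1)/(total + 1) p-value convention, so with 500
resamples the smallest reportable p is 1/501 (< 0.002) and the largest is
exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mi import (
    AdjustedMIMatrix,
    DiscretizationScheme,
    adjusted_mi_from_labels,
    adjusted_mi_matrix,
    label_matrix,
)
from .loss import _loss_from_retained, default_quantile_grid
from .table import CountTable

__all__ = [
    "StepTestResult",
    "StepScan",
    "permutation_step_test",
    "bootstrap_step_test",
    "scan_steps",
]


@dataclass(frozen=True)
class StepTestResult:
    step: tuple[float, float]
    method: str                   # "permutation" | "bootstrap"
    observed: float               # Δ_{k+1} or t_k
    n_resamples: int
    p_value: float
    alpha: float
    reject: bool
    degenerate: bool = False
    n_removed: tuple[int, int] = (0, 0)   # (r_k, r_{k+1})


@dataclass(frozen=True)
class StepScan:
    """Both tests on every adjacent quantile pair, plus a removal recommendation."""

    results: pd.DataFrame
    recommended_quantile: float
    decision_test: str
    alpha: float
    seed: int | None
    step_results: tuple[StepTestResult, ...] = field(default=(), repr=False)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _degrees(values: np.ndarray) -> np.ndarray:
    return values.sum(axis=1) - np.diag(values)


def _step_state(values: np.ndarray, q_lo: float, q_hi: float):
    """Retained index sets and losses at the two quantiles of one matrix."""
    from .loss import _removed_mask

    d = _degrees(values)
    ret = [np.flatnonzero(~_removed_mask(d, q)) for q in (q_lo, q_hi)]
    lam_lo = _loss_from_retained(values, ret[0])
    lam_hi = _loss_from_retained(values, ret[1])
    return ret[0], ret[1], lam_lo, lam_hi


def _permute_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently shuffle each column across samples."""
    idx = np.argsort(rng.random(labels.shape), axis=0)
    return np.take_along_axis(labels, idx, axis=0)


def _p_value(count_ge: int, n_resamples: int) -> float:
    return (1 + count_ge) / (n_resamples + 1)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _null_step_deltas(
    labels: np.ndarray,
    steps: list[tuple[float, float]],
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Δ* for every requested step under column-shuffle resampling.

    One permuted network serves all steps, keeping the scan-wide null
    consistent and the cost at one adjacency estimate per resample.
    """
    out = np.empty((n_resamples, len(steps)))
    for b in range(n_resamples):
        vals = adjusted_mi_from_labels(_permute_labels(labels, rng))
        d = _degrees(vals)
        quantiles = {q for pair in steps for q in pair}
        from .loss import _removed_mask

        lam = {
            q: _loss_from_retained(vals, np.flatnonzero(~_removed_mask(d, q)))
            for q in quantiles
        }
        out[b] = [lam[hi] - lam[lo] for lo, hi in steps]
    return out


def permutation_step_test(
    table: CountTable,
    q_lo: float,
    q_hi: float,
    *,
    scheme: DiscretizationScheme | None = None,
    adj: AdjustedMIMatrix | None = None,
    n_resamples: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> StepTestResult:
    """One-sided permutation test of the loss increment over (q_lo, q_hi).

    If no taxa fall between the two quantiles the step is degenerate and
    reported with p = 1.
    """
    if q_lo >= q_hi:
        raise ValueError("need q_lo < q_hi")
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    scheme = scheme or (adj.scheme if adj is not None else DiscretizationScheme())
    labels = label_matrix(table, scheme)
    values = adj.values if adj is not None else adjusted_mi_from_labels(labels)
    ret_lo, ret_hi, lam_lo, lam_hi = _step_state(values, q_lo, q_hi)
    r_lo = values.shape[0] - ret_lo.size
    r_hi = values.shape[0] - ret_hi.size
    observed = lam_hi - lam_lo
    if r_hi == r_lo:
        return StepTestResult(
            (q_lo, q_hi), "permutation", observed, n_resamples, 1.0, alpha,
            reject=False, degenerate=True, n_removed=(r_lo, r_hi),
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    deltas = _null_step_deltas(labels, [(q_lo, q_hi)], n_resamples, rng)[:, 0]
    p = _p_value(int((deltas >= observed).sum()), n_resamples)
    return StepTestResult(
        (q_lo, q_hi), "permutation", observed, n_resamples, p, alpha,
        reject=p < alpha, n_removed=(r_lo, r_hi),
    )


# ---------------------------------------------------------------------------
# bootstrap test
# ---------------------------------------------------------------------------


def _sigma_norm_sq(cov: np.ndarray, norm: str) -> float:
    if norm == "frobenius":
        return float((cov ** 2).sum())
    if norm == "spectral":
        return float(np.linalg.norm(np.atleast_2d(cov), 2) ** 2)
    raise ValueError(f"unknown matrix norm {norm!r}")


def bootstrap_step_test(
    table: CountTable,
    q_lo: float,
    q_hi: float,
    *,
    scheme: DiscretizationScheme | None = None,
    adj: AdjustedMIMatrix | None = None,
    n_resamples: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    norm: str = "frobenius",
    relative_abundance: bool = False,
) -> StepTestResult:
    """One-sided bootstrap test of the studentised loss increment.

    Resamples draw m_k + m_{k+1} columns with replacement from the pooled
    retained sets; the first m_k form Z*, the rest Y*.  Pairwise adjusted MI
    and covariance depend only on the pair of original columns, so resampled
    matrices are exact principal "submatrices with repetition" of the full
    ones — the resample loop is pure index arithmetic.  Resamples with
    constant columns are retained (their MI rows are zero by the degenerate
    rule), not redrawn.
    """
    if q_lo >= q_hi:
        raise ValueError("need q_lo < q_hi")
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    scheme = scheme or (adj.scheme if adj is not None else DiscretizationScheme())
    if adj is None:
        adj = adjusted_mi_matrix(table, scheme)
    values = adj.values
    ret_lo, ret_hi, lam_lo, lam_hi = _step_state(values, q_lo, q_hi)
    m_lo, m_hi = ret_lo.size, ret_hi.size
    if m_lo < 2 or m_hi < 2:
        raise ValueError(
            f"retained sets too small for the bootstrap: "
            f"{m_lo} at q={q_lo}, {m_hi} at q={q_hi}"
        )
    X = table.values.astype(float)
    if relative_abundance:
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        X = X / totals
    cov_full = np.cov(X, rowvar=False)
    s_lo = _sigma_norm_sq(cov_full[np.ix_(ret_lo, ret_lo)], norm)
    s_hi = _sigma_norm_sq(cov_full[np.ix_(ret_hi, ret_hi)], norm)
    denom = np.sqrt(s_hi / m_hi + s_lo / m_lo)
    if denom == 0.0:
        raise ValueError(
            f"covariance norms vanish for both retained sets "
            f"(q={q_lo}: {m_lo} taxa, q={q_hi}: {m_hi} taxa); "
            "the subsets are degenerate (constant columns)"
        )
    observed_delta = lam_hi - lam_lo
    t_obs = observed_delta / denom

    pool = np.concatenate([ret_lo, ret_hi])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    count_ge = 0
    for _ in range(n_resamples):
        cols = pool[rng.integers(0, pool.size, pool.size)]
        z, y = cols[:m_lo], cols[m_lo:]
        denom_n = float((values[np.ix_(cols, cols)] ** 2).sum())
        lam_z = 1.0 - float((values[np.ix_(z, z)] ** 2).sum()) / denom_n
        lam_y = 1.0 - float((values[np.ix_(y, y)] ** 2).sum()) / denom_n
        s_z = _sigma_norm_sq(cov_full[np.ix_(z, z)], norm)
        s_y = _sigma_norm_sq(cov_full[np.ix_(y, y)], norm)
        d = np.sqrt(s_y / m_hi + s_z / m_lo)
        if d == 0.0:
            count_ge += 1  # fully degenerate resample: count conservatively
            continue
        t_star = (lam_y - lam_z - observed_delta) / d
        if t_star >= t_obs:
            count_ge += 1
    p = _p_value(count_ge, n_resamples)
    return StepTestResult(
        (q_lo, q_hi), "bootstrap", t_obs, n_resamples, p, alpha,
        reject=p < alpha, degenerate=m_lo == m_hi,
        n_removed=(values.shape[0] - m_lo, values.shape[0] - m_hi),
    )


# ---------------------------------------------------------------------------
# grid scan
# ---------------------------------------------------------------------------


def scan_steps(
    table: CountTable,
    *,
    scheme: DiscretizationScheme | None = None,
    adj: AdjustedMIMatrix | None = None,
    grid: np.ndarray | None = None,
    n_permutations: int = 500,
    n_bootstrap: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    decision_test: str = "permutation",
) -> StepScan:
    """Run both step tests on every adjacent quantile pair.

    The recommended removal level is the largest q_k such that no step up to
    and including (q_{k−1}, q_k) rejects under ``decision_test``; if every
    step is degenerate (uniform degrees) the highest grid value is
    recommended with a warning.
    """
    if decision_test not in ("permutation", "bootstrap"):
        raise ValueError("decision_test must be 'permutation' or 'bootstrap'")
    grid = default_quantile_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("need at least two grid points to form steps")
    scheme = scheme or (adj.scheme if adj is not None else DiscretizationScheme())
    labels = label_matrix(table, scheme)
    if adj is None:
        adj = AdjustedMIMatrix(adjusted_mi_from_labels(labels), table.taxon_ids, scheme)
    values = adj.values
    steps = list(zip(grid[:-1], grid[1:]))

    # observed increments
    obs_rows = [_step_state(values, lo, hi) for lo, hi in steps]
    m = values.shape[0]
    observed = np.array([hi_l - lo_l for _, _, lo_l, hi_l in obs_rows])
    r_lo = np.array([m - row[0].size for row in obs_rows])
    r_hi = np.array([m - row[1].size for row in obs_rows])
    degenerate = r_lo == r_hi

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rng_perm, rng_boot = (np.random.default_rng(s) for s in ss.spawn(2))

    # shared permutation null across steps
    null_deltas = _null_step_deltas(labels, steps, n_permutations, rng_perm)
    p_perm = np.array(
        [
            1.0 if degenerate[s]
            else _p_value(int((null_deltas[:, s] >= observed[s]).sum()), n_permutations)
            for s in range(len(steps))
        ]
    )

    results: list[StepTestResult] = []
    p_boot = np.empty(len(steps))
    for s, (lo, hi) in enumerate(steps):
        perm_res = StepTestResult(
            (lo, hi), "permutation", observed[s], n_permutations, p_perm[s], alpha,
            reject=p_perm[s] < alpha and not degenerate[s],
            degenerate=bool(degenerate[s]), n_removed=(int(r_lo[s]), int(r_hi[s])),
        )
        boot_res = bootstrap_step_test(
            table, lo, hi, scheme=scheme, adj=adj,
            n_resamples=n_bootstrap, alpha=alpha, seed=rng_boot,
        )
        p_boot[s] = boot_res.p_value
        results.extend([perm_res, boot_res])

    reject_perm = (p_perm < alpha) & ~degenerate
    reject_boot = (p_boot < alpha) & ~degenerate
    reject = reject_perm if decision_test == "permutation" else reject_boot
    if degenerate.all():
        warnings.warn(
            "all quantile steps are degenerate (uniform degrees); "
            "recommending the highest grid value",
            stacklevel=2,
        )
        recommended = float(grid[-1])
    elif reject.any():
        recommended = float(steps[int(np.argmax(reject))][0])
    else:
        recommended = float(grid[-1])

    frame = pd.DataFrame(
        {
            "step_lo": [lo for lo, _ in steps],
            "step_hi": [hi for _, hi in steps],
            "n_removed_lo": r_lo,
            "n_removed_hi": r_hi,
            "delta": observed,
            "p_perm": p_perm,
            "p_boot": p_boot,
            "reject_perm": reject_perm,
            "reject_boot": reject_boot,
            "degenerate": degenerate,
        }
    )
    return StepScan(frame, recommended, decision_test, alpha, seed, tuple(results))
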