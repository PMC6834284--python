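"""Minimum-p-value survival screening with an empirically calibrated null.

The screen dichotomizes each expression feature at every rank split whose
low-group size k lies in ``floor(l*s) .. floor(h*s)`` (default percentile
range 0.15-0.85), takes the minimum logrank p over the sweep, and converts
it to a valid p-value against a single Monte-Carlo null shared by all
features: the distribution of the same minimum over random orderings of the
patients. Because only the patient ranking of a feature matters, one null
serves every eligible feature of a cohort.

The sweep is evaluated incrementally: for a fixed cohort the death times,
at-risk totals and per-death variance factors are precomputed once, and the
low-group at-risk counts for all k are cumulative sums along the candidate
ordering. Batches of orderings are processed as one 3-d array, which keeps
a full run (hundreds of patients, thousands of features, tens of thousands
of null sweeps) at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata, spearmanr

from .cohort import AbundanceMatrix, ClinicalCohort
from .survival import DEFAULT_HORIZONS, group_effect

__all__ = [
    "NullSpec", "NullDistribution", "ScanResult", "CohortSweep",
    "threshold_scan", "null_size", "build_null", "empirical_p", "bh_adjust",
    "run_neep", "plan_null", "robustness_simulation", "expression_split",
    "min_low_group_for_power", "save_null", "load_null",
    "RESULT_COLUMNS",
]

_P_FLOOR = np.finfo(float).tiny
_V_ATOL = 1e-12
# guards binary-float artifacts in l*s / h*s before flooring
_FLOOR_EPS = 1e-9


def _floor_frac(x: float) -> int:
    return int(math.floor(x + _FLOOR_EPS))


@dataclass(frozen=True)
class NullSpec:
    """Parameters a null distribution was built under."""

    s: int          # number of patients
    l: float        # lower percentile bound (default 0.15)
    h: float        # upper percentile bound (default 0.85)
    n_sims: int     # Monte-Carlo sweep count
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.l < self.h < 1:
            raise ValueError("need 0 < l < h < 1")
        if _floor_frac(self.l * self.s) < 1:
            raise ValueError("floor(l*s) must be >= 1")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class NullDistribution:
    """Sorted minimum-p values from Monte-Carlo null sweeps."""

    values: np.ndarray
    spec: NullSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.spec.n_sims:
            raise ValueError("null length does not match its spec")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("null values must be sorted ascending")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ValueError("null values must lie in (0, 1]")


class CohortSweep:
    """Precomputed logrank sweep over all rank splits of a fixed cohort.

    For an ordering of the patients and each low-group size k in the scan
    range, computes the logrank chi-square of "first k vs rest". All
    split-invariant quantities (death times t_j, deaths d_j, overall
    at-risk n_j, the cumulative E-increment sum_{t_j <= t} d_j/n_j and the
    variance factor c_j = d_j (n_j - d_j) / (n_j^2 (n_j - 1))) are computed
    once; per ordering only cumulative sums remain.
    """

    def __init__(self, time, event, l: float = 0.15, h: float = 0.85):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=np.int8)
        s = time.size
        if s < 2:
            raise ValueError("need at least two patients")
        if not 0 < l < h < 1:
            raise ValueError("need 0 < l < h < 1")
        k_lo = _floor_frac(l * s)
        k_hi = min(_floor_frac(h * s), s - 1)
        if k_lo < 1 or k_lo > k_hi:
            raise ValueError(f"empty threshold range for s={s}, l={l}, h={h}")
        if event.sum() == 0:
            raise ValueError("cohort has no deaths; logrank sweep undefined")

        death_times = np.unique(time[event == 1])
        d = np.array([np.sum((time == t) & (event == 1)) for t in death_times],
                     dtype=float)
        n_risk = np.array([np.sum(time >= t) for t in death_times], dtype=float)
        # number of death times <= time_i; patient i is at risk at death j
        # iff j < idx_i (0-based), censoring tied with a death stays at risk
        idx = np.searchsorted(death_times, time, side="right")
        self._R = np.arange(death_times.size)[None, :] < idx[:, None]
        self._e1add = np.concatenate(([0.0], np.cumsum(d / n_risk)))[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = d * (n_risk - d) / (n_risk ** 2 * (n_risk - 1))
        c[n_risk <= 1] = 0.0
        self._c = c
        self._n_risk = n_risk
        self._event = event.astype(float)
        self.s = s
        self.l, self.h = l, h
        self.k_lo, self.k_hi = k_lo, k_hi
        self.k_grid = np.arange(k_lo, k_hi + 1)
        self.n_death_times = int(death_times.size)

    def statistics(self, orders: np.ndarray) -> np.ndarray:
        """Chi-square statistics, shape (batch, len(k_grid)).

        ``orders`` is an integer array (batch, s); row b lists patient
        indices from lowest to highest candidate expression. Splits with
        (numerically) zero variance get statistic 0.
        """
        orders = np.atleast_2d(np.asarray(orders))
        if orders.shape[1] != self.s:
            raise ValueError("ordering length does not match cohort size")
        Rp = self._R[orders]                                  # (B, s, J)
        N1 = np.cumsum(Rp, axis=1, dtype=np.float64)
        O1 = np.cumsum(self._event[orders], axis=1)
        E1 = np.cumsum(self._e1add[orders], axis=1)
        V = np.einsum("bkj,j->bk", N1 * (self._n_risk - N1), self._c)
        sl = slice(self.k_lo - 1, self.k_hi)
        V = V[:, sl]
        num = (O1[:, sl] - E1[:, sl]) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(V > _V_ATOL, num / np.where(V > _V_ATOL, V, 1.0), 0.0)
        return stat

    def pvalues(self, orders: np.ndarray) -> np.ndarray:
        """Logrank p-values per split, shape (batch, len(k_grid))."""
        stat = self.statistics(orders)
        return np.maximum(_chi2.sf(stat, 1), _P_FLOOR)

    def min_p(self, orders: np.ndarray) -> np.ndarray:
        """Minimum p over the scan range for each ordering in the batch."""
        stat = self.statistics(orders)
        return np.maximum(_chi2.sf(stat.max(axis=1), 1), _P_FLOOR)


@dataclass(frozen=True)
class ScanResult:
    feature_id: str | None
    min_p: float
    k_star: int
    p_by_k: np.ndarray
    k_grid: np.ndarray


def _expression_order(x: np.ndarray, patient_ids: np.ndarray) -> np.ndarray:
    """Ascending order by abundance, ties broken by patient id (stable and
    deterministic, hence permutation-exchangeable)."""
    return np.lexsort((np.asarray(patient_ids, dtype=object), x))


def threshold_scan(x, cohort: ClinicalCohort, l: float = 0.15,
                   h: float = 0.85, sweep: CohortSweep | None = None,
                   feature_id: str | None = None) -> ScanResult:
    """Sweep every allowed low/high split of one feature.

    Patients are sorted by abundance (ties broken by patient id); for each
    low-group size k in ``floor(l*s) .. floor(h*s)`` the logrank test
    compares the k lowest-expressing patients against the rest. Returns the
    minimum p, the achieving k (smallest on ties) and the full p vector.
    """
    x = np.asarray(x, dtype=float)
    if x.size != cohort.n:
        raise ValueError("abundance vector not aligned to cohort")
    if np.all(x == x[0]):
        raise ValueError("constant feature has no informative split")
    if sweep is None:
        sweep = CohortSweep(cohort.time, cohort.event, l, h)
    order = _expression_order(x, cohort.patient_ids)
    p_by_k = sweep.pvalues(order[None, :])[0]
    j = int(np.argmin(p_by_k))           # first occurrence = smallest k
    return ScanResult(feature_id, float(p_by_k[j]), int(sweep.k_grid[j]),
                      p_by_k, sweep.k_grid.copy())


def null_size(s: int, l: float = 0.15, h: float = 0.85) -> int:
    """Exact number of distinct low/high partitions in the scan range:
    sum_{i=floor(l*s)}^{floor(h*s)} C(s, i) (arbitrary precision)."""
    k_lo = _floor_frac(l * s)
    k_hi = _floor_frac(h * s)
    if k_lo < 1 or k_lo > k_hi:
        raise ValueError("empty threshold range")
    return sum(math.comb(s, i) for i in range(k_lo, k_hi + 1))


def build_null(cohort: ClinicalCohort, l: float = 0.15, h: float = 0.85,
               n_sims: int = 1_000_000, seed: int = 0,
               batch: int | None = None) -> NullDistribution:
    """Monte-Carlo null of the minimum logrank p over the threshold sweep.

    Each simulation draws one uniform-random ordering of the patients and
    sweeps every allowed split exactly as :func:`threshold_scan` does.
    Orderings are realized as argsorts of iid uniforms, so the output is a
    pure function of ``(cohort, l, h, n_sims, seed)`` regardless of the
    internal batch size.
    """
    sweep = CohortSweep(cohort.time, cohort.event, l, h)
    rng = np.random.default_rng(seed)
    if batch is None:
        batch = max(1, int(4_000_000 / max(1, sweep.s * sweep.n_death_times)))
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        b = min(batch, n_sims - done)
        orders = np.argsort(rng.random((b, sweep.s)), axis=1)
        out[done:done + b] = sweep.min_p(orders)
        done += b
    out.sort()
    return NullDistribution(out, NullSpec(sweep.s, l, h, n_sims, seed))


def empirical_p(min_p, null: NullDistribution, mode: str = "plus-one"):
    """Calibrate minimum p-values against the shared null.

    With r = #{null values <= min_p} and N the null size:

    * ``"plus-one"`` (default): (r + 1) / (N + 1) — strictly positive, the
      standard conservative permutation-test estimator;
    * ``"plain"``: r / N, with r = 0 reported as 1/N (the method's original
      estimator; zero is replaced to keep downstream adjustment defined).

    Accepts a scalar or an array; monotone non-decreasing in ``min_p``, so
    feature ranking by calibrated p equals ranking by raw minimum p.
    """
    arr = np.atleast_1d(np.asarray(min_p, dtype=float))
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("min_p must lie in (0, 1]")
    r = np.searchsorted(null.values, arr, side="right").astype(float)
    n = null.spec.n_sims
    if mode == "plus-one":
        p = (r + 1.0) / (n + 1.0)
    elif mode == "plain":
        p = np.where(r == 0, 1.0 / n, r / n)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(p[0]) if np.isscalar(min_p) or np.ndim(min_p) == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


RESULT_COLUMNS = [
    "feature_id", "k_star", "low_n", "high_n", "min_p", "neep_p", "q_value",
    "significant", "hazard_ratio", "mort_low_1y", "mort_low_2y", "mort_low_5y",
    "mort_high_1y", "mort_high_2y", "mort_high_5y",
]


def run_neep(matrix: AbundanceMatrix, cohort: ClinicalCohort,
             l: float = 0.15, h: float = 0.85, n_sims: int = 100_000,
             seed: int = 0, fdr: float = 0.1, mode: str = "plus-one",
             horizons: Sequence[float] = DEFAULT_HORIZONS,
             null: NullDistribution | None = None) -> pd.DataFrame:
    """Screen every feature of ``matrix`` against ``cohort``.

    One shared null serves all features. Per feature: threshold sweep ->
    minimum p -> calibrated p against the null -> BH adjustment across all
    tested features -> effect sizes at the optimal split. The returned
    frame is sorted by calibrated p then feature id; feature ordering does
    not depend on the null (only significance calls do).
    """
    matrix = matrix.align_to(cohort)
    if null is None:
        null = build_null(cohort, l, h, n_sims=n_sims, seed=seed)
    else:
        if null.spec.s != cohort.n or null.spec.l != l or null.spec.h != h:
            raise ValueError("supplied null was built under different parameters")
    sweep = CohortSweep(cohort.time, cohort.event, l, h)

    values = matrix.data.to_numpy(dtype=float)
    rows = []
    for fid, x in zip(matrix.feature_ids, values):
        scan = threshold_scan(x, cohort, l, h, sweep=sweep, feature_id=fid)
        order = _expression_order(x, cohort.patient_ids)
        low, high = order[:scan.k_star], order[scan.k_star:]
        eff = group_effect((cohort.time[low], cohort.event[low]),
                           (cohort.time[high], cohort.event[high]),
                           horizons=horizons)
        rows.append((fid, scan.k_star, len(low), len(high), scan.min_p,
                     eff.hazard_ratio, eff.mortality_low, eff.mortality_high))

    frame = pd.DataFrame({
        "feature_id": [r[0] for r in rows],
        "k_star": [r[1] for r in rows],
        "low_n": [r[2] for r in rows],
        "high_n": [r[3] for r in rows],
        "min_p": [r[4] for r in rows],
        "hazard_ratio": [r[5] for r in rows],
    })
    for j, suffix in enumerate(("1y", "2y", "5y")):
        frame[f"mort_low_{suffix}"] = [r[6][j] for r in rows]
        frame[f"mort_high_{suffix}"] = [r[7][j] for r in rows]
    frame["neep_p"] = empirical_p(frame["min_p"].to_numpy(), null, mode=mode)
    frame["q_value"] = bh_adjust(frame["neep_p"].to_numpy())
    frame["significant"] = frame["q_value"] < fdr
    frame = frame.sort_values(["neep_p", "feature_id"], kind="stable")
    return frame[RESULT_COLUMNS].reset_index(drop=True)


def plan_null(m_features: int, multiplier: int = 10) -> tuple[int, float]:
    """Null-size planning: with N = multiplier * m_features simulations the
    probability that two adjacent sorted calibrated p-values are distinct
    is approximately 1 - m_features / N.

    Returns ``(N, distinct_probability)``; the exact product is returned
    (callers may round up for convenience).
    """
    if m_features < 1 or multiplier < 1:
        raise ValueError("m_features and multiplier must be >= 1")
    n = m_features * multiplier
    return n, 1.0 - m_features / n


def expression_split(x, patient_ids, k: int) -> tuple[list, list]:
    """Low/high patient-id lists for a split at low-group size ``k``,
    under the screen's deterministic ordering."""
    x = np.asarray(x, dtype=float)
    ids = np.asarray(patient_ids, dtype=object)
    order = _expression_order(x, ids)
    return list(ids[order[:k]]), list(ids[order[k:]])


def robustness_simulation(matrix: AbundanceMatrix, cohort: ClinicalCohort,
                          l: float = 0.15, h: float = 0.85,
                          fraction: float = 0.05, n_sims: int = 100,
                          seed: int = 0) -> tuple[pd.DataFrame, float]:
    """Rank stability of the screen under random patient removal.

    Each simulation removes ``floor(fraction * s)`` patients uniformly at
    random, reruns the threshold sweep for every feature on the reduced
    cohort, and ranks features by minimum p (average ranks on ties).
    Returns the per-simulation rank table (one row per simulation, one
    column per feature) and the mean Spearman correlation against the
    full-data ranks. Ranks, not p-values, are compared so that the smaller
    sample size does not masquerade as instability.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    matrix = matrix.align_to(cohort)
    values = matrix.data.to_numpy(dtype=float)
    ids = matrix.feature_ids

    def _min_p_vector(sub: ClinicalCohort, cols: np.ndarray) -> np.ndarray:
        sweep = CohortSweep(sub.time, sub.event, l, h)
        out = np.empty(len(ids))
        for i, x in enumerate(values[:, cols]):
            order = _expression_order(x, sub.patient_ids)
            out[i] = sweep.min_p(order[None, :])[0]
        return out

    all_cols = np.arange(cohort.n)
    full = _min_p_vector(cohort, all_cols)
    full_ranks = rankdata(full)

    rng = np.random.default_rng(seed)
    n_remove = int(math.floor(fraction * cohort.n))
    rank_rows, rhos = [], []
    for _ in range(n_sims):
        keep = np.sort(rng.choice(cohort.n, size=cohort.n - n_remove,
                                  replace=False))
        sub = cohort.subset(np.isin(all_cols, keep))
        sim = _min_p_vector(sub, keep)
        sim_ranks = rankdata(sim)
        rank_rows.append(sim_ranks)
        if np.ptp(full_ranks) == 0 or np.ptp(sim_ranks) == 0:
            rhos.append(np.nan)
        elif np.array_equal(sim_ranks, full_ranks):
            rhos.append(1.0)  # spearmanr is exact here; skip the call
        else:
            rhos.append(float(spearmanr(full_ranks, sim_ranks).statistic))
    table = pd.DataFrame(rank_rows, columns=ids)
    mean_rho = float(np.nanmean(rhos)) if rhos else float("nan")
    return table, mean_rho


def min_low_group_for_power(n_events: int, hazard_ratio: float = 2.0,
                            alpha: float = 0.1, power: float = 0.75,
                            two_sided: bool = True) -> float:
    """Approximate smallest group size with adequate logrank power.

    Uses the Schoenfeld approximation: the required number of events for a
    logrank test at allocation fraction p is
    ``D = (z_alpha + z_power)^2 / (p (1-p) log(HR)^2)``; solving
    ``p (1-p) >= (z_alpha + z_power)^2 / (D log(HR)^2)`` for the smaller
    root gives the minimum allocation fraction, returned as a fraction of
    the cohort. This is an approximation (the screen's own calibration does
    not depend on it); it exists to help choose the lower percentile bound.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    if hazard_ratio <= 0 or hazard_ratio == 1:
        raise ValueError("hazard_ratio must be positive and != 1")
    za = _norm.ppf(1 - alpha / (2 if two_sided else 1))
    zb = _norm.ppf(power)
    rhs = (za + zb) ** 2 / (n_events * math.log(hazard_ratio) ** 2)
    if rhs > 0.25:
        raise ValueError("requested power unattainable at any allocation")
    p_min = 0.5 - math.sqrt(0.25 - rhs)
    return p_min


def save_null(null: NullDistribution, path) -> None:
    """Persist a null distribution as TSV (spec header + sorted values)."""
    with open(path, "w") as fh:
        spec = null.spec
        fh.write(f"# s={spec.s}\tl={spec.l}\th={spec.h}"
                 f"\tn_sims={spec.n_sims}\tseed={spec.seed}\n")
        for v in null.values:
            fh.write(f"{v:.17g}\n")


def load_null(path) -> NullDistribution:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing null spec header line")
        fields = dict(item.split("=") for item in header[1:].split())
        spec = NullSpec(s=int(fields["s"]), l=float(fields["l"]),
                        h=float(fields["h"]), n_sims=int(fields["n_sims"]),
                        seed=int(fields["seed"]))
        values = np.array([float(line) for line in fh if line.strip()])
    return NullDistribution(values, spec)
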