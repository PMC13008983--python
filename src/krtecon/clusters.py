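"""Break-even performance clusters and their 2019 -> 2023 transition dynamics.

Countries are assigned to three payback-speed clusters by fixed break-even
thresholds with half-open intervals:

    A ("efficient")   BE in [0, 2.5) years
    B ("stable")      BE in [2.5, 4.0)
    C ("stressed")    BE in [4.0, inf)

A 3x3 transition matrix counts movements between the two observation years.
Chance-corrected temporal agreement is Cohen's kappa,
kappa = (p0 - pe)/(1 - pe) with p0 the diagonal share and pe the expected
agreement from the marginals.  Movement to a later letter (above the
diagonal) is "deterioration", to an earlier letter "improvement"; a zero
C -> A conditional probability is the "topological trap" signature.  The
stability rate is tested against a permutation null that shuffles the
second-year labels uniformly, preserving their multiset — under that scheme
the analytic null mean of matched labels is sum_i (r_i * c_i) / N^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLUSTER_LABELS",
    "DEFAULT_THRESHOLDS",
    "TransitionMatrix",
    "KappaResult",
    "TransitionStats",
    "StabilityTestResult",
    "assign_cluster",
    "assign_clusters",
    "transition_matrix",
    "cohen_kappa",
    "transition_stats",
    "permutation_stability_test",
]

CLUSTER_LABELS = ("A", "B", "C")
DEFAULT_THRESHOLDS = (2.5, 4.0)


def assign_cluster(be: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Map a break-even time (years) to its cluster label.

    Boundary convention: [0, t1) -> A, [t1, t2) -> B, [t2, inf) -> C, so a
    break-even exactly at 2.5 is B and exactly at 4.0 is C.
    """
    if not np.isfinite(be) or be < 0:
        raise ValueError(f"break-even must be finite and >= 0, got {be}")
    t1, t2 = thresholds
    if be < t1:
        return "A"
    if be < t2:
        return "B"
    return "C"


def assign_clusters(
    be_values, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> pd.Series:
    values = pd.Series(be_values)
    return values.map(lambda b: assign_cluster(b, thresholds))


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 counts; rows = first-year cluster, columns = second-year cluster."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLUSTER_LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the cluster labels")
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Printed layout with marginal totals."""
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df["Total"] = self.row_totals
        df.loc["Total"] = list(self.col_totals) + [self.n]
        return df


def transition_matrix(
    assignments_first: pd.Series, assignments_second: pd.Series
) -> TransitionMatrix:
    """Cross-tabulate per-country cluster labels between the two years.

    Both inputs are indexed by country; the country sets must match.
    """
    a1 = pd.Series(assignments_first)
    a2 = pd.Series(assignments_second)
    if set(a1.index) != set(a2.index):
        raise ValueError("country sets differ between the two years")
    a2 = a2.reindex(a1.index)
    k = len(CLUSTER_LABELS)
    counts = np.zeros((k, k), dtype=int)
    pos = {lab: i for i, lab in enumerate(CLUSTER_LABELS)}
    for lab1, lab2 in zip(a1, a2):
        counts[pos[lab1], pos[lab2]] += 1
    return TransitionMatrix(counts=counts)


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    p0: float
    pe: float
    defined: bool
    interpretation: str


_KAPPA_BANDS = [
    (0.0, "less than chance"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (np.inf, "almost perfect"),
]


def _interpret_kappa(kappa: float) -> str:
    if kappa < 0:
        return "less than chance"
    for upper, label in _KAPPA_BANDS[1:]:
        if kappa < upper:
            return label
    return "almost perfect"


def cohen_kappa(tm: TransitionMatrix) -> KappaResult:
    """Chance-corrected agreement between the two years' assignments.

    p0 = sum_i t_ii / N, pe = sum_i (row_i * col_i) / N^2,
    kappa = (p0 - pe)/(1 - pe).  pe = 1 leaves kappa undefined (flagged).
    """
    n = tm.n
    if n == 0:
        raise ValueError("empty transition matrix")
    p0 = float(np.trace(tm.counts)) / n
    pe = float(np.sum(tm.row_totals * tm.col_totals)) / n**2
    if pe == 1.0:
        return KappaResult(kappa=None, p0=p0, pe=pe, defined=False,
                           interpretation="undefined (pe = 1)")
    kappa = (p0 - pe) / (1.0 - pe)
    return KappaResult(kappa=float(kappa), p0=p0, pe=pe, defined=True,
                       interpretation=_interpret_kappa(kappa))


@dataclass(frozen=True)
class TransitionStats:
    stability_rate: float
    deterioration: int
    improvement: int
    conditional: pd.DataFrame  # P(second-year = j | first-year = i); NaN rows for empty clusters


def transition_stats(tm: TransitionMatrix) -> TransitionStats:
    """Diagonal stability, above/below-diagonal flow counts, row conditionals."""
    n = tm.n
    if n == 0:
        raise ValueError("empty transition matrix")
    counts = tm.counts
    stability = float(np.trace(counts)) / n
    deterioration = int(np.triu(counts, k=1).sum())
    improvement = int(np.tril(counts, k=-1).sum())
    rows = tm.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = counts / rows[:, None]
    cond[rows == 0] = np.nan  # conditional undefined for empty initial cluster
    conditional = pd.DataFrame(cond, index=tm.labels, columns=tm.labels)
    return TransitionStats(
        stability_rate=stability,
        deterioration=deterioration,
        improvement=improvement,
        conditional=conditional,
    )


@dataclass(frozen=True)
class StabilityTestResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_one_tailed: float
    M: int
    seed: int


def permutation_stability_test(
    assignments_first: pd.Series,
    assignments_second: pd.Series,
    M: int = 10_000,
    seed: int = 0,
) -> StabilityTestResult:
    """Permutation null for the observed stability (diagonal) rate.

    The second-year labels are permuted uniformly across countries M times,
    preserving their multiset (hence the marginals); the one-tailed p-value
    is the share of null stability rates at or above the observed rate.
    The analytic null mean under this scheme is sum_i r_i c_i / N^2.
    """
    if M < 100:
        raise ValueError("M must be >= 100")
    a1 = pd.Series(assignments_first)
    a2 = pd.Series(assignments_second).reindex(a1.index)
    if a2.isna().any():
        raise ValueError("country sets differ between the two years")
    first = a1.to_numpy()
    second = a2.to_numpy()
    n = len(first)
    observed = float(np.mean(first == second))
    rng = np.random.default_rng(seed)
    null = np.empty(M)
    for m in range(M):
        null[m] = np.mean(first == rng.permutation(second))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    if null_sd == 0:
        raise ValueError("degenerate null distribution (all labels identical)")
    z = (observed - null_mean) / null_sd
    p = float(np.mean(null >= observed))
    return StabilityTestResult(
        observed=observed, null_mean=null_mean, null_sd=null_sd,
        z=float(z), p_one_tailed=p, M=M, seed=seed,
    )
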