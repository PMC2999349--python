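"""Two-class significance analysis for microarrays, implemented from scratch.

The detector computes a moderated t statistic per gene,

    d = (mean_treated − mean_control) / (s + s0),

where ``s`` is the pooled standard error of the mean difference and ``s0``
is a small "fudge factor" chosen from the percentiles of the ``s``
distribution to stabilise ``d`` for low-variance genes (Tusher-style
coefficient-of-variation minimisation).  Significance is evaluated by
balanced sample-label permutations: for a grid of displacement thresholds
``delta``, genes whose ordered ``d`` departs from its permutation
expectation by at least ``delta`` are called, the median count of null
statistics beyond the calling cutoffs estimates the false positives, and
the per-gene q-value is the lowest false discovery rate at which the gene
is called.

:class:`SAMTwoClass` wraps this as a scikit-learn style estimator
(``fit(X, y)`` with trailing-underscore fitted attributes); the module
functions below it are the individual algorithm steps and stay usable on
their own.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def _pooled_se(x_control: np.ndarray, x_treated: np.ndarray) -> np.ndarray:
    """Pooled standard error of the mean difference, per gene (rows)."""
    n_c, n_t = x_control.shape[1], x_treated.shape[1]
    ss_c = ((x_control - x_control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_t = ((x_treated - x_treated.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    factor = (1.0 / n_t + 1.0 / n_c) / (n_c + n_t - 2)
    return np.sqrt(factor * (ss_c + ss_t))


def sam_statistic(values_control, values_treated, s0: float) -> float | np.ndarray:
    """Moderated t statistic d = Δmean / (s + s0).

    Accepts 1-D arrays (one gene) or 2-D arrays (genes × replicates).
    Swapping the two groups negates ``d``.
    """
    x_c = np.atleast_2d(np.asarray(values_control, dtype=float))
    x_t = np.atleast_2d(np.asarray(values_treated, dtype=float))
    if x_c.shape[1] < 2 or x_t.shape[1] < 2:
        raise ValueError("need at least 2 replicates in each group")
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    num = x_t.mean(axis=1) - x_c.mean(axis=1)
    d = num / (_pooled_se(x_c, x_t) + s0)
    return float(d[0]) if np.asarray(values_control).ndim == 1 else d


def choose_s0(per_gene_s: np.ndarray, per_gene_d_numerators: np.ndarray) -> float:
    """Fudge factor from the percentile grid 0, 5, ..., 100 of ``s``.

    For each candidate s0 the genes are windowed into up to 100
    equal-occupancy groups by ``s``; the spread of ``d`` in each window is
    summarised by a scaled MAD, and the candidate minimising the
    coefficient of variation of those spreads is chosen (ties toward the
    smaller percentile).  The result scales linearly with the data scale.
    """
    s = np.asarray(per_gene_s, dtype=float)
    num = np.asarray(per_gene_d_numerators, dtype=float)
    if s.shape != num.shape:
        raise ValueError("s and numerators must align")
    n = s.size
    if n < 100:
        warnings.warn("fewer than 100 genes: s0 selection is unstable", stacklevel=2)
    if np.allclose(s, s[0]):
        warnings.warn("all per-gene s identical; returning s0 = 0", stacklevel=2)
        return 0.0

    order = np.argsort(s, kind="stable")
    n_windows = min(100, max(2, n // 2))
    windows = np.array_split(order, n_windows)
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, percentiles)

    best_cv, best_s0 = np.inf, 0.0
    for s0 in candidates:
        d = num / (s + s0)
        spreads = []
        for w in windows:
            if w.size == 0:
                continue
            dw = d[w]
            spreads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        spreads = np.asarray(spreads)
        mean_v = spreads.mean()
        if mean_v == 0:
            continue
        cv = spreads.std(ddof=1) / mean_v
        if cv < best_cv - 1e-12:  # strict improvement: ties keep smaller percentile
            best_cv, best_s0 = cv, float(s0)
    return best_s0


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def balanced_assignments(
    n_samples: int,
    n_treated: int,
    observed: tuple[int, ...],
    n_permutations: int | str = "auto",
    max_permutations: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Label reassignments preserving group sizes, as a boolean matrix.

    Row b marks which samples play "treated" in permutation b.  When the
    number of distinct assignments C(n_samples, n_treated) is at most the
    budget, they are enumerated exhaustively (the observed labeling is one
    of them); otherwise the observed labeling plus a uniform sample of
    distinct assignments, seeded, is used.
    """
    from math import comb

    if isinstance(n_permutations, str):
        if n_permutations != "auto":
            raise ValueError("n_permutations must be an int or 'auto'")
        budget = max_permutations
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be ≥ 1")
        budget = int(n_permutations)

    total = comb(n_samples, n_treated)
    observed = tuple(sorted(observed))
    if total <= budget:
        combos = [tuple(c) for c in itertools.combinations(range(n_samples), n_treated)]
    else:
        rng = np.random.default_rng(seed)
        chosen = {observed}
        while len(chosen) < budget:
            pick = tuple(sorted(rng.permutation(n_samples)[:n_treated].tolist()))
            chosen.add(pick)
        combos = sorted(chosen)
    mask = np.zeros((len(combos), n_samples), dtype=bool)
    for b, c in enumerate(combos):
        mask[b, list(c)] = True
    return mask


def permutation_null(
    matrix: np.ndarray,
    treated_mask: np.ndarray,
    s0: float,
    n_permutations: int | str = "auto",
    seed: int | None = None,
    max_permutations: int = 1000,
) -> np.ndarray:
    """Null d distributions per balanced label permutation.

    Parameters
    ----------
    matrix : (n_genes, n_samples) log2 expression for control + one dose.
    treated_mask : boolean, the observed treated labels.
    s0 : the SAME fudge factor as the observed statistic.

    Returns a (n_permutations, n_genes) array of d statistics, one row per
    label assignment (unsorted gene order).
    """
    X = np.asarray(matrix, dtype=float)
    treated_mask = np.asarray(treated_mask, dtype=bool)
    n_samples = X.shape[1]
    n_t = int(treated_mask.sum())
    n_c = n_samples - n_t
    if n_t < 2 or n_c < 2:
        raise ValueError("need at least 2 replicates in each group")
    observed = tuple(np.flatnonzero(treated_mask))
    masks = balanced_assignments(
        n_samples, n_t, observed, n_permutations, max_permutations, seed
    )

    # vectorised group means / sums of squares over all assignments
    M = masks.astype(float)            # (B, n_samples)
    sum_t = X @ M.T                    # (n_genes, B)
    sum_c = X @ (1.0 - M).T
    q_t = (X ** 2) @ M.T
    q_c = (X ** 2) @ (1.0 - M).T
    mean_t, mean_c = sum_t / n_t, sum_c / n_c
    ss_t = np.maximum(q_t - n_t * mean_t ** 2, 0.0)
    ss_c = np.maximum(q_c - n_c * mean_c ** 2, 0.0)
    factor = (1.0 / n_t + 1.0 / n_c) / (n_c + n_t - 2)
    s = np.sqrt(factor * (ss_t + ss_c))
    d = (mean_t - mean_c) / (s + s0)
    return d.T  # (B, n_genes)


# ---------------------------------------------------------------------------
# delta scan / FDR / q-values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaRow:
    delta: float
    n_called: int
    median_false_positives: float
    fdr: float
    cut_low: float
    cut_up: float


def _cutoffs(d_sorted: np.ndarray, expected_d: np.ndarray, delta: float) -> tuple[float, float]:
    """Asymmetric calling cutoffs for one delta.

    Starting at the origin of the quantile-quantile plot of observed vs
    expected d and moving outward in each direction, the cutoff sits at the
    first gene whose displacement from the permutation expectation reaches
    delta; every gene beyond it is called.
    """
    diff = d_sorted - expected_d
    n = d_sorted.size
    origin = int(np.searchsorted(expected_d, 0.0, side="left"))
    up = np.flatnonzero(diff[origin:] >= delta)
    cut_up = float(d_sorted[origin + up[0]]) if up.size else np.inf
    low = np.flatnonzero(diff[:origin][::-1] <= -delta)
    cut_low = float(d_sorted[origin - 1 - low[0]]) if low.size else -np.inf
    return cut_low, cut_up


def delta_scan(
    observed_d: np.ndarray,
    null_d: np.ndarray,
    deltas: np.ndarray,
    pi0: float = 1.0,
) -> pd.DataFrame:
    """Delta table: genes called, median false positives and FDR per delta.

    ``median_false_positives`` is the median over permutations of the
    number of null d values beyond the observed cutoffs, scaled by ``pi0``
    (1 by default: the raw median, no null-proportion correction).
    FDR = median_false_positives / n_called, 0 by convention when nothing
    is called.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta grid")
    d_sorted = np.sort(np.asarray(observed_d, dtype=float))
    expected_d = np.sort(np.asarray(null_d, dtype=float), axis=1).mean(axis=0)
    null_sorted = np.sort(np.asarray(null_d, dtype=float), axis=1)

    rows = []
    for delta in deltas:
        cut_low, cut_up = _cutoffs(d_sorted, expected_d, float(delta))
        n_called = int((d_sorted >= cut_up).sum() + (d_sorted <= cut_low).sum())
        # per-permutation count of null statistics beyond the cutoffs
        n_genes = null_sorted.shape[1]
        if np.isfinite(cut_up):
            above = n_genes - np.array(
                [np.searchsorted(row, cut_up, side="left") for row in null_sorted]
            )
        else:
            above = np.zeros(null_sorted.shape[0], dtype=int)
        if np.isfinite(cut_low):
            below = np.array(
                [np.searchsorted(row, cut_low, side="right") for row in null_sorted]
            )
        else:
            below = np.zeros(null_sorted.shape[0], dtype=int)
        med_fp = float(np.median(above + below)) * pi0
        fdr = med_fp / n_called if n_called > 0 else 0.0
        rows.append(DeltaRow(float(delta), n_called, med_fp, min(fdr, 1.0), cut_low, cut_up))
    return pd.DataFrame(rows)


def default_delta_grid(observed_d: np.ndarray, null_d: np.ndarray, n_deltas: int = 60) -> np.ndarray:
    """Evenly spaced deltas from 0 to the largest observed displacement."""
    d_sorted = np.sort(np.asarray(observed_d, dtype=float))
    expected_d = np.sort(np.asarray(null_d, dtype=float), axis=1).mean(axis=0)
    max_disp = float(np.abs(d_sorted - expected_d).max())
    return np.linspace(0.0, max_disp, n_deltas)


def q_values(
    observed_d: np.ndarray,
    null_d: np.ndarray,
    deltas: np.ndarray | None = None,
    pi0: float = 1.0,
) -> np.ndarray:
    """Per-gene q-value: the lowest FDR among deltas at which the gene is
    called, made monotone non-increasing in the gene's displacement from
    its permutation expectation.  Genes never called get q = 1."""
    observed_d = np.asarray(observed_d, dtype=float)
    if deltas is None:
        deltas = default_delta_grid(observed_d, null_d)
    table = delta_scan(observed_d, null_d, deltas, pi0=pi0)

    order = np.argsort(observed_d, kind="stable")
    expected_d = np.sort(np.asarray(null_d, dtype=float), axis=1).mean(axis=0)
    disp = np.empty_like(observed_d)
    disp[order] = np.sort(observed_d) - expected_d

    q = np.ones_like(observed_d)
    for row in table.itertuples():
        called = (observed_d >= row.cut_up) | (observed_d <= row.cut_low)
        q[called] = np.minimum(q[called], row.fdr if row.n_called > 0 else 1.0)

    # enforce q monotone non-increasing in |displacement|
    rank = np.argsort(np.abs(disp), kind="stable")
    q[rank] = np.minimum.accumulate(q[rank])
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# DEG selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed genes for one dose-vs-control contrast."""

    dose: str
    direction: dict  # gene id -> "up" | "down"

    @property
    def gene_ids(self) -> frozenset:
        return frozenset(self.direction)

    def __len__(self) -> int:
        return len(self.direction)


def select_degs(
    sam_results: pd.DataFrame,
    dose: str,
    min_fold_change: float = 2.0,
    max_q: float = 0.05,
) -> DEGSet:
    """Genes with two-sided fold change ≥ ``min_fold_change`` and
    q < ``max_q``; direction from the sign of the mean difference."""
    if min_fold_change <= 0 or max_q <= 0:
        raise ValueError("thresholds must be positive")
    ok = (sam_results["fold_change"] >= min_fold_change) & (sam_results["q_value"] < max_q)
    sub = sam_results.loc[ok]
    return DEGSet(dose=dose, direction=dict(zip(sub["gene_id"], sub["direction"])))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SAMTwoClass(BaseEstimator):
    """Two-class permutation detector for differential expression.

    Parameters
    ----------
    control_label : str or None
        Which value of ``y`` is the control group; ``None`` takes the first
        unique label in sorted order.
    s0 : "tusher" or float
        Fudge factor; ``"tusher"`` selects it by the percentile-grid CV
        minimisation.
    n_permutations : int or "auto"
        Balanced label assignments to use.  "auto" enumerates exhaustively
        when the design admits at most ``max_permutations`` assignments
        (70 for a 4 vs 4 design) and samples ``max_permutations`` otherwise.
    n_deltas : int
        Size of the delta grid for the FDR scan.
    pi0 : float
        Null-proportion scale on the median false positives (1 = raw).
    random_state : int
        Seeds permutation sampling when the design is not enumerable.

    Attributes (after :meth:`fit`)
    ------------------------------
    gene_ids_ : ndarray of gene identifiers
    d_ : ndarray, observed moderated t per gene
    s_ : ndarray, pooled standard errors
    s0_ : float, fudge factor used
    fold_change_ : ndarray, two-sided unlogged fold change (≥ 1)
    direction_ : ndarray of "up"/"down"
    q_values_ : ndarray in [0, 1]
    delta_table_ : DataFrame with delta, n_called, median_false_positives, fdr
    null_d_ : (n_permutations, n_genes) null statistics
    expected_d_ : ndarray, permutation expectation of the order statistics
    results_ : tidy DataFrame (gene_id, d, fold_change, q_value, direction)
    """

    def __init__(
        self,
        control_label: str | None = None,
        s0: float | str = "tusher",
        n_permutations: int | str = "auto",
        max_permutations: int = 1000,
        n_deltas: int = 60,
        pi0: float = 1.0,
        random_state: int = 0,
    ):
        self.control_label = control_label
        self.s0 = s0
        self.n_permutations = n_permutations
        self.max_permutations = max_permutations
        self.n_deltas = n_deltas
        self.pi0 = pi0
        self.random_state = random_state

    def fit(self, X, y):
        """Fit on log2 expression.

        Parameters
        ----------
        X : (n_samples, n_genes) array or DataFrame of log2 values.
        y : length-``n_samples`` group labels (exactly two distinct).
        """
        if isinstance(X, pd.DataFrame):
            self.gene_ids_ = X.columns.to_numpy()
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self.gene_ids_ = np.arange(values.shape[1])
        y = np.asarray(y)
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError(f"need exactly 2 groups, got {labels.tolist()}")
        control = self.control_label if self.control_label is not None else labels[0]
        if control not in labels:
            raise ValueError(f"control label {control!r} not present in y")
        treated_mask = y != control
        n_c, n_t = int((~treated_mask).sum()), int(treated_mask.sum())
        if n_c < 2 or n_t < 2:
            raise ValueError("need at least 2 replicates in each group")
        self.classes_ = labels
        self.control_ = control

        G = values.T  # genes × samples
        x_c, x_t = G[:, ~treated_mask], G[:, treated_mask]
        self.numerator_ = x_t.mean(axis=1) - x_c.mean(axis=1)
        self.s_ = _pooled_se(x_c, x_t)
        self.s0_ = (
            choose_s0(self.s_, self.numerator_) if self.s0 == "tusher" else float(self.s0)
        )
        self.d_ = self.numerator_ / (self.s_ + self.s0_)

        # two-sided fold change on the unlogged scale
        lin_c, lin_t = np.exp2(x_c).mean(axis=1), np.exp2(x_t).mean(axis=1)
        ratio = lin_t / lin_c
        self.fold_change_ = np.maximum(ratio, 1.0 / ratio)
        self.direction_ = np.where(ratio >= 1.0, "up", "down")

        self.null_d_ = permutation_null(
            G,
            treated_mask,
            self.s0_,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            max_permutations=self.max_permutations,
        )
        self.expected_d_ = np.sort(self.null_d_, axis=1).mean(axis=0)
        deltas = default_delta_grid(self.d_, self.null_d_, self.n_deltas)
        self.delta_table_ = delta_scan(self.d_, self.null_d_, deltas, pi0=self.pi0)
        self.q_values_ = q_values(self.d_, self.null_d_, deltas, pi0=self.pi0)

        self.results_ = pd.DataFrame(
            {
                "gene_id": self.gene_ids_,
                "d": self.d_,
                "fold_change": self.fold_change_,
                "q_value": self.q_values_,
                "direction": self.direction_,
            }
        )
        return self

    def choose_delta(self, max_fdr: float = 0.05) -> float:
        """Smallest delta whose estimated FDR is below ``max_fdr`` (the
        delta that admits the most genes while keeping predicted false
        positives under the cap)."""
        t = self.delta_table_
        ok = t[t["fdr"] < max_fdr]
        if ok.empty:
            return float(t["delta"].iloc[-1])
        return float(ok["delta"].iloc[0])

    def called_at_delta(self, delta: float) -> np.ndarray:
        """Boolean mask of genes called at one delta."""
        d_sorted = np.sort(self.d_)
        cut_low, cut_up = _cutoffs(d_sorted, self.expected_d_, delta)
        return (self.d_ >= cut_up) | (self.d_ <= cut_low)

    def select_degs(
        self, dose: str, min_fold_change: float = 2.0, max_q: float = 0.05
    ) -> DEGSet:
        return select_degs(self.results_, dose, min_fold_change, max_q)


def write_sam_table(results: pd.DataFrame, path: str | Path, called: np.ndarray | None = None) -> Path:
    """Write the per-gene results (gene, d, FC, q, direction, called) as TSV."""
    path = Path(path)
    out = results.copy()
    out["called"] = called if called is not None else (
        (out["fold_change"] >= 2.0) & (out["q_value"] < 0.05)
    )
    out.to_csv(path, sep="\t", index=False)
    return path


def read_deg_table(path: str | Path, dose: str | None = None) -> DEGSet:
    """Read a DEG table written by :func:`write_sam_table`, keeping called genes."""
    t = pd.read_csv(path, sep="\t")
    sub = t[t["called"]] if "called" in t else t
    return DEGSet(
        dose=dose or Path(path).stem,
        direction=dict(zip(sub["gene_id"].astype(str), sub["direction"])),
    )
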