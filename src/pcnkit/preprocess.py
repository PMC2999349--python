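"""Sample QC and normalization chain for single-channel array intensities.

Six composable transformers, each a scikit-learn style estimator operating
on an :class:`~pcnkit.matrix.ExpressionMatrix`:

1. :class:`IntensityFloor` — raise every intensity below 5.0 to 5.0.
2. :class:`SampleQCFilter` — drop samples whose mean Pearson correlation
   with all other samples is below 0.80 (computed on log2 floored values).
3. :class:`PresentFlagFilter` — keep probes flagged present in ≥ 50% of
   samples.
4. :class:`PerChipNormalizer` — divide each sample by its 50th percentile.
5. :class:`PerGeneNormalizer` — divide each probe row by its across-sample
   median.
6. :class:`Log2Transformer` — elementwise log base 2.

Each stage records the matrix ``scale_state`` and refuses out-of-order
application.  :func:`preprocess` chains them in the documented default
order floor → QC → flag filter → per-chip → per-gene → log2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import PRESENT, ExpressionMatrix

logger = logging.getLogger(__name__)

# Percentiles computed with linear interpolation on sorted values, pinned
# for reproducibility (numpy's default).
_PCTL_METHOD = "linear"


def _require_state(m: ExpressionMatrix, allowed: tuple[str, ...], stage: str) -> None:
    if m.scale_state not in allowed:
        raise ValueError(
            f"{stage} expects scale_state in {allowed}, got {m.scale_state!r}"
        )


class IntensityFloor(TransformerMixin, BaseEstimator):
    """Clip raw intensities from below at ``floor`` (default 5.0).

    Values below the floor are set to the floor; values at or above it are
    untouched, so ordering above the floor is preserved.
    """

    def __init__(self, floor: float = 5.0):
        self.floor = floor

    def fit(self, m: ExpressionMatrix, y=None):
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        self.n_floored_ = int((m.intensities.to_numpy() < self.floor).sum())
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        _require_state(m, ("raw",), "IntensityFloor")
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        out = m.intensities.clip(lower=self.floor)
        return m.with_intensities(out, "floored")


class SampleQCFilter(TransformerMixin, BaseEstimator):
    """Drop samples poorly correlated with the rest of the experiment.

    A sample is excluded when its mean Pearson correlation with all *other*
    original samples is strictly below ``min_mean_correlation`` (a sample at
    exactly the threshold is retained).  Correlations are computed on log2
    of the (floored) intensities, which stabilises variance across the
    intensity range.

    Fitted attributes
    -----------------
    mean_correlation_ : pandas.Series
        Mean correlation of each sample with the others.
    removed_samples_ : list of str
    """

    def __init__(self, min_mean_correlation: float = 0.80):
        self.min_mean_correlation = min_mean_correlation

    def fit(self, m: ExpressionMatrix, y=None):
        if m.n_samples < 3:
            raise ValueError("sample QC needs at least 3 samples")
        log_vals = np.log2(m.intensities)
        corr = log_vals.corr(method="pearson")
        n = m.n_samples
        # mean over the n-1 other samples
        self.mean_correlation_ = (corr.sum(axis=0) - 1.0) / (n - 1)
        self.removed_samples_ = list(
            self.mean_correlation_.index[self.mean_correlation_ < self.min_mean_correlation]
        )
        if self.removed_samples_:
            logger.info(
                "QC removed %d/%d samples: %s",
                len(self.removed_samples_), n,
                {s: round(float(self.mean_correlation_[s]), 4) for s in self.removed_samples_},
            )
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        _require_state(m, ("raw", "floored"), "SampleQCFilter")
        keep = [s for s in m.sample_ids if s not in set(self.removed_samples_)]
        return m.subset_samples(keep)


class PresentFlagFilter(TransformerMixin, BaseEstimator):
    """Keep probes with present flags in at least ``min_present_fraction``
    of samples (inclusive; 4 of 8 passes at the default 0.5)."""

    def __init__(self, min_present_fraction: float = 0.5):
        self.min_present_fraction = min_present_fraction

    def fit(self, m: ExpressionMatrix, y=None):
        if m.flags.isna().to_numpy().any():
            raise ValueError("flags missing for some entries")
        frac = (m.flags == PRESENT).mean(axis=1)
        self.present_fraction_ = frac
        self.kept_probes_ = list(frac.index[frac >= self.min_present_fraction])
        logger.info(
            "flag filter kept %d/%d probes", len(self.kept_probes_), m.n_probes
        )
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        _require_state(m, ("raw", "floored"), "PresentFlagFilter")
        kept = [p for p in m.probe_ids if p in set(self.kept_probes_)]
        return m.subset_probes(kept)


class PerChipNormalizer(TransformerMixin, BaseEstimator):
    """Within-array normalization: divide each sample (chip) by its own
    50th percentile, so every column's median becomes 1."""

    def fit(self, m: ExpressionMatrix, y=None):
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        _require_state(m, ("floored",), "PerChipNormalizer")
        med = m.intensities.quantile(0.5, axis=0, interpolation=_PCTL_METHOD)
        if (med <= 0).any():
            bad = list(med.index[med <= 0])
            raise ValueError(f"non-positive 50th percentile for samples {bad}")
        out = m.intensities.div(med, axis=1)
        return m.with_intensities(out, "chip_normalized")


class PerGeneNormalizer(TransformerMixin, BaseEstimator):
    """Between-array normalization: divide each probe row by its median
    across samples, so every row's median becomes 1."""

    def fit(self, m: ExpressionMatrix, y=None):
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        _require_state(m, ("chip_normalized",), "PerGeneNormalizer")
        med = m.intensities.quantile(0.5, axis=1, interpolation=_PCTL_METHOD)
        if (med <= 0).any():
            bad = list(med.index[med <= 0])
            raise ValueError(f"non-positive median for probes {bad}")
        out = m.intensities.div(med, axis=0)
        return m.with_intensities(out, "gene_normalized")


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Elementwise log base 2 for statistical analysis."""

    def fit(self, m: ExpressionMatrix, y=None):
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        _require_state(m, ("gene_normalized",), "Log2Transformer")
        if (m.intensities.to_numpy() <= 0).any():
            raise ValueError("log2 requires strictly positive values")
        return m.with_intensities(np.log2(m.intensities), "log2")


def preprocess(
    m: ExpressionMatrix,
    floor: float = 5.0,
    min_mean_correlation: float = 0.80,
    min_present_fraction: float = 0.5,
    qc_before_floor: bool = False,
) -> tuple[ExpressionMatrix, dict]:
    """Run the full preprocessing chain and return the log2 matrix.

    The default order is floor → QC → flag filter → per-chip → per-gene →
    log2; flooring first guarantees positive values for the log2-scale QC
    correlations.  ``qc_before_floor=True`` runs QC on the raw scale first
    instead (correlations then use log2 of raw values clipped at a tiny
    positive epsilon).

    Returns the processed matrix and a report dict with the removed
    samples, their mean correlations, and probe counts before/after the
    flag filter.
    """
    report: dict = {}
    if qc_before_floor:
        safe = m.with_intensities(m.intensities.clip(lower=1e-12), m.scale_state)
        qc = SampleQCFilter(min_mean_correlation).fit(safe)
        m = qc.transform(m)
        m = IntensityFloor(floor).fit(m).transform(m)
    else:
        m = IntensityFloor(floor).fit(m).transform(m)
        qc = SampleQCFilter(min_mean_correlation).fit(m)
        m = qc.transform(m)
    report["removed_samples"] = list(qc.removed_samples_)
    report["mean_correlation"] = {
        k: float(v) for k, v in qc.mean_correlation_.items()
    }
    report["n_probes_before_flag_filter"] = m.n_probes
    flt = PresentFlagFilter(min_present_fraction).fit(m)
    m = flt.transform(m)
    report["n_probes_after_flag_filter"] = m.n_probes
    m = PerChipNormalizer().fit(m).transform(m)
    m = PerGeneNormalizer().fit(m).transform(m)
    m = Log2Transformer().fit(m).transform(m)
    return m, report
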