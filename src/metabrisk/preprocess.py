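"""QC-based feature retention, assay precision, and log + Pareto scaling.

The preprocessing contract feeding every multivariate analysis:

1. discard features detected in fewer than 80% of QC injections;
2. report assay precision as %RSD over replicate QC injections
   (RSD <= 15% being the conventional LC-MS acceptability bound);
3. impute missing abundances as half the per-feature observed minimum,
   natural-log transform, then Pareto scale
   ``x -> (log x - mean(log x)) / sqrt(sd(log x))`` per feature, so scaled
   columns have mean 0 and variance equal to the pre-scaling standard
   deviation (the usual compromise between no scaling and autoscaling).

Scaling parameters are fit within each study set separately, since the two
sets are modelled separately downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable


@dataclass
class QcReport:
    """Per-feature %RSD precision over replicate QC injections."""

    rsd: pd.Series              # %RSD (100 * sd / mean, sd with ddof=1)
    threshold: float
    computed: pd.Series         # False where mean abundance was 0

    @property
    def passed(self) -> pd.Series:
        return self.computed & (self.rsd <= self.threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rsd_percent": self.rsd, "computed": self.computed,
                             "pass": self.passed})


def qc_filter(table: FeatureTable, min_detect: float = 0.8) -> FeatureTable:
    """Retain features whose QC-injection detection fraction is >= ``min_detect``.

    Feature order is preserved; the operation is idempotent.  Raises if no
    feature survives.
    """
    det = table.qc_detection
    if det.isna().any():
        raise ValueError("qc_detection is not populated for all features")
    keep = det.index[det >= min_detect]
    if len(keep) == 0:
        raise ValueError(
            f"no feature reaches the QC detection threshold of {min_detect:.0%}")
    return table.subset_features(keep)


def rsd_report(qc_replicates: pd.DataFrame, threshold: float = 15.0) -> QcReport:
    """%RSD per feature from replicate QC injections (rows = replicates)."""
    if qc_replicates.shape[0] < 2:
        raise ValueError("need at least 2 QC replicates for an RSD")
    mean = qc_replicates.mean(axis=0)
    sd = qc_replicates.std(axis=0, ddof=1)
    computed = mean != 0
    rsd = pd.Series(np.where(computed, 100.0 * sd / mean.replace(0, np.nan), np.nan),
                    index=qc_replicates.columns)
    return QcReport(rsd=rsd, threshold=threshold, computed=computed)


def impute_half_min(abundance: pd.DataFrame) -> pd.DataFrame:
    """Replace missing abundances by half the per-feature observed minimum."""
    fill = abundance.min(axis=0, skipna=True) / 2.0
    return abundance.fillna(fill)


def log_pareto(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Impute, natural-log transform and Pareto scale a feature table.

    Returns a samples × features matrix with column means 0 and column
    variances equal to the standard deviation of the log-abundances.  Raises
    on non-positive abundances after imputation or on zero-variance features,
    which must be removed upstream.
    """
    abundance = table.abundance if isinstance(table, FeatureTable) else table
    filled = impute_half_min(abundance)
    vals = filled.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("non-positive or missing abundances remain after imputation")
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(abundance.columns[sd == 0][:5])
        raise ValueError(f"zero-variance features cannot be Pareto scaled: {bad}")
    scaled = (logged - logged.mean(axis=0)) / np.sqrt(sd)
    return pd.DataFrame(scaled, index=abundance.index, columns=abundance.columns)
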