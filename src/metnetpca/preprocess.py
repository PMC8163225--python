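"""QC-based feature filtering and LOESS signal-drift/batch normalization.

LC-MS intensities drift with injection order and jump between batches.
Pooled quality-control samples (QC) injected at regular intervals trace the
drift; a diluted QC (dQC) injected alongside probes whether a feature
responds to concentration at all.  Two standard steps are provided:

* :func:`qc_ratio_filter` removes features whose dQC/QC ratio behaves
  implausibly (median ratio outside a window, or ratio RSD above a cap).
* :func:`loess_normalize` divides every injection by a per-feature,
  per-batch LOESS drift curve fitted on the QCs, then aligns batch QC
  medians to the global QC median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["FeatureRun", "loess_normalize", "qc_ratio_filter", "UnnormalizableFeatureWarning"]


class UnnormalizableFeatureWarning(UserWarning):
    pass


@dataclass
class FeatureRun:
    """An injection sequence with per-injection metadata and feature intensities.

    ``meta`` has one row per injection with columns ``sample_id``,
    ``role`` (sample | QC | dQC), ``batch`` (int) and ``order`` (injection
    order, unique within batch).  ``intensities`` is aligned row-wise with
    ``meta`` and has one column per feature.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    unnormalizable: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"sample_id", "role", "batch", "order"}
        if not required.issubset(self.meta.columns):
            raise ValueError(f"meta must have columns {sorted(required)}")
        if len(self.meta) != len(self.intensities):
            raise ValueError("meta and intensities must have the same number of rows")
        bad_roles = set(self.meta["role"]) - {"sample", "QC", "dQC"}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        for batch, grp in self.meta.groupby("batch"):
            if grp["order"].duplicated().any():
                raise ValueError(f"duplicate injection orders in batch {batch}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def subset_features(self, keep: list[str]) -> "FeatureRun":
        return replace(self, intensities=self.intensities[keep].copy())

    def to_table(self) -> pd.DataFrame:
        """Long-format export: injection metadata followed by feature columns."""
        return pd.concat(
            [self.meta.reset_index(drop=True), self.intensities.reset_index(drop=True)], axis=1
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "FeatureRun":
        meta_cols = ["sample_id", "role", "batch", "order"]
        return cls(table[meta_cols].copy(), table.drop(columns=meta_cols).copy())


def loess_normalize(
    run: FeatureRun, span: float = 0.75, burn_in: int = 0
) -> FeatureRun:
    """Correct within-batch signal drift and between-batch offsets using QCs.

    Per feature and batch, a degree-1 LOESS of QC intensity on injection
    order gives the drift curve; every injection's intensity is divided by
    the drift value at its order (nearest fitted value outside the QC range
    — no extrapolation) and multiplied by the batch QC median.  Each batch
    is then rescaled by (global QC median / batch QC median) so recomputed
    QC medians agree across batches.

    Parameters
    ----------
    span
        LOESS smoothing fraction.
    burn_in
        Number of leading injections per batch (system conditioning)
        excluded from drift fitting.

    Features whose QC intensities are all zero in some batch cannot be
    normalized; they are passed through unchanged and recorded in
    ``unnormalizable``.
    """
    meta = run.meta.reset_index(drop=True)
    X = run.intensities.reset_index(drop=True).astype(float).copy()
    qc_mask = (meta["role"] == "QC").to_numpy()
    skipped: set[str] = set()

    for batch, idx in meta.groupby("batch").groups.items():
        idx = np.asarray(idx)
        order = meta.loc[idx, "order"].to_numpy(dtype=float)
        fit_ok = qc_mask[idx] & (order >= np.min(order) + burn_in)
        qc_rows = idx[fit_ok]
        if len(qc_rows) < 2:
            raise ValueError(f"batch {batch}: need >= 2 QC injections for drift fitting")
        qc_order = meta.loc[qc_rows, "order"].to_numpy(dtype=float)

        for feat in X.columns:
            y = X.loc[qc_rows, feat].to_numpy(dtype=float)
            if np.all(y == 0):
                skipped.add(feat)
                continue
            if np.any(y <= 0):
                # LOESS on nonpositive QC signal is unstable; flag and pass through
                skipped.add(feat)
                continue
            fitted = lowess(y, qc_order, frac=span, it=0, return_sorted=True)
            # nearest fitted value outside the QC order range (no extrapolation)
            drift = np.interp(order, fitted[:, 0], fitted[:, 1])
            if np.any(drift <= 0):
                skipped.add(feat)
                continue
            batch_median = float(np.median(y))
            X.loc[idx, feat] = X.loc[idx, feat].to_numpy() / drift * batch_median

    if skipped:
        warnings.warn(
            f"{len(skipped)} feature(s) could not be drift-normalized and were "
            f"passed through: {', '.join(sorted(skipped)[:5])}"
            + ("..." if len(skipped) > 5 else ""),
            UnnormalizableFeatureWarning,
            stacklevel=2,
        )

    # inter-batch: align every batch's QC median to the global QC median
    normalizable = [f for f in X.columns if f not in skipped]
    for feat in normalizable:
        batch_medians = {}
        for batch, idx in meta.groupby("batch").groups.items():
            idx = np.asarray(idx)
            batch_medians[batch] = float(np.median(X.loc[idx[qc_mask[idx]], feat]))
        global_median = float(np.median(X.loc[qc_mask, feat]))
        for batch, idx in meta.groupby("batch").groups.items():
            idx = np.asarray(idx)
            if batch_medians[batch] > 0:
                X.loc[idx, feat] = (
                    X.loc[idx, feat].to_numpy() * global_median / batch_medians[batch]
                )

    return FeatureRun(meta, X, unnormalizable=sorted(set(run.unnormalizable) | skipped))


def _pair_dqc_with_qc(meta: pd.DataFrame) -> list[tuple[int, int]]:
    """Pair each dQC injection with the nearest QC (by injection order, same batch)."""
    pairs = []
    for batch, grp in meta.groupby("batch"):
        qcs = grp[grp["role"] == "QC"]
        dqcs = grp[grp["role"] == "dQC"]
        if qcs.empty:
            continue
        for d_idx, d_row in dqcs.iterrows():
            gaps = (qcs["order"] - d_row["order"]).abs()
            q_idx = gaps.idxmin()
            pairs.append((d_idx, q_idx))
    return pairs


def qc_ratio_filter(
    run: FeatureRun,
    rsd_threshold: float = 50.0,
    ratio_low: float = 0.2,
    ratio_high: float = 0.8,
) -> tuple[FeatureRun, list[str]]:
    """Remove features with implausible dQC/QC dilution behaviour.

    For each feature, the dQC/QC intensity ratio is computed over adjacent
    dQC-QC injection pairs.  The feature is retained iff the relative
    standard deviation of this ratio series is <= ``rsd_threshold`` percent
    AND the median ratio lies in [``ratio_low``, ``ratio_high``].  A feature
    of a properly diluted QC should respond proportionally (ratio near the
    dilution factor) and stably (low RSD); everything else is analytical
    noise.

    Returns the filtered run and the removed feature ids (audit list).
    """
    meta = run.meta.reset_index(drop=True)
    X = run.intensities.reset_index(drop=True)
    if not (meta["role"] == "dQC").any():
        raise ValueError("no dQC injections: the dQC/QC ratio filter cannot be evaluated")
    pairs = _pair_dqc_with_qc(meta)
    if not pairs:
        raise ValueError("no dQC-QC pairs could be formed")

    removed: list[str] = []
    kept: list[str] = []
    for feat in X.columns:
        ratios = []
        for d_idx, q_idx in pairs:
            q = float(X.loc[q_idx, feat])
            d = float(X.loc[d_idx, feat])
            if q != 0:
                ratios.append(d / q)
        if not ratios:
            removed.append(feat)
            continue
        ratios = np.asarray(ratios)
        med = float(np.median(ratios))
        mean = float(np.mean(ratios))
        rsd = np.inf if mean == 0 else float(np.std(ratios, ddof=1) / abs(mean) * 100) if len(ratios) > 1 else 0.0
        if rsd <= rsd_threshold and ratio_low <= med <= ratio_high:
            kept.append(feat)
        else:
            removed.append(feat)
    return run.subset_features(kept), removed
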