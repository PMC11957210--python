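"""Proteomic QC cascade and per-cluster z-score normalization.

Stage order in :func:`run_qc`: analyte-level filters (LOD failure fraction,
scale-factor deviation, CV) -> per-analyte Tukey outlier masking on log10
values -> two-pass call-rate filtering of analytes and subjects -> per-cluster
z-score normalization of log10 values.  Filters only remove rows/columns or
mask cells; no retained value is altered before normalization.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from plasmad.datamodel import ProteomicsMatrix

log = logging.getLogger(__name__)


class QcError(ValueError):
    pass


@dataclasses.dataclass
class QcReport:
    analytes_removed: dict = dataclasses.field(default_factory=dict)  # reason -> [ids]
    samples_removed: dict = dataclasses.field(default_factory=dict)
    outlier_cells_masked: int = 0
    call_rate_before: pd.Series | None = None
    call_rate_after: pd.Series | None = None
    analytes_dropped_constant: list = dataclasses.field(default_factory=list)
    warnings: list = dataclasses.field(default_factory=list)

    def merge(self, other: "QcReport") -> None:
        for reason, ids in other.analytes_removed.items():
            self.analytes_removed.setdefault(reason, []).extend(ids)
        for reason, ids in other.samples_removed.items():
            self.samples_removed.setdefault(reason, []).extend(ids)
        self.outlier_cells_masked += other.outlier_cells_masked
        if other.call_rate_before is not None:
            self.call_rate_before = other.call_rate_before
        if other.call_rate_after is not None:
            self.call_rate_after = other.call_rate_after
        self.analytes_dropped_constant.extend(other.analytes_dropped_constant)
        self.warnings.extend(other.warnings)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for reason, ids in self.analytes_removed.items():
            rows += [("analyte", reason, i) for i in ids]
        for reason, ids in self.samples_removed.items():
            rows += [("sample", reason, i) for i in ids]
        rows += [("analyte", "constant_in_cluster", i) for i in self.analytes_dropped_constant]
        return pd.DataFrame(rows, columns=["entity", "reason", "id"])


@dataclasses.dataclass
class QcParams:
    lod_frac: float = 0.85
    sf_dev: float = 0.5
    cv_max: float = 0.15
    cv_scope: str = "plate"       # "plate" or "global"
    call_rate_pass1: float = 0.65
    call_rate_pass2: float = 0.85
    log10_before_zscore: bool = True


def apply_analyte_filters(
    matrix: ProteomicsMatrix,
    lod_frac: float = 0.85,
    sf_dev: float = 0.5,
    cv_max: float = 0.15,
    cv_scope: str = "plate",
) -> tuple[ProteomicsMatrix, QcReport]:
    """Remove analytes failing the LOD-fraction, scale-factor, or CV filter.

    An analyte fails LOD if at least ``lod_frac`` of the samples have a
    missing measurement or a value below the per-(analyte, plate) LOD.  It
    fails the scale-factor filter if |sf - plate-median sf| > ``sf_dev`` on
    any plate, and the CV filter if sd/mean of raw values exceeds ``cv_max``
    (per plate when ``cv_scope == "plate"``, pooled otherwise).
    """
    if not 0 < lod_frac <= 1:
        raise QcError("lod_frac must be in (0, 1]")
    if sf_dev <= 0 or cv_max <= 0:
        raise QcError("sf_dev and cv_max must be > 0")
    if cv_scope not in ("plate", "global"):
        raise QcError(f"unknown cv_scope {cv_scope!r}")

    vals = matrix.values
    report = QcReport()
    removed: dict[str, list] = {"lod": [], "scale_factor": [], "cv": []}
    plates = matrix.plate_of_sample

    if matrix.lod is not None:
        lod_per_cell = matrix.lod.loc[vals.columns, plates].to_numpy().T
        failed = vals.isna().to_numpy() | (vals.to_numpy() < lod_per_cell)
        frac = failed.mean(axis=0)
        removed["lod"] = list(vals.columns[frac >= lod_frac])

    if matrix.scale_factor is not None:
        sf = matrix.scale_factor.loc[vals.columns]
        dev = (sf - sf.median(axis=0)).abs()
        removed["scale_factor"] = list(vals.columns[(dev > sf_dev).any(axis=1)])

    if cv_scope == "global":
        cv = vals.std(axis=0, ddof=1) / vals.mean(axis=0)
        removed["cv"] = list(vals.columns[cv > cv_max])
    else:
        fails = pd.Series(False, index=vals.columns)
        for _, sub in vals.groupby(plates):
            with np.errstate(invalid="ignore"):
                cv = sub.std(axis=0, ddof=1) / sub.mean(axis=0)
            fails |= cv > cv_max
        removed["cv"] = list(vals.columns[fails])

    drop = set().union(*removed.values())
    keep = [a for a in vals.columns if a not in drop]
    if not keep:
        report.analytes_removed = removed
        raise QcError(f"all analytes removed by analyte filters; report: {removed}")
    report.analytes_removed = removed
    return matrix.subset(analyte_ids=keep), report


def flag_outliers_iqr(matrix: ProteomicsMatrix) -> tuple[ProteomicsMatrix, int]:
    """Mask per-analyte Tukey outliers of log10 values as missing.

    Fences use the standard convention (Q1 - 1.5*IQR, Q3 + 1.5*IQR) with
    linear-interpolation (type-7) quartiles; single pass.
    """
    vals = matrix.values.to_numpy(dtype=float).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.log10(vals)
    q1 = np.nanpercentile(logv, 25, axis=0)
    q3 = np.nanpercentile(logv, 75, axis=0)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (logv < lo[None, :]) | (logv > hi[None, :])
    n_masked = int(np.nansum(mask))
    vals[mask] = np.nan
    out = matrix.copy()
    out.values = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return out, n_masked


def _call_rates(vals: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    analyte = vals.notna().mean(axis=0)
    sample = vals.notna().mean(axis=1)
    return analyte, sample


def call_rate_filter(
    matrix: ProteomicsMatrix, pass1: float = 0.65, pass2: float = 0.85
) -> tuple[ProteomicsMatrix, QcReport]:
    """Two-pass call-rate filter over analytes and subjects.

    Pass 1 removes analytes and subjects with call rate < ``pass1``, judged
    simultaneously on the incoming matrix; call rates are then recomputed on
    the reduced matrix and pass 2 removes those < ``pass2``.
    """
    if not 0 < pass1 <= pass2 <= 1:
        raise QcError("need 0 < pass1 <= pass2 <= 1")
    vals = matrix.values
    report = QcReport()
    a_rate, s_rate = _call_rates(vals)
    report.call_rate_before = a_rate
    drop_a1 = list(vals.columns[a_rate < pass1])
    drop_s1 = list(vals.index[s_rate < pass1])
    vals = vals.drop(index=drop_s1, columns=drop_a1)
    if vals.empty:
        raise QcError("matrix empty after call-rate pass 1")
    a_rate2, s_rate2 = _call_rates(vals)
    drop_a2 = list(vals.columns[a_rate2 < pass2])
    drop_s2 = list(vals.index[s_rate2 < pass2])
    vals = vals.drop(index=drop_s2, columns=drop_a2)
    if vals.empty:
        raise QcError("matrix empty after call-rate pass 2")
    report.analytes_removed = {"call_rate_pass1": drop_a1, "call_rate_pass2": drop_a2}
    report.samples_removed = {"call_rate_pass1": drop_s1, "call_rate_pass2": drop_s2}
    report.call_rate_after = vals.notna().mean(axis=0)
    return matrix.subset(sample_ids=vals.index, analyte_ids=vals.columns), report


def zscore_normalize(
    matrix: ProteomicsMatrix,
    cluster_of_sample: pd.Series,
    log10_first: bool = True,
) -> tuple[ProteomicsMatrix, QcReport]:
    """Per-analyte, per-cluster z-score normalization (mean 0, sd 1, ddof=1).

    Missing entries are preserved.  Analytes constant within any cluster are
    dropped with a logged warning.
    """
    report = QcReport()
    cluster = cluster_of_sample.reindex(matrix.values.index)
    if cluster.isna().any():
        missing = list(cluster.index[cluster.isna()])
        raise QcError(f"samples without cluster label: {missing}")
    vals = matrix.values.to_numpy(dtype=float).copy()
    if log10_first:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log10(vals)
    out = np.full_like(vals, np.nan)
    degenerate = np.zeros(vals.shape[1], dtype=bool)
    carr = cluster.to_numpy()
    for c in pd.unique(carr):
        rows = np.where(carr == c)[0]
        block = vals[rows, :]
        mean = np.nanmean(block, axis=0)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(block, axis=0, ddof=1)
        degenerate |= ~(sd > 0)
        with np.errstate(invalid="ignore"):
            out[rows, :] = (block - mean[None, :]) / sd[None, :]
    cols = matrix.values.columns
    if degenerate.any():
        dropped = list(cols[degenerate])
        report.analytes_dropped_constant = dropped
        msg = f"dropping {len(dropped)} analyte(s) with zero within-cluster variance"
        report.warnings.append(msg)
        log.warning(msg)
    keep = ~degenerate
    normalized = ProteomicsMatrix(
        values=pd.DataFrame(out[:, keep], index=matrix.values.index, columns=cols[keep]),
        plate_of_sample=matrix.plate_of_sample.copy(),
        scale_factor=None if matrix.scale_factor is None else matrix.scale_factor.loc[cols[keep]],
        lod=None if matrix.lod is None else matrix.lod.loc[cols[keep]],
        scale="zscore",
    )
    return normalized, report


def run_qc(
    matrix: ProteomicsMatrix,
    cluster_of_sample: pd.Series | None = None,
    params: QcParams | None = None,
) -> tuple[ProteomicsMatrix, QcReport]:
    """Full QC cascade; returns the z-normalized matrix and an aggregate report."""
    params = params or QcParams()
    report = QcReport()
    m, rep = apply_analyte_filters(
        matrix, params.lod_frac, params.sf_dev, params.cv_max, params.cv_scope
    )
    report.merge(rep)
    m, n_masked = flag_outliers_iqr(m)
    report.outlier_cells_masked = n_masked
    m, rep = call_rate_filter(m, params.call_rate_pass1, params.call_rate_pass2)
    report.merge(rep)
    if cluster_of_sample is None:
        cluster_of_sample = pd.Series("all", index=m.values.index)
    m, rep = zscore_normalize(m, cluster_of_sample, log10_first=params.log10_before_zscore)
    report.merge(rep)
    return m, report
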