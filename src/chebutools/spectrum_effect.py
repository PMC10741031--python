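"""Spectrum–antioxidant effect correlation.

Links the fingerprint peak areas of herbal-extract batches to their
antioxidant assay results: DPPH radical-scavenging IC50, ABTS and FRAP
total antioxidant capacity (T-AOC).  Four tools:

* log-linear IC50 interpolation from dose–response data,
* Pearson correlation of peak areas vs the three assays, flagging peaks
  with r < −0.5 against IC50 (lower IC50 = more active) and r > +0.5
  against the T-AOC measures,
* Deng's grey relational analysis (resolution coefficient ρ, min-max or
  mean normalization) against a reference activity sequence,
* peak-area decrease scoring of the radical-pretreated (UPLC-DPPH)
  chromatogram versus control,

plus a consensus ranking across the three selection methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fingerprint_chemometrics import PeakTable

__all__ = [
    "ActivityTable",
    "CorrelationReport",
    "GraReport",
    "DpphDecreaseReport",
    "ic50_from_doseresponse",
    "pearson_matrix",
    "grey_relational_degrees",
    "dpph_peak_decrease",
    "consensus_antioxidants",
]

ASSAYS = ("dpph_ic50", "abts_taoc", "frap_taoc")


@dataclass
class ActivityTable:
    """Per-batch antioxidant assay values.

    ``dpph_ic50`` in µg/mL (lower = more active), ``abts_taoc`` and
    ``frap_taoc`` in mmol/g (higher = more active).  Batch ids must align
    with the fingerprint peak table.
    """

    frame: pd.DataFrame  # index = batch ids, columns = ASSAYS

    def __post_init__(self) -> None:
        missing = [c for c in ASSAYS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"activity table missing columns {missing}")
        if (self.frame[list(ASSAYS)].values <= 0).any():
            raise ValueError("activity values must be positive")

    @property
    def batch_ids(self) -> List[str]:
        return list(self.frame.index)

    @classmethod
    def from_csv(cls, path: str) -> "ActivityTable":
        return cls(frame=pd.read_csv(path, index_col=0))

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path)


@dataclass
class CorrelationReport:
    r: pd.DataFrame                 # peaks × assays Pearson coefficients
    ic50_flags: List[str]           # peaks with r < -0.5 vs IC50
    taoc_flags: List[str]           # peaks with r > +0.5 vs both T-AOC assays
    dual_flags: List[str]           # both of the above


@dataclass
class GraReport:
    reference_assay: str
    rho: float
    degrees: pd.Series              # per-peak grey relational degree
    selected: List[str]             # degree >= cutoff
    cutoff: float


@dataclass
class DpphDecreaseReport:
    decrease_percent: pd.Series     # per-peak mean percent decrease
    ranking: List[str]              # descending decrease
    within_noise_increases: List[str]  # peaks with negative decrease


# ---------------------------------------------------------------------------
# IC50
# ---------------------------------------------------------------------------

def ic50_from_doseresponse(
    concentrations: Sequence[float],
    inhibition_percent: Sequence[float],
) -> Tuple[Optional[float], str]:
    """IC50 by log-linear interpolation at the first 50% crossing.

    Returns ``(ic50, status)`` with status "ok" or "undefined" (the curve
    never reaches 50% in the tested range).  A non-monotone curve is
    interpolated at its first crossing with a warning status "ok-nonmonotone".
    """
    conc = np.asarray(concentrations, dtype=float)
    inhib = np.asarray(inhibition_percent, dtype=float)
    if conc.size < 2 or conc.size != inhib.size:
        raise ValueError("need >= 2 aligned (concentration, inhibition) points")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)
    conc, inhib = conc[order], inhib[order]
    status = "ok" if bool(np.all(np.diff(inhib) >= 0)) else "ok-nonmonotone"

    exact = np.where(inhib == 50.0)[0]
    if exact.size:
        return float(conc[exact[0]]), status
    for i in range(conc.size - 1):
        lo, hi = inhib[i], inhib[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            frac = (50.0 - lo) / (hi - lo)
            log_ic50 = np.log10(conc[i]) + frac * (np.log10(conc[i + 1]) - np.log10(conc[i]))
            return float(10 ** log_ic50), status
    return None, "undefined"


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def pearson_matrix(
    peaks: PeakTable,
    activities: ActivityTable,
    ic50_threshold: float = -0.5,
    taoc_threshold: float = 0.5,
) -> CorrelationReport:
    """Pearson r of each peak against each assay, with threshold flags.

    A constant peak or assay vector has no defined correlation; the cell is
    reported as NaN.  Requires ≥3 aligned batches.
    """
    if list(peaks.batch_ids) != list(activities.batch_ids):
        raise ValueError("peak table and activity table batch ids do not align")
    if len(peaks.batch_ids) < 3:
        raise ValueError("need at least 3 batches for correlation")
    X = peaks.areas
    r = pd.DataFrame(index=peaks.peak_ids, columns=list(ASSAYS), dtype=float)
    for assay in ASSAYS:
        yvec = activities.frame[assay].astype(float)
        if yvec.std(ddof=0) == 0:
            r[assay] = np.nan
            continue
        for peak in peaks.peak_ids:
            xvec = X[peak].astype(float)
            if xvec.std(ddof=0) == 0:
                r.loc[peak, assay] = np.nan
            else:
                r.loc[peak, assay] = float(np.corrcoef(xvec, yvec)[0, 1])
    ic50_flags = [p for p in peaks.peak_ids if r.loc[p, "dpph_ic50"] < ic50_threshold]
    taoc_flags = [
        p for p in peaks.peak_ids
        if r.loc[p, "abts_taoc"] > taoc_threshold and r.loc[p, "frap_taoc"] > taoc_threshold
    ]
    dual = [p for p in ic50_flags if p in taoc_flags]
    return CorrelationReport(r=r, ic50_flags=ic50_flags, taoc_flags=taoc_flags,
                             dual_flags=dual)


# ---------------------------------------------------------------------------
# Grey relational analysis
# ---------------------------------------------------------------------------

def _normalize(seq: np.ndarray, mode: str) -> np.ndarray:
    if mode == "minmax":
        span = seq.max() - seq.min()
        if span == 0:
            return np.zeros_like(seq)
        return (seq - seq.min()) / span
    if mode == "mean":
        mean = seq.mean()
        if mean == 0:
            raise ValueError("zero-mean sequence under mean normalization")
        return seq / mean
    raise ValueError(f"unknown normalization {mode!r}")


def grey_relational_degrees(
    reference: Sequence[float],
    comparisons: pd.DataFrame,
    rho: float = 0.5,
    normalization: str = "minmax",
    cutoff: float = 0.7,
    reference_name: str = "activity",
) -> GraReport:
    """Deng's grey relational degree of each peak column vs a reference.

    Steps: (1) normalize reference and comparison sequences; (2) deviations
    Δi(k) = |x0(k) − xi(k)|; (3) coefficients
    ξi(k) = (Δmin + ρ·Δmax) / (Δi(k) + ρ·Δmax) with Δmin/Δmax taken over all
    i and k; (4) degree ri = mean over k of ξi(k).  Degrees lie in (0, 1],
    with 1 iff the normalized sequences coincide.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    ref = _normalize(np.asarray(reference, dtype=float), normalization)
    if len(ref) != len(comparisons):
        raise ValueError("reference and comparison length mismatch")
    deviations = {}
    for col in comparisons.columns:
        comp = _normalize(comparisons[col].values.astype(float), normalization)
        deviations[col] = np.abs(ref - comp)
    all_dev = np.concatenate(list(deviations.values()))
    d_min, d_max = float(all_dev.min()), float(all_dev.max())
    degrees = {}
    for col, dev in deviations.items():
        if d_max == 0:
            xi = np.ones_like(dev)
        else:
            xi = (d_min + rho * d_max) / (dev + rho * d_max)
        degrees[col] = float(xi.mean())
    series = pd.Series(degrees, name="grey_relational_degree")
    selected = list(series[series >= cutoff].sort_values(ascending=False).index)
    return GraReport(reference_assay=reference_name, rho=rho, degrees=series,
                     selected=selected, cutoff=cutoff)


# ---------------------------------------------------------------------------
# UPLC-DPPH peak decrease
# ---------------------------------------------------------------------------

def dpph_peak_decrease(
    control: pd.DataFrame,
    treated: pd.DataFrame,
) -> DpphDecreaseReport:
    """Percent peak-area decrease after radical treatment.

    ``control`` and ``treated`` are replicate × peak area tables sharing
    peak columns (single rows allowed).  Decrease per peak is
    ``(mean control − mean treated) / mean control × 100``; negative values
    (within-noise increases) are flagged.  A zero control area leaves that
    peak's decrease undefined (NaN).
    """
    if list(control.columns) != list(treated.columns):
        raise ValueError("control and treated tables must share peak ids")
    ctrl_mean = control.mean(axis=0).astype(float)
    trt_mean = treated.mean(axis=0).astype(float)
    decrease = pd.Series(np.nan, index=control.columns, name="decrease_percent")
    nonzero = ctrl_mean != 0
    decrease[nonzero] = (ctrl_mean[nonzero] - trt_mean[nonzero]) / ctrl_mean[nonzero] * 100.0
    ranking = list(decrease.dropna().sort_values(ascending=False).index)
    negatives = list(decrease[decrease < 0].index)
    return DpphDecreaseReport(decrease_percent=decrease, ranking=ranking,
                              within_noise_increases=negatives)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_antioxidants(
    correlation: CorrelationReport,
    gra: GraReport,
    dpph: DpphDecreaseReport,
    dpph_percentile: float = 75.0,
) -> List[Tuple[str, int, float]]:
    """Rank peaks by how many methods select them.

    A peak scores one vote each for: dual Pearson flags (negative vs IC50
    and positive vs both T-AOC assays), grey relational degree above the
    cutoff, and a DPPH peak-area decrease above the ``dpph_percentile`` of
    all defined decreases.  Ties are broken by DPPH decrease, then peak id.
    Returns ``(peak, votes, dpph_decrease)`` tuples, votes > 0 only.
    """
    valid = dpph.decrease_percent.dropna()
    dpph_cut = float(np.percentile(valid.values, dpph_percentile)) if len(valid) else math.inf
    dpph_selected = set(valid[(valid >= dpph_cut) & (valid > 0)].index) if len(valid) else set()

    peaks = list(correlation.r.index)
    rows = []
    for peak in peaks:
        votes = 0
        if peak in correlation.dual_flags:
            votes += 1
        if peak in gra.selected:
            votes += 1
        if peak in dpph_selected:
            votes += 1
        if votes:
            dec = float(dpph.decrease_percent.get(peak, np.nan))
            rows.append((peak, votes, dec))
    rows.sort(key=lambda r: (-r[1], -(r[2] if not math.isnan(r[2]) else -math.inf), r[0]))
    return rows
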