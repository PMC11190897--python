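"""Ca2+ imaging trace analysis: normalization, QC, responder calls.

Traces are normalized to the F/F_pos scale: after background subtraction,
0 is the mean of the 10 s baseline before drug application and 1 is the
maximal fluorescence during KCl application. A ROI enters analysis only if
its KCl response rises >5% over baseline and its baseline is stable; a ROI
is responsive to a drug if its normalized fluorescence strictly exceeds
0.1 within the response window after drug onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import TraceSet

__all__ = [
    "NormalizedTrace",
    "ResponseCall",
    "normalize_trace",
    "qc_trace",
    "classify_response",
    "analyse_trace_set",
    "cosensitivity_table",
    "reporter_overlap",
]

RESPONSE_THRESHOLD = 0.1
KCL_MIN_RISE = 0.05
BASELINE_S = 10.0


@dataclass
class NormalizedTrace:
    values: np.ndarray  # F/F_pos per frame
    times: np.ndarray
    baseline_mean: float  # F0, background-subtracted raw units
    kcl_max: float  # raw units above baseline


@dataclass
class ResponseCall:
    roi_id: str
    drug: str
    responsive: bool
    peak: float
    qc_included: bool
    qc_reasons: tuple[str, ...] = ()


def _window_slice(times: np.ndarray, start: float, end: float) -> np.ndarray:
    if start < times[0] - 1e-9 or end > times[-1] + 1e-9:
        raise ValueError(f"window ({start}, {end}) outside record")
    return (times >= start) & (times <= end)


def _baseline_slice(times: np.ndarray, drug_onset: float, baseline_s: float) -> np.ndarray:
    # half-open [onset - baseline_s, onset): the onset frame already carries drug
    start = max(drug_onset - baseline_s, times[0])
    return (times >= start) & (times < drug_onset)


def normalize_trace(
    trace: np.ndarray,
    times: np.ndarray,
    background: float | np.ndarray,
    drug_onset: float,
    kcl_window: tuple[float, float],
    baseline_s: float = BASELINE_S,
) -> NormalizedTrace:
    """F/F_pos normalization.

    out(t) = (F(t) - B - F0) / (F_KClmax - F0) with F0 the mean of the
    background-subtracted trace over the ``baseline_s`` seconds before drug
    onset and F_KClmax the maximum during the KCl window. A KCl maximum at
    or below baseline is a QC failure, raised as ValueError here and turned
    into an excluded call by :func:`analyse_trace_set`.
    """
    f = np.asarray(trace, dtype=float) - background
    base = _baseline_slice(times, drug_onset, baseline_s)
    f0 = float(f[base].mean())
    kcl = _window_slice(times, *kcl_window)
    kcl_max = float(f[kcl].max())
    if kcl_max <= f0:
        raise ValueError("KCl maximum does not exceed baseline")
    values = (f - f0) / (kcl_max - f0)
    return NormalizedTrace(values=values, times=times, baseline_mean=f0, kcl_max=kcl_max - f0)


def qc_trace(
    trace: np.ndarray,
    times: np.ndarray,
    background: float | np.ndarray,
    drug_onset: float,
    kcl_window: tuple[float, float],
    baseline_s: float = BASELINE_S,
    kcl_min_rise: float = KCL_MIN_RISE,
    drift_tol: float = 0.05,
    baseline_cv_tol: float = 0.10,
) -> tuple[bool, tuple[str, ...]]:
    """Inclusion gate: KCl rise > ``kcl_min_rise`` of baseline, stable baseline.

    Baseline stability: |fitted linear slope| x window <= drift_tol x F0
    and baseline CV <= baseline_cv_tol. Reasons are listed on failure.
    """
    f = np.asarray(trace, dtype=float) - background
    reasons: list[str] = []
    base = _baseline_slice(times, drug_onset, baseline_s)
    f0 = float(f[base].mean())
    if f0 <= 0:
        return False, ("nonpositive baseline fluorescence",)
    kcl = _window_slice(times, *kcl_window)
    rise = (float(f[kcl].max()) - f0) / f0
    if rise <= kcl_min_rise:
        reasons.append(f"KCl rise {rise:.3f} <= {kcl_min_rise}")
    tb = times[base]
    slope = float(np.polyfit(tb, f[base], 1)[0])
    if abs(slope) * (tb[-1] - tb[0]) > drift_tol * f0:
        reasons.append("unstable baseline: drift")
    cv = float(f[base].std() / f0)
    if cv > baseline_cv_tol:
        reasons.append(f"unstable baseline: CV {cv:.3f} > {baseline_cv_tol}")
    return (not reasons), tuple(reasons)


def classify_response(
    norm: NormalizedTrace,
    drug_window: tuple[float, float],
    response_window_s: float = 90.0,
    threshold: float = RESPONSE_THRESHOLD,
    roi_id: str = "",
    drug: str = "",
) -> ResponseCall:
    """Responsive iff the normalized peak within [onset, onset +
    response_window_s] strictly exceeds the threshold (default 0.1)."""
    onset = drug_window[0]
    end = min(onset + response_window_s, norm.times[-1])
    sel = _window_slice(norm.times, onset, end)
    peak = float(norm.values[sel].max())
    return ResponseCall(
        roi_id=roi_id,
        drug=drug,
        responsive=peak > threshold,
        peak=peak,
        qc_included=True,
    )


def analyse_trace_set(
    ts: TraceSet,
    response_window_s: float = 90.0,
    threshold: float = RESPONSE_THRESHOLD,
    drift_tol: float = 0.05,
    baseline_cv_tol: float = 0.10,
) -> pd.DataFrame:
    """QC + normalize + classify every ROI for every drug window.

    Returns one row per ROI: qc_included, qc_reasons, per-drug peak and
    responsive flags, soma area and reporter flag when available.
    """
    times = ts.times
    rows = []
    for roi in ts.roi_ids:
        trace = ts.traces[roi].to_numpy()
        first_onset = ts.windows[0][1]
        ok, reasons = qc_trace(
            trace, times, ts.background, first_onset, ts.kcl_window,
            drift_tol=drift_tol, baseline_cv_tol=baseline_cv_tol,
        )
        row: dict = {"roi_id": roi, "qc_included": ok, "qc_reasons": ";".join(reasons)}
        for label, start, end in ts.windows:
            if ok:
                norm = normalize_trace(trace, times, ts.background, start, ts.kcl_window)
                call = classify_response(
                    norm, (start, end), response_window_s, threshold, roi_id=roi, drug=label
                )
                row[f"peak_{label}"] = call.peak
                row[f"responsive_{label}"] = call.responsive
            else:
                row[f"peak_{label}"] = np.nan
                row[f"responsive_{label}"] = False
        if ts.soma_area_um2 is not None:
            row["soma_area_um2"] = float(ts.soma_area_um2[roi])
        if ts.reporter is not None:
            row["reporter"] = bool(ts.reporter[roi])
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi_id", drop=False).rename_axis(None)


def cosensitivity_table(calls_a: pd.Series, calls_b: pd.Series) -> dict:
    """Joint responder structure of two drugs over the same ROI universe.

    Returns counts partitioning the universe (both, a_only, b_only,
    neither) plus the conditional fractions P(B|A) and P(A|B).
    """
    if not calls_a.index.equals(calls_b.index):
        raise ValueError("mismatched ROI sets")
    a = calls_a.astype(bool)
    b = calls_b.astype(bool)
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    out = {
        "n": len(a),
        "both": both,
        "a_only": a_only,
        "b_only": b_only,
        "neither": neither,
        "frac_b_given_a": both / a.sum() if a.sum() else float("nan"),
        "frac_a_given_b": both / b.sum() if b.sum() else float("nan"),
    }
    return out


def reporter_overlap(calls: pd.DataFrame, drug: str) -> dict:
    """Reporter expression among drug responders, plus soma-area summaries.

    Returns the fraction of responders that are reporter-positive, the
    overall reporter-positive fraction of QC-included ROIs, and mean +/-
    SEM soma area per class (reporter+/- and responder+/-).
    """
    df = calls[calls["qc_included"]]
    if "reporter" not in df:
        raise ValueError("no reporter flags available")
    resp = df[f"responsive_{drug}"].astype(bool)
    if resp.sum() == 0:
        raise ValueError("zero responders: overlap undefined")
    rep = df["reporter"].astype(bool)

    def _summ(x: pd.Series) -> dict:
        return {
            "n": int(len(x)),
            "mean": float(x.mean()) if len(x) else float("nan"),
            "sem": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan"),
        }

    out = {
        "responder_reporter_fraction": float(rep[resp].mean()),
        "overall_reporter_fraction": float(rep.mean()),
        "n_responders": int(resp.sum()),
        "n_rois": int(len(df)),
    }
    if "soma_area_um2" in df:
        out["soma_area_responders"] = _summ(df.loc[resp, "soma_area_um2"])
        out["soma_area_nonresponders"] = _summ(df.loc[~resp, "soma_area_um2"])
    return out


def soma_area_histogram(areas: pd.Series, bin_um2: float = 100.0) -> pd.Series:
    """Counts in fixed-width soma-area bins (cosmetic summary)."""
    top = float(np.ceil(areas.max() / bin_um2) * bin_um2)
    edges = np.arange(0.0, top + bin_um2, bin_um2)
    counts, _ = np.histogram(areas.to_numpy(), bins=edges)
    idx = [f"[{int(edges[i])},{int(edges[i + 1])})" for i in range(len(counts))]
    return pd.Series(counts, index=idx)
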