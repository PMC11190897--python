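"""Extracellular afferent-nerve analysis: spike detection, rate change,
concentration-response, waveform matching, distension response.

Spikes are field potentials exceeding twice the background noise. The
noise is estimated robustly (median absolute deviation scaled to RMS) on
a lightly smoothed trace — a 0.3 ms moving average consistent with the
100-1500 Hz acquisition band-pass — and the default threshold is twice a
peak-to-peak noise proxy (4x robust RMS) of that smoothed trace. Firing
is summarized as the peak change: maximal smoothed rate within 10 min
after drug onset minus the mean rate over the 5 min before it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from .simulate import Recording

__all__ = [
    "SpikeTrain",
    "PeakChange",
    "UnitAssignment",
    "detect_spikes",
    "rate_and_peak_change",
    "concentration_response",
    "match_units",
    "distension_response",
]

MAD_TO_RMS = 1.4826
NOISE_PEAK_TO_PEAK = 4.0  # robust RMS -> peak-to-peak proxy
THRESHOLD_MULT = 2.0  # "twice the background noise"


@dataclass
class SpikeTrain:
    times_s: np.ndarray
    amplitudes_uv: np.ndarray
    threshold_uv: float
    noise_uv: float
    duration_s: float

    def __post_init__(self) -> None:
        if len(self.times_s) > 1 and not (np.diff(self.times_s) > 0).all():
            raise ValueError("event times must be strictly increasing")


@dataclass
class PeakChange:
    baseline_rate: float  # spikes / s
    peak_rate: float
    peak_time_s: float

    @property
    def delta(self) -> float:
        return self.peak_rate - self.baseline_rate

    @property
    def percent_change(self) -> float:
        if self.baseline_rate == 0:
            return float("inf") if self.delta > 0 else 0.0
        return 100.0 * self.delta / self.baseline_rate


@dataclass
class UnitAssignment:
    labels: np.ndarray  # per-event unit id, 0-based
    templates: np.ndarray  # unit x snippet-sample mean waveforms
    n_units: int


def _smooth(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return v
    kernel = np.ones(width) / width
    return np.convolve(v, kernel, mode="same")


def detect_spikes(
    rec: Recording,
    noise_window: tuple[float, float] | None = None,
    dead_time_ms: float = 2.0,
    threshold_uv: float | None = None,
    smooth_ms: float = 0.3,
    noise_floor_uv: float = 0.0,
) -> SpikeTrain:
    """Absolute-value threshold crossing with a refractory dead time.

    Noise is MAD-based robust RMS of the smoothed trace over
    ``noise_window`` (whole record by default); threshold defaults to
    2 x (4 x robust RMS). One event per crossing group, timestamped at the
    absolute peak. ``threshold_uv`` overrides the automatic threshold (it
    applies to the smoothed trace).
    """
    width = max(int(round(smooth_ms * 1e-3 * rec.fs_hz)), 1)
    v = _smooth(rec.voltage_uv, width)
    if noise_window is None:
        seg = v
    else:
        i0, i1 = (int(round(w * rec.fs_hz)) for w in noise_window)
        seg = v[i0:i1]
    noise = MAD_TO_RMS * float(np.median(np.abs(seg - np.median(seg))))
    noise = max(noise, noise_floor_uv)
    if threshold_uv is None:
        if noise == 0:
            raise ValueError("zero noise estimate and no explicit threshold or floor")
        threshold_uv = THRESHOLD_MULT * NOISE_PEAK_TO_PEAK * noise

    absv = np.abs(v)
    above = absv > threshold_uv
    if not above.any():
        return SpikeTrain(
            np.array([]), np.array([]), float(threshold_uv), noise, rec.duration_s
        )
    idx = np.flatnonzero(above)
    dead = max(int(round(dead_time_ms * 1e-3 * rec.fs_hz)), 1)
    # split crossing samples into groups separated by >= dead time
    breaks = np.flatnonzero(np.diff(idx) >= dead)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    times = np.empty(len(starts))
    amps = np.empty(len(starts))
    for k, (s, e) in enumerate(zip(starts, ends)):
        grp = idx[s : e + 1]
        peak = grp[np.argmax(absv[grp])]
        times[k] = peak / rec.fs_hz
        amps[k] = absv[peak]
    # the peak-of-group rule can still leave two peaks closer than the dead
    # time; enforce it strictly
    keep = np.concatenate([[True], np.diff(times) >= dead_time_ms * 1e-3])
    return SpikeTrain(times[keep], amps[keep], float(threshold_uv), noise, rec.duration_s)


def rate_and_peak_change(
    train: SpikeTrain,
    drug_onset_s: float,
    bin_s: float = 1.0,
    smooth_s: float = 60.0,
    baseline_span_s: float = 300.0,
    post_span_s: float = 600.0,
) -> tuple[pd.Series, PeakChange]:
    """Smoothed rate histogram and the baseline-to-peak firing change.

    Rates are counted in ``bin_s`` bins and smoothed by a centered moving
    average over ``smooth_s``. Baseline = mean smoothed rate over the
    ``baseline_span_s`` before onset (shorter records use what is there,
    with a warning); peak = max smoothed rate in [onset, onset +
    post_span_s].
    """
    edges = np.arange(0.0, train.duration_s + bin_s, bin_s)
    counts, _ = np.histogram(train.times_s, bins=edges)
    rate = counts / bin_s
    width = max(int(round(smooth_s / bin_s)), 1)
    smoothed = _smooth(rate.astype(float), width)
    centers = edges[:-1] + bin_s / 2

    pre = (centers >= drug_onset_s - baseline_span_s) & (centers < drug_onset_s)
    if drug_onset_s < baseline_span_s:
        import warnings

        warnings.warn(
            f"only {drug_onset_s:.0f}s of pre-drug record; baseline uses available span",
            stacklevel=2,
        )
    if not pre.any():
        raise ValueError("no pre-drug bins")
    post = (centers >= drug_onset_s) & (centers <= drug_onset_s + post_span_s)
    if not post.any():
        raise ValueError("no bins after drug onset")

    baseline = float(smoothed[pre].mean())
    i_peak = np.flatnonzero(post)[np.argmax(smoothed[post])]
    pc = PeakChange(
        baseline_rate=baseline,
        peak_rate=float(smoothed[i_peak]),
        peak_time_s=float(centers[i_peak]),
    )
    return pd.Series(smoothed, index=centers, name="rate_hz"), pc


def _hill(x, emax, ec50, slope):
    return emax * x**slope / (ec50**slope + x**slope)


def concentration_response(
    peak_changes: dict[float, list[float]], fit_hill: bool = False
) -> tuple[pd.DataFrame, dict | None]:
    """Per-concentration n / mean / SEM, optional 3-parameter Hill fit.

    Empty concentration groups are omitted with a warning. The Hill fit
    (Emax, EC50, slope) needs at least three distinct concentrations.
    """
    rows = []
    for conc in sorted(peak_changes):
        vals = np.asarray(peak_changes[conc], dtype=float)
        if len(vals) == 0:
            import warnings

            warnings.warn(f"concentration {conc}: no recordings, omitted", stacklevel=2)
            continue
        rows.append(
            {
                "concentration": conc,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    fit = None
    if fit_hill:
        if len(table) < 3:
            raise ValueError("Hill fit needs >= 3 concentrations")
        x = table["concentration"].to_numpy()
        y = table["mean"].to_numpy()
        p0 = (max(y.max(), 1e-6), float(np.median(x)), 1.0)
        popt, _ = curve_fit(
            _hill, x, y, p0=p0, bounds=([0, 1e-9, 0.2], [np.inf, np.inf, 5.0]), maxfev=10_000
        )
        fit = {"emax": float(popt[0]), "ec50": float(popt[1]), "slope": float(popt[2])}
    return table, fit


def extract_snippets(
    rec: Recording, train: SpikeTrain, snippet_ms: float = 3.0
) -> np.ndarray:
    """Peak-aligned raw-voltage snippets around each event."""
    half = int(round(snippet_ms * 1e-3 * rec.fs_hz / 2))
    recenter = max(int(round(0.3e-3 * rec.fs_hz)), 1)
    n = len(rec.voltage_uv)
    snips = []
    for t in train.times_s:
        i = int(round(t * rec.fs_hz))
        # re-center on the raw absolute peak near the (smoothed) event time
        lo, hi = max(i - recenter, 0), min(i + recenter + 1, n)
        i = lo + int(np.argmax(np.abs(rec.voltage_uv[lo:hi])))
        if i - half < 0 or i + half >= n:
            continue
        snips.append(rec.voltage_uv[i - half : i + half])
    if not snips:
        raise ValueError("no complete snippets within the record")
    return np.asarray(snips)


def match_units(
    rec: Recording,
    train: SpikeTrain,
    snippet_ms: float = 3.0,
    merge_threshold: float = 1.5,
) -> UnitAssignment:
    """Single-unit assignment by waveform matching.

    Snippets are clustered by average-linkage agglomeration on Euclidean
    distance; the tree is cut where inter-cluster distance falls below
    ``merge_threshold`` x the expected noise distance between two
    waveforms of the same unit (sigma * sqrt(2m) for m snippet samples).
    """
    if len(train.times_s) < 10:
        raise ValueError("need >= 10 events for waveform matching")
    snips = extract_snippets(rec, train, snippet_ms)
    m = snips.shape[1]
    # raw-trace noise (snippets are unsmoothed; spikes are sparse enough
    # that the MAD is untouched by them)
    v = rec.voltage_uv
    sigma_raw = MAD_TO_RMS * float(np.median(np.abs(v - np.median(v))))
    noise_dist = sigma_raw * np.sqrt(2.0 * m)
    if noise_dist == 0:
        noise_dist = 1e-6
    z = linkage(snips, method="average", metric="euclidean")
    labels = fcluster(z, t=merge_threshold * noise_dist, criterion="distance") - 1
    n_units = int(labels.max()) + 1
    templates = np.stack([snips[labels == u].mean(axis=0) for u in range(n_units)])
    # iteratively merge the closest template pair while it falls below the
    # criterion: splits of one true unit have near-identical templates even
    # when snippet-level linkage keeps them apart
    while n_units > 1:
        d = pdist(templates)
        if d.min() >= merge_threshold * noise_dist:
            break
        flat = np.argmin(d)
        a, b = np.triu_indices(n_units, k=1)
        ia, ib = int(a[flat]), int(b[flat])
        labels[labels == ib] = ia
        labels[labels > ib] -= 1
        n_units -= 1
        templates = np.stack([snips[labels == u].mean(axis=0) for u in range(n_units)])
    return UnitAssignment(labels=labels, templates=templates, n_units=n_units)


def distension_response(
    train: SpikeTrain,
    pressure_mmhg: np.ndarray,
    fs_hz: float,
    pressure_threshold: float = 20.0,
    k_sd: float = 2.0,
    bin_s: float = 1.0,
) -> dict:
    """Is the unit driven by luminal distension above the threshold?

    Rates are binned at ``bin_s``; a unit is responsive when its mean rate
    in supra-threshold-pressure bins exceeds the sub-threshold mean by
    more than ``k_sd`` x the SD of sub-threshold bin rates.
    """
    n_bins = int(np.floor(len(pressure_mmhg) / (bin_s * fs_hz)))
    if n_bins < 2:
        raise ValueError("record too short for binned rates")
    edges = np.arange(0, n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times_s, bins=edges)
    rates = counts / bin_s
    p_bin = np.array(
        [
            pressure_mmhg[int(i * bin_s * fs_hz) : int((i + 1) * bin_s * fs_hz)].mean()
            for i in range(n_bins)
        ]
    )
    above = p_bin > pressure_threshold
    if not above.any():
        raise ValueError(f"pressure never exceeds {pressure_threshold} mm Hg")
    below = ~above
    rate_above = float(rates[above].mean())
    rate_below = float(rates[below].mean()) if below.any() else 0.0
    sd_below = float(rates[below].std(ddof=1)) if below.sum() > 1 else 0.0
    return {
        "responsive": rate_above - rate_below > k_sd * sd_below,
        "rate_above_hz": rate_above,
        "rate_below_hz": rate_below,
        "sd_below_hz": sd_below,
    }
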