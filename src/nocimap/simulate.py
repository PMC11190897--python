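"""Synthetic data generators with known ground truth.

Every downstream stage of the package consumes one of six input kinds:
bulk RNAseq counts, a single-neuron TPM matrix, Ca2+ fluorescence traces,
extracellular nerve recordings, two-channel micrographs, and gene-set
libraries. None of the corresponding biological datasets is bundled, so
these generators emulate each kind with planted, recoverable structure
(DE genes, receptor-positive cells, responder ROIs, spike trains, cell
counts). All randomness flows through a single integer seed; identical
arguments give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bulk_de import CountMatrix

__all__ = [
    "SimulationConfig",
    "simulate_bulk_counts",
    "simulate_neuron_expression",
    "simulate_trace_set",
    "simulate_recording",
    "simulate_micrograph",
    "TraceSet",
    "Recording",
]


# ---------------------------------------------------------------------------
# bulk counts


@dataclass
class SimulationConfig:
    """Parameters of the bulk NB count simulation.

    ``dispersion`` is the NB phi (variance = mu + phi*mu^2); 0 gives the
    Poisson limit. Planted DE genes receive a group-specific log2 fold
    change drawn N(0, fold_change_log_sd) with |lfc| >= 0.5 so "true DE"
    is unambiguous.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 8
    n_de_genes: int = 100
    baseline_mean_log_mu: float = 4.0
    baseline_sd_log_mu: float = 1.5
    dispersion: float = 0.2
    fold_change_log_sd: float = 2.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    group_names: tuple[str, str] = ("control", "case")

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples_per_group) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_bulk_counts(config: SimulationConfig) -> tuple[CountMatrix, dict]:
    """NB gene x sample counts with planted DE genes.

    Returns the count matrix and a ground-truth dict holding the DE gene
    ids and their planted log2 fold changes (case over control).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_samples_per_group

    log_mu = rng.normal(config.baseline_mean_log_mu, config.baseline_sd_log_mu, size=G)
    base_mu = np.exp(log_mu)

    de_idx = rng.choice(G, size=config.n_de_genes, replace=False)
    lfc = np.zeros(G)
    if config.n_de_genes:
        draws = rng.normal(0.0, config.fold_change_log_sd, size=4 * config.n_de_genes + 16)
        draws = draws[np.abs(draws) >= 0.5]
        while len(draws) < config.n_de_genes:  # pragma: no cover - ample margin
            draws = np.concatenate(
                [draws, rng.normal(0.0, config.fold_change_log_sd, size=4 * config.n_de_genes)]
            )
            draws = draws[np.abs(draws) >= 0.5]
        lfc[de_idx] = draws[: config.n_de_genes]

    lo, hi = config.library_size_range
    lib = rng.integers(lo, hi + 1, size=2 * n).astype(float)

    # per-gene relative abundance; case group gets the fold change
    rel = base_mu / base_mu.sum()
    rel_case = base_mu * 2.0**lfc
    rel_case = rel_case / rel_case.sum()
    mu = np.empty((G, 2 * n))
    mu[:, :n] = rel[:, None] * lib[None, :n]
    mu[:, n:] = rel_case[:, None] * lib[None, n:]

    counts = _nb_draw(rng, mu, config.dispersion)
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    sample_ids = [f"{g}_{j}" for g in config.group_names for j in range(n)]
    groups = pd.Series(
        [config.group_names[0]] * n + [config.group_names[1]] * n, index=sample_ids
    )
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), groups)
    truth = {
        "de_gene_ids": [gene_ids[i] for i in sorted(de_idx)],
        "log2fc": {gene_ids[i]: float(lfc[i]) for i in sorted(de_idx)},
    }
    return cm, truth


# ---------------------------------------------------------------------------
# single-neuron TPM matrix


@dataclass
class GeneSpec:
    """Expression rule for one gene in the simulated neuron matrix.

    ``rate_by_population`` maps population name -> probability that a cell
    of that population expresses the gene (lognormal TPM when positive).
    ``conditional_on`` optionally couples positivity to another gene's
    planted state: (gene, rate_if_positive, rate_if_negative).
    """

    gene: str
    rate_by_population: dict[str, float] = field(default_factory=dict)
    default_rate: float = 0.0
    log_tpm_mean: float = 3.0
    log_tpm_sd: float = 1.0
    dropout_tpm: float = 0.0
    conditional_on: tuple[str, float, float] | None = None


def simulate_neuron_expression(
    n_cells: int,
    populations: dict[str, float],
    gene_specs: list[GeneSpec],
    seed: int = 0,
    background_genes: int = 20,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Gene x cell TPM matrix with planted per-cell positivity.

    Returns (tpm DataFrame, population Series, truth dict with per-gene
    boolean positivity arrays). Population fractions must sum to 1.
    """
    fr = np.array(list(populations.values()), dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    rng = np.random.default_rng(seed)
    names = list(populations)
    pop = rng.choice(len(names), size=n_cells, p=fr)
    pop_labels = pd.Series([names[i] for i in pop], index=[f"cell{i:04d}" for i in range(n_cells)])

    flags: dict[str, np.ndarray] = {}
    rows = {}
    for spec in gene_specs:
        if spec.conditional_on is not None:
            parent, r_pos, r_neg = spec.conditional_on
            if parent not in flags:
                raise ValueError(f"conditional gene {spec.gene} listed before parent {parent}")
            rate = np.where(flags[parent], r_pos, r_neg)
        else:
            rate = np.array(
                [spec.rate_by_population.get(names[i], spec.default_rate) for i in pop]
            )
        positive = rng.random(n_cells) < rate
        tpm = np.where(
            positive,
            np.exp(rng.normal(spec.log_tpm_mean, spec.log_tpm_sd, size=n_cells)),
            spec.dropout_tpm,
        )
        flags[spec.gene] = positive
        rows[spec.gene] = tpm
    for b in range(background_genes):
        rows[f"bg{b:03d}"] = np.exp(rng.normal(1.0, 1.0, size=n_cells))

    tpm_df = pd.DataFrame(rows, index=pop_labels.index).T
    truth = {g: f.tolist() for g, f in flags.items()}
    return tpm_df, pop_labels, truth


# ---------------------------------------------------------------------------
# Ca2+ traces


@dataclass
class TraceSet:
    """Per-ROI fluorescence series with shared acquisition metadata."""

    traces: pd.DataFrame  # time in rows (seconds index), one column per ROI
    frame_rate_hz: float
    windows: list[tuple[str, float, float]]  # (label, start_s, end_s)
    kcl_window: tuple[float, float]
    background: float = 0.0
    soma_area_um2: pd.Series | None = None
    reporter: pd.Series | None = None

    @property
    def roi_ids(self) -> pd.Index:
        return self.traces.columns

    @property
    def times(self) -> np.ndarray:
        return self.traces.index.to_numpy(dtype=float)


def _transient(t: np.ndarray, onset: float, amp: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel, unit peak, scaled to ``amp``."""
    dt = t - onset
    k = np.where(dt > 0, np.exp(-dt / decay) - np.exp(-dt / rise), 0.0)
    peak = k.max() if k.max() > 0 else 1.0
    return amp * k / peak


def simulate_trace_set(
    n_rois: int,
    frame_rate_hz: float = 2.5,
    duration_s: float = 240.0,
    drug_window: tuple[float, float] = (60.0, 90.0),
    kcl_window: tuple[float, float] = (180.0, 210.0),
    responder_fraction: float = 0.4,
    responder_amplitude: float = 0.5,
    amplitude_sd: float = 0.1,
    kcl_amplitude: float = 1.0,
    dead_fraction: float = 0.0,
    noise_sd: float = 0.02,
    background: float = 10.0,
    baseline_level: float = 50.0,
    rise_s: float = 1.0,
    decay_s: float = 8.0,
    seed: int = 0,
    drug_label: str = "drug",
) -> tuple[TraceSet, dict]:
    """Fluorescence traces with planted responders and KCl positives.

    Responder amplitude is expressed on the normalized F/F_pos scale
    (fraction of the KCl response); noise_sd on the same scale. A planted
    "dead" fraction receives no KCl transient and must fail downstream QC.
    """
    for w in (drug_window, kcl_window):
        if not (0 <= w[0] < w[1] <= duration_s):
            raise ValueError(f"window {w} outside record of {duration_s}s")
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration_s, 1.0 / frame_rate_hz)

    responder = rng.random(n_rois) < responder_fraction
    dead = rng.random(n_rois) < dead_fraction
    responder &= ~dead
    amps = np.clip(rng.normal(responder_amplitude, amplitude_sd, size=n_rois), 0.15, None)
    soma = np.clip(rng.normal(500.0, 150.0, size=n_rois), 80.0, None)
    reporter = rng.random(n_rois) < 0.8

    kcl_scale = kcl_amplitude * baseline_level  # raw fluorescence units
    data = np.empty((len(t), n_rois))
    for i in range(n_rois):
        y = np.full_like(t, baseline_level) + background
        if not dead[i]:
            y += _transient(t, kcl_window[0], kcl_scale, rise_s, decay_s)
            if responder[i]:
                y += _transient(t, drug_window[0], amps[i] * kcl_scale, rise_s, decay_s)
        y += rng.normal(0.0, noise_sd * kcl_scale, size=len(t))
        data[:, i] = np.maximum(y, 0.0)

    roi_ids = [f"roi{i:04d}" for i in range(n_rois)]
    ts = TraceSet(
        traces=pd.DataFrame(data, index=t, columns=roi_ids),
        frame_rate_hz=frame_rate_hz,
        windows=[(drug_label, *drug_window)],
        kcl_window=kcl_window,
        background=background,
        soma_area_um2=pd.Series(soma, index=roi_ids),
        reporter=pd.Series(reporter, index=roi_ids),
    )
    truth = {
        "responder": responder.tolist(),
        "dead": dead.tolist(),
        "amplitude": amps.tolist(),
        "soma_area_um2": soma.tolist(),
        "reporter": reporter.tolist(),
    }
    return ts, truth


# ---------------------------------------------------------------------------
# nerve recording


@dataclass
class UnitSpec:
    """One afferent unit: biphasic template amplitude and firing rates."""

    amplitude_uv: float
    baseline_rate_hz: float
    drug_rate_hz: float
    width_ms: float = 2.0


@dataclass
class Recording:
    """Single-channel extracellular voltage plus optional luminal pressure."""

    voltage_uv: np.ndarray
    fs_hz: float
    drug_window: tuple[float, float]
    pressure_mmhg: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return len(self.voltage_uv) / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltage_uv)) / self.fs_hz


def spike_template(width_ms: float, fs_hz: float) -> np.ndarray:
    """Biphasic difference-of-Gaussians waveform, unit positive peak.

    The repolarization lobe is half the depolarization amplitude, as in
    real extracellular field potentials, so the absolute peak is always
    the positive lobe.
    """
    n = int(round(width_ms * 1e-3 * fs_hz))
    t = (np.arange(n) - n / 2) / fs_hz * 1e3  # ms, centered
    sig = width_ms / 7.0
    w = np.exp(-((t + sig) ** 2) / (2 * sig**2)) - 0.5 * np.exp(
        -((t - sig) ** 2) / (2 * (1.5 * sig) ** 2)
    )
    return w / np.abs(w).max()


def simulate_recording(
    duration_s: float = 120.0,
    fs_hz: float = 20_000.0,
    units: list[UnitSpec] | None = None,
    noise_uv: float = 15.0,
    drug_window: tuple[float, float] = (60.0, 120.0),
    pressure_ramp: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Voltage record as a sum of biphasic templates at Poisson times.

    Each unit fires at its baseline rate outside the drug window and at
    its drug rate inside it. ``pressure_ramp`` = (start_s, end_s,
    peak_mmhg) adds a triangular luminal-pressure channel. Truth holds
    exact event times per unit and a detectability warning for units whose
    amplitude does not exceed twice the noise RMS.
    """
    if fs_hz < 10_000:
        raise ValueError("sampling rate must be >= 10 kHz")
    units = units if units is not None else [UnitSpec(120.0, 1.0, 10.0)]
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    v = rng.normal(0.0, noise_uv, size=n) if noise_uv > 0 else np.zeros(n)

    truth_units = []
    for u in units:
        tpl = spike_template(u.width_ms, fs_hz) * u.amplitude_uv
        peak_off = int(np.argmax(np.abs(tpl)))  # align truth times to the peak
        times = []
        for lo, hi, rate in _rate_segments(duration_s, drug_window, u):
            if rate <= 0:
                continue
            n_ev = rng.poisson(rate * (hi - lo))
            times.append(rng.uniform(lo, hi, size=n_ev))
        ev = np.sort(np.concatenate(times)) if times else np.array([])
        # enforce a refractory gap of one template width
        if len(ev) > 1:
            keep = np.concatenate([[True], np.diff(ev) > u.width_ms * 1e-3])
            ev = ev[keep]
        for s in ev:
            i0 = int(round(s * fs_hz)) - peak_off
            j0 = max(i0, 0)
            j1 = min(i0 + len(tpl), n)
            v[j0:j1] += tpl[j0 - i0 : j1 - i0]
        truth_units.append(
            {
                "times_s": ev.tolist(),
                "amplitude_uv": u.amplitude_uv,
                "baseline_rate_hz": u.baseline_rate_hz,
                "drug_rate_hz": u.drug_rate_hz,
                "detectable": bool(u.amplitude_uv > 2 * noise_uv),
            }
        )

    pressure = None
    if pressure_ramp is not None:
        t0, t1, peak = pressure_ramp
        tt = np.arange(n) / fs_hz
        up = np.clip((tt - t0) / max((t1 - t0) / 2, 1e-9), 0, 1)
        down = np.clip((t1 - tt) / max((t1 - t0) / 2, 1e-9), 0, 1)
        pressure = peak * np.minimum(up, down)
        pressure[(tt < t0) | (tt > t1)] = 0.0

    rec = Recording(voltage_uv=v, fs_hz=fs_hz, drug_window=drug_window, pressure_mmhg=pressure)
    return rec, {"units": truth_units, "noise_uv": noise_uv}


def _rate_segments(duration_s, drug_window, unit):
    d0 = min(max(drug_window[0], 0.0), duration_s)
    d1 = min(max(drug_window[1], d0), duration_s)
    segs = []
    if d0 > 0:
        segs.append((0.0, d0, unit.baseline_rate_hz))
    if d1 > d0:
        segs.append((d0, d1, unit.drug_rate_hz))
    if d1 < duration_s:
        segs.append((d1, duration_s, unit.baseline_rate_hz))
    return segs


# ---------------------------------------------------------------------------
# micrograph


def simulate_micrograph(
    n_green: int,
    n_blue_only: int,
    image_shape: tuple[int, int] = (512, 512),
    radius_range: tuple[int, int] = (8, 14),
    min_separation: float | None = None,
    foreground: int = 200,
    background_level: int = 20,
    noise_sd: float = 4.0,
    seed: int = 0,
    max_tries: int = 20_000,
) -> tuple[np.ndarray, dict]:
    """Two-channel 8-bit micrograph with planted cell counts.

    Channel 0 (neuron marker, "green") contains ``n_green`` disks; channel
    1 (nuclear, "blue") contains disks at all ``n_green + n_blue_only``
    positions — every neuron has a nucleus, blue-only objects are
    non-neuronal. ``min_separation`` (default 2.2 x max radius) controls
    crowding; lowering it toward 1.0 x produces touching objects.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    r_lo, r_hi = radius_range
    if min_separation is None:
        min_separation = 2.2 * r_hi
    n_total = n_green + n_blue_only

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n_total:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place objects: frame too crowded")
        r = rng.uniform(r_lo, r_hi)
        y = rng.uniform(r + 2, h - r - 2)
        x = rng.uniform(r + 2, w - r - 2)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_separation**2 for cy, cx in centers):
            centers.append((y, x))
            radii.append(r)

    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((2, h, w), dtype=float)
    img += background_level
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[1][mask] = foreground  # every object has a nucleus
        if i < n_green:
            img[0][mask] = foreground
    img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = {
        "centers": [list(c) for c in centers],
        "radii": radii,
        "is_neuron": [i < n_green for i in range(n_total)],
        "n_green": n_green,
        "n_blue": n_total,
        "neuron_fraction": (n_green / n_total) if n_total else 0.0,
    }
    return img, truth


# ---------------------------------------------------------------------------
# file output


def write_counts_tsv(cm: CountMatrix, counts_path, groups_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.groups.values}).to_csv(
        groups_path, sep="\t", index=False
    )


def read_counts_tsv(counts_path, groups_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t").set_index("sample_id")["group"]
    return CountMatrix(counts, groups)


def write_trace_h5(ts: TraceSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=ts.times)
        f.create_dataset("traces", data=ts.traces.to_numpy())
        f.attrs["roi_ids"] = list(ts.roi_ids)
        f.attrs["frame_rate_hz"] = ts.frame_rate_hz
        f.attrs["kcl_window"] = ts.kcl_window
        f.attrs["background"] = ts.background
        f.attrs["window_labels"] = [w[0] for w in ts.windows]
        f.attrs["window_spans"] = [(w[1], w[2]) for w in ts.windows]
        if ts.soma_area_um2 is not None:
            f.create_dataset("soma_area_um2", data=ts.soma_area_um2.to_numpy())
        if ts.reporter is not None:
            f.create_dataset("reporter", data=ts.reporter.to_numpy())


def read_trace_h5(path) -> TraceSet:
    import h5py

    with h5py.File(path, "r") as f:
        t = f["time_s"][:]
        data = f["traces"][:]
        roi_ids = list(f.attrs["roi_ids"])
        windows = [
            (str(lbl), float(a), float(b))
            for lbl, (a, b) in zip(f.attrs["window_labels"], f.attrs["window_spans"])
        ]
        soma = f["soma_area_um2"][:] if "soma_area_um2" in f else None
        rep = f["reporter"][:] if "reporter" in f else None
        return TraceSet(
            traces=pd.DataFrame(data, index=t, columns=roi_ids),
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            windows=windows,
            kcl_window=tuple(f.attrs["kcl_window"]),
            background=float(f.attrs["background"]),
            soma_area_um2=pd.Series(soma, index=roi_ids) if soma is not None else None,
            reporter=pd.Series(rep.astype(bool), index=roi_ids) if rep is not None else None,
        )


def write_recording_h5(rec: Recording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("voltage_uv", data=rec.voltage_uv)
        if rec.pressure_mmhg is not None:
            f.create_dataset("pressure_mmhg", data=rec.pressure_mmhg)
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["drug_window"] = rec.drug_window


def read_recording_h5(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        return Recording(
            voltage_uv=f["voltage_uv"][:],
            fs_hz=float(f.attrs["fs_hz"]),
            drug_window=tuple(f.attrs["drug_window"]),
            pressure_mmhg=f["pressure_mmhg"][:] if "pressure_mmhg" in f else None,
        )


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
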