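"""Seeded generators for every input class the pipelines consume.

Each generator emulates one experimental protocol with known ground truth:

* stimulus-evoked calcium transients transduced through the Hill response
  of an intensity sensor (RCaMP1e-like),
* FCCP depletion / washout-recovery ATP trajectories seen through a
  ratiometric FRET sensor (ATeam1.03-like),
* roGFP-style redox traces with DTT and H₂O₂ calibration plateaus,
* TMRM mito/cytosol ROI intensity pairs around an FCCP challenge,
* Poisson-timed synchronized network bursts over a few hundred neurons,
* 1:1 binding titration shift series with an mM-range Kd.

The forward models reuse :mod:`sensortrace.sensors` — no duplicated math —
so pipeline inversions tested against these generators are true round-trips.
Noise is additive Gaussian on the emitted signal, with SNR defined as peak
signal amplitude divided by the noise SD. Every generator is deterministic
given its seed, which is recorded in the returned :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nmr import TitrationSeries
from .sensors import ATEAM103, RCAMP1E, SensorSpec, hill_fraction_bound, ratio_from_atp
from .traces import TimeSeriesTrace

__all__ = [
    "GroundTruth",
    "gen_dff_population",
    "gen_calcium_population",
    "gen_atp_trace",
    "gen_redox_trace",
    "gen_tmrm_pairs",
    "gen_network_raster",
    "gen_titration",
]


@dataclass
class GroundTruth:
    """True parameters behind one synthetic dataset."""

    scenario: str
    parameters: dict
    seed: int
    noise_model: str = "additive_gaussian"

    def as_metadata(self) -> dict:
        return {"scenario": self.scenario, "seed": self.seed,
                "noise_model": self.noise_model, **self.parameters}


def _transient(t: np.ndarray, onset: float, amplitude: float, tau: float) -> np.ndarray:
    """Instantaneous-rise, mono-exponential-decay kernel."""
    out = np.zeros_like(t)
    after = t >= onset
    out[after] = amplitude * np.exp(-(t[after] - onset) / tau)
    return out


def gen_dff_population(
    n_neurons: int = 100,
    stim_time: float = 10.0,
    amplitude: float = 1.2,
    tau: float = 2.0,
    responder_fraction: float = 0.96,
    snr: float = 10.0,
    duration: float = 40.0,
    dt: float = 0.1,
    seed: int = 0,
) -> Tuple[List[TimeSeriesTrace], GroundTruth]:
    """Population of ΔF/F0-domain stimulus-evoked transients.

    Emits already-normalized traces whose decay is exactly mono-exponential
    with the stated τ — the reference for decay-kinetics recovery, where the
    truth must live in the fluorescence domain. Exactly
    round(responder_fraction·n) traces carry a transient; the rest are noise.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    n_resp = int(round(responder_fraction * n_neurons))
    resp_idx = set(rng.permutation(n_neurons)[:n_resp].tolist())
    sigma = amplitude / snr
    traces = []
    for i in range(n_neurons):
        y = rng.normal(0.0, sigma, size=t.size)
        if i in resp_idx:
            y += _transient(t, stim_time, amplitude, tau)
        traces.append(
            TimeSeriesTrace(
                trace_id=f"n{i:03d}", t=t.copy(), values=y,
                events=[("stimulus", stim_time)], units="dF/F0",
            )
        )
    truth = GroundTruth(
        scenario="dff_population",
        parameters=dict(
            n_neurons=n_neurons, stim_time=stim_time, amplitude=amplitude,
            tau=tau, responder_fraction=responder_fraction,
            n_responders=n_resp, snr=snr, dt=dt,
        ),
        seed=seed,
    )
    return traces, truth


def gen_calcium_population(
    n_neurons: int = 100,
    stim_time: float = 10.0,
    ca_rest: float = 0.1,  # μM
    ca_amplitude: float = 1.5,  # μM above rest at the transient peak
    tau: float = 2.0,  # s, free-Ca²⁺ clearance
    sensor: SensorSpec = RCAMP1E,
    responder_fraction: float = 0.96,
    snr: float = 10.0,
    f_background: float = 20.0,
    f_span: float = 200.0,
    duration: float = 40.0,
    dt: float = 0.1,
    seed: int = 0,
) -> Tuple[List[TimeSeriesTrace], GroundTruth]:
    """Raw-fluorescence calcium population seen through the Hill sensor model.

    The underlying free-Ca²⁺ transient (rest + amplitude·exp-decay) is
    transduced through :func:`hill_fraction_bound` before noise, so sensor
    saturation at large amplitudes (KCl-like depolarization) is reproduced
    by raising ``ca_amplitude`` well above the sensor Kd.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    n_resp = int(round(responder_fraction * n_neurons))
    resp_idx = set(rng.permutation(n_neurons)[:n_resp].tolist())

    f_rest = f_background + f_span * hill_fraction_bound(ca_rest, sensor)
    f_peak = f_background + f_span * hill_fraction_bound(ca_rest + ca_amplitude, sensor)
    sigma = max(f_peak - f_rest, 1e-12) / snr

    traces = []
    for i in range(n_neurons):
        ca = np.full(t.size, ca_rest)
        if i in resp_idx:
            ca = ca + _transient(t, stim_time, ca_amplitude, tau)
        f = f_background + f_span * hill_fraction_bound(ca, sensor)
        f = f + rng.normal(0.0, sigma, size=t.size)
        traces.append(
            TimeSeriesTrace(
                trace_id=f"n{i:03d}", t=t.copy(), values=f,
                events=[("stimulus", stim_time)],
            )
        )
    truth = GroundTruth(
        scenario="calcium_population",
        parameters=dict(
            n_neurons=n_neurons, stim_time=stim_time, ca_rest=ca_rest,
            ca_amplitude=ca_amplitude, tau=tau, sensor=sensor.name,
            responder_fraction=responder_fraction, n_responders=n_resp,
            snr=snr, peak_dff_true=(f_peak - f_rest) / f_rest, dt=dt,
        ),
        seed=seed,
    )
    return traces, truth


def _atp_trajectory(
    t: np.ndarray,
    baseline: float,
    consumption_rate: float,
    production_rate: float,
    events: Sequence[Tuple[str, float]],
    kainate_factor: float,
) -> np.ndarray:
    """Piecewise-linear true ATP (mM), clipped to [0, baseline]."""
    # breakpoints: challenge onsets decline, washouts recover
    slope_changes = []
    for label, when in events:
        if label == "FCCP_on":
            slope_changes.append((when, consumption_rate))
        elif label == "kainate_on":
            slope_changes.append((when, consumption_rate * kainate_factor))
        elif label == "washout":
            factor = kainate_factor if any(
                lbl == "kainate_on" and w < when for lbl, w in events
            ) else 1.0
            slope_changes.append((when, production_rate * factor))
    slope_changes.sort()

    atp = np.empty_like(t)
    value, slope, prev = baseline, 0.0, t[0]
    j = 0
    for i, ti in enumerate(t):
        while j < len(slope_changes) and slope_changes[j][0] <= ti:
            value = float(np.clip(value + slope * (slope_changes[j][0] - prev), 0.0, baseline))
            prev, slope = slope_changes[j][0], slope_changes[j][1]
            j += 1
        atp[i] = np.clip(value + slope * (ti - prev), 0.0, baseline)
    return atp


def gen_atp_trace(
    baseline_atp: float = 2.0,  # mM
    consumption_rate: float = -0.04,  # mM/s after FCCP
    production_rate: float = 0.03,  # mM/s after washout
    events: Optional[Sequence[Tuple[str, float]]] = None,
    sensor: SensorSpec = ATEAM103,
    rmin: float = 0.5,
    snr: float = 20.0,
    duration: float = 600.0,
    dt: float = 1.0,
    kainate_factor: float = 1.5,
    seed: int = 0,
    trace_id: str = "atp",
) -> Tuple[TimeSeriesTrace, GroundTruth]:
    """FCCP-uncoupling ATP assay trace: ratio = FRET(ATP(t)) + noise.

    The default protocol is baseline, FCCP challenge (ATP declines linearly
    to the 0-mM floor and plateaus), washout recovery, then a second, harsher
    FCCP+kainate challenge. The depletion plateau at the floor is what the
    assay uses as the sensor's Rmin calibration.
    """
    if events is None:
        events = [
            ("FCCP_on", 60.0), ("washout", 240.0),
            ("kainate_on", 360.0), ("washout", 480.0),
        ]
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    atp = _atp_trajectory(
        t, baseline_atp, consumption_rate, production_rate, list(events),
        kainate_factor,
    )
    ratio = ratio_from_atp(atp, sensor, rmin=rmin)
    peak_signal = float(ratio_from_atp(baseline_atp, sensor, rmin=rmin) - rmin)
    noise = rng.normal(0.0, peak_signal / snr, size=t.size) if np.isfinite(snr) else 0.0
    trace = TimeSeriesTrace(
        trace_id=trace_id, t=t, values=ratio + noise,
        events=list(events), units="FRET ratio",
    )
    truth = GroundTruth(
        scenario="atp_fccp",
        parameters=dict(
            baseline_atp=baseline_atp, consumption_rate=consumption_rate,
            production_rate=production_rate, rmin=rmin, sensor=sensor.name,
            kainate_factor=kainate_factor, snr=snr, dt=dt,
        ),
        seed=seed,
    )
    return trace, truth


def gen_redox_trace(
    fraction_reduced: float = 0.9,
    f_red: float = 2.0,
    f_ox: float = 0.5,
    dtt_on: float = 120.0,
    h2o2_on: float = 300.0,
    duration: float = 480.0,
    tau_transition: float = 5.0,
    snr: float = 30.0,
    dt: float = 0.5,
    seed: int = 0,
    trace_id: str = "rogfp",
) -> Tuple[TimeSeriesTrace, GroundTruth]:
    """roGFP-style ratio trace: baseline, DTT-reduced plateau, H₂O₂-oxidized plateau.

    The baseline sits at f_ox + fraction_reduced·(f_red − f_ox); each
    superfusion switch relaxes exponentially (τ ``tau_transition``) to the
    new plateau, emulating solution exchange. Reduced-high ratio convention.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    base_level = f_ox + fraction_reduced * (f_red - f_ox)
    y = np.full(t.size, base_level)
    for onset, target in ((dtt_on, f_red), (h2o2_on, f_ox)):
        after = t >= onset
        start = y[after][0] if np.any(after) else base_level
        y[after] = target + (start - target) * np.exp(-(t[after] - onset) / tau_transition)
    noise_sd = abs(f_red - f_ox) / snr
    trace = TimeSeriesTrace(
        trace_id=trace_id, t=t, values=y + rng.normal(0.0, noise_sd, t.size),
        events=[("DTT_on", dtt_on), ("H2O2_on", h2o2_on)],
        units="ratio",
    )
    truth = GroundTruth(
        scenario="redox_calibration",
        parameters=dict(
            fraction_reduced=fraction_reduced, f_red=f_red, f_ox=f_ox,
            dtt_on=dtt_on, h2o2_on=h2o2_on, snr=snr, dt=dt,
        ),
        seed=seed,
    )
    return trace, truth


def gen_tmrm_pairs(
    n_pairs: int = 30,
    ratio_mean: float = 4.0,
    ratio_sd: float = 1.0,
    cyto_level: float = 20.0,
    fccp_time: float = 60.0,
    duration: float = 120.0,
    mito_post_factor: float = 0.4,
    cyto_post_factor: float = 1.6,
    snr: float = 20.0,
    dt: float = 1.0,
    seed: int = 0,
) -> Tuple[List[Tuple[TimeSeriesTrace, TimeSeriesTrace]], GroundTruth]:
    """Paired mito/cytosol TMRM ROI intensity traces around an FCCP challenge.

    Each pair's true pre-FCCP mito/cyto ratio is drawn from
    N(ratio_mean, ratio_sd²) truncated at 1.2 (polarized mitochondria are
    brighter than cytosol). After FCCP the mito signal collapses toward the
    cytosolic level and the cytosolic signal rises as dye redistributes.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    pre = t < fccp_time
    pairs = []
    true_ratios = []
    for i in range(n_pairs):
        ratio = max(1.2, rng.normal(ratio_mean, ratio_sd))
        true_ratios.append(ratio)
        mito_pre = cyto_level * ratio
        mito = np.where(pre, mito_pre, mito_pre * mito_post_factor)
        cyto = np.where(pre, cyto_level, cyto_level * cyto_post_factor)
        sd = mito_pre / snr
        ev = [("FCCP_on", fccp_time)]
        pairs.append((
            TimeSeriesTrace(f"mito{i:02d}", t.copy(),
                            mito + rng.normal(0, sd, t.size), events=list(ev)),
            TimeSeriesTrace(f"cyto{i:02d}", t.copy(),
                            cyto + rng.normal(0, sd / 2, t.size), events=list(ev)),
        ))
    truth = GroundTruth(
        scenario="tmrm_pairs",
        parameters=dict(
            n_pairs=n_pairs, ratio_mean=ratio_mean, ratio_sd=ratio_sd,
            true_ratio_sample_mean=float(np.mean(true_ratios)),
            fccp_time=fccp_time, snr=snr,
        ),
        seed=seed,
    )
    return pairs, truth


def gen_network_raster(
    n_neurons: int = 225,
    burst_rate_per_min: float = 10.0,
    participation: float = 0.8,
    indep_rate_hz: float = 0.02,
    kernel_tau: float = 1.0,
    amplitude: float = 1.0,
    recording_length: float = 180.0,
    dt: float = 0.1,
    snr: float = 10.0,
    jitter_sd: float = 0.1,
    min_burst_gap: float = 2.0,
    f0: float = 100.0,
    seed: int = 0,
) -> Tuple[List[TimeSeriesTrace], GroundTruth]:
    """Spontaneous-activity raster with stochastically timed synchronized bursts.

    Burst onsets follow a hard-core renewal process: a refractory gap of
    ``min_burst_gap`` seconds (network refractoriness; also keeps distinct
    bursts resolvable) plus an exponential waiting time whose mean is set so
    the realized rate matches ``burst_rate_per_min`` — Poisson-like timing
    without the rate suppression a naive dead-time thinning would cause.
    Each burst
    recruits each neuron independently with probability ``participation``,
    with a small Gaussian onset jitter. Neurons additionally fire
    independent events at ``indep_rate_hz``. Traces are raw fluorescence
    F0·(1 + ΔF/F0): event kernels (instant rise, exponential decay) plus
    Gaussian noise with SD = amplitude/snr.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, recording_length, dt)

    # renewal burst onsets with refractory gap; edges avoided so each
    # burst's rise is inside the recording
    burst_onsets: List[float] = []
    if burst_rate_per_min > 0:
        mean_gap = 60.0 / burst_rate_per_min
        if mean_gap <= min_burst_gap:
            raise ValueError(
                f"burst rate {burst_rate_per_min}/min incompatible with a "
                f"{min_burst_gap}-s refractory gap"
            )
        exp_mean = mean_gap - min_burst_gap
        t_next = 2.0 + rng.exponential(exp_mean)
        while t_next < recording_length - 2.0:
            burst_onsets.append(float(t_next))
            t_next += min_burst_gap + rng.exponential(exp_mean)

    sigma = amplitude / snr
    traces = []
    per_burst_counts = np.zeros(len(burst_onsets))
    for i in range(n_neurons):
        dff = rng.normal(0.0, sigma, size=t.size)
        onsets = []
        for b, onset in enumerate(burst_onsets):
            if rng.random() < participation:
                onsets.append(onset + abs(rng.normal(0.0, jitter_sd)))
                per_burst_counts[b] += 1
        n_ind = rng.poisson(indep_rate_hz * recording_length)
        onsets.extend(rng.uniform(0.0, recording_length, n_ind).tolist())
        for o in onsets:
            dff += _transient(t, o, amplitude, kernel_tau)
        traces.append(
            TimeSeriesTrace(trace_id=f"n{i:03d}", t=t.copy(), values=f0 * (1.0 + dff))
        )
    truth = GroundTruth(
        scenario="network_raster",
        parameters=dict(
            n_neurons=n_neurons, burst_rate_per_min=burst_rate_per_min,
            participation=participation, indep_rate_hz=indep_rate_hz,
            n_bursts_true=len(burst_onsets),
            burst_onsets_true=burst_onsets,
            mean_participation_true=float(per_burst_counts.mean() / n_neurons)
            if burst_onsets else None,
            recording_length=recording_length, snr=snr, dt=dt,
        ),
        seed=seed,
    )
    return traces, truth


def gen_titration(
    kd_true: float = 1.95,  # mM
    delta_max: Optional[Dict[int, float]] = None,  # residue -> ppm
    conc: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.5, 6.0),
    noise_fraction: float = 0.05,
    seed: int = 0,
) -> Tuple[List[TitrationSeries], GroundTruth]:
    """Per-residue 1:1 binding titration series with proportional noise.

    Shifts follow the ligand-excess hyperbola Δδmax·L/(Kd + L); each point
    carries multiplicative Gaussian noise with relative SD
    ``noise_fraction`` (shift-proportional error, as for peak positions
    read off well-resolved spectra). Defaults emulate four reporter
    residues of a weak (≈2 mM) protein–peptide interaction titrated to
    6 mM ligand.
    """
    if delta_max is None:
        delta_max = {94: 0.30, 120: 0.22, 134: 0.18, 196: 0.12}
    rng = np.random.default_rng(seed)
    conc = np.asarray(conc, dtype=float)
    series = []
    for residue, dmax in delta_max.items():
        clean = dmax * conc / (kd_true + conc)
        noisy = clean * (1.0 + rng.normal(0.0, noise_fraction, size=conc.size))
        noisy[conc == 0.0] = 0.0  # reference point defines zero shift
        series.append(TitrationSeries(residue=residue, ligand_conc=conc.copy(), shifts=noisy))
    truth = GroundTruth(
        scenario="nmr_titration",
        parameters=dict(
            kd_true=kd_true, delta_max=dict(delta_max),
            conc=conc.tolist(), noise_fraction=noise_fraction,
        ),
        seed=seed,
        noise_model="proportional_gaussian",
    )
    return series, truth
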