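"""Protocol-aware end-to-end assays.

Combines the sensor models with the trace primitives:

* :func:`atp_fccp_assay` — FCCP-uncoupling ATP assay: Rmin calibration from
  the depletion plateau, ratio→mM inversion, slope-based consumption and
  production rates, optional second FCCP+kainate challenge.
* :func:`redox_assay` — DTT/H₂O₂-calibrated roGFP assay yielding fraction
  oxidized and the compartment redox potential (pH-corrected for the
  mitochondrial matrix).
* :func:`tmrm_assay` — paired-ROI TMRM ratio as relative mitochondrial
  membrane potential, with an FCCP-response check per pair.
* :func:`calcium_stim_assay` — stimulus-evoked population calcium analysis:
  per-neuron transient metrics and the responder fraction with a binomial
  confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .sensors import (
    CONSTANTS,
    ATEAM103,
    CalibrationError,
    PhysConstants,
    SensorSpec,
    atp_from_ratio,
    fraction_reduced,
    ph_adjusted_e0,
    redox_potential,
)
from .traces import (
    RateEstimate,
    smooth,
    TimeSeriesTrace,
    TransientMetrics,
    WindowError,
    compute_dff,
    estimate_rate,
    transient_metrics,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtpAssayResult",
    "RedoxResult",
    "TmrmResult",
    "CalciumAssayResult",
    "PolarityError",
    "atp_fccp_assay",
    "redox_assay",
    "tmrm_assay",
    "calcium_stim_assay",
]

#: default compartmental pH values
COMPARTMENT_PH = {"cytosol": 7.0, "mitochondria": 7.98}


class PolarityError(CalibrationError):
    """Calibration plateaus are in the wrong order for the declared sensor."""


@dataclass
class ChallengeRates:
    """Consumption/production rates for one uncoupling challenge."""

    onset: float
    washout: Optional[float]
    consumption: RateEstimate
    production: Optional[RateEstimate]
    plateau_ratio: float  # mean raw ratio over the depletion plateau


@dataclass
class AtpAssayResult:
    baseline_atp: float  # mM
    rmin: float  # raw ratio at full depletion
    consumption_rate: float  # mM/s (negative)
    production_rate: float  # mM/s (positive)
    challenges: List[ChallengeRates]
    atp_trace: TimeSeriesTrace  # quantified mM trace
    second_challenge: Optional[ChallengeRates] = None


@dataclass
class RedoxResult:
    compartment: str
    ph: float
    fraction_reduced: float
    fraction_oxidized: float
    potential: float  # V
    calibration: dict  # f_red, f_ox and their plateau windows


@dataclass
class TmrmResult:
    roi_pairs: List[Tuple[float, float]]  # (mito mean, cyto mean) pre-FCCP
    ratios: List[float]
    fccp_response: List[bool]

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))


@dataclass
class CalciumAssayResult:
    metrics: List[TransientMetrics]
    responder_fraction: float
    responder_ci: Tuple[float, float]  # 95% binomial CI
    n_neurons: int
    peak_mean: Optional[float] = None  # over responders
    peak_sd: Optional[float] = None
    decay_mean: Optional[float] = None
    decay_sd: Optional[float] = None


def _challenge_blocks(trace: TimeSeriesTrace) -> List[dict]:
    """Pair each uncoupling onset (FCCP_on / kainate_on) with the next washout."""
    onsets = sorted(
        (w, lbl) for lbl, w in trace.events if lbl in ("FCCP_on", "kainate_on")
    )
    washes = sorted(w for lbl, w in trace.events if lbl == "washout")
    blocks = []
    for when, lbl in onsets:
        wash = next((w for w in washes if w > when), None)
        nxt = next((w for w, _ in onsets if w > when), None)
        blocks.append(
            dict(label=lbl, onset=when, washout=wash,
                 end=min(x for x in (nxt, trace.t[-1]) if x is not None))
        )
    return blocks


def atp_fccp_assay(
    ratio_trace: TimeSeriesTrace,
    spec: SensorSpec = ATEAM103,
    plateau_fraction: float = 0.2,
    plateau_slope_tol: float = 2e-3,
    rate_auto_length: float = 20.0,
    min_r_squared: float = 0.8,
    rate_smooth_width: int = 5,
    rate_floor_mM: float = 0.5,
) -> AtpAssayResult:
    """Quantify an FCCP-uncoupling FRET-ratio recording in mM ATP.

    Rmin is the mean raw ratio over the depletion plateau — the last
    ``plateau_fraction`` of each challenge's uncoupled interval, taking the
    deepest challenge. The plateau must be settled: an absolute OLS slope
    above ``plateau_slope_tol`` (ratio units/s) raises
    :class:`~sensortrace.sensors.CalibrationError`. The whole trace is then
    converted to mM via the inverse Hill model and consumption/production
    rates are the steepest reliable 20-s OLS slopes after each uncoupling
    onset and washout respectively.

    Rate windows are anchored to the protocol rather than searched: the
    consumption window opens just after the uncoupling onset and the
    production window where the signal first leaves the depletion floor
    after washout, each spanning ``rate_auto_length`` seconds. Estimation
    runs on a lightly smoothed copy of the ratio trace and ignores samples
    below ``rate_floor_mM`` (the inverse Hill model's derivative diverges
    as the ratio approaches Rmin, so ratio noise near the depletion floor
    maps to large mM noise) and within 10% of the baseline concentration
    (where recovery saturates). The quantified trace in the result is the
    raw (unsmoothed) conversion.
    """
    blocks = _challenge_blocks(ratio_trace)
    if not blocks or all(b["washout"] is None for b in blocks):
        raise WindowError("trace must contain FCCP_on and washout events")

    # Rmin from the deepest settled depletion plateau
    plateau_stats = []
    for b in blocks:
        stop = b["washout"] if b["washout"] is not None else ratio_trace.t[-1]
        start = stop - plateau_fraction * (stop - b["onset"])
        mask = ratio_trace.window_mask(start, stop)
        if np.count_nonzero(mask) < 5:
            raise CalibrationError("depletion plateau has fewer than 5 samples")
        seg_t, seg_y = ratio_trace.t[mask], ratio_trace.values[mask]
        slope = float(stats.linregress(seg_t, seg_y).slope)
        if abs(slope) > plateau_slope_tol:
            raise CalibrationError(
                f"depletion plateau not settled: |slope| {abs(slope):.2e} "
                f"> {plateau_slope_tol:.2e} ratio/s"
            )
        plateau_stats.append((float(np.mean(seg_y)), (start, stop)))
    rmin = min(m for m, _ in plateau_stats)

    # quantify the full trace in mM
    rel = ratio_trace.values / rmin
    atp = atp_from_ratio(np.minimum(rel, spec.dynamic_range - 1e-9), spec)
    atp_trace = replace(ratio_trace, values=np.asarray(atp), units="mM")

    # smoothed, floor-masked copy for slope estimation
    rel_sm = smooth(ratio_trace.values, rate_smooth_width) / rmin
    atp_sm = np.asarray(
        atp_from_ratio(np.minimum(rel_sm, spec.dynamic_range - 1e-9), spec)
    )
    rate_trace = replace(ratio_trace, values=atp_sm, units="mM")

    baseline_mask = ratio_trace.t < blocks[0]["onset"]
    baseline_atp = float(np.mean(atp_trace.values[baseline_mask])) if np.any(
        baseline_mask
    ) else 0.0

    dt = float(np.median(np.diff(ratio_trace.t)))
    margin = rate_smooth_width * dt  # skip smoothing-rounded corners
    ceiling = 0.9 * baseline_atp if baseline_atp > rate_floor_mM else None

    challenges: List[ChallengeRates] = []
    for b, (pmean, _) in zip(blocks, plateau_stats):
        cons = _anchored_rate(
            rate_trace, b["onset"],
            b["washout"] if b["washout"] is not None else b["end"],
            rate_auto_length, min_r_squared,
            floor=rate_floor_mM, ceiling=None, margin=margin,
        )
        prod = None
        if b["washout"] is not None:
            prod = _anchored_rate(
                rate_trace, b["washout"], b["end"],
                rate_auto_length, min_r_squared,
                floor=rate_floor_mM, ceiling=ceiling, margin=margin,
            )
        challenges.append(
            ChallengeRates(
                onset=b["onset"], washout=b["washout"],
                consumption=cons, production=prod, plateau_ratio=pmean,
            )
        )

    first = challenges[0]
    second = next(
        (c for c, b in zip(challenges, blocks) if b["label"] == "kainate_on"), None
    )
    return AtpAssayResult(
        baseline_atp=baseline_atp,
        rmin=rmin,
        consumption_rate=first.consumption.slope,
        production_rate=first.production.slope if first.production else np.nan,
        challenges=challenges,
        atp_trace=atp_trace,
        second_challenge=second,
    )


def _anchored_rate(
    trace: TimeSeriesTrace, start: float, stop: float,
    length: float, min_r_squared: float,
    floor: float, ceiling: Optional[float], margin: float,
) -> RateEstimate:
    """OLS slope over a protocol-anchored window.

    Samples in [start, stop] outside (floor, ceiling) are dropped — what
    remains is the quasi-linear stretch of the curve — and the fit covers
    all of it, skipping ``margin`` seconds at the front but at least
    ``length`` seconds where available. Falls back to the unmasked window
    when masking leaves fewer than 3 samples (fully depleted / flat
    recordings).
    """
    in_win = trace.window_mask(start, stop)
    if np.count_nonzero(in_win) < 3:
        raise WindowError(f"fewer than 3 samples in [{start}, {stop}]")
    usable = in_win & (trace.values >= floor)
    if ceiling is not None:
        usable &= trace.values <= ceiling
    if np.count_nonzero(usable) < 3:
        usable = in_win  # flat/depleted segment: report its (near-zero) slope
    t_sub, y_sub = trace.t[usable], trace.values[usable]
    t0 = float(t_sub[0]) + margin
    sel = t_sub >= t0
    # guard against gaps: keep the leading contiguous run only
    gaps = np.nonzero(np.diff(t_sub[sel]) > 10 * np.median(np.diff(trace.t)))[0]
    if gaps.size:
        keep = np.zeros_like(t_sub, dtype=bool)
        keep[np.nonzero(sel)[0][: gaps[0] + 1]] = True
        sel = keep
    if np.count_nonzero(sel) < 3:
        sel = np.ones_like(t_sub, dtype=bool)
    est = estimate_rate(t_sub[sel], y_sub[sel],
                        window=(float(t_sub[sel][0]), float(t_sub[sel][-1])))
    est.reliable = est.r_squared >= min_r_squared
    return est


def redox_assay(
    ratio_trace: TimeSeriesTrace,
    compartment: str = "cytosol",
    constants: PhysConstants = CONSTANTS,
    keq: float = 0.070,
    ph: Optional[float] = None,
    plateau_fraction: float = 0.5,
    drift_tol: float = 0.1,
    noise_tol: float = 0.25,
) -> RedoxResult:
    """Fraction oxidized and redox potential from a DTT/H₂O₂-calibrated trace.

    Calibration plateaus are the last ``plateau_fraction`` of the DTT phase
    (fully reduced) and of the H₂O₂ phase (fully oxidized); each must have
    ≥ 5 samples. Stability is judged relative to the calibration span
    |f_red − f_ox|: the drift across a plateau (OLS slope × duration) must
    stay below ``drift_tol``·span and the sample SD below ``noise_tol``·span.
    The sensor is reduced-high: a reduced plateau below the oxidized one
    raises :class:`PolarityError`. For the mitochondrial matrix the DTT
    reference midpoint is shifted to pH 7.98 before the Nernst conversion.
    """
    dtt_on = ratio_trace.event_time("DTT_on")
    h2o2_on = ratio_trace.event_time("H2O2_on")
    if dtt_on is None or h2o2_on is None:
        raise CalibrationError("trace must contain DTT_on and H2O2_on events")
    if not (ratio_trace.t[0] < dtt_on < h2o2_on):
        raise CalibrationError("phases must be ordered baseline < DTT < H2O2")

    def plateau(start: float, stop: float):
        lo = stop - plateau_fraction * (stop - start)
        mask = ratio_trace.window_mask(lo, stop)
        seg_t, seg = ratio_trace.t[mask], ratio_trace.values[mask]
        if seg.size < 5:
            raise CalibrationError("calibration plateau has fewer than 5 samples")
        drift = float(stats.linregress(seg_t, seg).slope) * (stop - lo)
        sd = float(np.std(seg, ddof=1))
        return float(np.mean(seg)), drift, sd, (lo, stop)

    f_red, red_drift, red_sd, red_win = plateau(dtt_on, h2o2_on)
    f_ox, ox_drift, ox_sd, ox_win = plateau(h2o2_on, float(ratio_trace.t[-1]))
    span = abs(f_red - f_ox)
    if span == 0:
        raise CalibrationError("degenerate calibration: plateaus coincide")
    for name, drift, sd in (("reduced", red_drift, red_sd),
                            ("oxidized", ox_drift, ox_sd)):
        if abs(drift) > drift_tol * span:
            raise CalibrationError(
                f"{name} plateau not settled: drift {abs(drift):.3g} exceeds "
                f"{drift_tol:.0%} of the calibration span {span:.3g}"
            )
        if sd > noise_tol * span:
            raise CalibrationError(
                f"{name} plateau unstable: SD {sd:.3g} exceeds "
                f"{noise_tol:.0%} of the calibration span {span:.3g}"
            )
    if f_red <= f_ox:
        raise PolarityError(
            "reduced plateau below oxidized plateau: reversed calibration for "
            "a reduced-high sensor"
        )

    baseline = float(np.mean(ratio_trace.values[ratio_trace.t < dtt_on]))
    frac_red = fraction_reduced(baseline, f_red, f_ox)

    if ph is None:
        try:
            ph = COMPARTMENT_PH[compartment]
        except KeyError:
            raise ValueError(f"unknown compartment {compartment!r}") from None
    e0 = ph_adjusted_e0(constants.e0_dtt, ph, constants)
    potential = redox_potential(frac_red, constants.with_e0_dtt(e0), keq)

    return RedoxResult(
        compartment=compartment,
        ph=ph,
        fraction_reduced=frac_red,
        fraction_oxidized=1.0 - frac_red,
        potential=potential,
        calibration=dict(f_red=f_red, f_ox=f_ox,
                         f_red_window=red_win, f_ox_window=ox_win),
    )


def tmrm_assay(
    roi_pair_traces: Sequence[Tuple[TimeSeriesTrace, TimeSeriesTrace]],
    fccp_time: float,
    settle: float = 10.0,
    alpha: float = 0.05,
) -> TmrmResult:
    """Relative mitochondrial membrane potential from paired TMRM ROIs.

    The readout per pair is the pre-FCCP mito/cytosol mean-intensity ratio.
    ``fccp_response`` is True when, comparing pre-FCCP samples with samples
    from ``settle`` seconds after FCCP onward, the mito signal declines AND
    the adjacent cytosolic signal rises (one-sided Welch tests at ``alpha``)
    — the dye-redistribution signature of a collapsed potential.
    """
    pairs, ratios, responses = [], [], []
    for mito, cyto in roi_pair_traces:
        if mito.t.shape != cyto.t.shape or np.any(mito.t != cyto.t):
            raise ValueError(
                f"ROI pair {mito.trace_id}/{cyto.trace_id} not aligned in time"
            )
        if not (mito.t[0] < fccp_time < mito.t[-1]):
            raise ValueError("fccp_time outside trace span")
        pre = mito.t < fccp_time
        post = mito.t >= fccp_time + settle
        m_pre, m_post = mito.values[pre], mito.values[post]
        c_pre, c_post = cyto.values[pre], cyto.values[post]
        p_decline = stats.ttest_ind(
            m_post, m_pre, equal_var=False, alternative="less"
        ).pvalue
        p_rise = stats.ttest_ind(
            c_post, c_pre, equal_var=False, alternative="greater"
        ).pvalue
        pairs.append((float(np.mean(m_pre)), float(np.mean(c_pre))))
        ratios.append(float(np.mean(m_pre) / np.mean(c_pre)))
        responses.append(bool(p_decline < alpha and p_rise < alpha))
    return TmrmResult(roi_pairs=pairs, ratios=ratios, fccp_response=responses)


def calcium_stim_assay(
    traces: Sequence[TimeSeriesTrace],
    stim_time: float,
    responder_k: float = 3.0,
    search_window: Optional[float] = None,
    ci_alpha: float = 0.05,
) -> CalciumAssayResult:
    """Population analysis of stimulus-evoked calcium transients.

    Raw traces are ΔF/F0-normalized against the pre-stimulus segment;
    already-normalized traces (units ``dF/F0``) are used as-is. Reports
    per-neuron transient metrics, the responder fraction with a Wilson
    binomial confidence interval, and responder-group summaries of peak
    amplitude and decay time.
    """
    if not traces:
        raise ValueError("empty population")
    metrics = []
    for tr in traces:
        dff = tr if tr.units == "dF/F0" else compute_dff(
            tr, baseline_window=(float(tr.t[0]), stim_time)
        )
        metrics.append(
            transient_metrics(
                dff, stim_time,
                search_window=search_window,
                baseline_window=(float(tr.t[0]), stim_time),
                responder_k=responder_k,
            )
        )
    n = len(metrics)
    n_resp = sum(m.responder for m in metrics)
    lo, hi = proportion_confint(n_resp, n, alpha=ci_alpha, method="wilson")
    resp = [m for m in metrics if m.responder]
    peaks = np.array([m.peak_dff for m in resp])
    decays = np.array([m.decay_time for m in resp if np.isfinite(m.decay_time)])
    return CalciumAssayResult(
        metrics=metrics,
        responder_fraction=n_resp / n,
        responder_ci=(float(lo), float(hi)),
        n_neurons=n,
        peak_mean=float(peaks.mean()) if peaks.size else None,
        peak_sd=float(peaks.std(ddof=1)) if peaks.size > 1 else None,
        decay_mean=float(decays.mean()) if decays.size else None,
        decay_sd=float(decays.std(ddof=1)) if decays.size > 1 else None,
    )
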