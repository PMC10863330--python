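"""Synthetic MEP experiment datasets and trial-level processing.

Emulates the study design — 21 participants x 5 current conditions
(sham, 0.5, 1.0, 1.5, 2.0 mA) x 2 TMS directions (PA/AP) x 4 time points
(baseline, 0, 15, 30 min) with 20 trials per cell — with the statistical
structure the downstream analysis assumes: log-normal MEP sizes,
participant-level random intercepts and field slopes, a cubic electric
field effect peaking near a configurable field value, a shared
session-level excitability that produces regression-to-the-mean after
baseline normalization, and a monotone latency drift over time points
plus a fixed PA/AP latency offset.

The generator embeds its ground-truth parameters so parameter-recovery
experiments can compare fitted against generating values.  Trial-level
EMG traces, peak-to-peak sizing, amplifier-scaling correction and
cross-correlation latency estimation are provided to exercise the raw
processing chain; the default pipeline generates cell-level sizes
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "TruthParams",
    "MEPDataset",
    "AMPLIFIER_CORRECTION",
    "cubic_field_effect",
    "generate_dataset",
    "synthesize_traces",
    "peak_to_peak",
    "average_cell",
    "apply_amplifier_correction",
    "latency_by_xcorr",
    "normalize_to_baseline",
    "load_mep_table",
]

#: Scaling correction for MEP sizes recorded with the wrong amplifier model.
AMPLIFIER_CORRECTION = 13500.0 / 4444.0

TIMEPOINTS = ("baseline", "0min", "15min", "30min")


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design: who gets what, when."""

    n_participants: int = 21
    currents_mA: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    directions: tuple[str, ...] = ("PA", "AP")
    timepoints: tuple[str, ...] = TIMEPOINTS
    trials_per_cell: int = 20
    n_male: int | None = None  # default: the study's 12:21 ratio, scaled
    morning_fraction: float = 49.0 / 105.0

    @property
    def n_male_effective(self) -> int:
        if self.n_male is not None:
            if not 0 <= self.n_male <= self.n_participants:
                raise ValueError("n_male out of range")
            return self.n_male
        return int(round(self.n_participants * 12.0 / 21.0))

    def session_orders(self) -> np.ndarray:
        """Latin-square condition order per participant (cyclic rows).

        Row ``p`` of the square assigns the condition index of each session
        for participant ``p``; each participant sees each condition once
        and the order is balanced across participants.
        """
        k = len(self.currents_mA)
        base = np.arange(k)
        rows = np.stack([(base + r) % k for r in range(k)])
        reps = int(np.ceil(self.n_participants / k))
        return np.tile(rows, (reps, 1))[: self.n_participants]


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters (log scale unless noted)."""

    beta0: float = 0.0  # grand mean of log normalized MEP
    peak_E: float = 0.44  # field value (V/m) maximizing the response
    peak_height: float = float(np.log(1.27))  # log gain at the peak vs sham
    trough_E: float = 2.2  # second stationary point of the cubic (V/m)
    intercept_sd: float = 0.35  # participant-level 'level effect'
    field_slope_sd: float = 0.25  # participant-specific field sensitivity, per V/m
    session_sd: float = 0.20  # shared session-level excitability
    measurement_sd: float = 0.18  # per-cell measurement noise (20-trial mean)
    residual_sd: float = 0.15  # post-cell residual variation
    direction_effect: float = 0.0  # AP minus PA on log MEP
    timepoint_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    baseline_mean_uV: float = 409.0
    baseline_sd_uV: float = 234.0
    efdi_per_ma_mean: float = 0.56  # V/m at 1 mA
    efdi_per_ma_sd: float = 0.20
    latency_base_ms: float = 22.0
    latency_participant_sd: float = 0.8
    latency_drift_ms: tuple[float, float, float, float] = (0.0, 0.15, 0.3, 0.4)
    ap_latency_offset_ms: float = 0.7
    latency_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("measurement_sd", "residual_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_E < 0:
            raise ValueError("peak_E must be >= 0")
        if self.trough_E <= self.peak_E:
            raise ValueError("trough_E must exceed peak_E")


def cubic_field_effect(E, truth: TruthParams) -> np.ndarray:
    """Cubic dose-response f(E) on the log scale with f(0)=0.

    Stationary points at ``peak_E`` (maximum) and ``trough_E``; scaled so
    f(peak_E) = ``peak_height``.  With the default trough beyond the
    observed field range the curve rises to the peak and decreases
    thereafter.
    """
    E = np.asarray(E, dtype=float)
    p, q = truth.peak_E, truth.trough_E
    if truth.peak_height == 0.0:
        return np.zeros_like(E)
    shape = lambda x: x**3 - 1.5 * (p + q) * x**2 + 3 * p * q * x  # noqa: E731
    c3 = truth.peak_height / shape(p)
    return c3 * shape(E)


@dataclass
class MEPDataset:
    """Long-format MEP table plus the embedded generating truth."""

    table: pd.DataFrame
    truth: TruthParams
    design: StudyDesign
    miscalibrated: bool = False


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def generate_dataset(
    design: StudyDesign | None = None,
    truth: TruthParams | None = None,
    field_metrics: Sequence[float] | None = None,
) -> MEPDataset:
    """Simulate one complete experiment.

    ``field_metrics`` optionally supplies per-participant EFDI-per-mA
    values (e.g. from the FEM pipeline); otherwise they are drawn from a
    log-normal matched to mean 0.56, SD 0.20 V/m at 1 mA.  Deterministic
    given ``truth.seed``.
    """
    design = design or StudyDesign()
    truth = truth or TruthParams()
    rng = np.random.default_rng(truth.seed)
    npart = design.n_participants
    orders = design.session_orders()

    if field_metrics is not None:
        efdi_per_ma = np.asarray(field_metrics, dtype=float)
        if len(efdi_per_ma) != npart:
            raise ValueError("need one EFDI-per-mA value per participant")
    else:
        mu, sg = _lognormal_params(truth.efdi_per_ma_mean, truth.efdi_per_ma_sd)
        efdi_per_ma = rng.lognormal(mu, sg, size=npart)

    n_male = design.n_male_effective
    genders = np.array(["M"] * n_male + ["F"] * (npart - n_male))
    rng.shuffle(genders)
    alpha = rng.normal(0.0, truth.intercept_sd, size=npart)
    slope = rng.normal(0.0, truth.field_slope_sd, size=npart)
    lat_part = rng.normal(0.0, truth.latency_participant_sd, size=npart)
    mu_b, sg_b = _lognormal_params(truth.baseline_mean_uV, truth.baseline_sd_uV)

    post_tp = [t for t in design.timepoints if t != "baseline"]
    tp_eff = dict(zip(post_tp, truth.timepoint_effects))
    drift = dict(zip(design.timepoints, truth.latency_drift_ms))

    rows = []
    for p in range(npart):
        pid = f"P{p + 1:02d}"
        for s, cond_idx in enumerate(orders[p]):
            current = design.currents_mA[cond_idx]
            efdi = efdi_per_ma[p] * current
            tod = "morning" if rng.random() < design.morning_fraction else "afternoon"
            session_level = rng.normal(0.0, truth.session_sd)
            for d in design.directions:
                # shared latent excitability of this participant/session/direction
                level = mu_b + rng.normal(0.0, sg_b) + session_level
                log_baseline_obs = level + rng.normal(0.0, truth.measurement_sd)
                lat_dir = truth.ap_latency_offset_ms if d == "AP" else 0.0
                for t in design.timepoints:
                    if t == "baseline":
                        log_mep = log_baseline_obs
                    else:
                        log_mep = (
                            level
                            + truth.beta0
                            + alpha[p]
                            + float(cubic_field_effect(efdi, truth))
                            + slope[p] * efdi
                            + (truth.direction_effect if d == "AP" else 0.0)
                            + tp_eff[t]
                            + rng.normal(0.0, truth.measurement_sd)
                            + rng.normal(0.0, truth.residual_sd)
                        )
                    latency = (
                        truth.latency_base_ms
                        + lat_part[p]
                        + drift[t]
                        + lat_dir
                        + rng.normal(0.0, truth.latency_noise_sd)
                    )
                    rows.append(
                        {
                            "participant": pid,
                            "session_number": s + 1,
                            "condition_mA": current,
                            "E_FDI": efdi,
                            "direction": d,
                            "timepoint": t,
                            "mep_size_uV": float(np.exp(log_mep)),
                            "latency_ms": latency,
                            "baseline_mep_uV": float(np.exp(log_baseline_obs)),
                            "time_of_day": tod,
                            "gender": genders[p],
                        }
                    )
    table = pd.DataFrame(rows)
    return MEPDataset(table=table, truth=truth, design=design)


# ---------------------------------------------------------------------------
# trial-level processing


def synthesize_traces(
    mean_amplitude_uV: float,
    latency_ms: float,
    truth: TruthParams | None = None,
    n_trials: int = 20,
    duration_ms: float = 100.0,
    sampling_rate_hz: float = 3000.0,
    noise_uV: float = 5.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate EMG traces for one cell: (n_trials, n_samples) in uV.

    Each trace is a Gabor-like biphasic MEP waveform at the given latency
    with trial-to-trial log-normal amplitude jitter, plus white noise.
    """
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_ms / 1000.0 * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz * 1000.0  # ms
    amps = mean_amplitude_uV * rng.lognormal(0.0, 0.25, size=n_trials)
    traces = np.empty((n_trials, n))
    for i in range(n_trials):
        tt = t - latency_ms
        wave = np.sin(2 * np.pi * tt / 8.0) * np.exp(-((tt - 4.0) ** 2) / (2 * 3.0**2))
        traces[i] = amps[i] / 2.0 * wave + rng.normal(0.0, noise_uV, size=n)
    return traces


def peak_to_peak(trace: np.ndarray) -> float:
    """Peak-to-peak amplitude (max minus min) of one trace."""
    trace = np.asarray(trace, dtype=float)
    return float(trace.max() - trace.min())


def average_cell(traces: np.ndarray) -> float:
    """Cell MEP size: mean peak-to-peak amplitude over the trials."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    return float(np.mean([peak_to_peak(tr) for tr in traces]))


def apply_amplifier_correction(dataset: MEPDataset) -> MEPDataset:
    """Undo the amplifier-model scaling error (x 13500/4444) if flagged."""
    if not dataset.miscalibrated:
        return dataset
    table = dataset.table.copy()
    for col in ("mep_size_uV", "baseline_mep_uV"):
        table[col] = table[col] * AMPLIFIER_CORRECTION
    return MEPDataset(table, dataset.truth, dataset.design, miscalibrated=False)


def latency_by_xcorr(
    mean_trace: np.ndarray,
    reference_trace: np.ndarray,
    sampling_rate_hz: float = 3000.0,
) -> float:
    """Delay (ms) of the mean trace relative to the reference.

    Argmax of the normalized cross-correlation over all lags; ties are
    broken toward the smallest absolute lag.
    """
    a = np.asarray(mean_trace, dtype=float)
    b = np.asarray(reference_trace, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    cc = np.correlate(a, b, mode="full")
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom > 0:
        cc = cc / denom
    lags = np.arange(-(len(b) - 1), len(a))
    best = cc.max()
    candidates = lags[cc >= best - 1e-12]
    lag = candidates[np.argmin(np.abs(candidates))]
    return float(lag) / sampling_rate_hz * 1000.0


def normalize_to_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Divide post-tDCS MEP sizes by the same-session, same-direction baseline.

    Returns the post-stimulation analysis table with a ``normalized_mep``
    column; baseline rows are dropped.
    """
    req = {"participant", "session_number", "direction", "timepoint", "mep_size_uV"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    base = table[table["timepoint"] == "baseline"]
    if base.empty:
        raise ValueError("no baseline rows present")
    key = ["participant", "session_number", "direction"]
    ref = base.set_index(key)["mep_size_uV"]
    if ref.index.has_duplicates:
        raise ValueError("duplicate baseline rows for a participant/session/direction")
    post = table[table["timepoint"] != "baseline"].copy()
    idx = pd.MultiIndex.from_frame(post[key])
    if not idx.isin(ref.index).all():
        bad = idx[~idx.isin(ref.index)][0]
        raise ValueError(f"missing baseline for {bad}")
    post["normalized_mep"] = post["mep_size_uV"].to_numpy() / ref.loc[idx].to_numpy()
    return post.reset_index(drop=True)


#: Canonical column names expected by the analysis, for the deposited-data loader.
SCHEMA_COLUMNS = (
    "participant",
    "session_number",
    "condition_mA",
    "E_FDI",
    "direction",
    "timepoint",
    "mep_size_uV",
    "latency_ms",
    "baseline_mep_uV",
    "time_of_day",
    "gender",
)


def load_mep_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a long-format MEP CSV, renaming columns via ``column_map``.

    ``column_map`` maps source column names to the canonical schema names,
    so externally deposited tables with arbitrary headers can be adapted
    without code changes.  Synthetic and external data are interchangeable
    downstream.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("participant", "timepoint", "mep_size_uV") if c not in df.columns]
    if missing:
        raise ValueError(f"required columns missing after mapping: {missing}")
    return df
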