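"""Synthetic microsensor traces and water-column profiles with ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes, so that every estimator in the package can be tested for parameter
recovery against a known truth:

* spike-decay traces: repeated Na2S spikes into a stirred MnO2 vessel decay
  exponentially at ``k_total = k_cell * abundance + k_background`` until a
  pasteurization event kills the biological term;
* depth profiles: sulfide zero above the euxinic boundary and increasing
  linearly below it, with a Gaussian-peaked Campylobacterota abundance
  centred near the boundary (the field pattern of *Sulfurimonas* spp.).

Default truth values are the study conditions of the laboratory experiment
this emulates: ``k_cell = -1.05e-13 l cell^-1 s^-1`` at an abundance of
5e10 cells l^-1 (5e7 ml^-1), a sterile background of ``-1.25e-3 s^-1``
(a 30 uM spike decays below 1 uM in ~45 min), eight 30 uM spikes before and
three after pasteurization, and additive Gaussian sensor noise of 0.3 uM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinetics import SensorTrace
from .profiles import DepthProfile
from .speciation import h2s_from_total

__all__ = ["TraceTruth", "ProfileTruth", "default_spike_schedule", "make_trace", "make_profiles"]


def default_spike_schedule(
    n_pre: int = 8,
    n_post: int = 3,
    pre_spacing: float = 700.0,
    post_spacing: float = 2900.0,
    amplitude: float = 30.0,
) -> tuple[list[float], list[float], float]:
    """Spike times, amplitudes and pasteurization time for an n_pre + n_post run.

    Spacing defaults leave each biological spike ~12 min and each sterile/post
    spike ~48 min to decay, comfortably past the 1 uM segmentation floor.
    """
    pre_times = [i * pre_spacing for i in range(n_pre)]
    pasteurization = n_pre * pre_spacing
    post_times = [pasteurization + 50.0 + i * post_spacing for i in range(n_post)]
    times = pre_times + post_times
    return times, [amplitude] * len(times), pasteurization


@dataclass
class TraceTruth:
    """Ground truth for a synthetic spike-decay trace.

    Rate coefficients are negative (decay); ``k_cell_true`` is in litres per
    cell per second, ``abundance`` in cells per litre, ``k_background_true``
    in s^-1 (the sterile/chemical removal in the vessel, a single lumped
    coefficient).  ``pasteurization_time`` of ``None`` means no
    pasteurization event.
    """

    k_cell_true: float = -1.05e-13
    abundance: float = 5e10
    k_background_true: float = -1.25e-3
    spike_times: list[float] = field(default_factory=list)
    spike_amplitudes: list[float] = field(default_factory=list)
    pasteurization_time: float | None = None
    noise_sd: float = 0.3
    seed: int = 0
    sample_interval: float = 1.0
    duration: float | None = None
    initial_concentration: float = 0.0
    pH: float = 7.0
    temp_C: float = 10.0
    salinity: float = 22.0
    overlap_floor: float = 1.0

    @classmethod
    def default_experiment(cls, seed: int = 0, **overrides) -> "TraceTruth":
        """The 8 pre- + 3 post-pasteurization 30 uM spike experiment."""
        times, amps, past = default_spike_schedule()
        params = dict(
            spike_times=times,
            spike_amplitudes=amps,
            pasteurization_time=past,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if self.k_cell_true > 0 or self.k_background_true > 0:
            raise ValueError("rate coefficients must be <= 0 (decay convention)")
        if len(self.spike_times) != len(self.spike_amplitudes):
            raise ValueError("spike_times and spike_amplitudes must have equal length")
        if len(self.spike_times) > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        for a in self.spike_amplitudes:
            if not 0 < a <= 100:
                raise ValueError(f"spike amplitude {a} uM outside (0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    @property
    def k_bio(self) -> float:
        return self.k_cell_true * self.abundance

    def k_total(self, pre_pasteurization: bool) -> float:
        if pre_pasteurization:
            return self.k_bio + self.k_background_true
        return self.k_background_true


def make_trace(truth: TraceTruth) -> SensorTrace:
    """Simulate a spike-decay microsensor trace from the given truth.

    Concentration jumps by the spike amplitude at each spike time and decays
    exponentially between events at the phase-appropriate total rate.  Noise
    is additive zero-mean Gaussian on the total-sulfide channel; the
    as-measured H2S channel is produced by applying the inverse speciation
    correction at the configured pH/T/S.  Concentrations are clipped at zero.
    A spike arriving before the previous one has decayed below
    ``truth.overlap_floor`` raises a warning, not an error.
    """
    truth.validate()

    if truth.duration is not None:
        duration = truth.duration
    elif truth.spike_times:
        last = truth.spike_times[-1]
        tail_pre = truth.pasteurization_time is None or last < truth.pasteurization_time
        # leave the final spike enough time to decay to ~1% of a 30 uM spike
        k_tail = abs(truth.k_total(tail_pre))
        duration = last + (6.0 / k_tail if k_tail > 0 else 600.0)
    else:
        duration = 600.0

    time = np.arange(0.0, duration + 0.5 * truth.sample_interval, truth.sample_interval)

    # event-ordered piecewise-exponential simulation
    events: list[tuple[float, str, float]] = [
        (t, "spike", a) for t, a in zip(truth.spike_times, truth.spike_amplitudes)
    ]
    if truth.pasteurization_time is not None:
        events.append((truth.pasteurization_time, "pasteurization", 0.0))
    events.sort(key=lambda e: e[0])

    conc = np.empty_like(time)
    c_now = float(truth.initial_concentration)
    t_now = 0.0
    pre = True
    pos = 0
    overlap = False
    for t_ev, kind, amp in events + [(float("inf"), "end", 0.0)]:
        k = truth.k_total(pre)
        seg = slice(pos, int(np.searchsorted(time, t_ev, side="left")))
        conc[seg] = c_now * np.exp(k * (time[seg] - t_now))
        if not np.isfinite(t_ev):
            break
        c_now = c_now * np.exp(k * (t_ev - t_now))
        t_now = t_ev
        pos = seg.stop
        if kind == "spike":
            if c_now > truth.overlap_floor:
                overlap = True
            c_now += amp
        elif kind == "pasteurization":
            pre = False

    if overlap:
        warnings.warn(
            "overlapping spikes: a spike arrived before the previous decay "
            f"fell below {truth.overlap_floor} uM",
            stacklevel=2,
        )

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        conc = conc + rng.normal(0.0, truth.noise_sd, size=conc.shape)
    conc = np.clip(conc, 0.0, None)

    h2s = h2s_from_total(conc, truth.pH, truth.temp_C, truth.salinity)

    trace_events = [(t, "spike") for t in truth.spike_times]
    if truth.pasteurization_time is not None:
        trace_events.append((truth.pasteurization_time, "pasteurization"))
    trace_events.sort(key=lambda e: e[0])

    truth_record = asdict(truth)
    truth_record["overlap_warning"] = overlap
    return SensorTrace(
        time=time,
        h2s=h2s,
        total_sulfide=conc,
        pH=truth.pH,
        temp_C=truth.temp_C,
        salinity=truth.salinity,
        events=trace_events,
        truth=truth_record,
    )


@dataclass
class ProfileTruth:
    """Ground truth for a synthetic water-column depth profile.

    Depth is positive downward.  Sulfide is zero above the euxinic boundary
    and increases linearly below it at ``sulfide_gradient`` (mmol m^-3 m^-1,
    numerically equal to uM m^-1).  Campylobacterota abundance is a Gaussian
    peak of width ``peak_width`` (m) on a constant background.
    """

    sulfide_gradient: float = 0.67
    euxinic_boundary_depth: float = 106.0
    abundance_peak: float = 6.5e7
    abundance_peak_depth: float = 100.0
    abundance_background: float = 2e6
    peak_width: float = 6.0
    depth_range: tuple[float, float] = (80.0, 120.0)
    depth_step: float = 0.2
    f_sulfurimonas: float = 0.96
    noise_rel: float = 0.0  # relative log-normal scatter on abundance
    seed: int = 0

    def validate(self) -> None:
        top, bottom = self.depth_range
        if not (0 < top < bottom):
            raise ValueError("depth_range must be ordered, positive downward")
        if self.depth_step <= 0:
            raise ValueError("depth_step must be positive")
        if self.sulfide_gradient < 0:
            raise ValueError("sulfide_gradient must be >= 0")
        if not top <= self.abundance_peak_depth <= bottom:
            raise ValueError("abundance peak must lie inside depth_range")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if not 0 <= self.f_sulfurimonas <= 1:
            raise ValueError("f_sulfurimonas must lie in [0, 1]")


def make_profiles(truth: ProfileTruth) -> DepthProfile:
    """Generate a synthetic depth profile on the configured grid.

    Besides the sulfide and abundance fields of the truth, the profile
    carries a static O2 column (declining linearly to zero at 90 m, so the
    suboxic zone separates O2 from sulfide) and a strictly increasing
    potential-density coordinate sigma_theta for alignment exercises.
    """
    truth.validate()
    top, bottom = truth.depth_range
    z = np.arange(top, bottom + 0.5 * truth.depth_step, truth.depth_step)

    s2 = np.where(
        z > truth.euxinic_boundary_depth,
        truth.sulfide_gradient * (z - truth.euxinic_boundary_depth),
        0.0,
    )
    abundance = truth.abundance_background + truth.abundance_peak * np.exp(
        -((z - truth.abundance_peak_depth) ** 2) / (2.0 * truth.peak_width**2)
    )
    if truth.noise_rel > 0:
        rng = np.random.default_rng(truth.seed)
        abundance = abundance * np.exp(
            rng.normal(0.0, truth.noise_rel, size=abundance.shape)
        )

    o2 = np.clip(10.0 * (90.0 - z) / 10.0, 0.0, None)  # 10 uM at 80 m -> 0 at 90 m
    sigma_theta = 15.5 + 0.045 * (z - top) + 2e-4 * (z - top) ** 2

    df = pd.DataFrame(
        {
            "depth_m": z,
            "sigma_theta": sigma_theta,
            "s2_uM": s2,
            "o2_uM": o2,
            "ca_epsy914_cells_per_l": abundance,
            "f_sulfurimonas": np.full_like(z, truth.f_sulfurimonas),
        }
    )
    return DepthProfile(data=df, label="synthetic", truth=asdict(truth))
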