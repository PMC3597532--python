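"""Synthetic observed time courses with the structure of blot-densitometry
clock data.

Real reference data for this system are sparse Northern/Western blot
series digitised from figures: relative kaiBC mRNA standardised to mean
1, and unphosphorylated / total-phosphorylated KaiC as fractions of
total KaiC, sampled every few hours over about two days in constant
light.  :func:`generate_observed` emulates exactly that statistical
shape; :func:`generate_from_model` produces ground-truth tables from a
forward simulation for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import simulate
from .params import FeedbackSpec, PTOParameters, TTFLParameters

#: Second-harmonic amplitude relative to the fundamental; blot traces are
#: not pure sinusoids.
HARMONIC_RATIO = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape parameters of a synthetic observed time course.

    Defaults encode the canonical wild-type LL phenotype: ~25 h period,
    kaiBC mRNA peaking mid-subjective-day (9 h after dawn), UKaiC peaking
    early (3 h), PKaiC in the subjective night (11 h), sparse 4 h
    sampling over 48 h, 5 % relative noise.
    """

    period: float = 25.0
    mRNA_peak_phase: float = 9.0
    UKaiC_peak_phase: float = 3.0
    PKaiC_peak_phase: float = 11.0
    mRNA_rel_amplitude: float = 0.6
    frac_amplitude: float = 0.3
    sampling_interval: float = 4.0
    duration: float = 48.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        for name in ("mRNA_peak_phase", "UKaiC_peak_phase", "PKaiC_peak_phase"):
            v = getattr(self, name)
            if not 0 <= v < self.period:
                raise ValueError(f"{name} must lie in [0, period)")
        if not 0 < self.mRNA_rel_amplitude < 1:
            raise ValueError("mRNA_rel_amplitude must be in (0, 1)")
        if not 0 < self.frac_amplitude <= 0.5:
            raise ValueError("frac_amplitude must be in (0, 0.5]")
        if self.sampling_interval <= 0 or self.duration <= 0:
            raise ValueError("sampling_interval and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def _waveform(t: np.ndarray, period: float, peak: float) -> np.ndarray:
    """Fundamental plus one in-phase harmonic, unit peak amplitude at
    ``t = peak`` (mod period)."""
    theta = 2 * np.pi * (t - peak) / period
    return (np.cos(theta) + HARMONIC_RATIO * np.cos(2 * theta)) / (1 + HARMONIC_RATIO)


def generate_observed(spec: SyntheticSpec) -> simulate.TimeSeries:
    """Synthetic observed table with channels mBC_rel, UKaiC_frac, PKaiC_frac.

    The mRNA channel is standardised to mean 1 (before noise); the two
    fraction channels are built from independent waveforms at their
    nominal peak phases and renormalised to sum exactly to 1, which
    shifts the realised peaks slightly (< ~1 h) from the nominal phases.
    Noise is additive Gaussian per channel, scaled by the channel
    amplitude, then clipped to the valid range.
    """
    t = np.arange(0.0, spec.duration + spec.sampling_interval / 2,
                  spec.sampling_interval)
    t = t[t <= spec.duration + 1e-9]

    mbc = 1.0 + spec.mRNA_rel_amplitude * _waveform(t, spec.period,
                                                    spec.mRNA_peak_phase)
    mbc = mbc / mbc.mean()

    u_raw = 0.5 + spec.frac_amplitude * _waveform(t, spec.period,
                                                  spec.UKaiC_peak_phase)
    p_raw = 0.5 + spec.frac_amplitude * _waveform(t, spec.period,
                                                  spec.PKaiC_peak_phase)
    total = u_raw + p_raw
    u_frac = u_raw / total
    p_frac = p_raw / total

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mbc = mbc + rng.normal(0, spec.noise_sd * spec.mRNA_rel_amplitude,
                               size=t.shape)
        mbc = np.clip(mbc, 0.0, None)
        du = rng.normal(0, spec.noise_sd * 2 * spec.frac_amplitude, size=t.shape)
        u_frac = np.clip(u_frac + du, 0.0, 1.0)
        p_frac = np.clip(p_frac + rng.normal(
            0, spec.noise_sd * 2 * spec.frac_amplitude, size=t.shape), 0.0, 1.0)

    return simulate.TimeSeries(t, {"mBC_rel": mbc, "UKaiC_frac": u_frac,
                                   "PKaiC_frac": p_frac})


def generate_from_model(p: PTOParameters, q: TTFLParameters,
                        spec: FeedbackSpec, noise_sd: float = 0.0,
                        seed: int = 0,
                        sampling_interval: float = 4.0,
                        duration: float = 48.0,
                        burn_in: float = 240.0,
                        rtol: float = 1e-8, atol: float = 1e-10,
                        ) -> tuple[simulate.TimeSeries, TTFLParameters]:
    """Forward-simulate and sample a blot-style observed table.

    Runs the model to its settled cycle, records from the dawn anchor,
    samples the three observable channels on the synthetic grid, adds
    seeded Gaussian noise, and returns the table together with the
    generating TTFL parameters (the recovery target).

    Raises ``ValueError`` if the parameter set does not oscillate.
    """
    # record at least three cycles so rhythmicity can be verified, even
    # when the sampled table itself is shorter
    res = simulate.run_experiment(p, q, spec, burn_in=burn_in,
                                  record=max(duration + 1.0, 85.0),
                                  rtol=rtol, atol=atol)
    from . import metrics  # local import: metrics depends on simulate
    diag = metrics.diagnose(res.wild_type)
    if not diag.sustained or diag.period is None:
        raise ValueError(
            "parameter set is not rhythmic; synthetic ground truth needs a "
            "sustained oscillation (try the calibrated defaults)")
    t = np.arange(0.0, duration + sampling_interval / 2, sampling_interval)
    t = t[t <= duration + 1e-9]
    w = res.wild_type
    mbc = np.interp(t, w.t, w["mBC"])
    mbc_rel = mbc / mbc.mean()
    u_frac = np.interp(t, w.t, w["UKaiC_frac"])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mbc_rel = np.clip(mbc_rel * (1 + rng.normal(0, noise_sd, t.shape)), 0, None)
        u_frac = np.clip(u_frac * (1 + rng.normal(0, noise_sd, t.shape)), 0, 1)
    table = simulate.TimeSeries(t, {"mBC_rel": mbc_rel, "UKaiC_frac": u_frac,
                                    "PKaiC_frac": 1.0 - u_frac})
    return table, q
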