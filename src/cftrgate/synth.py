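"""Synthetic patch-clamp recordings from gating-cycle trajectories.

This module is the forward model of the recording chain: channel trajectories
are rendered into current time series (unitary current for conducting states,
baseline otherwise), Gaussian recording noise is added, and the acquisition
low-pass filter is applied.  The ATP-removal protocol (opening rate set to
zero at ``t_atp_off``) produces the macroscopic relaxations and the
"last-channel" single-channel segments that the analysis modules consume.

Sign convention: inward current is negative, so an open channel at negative
membrane potential contributes ``i_unit < 0``; downstream normalization
removes the sign.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .gating import (
    OPEN_STATES,
    GenotypePreset,
    RateScheme,
    StateTrajectory,
    bursting_fraction,
    coupling_ratio,
    intraburst_equilibrium,
    simulate_with_atp_removal,
)

__all__ = [
    "RecordingSpec",
    "Protocol",
    "CurrentTrace",
    "GAUSSIAN_SIGMA_COEF",
    "render_single_channel",
    "render_macroscopic",
    "sample_closing_times",
    "generate_fixture_set",
]

#: sigma_t * fc for a Gaussian filter with -3 dB cutoff fc.
GAUSSIAN_SIGMA_COEF = 0.1325


@dataclass(frozen=True)
class RecordingSpec:
    """Recording chain parameters.

    ``fs`` sampling rate (Hz), ``f_acq`` acquisition low-pass cutoff (Hz),
    ``i_unit`` unitary current (pA; negative for inward current), ``noise_sd``
    baseline Gaussian noise SD (pA) before acquisition filtering.
    """

    fs: float = 10_000.0
    f_acq: float = 2_000.0
    i_unit: float = -0.5
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.f_acq:
            raise ValueError(
                f"fs = {self.fs} Hz must exceed 2 * f_acq = {2 * self.f_acq} Hz "
                "(aliasing)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.i_unit == 0:
            raise ValueError("i_unit must be nonzero")


@dataclass(frozen=True)
class Protocol:
    """ATP-removal protocol: ATP present on [0, t_atp_off), absent after."""

    t_atp_off: float
    t_end: float
    n_channels: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.t_atp_off < self.t_end:
            raise ValueError("need 0 <= t_atp_off < t_end")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass
class CurrentTrace:
    """Uniformly sampled current time series.

    ``markers`` carries protocol event times (s), e.g. ``t_atp_off``;
    ``meta`` carries recording metadata (i_unit, f_acq, seed, ...) that the
    TSV dialect round-trips as '#'-prefixed header lines.
    """

    t0: float
    fs: float
    samples: np.ndarray
    markers: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def slice(self, t_start: float, t_stop: float) -> "CurrentTrace":
        i0 = max(0, int(math.ceil((t_start - self.t0) * self.fs)))
        i1 = min(len(self.samples), int(math.floor((t_stop - self.t0) * self.fs)) + 1)
        if i1 <= i0:
            raise ValueError(f"empty slice [{t_start}, {t_stop}]")
        return CurrentTrace(self.t0 + i0 / self.fs, self.fs,
                            self.samples[i0:i1].copy(),
                            markers=dict(self.markers), meta=dict(self.meta))


def _acquisition_filter(x: np.ndarray, fs: float, f_acq: float) -> np.ndarray:
    """Gaussian low-pass emulating the acquisition filter (-3 dB at f_acq)."""
    sigma = GAUSSIAN_SIGMA_COEF * fs / f_acq
    return gaussian_filter1d(x, sigma, mode="nearest")


def render_single_channel(
    trajectory: StateTrajectory,
    spec: RecordingSpec | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    markers: dict[str, float] | None = None,
) -> CurrentTrace:
    """Render one channel's trajectory into a sampled current trace.

    Conducting states map to ``i_unit``, all closed states to 0; Gaussian
    noise of SD ``noise_sd`` is added per sample and the acquisition filter
    applied.  Deterministic under a fixed seed.
    """
    spec = spec or RecordingSpec()
    if trajectory.duration < 1.0 / spec.fs:
        raise ValueError("trajectory shorter than one sampling interval")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(math.floor(trajectory.duration * spec.fs))
    t = trajectory.t0 + np.arange(n) / spec.fs
    open_mask = np.isin(trajectory.state_at(t), list(OPEN_STATES))
    x = np.where(open_mask, spec.i_unit, 0.0)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    x = _acquisition_filter(x, spec.fs, spec.f_acq)
    return CurrentTrace(
        trajectory.t0, spec.fs, x, markers=dict(markers or {}),
        meta={"i_unit": spec.i_unit, "f_acq": spec.f_acq, "noise_sd": spec.noise_sd,
              "seed": seed, "n_channels": 1},
    )


def sample_closing_times(
    scheme: RateScheme, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Terminal closing times (s after ATP removal) for ``n`` bursting channels.

    Exact phase-type draw for a channel that is in a burst at the moment of
    ATP removal: the burst phase (B1 vs B2) is drawn from the stationary
    within-burst split, the residual B1 lifetime is Exp(k_1 + k_minus1), and
    hydrolytic exits append an Exp(k_2) dwell in B2.
    """
    ktot = scheme.k_1 + scheme.k_minus1
    if ktot == 0:
        raise ValueError("k_1 + k_minus1 = 0: bursts never terminate")
    t_b1 = 1.0 / ktot
    cr = coupling_ratio(scheme)
    t_b2 = cr / scheme.k_2 if scheme.k_1 > 0 else 0.0
    p_b1 = t_b1 / (t_b1 + t_b2)
    in_b1 = rng.random(n) < p_b1
    times = np.empty(n)
    n1 = int(in_b1.sum())
    # channels caught in B1: residual Exp(ktot), then B2 with probability CR
    t1 = rng.exponential(1.0 / ktot, size=n1)
    if scheme.k_1 > 0:
        goes_b2 = rng.random(n1) < cr
        t1 = t1 + np.where(goes_b2, rng.exponential(1.0 / scheme.k_2, size=n1), 0.0)
        times[~in_b1] = rng.exponential(1.0 / scheme.k_2, size=n - n1)
    else:
        times[~in_b1] = 0.0  # unreachable: t_b2 == 0 puts every channel in B1
    times[in_b1] = t1
    return times


def render_macroscopic(
    preset: GenotypePreset | RateScheme,
    protocol: Protocol,
    spec: RecordingSpec | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> CurrentTrace:
    """Summed current of ``n_channels`` independent channels through ATP removal.

    Channels start from the stationary distribution with ATP present; at
    ``t_atp_off`` the opening rate is set to zero so the ensemble current
    decays as channels terminally close.  For ``n_channels > 100`` a fast
    exact path is used: the number of bursting channels at removal is
    binomial in the stationary bursting fraction, terminal closing times are
    phase-type draws (:func:`sample_closing_times`), and the fast intraburst
    flicker telegraph is replaced by its mean open probability — identical in
    distribution for the relaxation quantities analyzed downstream.  For
    small ``n_channels`` every channel is simulated exactly.
    """
    spec = spec or RecordingSpec()
    scheme = preset.scheme if isinstance(preset, GenotypePreset) else preset
    if rng is None:
        rng = np.random.default_rng(seed)
    n_samp = int(math.floor(protocol.t_end * spec.fs))
    t = np.arange(n_samp) / spec.fs
    p_open_b, _ = intraburst_equilibrium(scheme)

    if protocol.n_channels > 100:
        p_b = bursting_fraction(scheme)
        n_burst = rng.binomial(protocol.n_channels, p_b)
        closing = np.sort(sample_closing_times(scheme, n_burst, rng))
        post = t >= protocol.t_atp_off
        surviving = np.full(n_samp, float(n_burst))
        surviving[post] = n_burst - np.searchsorted(
            closing, t[post] - protocol.t_atp_off, side="right")
        x = spec.i_unit * p_open_b * surviving
    else:
        x = np.zeros(n_samp)
        for _ in range(protocol.n_channels):
            traj = simulate_with_atp_removal(
                scheme, protocol.t_atp_off, protocol.t_end, rng=rng)
            states = traj.state_at(t)
            x += np.where(np.isin(states, list(OPEN_STATES)), spec.i_unit, 0.0)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n_samp)
    x = _acquisition_filter(x, spec.fs, spec.f_acq)
    return CurrentTrace(
        0.0, spec.fs, x, markers={"t_atp_off": protocol.t_atp_off},
        meta={"i_unit": spec.i_unit, "f_acq": spec.f_acq, "noise_sd": spec.noise_sd,
              "seed": seed, "n_channels": protocol.n_channels},
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

# problem sizes for generated fixtures; macroscopic relaxations are sampled at
# 100 Hz (anti-alias cutoff 25 Hz) since their kinetics live on the seconds
# scale, last-channel traces at 1 kHz (cutoff 250 Hz) which comfortably
# oversamples the 100 Hz analysis bandwidth
_MACRO_SPEC = dict(fs=100.0, f_acq=25.0)
_LAST_SPEC = dict(fs=1000.0, f_acq=250.0)


def generate_fixture_set(
    genotypes: list[str],
    out_dir: str | Path,
    seed: int,
    *,
    n_channels_macro: int = 1000,
    n_channels_last: int = 5,
) -> dict:
    """Write per-genotype synthetic datasets and a manifest.

    For each genotype: one macroscopic ATP-removal relaxation (default 1000
    channels) and one small-patch trace (default 5 channels) whose tail is a
    last-channel segment.  The manifest (JSON) records true parameters and the
    derived per-file seeds; re-running with the same seed reproduces
    byte-identical files.
    """
    from .io import write_trace  # local import to avoid a cycle
    from .presets import make_preset

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "genotypes": {}}
    root = np.random.SeedSequence(seed)
    for i, name in enumerate(genotypes):
        preset = make_preset(name)
        scheme = preset.scheme
        tau_b = 1.0 / (scheme.k_1 + scheme.k_minus1) if scheme.k_1 else 1.0 / scheme.k_minus1
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(seed, spawn_key=(i,)).spawn(2)]
        t_off = 10.0
        t_end_macro = t_off + min(4.0 * tau_b, 1600.0)
        macro = render_macroscopic(
            preset, Protocol(t_off, t_end_macro, n_channels_macro),
            RecordingSpec(**_MACRO_SPEC), seed=seeds[0])
        macro_path = out_dir / f"{preset.name}_macroscopic.tsv"
        write_trace(macro, macro_path)

        rng = np.random.default_rng(seeds[1])
        t_end_last = t_off + min(3.0 * tau_b * n_channels_last, 600.0)
        spec_last = RecordingSpec(**_LAST_SPEC)
        n_samp = int(math.floor(t_end_last * spec_last.fs))
        t = np.arange(n_samp) / spec_last.fs
        x = np.zeros(n_samp)
        for _ in range(n_channels_last):
            traj = simulate_with_atp_removal(scheme, t_off, t_end_last, rng=rng)
            states = traj.state_at(t)
            x += np.where(np.isin(states, list(OPEN_STATES)), spec_last.i_unit, 0.0)
        if spec_last.noise_sd > 0:
            x = x + rng.normal(0.0, spec_last.noise_sd, size=n_samp)
        x = _acquisition_filter(x, spec_last.fs, spec_last.f_acq)
        last = CurrentTrace(0.0, spec_last.fs, x, markers={"t_atp_off": t_off},
                            meta={"i_unit": spec_last.i_unit,
                                  "f_acq": spec_last.f_acq,
                                  "noise_sd": spec_last.noise_sd,
                                  "seed": seeds[1],
                                  "n_channels": n_channels_last})
        last_path = out_dir / f"{preset.name}_last_channel.tsv"
        write_trace(last, last_path)

        manifest["genotypes"][preset.name] = {
            "rates": {k: getattr(scheme, k) for k in
                      ("k_open", "k_1", "k_minus1", "k_2", "k_OC", "k_CO")},
            "tau_b_s": tau_b,
            "seeds": {"macroscopic": seeds[0], "last_channel": seeds[1]},
            "files": {"macroscopic": macro_path.name,
                      "last_channel": last_path.name},
            "n_channels": {"macroscopic": n_channels_macro,
                           "last_channel": n_channels_last},
            "t_atp_off_s": t_off,
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for fixture reproducibility checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
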