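"""End-to-end analysis pipeline.

Chains the two analysis paths over synthetic recordings:

* macroscopic: render ATP-removal relaxations per genotype -> normalize to
  the pre-removal steady state -> single-exponential fit -> replicate
  aggregation -> (when the four corner genotypes are present) a rate-based
  mutant cycle with interaction energy.
* single-channel: render a small patch -> locate the last-channel window ->
  Gaussian filter, half-amplitude idealization -> intraburst statistics.

Everything is driven by a single JSON-able config with one integer seed; all
stochastic stages draw substreams deterministically from it, so re-running a
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gating import mean_burst_duration
from .io import write_results_json, write_trace
from .presets import make_preset
from .relaxation import aggregate_replicates, fit_single_exponential, normalize_steady_state
from .synth import Protocol, RecordingSpec, render_macroscopic
from .thermo import CornerEstimate, MutantCycle, mutant_cycle_interaction

log = logging.getLogger("cftrgate")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "CYCLE_ROLES"]

#: genotype -> role in the closure-rate mutant cycle of the Q1371/G576 pair
CYCLE_ROLES = {
    "hE1371Q": "background",
    "hE1371Q_G576del": "singleA",
    "hE1371S": "singleB",
    "hE1371S_G576del": "double",
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    genotypes: list[str]
    output_dir: str
    t_atp_off: float = 10.0
    t_end: float | None = None       # None: per-genotype 4 * tau_b after removal
    n_channels: int = 1000
    n_replicates: int = 8
    fs: float = 100.0
    f_acq: float = 25.0
    i_unit: float = -0.5
    noise_sd: float = 0.05
    fc_analysis: float = 100.0
    window: float = 2.0              # steady-state normalization window (s)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("config requires an integer seed")
        if not self.genotypes:
            raise ValueError("config requires a non-empty genotype list")
        if self.fs <= 2 * self.f_acq:
            raise ValueError("fs must exceed 2 * f_acq")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for SEM aggregation")
        for g in self.genotypes:
            make_preset(g)  # raises KeyError with the documented presets

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        flat = dict(d)
        for section in ("protocol", "recording", "analysis"):
            flat.update(flat.pop(section, {}) or {})
        known = {f for f in cls.__dataclass_fields__}
        extra = set(flat) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**flat)

    def config_hash(self) -> str:
        # the hash covers everything that influences the numbers, not where
        # they are written
        d = asdict(self)
        d.pop("output_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run the macroscopic analysis path and, if possible, the mutant cycle.

    Writes, under ``output_dir``: one example trace per genotype, a fit JSON
    per genotype (tau, SEM, n, amplitude, window), a mutant-cycle JSON when
    the four corner genotypes are all present, and a provenance log.  Returns
    the results bundle as a dict.
    """
    if isinstance(config, dict):
        try:
            config = RunConfig.from_dict(config)
        except (TypeError, ValueError, KeyError) as err:
            raise PipelineError("config", str(err)) from err
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                    "version": __version__, "genotypes": {}}
    spec = RecordingSpec(fs=config.fs, f_acq=config.f_acq,
                         i_unit=config.i_unit, noise_sd=config.noise_sd)
    root = np.random.SeedSequence(config.seed)

    for gi, name in enumerate(config.genotypes):
        preset = make_preset(name)
        tau_true = mean_burst_duration(preset.scheme)
        t_end = config.t_end or config.t_atp_off + min(4.0 * tau_true, 1600.0)
        protocol = Protocol(config.t_atp_off, t_end, config.n_channels)
        fits = []
        result_path = out / f"{preset.name}_fit.json"
        try:
            seeds = np.random.SeedSequence(config.seed, spawn_key=(gi,)) \
                .spawn(config.n_replicates)
            for rep, ss in enumerate(seeds):
                rep_seed = int(ss.generate_state(1)[0] % (2**31))
                trace = render_macroscopic(preset, protocol, spec, seed=rep_seed)
                if rep == 0:
                    write_trace(trace, out / f"{preset.name}_macroscopic.tsv")
                norm = normalize_steady_state(trace, window=config.window)
                fits.append(fit_single_exponential(
                    norm, ensemble_size=config.n_channels))
            agg = aggregate_replicates(fits)
        except (ValueError, RuntimeError) as err:
            result_path.with_suffix(".partial.json").write_text(
                json.dumps({"genotype": preset.name, "error": str(err)}) + "\n")
            raise PipelineError(f"relaxation:{preset.name}", str(err)) from err
        rates = [f.rate for f in fits]
        entry = {
            "genotype": preset.name,
            "tau_s": agg.tau,
            "sem_tau_s": agg.sem_tau,
            "n": agg.n,
            "amplitude": agg.amplitude,
            "window": list(agg.t_fit),
            "rate_per_s": float(np.mean(rates)),
            "sem_rate_per_s": float(np.std(rates, ddof=1) / np.sqrt(len(rates))),
            "true_tau_s": tau_true,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
        write_results_json(entry, result_path)
        bundle["genotypes"][preset.name] = entry
        log.info("fit %s: tau = %.4g +/- %.2g s (true %.4g)",
                 preset.name, agg.tau, agg.sem_tau, tau_true)

    present = {g: bundle["genotypes"][g] for g in CYCLE_ROLES
               if g in bundle["genotypes"]}
    if len(present) == 4:
        corners = {}
        for geno, role in CYCLE_ROLES.items():
            e = bundle["genotypes"][geno]
            corners[role] = CornerEstimate(
                label=geno, kind="rate", mean=e["rate_per_s"],
                sem=e["sem_rate_per_s"], n=e["n"])
        cycle = MutantCycle(background=corners["background"],
                            single_A=corners["singleA"],
                            single_B=corners["singleB"],
                            double=corners["double"])
        try:
            coupling = mutant_cycle_interaction(cycle)
        except ValueError as err:
            raise PipelineError("mutant-cycle", str(err)) from err
        cyc_entry = {
            "transition": coupling.transition,
            "ddG_int_kT": coupling.ddG_int,
            "sem_kT": coupling.sem,
            "p": coupling.p,
            "sides_kT": [list(s) for s in coupling.sides],
            "corners": {r: {"genotype": c.label, "rate_per_s": c.mean,
                            "sem": c.sem, "n": c.n}
                        for r, c in corners.items()},
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
        write_results_json(cyc_entry, out / "mutant_cycle.json")
        bundle["mutant_cycle"] = cyc_entry
        log.info("mutant cycle: ddG_int = %.3f +/- %.3f kT (p = %.2g)",
                 coupling.ddG_int, coupling.sem, coupling.p)

    write_results_json(
        {"seed": config.seed, "config": asdict(config),
         "config_hash": config.config_hash(), "version": __version__},
        out / "run_log.json")
    return bundle
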