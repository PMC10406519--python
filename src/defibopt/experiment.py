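"""Config-driven, reproducible experiment pipelines.

An experiment is described by a YAML/dict config naming one pipeline
(``episodes``, ``tdom``, ``adp``, ``dose-response``, ``tr`` or ``ga``)
plus its inputs, and produces an output directory containing a
manifest (config copy, package version, seeds, wall time) next to the
pipeline outputs.  Every random draw derives from the single master
seed through named substreams, so components can be re-run
independently yet reproducibly, and re-running an identical config
reproduces all outputs except timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .adp import DEFAULT_CUTOFFS_HZ, derive_adp_spec, dose_response, mean_power_spectrum
from .episodes import (
    EpisodeLibrary,
    build_episode_library,
    estimate_dominant_period_from_record,
    record_episode,
)
from .ga import (
    GAHyperparams,
    SimulationBackend,
    SurrogateBackend,
    init_population,
    run_ga,
)
from .models import MODEL_NAMES, load_parameter_set
from .pacing import PacingProtocol, pacing_cost, termination_ratio
from .solver import GridSpec

__all__ = ["ExperimentConfig", "run_experiment", "substream"]

PIPELINES = ("episodes", "tdom", "adp", "dose-response", "tr", "ga")


def substream(master_seed: int, name: str) -> int:
    """Derive a named, stable 31-bit substream seed from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class ExperimentConfig:
    """Validated experiment description."""

    pipeline: str
    model: str
    out_dir: str
    seed: int = 0
    grid_n: int | None = None
    library_path: str | None = None
    n_episodes: int = 10
    burn_in: float = 2000.0
    record_s: float = 10.0
    n_pulses: int = 5
    cutoff_hz: float | None = None
    amplitudes: list[float] = field(default_factory=list)
    t_dom: float | None = None
    n_distributions: int = 5
    protocol_path: str | None = None
    ga: dict = field(default_factory=dict)

    def __post_init__(self):
        problems = []
        if self.pipeline not in PIPELINES:
            problems.append(
                f"pipeline {self.pipeline!r} not one of {', '.join(PIPELINES)}"
            )
        if self.model not in MODEL_NAMES:
            problems.append(
                f"model {self.model!r} not one of {', '.join(MODEL_NAMES)}"
            )
        if self.pipeline in ("dose-response", "tr") and not self.library_path:
            problems.append(
                f"pipeline {self.pipeline!r} needs library_path "
                "(create one with 'defibopt episodes make')"
            )
        if problems:
            raise ValueError("invalid config:\n  - " + "\n  - ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def grid(self) -> GridSpec:
        if self.grid_n is not None:
            return GridSpec(self.grid_n, self.grid_n)
        n = 512 if self.model == "BOCF" else 256
        return GridSpec(n, n)


def _load_library(cfg: ExperimentConfig) -> EpisodeLibrary:
    return EpisodeLibrary.load(cfg.library_path)


def _save_population(pop, path: Path) -> None:
    path.write_text(json.dumps([
        {
            "amplitudes": list(e.protocol.amplitudes),
            "intervals": list(e.protocol.intervals),
            "pulse_len": e.protocol.pulse_len,
            "pc": e.pc,
            "tr": e.tr,
            "birth_gen": e.birth_gen,
        }
        for e in pop
    ], indent=2))


def _load_population(path: Path):
    from .ga import PopulationEntry

    if not path.exists():
        raise FileNotFoundError(f"no population checkpoint at {path}")
    return [
        PopulationEntry(
            PacingProtocol(
                tuple(d["amplitudes"]), tuple(d["intervals"]), d["pulse_len"]
            ),
            d["pc"], d["tr"], d["birth_gen"],
        )
        for d in json.loads(path.read_text())
    ]


def _need_t_dom(cfg: ExperimentConfig) -> float:
    if cfg.t_dom is None:
        raise ValueError(
            "this pipeline needs t_dom (ms); run the 'tdom' pipeline first"
        )
    return cfg.t_dom


def run_experiment(config: ExperimentConfig | dict) -> dict:
    """Execute the configured pipeline; returns the result summary dict.

    Writes ``manifest.json`` plus pipeline outputs into ``out_dir``.
    """
    cfg = ExperimentConfig(**config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    params = load_parameter_set(cfg.model)
    grid = cfg.grid()
    result: dict = {"pipeline": cfg.pipeline, "model": cfg.model}

    if cfg.pipeline == "episodes":
        lib = build_episode_library(
            params,
            n=cfg.n_episodes,
            seed=substream(cfg.seed, "episodes"),
            burn_in=cfg.burn_in,
            grid=grid,
            validate_ms=(5.0 * cfg.t_dom) if cfg.t_dom else None,
        )
        lib.save(out / "library")
        result["n_episodes"] = len(lib)
        result["library"] = str(out / "library")

    elif cfg.pipeline == "tdom":
        from .episodes import make_fibrillation_ic

        ic = make_fibrillation_ic(
            params, substream(cfg.seed, "episodes"), cfg.burn_in, grid
        )
        records, _ = record_episode(params, ic, grid, cfg.record_s, (120.0,))
        dom = estimate_dominant_period_from_record(records[120.0], 120.0)
        result["t_dom_ms"] = dom.t_dom
        result["mean_freq_hz"] = dom.mean_freq_hz
        result["n_pixels_used"] = dom.n_pixels_used

    elif cfg.pipeline == "adp":
        from .episodes import make_fibrillation_ic

        ic = make_fibrillation_ic(
            params, substream(cfg.seed, "episodes"), cfg.burn_in, grid
        )
        records, _ = record_episode(params, ic, grid, cfg.record_s, (100.0,))
        spectrum = mean_power_spectrum(records[100.0], sampling_ms=10.0)
        cutoff = cfg.cutoff_hz or DEFAULT_CUTOFFS_HZ[cfg.model]
        spec = derive_adp_spec(spectrum, cutoff, cfg.n_pulses)
        result["cutoff_hz"] = spec.cutoff_hz
        result["intervals_ms"] = list(spec.intervals)

    elif cfg.pipeline == "dose-response":
        lib = _load_library(cfg)
        t_dom = _need_t_dom(cfg)
        cutoff = cfg.cutoff_hz or DEFAULT_CUTOFFS_HZ[cfg.model]
        if cfg.protocol_path:
            base = PacingProtocol.load(cfg.protocol_path)
            from .adp import ADPProtocolSpec

            spec = ADPProtocolSpec(cutoff, base.n_pulses, base.intervals)
        else:
            raise ValueError("dose-response needs protocol_path with ADP timings")
        curve = dose_response(
            params,
            spec,
            cfg.amplitudes or list(np.linspace(0.0, 1.0, 11)),
            lib,
            t_dom,
            cfg.n_distributions,
            substream(cfg.seed, "sites"),
        )
        curve.to_csv(out / "dose_response.csv", index=False)
        result["curve"] = str(out / "dose_response.csv")

    elif cfg.pipeline == "tr":
        lib = _load_library(cfg)
        t_dom = _need_t_dom(cfg)
        if not cfg.protocol_path:
            raise ValueError("tr pipeline needs protocol_path")
        proto = PacingProtocol.load(cfg.protocol_path)
        tr, succ, att = termination_ratio(
            proto, lib, t_dom, cfg.n_distributions, substream(cfg.seed, "sites")
        )
        result.update(
            {"tr": tr, "successes": succ, "attempts": att, "pc": pacing_cost(proto)}
        )

    elif cfg.pipeline == "ga":
        hp = GAHyperparams(seed=substream(cfg.seed, "ga"), **cfg.ga.get("hyperparams", {}))
        backend_name = cfg.ga.get("backend", "simulation")
        if backend_name == "simulation":
            if not cfg.library_path:
                raise ValueError(
                    "simulation-backed GA needs library_path "
                    "(create one with 'defibopt episodes make')"
                )
            lib = _load_library(cfg)
            t_dom = _need_t_dom(cfg)
            fitness = SimulationBackend(
                lib, t_dom, cfg.n_distributions, substream(cfg.seed, "sites")
            )
        elif backend_name == "surrogate":
            rng_t = np.random.default_rng(substream(cfg.seed, "surrogate"))
            target = PacingProtocol(
                tuple(rng_t.uniform(*hp.amp_range, hp.n_pulses)),
                tuple(rng_t.uniform(*hp.interval_range, hp.n_pulses - 1)),
                hp.pulse_len,
            )
            fitness = SurrogateBackend(target, hp)
        else:
            raise ValueError(f"unknown ga backend {backend_name!r}")
        rng = np.random.default_rng(substream(cfg.seed, "ga-init"))
        scheme = cfg.ga.get("scheme", "uniform")
        base = (
            PacingProtocol.load(cfg.protocol_path) if cfg.protocol_path else None
        )
        start_gen = int(cfg.ga.get("start_generation", 0))
        if start_gen > 0:
            pop = _load_population(out / "population.json")
        else:
            pop = init_population(scheme, hp, fitness, rng, base_protocol=base)
        pop, hist = run_ga(pop, hp, fitness, start_generation=start_gen)
        hist.frame().to_csv(
            out / "ga_history.csv",
            index=False,
            mode="a" if start_gen > 0 else "w",
            header=start_gen == 0,
        )
        _save_population(pop, out / "population.json")
        best = max(pop, key=lambda e: (e.tr, -e.pc))
        best.protocol.save(out / "best_protocol.json")
        result.update(
            {
                "best_tr": best.tr,
                "best_pc": best.pc,
                "history": str(out / "ga_history.csv"),
                "best_protocol": str(out / "best_protocol.json"),
            }
        )

    manifest = {
        "config": asdict(cfg),
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 3),
        "result": result,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
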