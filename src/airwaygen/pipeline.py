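"""End-to-end pipeline: anatomy (synthetic or from files) -> distal growth ->
diameters -> morphometry -> resistance, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from . import __version__
from .core import AirwayTree, LobeSurface, assign_generations, \
    assign_horsfield_orders, assign_strahler_orders
from .diameters import DiameterScheme, apply_scheme
from .generation import GenerationConfig, generate_complete_tree
from .io import read_surface, read_tree, tree_bytes, write_surface, write_tree
from .morphometry import summarize
from .resistance import (FluidProperties, resistance_decomposition,
                         solve_flow, total_resistance,
                         PA_S_PER_M3_TO_CMH2O_S_PER_L)
from .synthetic import AnatomyConfig, ConstrictionSpec, make_anatomy

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_FLOW_RATES_L_PER_S = (0.17, 0.83, 1.67)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``airways``/``lobes`` paths are given the pipeline starts from files;
    otherwise the synthetic anatomy front end supplies them.
    """

    output_dir: str = "airwaygen_run"
    airways: Optional[str] = None  # tree file; None -> synthetic
    lobes: Sequence[str] = ()  # surface files; empty -> synthetic
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    scheme: DiameterScheme = field(default_factory=DiameterScheme)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    flow_rates_L_per_s: Sequence[float] = DEFAULT_FLOW_RATES_L_PER_S
    rng_seed: int = 0


def _config_dict(config: RunConfig) -> Dict:
    d = asdict(config)
    d["lobes"] = list(d["lobes"])
    d["flow_rates_L_per_s"] = list(d["flow_rates_L_per_s"])
    return d


def run_pipeline(config: RunConfig) -> Dict:
    """Run all stages and write the four artifacts (complete tree, morphometry
    CSV, resistance JSON, manifest).  Returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}
    manifest: Dict = {
        "version": __version__,
        "config": _config_dict(config),
        "seed": config.rng_seed,
        "timings_s": timings,
    }

    t0 = time.perf_counter()
    if config.airways and config.lobes:
        central = read_tree(config.airways)
        lobes = [read_surface(p) for p in config.lobes]
    else:
        anat = config.anatomy
        anat.rng_seed = config.rng_seed
        lobes = None
        lobes, central = make_anatomy(anat)
        write_tree(central, out / "central_tree.vtk")
        for lobe in lobes:
            write_surface(lobe, out / f"lobe_{lobe.label}.stl")
    timings["ingest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    gen = config.generation
    gen.rng_seed = config.rng_seed
    tree, stats = generate_complete_tree(central, lobes, gen)
    timings["generate"] = time.perf_counter() - t0
    manifest["growth"] = {
        "initial_seeds": stats.initial_seeds,
        "consumed": stats.consumed,
        "discarded": stats.discarded,
        "rounds": stats.rounds,
    }

    t0 = time.perf_counter()
    assign_generations(tree)
    assign_horsfield_orders(tree)
    assign_strahler_orders(tree)
    apply_scheme(tree, config.scheme)
    write_tree(tree, out / "complete_tree.vtk")
    timings["diameters"] = time.perf_counter() - t0
    manifest["tree_sha256"] = hashlib.sha256(tree_bytes(tree)).hexdigest()
    manifest["n_branches"] = len(tree.branches)
    manifest["n_terminal"] = len(tree.terminal_branches())

    t0 = time.perf_counter()
    report = summarize(tree)
    report.per_branch.to_csv(out / "morphometry_per_branch.csv", index=False)
    report.summary.to_csv(out / "morphometry_summary.csv")
    timings["morphometry"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    resist: List[Dict] = []
    state = solve_flow(tree, 1.0, model="poiseuille", props=config.fluid)
    dec = resistance_decomposition(tree, state)
    resist.append(_resist_record("poiseuille", None, dec))
    for q in config.flow_rates_L_per_s:
        state = solve_flow(tree, q * 1e-3, model="pedley", props=config.fluid)
        dec = resistance_decomposition(tree, state)
        resist.append(_resist_record("pedley", q, dec))
    (out / "resistance.json").write_text(json.dumps(resist, indent=2))
    timings["resistance"] = time.perf_counter() - t0

    manifest["resistance"] = resist
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _resist_record(model, flow_L_per_s, dec) -> Dict:
    return {
        "model": model,
        "flow_L_per_s": flow_L_per_s,
        "total_Pa_s_per_m3": dec.total,
        "total_cmH2O_s_per_L": dec.total_cmH2O_s_per_L,
        "generated_fraction": dec.generated_fraction,
        "per_generation_fraction": {str(k): v for k, v
                                    in dec.per_generation_fraction.items()},
        "iterations": dec.iterations,
        "residual": dec.residual,
    }
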