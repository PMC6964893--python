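"""Stage-wise pipeline: simulate -> fit -> run -> dsa / psa / scenario.

Each stage writes plain CSV/JSON artifacts under the output directory; a
manifest records the configuration hash, seeds, package versions and stage
timings so any run is reproducible from (config file, seed set).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, config_hash
from .model import CEModel
from .sensitivity import ceac, run_dsa, run_psa, run_scenario
from .synthetic import TrialData, generate_trial, read_trial, write_trial

__all__ = ["STAGES", "MissingArtifactError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "run", "dsa", "psa", "scenario")
_REQUIRES = {
    "simulate": (),
    "fit": ("simulate",),
    "run": ("fit",),
    "dsa": ("run",),
    "psa": ("run",),
    "scenario": ("run",),
}
_ARTIFACTS = {
    "simulate": "ipd.csv",
    "fit": "fits.json",
    "run": "base_case.json",
}


class MissingArtifactError(RuntimeError):
    """A requested stage's prerequisite artifact is absent."""


def _check_dependencies(stages: list[str], outdir: Path) -> None:
    done = set()
    for stage in stages:
        for req in _REQUIRES[stage]:
            artifact = _ARTIFACTS.get(req)
            if req in done or req in stages[: stages.index(stage)]:
                continue
            if artifact and (outdir / artifact).exists():
                continue
            raise MissingArtifactError(
                f"stage {stage!r} requires {req!r} (missing artifact "
                f"{artifact or req} under {outdir})"
            )
        done.add(stage)


def run_pipeline(
    config: ModelConfig,
    stages=STAGES,
    output_dir: str | Path = "results",
    seed: int | None = None,
) -> dict:
    """Execute the requested stages in dependency order.

    ``seed`` overrides the configured trial seed (the PSA seed is derived
    from it); every artifact is a text file.  Returns a manifest dict, also
    written to ``manifest.json``.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ValueError(f"no valid stages requested; choose from {STAGES}")
    _check_dependencies(stages, outdir)

    seeds = dict(config.seeds)
    if seed is not None:
        seeds["trial"] = int(seed)
        seeds["psa"] = (int(seed) * 1_000_003 + 17) % (2**31)

    timings: dict[str, float] = {}
    trial: TrialData | None = None
    model: CEModel | None = None
    base = None

    def need_trial() -> TrialData:
        nonlocal trial
        if trial is None:
            trial = read_trial(outdir)
        return trial

    def need_model() -> CEModel:
        nonlocal model
        if model is None:
            model = CEModel(config, need_trial()).fit()
        return model

    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        if stage == "simulate":
            trial = generate_trial(config.arms, seeds["trial"])
            write_trial(trial, outdir)
        elif stage == "fit":
            m = need_model()
            fits = {
                arm: {ep: f.to_dict() for ep, f in af.fits.items()}
                for arm, af in m.arm_fits.items()
            }
            (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
            for arm, af in m.arm_fits.items():
                for ep, curve in af.km.items():
                    curve.to_frame().to_csv(outdir / f"km_{arm}_{ep}.csv", index=False)
            for (arm, ep), table in m.selection_report().items():
                table.to_csv(outdir / f"selection_{arm}_{ep}.csv", index=False)
        elif stage == "run":
            m = need_model()
            base = m.base_case()
            (outdir / "base_case.json").write_text(json.dumps(base.summary(), indent=2))
            base.cost_table().round(2).to_csv(outdir / "cost_breakdown.csv")
            for arm, snap in m.occupancy_tables().items():
                snap.to_csv(outdir / f"occupancy_{arm}.csv", index=False)
            for arm, c in m.base_curves().items():
                pd.DataFrame(
                    {
                        "week": np.arange(len(c["pfs"].surv)),
                        "pfs": c["pfs"].surv,
                        "os": c["os"].surv,
                        "duration": c["duration"].surv,
                    }
                ).to_csv(outdir / f"curves_{arm}.csv", index=False)
        elif stage == "dsa":
            tornado = run_dsa(need_model())
            tornado.to_csv(outdir / "dsa_tornado.csv", index=False)
        elif stage == "psa":
            m = need_model()
            psa_result = run_psa(m, seed=seeds["psa"])
            psa_result.samples.to_csv(outdir / "psa_samples.csv", index=False)
            (outdir / "psa_summary.json").write_text(json.dumps(psa_result.summary(), indent=2))
            grid = np.arange(0.0, config.psa.wtp_grid_max + 1, config.psa.wtp_grid_step)
            ceac(psa_result.samples, grid).to_csv(outdir / "ceac.csv", index=False)
        elif stage == "scenario":
            result = run_scenario(need_model())
            (outdir / "scenario.json").write_text(json.dumps(result.summary(), indent=2))
            result.cost_table().round(2).to_csv(outdir / "scenario_cost_breakdown.csv")
        timings[stage] = time.perf_counter() - t0

    manifest = {
        "config_hash": config_hash(config),
        "seeds": seeds,
        "stages": stages,
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "versions": {"psmcea": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
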