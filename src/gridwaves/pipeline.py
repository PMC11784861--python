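"""End-to-end orchestration: staged runs with a reproducibility manifest.

A :class:`RunConfig` lists stages and per-stage parameter blocks; running
it produces a run directory holding the shared HDF5 container, TSV/JSON
exports and a manifest recording the config hash, seeds and package
version.  Reruns with the same config and seeds reproduce every output
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gwio
from .containers import wave_events_to_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "preprocess", "detect-waves", "ensembles", "csd", "simulate")


@dataclass
class RunConfig:
    """Stage list plus per-stage parameter blocks.

    Every stochastic stage takes its seed from ``seed`` unless the stage
    block overrides it.  Round-trips losslessly through YAML.
    """

    stages: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "run"
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stages": list(self.stages), "seed": self.seed,
                "out_dir": self.out_dir, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(stages=list(d.get("stages", [])), seed=int(d.get("seed", 0)),
                   out_dir=d.get("out_dir", "run"), params=d.get("params", {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    override = cfg.params.get(stage, {}).get("seed")
    if override is not None:
        return int(override)
    # stable per-stage derivation, kept below 2**31
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return (cfg.seed * 1000 + int.from_bytes(h[:2], "big")) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in dependency order.

    Returns the run directory.  A missing upstream artifact fails fast
    naming the dependency.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5 = out / "data.h5"
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stage_seeds": {},
        "timing_s": {},
        "outputs": {},
    }
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage '{stage}'")
        t0 = time.time()
        seed = _stage_seed(config, stage)
        manifest["stage_seeds"][stage] = seed
        p = dict(config.params.get(stage, {}))
        p.pop("seed", None)
        logger.info("stage %s (seed %d)", stage, seed)

        if stage == "synth":
            from .synth import TrialSetSpec, WaveFieldSpec, generate_trial_lfp

            wave = WaveFieldSpec(seed=seed, **p.get("wave", {}))
            trials = TrialSetSpec(seed=seed, **p.get("trials", {}))
            lfp, labels = generate_trial_lfp(trials, wave)
            gwio.save_grid_lfp(h5, lfp)
            gwio.save_touch_times(h5, labels["touch_time_s"].to_numpy())
            labels.to_csv(out / "trial_labels.tsv", sep="\t", index=False)
            manifest["outputs"]["synth"] = ["data.h5:/lfp", "trial_labels.tsv"]

        elif stage == "preprocess":
            if not h5.exists():
                raise FileNotFoundError("preprocess needs the synth stage output (data.h5:/lfp)")
            from .preprocess import bandpass, downsample, remove_scan_artifact

            lfp = gwio.load_grid_lfp(h5)
            if p.get("notch", False):
                lfp = remove_scan_artifact(lfp)
            target_fs = p.get("downsample")
            if target_fs:
                lfp = downsample(lfp, float(target_fs))
            lfp = bandpass(lfp, p.get("band", "wideband"))
            gwio.save_grid_lfp(h5, lfp)
            manifest["outputs"]["preprocess"] = ["data.h5:/lfp"]

        elif stage == "detect-waves":
            if not h5.exists():
                raise FileNotFoundError("detect-waves needs data.h5:/lfp from synth/preprocess")
            from .preprocess import reference_channel
            from .waves import WaveDetector

            lfp = gwio.load_grid_lfp(h5)
            try:
                touch = gwio.load_touch_times(h5)
            except KeyError:
                touch = None
            trig = p.get("trigger_channel")
            if trig is None:
                trig = reference_channel(lfp, touch) if touch is not None else 0
            det = WaveDetector(
                trigger_channel=int(trig),
                n_shuffles=int(p.get("null_shuffles", 1000)),
                band=p.get("band", "wideband"),
                late_window=tuple(p.get("late_window", (0.1, 0.3))),
                seed=seed,
            )
            det.fit(lfp)
            det.detect(touch)
            gwio.save_analytic_field(h5, det.field_)
            gwio.save_wave_table(out / "waves.tsv", det.events_frame())
            manifest["outputs"]["detect-waves"] = ["waves.tsv", "data.h5:/gp"]

        elif stage == "ensembles":
            from .ensembles import EnsembleDetector
            from .synth import EnsembleRasterSpec, EnsembleSpec, generate_calcium_raster

            if "raster" in p:
                ens_specs = [EnsembleSpec(**e) for e in p["raster"].pop("ensembles", [])]
                raster, _ = generate_calcium_raster(
                    EnsembleRasterSpec(seed=seed, ensembles=ens_specs, **p["raster"])
                )
                gwio.save_calcium(h5, raster)
            else:
                raster = gwio.load_calcium(h5)
            det = EnsembleDetector(
                bin_ms=float(p.get("bin_ms", 300.0)),
                dice_thresh=float(p.get("dice_thresh", 0.25)),
                n_shuffles=int(p.get("shuffles", 1000)),
                seed=seed,
            ).fit(raster)
            gwio.save_ensembles_json(out / "ensembles.json", det.ensembles_)
            manifest["outputs"]["ensembles"] = ["ensembles.json"]

        elif stage == "csd":
            from .laminar import csd as csd_fn
            from .synth import LaminarDipoleSpec, generate_laminar_lfp

            if "dipole" in p:
                lam, _ = generate_laminar_lfp(LaminarDipoleSpec(seed=seed, **p["dipole"]))
                gwio.save_laminar(h5, lam)
            else:
                lam = gwio.load_laminar(h5)
            cmap = csd_fn(lam, n=int(p.get("n", 2)))
            np.savetxt(out / "csd.tsv", cmap, delimiter="\t")
            manifest["outputs"]["csd"] = ["csd.tsv"]

        elif stage == "simulate":
            from .network import NetworkConfig, build_network, simulate

            cfg_net = NetworkConfig(seed=seed, **p.get("network", {}))
            net = build_network(cfg_net)
            rec = simulate(net, float(p.get("duration_s", 2.0)), seed=seed)
            np.savetxt(out / "spikes.tsv", rec.spikes, delimiter="\t",
                       header="t_s\tneuron_id", comments="")
            np.savetxt(
                out / "neurons.tsv",
                np.column_stack([rec.positions, rec.is_excitatory]),
                delimiter="\t", header="x_mm\ty_mm\tis_excitatory", comments="",
            )
            if rec.sim_lfp is not None:
                gwio.save_grid_lfp(h5, rec.as_grid_lfp())
            manifest["outputs"]["simulate"] = ["spikes.tsv", "neurons.tsv", "data.h5:/lfp"]

        manifest["timing_s"][stage] = round(time.time() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
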