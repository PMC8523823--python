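"""Plain-text file I/O: trial tables, manifests, parameter files.

Everything on disk is diffable text: per-trial CSV tables with a fixed
column layout (time, emg_TA, emg_SOL, emg_GAL, emg_GAM, theta, tau_id,
grf_v, grf_ap) and ``# key=value`` header lines for scalar metadata, a CSV
dataset manifest, YAML for parameters / truth provenance, and CSV result
tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .activation import ActivationParams
from .mtu import MuscleParams
from .pipeline import MUSCLES, ModelParams
from .synth import GaitTrial, SyntheticTruth

__all__ = [
    "write_trial", "read_trial", "write_dataset", "read_dataset",
    "write_truth", "write_model_params", "read_model_params",
]

TRIAL_COLUMNS = ("time", "emg_TA", "emg_SOL", "emg_GAL", "emg_GAM",
                 "theta", "tau_id", "grf_v", "grf_ap")


def write_trial(trial: GaitTrial, path: str | Path) -> None:
    path = Path(path)
    header = {
        "rate": trial.rate,
        "stance_start": trial.stance_start,
        "stance_stop": trial.stance_stop,
        "condition": trial.condition,
        "subject": trial.subject,
        "trial": trial.trial,
        "raw_emg": int(trial.raw_emg),
    }
    n = trial.time.size
    cols = {
        "time": trial.time,
        **{f"emg_{m}": trial.emg[m] for m in MUSCLES},
        "theta": trial.theta,
        "tau_id": trial.tau_id,
        "grf_v": trial.grf_v if trial.grf_v is not None else np.full(n, np.nan),
        "grf_ap": trial.grf_ap if trial.grf_ap is not None else np.full(n, np.nan),
    }
    with path.open("w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.9g")


def read_trial(path: str | Path) -> GaitTrial:
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            skip += 1
    df = pd.read_csv(path, skiprows=skip)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    grf_v = df["grf_v"].to_numpy()
    grf_ap = df["grf_ap"].to_numpy()
    return GaitTrial(
        rate=float(meta["rate"]),
        time=df["time"].to_numpy(),
        emg={m: df[f"emg_{m}"].to_numpy() for m in MUSCLES},
        theta=df["theta"].to_numpy(),
        tau_id=df["tau_id"].to_numpy(),
        grf_v=None if np.all(np.isnan(grf_v)) else grf_v,
        grf_ap=None if np.all(np.isnan(grf_ap)) else grf_ap,
        stance_start=int(meta["stance_start"]),
        stance_stop=int(meta["stance_stop"]),
        condition=meta["condition"],
        subject=int(meta["subject"]),
        trial=int(meta["trial"]),
        raw_emg=bool(int(meta.get("raw_emg", "0"))),
    )


def write_dataset(trials: Sequence[GaitTrial], outdir: str | Path) -> Path:
    """Write one CSV per trial plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in trials:
        name = f"s{t.subject:02d}_{t.condition}_t{t.trial:02d}.csv"
        write_trial(t, outdir / name)
        rows.append({"file": name, "subject": t.subject,
                     "condition": t.condition, "trial": t.trial})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest: str | Path) -> list[GaitTrial]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    return [read_trial(manifest.parent / f) for f in df["file"]]


def _model_to_dict(model: ModelParams) -> dict:
    return {
        "activation": dataclasses.asdict(model.activation),
        "muscles": {m: dataclasses.asdict(p) for m, p in model.muscles.items()},
        "gamma_df": model.gamma_df,
        "gamma_pf": model.gamma_pf,
        "lm0_mult": dict(model.lm0_mult),
        "lst_mult": dict(model.lst_mult),
    }


def write_model_params(model: ModelParams, path: str | Path,
                       extra: dict | None = None) -> None:
    doc = _model_to_dict(model)
    if extra:
        doc["provenance"] = extra
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model_params(path: str | Path) -> ModelParams:
    doc = yaml.safe_load(Path(path).read_text())
    return ModelParams(
        activation=ActivationParams(**doc["activation"]),
        muscles={m: MuscleParams(**p) for m, p in doc["muscles"].items()},
        gamma_df=doc["gamma_df"],
        gamma_pf=doc["gamma_pf"],
        lm0_mult=doc.get("lm0_mult", {}),
        lst_mult=doc.get("lst_mult", {}),
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the ground-truth description (parameters + generator knobs)."""
    doc = {
        "model": _model_to_dict(truth.model),
        "bursts": {m: [dataclasses.asdict(b) for b in bs]
                   for m, bs in truth.bursts.items()},
        "surface_effects": dict(truth.surface_effects),
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "rate": truth.rate,
        "stance_duration": truth.stance_duration,
        "angle_scale": truth.angle_scale,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
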