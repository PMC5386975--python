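"""End-to-end pipeline driver: synth -> preprocess -> SEP/maps -> decode."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decoding, mapping, sep
from .geometry import default_geometry
from .preprocess import (
    PreprocConfig,
    common_average_reference,
    extract_epochs,
    select_decode_trials,
)
from .recording import BASELINE_LEN, CONDITIONS, FULL_OFFSET
from .synth import SynthConfig, generate_recording

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def _asdict_cfg(obj):
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, frozenset):
            d[k] = sorted(v)
    return d


@dataclass
class PipelineConfig:
    """Serializable description of one full synthetic run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    decode_modes: tuple = ("full", "shuffle", "single_channel")
    C: float = decoding.DEFAULT_C_TIMESERIES
    n_permutations: int = 20
    seeds: dict = field(default_factory=lambda: {"cv": 0, "perm": 1})
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps({
            "synth": _asdict_cfg(self.synth),
            "preproc": _asdict_cfg(self.preproc),
            "decode_modes": list(self.decode_modes),
            "C": self.C,
            "n_permutations": self.n_permutations,
            "seeds": self.seeds,
            "out_dir": self.out_dir,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        pp = d.get("preproc", {})
        if pp.get("car_channels") is not None:
            pp["car_channels"] = tuple(pp["car_channels"])
        sy = d.get("synth", {})
        for k in ("broken_channels", "early_amp_uv", "early_center_um"):
            if sy.get(k) is not None:
                sy[k] = tuple(sy[k])
        if sy.get("finger_centers_um") is not None:
            sy["finger_centers_um"] = {
                k: tuple(v) for k, v in sy["finger_centers_um"].items()}
        return cls(
            synth=SynthConfig(**sy),
            preproc=PreprocConfig(**pp),
            decode_modes=tuple(d.get("decode_modes", ("full",))),
            C=d.get("C", decoding.DEFAULT_C_TIMESERIES),
            n_permutations=d.get("n_permutations", 20),
            seeds=d.get("seeds", {"cv": 0, "perm": 1}),
            out_dir=d.get("out_dir"),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _write_csv(df, path, header_meta: str):
    with open(path, "w") as fh:
        fh.write(f"# {header_meta}\n")
        df.to_csv(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and optionally writes) all tables.

    Stage failures abort with a :class:`PipelineError` naming the stage.
    Identical configs produce identical results.
    """
    results: dict = {"config_hash": config.config_hash(), "seeds": config.seeds}
    meta = f"config_hash={config.config_hash()} seeds={json.dumps(config.seeds)}"
    out = pathlib.Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())

    try:
        geometry = default_geometry()
        rec = generate_recording(config.synth, geometry)
        geometry = rec.geometry
        log.info("synth: %d triggers, %d channels, %d samples",
                 rec.n_triggers, rec.n_channels, rec.n_samples)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("synth", e) from e

    try:
        rec = common_average_reference(
            rec, car_channels=config.preproc.car_channels, copy=False)
        # 600 post-trigger samples: covers the decode window, the 33 ms
        # band-power window and the 98 ms surface-map sequence
        epochs = extract_epochs(rec, span=(BASELINE_LEN, 600),
                                cfg=config.preproc)
        log.info("preprocess: %d trials x %d channels retained",
                 epochs.n_trials, epochs.n_channels)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("preprocess", e) from e

    try:
        rms = sep.rest_rms(rec)
        results["rest_rms_uv"] = rms
        hg = {}
        traj = {}
        interp = mapping.CanvasInterpolator(geometry)
        for cond in CONDITIONS:
            if cond.intensity_ma != 4:
                continue
            avg = sep.average_epochs(epochs, cond)
            hg[str(cond)] = sep.band_power_map(avg)
            t = mapping.cog_trajectory(avg, geometry, time_range=(0, FULL_OFFSET),
                                       interpolator=interp)
            traj[str(cond)] = t.to_dataframe(geometry)
        results["high_gamma_power"] = pd.DataFrame(hg)
        results["cog_trajectories"] = traj
        if out is not None:
            _write_csv(pd.DataFrame({"rest_rms_uv": rms}), out / "rest_rms.csv", meta)
            _write_csv(results["high_gamma_power"], out / "high_gamma_power.csv", meta)
            for name, df in traj.items():
                _write_csv(df, out / f"cog_{name}.csv", meta)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("sep_analysis", e) from e

    if not config.decode_modes:
        return results

    try:
        dec = select_decode_trials(epochs)
        fm = decoding.build_features(dec)
        cv_seed = int(config.seeds.get("cv", 0))
        acc_rows = []
        if "full" in config.decode_modes:
            res = decoding.crossval_svm(fm, C=config.C, seed=cv_seed)
            results["full"] = res
            acc_rows.append({"mode": "full", "mean_acc": res.mean_acc,
                             "sd_acc": res.sd_acc})
            if out is not None:
                _write_csv(pd.DataFrame(res.confusion,
                                        index=[str(c) for c in CONDITIONS],
                                        columns=[str(c) for c in CONDITIONS]),
                           out / "confusion_full.csv", meta)
        if "shuffle" in config.decode_modes:
            accs = decoding.shuffled_label_control(
                fm, n_permutations=config.n_permutations, C=config.C,
                seed=int(config.seeds.get("perm", 1)))
            results["shuffle"] = accs
            acc_rows.append({"mode": "shuffle", "mean_acc": accs.mean(),
                             "sd_acc": accs.std(ddof=1)})
        if "single_channel" in config.decode_modes:
            sc = decoding.single_channel_accuracy_map(dec, C=config.C,
                                                      seed=cv_seed)
            results["single_channel"] = sc
            acc_rows.append({"mode": "single_channel_best",
                             "mean_acc": sc.max(), "sd_acc": np.nan})
            if out is not None:
                _write_csv(pd.DataFrame({"mean_acc": sc}),
                           out / "single_channel_accuracy.csv", meta)
        results["accuracy"] = pd.DataFrame(acc_rows)
        if out is not None and acc_rows:
            _write_csv(results["accuracy"].set_index("mode"),
                       out / "accuracy.csv", meta)
            (out / "run_meta.json").write_text(json.dumps(
                {"config_hash": config.config_hash(), "seeds": config.seeds},
                indent=2))
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("decode", e) from e

    return results
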