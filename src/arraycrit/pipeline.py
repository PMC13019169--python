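"""Configuration, schema validation, run manifests and stage chaining.

All tabular outputs are plain CSV with headers; configs, windows and truth
records are JSON.  Every stochastic stage consumes an explicit seed that is
recorded, together with input/output file digests, in a per-stage run
manifest so that identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["ValidationReport", "RunManifest", "validate", "run_pipeline", "SCHEMAS"]

#: required columns / structure per schema name
SCHEMAS: dict = {
    "trace": ["time", "activity"],
    "activity": ["cell_id", "time_s", "activity"],
    "traces": ["cell_id", "time_s", "donor", "acceptor"],
    "events": ["cell_id", "t_event_s", "direction", "amplitude", "tau_s", "residence_s"],
    "summary": ["cell_id", "mean_activity", "delta_G", "n_events", "is_two_state"],
    "sweep": ["L", "J", "Hb", "n_events", "mean_dt", "mean_tau", "r", "polarized", "seed"],
    "isoline": ["r_target", "L", "J_iso", "pct_dev"],
    "responses": ["J", "dH", "t_R", "amplitude", "speed", "n_reps", "censored_frac"],
    "windows": None,  # JSON
    "truth": None,  # JSON
    "config": None,  # JSON
}


@dataclass
class ValidationReport:
    ok: bool
    schema: str
    messages: list = field(default_factory=list)

    def fail(self, msg: str) -> None:
        self.ok = False
        self.messages.append(msg)


def _validate_windows(obj, rep: ValidationReport) -> None:
    for key in ("attractant", "repellent"):
        if key not in obj:
            rep.fail(f"missing key {key!r}")
            return
    ivs = []
    for key in ("attractant", "repellent"):
        for w in obj[key]:
            if len(w) != 2 or not w[0] < w[1]:
                rep.fail(f"malformed interval {w} in {key}")
                return
            ivs.append((float(w[0]), float(w[1])))
    ivs.sort()
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            rep.fail(f"overlapping windows [{a0},{a1}) and [{b0},{b1})")


def validate(path, schema_name: str) -> ValidationReport:
    """Validate a CSV/JSON artefact against a named schema.

    CSV schemas check required columns, finite numeric content and, for
    time-series schemas, per-cell strictly increasing time.  JSON schemas
    check structure (e.g. non-overlapping stimulus windows).
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; options: {sorted(SCHEMAS)}")
    rep = ValidationReport(ok=True, schema=schema_name)
    path = Path(path)
    if not path.exists():
        rep.fail(f"file not found: {path}")
        return rep
    cols = SCHEMAS[schema_name]
    if cols is None:
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            rep.fail(f"invalid JSON: {e}")
            return rep
        if schema_name == "windows":
            _validate_windows(obj, rep)
        elif schema_name in ("truth", "config") and not isinstance(obj, dict):
            rep.fail("top-level JSON object expected")
        return rep
    try:
        df = pd.read_csv(path)
    except Exception as e:  # malformed CSV
        rep.fail(f"unreadable CSV: {e}")
        return rep
    missing = [c for c in cols if c not in df.columns]
    if missing:
        rep.fail(f"missing columns: {missing}")
        return rep
    time_col = {"trace": "time", "activity": "time_s", "traces": "time_s"}.get(schema_name)
    if time_col is not None:
        group = df.groupby("cell_id") if "cell_id" in cols else [(None, df)]
        for cid, g in group:
            t = g[time_col].to_numpy()
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                row = g.index[bad[0] + 1]
                rep.fail(f"non-monotone {time_col} at row {row}" + (f" (cell {cid})" if cid else ""))
                break
    return rep


@dataclass
class RunManifest:
    stage: str
    config: dict
    seed: Optional[int]
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stamp() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def run_stage(
    stage: str,
    func: Callable[[], list],
    config: dict,
    seed: Optional[int],
    inputs: list,
    out_dir,
) -> RunManifest:
    """Run one stage, hashing inputs and outputs into a manifest."""
    man = RunManifest(stage=stage, config=config, seed=seed, started=_stamp())
    for p in inputs:
        if not Path(p).exists():
            raise FileNotFoundError(f"stage {stage!r}: missing input {p}")
        man.inputs[str(p)] = file_digest(p)
    outputs = func()
    for p in outputs:
        man.outputs[str(p)] = file_digest(p)
    man.finished = _stamp()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"manifest_{stage}.json").write_text(man.to_json())
    return man


def run_pipeline(config: dict, out_dir) -> list[RunManifest]:
    """Chain synthetic -> FRET -> events -> summary stages end to end.

    ``config`` keys: ``stages`` (ordered subset of synth/fret/events),
    ``seed``, ``n_cells`` and optional per-stage overrides.  Sub-seeds are
    derived deterministically from the top-level seed.  A stage failure
    halts the pipeline, leaving manifests of completed stages behind.
    """
    from .fret import StimulusWindows, process_experiment
    from .switching import EventDetectionParams, analyze_trace
    from .synthetic import gen_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["synth", "fret", "events"])
    manifests = []

    paths = {
        "traces": out_dir / "traces.csv",
        "windows": out_dir / "windows.json",
        "truth": out_dir / "truth.json",
        "activity": out_dir / "activity.csv",
        "events": out_dir / "events.csv",
        "summary": out_dir / "cells.csv",
    }

    if "synth" in stages:
        def _synth():
            bundle = gen_cohort(
                int(config.get("n_cells", 10)),
                seed=seed,
                **config.get("synth", {}),
            )
            bundle["traces"].to_csv(paths["traces"], index=False)
            paths["windows"].write_text(json.dumps(bundle["windows"], indent=2))
            paths["truth"].write_text(json.dumps(bundle["truth"], indent=2, default=str))
            return [paths["traces"], paths["windows"], paths["truth"]]

        manifests.append(run_stage("synth", _synth, config, seed, [], out_dir))

    if "fret" in stages:
        def _fret():
            rep = validate(paths["traces"], "traces")
            if not rep.ok:
                raise ValueError(f"invalid traces input: {rep.messages}")
            traces = pd.read_csv(paths["traces"])
            win = StimulusWindows(**json.loads(paths["windows"].read_text()))
            act = process_experiment(traces, win)
            act.to_csv(paths["activity"], index=False)
            return [paths["activity"]]

        manifests.append(
            run_stage("fret", _fret, config, None, [paths["traces"], paths["windows"]], out_dir)
        )

    if "events" in stages:
        def _events():
            act = pd.read_csv(paths["activity"])
            win = StimulusWindows(**json.loads(paths["windows"].read_text()))
            det = EventDetectionParams(**config.get("detection", {}))
            ev_rows, sum_rows = [], []
            for cid, g in act.groupby("cell_id", sort=True):
                t = g["time_s"].to_numpy()
                buf = win.buffer_mask(t)
                summary, events = analyze_trace(
                    t, g["activity"].to_numpy(), det, cell_id=str(cid), buffer_mask=buf
                )
                for e in events:
                    ev_rows.append(
                        {
                            "cell_id": cid, "t_event_s": e.t_event, "direction": e.direction,
                            "amplitude": e.amplitude, "tau_s": e.tau, "residence_s": e.residence,
                        }
                    )
                sum_rows.append(vars(summary) | {"cell_id": cid})
            pd.DataFrame(
                ev_rows,
                columns=["cell_id", "t_event_s", "direction", "amplitude", "tau_s", "residence_s"],
            ).to_csv(paths["events"], index=False)
            pd.DataFrame(sum_rows).to_csv(paths["summary"], index=False)
            return [paths["events"], paths["summary"]]

        manifests.append(
            run_stage("events", _events, config, None, [paths["activity"], paths["windows"]], out_dir)
        )
    return manifests
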