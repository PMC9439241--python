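"""Plain-text I/O: RR CSVs, phase sidecars, cohort manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RRSeries
from .protocol import GETProtocol, Segment
from .synthetic import SubjectData


def write_rr_csv(rr: RRSeries, path) -> None:
    pd.DataFrame({"time_s": rr.t_s, "rr_ms": rr.rr_ms}).to_csv(path, index=False)


def write_phases_csv(protocol: GETProtocol, path) -> None:
    """One row per constant-power protocol segment (keeps the step structure)."""
    edges = protocol.boundaries_s
    rows = [{"phase": seg.phase, "start_s": edges[i], "end_s": edges[i + 1],
             "power_w": seg.power_w}
            for i, seg in enumerate(protocol.segments)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rr_csv(rr_path, phases_path) -> tuple[RRSeries, GETProtocol]:
    """Read a two-column RR CSV plus its phases sidecar.

    The sidecar gives (phase, start_s, end_s, power_w) spans; beats are
    labelled by the span containing their timestamp. The reconstructed
    protocol treats each span as one constant-power segment, which is
    enough for time-mode windowing and mean-power covariates of external
    recordings (simulated data keep their exact stepwise protocol).
    """
    rr_df = pd.read_csv(rr_path)
    ph_df = pd.read_csv(phases_path)
    segs = tuple(Segment(r["phase"], r["end_s"] - r["start_s"], r["power_w"])
                 for _, r in ph_df.iterrows())
    protocol = GETProtocol(segs)
    t = rr_df["time_s"].to_numpy(dtype=float)
    phases = np.asarray(protocol.phase_at(t))
    return RRSeries(t, rr_df["rr_ms"].to_numpy(dtype=float), phases), protocol


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_cohort(cohort: list[SubjectData], out_dir, seed=None) -> dict:
    """Write per-subject RR/phases/VO2 CSVs and a JSON manifest; return it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n_subjects": len(cohort), "subjects": []}
    for i, data in enumerate(cohort):
        rr_path = out / f"subject_{i:02d}_rr.csv"
        ph_path = out / f"subject_{i:02d}_phases.csv"
        vo2_path = out / f"subject_{i:02d}_vo2.csv"
        write_rr_csv(data.rr, rr_path)
        write_phases_csv(data.protocol, ph_path)
        pd.DataFrame({"time_s": data.vo2_t_s, "vo2_ml_kg_min": data.vo2}).to_csv(
            vo2_path, index=False)
        c, t = data.crf, data.truth
        manifest["subjects"].append({
            "id": i,
            "files": {"rr": rr_path.name, "phases": ph_path.name, "vo2": vo2_path.name},
            "checksums": {"rr": sha256_of(rr_path), "phases": sha256_of(ph_path),
                          "vo2": sha256_of(vo2_path)},
            "crf": {"vo2max": c.vo2max, "map_w": c.map_w, "pvt1_w": c.pvt1_w,
                    "pvt2_w": c.pvt2_w, "peak_hr": c.peak_hr, "hrr": c.hrr},
            "truth": {"rr_rest": t.rr_rest, "ode_gain": t.ode_gain,
                      "ode_tau": t.ode_tau, "vo2_tau": t.vo2_tau,
                      "b_true": t.b_true, "tau_true": t.tau_true,
                      "exhaustion_power": t.exhaustion_power},
            "n_beats": len(data.rr),
            "artifact_idx": {k: [int(j) for j in v]
                             for k, v in data.artifact_idx.items()},
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_cohort(in_dir) -> list[SubjectData]:
    """Reload a cohort written by :func:`write_cohort`."""
    from .protocol import make_protocol
    from .synthetic import CRFIndices, SubjectTruth

    root = Path(in_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cohort = []
    for sub in manifest["subjects"]:
        rr, _ = read_rr_csv(root / sub["files"]["rr"], root / sub["files"]["phases"])
        vo2_df = pd.read_csv(root / sub["files"]["vo2"])
        c = sub["crf"]
        crf = CRFIndices(vo2max=c["vo2max"], map_w=c["map_w"], pvt1_w=c["pvt1_w"],
                         pvt2_w=c["pvt2_w"], peak_hr=c["peak_hr"], hrr=c["hrr"])
        t = sub["truth"]
        truth = SubjectTruth(rr_rest=t["rr_rest"], ode_gain=t["ode_gain"],
                             ode_tau=t["ode_tau"], vo2_tau=t["vo2_tau"],
                             b_true=t["b_true"], tau_true=t["tau_true"],
                             crf=crf, exhaustion_power=t["exhaustion_power"])
        protocol = make_protocol(exhaustion_power_w=t["exhaustion_power"])
        cohort.append(SubjectData(
            rr, vo2_df["time_s"].to_numpy(), vo2_df["vo2_ml_kg_min"].to_numpy(),
            crf, truth, protocol, trend_ms=np.empty(0),
            artifact_idx={k: np.asarray(v, dtype=int)
                          for k, v in sub.get("artifact_idx", {}).items()},
        ))
    return cohort
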