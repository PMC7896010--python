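"""End-to-end orchestration: synthesize -> measure -> coherence -> conditioning
-> population statistics -> loop model, from one JSON-serializable run
configuration with a single master seed.

Every stage derives its own seed deterministically from the master seed via a
counter-based split (adding a stage never perturbs earlier stages), reads its
inputs only from files declared by earlier stages, and appends an ISO-stamped
line to the run log. Re-running with an identical configuration is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from renshaw._rng import child_seed
from renshaw.coherence import CoherenceConfig, binarize_train, coherence_spectrum, average_coherence, pooled_band_phase
from renshaw.errors import RenshawError
from renshaw.io import read_recording, write_recording
from renshaw.loop_model import ModelConfig, band_phase, model_coherence, simulate_loop
from renshaw.nonlinearity import conditioning_curve
from renshaw.popstats import (
    ConnectionRecord,
    benjamini_hochberg,
    bootstrap_ci,
    permutation_category_test,
    population_measures,
)
from renshaw.signal_prep import (
    classify_motoneuron,
    interpolate_stimulus_window,
    measure_ipsp,
    triggered_average,
)
from renshaw.synthetic import (
    IPSPKernel,
    NonlinearityConfig,
    RecordingConfig,
    TrainConfig,
    generate_poisson_train,
    synthesize_recording,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "master_seed": 1,
    "cohort": {
        "n_motoneurons": 6,
        "nerves": ["deep_radial", "median_arm"],
        "duration_s": 40.0,
        "mean_rate_hz": 10.0,
        "dead_time_s": 0.003,
        "detect_probability": 0.6,
        "amplitude_mean_uv": 250.0,
        "amplitude_sd_uv": 100.0,
        "noise_sd_uv": 100.0,
    },
    "measure": {"artifact_window_ms": [0.0, 3.0], "search_window_ms": [1.0, 50.0]},
    "coherence": {"window_len": 16384, "alpha": 0.05, "band_hz": [8.0, 12.0]},
    "conditioning": {"nerve": "deep_radial", "mode": "short", "min_triggers": 10},
    "stats": {"n_boot": 2000, "n_perm": 2000, "q": 0.05},
    "model": {"enabled": True, "duration_s": 30.0, "rise_ms": [1.0, 4.0, 8.0]},
}


def _log(log_path: Path, msg: str) -> None:
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    line = f"{stamp} {msg}"
    print(line)
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(line + "\n")


def _merged(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]


_ANTIDROMIC_CYCLE = [
    "deep_radial", "median_arm", "ulnar_arm", "radial_axilla", None, "median_wrist",
]


def _stage_synth(cfg: dict, out_dir: Path, log: Path) -> list[Path]:
    c = cfg["cohort"]
    seed0 = cfg["master_seed"]
    dirs: list[Path] = []
    rng = np.random.default_rng(child_seed(seed0, "synth", "cohort"))
    for i in range(c["n_motoneurons"]):
        kernels = {}
        for nerve in c["nerves"]:
            # first motoneuron always responds strongly (used by conditioning)
            if i == 0 or rng.random() < c["detect_probability"]:
                amp = max(60.0, rng.normal(c["amplitude_mean_uv"], c["amplitude_sd_uv"]))
                kernels[nerve] = IPSPKernel(amplitude_uv=float(amp))
        anti = _ANTIDROMIC_CYCLE[i % len(_ANTIDROMIC_CYCLE)]
        rec_cfg = RecordingConfig(
            kernels=kernels,
            noise_sd_uv=c["noise_sd_uv"],
            motoneuron_id=f"mn{i}",
            seed=child_seed(seed0, "synth", i),
        )
        trains = [
            generate_poisson_train(
                TrainConfig(
                    duration=c["duration_s"],
                    mean_rate=c["mean_rate_hz"],
                    dead_time=c["dead_time_s"],
                    seed=child_seed(seed0, "synth", i, nerve),
                ),
                nerve,
            )
            for nerve in c["nerves"]
        ]
        rec = synthesize_recording(rec_cfg, trains)
        rec.meta["antidromic_nerves"] = [anti] if anti else []
        d = write_recording(out_dir / "recordings" / f"mn{i}", rec)
        dirs.append(d)
    _log(log, f"synth: wrote {len(dirs)} recordings")
    return dirs


def _stage_measure(cfg: dict, rec_dirs: Sequence[Path], out_dir: Path, log: Path) -> Path:
    m = cfg["measure"]
    s0, s1 = (v * 1e-3 for v in m["search_window_ms"])
    rows = []
    for d in rec_dirs:
        rec = read_recording(d)
        category = classify_motoneuron(rec.meta.get("antidromic_nerves", []))
        for tr in rec.trains:
            # amplitude measurement runs on the raw trace: the search window
            # already clears the artifact; interpolation is for coherence
            avg = triggered_average(rec.intracellular, tr.times, rec.sample_rate)
            meas = measure_ipsp(avg, (s0, s1))
            measurable = tr.nerve_id not in rec.meta.get("antidromic_nerves", [])
            rows.append(
                {
                    "motoneuron_id": rec.meta.get("motoneuron_id", d.name),
                    "category": category,
                    "nerve": tr.nerve_id,
                    "amplitude_uv": meas.amplitude_uv if meas.detected else 0.0,
                    "onset_ms": meas.onset_latency * 1e3,
                    "peak_ms": meas.peak_latency * 1e3,
                    "detected": meas.detected,
                    "measurable": measurable,
                }
            )
    path = out_dir / "measurements.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _log(log, f"measure: {len(rows)} motoneuron-nerve pairs -> {path.name}")
    return path


def _stage_coherence(cfg: dict, rec_dirs: Sequence[Path], out_dir: Path, log: Path) -> Path:
    ccfg_d = cfg["coherence"]
    ccfg = CoherenceConfig(window_len=ccfg_d["window_len"], alpha=ccfg_d["alpha"])
    w0, w1 = (v * 1e-3 for v in cfg["measure"]["artifact_window_ms"])
    spectra = []
    for d in rec_dirs:
        rec = read_recording(d)
        for tr in rec.trains:
            clean = interpolate_stimulus_window(
                rec.intracellular, tr.times, (w0, w1), rec.sample_rate
            )
            x = binarize_train(tr, rec.sample_rate, len(clean))
            spectra.append(coherence_spectrum(x, clean, ccfg))
    avg = average_coherence(spectra)
    band = tuple(ccfg_d["band_hz"])
    try:
        mean_phase, counts, edges = pooled_band_phase(spectra, band)
    except RenshawError:
        mean_phase, counts, edges = float("nan"), None, None
    df = pd.DataFrame({"freq_hz": avg.freqs, "coh": avg.coh, "phase_rad": avg.phase})
    path = out_dir / "coherence_avg.csv"
    df.to_csv(path, index=False)
    header = {
        "n_pairs": len(spectra),
        "n_segments_total": avg.n_segments,
        "sig_level": avg.sig_level,
        "band_hz": list(band),
        "pooled_band_phase_rad": mean_phase,
    }
    (out_dir / "coherence_avg.json").write_text(json.dumps(header, indent=1), "utf-8")
    _log(log, f"coherence: {len(spectra)} pairs, pooled {band} Hz phase "
              f"{mean_phase:.3f} rad")
    return path


def _stage_conditioning(cfg: dict, rec_dirs: Sequence[Path], out_dir: Path, log: Path) -> Path:
    c = cfg["conditioning"]
    rec = read_recording(rec_dirs[0])
    axis_mode = "frequency" if c["mode"] == "long" else "interval"
    curve = conditioning_curve(
        rec, c["nerve"], axis_mode=axis_mode, min_triggers=c["min_triggers"]
    )
    path = out_dir / "conditioning_curve.csv"
    curve.to_frame().to_csv(path, index=False)
    _log(log, f"conditioning: {c['mode']} curve on {c['nerve']} "
              f"({curve.unconditioned_uv:.0f} µV unconditioned)")
    return path


def _stage_popstats(cfg: dict, measurements_csv: Path, out_dir: Path, log: Path) -> Path:
    s = cfg["stats"]
    seed0 = cfg["master_seed"]
    df = pd.read_csv(measurements_csv)
    records = [
        ConnectionRecord(
            motoneuron_id=str(r.motoneuron_id),
            category=str(r.category),
            nerve=str(r.nerve),
            amplitude_uv=float(r.amplitude_uv),
            detected=bool(r.detected),
            measurable=bool(r.measurable),
        )
        for r in df.itertuples()
    ]
    report: dict[str, Any] = {}
    for group_by in ("category", "nerve"):
        measures = population_measures(records, group_by)
        cis = {
            m: bootstrap_ci(records, group_by, m, s["n_boot"],
                            child_seed(seed0, "popstats", group_by, m))
            for m in ("amplitude", "incidence", "product")
        }
        groups = sorted(measures)
        pvals = [
            permutation_category_test(
                records, g, "product", s["n_perm"],
                child_seed(seed0, "popstats", group_by, g), group_by,
            )
            for g in groups
        ]
        accepted = benjamini_hochberg(pvals, s["q"])
        report[group_by] = {
            g: {
                "amplitude_uv": measures[g].amplitude_uv,
                "incidence_pct": measures[g].incidence_pct,
                "product_uv": measures[g].product_uv,
                "n_measurable": measures[g].n_measurable,
                "n_detected": measures[g].n_detected,
                "ci95": {m: cis[m][g] for m in cis},
                "p_perm": pvals[i],
                "accepted": bool(accepted[i]),
            }
            for i, g in enumerate(groups)
        }
    report["m_comparisons"] = {gb: len(report[gb]) for gb in ("category", "nerve")}
    path = out_dir / "popstats.json"
    path.write_text(json.dumps(report, indent=1), "utf-8")
    _log(log, f"popstats: groups category={len(report['category'])} "
              f"nerve={len(report['nerve'])}")
    return path


def _stage_model(cfg: dict, out_dir: Path, log: Path) -> Path | None:
    m = cfg["model"]
    if not m.get("enabled", True):
        return None
    seed0 = cfg["master_seed"]
    band = tuple(cfg["coherence"]["band_hz"])
    train = generate_poisson_train(
        TrainConfig(duration=m["duration_s"], seed=child_seed(seed0, "model", "train")),
        "motor",
    )
    out: dict[str, float] = {}
    for rise in m["rise_ms"]:
        mcfg = ModelConfig(
            epsp_rise_ms=rise,
            duration_s=m["duration_s"],
            seed=child_seed(seed0, "model", "sim"),
        )
        res = simulate_loop(mcfg, train)
        spec = model_coherence(res)
        out[f"band_phase_rad_rise_{rise:g}ms"] = band_phase(spec, band)
    path = out_dir / "model_phases.json"
    path.write_text(json.dumps(out, indent=1), "utf-8")
    _log(log, "model: " + ", ".join(f"{k}={v:.3f}" for k, v in out.items()))
    return path


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the run report.

    A stage failure aborts the run with the stage name attached to the error.
    """
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = out / "pipeline.log"
    chash = _config_hash(cfg)
    (out / "run_config.json").write_text(json.dumps(cfg, indent=1), "utf-8")
    _log(log, f"run start (config hash {chash})")
    report: dict[str, Any] = {"config_hash": chash, "master_seed": cfg["master_seed"]}
    stage = "synth"
    try:
        rec_dirs = _stage_synth(cfg, out, log)
        report["recordings"] = [str(d) for d in rec_dirs]
        stage = "measure"
        mpath = _stage_measure(cfg, rec_dirs, out, log)
        report["measurements"] = str(mpath)
        stage = "coherence"
        report["coherence"] = str(_stage_coherence(cfg, rec_dirs, out, log))
        stage = "conditioning"
        report["conditioning"] = str(_stage_conditioning(cfg, rec_dirs, out, log))
        stage = "popstats"
        report["popstats"] = str(_stage_popstats(cfg, mpath, out, log))
        stage = "model"
        model_path = _stage_model(cfg, out, log)
        if model_path:
            report["model"] = str(model_path)
    except Exception as exc:
        _log(log, f"run aborted in stage {stage!r}: {exc}")
        raise RenshawError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=1), "utf-8")
    _log(log, "run complete")
    return report
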