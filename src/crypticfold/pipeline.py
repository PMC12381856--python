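"""End-to-end orchestration from a single validated configuration.

A run executes, in order and only where inputs are configured:
global kinetic fitting of unfolding curves, Markov-state macrostate
assignment of an RMSD feature series, exposure-change detection between
two conformer ensembles, cryptic-APR analysis of an aggregation
profile, and mutation surface/hydrophobicity accounting.  Every run
writes a JSON manifest recording package version, seeds, input file
digests and every default that was applied, so each output number is
reproducible from the manifest alone.  Later stages can be fed directly
from files (e.g. a precomputed rASA profile), skipping earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cfio
from .apr import (
    classify_mutation_locations,
    flag_cryptic_aprs,
    overlap_exposed_aprs,
    parse_mutations,
    segment_aprs,
    surface_hydrophobicity_change,
)
from .fitting import global_fit
from .kinetics import barrier_at
from .msm import FeatureSeries, assign_macrostates, ck_test
from .sasa import exposure_change, frames_from_pdb, state_exposure_summary

log = logging.getLogger("crypticfold")

C0 = 273.15

STAGES = ("fit_unfolding", "msm", "exposure", "cryptic_apr", "mutations")

_DEFAULTS = {
    "fit_unfolding": {"constraint": "auto", "weights": "inverse_variance",
                      "n_starts": 20, "report_temps_C": [40.0, 60.0, 80.0]},
    "msm": {"lag_frames": 10, "n_micro": 50, "n_macro": 3,
            "min_traj_ns": 0.0, "ck_factors": [2, 3, 5], "reversible": False},
    "exposure": {"probe": 1.4, "points": 960, "threshold": 0.25,
                 "residue_range": None, "mode": "mean",
                 "max_sasa_table": None},
    "cryptic_apr": {"threshold": 0.25, "min_apr_len": 1, "min_hits": 2},
    "mutations": {"scales": ["kyte-doolittle", "eisenberg"], "threshold": 0.25},
}


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "crypticfold_out"
    stages: dict = field(default_factory=dict)
    defaults_applied: dict = field(default_factory=dict)


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _load_config_mapping(source):
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(source) -> PipelineConfig:
    """Validate a config mapping or file; raise ConfigError with the
    full collected error list on failure.

    Unknown stages, dangling file paths, out-of-range thresholds and
    non-integer seeds are all collected before raising.  Defaults are
    filled in and recorded for the manifest.
    """
    raw = _load_config_mapping(source)
    errors = []
    seed = raw.get("seed", 1)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append(f"seed must be an integer, got {seed!r}")
    out_dir = raw.get("output_dir", "crypticfold_out")
    stages = {}
    defaults_applied = {}
    for key in raw:
        if key not in ("seed", "output_dir") and key not in STAGES:
            errors.append(f"unknown section {key!r}")
    for stage in STAGES:
        if stage not in raw:
            continue
        conf = dict(raw[stage])
        applied = {}
        for dk, dv in _DEFAULTS[stage].items():
            if dk not in conf:
                conf[dk] = dv
                applied[dk] = dv
        for pk in ("datasets", "features", "native_pdb", "other_pdb",
                   "sequence_fasta", "profile", "native_rasa", "fasta",
                   "max_sasa_table"):
            if pk in conf and conf[pk] is not None:
                paths = conf[pk] if isinstance(conf[pk], list) else [conf[pk]]
                for p in paths:
                    if isinstance(p, str) and not Path(p).exists():
                        errors.append(f"{stage}.{pk}: file not found: {p}")
        for tk in ("threshold",):
            if tk in conf and conf[tk] is not None:
                if not (0.0 <= float(conf[tk]) <= 1.0):
                    errors.append(
                        f"{stage}.{tk}: value {conf[tk]} outside [0, 1]")
        stages[stage] = conf
        defaults_applied[stage] = applied
    if "fit_unfolding" in stages and not stages["fit_unfolding"].get("datasets"):
        errors.append("fit_unfolding.datasets: at least one curve file required")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(seed=seed, output_dir=out_dir, stages=stages,
                          defaults_applied=defaults_applied)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _load_exposed(spec) -> set:
    if isinstance(spec, (list, tuple, set)):
        return set(int(i) for i in spec)
    df = pd.read_csv(spec, comment="#")
    return set(df.iloc[:, 0].astype(int).tolist())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    A stage failure is recorded in the manifest (``status: failed``) and
    aborts downstream stages.  All outputs are deterministic for a fixed
    config: every random draw is seeded from ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "defaults_applied": config.defaults_applied,
        "inputs": {},
        "stages": {},
    }
    results = {}
    try:
        aborted = False
        for stage in STAGES:
            if stage not in config.stages:
                continue
            if aborted:
                manifest["stages"][stage] = {"status": "not_run"}
                continue
            conf = config.stages[stage]
            log.info("running stage %s", stage)
            try:
                res = _STAGE_RUNNERS[stage](conf, config, out, manifest, results)
                manifest["stages"][stage] = {"status": "completed", **res}
                results[stage] = res
            except Exception as exc:  # noqa: BLE001 - recorded, then stop
                log.error("stage %s failed: %s", stage, exc)
                manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
                aborted = True
    finally:
        log.removeHandler(handler)
        handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _record_inputs(manifest, paths):
    for p in paths:
        if isinstance(p, str) and Path(p).exists():
            manifest["inputs"][p] = _digest(p)


def _run_fit(conf, config, out, manifest, results):
    paths = conf["datasets"]
    _record_inputs(manifest, paths)
    curves = [cfio.read_curve(p) for p in paths]
    fit = global_fit(curves, constraint=conf["constraint"],
                     weights=conf["weights"], n_starts=conf["n_starts"],
                     seed=config.seed)
    cfio.fit_result_to_json(fit, out / "fit_result.json")
    temps = [t + C0 for t in conf["report_temps_C"]]
    report = barrier_at(fit.params, temps)
    cfio.barrier_report_to_frame(report).to_csv(out / "barriers.csv", index=False)
    return {"rss": fit.rss, "constraint_used": fit.constraint_used,
            "params": fit.params.as_dict(),
            "outputs": ["fit_result.json", "barriers.csv"]}


def _read_features(path) -> FeatureSeries:
    df = pd.read_csv(path, comment="#")
    trajs = [g["rmsd"].to_numpy(dtype=float)
             for _, g in df.groupby("traj_id", sort=True)]
    return FeatureSeries(trajs)


def write_features(series: FeatureSeries, path) -> None:
    rows = []
    for tid, t in enumerate(series.trajectories):
        for frame, v in enumerate(t):
            rows.append((tid, frame, v))
    pd.DataFrame(rows, columns=["traj_id", "frame", "rmsd"]).to_csv(
        path, index=False)


def _run_msm(conf, config, out, manifest, results):
    _record_inputs(manifest, [conf.get("features")])
    series = _read_features(conf["features"])
    if conf["min_traj_ns"]:
        series = series.filter_min_length(conf["min_traj_ns"])
    macro, micro, labels = assign_macrostates(
        series, n_micro=conf["n_micro"], n_macro=conf["n_macro"],
        lag=conf["lag_frames"], seed=config.seed,
        reversible=conf["reversible"])
    ck = ck_test(micro.assignments, conf["lag_frames"],
                 factors=conf["ck_factors"], n_states=micro.k)
    np.savetxt(out / "macro_transition_matrix.csv",
               macro.transition_matrix, delimiter=",")
    pd.DataFrame({
        "label": macro.labels,
        "population": macro.populations,
        "mean_rmsd_A": macro.mean_rmsd,
    }).to_csv(out / "macrostates.csv", index=False)
    frame_lab = np.concatenate(labels)
    pd.DataFrame({"frame": np.arange(frame_lab.size),
                  "macrostate": frame_lab}).to_csv(
        out / "frame_macrostates.csv", index=False)
    return {"populations": macro.populations.tolist(),
            "mean_rmsd": macro.mean_rmsd.tolist(),
            "ck_test": ck,
            "outputs": ["macro_transition_matrix.csv", "macrostates.csv",
                        "frame_macrostates.csv"]}


def _run_exposure(conf, config, out, manifest, results):
    _record_inputs(manifest, [conf["native_pdb"], conf["other_pdb"],
                              conf.get("sequence_fasta"),
                              conf.get("max_sasa_table")])
    native = frames_from_pdb(conf["native_pdb"])
    other = frames_from_pdb(conf["other_pdb"])
    if conf.get("sequence_fasta"):
        sequence = next(iter(cfio.read_fasta(conf["sequence_fasta"]).values()))
    else:
        _, rtypes = native[0].residues()
        sequence = "".join(rtypes)
    max_table = None
    if conf.get("max_sasa_table"):
        df = pd.read_csv(conf["max_sasa_table"], comment="#")
        max_table = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    profiles = {}
    for tag, frames in (("native", native), ("other", other)):
        mean_rasa, frac_exposed = state_exposure_summary(
            frames, sequence, max_table=max_table, probe=conf["probe"],
            n_sphere_points=conf["points"], threshold=conf["threshold"])
        profiles[tag] = frac_exposed if conf["mode"] == "fraction" else mean_rasa
        cfio.write_profile(mean_rasa, out / f"rasa_{tag}.csv", "mean_rasa")
    rng = conf.get("residue_range")
    res_idx, _ = native[0].residues()
    change = exposure_change(profiles["native"], profiles["other"],
                             threshold=conf["threshold"],
                             residue_index=res_idx)
    if rng:
        lo, hi = rng
        change.newly_exposed = {r for r in change.newly_exposed if lo <= r <= hi}
        change.newly_buried = {r for r in change.newly_buried if lo <= r <= hi}
    pd.DataFrame({"residue_index": sorted(change.newly_exposed)}).to_csv(
        out / "newly_exposed.csv", index=False)
    pd.DataFrame({"residue_index": sorted(change.newly_buried)}).to_csv(
        out / "newly_buried.csv", index=False)
    return {"n_newly_exposed": len(change.newly_exposed),
            "n_newly_buried": len(change.newly_buried),
            "outputs": ["rasa_native.csv", "rasa_other.csv",
                        "newly_exposed.csv", "newly_buried.csv"]}


def _run_cryptic_apr(conf, config, out, manifest, results):
    _record_inputs(manifest, [conf.get("profile"), conf.get("native_rasa")])
    profile = cfio.read_profile(conf["profile"], "score")
    exposed_spec = conf.get("exposed")
    if exposed_spec is None and "exposure" in results:
        exposed_spec = str(out / "newly_exposed.csv")
    exposed = _load_exposed(exposed_spec)
    segments = segment_aprs(profile, threshold=conf["threshold"],
                            min_length=conf["min_apr_len"])
    report = overlap_exposed_aprs(exposed, segments)
    if conf.get("native_rasa"):
        native_rasa = cfio.read_profile(conf["native_rasa"], "mean_rasa")
        report.cryptic_aprs = flag_cryptic_aprs(
            segments, exposed, native_rasa, min_hits=conf["min_hits"])
    (out / "overlap_report.json").write_text(
        json.dumps(report.as_dict(), indent=2) + "\n")
    pd.DataFrame([
        {"start": s.start, "end": s.end, "peak_score": s.peak_score,
         "mean_score": s.mean_score} for s in segments
    ]).to_csv(out / "apr_segments.csv", index=False)
    return {"n_segments": len(segments),
            "fraction_pct": report.fraction_pct,
            "n_cryptic": len(report.cryptic_aprs),
            "outputs": ["overlap_report.json", "apr_segments.csv"]}


def _run_mutations(conf, config, out, manifest, results):
    _record_inputs(manifest, [conf.get("fasta"), conf.get("rasa")])
    sequence = None
    if conf.get("fasta"):
        sequence = next(iter(cfio.read_fasta(conf["fasta"]).values()))
    muts = parse_mutations(conf["spec"], sequence)
    res = {"n_mutations": len(muts), "mutations": [str(m) for m in muts]}
    if conf.get("rasa"):
        rasa = cfio.read_profile(conf["rasa"], "mean_rasa")
        per, counts = classify_mutation_locations(
            muts, rasa, threshold=conf["threshold"])
        res["locations"] = per
        res["counts"] = counts
        if sequence is not None:
            res["hydrophobicity_change_pct"] = {
                sc: surface_hydrophobicity_change(
                    sequence, muts, rasa, scale=sc,
                    threshold=conf["threshold"])
                for sc in conf["scales"]
            }
    (out / "mutations.json").write_text(json.dumps(res, indent=2) + "\n")
    return {**{k: v for k, v in res.items() if k != "locations"},
            "outputs": ["mutations.json"]}


_STAGE_RUNNERS = {
    "fit_unfolding": _run_fit,
    "msm": _run_msm,
    "exposure": _run_exposure,
    "cryptic_apr": _run_cryptic_apr,
    "mutations": _run_mutations,
}
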