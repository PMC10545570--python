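"""Config-driven end-to-end run: simulate/ingest -> preprocess -> ANOVA ->
model fits and comparison (full and theta-restricted frequency ranges) ->
spectral battery, with every intermediate artifact written to disk and a
machine-readable JSON report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import (posthoc_bonferroni, rm_anova_validity_by_ctoa,
                    select_replication_ctoas, subset_cell_means)
from .compare import compare, per_participant_winners
from .io import dump_config, read_trials, write_trials
from .models import FrequencyBounds, fit_all
from .preprocess import FilterRules, preprocess
from .simulate import DesignConfig, EffectParams, NoiseParams, simulate_cohort
from .spectral import run_spectral_battery

log = logging.getLogger("denseior")

FREQ_PRESETS = {"full": FrequencyBounds.full, "theta": FrequencyBounds.theta}


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    effect: EffectParams = field(default_factory=EffectParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    filters: FilterRules = field(default_factory=FilterRules)
    input_csv: str | None = None   # None -> simulate
    freq_presets: tuple = ("full", "theta")
    n_perm: int = 10000
    seed: int = 1

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        presets = tuple(run.get("freq_presets", ("full", "theta")))
        unknown = [p for p in presets if p not in FREQ_PRESETS]
        if unknown:
            raise ValueError(f"unknown frequency presets: {unknown}")
        filters = {k: (None if v == "" else v)
                   for k, v in raw.get("filters", {}).items()}
        return cls(design=DesignConfig(**raw.get("design", {})),
                   effect=EffectParams(**raw.get("effect", {})),
                   noise=NoiseParams(**raw.get("noise", {})),
                   filters=FilterRules(**filters),
                   input_csv=run.get("input_csv") or None,
                   freq_presets=presets,
                   n_perm=int(run.get("n_perm", 10000)),
                   seed=int(run.get("seed", 1)))

    def to_toml(self, path) -> None:
        extra = {
            "filters": dataclasses.asdict(self.filters),
            "run": {"input_csv": self.input_csv or "",
                    "freq_presets": list(self.freq_presets),
                    "n_perm": self.n_perm, "seed": self.seed},
        }
        dump_config(self.design, self.effect, self.noise, path,
                    extra=extra)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.random.SeedSequence):
        return list(obj.entropy) if isinstance(obj.entropy, (list, tuple)) \
            else obj.entropy
    return obj


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def fit_and_compare(diff_course, fbounds: FrequencyBounds):
    """Grand-average fits of the five models, per-participant fits, the
    comparison table, and the winner tallies for one frequency preset."""
    t = diff_course.ctoa
    fits = fit_all(t, diff_course.diff, fbounds=fbounds)
    table = compare(fits)
    per_participant = {
        pid: fit_all(t, diff_course.per_participant_diff[i], fbounds=fbounds)
        for i, pid in enumerate(diff_course.participants)}
    tallies = per_participant_winners(per_participant)
    return fits, table, tallies


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the whole pipeline; returns the report dict (also written
    to ``outdir/report.json`` beside all stage artifacts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    report: dict = {"version": __version__, "seed": config.seed,
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    config.to_toml(outdir / "config.toml")

    t0 = time.time()
    if config.input_csv:
        trials = read_trials(config.input_csv)
        log.info("loaded %d trials from %s", len(trials), config.input_csv)
    else:
        trials = simulate_cohort(config.design, config.effect, config.noise,
                                 master_seed=config.seed)
        log.info("simulated %d trials (%d participants)", len(trials),
                 config.design.n_participants)
    write_trials(trials, outdir / "trials.csv")
    timings["data"] = time.time() - t0

    t0 = time.time()
    summaries, filter_log, cm, tcs, diff = preprocess(trials, config.filters)
    n_excl = sum(s.excluded for s in summaries)
    log.info("screening: %d/%d participants excluded; trial filter: %s",
             n_excl, len(summaries), filter_log)
    _write_json({"participants": summaries, "trial_filter": filter_log},
                outdir / "screening.json")
    ctoa_ms = np.rint(cm.ctoa * 1000).astype(int)
    pd.DataFrame({
        "ctoa_ms": ctoa_ms,
        "valid_mean": tcs["valid"].mean_z_rt,
        "valid_se_morey": tcs["valid"].within_subject_se,
        "invalid_mean": tcs["invalid"].mean_z_rt,
        "invalid_se_morey": tcs["invalid"].within_subject_se,
        "diff_mean": diff.diff, "diff_se": diff.se,
    }).to_csv(outdir / "timecourses.csv", index=False)
    per = pd.DataFrame(diff.per_participant_diff, columns=ctoa_ms,
                       index=diff.participants)
    per.rename_axis("participant_id").to_csv(
        outdir / "difference_per_participant.csv")
    timings["preprocess"] = time.time() - t0
    report["screening"] = {"n_participants": len(summaries),
                           "n_excluded": n_excl,
                           "trial_filter": filter_log}

    t0 = time.time()
    rep_ctoas = select_replication_ctoas(cm.ctoa)
    sub = subset_cell_means(cm, rep_ctoas)
    anova_rows = rm_anova_validity_by_ctoa(sub)
    posthoc_rows = posthoc_bonferroni(sub)
    pd.DataFrame([dataclasses.asdict(r) for r in anova_rows]).to_csv(
        outdir / "anova.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in posthoc_rows]).to_csv(
        outdir / "posthoc.csv", index=False)
    timings["anova"] = time.time() - t0
    report["replication_ctoas_ms"] = [round(c * 1000) for c in rep_ctoas]
    report["anova"] = anova_rows
    report["posthoc"] = posthoc_rows

    report["model_comparison"] = {}
    for preset in config.freq_presets:
        t0 = time.time()
        fb = FREQ_PRESETS[preset]()
        fits, table, tallies = fit_and_compare(diff, fb)
        table.to_csv(outdir / f"model_comparison_{preset}.csv", index=False)
        _write_json(tallies, outdir / f"winner_tally_{preset}.json")
        report["model_comparison"][preset] = {
            "frequency_bounds_hz": [fb.f_min, fb.f_max],
            "table": table.to_dict(orient="records"),
            "winner_tally": tallies,
            "f_at_lower_bound": {m: fr.f_at_lower_bound
                                 for m, fr in fits.items()
                                 if m in ("rhythmic", "hybrid")},
        }
        timings[f"fits_{preset}"] = time.time() - t0

    t0 = time.time()
    stacked_valid = cm.valid
    stacked_invalid = cm.invalid
    battery = run_spectral_battery(stacked_valid, stacked_invalid,
                                   diff.per_participant_diff, cm.ctoa,
                                   n_perm=config.n_perm, seed=config.seed)
    spec_report = {}
    rows = []
    for name, res in battery.items():
        spec_report[name] = {
            "threshold_95": res.threshold_95,
            "n_permutations": res.n_permutations,
            "significant_bins_hz": res.freqs[res.significant].tolist(),
        }
        for f, a, p in zip(res.freqs, res.amplitude, res.p):
            rows.append({"condition": name, "bin_hz": f, "amplitude": a,
                         "p": p})
    pd.DataFrame(rows).to_csv(outdir / "spectra.csv", index=False)
    _write_json(spec_report, outdir / "spectra.json")
    timings["spectral"] = time.time() - t0
    report["spectral"] = spec_report

    timings["total"] = time.time() - t_start
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    _write_json(report, outdir / "report.json")
    log.info("pipeline finished in %.1f s", timings["total"])
    return _jsonable(report)
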