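"""Before/after session comparison, group summaries and the pipeline driver.

The inferential statistics here are deliberately thin wrappers around
scipy (a routine paired Wilcoxon signed-rank test); the substance of the
package is the measurement pipeline, not the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__, imaging, quantal, stdp, synthetic
from .errors import ParameterError, ValidationError
from .imaging import OdiResult

#: metrics summarized across sessions by :func:`summarize_group`
METRICS = ("odi", "amp_contra", "amp_ipsi")

MIN_N_FOR_P = 5  # below this the paired rank test is omitted


@dataclass(frozen=True)
class SessionResult:
    """Before/after contrast for one animal."""

    label: str
    before: OdiResult
    after: OdiResult
    delta_odi: float
    delta_amp_contra: float
    delta_amp_ipsi: float


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- s.e.m. per metric, with a routine paired rank-test p-value."""

    n: int
    metrics: dict  # metric -> {mean_before, mean_after, sem_before, sem_after, p_value}
    test_name: str = "wilcoxon_signed_rank (routine)"


def compare_sessions(
    before: OdiResult, after: OdiResult, label: str = ""
) -> SessionResult:
    """Deltas (after - before) of ODI and per-eye ROI amplitudes.

    The ROI is derived independently per session (sessions are imaged on
    separate days); only the analysis settings must match.
    """
    if before.threshold_fraction != after.threshold_fraction:
        raise ValidationError(
            "sessions analyzed with different ROI threshold fractions: "
            f"{before.threshold_fraction} vs {after.threshold_fraction}"
        )
    if len(before.bin_edges) != len(after.bin_edges):
        raise ValidationError("sessions analyzed with different histogram binning")
    return SessionResult(
        label=label,
        before=before,
        after=after,
        delta_odi=after.odi - before.odi,
        delta_amp_contra=after.amp_contra - before.amp_contra,
        delta_amp_ipsi=after.amp_ipsi - before.amp_ipsi,
    )


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def summarize_group(sessions: list[SessionResult]) -> GroupSummary:
    """Per-metric group means and s.e.m. over sessions, with paired p-values."""
    if not sessions:
        raise ParameterError("summarize_group requires at least one session")
    out = {}
    for metric in METRICS:
        b = np.array([getattr(s.before, metric) for s in sessions])
        a = np.array([getattr(s.after, metric) for s in sessions])
        entry = {
            "mean_before": float(b.mean()),
            "mean_after": float(a.mean()),
            "sem_before": _sem(b),
            "sem_after": _sem(a),
            "p_value": None,
        }
        if len(sessions) >= MIN_N_FOR_P and np.any(a != b):
            entry["p_value"] = float(stats.wilcoxon(b, a).pvalue)
        out[metric] = entry
    return GroupSummary(n=len(sessions), metrics=out)


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 1,
    "imaging": {
        "n_animals": 3,
        "odi_before": 0.30,
        "odi_after": 0.10,
        "shape": [48, 48],
        "radius": 16,
        "duration_s": 100.0,
        "frame_rate_hz": 10.0,
        "stim_freq_hz": 0.12,
        "noise_sd": 1e-3,
        "roi_fraction": 0.3,
        "sigma_px": 1.0,
        "n_bins": 50,
    },
    "quantal": {
        "n_cells": 3,
        "n_sweeps": 30,
        "spont_rate": 1.0,
        "evoked_rate": 7.0,
        "spont_amp_mean": 12.0,
        "evoked_amp_mean": 18.0,
        "noise_rms": 2.0,
    },
    "stdp": {
        "baseline_slope": 2.0,
        "post_ratios": [0.6, 1.0, 1.235],
        "slope_noise_frac": 0.05,
    },
}


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Simulate -> analyze -> report, end to end and deterministically.

    Writes ``sessions.csv``, ``group_summary.json``, ``odi_histograms.csv``,
    ``quantal.csv``, ``stdp.csv`` and ``run_log.txt`` under ``out_dir`` and
    returns the paths.  Reruns with an identical config are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    written: dict[str, Path] = {}

    # ---- imaging branch
    icfg = config.get("imaging")
    if icfg:
        rows, hist_rows, results = [], [], []
        for animal in range(int(icfg.get("n_animals", 1))):
            odis = {}
            for stage in ("before", "after"):
                truth = synthetic.ImagingTruth.from_odi(
                    float(icfg[f"odi_{stage}"]),
                    shape=tuple(icfg.get("shape", (48, 48))),
                    radius=float(icfg.get("radius", 16)),
                    noise_sd=float(icfg.get("noise_sd", 1e-3)),
                    seed=seed * 10_000 + animal * 10 + (0 if stage == "before" else 1),
                )
                stacks = synthetic.gen_session(
                    truth,
                    duration=float(icfg.get("duration_s", 100.0)),
                    frame_rate=float(icfg.get("frame_rate_hz", 10.0)),
                    stim_freq=float(icfg.get("stim_freq_hz", 0.12)),
                )
                analysis = imaging.analyze_session(
                    stacks.values(),
                    threshold_fraction=float(icfg.get("roi_fraction", 0.3)),
                    sigma=float(icfg.get("sigma_px", 1.0)),
                    n_bins=int(icfg.get("n_bins", 50)),
                )
                odis[stage] = analysis.odi_result
                centers = 0.5 * (
                    analysis.odi_result.bin_edges[:-1]
                    + analysis.odi_result.bin_edges[1:]
                )
                for c, n in zip(centers, analysis.odi_result.counts):
                    hist_rows.append(
                        {
                            "animal": animal,
                            "stage": stage,
                            "bin_center": c,
                            "count": int(n),
                        }
                    )
            sr = compare_sessions(odis["before"], odis["after"], label=f"animal{animal}")
            results.append(sr)
            rows.append(
                {
                    "label": sr.label,
                    "odi_before": sr.before.odi,
                    "odi_after": sr.after.odi,
                    "delta_odi": sr.delta_odi,
                    "amp_contra_before": sr.before.amp_contra,
                    "amp_contra_after": sr.after.amp_contra,
                    "delta_amp_contra": sr.delta_amp_contra,
                    "amp_ipsi_before": sr.before.amp_ipsi,
                    "amp_ipsi_after": sr.after.amp_ipsi,
                    "delta_amp_ipsi": sr.delta_amp_ipsi,
                    "n_pixels_before": sr.before.n_pixels,
                    "n_pixels_after": sr.after.n_pixels,
                    "roi_fraction": sr.before.threshold_fraction,
                }
            )
        written["sessions"] = out_dir / "sessions.csv"
        pd.DataFrame(rows).to_csv(written["sessions"], index=False)
        written["odi_histograms"] = out_dir / "odi_histograms.csv"
        pd.DataFrame(hist_rows).to_csv(written["odi_histograms"], index=False)
        summary = summarize_group(results)
        written["group_summary"] = out_dir / "group_summary.json"
        _json_dump(
            {"n": summary.n, "test": summary.test_name, "metrics": summary.metrics},
            written["group_summary"],
        )

    # ---- quantal branch
    qcfg = config.get("quantal")
    if qcfg:
        qrows = []
        for cell in range(int(qcfg.get("n_cells", 1))):
            truth = synthetic.EphysTruth(
                spont_rate=float(qcfg.get("spont_rate", 1.0)),
                evoked_rate=float(qcfg.get("evoked_rate", 7.0)),
                spont_amp_mean=float(qcfg.get("spont_amp_mean", 12.0)),
                evoked_amp_mean=float(qcfg.get("evoked_amp_mean", 18.0)),
                noise_rms=float(qcfg.get("noise_rms", 2.0)),
                seed=seed * 10_000 + 500 + cell,
            )
            sweeps, truth = synthetic.gen_sr_sweeps(
                int(qcfg.get("n_sweeps", 30)), truth
            )
            est = quantal.analyze_cell(sweeps)
            qrows.append(
                {
                    "cell": cell,
                    "rms_noise": est.rms_noise,
                    "pre_amp": est.pre_amp,
                    "pre_freq": est.pre_freq,
                    "post_amp": est.post_amp,
                    "post_freq": est.post_freq,
                    "evoked_amp": est.evoked_amp,
                    "included": est.included,
                    "exclusion_reason": est.exclusion_reason,
                    "true_corrected_amp": truth.true_corrected_amp,
                }
            )
        written["quantal"] = out_dir / "quantal.csv"
        pd.DataFrame(qrows).to_csv(written["quantal"], index=False)

    # ---- stdp branch
    scfg = config.get("stdp")
    if scfg:
        srows = []
        for i, ratio in enumerate(scfg.get("post_ratios", [1.0])):
            sweeps = synthetic.gen_stdp_sweeps(
                baseline_slope=float(scfg.get("baseline_slope", 2.0)),
                post_ratio=float(ratio),
                slope_noise_frac=float(scfg.get("slope_noise_frac", 0.0)),
                seed=seed * 10_000 + 900 + i,
            )
            _, pres = stdp.analyze_plasticity(sweeps)
            srows.append(
                {
                    "post_ratio": ratio,
                    "baseline_slope": pres.baseline_mean,
                    "final_percent": pres.final_percent,
                    "n_endpoint": pres.n_endpoint,
                }
            )
        written["stdp"] = out_dir / "stdp.csv"
        pd.DataFrame(srows).to_csv(written["stdp"], index=False)

    # ---- run log (no timestamps: reruns must be byte-identical)
    log = out_dir / "run_log.txt"
    log.write_text(
        "odmap pipeline run\n"
        f"version: {__version__}\n"
        f"config: {json.dumps(config, sort_keys=True)}\n"
        f"outputs: {sorted(p.name for p in written.values())}\n"
    )
    written["log"] = log
    return written
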