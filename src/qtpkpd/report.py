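"""Pipeline orchestration: simulate -> fit -> risk -> interspecies comparison.

``run_pipeline`` executes the full analysis for a set of species x compound
studies from a single YAML-able config and returns a comparison report (the
per-species posterior summary rows, risk curve, Cp50 and safety margin,
plus provenance: seeds and generating parameters).  Every number in the
report is derived from stored posterior draws, so rows can be regenerated.

Safety margins are computed against a single reference Cmax — by convention
the human peak concentration — so the preclinical margins are expressed
relative to clinically attained exposure.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, risk as risk_mod
from .datasets import StudyDataset
from .params import StudyPreset, load_preset
from .pk import balance_phases, time_of_peak
from .simulate import generate_from_preset

__all__ = ["run_pipeline", "compare_species", "load_config"]

log = logging.getLogger("qtpkpd")


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _study_seed(base_seed: int, index: int) -> int:
    return (int(base_seed) * 131 + 17 * index + 1) % (2 ** 31)


def _analyse_study(name: str, preset: StudyPreset, ds: StudyDataset, cfg: bayes.ModelConfig,
                   threshold_ms: float, out_dir: Path | None) -> dict:
    fit_ = bayes.fit(ds, cfg)
    if not fit_.converged:
        log.warning("%s: fit flagged non-converged (R-hat >= 1.1)", name)
    summary = bayes.posterior_summary(fit_)
    diag = bayes.diagnostics(fit_)
    curve = risk_mod.risk_curve(fit_.slope_draws(), threshold_ms=threshold_ms)
    row = {
        "species": preset.species,
        "compound": preset.compound,
        "n_subjects": ds.n_subjects,
        "n_records": len(ds.df),
        "converged": fit_.converged,
        "cp50_nM": curve.cp50_nM,
        "summary": {p: {"median": r["median"], "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"], "unit": r["unit"]}
                    for p, r in summary.iterrows()},
        "cmax_ref_nM": preset.cmax_ref_nM,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        ds.to_csv(out_dir / f"{name}_dataset.csv")
        fit_.draws_to_csv(out_dir / f"{name}_draws.csv")
        diag.to_csv(out_dir / f"{name}_diagnostics.csv")
        summary.to_csv(out_dir / f"{name}_summary.csv")
        pd.DataFrame({"conc_nM": curve.conc_grid_nM, "prob": curve.prob}).to_csv(
            out_dir / f"{name}_risk_curve.csv", index=False)
    return row, fit_, curve


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the full simulate -> fit -> risk pipeline for each configured study.

    ``config`` keys: ``studies`` (list of preset names, preset YAML paths, or
    ``{name, data}`` entries pointing at a user CSV), ``seed``, ``model``
    (MCMC settings), ``risk`` (``threshold_ms``, ``cmax_ref`` = species name
    or nM value).  Fully reproducible given the seed.
    """
    studies = config.get("studies")
    if not studies:
        raise ValueError("config must name at least one study preset")
    seed = int(config.get("seed", 0))
    model_cfg = dict(config.get("model", {}))
    risk_cfg = dict(config.get("risk", {}))
    threshold = float(risk_cfg.get("threshold_ms", 10.0))
    out_path = Path(out_dir) if out_dir is not None else None

    rows, fits, curves, presets, datasets = {}, {}, {}, {}, {}
    for idx, entry in enumerate(studies):
        if isinstance(entry, dict):
            name, data = entry["name"], entry.get("data")
        else:
            name, data = entry, None
        preset = load_preset(name)
        presets[name] = preset
        study_seed = _study_seed(seed, idx)
        if data:
            ds = StudyDataset.read_csv(data)
            log.info("%s: loaded %d records from %s", name, len(ds.df), data)
        else:
            ds = generate_from_preset(preset, study_seed)
            log.info("%s: simulated %d records (seed %d)", name, len(ds.df), study_seed)
        if preset.design.balance_n_per_phase:
            tmax = time_of_peak(preset.pk)
            before = len(ds.df)
            ds = StudyDataset(
                balance_phases(ds.df, tmax, preset.design.balance_n_per_phase), dict(ds.meta))
            log.info("%s: balanced %d -> %d records (tmax %.2f h)",
                     name, before, len(ds.df), tmax)
        cfg = bayes.ModelConfig(seed=study_seed, **model_cfg)
        try:
            row, fit_, curve = _analyse_study(name, preset, ds, cfg, threshold, out_path)
        except Exception as exc:  # stage-tagged failure
            raise RuntimeError(f"pipeline stage 'fit/risk' failed for study {name!r}: {exc}") from exc
        rows[name], fits[name], curves[name], datasets[name] = row, fit_, curve, ds

    # reference Cmax: a species name (default human) or an explicit nM value
    cmax_ref_spec = risk_cfg.get("cmax_ref", "human")
    if isinstance(cmax_ref_spec, (int, float)):
        cmax_ref, cmax_species = float(cmax_ref_spec), "explicit"
    else:
        cands = [p for p in presets.values() if p.species == cmax_ref_spec
                 and p.cmax_ref_nM]
        if cands:
            cmax_ref, cmax_species = float(cands[0].cmax_ref_nM), cmax_ref_spec
        else:
            cmax_ref, cmax_species = None, cmax_ref_spec
    for name, row in rows.items():
        if cmax_ref and row["cp50_nM"]:
            row["margin"] = risk_mod.safety_margin(row["cp50_nM"], cmax_ref,
                                                   cmax_species).margin
        else:
            row["margin"] = None

    report = {
        "global": {"seed": seed, "threshold_ms": threshold,
                   "cmax_ref_nM": cmax_ref, "cmax_species": cmax_species,
                   "model": model_cfg},
        "studies": rows,
    }
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "report.json").write_text(json.dumps(report, indent=1, default=_jsonable))
        _plot_risk_curves(curves, threshold, out_path / "risk_curves.png")
        _plot_gof(fits, datasets, out_path / "goodness_of_fit.png")
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def compare_species(report: dict) -> pd.DataFrame:
    """Interspecies comparison table, sorted by Cp50 descending.

    Includes each study's posterior median slope, its ratio to the human
    slope (where a human study is present) and the safety margin.
    """
    rows = []
    for name, r in report["studies"].items():
        rows.append({
            "study": name, "species": r["species"], "compound": r["compound"],
            "slope_ms_per_nM": r["summary"]["slope"]["median"],
            "cp50_nM": r["cp50_nM"], "margin": r["margin"],
            "converged": r["converged"],
        })
    if len(rows) < 2:
        raise ValueError("comparison requires >= 2 studies")
    df = pd.DataFrame(rows)
    human = df[df["species"] == "human"]
    ref_slope = float(human["slope_ms_per_nM"].iloc[0]) if len(human) else np.nan
    df["slope_ratio_vs_human"] = df["slope_ms_per_nM"] / ref_slope
    return df.sort_values("cp50_nM", ascending=False, na_position="last").reset_index(drop=True)


# --------------------------------------------------------------------------- figures

def _plot_risk_curves(curves: dict, threshold: float, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.semilogx(curve.conc_grid_nM, curve.prob, label=name)
        if curve.cp50_nM:
            ax.axvline(curve.cp50_nM, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("concentration [nM]")
    ax.set_ylabel(f"P(QT prolongation >= {threshold:g} ms)")
    ax.axhline(0.5, ls="--", lw=0.8, color="k")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def predicted_qt(fit_, ds: StudyDataset) -> np.ndarray:
    """Individual-prediction of each record's QT from per-subject posterior
    medians (goodness-of-fit diagnostic)."""
    med = np.median(fit_.subject_draws, axis=(0, 1))  # (S, 5): qtc0, alpha, amp, phase, slope
    index = {s: k for k, s in enumerate(fit_.subject_ids)}
    g = np.array([index[s] for s in ds.df["ID"]])
    rr_s = ds.df["RR"].to_numpy(float) / 1000.0
    clock = ds.clock_time_h()
    w = 2.0 * np.pi / 24.0
    return (med[g, 0] * rr_s ** med[g, 1]
            + med[g, 2] * np.cos(w * (clock - med[g, 3]))
            + med[g, 4] * ds.df["CONC"].to_numpy(float))


def _plot_gof(fits: dict, datasets: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = max(len(fits), 1)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (name, fit_) in zip(axes[0], fits.items()):
        ds = datasets[name]
        obs = ds.df["QT"].to_numpy(float)
        pred = predicted_qt(fit_, ds)
        ax.scatter(obs, pred, s=6, alpha=0.5)
        lims = [min(obs.min(), pred.min()) * 0.97, max(obs.max(), pred.max()) * 1.03]
        ax.plot(lims, lims, "k-", lw=0.8)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("observed QT [ms]")
        ax.set_ylabel("individual predicted QT [ms]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
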