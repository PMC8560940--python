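"""End-to-end orchestration: simulate, quantify subjects, report statistics.

The functions here glue the I/O, quantification, synthesis and statistics
modules into reproducible runs.  Every output directory receives the exact
configuration and seeds needed to regenerate it (``run_config.yaml`` +
``run.log``), so a rerun with the same inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from . import quant, stats, synthetic

__all__ = ["RunConfig", "quantify_subject", "run_subject", "run_cohort", "simulate"]

DEFAULT_CODE_BOOK = synthetic.DEFAULT_CODE_BOOK


@dataclass(frozen=True)
class RunConfig:
    """Run-wide knobs, echoed verbatim into every output directory."""

    code_book: dict = field(default_factory=lambda: dict(DEFAULT_CODE_BOOK))
    signal_floor: float = 0.0
    erosion_radius: int = 0
    quantile_rule: str = "linear"
    alpha: float = 0.05
    seed: int = 0

    def echo(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        (out_dir / "run_config.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))


def quantify_subject(
    study: gio.DixonStudy,
    label_map: gio.LabelMap,
    landmarks: gio.LandmarkSet,
    metadata: dict,
    config: Optional[RunConfig] = None,
) -> quant.SubjectRecord:
    """Measure both GMAX sides of one subject from in-memory volumes."""
    config = config or RunConfig()
    ff_map = quant.compute_ff_map(study, signal_floor=config.signal_floor)
    metrics = {}
    for side in ("left", "right"):
        bulk = quant.extract_bulk(label_map, landmarks, side)
        code = label_map.code_for_side(side)
        metrics[side] = quant.muscle_metrics(
            ff_map, bulk, code, erosion_radius=config.erosion_radius
        )
    anthro = quant.Anthropometrics(
        sex=str(metadata["sex"]),
        weight_kg=float(metadata["weight_kg"]),
        height_cm=float(metadata["height_cm"]),
    )
    return quant.summarize_subject(metrics["left"], metrics["right"], anthro, metadata)


def run_subject(
    subject_dir,
    metadata: dict,
    out_dir=None,
    config: Optional[RunConfig] = None,
) -> quant.SubjectRecord:
    """Quantify one on-disk subject (water/fat/label NIfTI + landmarks JSON)."""
    config = config or RunConfig()
    subject_dir = Path(subject_dir)
    sid = metadata.get("subject_id", subject_dir.name)
    try:
        study = gio.read_dixon_study(
            subject_dir / "water.nii.gz", subject_dir / "fat.nii.gz", subject_id=sid
        )
        label_map = gio.read_label_map(
            subject_dir / "label.nii.gz", study.geometry, config.code_book
        )
        landmarks = gio.read_landmarks(subject_dir / "landmarks.json", study.geometry)
    except (OSError, ValueError) as exc:
        raise type(exc)(f"subject {sid}: {exc}") from exc
    record = quantify_subject(study, label_map, landmarks, metadata, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(record.to_side_rows()).to_csv(
            out_dir / f"{sid}_metrics.csv", index=False
        )
    return record


def _stats_report(
    table: pd.DataFrame, config: RunConfig, out_dir: Path, log: list[str]
) -> dict:
    """Descriptives, group tests, regressions and logistic models on a table."""
    out: dict = {}
    subj = stats.subject_level(table)
    groups_present = list(dict.fromkeys(subj["group"]))

    out["descriptives_ff"] = stats.descriptive_table(
        subj, "ff_pct", quantile_rule=config.quantile_rule
    )
    for gname, sub in subj.groupby("group"):
        if 3 <= len(sub) <= 5000:
            res = stats.normality_gate(sub["ff_pct"], name=f"ff:{gname}")
            log.append(f"{res.name}: W={res.statistic:.4f} p={res.p_value:.4f}")

    omnibus_rows = []
    posthoc_rows = []
    if len(groups_present) >= 2:
        for metric in ("ff_pct", "normalized_volume", "normalized_lean_volume"):
            if metric not in subj:
                continue
            vecs = [sub[metric].to_numpy() for _, sub in subj.groupby("group", sort=False)]
            names = [g for g, _ in subj.groupby("group", sort=False)]
            kw = stats.kruskal_wallis(vecs)
            omnibus_rows.append(
                {"metric": metric, "H": kw.statistic, "p_value": kw.p_value, "n": kw.n}
            )
            for res in stats.posthoc_pairwise(vecs, names):
                posthoc_rows.append(
                    {
                        "metric": metric,
                        "pair": res.name,
                        "p_adj": res.p_value,
                        "mean_diff": res.effect,
                    }
                )
    else:
        log.append("only one group present: omnibus tests skipped")
    out["omnibus"] = pd.DataFrame(omnibus_rows)
    out["posthoc"] = pd.DataFrame(posthoc_rows)

    # left/right pairing per group (side-level table required)
    pair_rows = []
    if "side" in table.columns:
        wide = table.pivot_table(
            index=["subject_id", "group"], columns="side", values="ff_pct"
        ).reset_index()
        if {"left", "right"} <= set(wide.columns):
            strata = [(g, sub) for g, sub in wide.groupby("group", sort=False)]
            healthy = wide[wide["group"] != "Pain"]
            if len(healthy) and "Pain" in set(wide["group"]):
                strata.append(("All healthy", healthy))
            for gname, sub in strata:
                if len(sub) < 2:
                    continue
                res = stats.wilcoxon_paired(sub["left"], sub["right"])
                pair_rows.append(
                    {
                        "group": gname,
                        "n": len(sub),
                        "median_diff_left_minus_right": res.effect,
                        "p_value": res.p_value,
                    }
                )
    out["side_pairing"] = pd.DataFrame(pair_rows)

    healthy_subj = subj[subj["group"] != "Pain"]
    if len(healthy_subj) >= 4:
        thr, flags = stats.outlier_flags(
            healthy_subj["ff_pct"], quantile_rule=config.quantile_rule
        )
        out["outliers"] = pd.DataFrame(
            {
                "subject_id": healthy_subj["subject_id"],
                "ff_pct": healthy_subj["ff_pct"],
                "outlier": flags,
            }
        )
        log.append(f"healthy FF outlier threshold (Q3+1.5*IQR): {thr:.1f}%")

    if "side" in table.columns and len(groups_present) >= 2:
        fit = stats.hierarchical_linear_regression(table, alpha=config.alpha)
        out["hierarchical_fit"] = fit.to_frame()
        out["hierarchical_final"] = fit.final_coefficients.reset_index(names="term")
        log.append(f"hierarchical final model: {fit.final_formula} (R2={fit.r2_final:.3f})")

    for outcome in ("active_vs_not", "pain_vs_healthy"):
        wanted = {"Pain", "Low"} if outcome == "active_vs_not" else {"Pain"}
        if not wanted <= set(groups_present):
            continue
        try:
            lfit = stats.logistic_model(table, outcome=outcome)
        except ValueError as exc:
            log.append(f"logistic {outcome} skipped: {exc}")
            continue
        out[f"logistic_{outcome}"] = lfit.table.reset_index(names="predictor")
        log.append(f"logistic {outcome}: n={lfit.n} converged={lfit.converged}")

    for name, frame in out.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    return out


def run_cohort(
    cohort_dir,
    out_dir,
    config: Optional[RunConfig] = None,
    table: Optional[pd.DataFrame] = None,
    skip_failures: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Quantify every subject under ``cohort_dir`` and run the full report.

    Alternatively pass ``table`` (a side-level cohort table) to run the
    statistics only.  Returns the cohort table and the dict of report frames.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"alpha={config.alpha} seed={config.seed}"]

    if table is None:
        cohort_dir = Path(cohort_dir)
        meta = gio.read_metadata_table(cohort_dir / "metadata.csv")
        rows = []
        for _, m in meta.iterrows():
            sdir = cohort_dir / str(m["subject_id"])
            try:
                record = run_subject(sdir, m.to_dict(), config=config)
            except Exception as exc:
                if skip_failures:
                    log.append(f"SKIPPED subject {m['subject_id']}: {exc}")
                    continue
                raise
            rows.extend(record.to_side_rows())
            log.append(
                f"subject {record.subject_id}: bulk slices "
                f"L={record.left.bulk_slice_range} R={record.right.bulk_slice_range}, "
                f"undefined L={record.left.undefined_count} R={record.right.undefined_count}"
            )
        table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no subjects quantified")
    table.to_csv(out_dir / "cohort_table.csv", index=False)
    report = _stats_report(table, config, out_dir, log)
    config.echo(out_dir)
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return table, report


def simulate(
    out_dir,
    cohort_spec: Optional[synthetic.CohortSpec] = None,
    phantom_template: Optional[synthetic.PhantomSpec] = None,
    imaging: bool = True,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Write a synthetic cohort (tables, and phantoms when ``imaging``) to disk."""
    config = config or RunConfig()
    cohort_spec = cohort_spec or synthetic.CohortSpec(seed=config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if not imaging:
        table, truth = synthetic.generate_cohort_table(cohort_spec)
        table.to_csv(out_dir / "cohort_table.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
        config.echo(out_dir)
        return table

    bundles, table, truth = synthetic.generate_imaging_cohort(
        cohort_spec, phantom_template
    )
    meta_rows = []
    truth_rows = []
    for b in bundles:
        sdir = out_dir / b.subject_id
        # float32 is ample for magnitude channels and halves the files
        gio.write_volume(
            b.study.water.astype(np.float32), b.study.geometry, sdir / "water.nii.gz"
        )
        gio.write_volume(
            b.study.fat.astype(np.float32), b.study.geometry, sdir / "fat.nii.gz"
        )
        gio.write_volume(
            b.label_map.labels.astype(np.int16), b.study.geometry, sdir / "label.nii.gz"
        )
        lm = b.landmarks
        (sdir / "landmarks.json").write_text(
            json.dumps(
                {
                    "convention": "voxel",
                    "left": {"LT_tip": list(lm.left.lt_tip), "ASIS": list(lm.left.asis)},
                    "right": {
                        "LT_tip": list(lm.right.lt_tip),
                        "ASIS": list(lm.right.asis),
                    },
                }
            )
        )
        meta_rows.append({**b.metadata})
        for side in ("left", "right"):
            t = getattr(b.truth, side)
            truth_rows.append(
                {
                    "subject_id": b.subject_id,
                    "side": side,
                    "true_mean_ff_pct": 100.0 * t.true_mean_ff,
                    "true_voxel_count": t.voxel_count,
                    "true_volume_ml": t.volume_ml,
                    "seed": b.truth.seed,
                }
            )
    meta = pd.DataFrame(meta_rows)
    for col in gio.METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    meta[gio.METADATA_COLUMNS].to_csv(out_dir / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    table.to_csv(out_dir / "cohort_table_truth.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    config.echo(out_dir)
    return table
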