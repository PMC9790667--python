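"""End-to-end orchestration: detect -> SPA -> statistics -> report.

The pipeline consumes either a manifest of EDF files with sidecar CSVs or an
in-memory synthetic cohort, and produces the per-subject SPA table, the
15-index group-comparison report, the logistic-selection / ROC / cut-off
report and run metadata. Every number in the human-readable report is taken
from the machine-readable result dictionaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eeg_io import (EligibilityError, extract_n2, read_edf,
                     read_sidecar_bad_channels, read_sidecar_segments,
                     segments_from_annotations, bad_channels_from_annotations,
                     apply_filters)
from .detection import DetectorParams, SpindleEvent, detect_spindles
from .spa import SPA_COLUMNS, spa_index_set, spa_table
from .stats import (diagnostic_metrics, forward_conditional_logistic,
                    grubbs_test, holm_adjust, mann_whitney_u, roc_auc,
                    shapiro_wilk)

logger = logging.getLogger("spindlespa")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_stats",
           "detect_cohort", "events_to_frame"]


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    manifest: str | None = None          # manifest CSV for EDF input
    n2_sidecar: str | None = None
    bad_channel_sidecar: str | None = None
    output_dir: str | None = None
    detector: DetectorParams = field(default_factory=DetectorParams)
    hp_hz: float = 0.3
    lp_hz: float = 70.0
    cutoff: float = 0.65
    p_enter: float = 0.05
    p_remove: float = 0.1
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        det = d.pop("detector", {})
        if isinstance(det.get("sigma_band"), list):
            det["sigma_band"] = tuple(det["sigma_band"])
        return cls(detector=DetectorParams(**det), **d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), f,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class PipelineResult:
    spa: pd.DataFrame
    events: pd.DataFrame
    comparisons: pd.DataFrame | None
    selection: dict | None
    roc: dict | None
    diagnostics: dict | None
    grubbs: pd.DataFrame | None
    excluded_subjects: list[tuple[str, str]]
    metadata: dict


def events_to_frame(events: list[SpindleEvent]) -> pd.DataFrame:
    cols = ["subject_id", "derivation", "onset_s", "duration_s",
            "osc_freq_hz", "mean_power_uv2", "band"]
    rows = [(e.subject_id, e.derivation, e.onset_s, e.duration_s,
             e.osc_freq_hz, e.mean_power_uv2, e.band) for e in events]
    return pd.DataFrame(rows, columns=cols)


def _load_manifest_subjects(config: RunConfig):
    """Yield (subject_id, lesion_side, outcome, N2 bipolar recording)."""
    manifest = pd.read_csv(config.manifest)
    base = Path(config.manifest).parent
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        rec = read_edf(base / str(row["edf_path"]), subject_id=sid)
        segments = segments_from_annotations(rec)
        excluded = bad_channels_from_annotations(rec)
        if config.n2_sidecar:
            segments += read_sidecar_segments(base / config.n2_sidecar, sid)
        if config.bad_channel_sidecar:
            excluded |= read_sidecar_bad_channels(
                base / config.bad_channel_sidecar, sid)
        rec = apply_filters(rec, config.hp_hz, config.lp_hz)
        bip = extract_n2(rec, segments, excluded=excluded)
        yield sid, str(row["lesion_side"]), str(row.get("outcome", "")), bip


def _cohort_subjects(cohort, config: RunConfig):
    for s in cohort.subjects:
        rec = apply_filters(s.recording, config.hp_hz, config.lp_hz)
        bip = extract_n2(rec, s.n2_segments)
        yield s.spec.subject_id, s.spec.lesion_side, s.spec.group, bip


def detect_cohort(config: RunConfig, cohort=None):
    """Run detection + SPA for every eligible subject.

    Returns (spa DataFrame, events DataFrame, exclusions). Subjects failing
    the N2-duration criterion are excluded and logged, not fatal.
    """
    source = (_cohort_subjects(cohort, config) if cohort is not None
              else _load_manifest_subjects(config))
    index_sets, all_events, outcomes = [], [], {}
    excluded: list[tuple[str, str]] = []
    for item in source:
        sid, side, outcome, bip = item
        try:
            events = detect_spindles(bip, config.detector)
        except (EligibilityError, ValueError) as err:
            logger.warning("subject %s excluded: %s", sid, err)
            excluded.append((sid, str(err)))
            continue
        all_events.extend(events)
        index_sets.append(spa_index_set(events, sid, side,
                                        excluded=bip.excluded))
        outcomes[sid] = outcome
    if not index_sets:
        raise RuntimeError("no eligible subjects")
    table = spa_table(index_sets, outcomes=outcomes if any(outcomes.values())
                      else None)
    return table, events_to_frame(all_events), excluded


def run_stats(spa: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Statistical stage on a cohort SPA table with an `outcome` column.

    Produces the per-index normality gate and Mann-Whitney comparisons
    (raw p plus a clearly separated Holm-adjusted column), the forward
    stepwise logistic selection over the significant indexes, and ROC /
    cut-off diagnostics and per-group Grubbs screening for the selected
    index. Skipped with a notice when only one outcome class is present.
    """
    config = config or RunConfig()
    out: dict = {"notice": None}
    if "outcome" not in spa.columns or spa["outcome"].nunique() < 2:
        out["notice"] = "single outcome class: group statistics skipped"
        return out
    y = (spa["outcome"] == "UCP").astype(int)
    ucp = spa[y == 1]
    typ = spa[y == 0]

    comp_rows = []
    for col in SPA_COLUMNS:
        a = ucp[col].dropna().to_numpy()
        b = typ[col].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        c = mann_whitney_u(a, b, index_name=col)
        try:
            _, sw_p = shapiro_wilk(np.concatenate([a, b]))
        except ValueError:
            sw_p = float("nan")
        comp_rows.append({
            "index": col, "median_ucp": c.median_a, "iqr_ucp": c.iqr_a,
            "median_typical": c.median_b, "iqr_typical": c.iqr_b,
            "n_ucp": c.n_a, "n_typical": c.n_b, "U": c.u, "p": c.p,
            "method": c.method, "shapiro_p": sw_p,
        })
    comparisons = pd.DataFrame(comp_rows)
    comparisons["p_holm"] = holm_adjust(list(comparisons["p"]))
    out["comparisons"] = comparisons

    candidates = list(comparisons.loc[comparisons["p"] < config.alpha, "index"])
    out["candidates"] = candidates
    if not candidates:
        out["notice"] = "no index significant at alpha: selection skipped"
        return out

    df = spa.copy()
    df["_y"] = y
    sel = forward_conditional_logistic(df, candidates, "_y",
                                       p_enter=config.p_enter,
                                       p_remove=config.p_remove)
    out["selection"] = {
        "candidates": sel.candidates, "selected": sel.selected,
        "coef": sel.coef, "wald": sel.wald, "wald_p": sel.wald_p,
        "intercept": sel.intercept, "nagelkerke_r2": sel.nagelkerke_r2,
        "classification_accuracy": sel.classification_accuracy,
        "n": sel.n, "separation_warning": sel.separation_warning,
        "steps": sel.steps,
    }
    best = sel.selected[0] if sel.selected else candidates[0]
    out["best_index"] = best

    mask = spa[best].notna()
    scores = spa.loc[mask, best].to_numpy()
    labels = y[mask].to_numpy()
    roc = roc_auc(scores, labels, positive_low=True, with_curve=True)
    out["roc"] = {"index": best, "auc": roc.auc, "se": roc.se,
                  "ci95": list(roc.ci95), "orientation": roc.orientation,
                  "curve": roc.curve}
    dm = diagnostic_metrics(scores, labels, cutoff=config.cutoff)
    out["diagnostics"] = {
        "index": best, "cutoff": dm.cutoff, "tp": dm.tp, "fp": dm.fp,
        "tn": dm.tn, "fn": dm.fn, "sensitivity": dm.sensitivity,
        "specificity": dm.specificity, "ppv": dm.ppv, "npv": dm.npv,
    }

    grubbs_rows = []
    for col in SPA_COLUMNS:
        for name, grp in (("UCP", ucp), ("typical", typ)):
            vals = grp[col].dropna()
            if vals.size < 3 or vals.std(ddof=1) == 0:
                continue
            g = grubbs_test(vals.to_numpy(), alpha=config.alpha,
                            ids=list(grp.loc[vals.index, "subject_id"]),
                            index_name=col, group=name)
            grubbs_rows.append({
                "index": col, "group": name, "n": g.n, "G": g.g,
                "critical": g.critical, "outlier_id": g.outlier_id,
                "outlier_value": g.outlier_value,
            })
    out["grubbs"] = pd.DataFrame(grubbs_rows)
    return out


def _comparisons_markdown(comparisons: pd.DataFrame) -> str:
    lines = ["| Index | UCP median (IQR) | Typical median (IQR) | U | p | p (Holm) |",
             "|---|---|---|---|---|---|"]
    for _, r in comparisons.iterrows():
        lines.append(
            f"| {r['index']} | {r['median_ucp']:.2f} ({r['iqr_ucp']:.2f}) "
            f"| {r['median_typical']:.2f} ({r['iqr_typical']:.2f}) "
            f"| {r['U']:.1f} | {r['p']:.3g} | {r['p_holm']:.3g} |")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, cohort=None) -> PipelineResult:
    """Full run: detection, SPA, statistics, optional on-disk report bundle."""
    spa, events, excluded = detect_cohort(config, cohort=cohort)
    stats = run_stats(spa, config) if "outcome" in spa.columns else {"notice":
                                                                     "no outcomes"}
    metadata = {
        "package_version": __version__,
        "config": json.loads(json.dumps(config.to_dict())),
        "n_subjects": int(len(spa)),
        "n_excluded": len(excluded),
        "excluded": [{"subject_id": s, "reason": r} for s, r in excluded],
        "notice": stats.get("notice"),
    }
    result = PipelineResult(
        spa=spa, events=events,
        comparisons=stats.get("comparisons"),
        selection=stats.get("selection"),
        roc=stats.get("roc"),
        diagnostics=stats.get("diagnostics"),
        grubbs=stats.get("grubbs"),
        excluded_subjects=excluded,
        metadata=metadata,
    )
    if config.output_dir:
        _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.spa.to_csv(outdir / "spa_table.csv", index=False)
    result.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    machine: dict = {"metadata": result.metadata}
    if result.comparisons is not None:
        result.comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
        (outdir / "group_comparisons.md").write_text(
            _comparisons_markdown(result.comparisons))
        machine["comparisons"] = result.comparisons.to_dict("records")
    if result.selection is not None:
        machine["selection"] = result.selection
    if result.roc is not None:
        roc = dict(result.roc)
        curve = roc.pop("curve", None)
        if curve is not None:
            curve.to_csv(outdir / "roc_curve.csv", index=False)
        machine["roc"] = roc
    if result.diagnostics is not None:
        machine["diagnostics"] = result.diagnostics
    if result.grubbs is not None:
        result.grubbs.to_csv(outdir / "grubbs.csv", index=False)
    with open(outdir / "report.json", "w") as f:
        json.dump(machine, f, indent=2, default=float)
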