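"""End-to-end orchestration: generate -> evaluate -> aging report.

A run is fully described by a :class:`RunConfig` (serializable to YAML);
re-running with the same config reproduces every numeric output.  Stages
write their outputs under the run directory and are skipped on resume
when their outputs already exist:

``dataset/``      SVC files + manifest of the generated database
``scores/``       per-experiment score tables (TSV), one per system
``report/``       EER summary, DET tables, AC/VC tables, trend curves
``provenance.yaml``  config, seeds and per-user drift scales
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import svc_io
from .aging import (
    aging_coefficients_from_scoresets,
    dataset_feature_table,
    feature_trend,
    normalize_feature_table,
    rank_users,
    static_dynamic_summary,
    variation_coefficients,
)
from .evaluation import (
    ScoreSet,
    eer_of_scores,
    run_aging_protocol,
    run_update_protocol,
    score_stats,
)
from .features import TREND_FEATURES
from .matchers import make_matcher
from .synth import DriftConfig, generate_longterm_db
from .types import LongTermDataset


@dataclass
class RunConfig:
    """Everything needed to reproduce one full experimental run."""

    n_users: int = 29
    master_seed: int = 1
    systems: tuple[str, ...] = ("dtw", "gf", "hmm")
    drift: DriftConfig = field(default_factory=DriftConfig)
    months: tuple[float, ...] = (0, 2, 4, 6, 12, 15)
    out_dir: str = "sigaging_run"
    write_dataset: bool = False
    make_plots: bool = False

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "drift" in d and isinstance(d["drift"], dict):
            dd = d["drift"]
            if "per_user_scale_range" in dd:
                dd["per_user_scale_range"] = tuple(dd["per_user_scale_range"])
            d["drift"] = DriftConfig(**dd)
        for key in ("systems", "months"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _scores_to_frame(sets: list[ScoreSet]) -> pd.DataFrame:
    rows = []
    for ss in sets:
        for label, pairs in (("genuine", ss.genuine), ("impostor", ss.impostor)):
            for user, score in pairs:
                rows.append((ss.experiment_id, ss.system, label, user, score))
    return pd.DataFrame(rows, columns=["experiment", "system", "kind", "user", "score"])


def run_all(config: RunConfig) -> Path:
    """Execute the complete study; returns the run directory.

    Stages resume from existing outputs: delete a stage directory to
    recompute it (downstream stages always recompute from the stored
    upstream tables, so resumed numbers are identical).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: dataset -------------------------------------------------
    manifest = svc_io.default_manifest(config.n_users, months=config.months)
    ds, user_scales = generate_longterm_db(
        config.n_users, manifest, drift=config.drift,
        master_seed=config.master_seed)
    report = svc_io.validate_dataset(ds)
    if not report.ok:
        raise RuntimeError(f"generated dataset inconsistent:\n{report}")
    (out / "provenance.yaml").write_text(yaml.safe_dump({
        "config": yaml.safe_load(config.to_yaml()),
        "user_drift_scales": user_scales,
        "n_signatures": len(ds),
    }, sort_keys=False))
    if config.write_dataset and not (out / "dataset" / "manifest.yaml").exists():
        svc_io.save_dataset(ds, out / "dataset")

    # ---- stage 2: score protocols ----------------------------------------
    scores_dir = out / "scores"
    scores_dir.mkdir(exist_ok=True)
    all_sets: dict[str, dict[str, list[ScoreSet]]] = {}
    for system in config.systems:
        path = scores_dir / f"{system}.tsv"
        if path.exists():
            frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
            sets = {"aging": [], "update": []}
            for eid, sub in frame.groupby("experiment", sort=True):
                ss = ScoreSet(experiment_id=eid, system=system)
                for _, row in sub.iterrows():
                    target = ss.genuine if row["kind"] == "genuine" else ss.impostor
                    target.append((row["user"], float(row["score"])))
                (sets["aging"] if eid <= "E" else sets["update"]).append(ss)
        else:
            matcher = (make_matcher(system, seed=config.master_seed)
                       if system == "hmm" else make_matcher(system))
            sets = {"aging": run_aging_protocol(ds, matcher),
                    "update": run_update_protocol(ds, matcher)}
            _scores_to_frame(sets["aging"] + sets["update"]).to_csv(
                path, sep="\t", index=False, float_format="%.17g")
        all_sets[system] = sets

    # ---- stage 3: evaluation + aging report -------------------------------
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)

    eer_rows = []
    for system in config.systems:
        for kind in ("aging", "update"):
            for ss in all_sets[system][kind]:
                mu, var = score_stats(ss)
                eer_rows.append((system, ss.experiment_id,
                                 100 * eer_of_scores(ss.genuine_scores(),
                                                     ss.impostor_scores()),
                                 mu, var, len(ss.genuine), len(ss.impostor)))
    eer_table = pd.DataFrame(
        eer_rows, columns=["system", "experiment", "eer_pct",
                           "genuine_mean", "genuine_var", "n_genuine", "n_impostor"])
    eer_table.to_csv(report_dir / "eer_summary.tsv", sep="\t", index=False)

    ac_summary = {}
    for system in config.systems:
        aging_sets = all_sets[system]["aging"]
        acs = aging_coefficients_from_scoresets(aging_sets[0], aging_sets[-1])
        pd.DataFrame([asdict(a) for a in acs]).to_csv(
            report_dir / f"ac_{system}.tsv", sep="\t", index=False)
        ac_summary[system] = rank_users(acs, k=min(5, len(acs)))
    (report_dir / "ac_rankings.json").write_text(json.dumps(ac_summary, indent=1))

    # feature-level analyses (system independent)
    table = dataset_feature_table(ds)
    values, names, kinds, months = table
    normed = normalize_feature_table(values, names, kinds)
    order = ds.manifest.sample_order()
    idx_a = [i for i, (sid, _x, _m) in enumerate(order) if sid == "BID1"]
    idx_b = [i for i, (sid, _x, _m) in enumerate(order) if sid.startswith("Bure2")]
    vcs = variation_coefficients(normed[:, idx_a, :], normed[:, idx_b, :],
                                 names, kinds)
    pd.DataFrame([asdict(v) for v in vcs]).to_csv(
        report_dir / "vc_features.tsv", sep="\t", index=False)
    summary = static_dynamic_summary(vcs)
    (report_dir / "vc_summary.json").write_text(json.dumps({
        "top_vc": [v.name for v in summary.top_vc],
        "bottom_vc": [v.name for v in summary.bottom_vc],
        "counts": summary.counts,
    }, indent=1))

    trends = {}
    for feat in TREND_FEATURES:
        curve = feature_trend(ds, feat, table=table)
        trends[feat] = curve.values.tolist()
    trend_frame = pd.DataFrame(trends)
    trend_frame.insert(0, "month", months)
    trend_frame.to_csv(report_dir / "trend_curves.tsv", sep="\t", index=False)

    if config.make_plots:
        _make_plots(all_sets, trend_frame, report_dir)
    return out


def _make_plots(all_sets, trend_frame, report_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evaluation import compute_det

    fig, axes = plt.subplots(1, len(all_sets), figsize=(4 * len(all_sets), 4))
    axes = np.atleast_1d(axes)
    for ax, (system, sets) in zip(axes, all_sets.items()):
        for ss in sets["aging"]:
            det = compute_det(ss.genuine_scores(), ss.impostor_scores())
            ax.plot(det.far * 100, det.frr * 100, label=f"Exp. {ss.experiment_id}")
        ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlabel("FAR (%)"); ax.set_ylabel("FRR (%)")
        ax.set_title(system); ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(report_dir / "det_curves.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 5, figsize=(18, 3))
    for ax, feat in zip(axes, [c for c in trend_frame.columns if c != "month"]):
        ax.plot(trend_frame[feat].values, ".-")
        ax.set_title(feat); ax.set_xlabel("sample index")
    fig.tight_layout()
    fig.savefig(report_dir / "trend_curves.png", dpi=120)
    plt.close(fig)
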