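"""Study-shaped cohort pipeline: generate → perturb → evaluate → volumetry → stats.

``run_cohort`` executes the full desk-scale experiment on a synthetic cohort:
for every patient a ground-truth ("manual") label volume is generated, an
automated segmentation is simulated by perturbation, segmentation quality
(Dice, volumetric similarity) and trunk/branch classification are evaluated,
FLR volumetry is computed for 2 methods × 2 settings (manual/automated ×
blood-filled/blood-free), candidacy decisions are taken, and the agreement
statistics (Bland–Altman, McNemar, Mann–Whitney, Kruskal–Wallis) are
assembled into a :class:`CohortReport`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as hio
from .flr import candidacy, volumetry
from .metrics import evaluate_structure_groups
from .phantom import (
    DEFAULT_CONDITION_MIX,
    DEFAULT_RESECTION_MIX,
    PatientPhantom,
    PerturbationConfig,
    PhantomConfig,
    child_seed,
    generate_cohort,
    perturb_segmentation,
)
from .stats import (
    BlandAltmanResult,
    McNemarResult,
    RankTestResult,
    bland_altman,
    kruskal_wallis,
    mann_whitney_u,
    mcnemar_exact,
)
from .vesseltree import accuracy_table, classify_vessel
from .volume import Structure

log = logging.getLogger("hepavol")

#: Default per-group Dice targets of the simulated automated segmentation,
#: calibrated to the performance range typical of 3D U-Net vessel models
#: (hepatic veins ≈ 0.66, portal veins ≈ 0.67) and near-ceiling whole-liver
#: segmentation.
DEFAULT_TARGET_DSC: Mapping[str, float] = {
    "liver": 0.97,
    "hepatic_veins": 0.66,
    "portal_veins": 0.67,
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one full cohort run."""

    n_patients: int = 32
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    target_dsc: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_DSC))
    branch_dropout_prob: float = 0.05
    tolerance_mm: Optional[float] = None  # classification tolerance; None = 1 voxel
    method: str = "perturb"  # "perturb" or "identity" (automated == manual)
    condition_mix: Optional[Mapping[str, float]] = None
    resection_mix: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.method not in ("perturb", "identity"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class CohortReport:
    """All per-patient rows and cohort-level statistics of one run."""

    metrics: pd.DataFrame
    classifications: pd.DataFrame
    accuracy: pd.DataFrame
    volumetry: pd.DataFrame
    candidacy: pd.DataFrame
    agreement: dict[str, BlandAltmanResult]
    mcnemar: dict[str, McNemarResult]
    ranktests: dict[str, Optional[RankTestResult]]
    meta: dict

    @property
    def n_flr_measurements(self) -> int:
        """One FLR% per patient × method × setting (n × 2 × 2 in a full run)."""
        return int(self.volumetry["flr_pct"].notna().sum())


def _config_hash(config: CohortConfig) -> str:
    doc = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _automated(phantom: PatientPhantom, config: CohortConfig, seed: int, i: int):
    if config.method == "identity":
        return phantom.truth
    cfg = PerturbationConfig(
        target_dsc=dict(config.target_dsc),
        branch_dropout_prob=config.branch_dropout_prob,
        seed=child_seed(seed, "perturb", i),
    )
    return perturb_segmentation(phantom.truth, cfg, trees=phantom.trees)


def run_cohort(
    config: CohortConfig, seed: int, out_dir: Optional[str | Path] = None
) -> CohortReport:
    """Run the full pipeline on a synthetic cohort; deterministic given seed.

    With ``out_dir`` set, per-patient NIfTI volumes (truth + automated),
    vessel-tree JSONs, all CSV tables and a JSON report are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)

    try:
        cohort = generate_cohort(
            config.n_patients, config.phantom, seed=child_seed(seed, "phantom"),
            condition_mix=config.condition_mix, resection_mix=config.resection_mix,
        )
        metric_rows, class_rows, vol_rows, cand_rows = [], [], [], []
        for i, phantom in enumerate(cohort):
            stage = "perturb"
            try:
                auto = _automated(phantom, config, seed, i)
                stage = "metrics"
                m = evaluate_structure_groups(auto, phantom.truth)
                m.insert(0, "patient", phantom.id)
                m["condition"] = phantom.condition
                metric_rows.append(m)
                stage = "classification"
                for vessel, tree in phantom.trees.items():
                    if vessel == Structure.IVC:
                        continue
                    r = classify_vessel(tree, auto, tolerance_mm=config.tolerance_mm)
                    class_rows.append(
                        dict(patient=phantom.id, vessel=vessel.value,
                             trunk_accurate=r.trunk_accurate,
                             branches_accurate=r.branches_accurate)
                    )
                stage = "volumetry"
                for method, volume in (("manual", phantom.truth), ("automated", auto)):
                    res = volumetry(volume, phantom.plan)
                    for setting, tlv, flr_ml, flr_pct in (
                        ("blood_filled", res.tlv_filled, res.flr_filled, res.flr_pct_filled),
                        ("blood_free", res.tlv_free, res.flr_free, res.flr_pct_free),
                    ):
                        vol_rows.append(
                            dict(patient=phantom.id, method=method, setting=setting,
                                 condition=phantom.condition, resection=phantom.resection,
                                 tlv_ml=tlv, flr_ml=flr_ml, flr_pct=flr_pct,
                                 v_lesion_ml=res.v_lesion, v_hv_ml=res.v_hv,
                                 v_pv_ml=res.v_pv)
                        )
                        decision = candidacy(flr_pct, phantom.condition, basis=setting)
                        cand_rows.append(
                            dict(patient=phantom.id, method=method, basis=setting,
                                 condition=phantom.condition, flr_pct=flr_pct,
                                 threshold_pct=decision.threshold_pct,
                                 candidate=decision.candidate)
                        )
                stage = "write"
                if out is not None:
                    pdir = out / "volumes"
                    hio.write_label_volume(
                        phantom.truth, pdir / f"{phantom.id}_truth.nii.gz",
                        meta=dict(condition=phantom.condition, resection=phantom.resection,
                                  seed=seed,
                                  plan=dict(point_mm=list(phantom.plan.point_mm),
                                            normal=list(phantom.plan.normal))),
                    )
                    hio.write_label_volume(auto, pdir / f"{phantom.id}_automated.nii.gz",
                                           meta=dict(condition=phantom.condition))
                    hio.write_vessel_trees(phantom.trees, pdir / f"{phantom.id}_trees.json")
                log.info("patient %s (%s, %s): all stages complete",
                         phantom.id, phantom.condition, phantom.resection)
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed for patient {phantom.id}: {exc}"
                ) from exc

        metrics = pd.concat(metric_rows, ignore_index=True)
        classifications = pd.DataFrame(class_rows)
        accuracy = _accuracy_from_rows(classifications)
        volumetry_df = pd.DataFrame(vol_rows)
        candidacy_df = pd.DataFrame(cand_rows)

        agreement = _agreement_stats(metrics, volumetry_df)
        mcnemar = _mcnemar_stats(candidacy_df)
        ranktests = _rank_stats(metrics, volumetry_df)

        meta = dict(
            seed=int(seed),
            n_patients=int(config.n_patients),
            method=config.method,
            config_hash=_config_hash(config),
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        report = CohortReport(
            metrics=metrics, classifications=classifications, accuracy=accuracy,
            volumetry=volumetry_df, candidacy=candidacy_df, agreement=agreement,
            mcnemar=mcnemar, ranktests=ranktests, meta=meta,
        )
        if out is not None:
            report_tables(report, out)
            (out / "report.json").write_text(report_json(report))
        return report
    finally:
        if out is not None:
            log.removeHandler(handler)
            handler.close()


def _accuracy_from_rows(classifications: pd.DataFrame) -> pd.DataFrame:
    from .vesseltree import ClassificationResult

    results = [
        ClassificationResult(
            vessel=Structure(row.vessel),
            trunk_accurate=bool(row.trunk_accurate),
            branches_accurate=(None if row.branches_accurate is None
                               or (isinstance(row.branches_accurate, float)
                                   and np.isnan(row.branches_accurate))
                               else bool(row.branches_accurate)),
        )
        for row in classifications.itertuples()
    ]
    return accuracy_table(results)


def _agreement_stats(metrics: pd.DataFrame, vol: pd.DataFrame) -> dict[str, BlandAltmanResult]:
    out: dict[str, BlandAltmanResult] = {}
    # automated vs manual vessel volumes (per structure group)
    for group, key in (("hepatic_veins", "hv_volume"), ("portal_veins", "pv_volume")):
        sub = metrics[metrics["group"] == group]
        pairs = list(zip(sub["volume_pred_ml"], sub["volume_truth_ml"]))
        if len(pairs) >= 3:
            out[f"{key}_auto_vs_manual"] = bland_altman(pairs)
    # automated vs manual FLR and FLR%, per setting
    for setting in ("blood_free", "blood_filled"):
        sub = vol[vol["setting"] == setting].pivot(
            index="patient", columns="method", values=["flr_ml", "flr_pct"]
        )
        for value, key in (("flr_ml", "flr"), ("flr_pct", "flr_pct")):
            pairs = list(zip(sub[(value, "automated")], sub[(value, "manual")]))
            if len(pairs) >= 3:
                out[f"{key}_{setting}_auto_vs_manual"] = bland_altman(pairs)
    # blood-free vs blood-filled, per method
    for method in ("manual", "automated"):
        sub = vol[vol["method"] == method].pivot(
            index="patient", columns="setting", values=["flr_ml", "flr_pct"]
        )
        for value, key in (("flr_ml", "flr"), ("flr_pct", "flr_pct")):
            pairs = list(zip(sub[(value, "blood_free")], sub[(value, "blood_filled")]))
            if len(pairs) >= 3:
                out[f"{key}_free_vs_filled_{method}"] = bland_altman(pairs)
    return out


def _mcnemar_stats(cand: pd.DataFrame) -> dict[str, McNemarResult]:
    out: dict[str, McNemarResult] = {}
    for basis in ("blood_free", "blood_filled"):
        sub = cand[cand["basis"] == basis].pivot(
            index="patient", columns="method", values="candidate"
        )
        b = int((sub["manual"] & ~sub["automated"]).sum())
        c = int((~sub["manual"] & sub["automated"]).sum())
        out[f"candidacy_auto_vs_manual_{basis}"] = mcnemar_exact(b, c)
    for method in ("manual", "automated"):
        sub = cand[cand["method"] == method].pivot(
            index="patient", columns="basis", values="candidate"
        )
        b = int((sub["blood_filled"] & ~sub["blood_free"]).sum())
        c = int((~sub["blood_filled"] & sub["blood_free"]).sum())
        out[f"candidacy_free_vs_filled_{method}"] = mcnemar_exact(b, c)
    return out


def _rank_stats(metrics: pd.DataFrame, vol: pd.DataFrame) -> dict[str, Optional[RankTestResult]]:
    out: dict[str, Optional[RankTestResult]] = {}
    for setting in ("blood_free", "blood_filled"):
        for value, key in (("flr_ml", "flr"), ("flr_pct", "flr_pct")):
            sub = vol[vol["setting"] == setting]
            x = sub.loc[sub["method"] == "automated", value].to_numpy()
            y = sub.loc[sub["method"] == "manual", value].to_numpy()
            out[f"{key}_{setting}_auto_vs_manual"] = mann_whitney_u(x, y)
    # subgroup (liver-condition) comparison of per-patient vessel DSC
    for group in ("hepatic_veins", "portal_veins"):
        sub = metrics[metrics["group"] == group]
        groups = [g["dsc"].to_numpy() for _, g in sub.groupby("condition") if len(g)]
        out[f"dsc_{group}_by_condition"] = (
            kruskal_wallis(groups) if len(groups) >= 2 else None
        )
    return out


# --------------------------------------------------------------------------
# report serialization
# --------------------------------------------------------------------------


def report_json(report: CohortReport) -> str:
    """Serialize a cohort report to deterministic JSON (timestamp in meta)."""
    doc = dict(
        meta=report.meta,
        n_flr_measurements=report.n_flr_measurements,
        metrics=report.metrics.to_dict(orient="records"),
        classifications=report.classifications.to_dict(orient="records"),
        accuracy=report.accuracy.to_dict(orient="records"),
        volumetry=report.volumetry.to_dict(orient="records"),
        candidacy=report.candidacy.to_dict(orient="records"),
        agreement={k: dataclasses.asdict(v) for k, v in report.agreement.items()},
        mcnemar={k: dataclasses.asdict(v) for k, v in report.mcnemar.items()},
        ranktests={
            k: (None if v is None else dataclasses.asdict(v))
            for k, v in report.ranktests.items()
        },
    )
    return json.dumps(doc, sort_keys=True, indent=1, default=float)


def report_tables(report: CohortReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort CSV tables; returns the mapping name → path.

    ``accuracy.csv`` mirrors the per-vessel trunk/branch accuracy table,
    ``volumes.csv`` the per-condition manual vs automated vessel volumes, and
    ``candidacy.csv`` the 2×2 method × setting candidate counts.
    """
    for name in ("metrics", "volumetry", "candidacy", "accuracy"):
        df = getattr(report, name)
        if df is None or df.empty:
            raise ValueError(f"incomplete report: {name} table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["accuracy"] = out / "accuracy.csv"
    report.accuracy.to_csv(paths["accuracy"], index=False, float_format="%.2f")

    vols = (
        report.metrics[report.metrics["group"].isin(["hepatic_veins", "portal_veins"])]
        .groupby(["group", "condition"])
        .agg(
            n=("patient", "count"),
            volume_manual_ml=("volume_truth_ml", "mean"),
            volume_automated_ml=("volume_pred_ml", "mean"),
        )
        .reset_index()
    )
    paths["volumes"] = out / "volumes.csv"
    vols.to_csv(paths["volumes"], index=False, float_format="%.2f")

    cand = (
        report.candidacy.groupby(["method", "basis"])["candidate"]
        .sum()
        .unstack("basis")
        .rename(columns=lambda c: f"candidates_{c}")
        .reset_index()
    )
    paths["candidacy"] = out / "candidacy.csv"
    cand.to_csv(paths["candidacy"], index=False)

    paths["metrics"] = out / "metrics.csv"
    report.metrics.to_csv(paths["metrics"], index=False, float_format="%.4f")
    paths["volumetry"] = out / "volumetry.csv"
    report.volumetry.to_csv(paths["volumetry"], index=False, float_format="%.4f")
    paths["classifications"] = out / "classifications.csv"
    report.classifications.to_csv(paths["classifications"], index=False)
    return paths
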