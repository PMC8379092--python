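"""End-to-end orchestration: simulate/load -> select -> classify ->
evaluate -> associate, with JSON/CSV artifacts and a rendered report.

A run executes the full analysis for each requested modality subset
(combined, diffusion-only, perfusion-only), producing one metrics row
per subset plus McNemar comparisons of the combined model against each
single-modality model, a consensus-feature table with group statistics,
and the feature-cognition association grid for the combined model.

Every stage seed is derived from the single run seed with a fixed
splitting rule, so stages can be re-run in isolation and the whole run
is a pure function of (cohort bytes, configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import associations as assoc_mod
from .associations import association_table, chi_square_2x2, group_compare
from .classifier import (
    ConsensusSet,
    LoocvResult,
    SparseLogisticConfig,
    consensus_features,
    loocv_run,
)
from .evaluation import confusion_metrics, mcnemar_compare, roc_auc
from .lasso import LassoConfig
from .schema import COGNITIVE_TESTS, Cohort, FeatureName, load_cohort, write_cohort
from .selection import ReducedFeatureSets, nested_fs
from .synthetic import SyntheticConfig, default_paper_config, generate_cohort

logger = logging.getLogger("diffperf")

MODALITY_SUBSETS = ("combined", "dti", "cbf")
ASSOCIATION_TESTS = ("TMT_A", "TMT_B", "Stroop_CT", "VFT")

# stage tags for the seed-splitting rule
_STAGE = {"simulate": 1, "selection": 2, "classification": 3}


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage seed (< 2^31) from the run seed."""
    return int(
        np.random.SeedSequence([seed, _STAGE[stage], index])
        .generate_state(1)[0] % 2**31
    )


@dataclass
class PipelineConfig:
    """Everything one run needs; JSON-serializable."""

    seed: int = 0
    feature_path: str | None = None
    phenotype_path: str | None = None
    simulate: bool = True
    synthetic: SyntheticConfig | None = None
    modalities: tuple[str, ...] = MODALITY_SUBSETS
    lasso: LassoConfig = field(default_factory=LassoConfig)
    logistic: SparseLogisticConfig = field(default_factory=SparseLogisticConfig)
    consensus_threshold: float = 0.75
    association_tests: tuple[str, ...] = ASSOCIATION_TESTS
    outdir: str = "diffperf_run"

    def validate(self) -> None:
        for m in self.modalities:
            if m not in MODALITY_SUBSETS:
                raise ValueError(f"unknown modality subset {m!r}")
        if not self.simulate and not (self.feature_path and self.phenotype_path):
            raise ValueError("need cohort paths unless simulate=True")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _restrict(cohort: Cohort, modality: str) -> Cohort:
    if modality == "combined":
        return cohort
    return cohort.restrict_features(
        "diffusion" if modality == "dti" else "perfusion"
    )


@dataclass
class ModalityResult:
    modality: str
    reduced: ReducedFeatureSets
    loocv: LoocvResult
    consensus: ConsensusSet
    metrics: dict
    roc: dict


@dataclass
class RunResult:
    cohort: Cohort
    config: PipelineConfig
    per_modality: dict[str, ModalityResult]
    mcnemar: dict[str, dict]
    associations: list
    demographics: pd.DataFrame
    consensus_table: pd.DataFrame


def _demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Table-1 analogue: per-group mean (SD) and a group test per row."""
    y = cohort.diagnosis
    case, ctrl = y == 1, y == 0
    rows = []
    cov = cohort.covariates()
    male_counts = np.array([
        [int(cohort.sex[case].sum()), int(case.sum() - cohort.sex[case].sum())],
        [int(cohort.sex[ctrl].sum()), int(ctrl.sum() - cohort.sex[ctrl].sum())],
    ])
    stat, p = chi_square_2x2(male_counts)
    rows.append({
        "variable": "male_fraction",
        "vMCI": float(cohort.sex[case].mean()),
        "control": float(cohort.sex[ctrl].mean()),
        "test": "chi-square", "p": p,
    })
    named = {"age": cov[:, 1], "education": cov[:, 2]}
    tests_present = [
        t for t in COGNITIVE_TESTS
        if all(t in s.cognitive_scores for s in cohort.subjects)
    ]
    for t in tests_present:
        named[t] = cohort.cognitive(t)
    for name, vals in named.items():
        test, stat, p = group_compare(vals, y)
        rows.append({
            "variable": name,
            "vMCI": float(vals[case].mean()),
            "control": float(vals[ctrl].mean()),
            "test": test, "p": p,
        })
    return pd.DataFrame(rows)


def _consensus_table(cohort: Cohort, cs: ConsensusSet) -> pd.DataFrame:
    """Table-3 analogue: frequency, type, region, group means, p, FDR."""
    y = cohort.diagnosis
    case, ctrl = y == 1, y == 0
    rows = []
    for col in sorted(cs.features, key=lambda c: -cs.frequencies[c]):
        f = FeatureName.from_column(col)
        vals = cohort.table[col].to_numpy(dtype=float)
        test, stat, p = group_compare(vals, y)
        rows.append({
            "frequency": round(cs.frequencies[col], 3),
            "type": f.metric,
            "region": f.region,
            "vMCI_mean": float(vals[case].mean()),
            "control_mean": float(vals[ctrl].mean()),
            "test": test,
            "p": p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = assoc_mod.bh_fdr(df["p"].to_numpy())
    return df


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis and write artifacts to config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        syn = config.synthetic or default_paper_config(
            seed=stage_seed(config.seed, "simulate")
        )
        if config.synthetic is None:
            logger.info("simulating default cohort, seed %d", syn.seed)
        cohort = generate_cohort(syn)
        write_cohort(cohort, outdir / "features.csv", outdir / "phenotypes.csv")
    else:
        cohort = load_cohort(config.feature_path, config.phenotype_path)

    per_modality: dict[str, ModalityResult] = {}
    for mi, modality in enumerate(config.modalities):
        sub = _restrict(cohort, modality)
        sel_seed = stage_seed(config.seed, "selection", mi)
        logger.info("modality %s: nested FS (seed %d)", modality, sel_seed)
        reduced = nested_fs(sub, config.lasso, seed=sel_seed)
        (outdir / f"selection_{modality}.json").write_text(reduced.to_json())

        clf_seed = stage_seed(config.seed, "classification", mi)
        logger.info("modality %s: LOOCV (seed %d)", modality, clf_seed)
        loocv = loocv_run(sub, reduced, config.logistic, seed=clf_seed)
        (outdir / f"predictions_{modality}.json").write_text(
            json.dumps(loocv.to_dict(), indent=2)
        )
        cs = consensus_features(loocv, config.consensus_threshold)
        cm = confusion_metrics(loocv.predicted_labels, loocv.true_labels)
        roc = roc_auc(loocv.probabilities, loocv.true_labels)
        metrics = {**cm.to_dict(), "AUC": round(roc.auc, 3)}
        per_modality[modality] = ModalityResult(
            modality=modality, reduced=reduced, loocv=loocv,
            consensus=cs, metrics=metrics, roc=roc.to_dict(),
        )
        pd.DataFrame({
            "fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds,
        }).to_csv(outdir / f"roc_{modality}.csv", index=False)

    mcnemar: dict[str, dict] = {}
    if "combined" in per_modality:
        ref = per_modality["combined"].loocv
        for other in ("cbf", "dti"):
            if other in per_modality:
                mc = mcnemar_compare(
                    ref.predicted_labels,
                    per_modality[other].loocv.predicted_labels,
                    ref.true_labels,
                )
                mcnemar[f"combined_vs_{other}"] = mc.to_dict()

    metrics_rows = [
        {"model": m, **res.metrics} for m, res in per_modality.items()
    ]
    (outdir / "metrics.json").write_text(json.dumps({
        "seed": config.seed,
        "models": metrics_rows,
        "mcnemar": mcnemar,
    }, indent=2))

    # association grid on the combined model's consensus features
    associations = []
    primary = per_modality.get("combined") or next(iter(per_modality.values()))
    tests = [
        t for t in config.association_tests
        if all(t in s.cognitive_scores for s in cohort.subjects)
    ]
    if primary.consensus.features and tests:
        associations = association_table(
            cohort, primary.consensus, tests, group="vMCI"
        )
        assoc_mod.records_to_frame(associations).to_csv(
            outdir / "associations_vmci.csv", index=False
        )

    demographics = _demographics_table(cohort)
    demographics.to_csv(outdir / "demographics.csv", index=False)
    consensus_table = _consensus_table(cohort, primary.consensus)
    consensus_table.to_csv(outdir / "consensus_features.csv", index=False)

    freq_rows = [
        {"modality": m, "feature": f, "frequency": q}
        for m, res in per_modality.items()
        for f, q in sorted(res.consensus.frequencies.items())
    ]
    pd.DataFrame(freq_rows).to_csv(outdir / "frequencies.csv", index=False)

    (outdir / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str)
    )
    return RunResult(
        cohort=cohort, config=config, per_modality=per_modality,
        mcnemar=mcnemar, associations=associations,
        demographics=demographics, consensus_table=consensus_table,
    )


def _fmt_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    if df.empty:
        return "(empty)\n"
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(lambda v: floatfmt.format(v))
    return show.to_string(index=False) + "\n"


def render_report(outdir: str | Path) -> str:
    """Human-readable summary of a finished run directory."""
    outdir = Path(outdir)
    required = ["metrics.json", "demographics.csv", "consensus_features.csv"]
    for name in required:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing artifact: {outdir / name}")
    metrics = json.loads((outdir / "metrics.json").read_text())
    demo = pd.read_csv(outdir / "demographics.csv")
    cons = pd.read_csv(outdir / "consensus_features.csv")

    lines = ["# diffperf run report", ""]
    lines += ["## Cohort demographics and cognition", "", _fmt_table(demo)]
    lines += ["## Classifier performance", ""]
    lines.append(_fmt_table(pd.DataFrame(metrics["models"])))
    if metrics.get("mcnemar"):
        lines += ["## Paired comparisons (McNemar)", ""]
        lines.append(_fmt_table(pd.DataFrame(
            [{"comparison": k, **v} for k, v in metrics["mcnemar"].items()]
        )))
    lines += ["## Consensus discriminative features", ""]
    if cons.empty:
        lines.append("No consensus features reached the threshold.\n")
    else:
        lines.append(_fmt_table(cons))
    assoc_path = outdir / "associations_vmci.csv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path)
        lines += ["## Feature-cognition associations (vMCI group)", "",
                  _fmt_table(assoc)]
    report = "\n".join(lines)
    (outdir / "report.md").write_text(report)
    return report
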