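"""End-to-end orchestration: expression screen → panel → IHC calls → pair
enumeration → survival screen → two-marker combinations.

The configuration object carries every tunable constant of the procedure
(fold-change cutoffs, permutation count, panel thresholds, minimum subset
size, follow-up horizon, significance level, seed) and round-trips
losslessly through YAML. Every stage is a pure function of (inputs, config,
seed): two runs with the same configuration produce byte-identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, expression, ihc, simulate, survival

logger = logging.getLogger("slmarker")

EXIT_INPUT_ERROR = 2
EXIT_MODEL_ERROR = 3

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and the process exit code."""

    def __init__(self, stage: str, message: str, exit_code: int = EXIT_INPUT_ERROR):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """All tunable parameters of the screen, with the study's defaults."""

    fold_cutoff: float = 1.5
    validation_fold_cutoff: float = 1.4
    n_perm: int = 10_000
    panel_threshold: float = 0.15
    kras_threshold: float = 0.25
    min_subset: int = 5
    horizon_months: float = 120.0
    alpha: float = 0.05
    seed: int = 20210415
    combine_protective: str = "complement"
    combine_top: int = 8  # combine at most this many top markers pairwise
    tested_patterns: tuple[str, ...] = ("uu", "du")
    # input paths (None = stage skipped or packaged default used)
    expression_path: str | None = None
    labels_path: str | None = None
    sl_pairs_path: str | None = None
    ihc_scores_path: str | None = None
    clinical_path: str | None = None
    stain_panel_path: str | None = None
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1 or self.validation_fold_cutoff <= 1:
            raise ValueError("fold cutoffs must be > 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name in ("panel_threshold", "kras_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_subset < 1:
            raise ValueError("min_subset must be >= 1")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")
        if self.combine_protective not in ("complement", "as-is"):
            raise ValueError("combine_protective must be 'complement' or 'as-is'")
        self.tested_patterns = tuple(self.tested_patterns)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["tested_patterns"] = list(d["tested_patterns"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "tested_patterns" in d:
            d["tested_patterns"] = tuple(d["tested_patterns"])
        return cls(**d)


def _require(path: str | None, stage: str, what: str) -> Path:
    if path is None:
        raise PipelineError(stage, f"no {what} file configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"{what} file not found: {p}")
    return p


def _write(df: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages


def stage_screen_expression(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    stage = "screen-expression"
    matrix = expression.ExpressionMatrix.read_tsv(_require(config.expression_path, stage, "expression matrix"))
    labels = expression.SampleLabels.read_tsv(_require(config.labels_path, stage, "sample labels"))
    pairs = expression.SLPairTable.read_tsv(_require(config.sl_pairs_path, stage, "SL pair list"))
    logger.info("%s: %d genes x %d samples, %d candidate pairs", stage,
                len(matrix.gene_ids), len(matrix.sample_ids), len(pairs))
    records = expression.screen_sl_pairs(
        matrix, labels, pairs,
        fold_cutoff=config.fold_cutoff,
        n_perm=config.n_perm,
        seed=config.seed,
        tested_patterns=config.tested_patterns,
    )
    table = expression.select_initial_panel(
        records, threshold=config.panel_threshold, kras_threshold=config.kras_threshold
    )
    _write(table, outdir / "pattern_fractions.tsv")
    logger.info("%s: %d pairs screened, %d selected", stage, len(table), int(table["selected"].sum()))
    return table


def stage_call_ihc(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    stage = "call-ihc"
    panel = ihc.load_panel(config.stain_panel_path)
    scores = ihc.read_scores(_require(config.ihc_scores_path, stage, "IHC score"))
    calls = ihc.call_stains(scores, panel)
    out = calls.reset_index()
    _write(out, outdir / "ihc_calls.csv", sep=",")
    logger.info("%s: %d patients x %d stains called", stage, calls.shape[0], calls.shape[1])
    return calls


def stage_enumerate_pairs(config: PipelineConfig, outdir: Path) -> list:
    stage = "enumerate-pairs"
    panel = ihc.load_panel(config.stain_panel_path)
    pairs = ihc.enumerate_stain_pairs(panel)
    df = pd.DataFrame(
        [(a.stain_id, b.stain_id) for a, b in pairs], columns=["stain_a", "stain_b"]
    )
    _write(df, outdir / "stain_pairs.tsv")
    logger.info("%s: %d stains -> %d distinct pairs", stage, len(panel), len(pairs))
    return pairs


def build_markers(panel, pairs) -> list[ihc.MarkerDefinition]:
    """Single markers (one per stain, over-pattern) plus every direction
    pattern of every distinct stain pair."""
    markers = [ihc.MarkerDefinition((s.stain_id,), (ihc.OVER,)) for s in panel]
    for a, b in pairs:
        for pa in (ihc.OVER, ihc.UNDER):
            for pb in (ihc.OVER, ihc.UNDER):
                markers.append(ihc.MarkerDefinition((a.stain_id, b.stain_id), (pa, pb)))
    return markers


def stage_survival_screen(
    config: PipelineConfig, outdir: Path, calls: pd.DataFrame
) -> tuple[list, pd.DataFrame]:
    stage = "survival-screen"
    clinical = pd.read_csv(_require(config.clinical_path, stage, "clinical"), dtype={"patient_id": str})
    panel = ihc.load_panel(config.stain_panel_path)
    pairs = ihc.enumerate_stain_pairs(panel)
    markers = build_markers(panel, pairs)
    results = survival.screen_markers(
        markers, calls, clinical,
        min_subset=config.min_subset,
        horizon_months=config.horizon_months,
    )
    frame = survival.screen_to_frame(results)
    _write(frame, outdir / "survival_screen.tsv")
    n_tested = sum(r.status == "tested" for r in results)
    logger.info("%s: %d markers (%d tested, %d skipped)", stage, len(results),
                n_tested, len(results) - n_tested)
    return results, frame


def stage_combine(
    config: PipelineConfig, outdir: Path, results: list, calls: pd.DataFrame
) -> pd.DataFrame:
    stage = "combine"
    clinical = pd.read_csv(_require(config.clinical_path, stage, "clinical"), dtype={"patient_id": str})
    significant = [
        r
        for r in results
        if r.status == "tested" and r.univariate is not None and r.univariate.p("marker") < config.alpha
    ]
    significant.sort(key=lambda r: r.univariate.p("marker"))
    significant = significant[: config.combine_top]
    # orientation from the estimated direction: HR < 1 means the pattern
    # subset has the better survival, so its complement carries the risk
    markers = []
    for r in significant:
        orientation = "protective" if r.univariate.hr("marker") < 1 else "risk"
        markers.append(ihc.MarkerDefinition(r.marker.stain_ids, r.marker.risk_pattern, orientation))
    rows = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            res = survival.combine_markers(
                markers[i], markers[j], calls, clinical,
                min_subset=config.min_subset,
                horizon_months=config.horizon_months,
                combine_protective=config.combine_protective,
            )
            row = {
                "combination": res.display_label(),
                "n": res.n,
                "n_risk": res.n_risk,
                "status": res.status,
                "hr_adj": np.nan,
                "ci_low_adj": np.nan,
                "ci_high_adj": np.nan,
                "p_adj": np.nan,
                "lr_chi2_adj": np.nan,
            }
            if res.adjusted is not None:
                row.update(
                    hr_adj=res.adjusted.hr("marker"),
                    ci_low_adj=res.adjusted.ci("marker")[0],
                    ci_high_adj=res.adjusted.ci("marker")[1],
                    p_adj=res.adjusted.p("marker"),
                    lr_chi2_adj=res.adjusted.lr_chi2,
                )
            rows.append(row)
    frame = pd.DataFrame(rows, columns=[
        "combination", "n", "n_risk", "status", "hr_adj", "ci_low_adj",
        "ci_high_adj", "p_adj", "lr_chi2_adj",
    ])
    _write(frame, outdir / "combinations.tsv")
    logger.info("%s: %d significant markers -> %d combinations", stage, len(markers), len(frame))
    return frame


def stage_simulate(config: PipelineConfig, outdir: Path,
                   expr_truth: simulate.ExpressionTruth | None = None,
                   cohort_truth: simulate.CohortTruth | None = None) -> PipelineConfig:
    """Generate synthetic inputs and return a config pointing at them."""
    stage = "simulate"
    outdir.mkdir(parents=True, exist_ok=True)
    if expr_truth is None:
        expr_truth = simulate.ExpressionTruth(
            planted=[
                simulate.PlantedPair("SLA1", "SLB1", "uu", 0.4),
                simulate.PlantedPair("SLA2", "SLB2", "du", 0.3),
                simulate.PlantedPair("KRAS", "SLB3", "du", 0.35),
            ],
            seed=config.seed,
        )
    panel = ihc.load_panel(config.stain_panel_path)
    if cohort_truth is None:
        ids = [s.stain_id for s in panel]
        markers = []
        if len(ids) >= 4:
            markers = [
                simulate.PlantedMarker((ids[0], ids[1]), ("under", "under"), 0.08, np.log(7.5)),
                simulate.PlantedMarker((ids[2], ids[3]), ("over", "over"), 0.25, np.log(3.0)),
            ]
        cohort_truth = simulate.CohortTruth(markers=markers, seed=config.seed + 1)
    matrix, labels, sl_pairs = simulate.simulate_expression(expr_truth)
    scores, clinical, true_calls = simulate.simulate_cohort(cohort_truth, panel)

    matrix.write_tsv(outdir / "expression.tsv")
    labels.write_tsv(outdir / "labels.tsv")
    sl_pairs.write_tsv(outdir / "sl_pairs.tsv")
    scores.to_csv(outdir / "ihc_scores.csv", index=False, float_format=_FLOAT_FMT)
    clinical.to_csv(outdir / "clinical.csv", index=False, float_format=_FLOAT_FMT)
    true_calls.reset_index().to_csv(outdir / "true_calls.csv", index=False)
    truth = {
        "expression": {
            "planted": [dataclasses.asdict(p) for p in expr_truth.planted],
            "n_cancer": expr_truth.n_cancer,
            "n_control": expr_truth.n_control,
            "seed": expr_truth.seed,
        },
        "cohort": {
            "markers": [
                {**dataclasses.asdict(m), "stain_ids": list(m.stain_ids),
                 "risk_pattern": list(m.risk_pattern)}
                for m in cohort_truth.markers
            ],
            "n_patients": cohort_truth.n_patients,
            "baseline_hazard": cohort_truth.baseline_hazard,
            "censoring_rate": cohort_truth.censoring_rate,
            "stage_log_hr": cohort_truth.stage_log_hr,
            "seed": cohort_truth.seed,
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    logger.info("%s: wrote synthetic inputs to %s", stage, outdir)
    return dataclasses.replace(
        config,
        expression_path=str(outdir / "expression.tsv"),
        labels_path=str(outdir / "labels.tsv"),
        sl_pairs_path=str(outdir / "sl_pairs.tsv"),
        ihc_scores_path=str(outdir / "ihc_scores.csv"),
        clinical_path=str(outdir / "clinical.csv"),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the report bundle as a dict of
    DataFrames. Any stage failure raises PipelineError naming the stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    bundle: dict = {}
    try:
        logger.info("slmarker %s | seed=%d", __version__, config.seed)
        config.to_yaml(outdir / "config.yaml")
        bundle["pattern_fractions"] = stage_screen_expression(config, outdir)
        calls = stage_call_ihc(config, outdir)
        bundle["ihc_calls"] = calls
        stage_enumerate_pairs(config, outdir)
        results, frame = stage_survival_screen(config, outdir, calls)
        bundle["survival_screen"] = frame
        bundle["combinations"] = stage_combine(config, outdir, results, calls)
        _write_summary(outdir, config, bundle)
    except PipelineError:
        raise
    except FileNotFoundError as err:
        raise PipelineError("io", str(err), EXIT_INPUT_ERROR) from err
    finally:
        logger.removeHandler(handler)
        handler.close()
    return bundle


def _write_summary(outdir: Path, config: PipelineConfig, bundle: dict) -> None:
    """A compact report mirroring a univariate/adjusted hazard-ratio table."""
    lines = [f"slmarker {__version__} summary (seed={config.seed})", ""]
    screen = bundle["survival_screen"]
    tested = screen[screen["status"] == "tested"]
    sig = tested[tested["p"] < config.alpha]
    lines.append(f"expression pairs selected: {int(bundle['pattern_fractions']['selected'].sum())}"
                 f" of {len(bundle['pattern_fractions'])}")
    lines.append(f"markers tested: {len(tested)} of {len(screen)}; significant at "
                 f"alpha={config.alpha}: {len(sig)}")
    lines.append("")
    lines.append("marker\tn_risk/n\tHR (95% CI)\tp\tHR_adj (95% CI)\tp_adj")
    for _, r in sig.iterrows():
        lines.append(
            f"{r['marker']}\t{int(r['n_risk'])}/{int(r['n'])}\t"
            f"{r['hr']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})\t{r['p']:.4g}\t"
            f"{r['hr_adj']:.2f} ({r['ci_low_adj']:.2f}-{r['ci_high_adj']:.2f})\t{r['p_adj']:.4g}"
        )
    combos = bundle["combinations"]
    ok = combos[combos["status"] == "tested"]
    lines.append("")
    lines.append(f"two-marker combinations tested: {len(ok)} of {len(combos)}")
    for _, r in ok[ok["p_adj"] < config.alpha].iterrows():
        lines.append(
            f"{r['combination']}\t{int(r['n_risk'])}/{int(r['n'])}\t"
            f"{r['hr_adj']:.2f} ({r['ci_low_adj']:.2f}-{r['ci_high_adj']:.2f})\t{r['p_adj']:.4g}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
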