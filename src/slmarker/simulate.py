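"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`simulate_expression` — a cancer/control expression matrix with
  log-normal background intensities and, per planted gene pair, a chosen
  fraction of cancer samples carrying coordinated fold shifts in the planted
  pattern's directions. Defaults mirror a 57-cancer / 22-control microarray
  study.
* :func:`simulate_cohort` — an IHC-scored patient cohort (default 160
  patients, three cancerous cores per stain) with configurable over-call
  prevalence and inter-stain dependence, plus survival times drawn from a
  proportional-hazards model with planted log-hazard effects for chosen
  markers and stage, under independent exponential censoring.

Both are bit-reproducible given (truth, seed); every stochastic choice flows
through a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, SampleLabels, SLPairTable
from .ihc import GRADES, OVER, UNDER, CutoffRule, MarkerDefinition, StainDefinition

# ---------------------------------------------------------------------------
# expression


@dataclass
class PlantedPair:
    """A gene pair with a target joint-regulation pattern planted at a
    target fraction of cancer samples."""

    gene_a: str
    gene_b: str
    pattern: str = "uu"  # uu | ud | du | dd
    fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.pattern not in ("uu", "ud", "du", "dd"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")


@dataclass
class ExpressionTruth:
    """Ground truth for a synthetic expression screen.

    ``background_call_rate`` sets the probability that a background
    (unplanted) gene spuriously crosses the fold-change cutoff in a given
    cancer sample; the background noise scale is derived from it.
    ``shift_margin`` (log2 units) is added beyond the cutoff for planted
    shifts so noise rarely erases a planted call.
    """

    n_cancer: int = 57
    n_control: int = 22
    n_genes: int = 300
    planted: list[PlantedPair] = field(default_factory=list)
    n_background_pairs: int = 20
    background_call_rate: float = 0.10
    fold_cutoff: float = 1.5
    shift_margin: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per class")
        if not 0 < self.background_call_rate < 1:
            raise ValueError("background_call_rate must be in (0, 1)")


def _background_sigma(truth: ExpressionTruth) -> float:
    """Noise scale (log2) such that a background gene's log ratio against the
    averaged controls crosses the cutoff at the configured base rate."""
    z = stats.norm.ppf(1 - truth.background_call_rate / 2)
    inflation = np.sqrt(1 + 1 / truth.n_control)  # control mean adds variance
    return np.log2(truth.fold_cutoff) / (z * inflation)


def simulate_expression(
    truth: ExpressionTruth,
) -> tuple[ExpressionMatrix, SampleLabels, SLPairTable]:
    """Generate (matrix, labels, pair list) with planted pattern fractions.

    Planted genes are appended to the background gene set; for each planted
    pair a ``round(fraction · n_cancer)`` subset of cancer samples receives
    fold shifts of at least the cutoff (plus margin) in the pattern's
    directions. The returned pair table holds the planted pairs followed by
    background (null) pairs.
    """
    rng = np.random.default_rng(truth.seed)
    sigma = _background_sigma(truth)
    n_samples = truth.n_cancer + truth.n_control
    cancer_ids = [f"T{i + 1:03d}" for i in range(truth.n_cancer)]
    control_ids = [f"N{i + 1:03d}" for i in range(truth.n_control)]

    genes = [f"G{i + 1:04d}" for i in range(truth.n_genes)]
    planted_genes = []
    for p in truth.planted:
        for g in (p.gene_a, p.gene_b):
            if g not in genes and g not in planted_genes:
                planted_genes.append(g)
    all_genes = genes + planted_genes

    mu = rng.uniform(4.0, 10.0, size=len(all_genes))
    log2_values = mu[:, None] + rng.normal(0.0, sigma, size=(len(all_genes), n_samples))
    values = pd.DataFrame(
        np.exp2(log2_values), index=all_genes, columns=cancer_ids + control_ids
    )

    shift = np.log2(truth.fold_cutoff) + truth.shift_margin
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    cancer_cols = np.arange(truth.n_cancer)
    for p in truth.planted:
        k = int(round(p.fraction * truth.n_cancer))
        if p.fraction > 0 and k < 1:
            warnings.warn(
                f"planted fraction {p.fraction} yields no cancer sample at "
                f"n_cancer={truth.n_cancer}",
                stacklevel=2,
            )
        chosen = rng.choice(cancer_cols, size=k, replace=False)
        for gene, direction in zip((p.gene_a, p.gene_b), p.pattern):
            sign = 1.0 if direction == "u" else -1.0
            values.iloc[gene_pos[gene], chosen] *= 2.0 ** (sign * shift)

    labels = SampleLabels(
        pd.Series(
            ["cancer"] * truth.n_cancer + ["control"] * truth.n_control,
            index=cancer_ids + control_ids,
        )
    )
    pairs = [(p.gene_a, p.gene_b) for p in truth.planted]
    prov = ["planted"] * len(pairs)
    bg = [g for g in genes if g not in {x for pr in pairs for x in pr}]
    for i in range(min(truth.n_background_pairs, len(bg) // 2)):
        pairs.append((bg[2 * i], bg[2 * i + 1]))
        prov.append("background")
    return ExpressionMatrix(values), labels, SLPairTable(pairs, prov)


# ---------------------------------------------------------------------------
# IHC cohort + survival


@dataclass
class PlantedMarker:
    """A single or paired stain marker with planted risk prevalence and
    log hazard ratio."""

    stain_ids: tuple[str, ...]
    risk_pattern: tuple[str, ...]
    prevalence: float = 0.2
    log_hr: float = 0.0
    orientation: str = "risk"

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        self.risk_pattern = tuple(
            {"↑": OVER, "↓": UNDER, "up": OVER, "down": UNDER, OVER: OVER, UNDER: UNDER}[a]
            for a in self.risk_pattern
        )

    def definition(self) -> MarkerDefinition:
        return MarkerDefinition(self.stain_ids, self.risk_pattern, self.orientation)


@dataclass
class CohortTruth:
    """Ground truth for a synthetic IHC + survival cohort.

    Hazard for patient i is ``baseline_hazard · exp(Σ_m β_m · risk_m(i) +
    β_stage · late_stage(i))`` with exponential event times (per-month
    rates) and independent exponential censoring; stage probabilities mirror
    a predominantly early-stage oral-cancer cohort. ``stain_dependence`` is
    the pairwise latent (Gaussian copula) correlation between background
    stain calls.
    """

    n_patients: int = 160
    markers: list[PlantedMarker] = field(default_factory=list)
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.008
    stage_probs: tuple[float, float, float, float] = (0.43, 0.17, 0.13, 0.27)
    stage_log_hr: float = log(3.15)
    background_over_prevalence: float = 0.5
    stain_dependence: float = 0.0
    n_cores: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if not 0 <= self.stain_dependence < 1:
            raise ValueError("stain_dependence must be in [0, 1)")


def _percent_range(rule: CutoffRule) -> tuple[float, float] | None:
    """A percent interval consistent with a rule's percent atoms, or None."""
    low, high = 0.0, 100.0
    seen = False
    for atom in rule.atoms:
        if atom.quantity != "percent":
            continue
        seen = True
        if atom.op in (">", ">="):
            low = max(low, atom.threshold + (1.0 if atom.op == ">" else 0.0))
            high = min(100.0, low + 40.0)
        else:
            high = min(high, atom.threshold - (1.0 if atom.op == "<" else 0.0))
            high = max(high, 0.0)
    return (low, high) if seen else None


def _grades_for(rule: CutoffRule) -> list[float]:
    """Constant grades satisfying a rule's intensity atoms.

    All rules are conjunctions of one-sided thresholds, so any mean of
    grades drawn from this set satisfies the same atoms — core-level noise
    can therefore never flip the intended call.
    """
    grades = [
        g
        for g in GRADES
        if all(a.holds(g, None) for a in rule.atoms if a.quantity == "intensity")
    ]
    return grades if grades else list(GRADES)


def _score_rows(
    rng: np.random.Generator,
    patient: str,
    stain: StainDefinition,
    call: str,
    n_cores: int,
) -> list[dict]:
    rule = stain.over_rule if call == OVER else stain.under_rule
    grades = _grades_for(rule)
    pct_range = _percent_range(rule)
    rows = []
    for core in range(n_cores):
        pct = np.nan
        if pct_range is not None:
            lo, hi = pct_range
            pct = float(rng.uniform(lo, hi)) if hi > lo else lo
        rows.append(
            {
                "patient_id": patient,
                "stain_id": stain.stain_id,
                "core_id": f"core{core + 1}",
                "intensity": float(rng.choice(grades)),
                "percent": pct,
            }
        )
    return rows


def simulate_cohort(
    truth: CohortTruth, panel: Sequence[StainDefinition], with_scores: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (core score table, clinical table, true call table).

    Background stain calls are drawn from a Gaussian-copula threshold model
    at the configured over-prevalence and pairwise dependence. For each
    planted marker a Bernoulli(prevalence) indicator assigns its component
    calls: risk patients receive exactly the risk pattern, the rest a
    uniformly drawn non-matching pattern. Core grades are then sampled so the
    aggregated call always equals the intended call.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    by_id = {s.stain_id: s for s in panel}
    for m in truth.markers:
        for sid in m.stain_ids:
            if sid not in by_id:
                raise KeyError(f"planted marker references unknown stain {sid!r}")

    # background calls: latent factor model x = sqrt(rho) z + sqrt(1-rho) eps
    rho = truth.stain_dependence
    z = rng.normal(size=n)
    thresh = stats.norm.ppf(truth.background_over_prevalence)
    calls = pd.DataFrame(index=pd.Index(patients, name="patient_id"), dtype=object)
    for stain in panel:
        x = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=n)
        calls[stain.stain_id] = np.where(x < thresh, OVER, UNDER)

    # planted markers overwrite their component stains
    indicators: list[tuple[PlantedMarker, np.ndarray]] = []
    for m in truth.markers:
        ind = rng.random(n) < m.prevalence
        indicators.append((m, ind))
        k = len(m.stain_ids)
        patterns = [
            tuple(OVER if (j >> b) & 1 else UNDER for b in range(k))
            for j in range(2**k)
        ]
        non_risk = [p for p in patterns if p != tuple(m.risk_pattern)]
        for i in range(n):
            pattern = (
                tuple(m.risk_pattern)
                if ind[i]
                else non_risk[rng.integers(len(non_risk))]
            )
            for sid, c in zip(m.stain_ids, pattern):
                calls.iloc[i, calls.columns.get_loc(sid)] = c

    # core-level scores consistent with every call; replicate studies that
    # need only the calls can skip the (deterministically seeded) score draw
    rows = []
    score_rng = np.random.default_rng(rng.integers(2**31))
    if with_scores:
        for i, patient in enumerate(patients):
            for stain in panel:
                rows.extend(
                    _score_rows(score_rng, patient, stain, calls.iloc[i][stain.stain_id], truth.n_cores)
                )
    scores = pd.DataFrame(rows, columns=["patient_id", "stain_id", "core_id", "intensity", "percent"])

    # clinical covariates
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=np.array(truth.stage_probs) / sum(truth.stage_probs))
    late = np.isin(stage, ("III", "IV")).astype(float)
    lp = truth.stage_log_hr * late
    for m, ind in indicators:
        lp = lp + m.log_hr * ind
    rate = truth.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if truth.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / truth.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "time": np.maximum(time, 1e-3),
            "event": event,
            "stage": stage,
            "grade": rng.choice(["low", "intermediate", "high"], size=n, p=(0.43, 0.55, 0.02)),
            "ln_metastasis": rng.choice(["yes", "no"], size=n, p=(0.3, 0.7)),
            "age": np.round(rng.normal(55, 10, size=n), 1),
            "sex": rng.choice(["male", "female"], size=n, p=(0.9, 0.1)),
            "alcohol": rng.choice(["yes", "no"], size=n, p=(0.5, 0.5)),
            "betel": rng.choice(["yes", "no"], size=n, p=(0.6, 0.4)),
            "smoking": rng.choice(["yes", "no"], size=n, p=(0.7, 0.3)),
        }
    )
    return scores, clinical, calls
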