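"""Immunohistochemistry panel encoding, per-patient calls, and pair enumeration.

Each stain is a protein assayed in one cellular compartment — nucleus (N),
cytoplasm (C) or membrane (M) — scored per tissue core on the ordinal grade
scale 0 / ± / 1+ / 2+ / 3+ (coded 0, 0.5, 1, 2, 3) with an optional
percent-positive reading. Core scores are averaged per patient and a
stain-specific cutoff rule classifies the patient as over- or
under-expressing. The under- and over-rules of every stain partition the
score space: each aggregated score maps to exactly one call.

The default panel (29 stains over 21 proteins, 8 proteins assayed in two
compartments) ships with the package as ``data/ihc_panel_oscc.csv``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

GRADE_CODES = {"0": 0.0, "±": 0.5, "+-": 0.5, "+/-": 0.5, "1+": 1.0, "2+": 2.0, "3+": 3.0}
GRADES = (0.0, 0.5, 1.0, 2.0, 3.0)

OVER = "over"
UNDER = "under"

_ARROWS = {"↑": OVER, "up": OVER, OVER: OVER, "↓": UNDER, "down": UNDER, UNDER: UNDER}


# ---------------------------------------------------------------------------
# cutoff rules


@dataclass(frozen=True)
class RuleAtom:
    """One comparison against either the aggregated intensity grade or the
    aggregated percent-positive reading."""

    quantity: str  # "intensity" | "percent"
    op: str  # "<", "<=", ">", ">="
    threshold: float

    _OPS = {
        "<": np.less,
        "<=": np.less_equal,
        ">": np.greater,
        ">=": np.greater_equal,
    }

    def holds(self, intensity: float, percent: float | None) -> bool:
        if self.quantity == "percent":
            if percent is None or (isinstance(percent, float) and np.isnan(percent)):
                raise ValueError("rule references percent-positive but none was provided")
            value = percent
        else:
            value = intensity
        return bool(self._OPS[self.op](value, self.threshold))


@dataclass(frozen=True)
class CutoffRule:
    """Conjunction of rule atoms, e.g. '≥1+ and ≥10%'."""

    atoms: tuple[RuleAtom, ...]
    text: str

    def holds(self, intensity: float, percent: float | None = None) -> bool:
        return all(a.holds(intensity, percent) for a in self.atoms)

    @property
    def uses_percent(self) -> bool:
        return any(a.quantity == "percent" for a in self.atoms)


_ATOM_RE = re.compile(r"^(<=|>=|<|>)\s*([\d.]+)\s*(\+|%)?$")


def parse_rule(text: str) -> CutoffRule:
    """Parse a cutoff expression such as '<1+', '≤1+', '≥1+ and ≥10%', '>0%'.

    Unicode comparators (≤ ≦ ≥ ≧) are accepted; '1+' denotes the coded
    intensity grade 1 and '10%' a percent-positive threshold. Conjunctions
    are joined by 'and'. Raises ValueError on anything unparseable, so
    malformed panels fail at load time rather than call time.
    """
    norm = (
        text.replace("≦", "<=")
        .replace("≤", "<=")
        .replace("≧", ">=")
        .replace("≥", ">=")
        .strip()
    )
    atoms = []
    for part in re.split(r"\band\b|&", norm):
        part = part.replace(" ", "")
        if not part:
            raise ValueError(f"empty clause in rule {text!r}")
        m = _ATOM_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse cutoff rule {text!r} (clause {part!r})")
        op, value, suffix = m.groups()
        quantity = "percent" if suffix == "%" else "intensity"
        atoms.append(RuleAtom(quantity, op, float(value)))
    return CutoffRule(tuple(atoms), text)


# ---------------------------------------------------------------------------
# stains and markers


@dataclass(frozen=True)
class StainDefinition:
    """A protein assayed in one compartment, with its over/under cutoff rules."""

    stain_id: str  # e.g. "RB1(N)"
    protein: str
    compartment: str  # N | C | M
    under_rule: CutoffRule
    over_rule: CutoffRule

    def __post_init__(self) -> None:
        if self.compartment not in ("N", "C", "M"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def call(self, intensity: float, percent: float | None = None) -> str:
        """Over iff the over-rule holds; under otherwise.

        The complement semantics guarantees every score maps to exactly one
        call even for conjunctive rules whose stated under-clause leaves a
        gap (e.g. an 'intensity AND percent' over-rule where only the percent
        clause fails).
        """
        return OVER if self.over_rule.holds(intensity, percent) else UNDER

    def check_partition(self) -> None:
        """Verify the stated rules never both hold on a grid of plausible scores.

        Together with the over-else-under call semantics this ensures every
        score receives exactly one call and never a contradictory pair.
        """
        percents = np.arange(0.0, 100.1, 5.0)
        for grade in np.arange(0.0, 3.01, 0.25):
            for pct in percents if (self.over_rule.uses_percent or self.under_rule.uses_percent) else [None]:
                if self.over_rule.holds(grade, pct) and self.under_rule.holds(grade, pct):
                    raise ValueError(
                        f"{self.stain_id}: over and under rules overlap at "
                        f"grade={grade}, percent={pct}"
                    )


@dataclass(frozen=True)
class MarkerDefinition:
    """A single stain or ordered stain pair with a risk direction pattern.

    ``risk_pattern`` gives, per stain, the call ('over'/'under', arrows ↑/↓
    accepted) that places a patient in the risk group; the marker partitions
    patients into that group versus "otherwise". ``orientation`` records
    whether the risk group carries excess hazard ('risk') or reduced hazard
    ('protective') — protective markers contribute their complement when
    combined with others.
    """

    stain_ids: tuple[str, ...]
    risk_pattern: tuple[str, ...]
    orientation: str = "risk"

    def __post_init__(self) -> None:
        if len(self.stain_ids) not in (1, 2):
            raise ValueError("markers are single stains or stain pairs")
        if len(self.risk_pattern) != len(self.stain_ids):
            raise ValueError("risk_pattern length must match number of stains")
        object.__setattr__(
            self, "risk_pattern", tuple(_ARROWS[a] for a in self.risk_pattern)
        )
        if self.orientation not in ("risk", "protective"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def arity(self) -> int:
        return len(self.stain_ids)

    def label(self) -> str:
        arrows = {OVER: "↑", UNDER: "↓"}
        return "-".join(f"{s}{arrows[p]}" for s, p in zip(self.stain_ids, self.risk_pattern))


def parse_marker_label(label: str) -> MarkerDefinition:
    """Inverse of :meth:`MarkerDefinition.label`, e.g. 'CSNK1E(C)↓-SHC1(N)↓'."""
    stain_ids, pattern = [], []
    for token in label.split("-"):
        token = token.strip()
        if not token or token[-1] not in "↑↓":
            raise ValueError(f"cannot parse marker label {label!r}")
        stain_ids.append(token[:-1])
        pattern.append(token[-1])
    return MarkerDefinition(tuple(stain_ids), tuple(pattern))


# ---------------------------------------------------------------------------
# panel IO


def load_panel(path=None) -> list[StainDefinition]:
    """Load a stain panel CSV (stain_id, protein, compartment, under_rule,
    over_rule); with no path, the packaged default 29-stain OSCC panel."""
    if path is None:
        ref = resources.files("slmarker").joinpath("data/ihc_panel_oscc.csv")
        with ref.open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    stains = []
    for row in df.itertuples(index=False):
        stain = StainDefinition(
            stain_id=row.stain_id,
            protein=row.protein,
            compartment=row.compartment,
            under_rule=parse_rule(row.under_rule),
            over_rule=parse_rule(row.over_rule),
        )
        stain.check_partition()
        stains.append(stain)
    ids = [s.stain_id for s in stains]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stain_id in panel")
    return stains


# ---------------------------------------------------------------------------
# scoring


def _code_grade(value) -> float:
    if isinstance(value, str):
        v = value.strip()
        if v in GRADE_CODES:
            return GRADE_CODES[v]
        value = float(v)
    value = float(value)
    if value not in GRADES:
        raise ValueError(f"intensity grade {value} not in the five-level scale {GRADES}")
    return value


def read_scores(path) -> pd.DataFrame:
    """Read an IHC score CSV (patient_id, stain_id, core_id, intensity, percent)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "stain_id": str})
    df["intensity"] = df["intensity"].map(_code_grade)
    if "percent" not in df.columns:
        df["percent"] = np.nan
    return df


def aggregate_cores(scores: pd.DataFrame) -> tuple[float, float]:
    """Mean coded intensity (and mean percent) over a patient's cancerous cores.

    ``scores`` holds the rows for one patient × stain; typically three cores
    are available but tissue loss is routine, so any positive number is
    accepted. Returns (mean intensity, mean percent); percent is NaN when
    absent.
    """
    if len(scores) == 0:
        raise ValueError("no core scores to aggregate")
    intensity = float(np.mean([_code_grade(v) for v in scores["intensity"]]))
    if "percent" in scores.columns and scores["percent"].notna().any():
        percent = float(scores["percent"].dropna().astype(float).mean())
    else:
        percent = float("nan")
    return intensity, percent


def apply_cutoff(intensity: float, stain: StainDefinition, percent: float | None = None):
    """Classify one aggregated score as over/under by the stain's rules."""
    call = stain.call(intensity, percent)
    return call


def call_stains(scores: pd.DataFrame, panel: Sequence[StainDefinition]) -> pd.DataFrame:
    """Patient × stain over/under calls from a long-format core score table.

    Patients without any core for a stain are left missing for that stain
    (complete-case handling happens marker-wise downstream).
    """
    by_stain = {s.stain_id: s for s in panel}
    records = []
    for (patient, stain_id), grp in scores.groupby(["patient_id", "stain_id"], sort=True):
        stain = by_stain.get(stain_id)
        if stain is None:
            continue
        intensity, percent = aggregate_cores(grp)
        pct = None if np.isnan(percent) else percent
        records.append({"patient_id": patient, "stain_id": stain_id, "call": stain.call(intensity, pct)})
    calls = pd.DataFrame(records)
    return calls.pivot(index="patient_id", columns="stain_id", values="call")


def enumerate_stain_pairs(
    stains: Sequence[StainDefinition],
) -> list[tuple[StainDefinition, StainDefinition]]:
    """All unordered stain pairs, excluding pairs of the same protein.

    For n stains over proteins with multiplicities k_p the count is
    C(n, 2) − Σ_p C(k_p, 2); the default 29-stain panel yields 398 pairs.
    """
    ids = [s.stain_id for s in stains]
    if len(set(ids)) != len(ids):
        raise ValueError("stain_ids must be unique")
    return [(a, b) for a, b in combinations(stains, 2) if a.protein != b.protein]


def marker_membership(calls: pd.DataFrame, marker: MarkerDefinition) -> pd.Series:
    """Binary risk-group indicator per patient (1 = matches the full risk pattern).

    Patients missing any component call are dropped (complete-case per
    marker).
    """
    missing = [s for s in marker.stain_ids if s not in calls.columns]
    if missing:
        raise KeyError(f"stains not present in call table: {missing}")
    sub = calls[list(marker.stain_ids)].dropna()
    ind = np.ones(len(sub), dtype=int)
    for stain_id, wanted in zip(marker.stain_ids, marker.risk_pattern):
        ind &= (sub[stain_id] == wanted).to_numpy(dtype=int)
    return pd.Series(ind, index=sub.index, name=marker.label())
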