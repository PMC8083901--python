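"""Expression-based screening of synthetic-lethal gene pairs.

The screen takes a linear-scale expression matrix (genes × samples, with a
cancer/control label per sample) and a list of candidate gene pairs, and
produces per-pair joint regulation "pattern fractions" with permutation
p-values and Storey q-values.

Pipeline: quantile normalization → per-cancer-sample log2 ratio against the
averaged controls → three-level regulation call at a fold-change cutoff →
ordered-pattern fractions over cancer samples → permutation null obtained by
rearranging which samples play the role of controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .qvalue import storey_qvalues

PATTERNS = ("uu", "ud", "du", "dd")
Pattern = Literal["uu", "ud", "du", "dd"]

CANCER = "cancer"
CONTROL = "control"


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Linear-scale intensities, genes × samples.

    ``values`` is a DataFrame indexed by gene symbol with sample identifiers
    as columns. Duplicate gene or sample identifiers are rejected; all
    entries must be finite and strictly positive (log ratios are taken
    downstream).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr <= 0).any():
            raise ValueError("expression matrix must be strictly positive (linear scale)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        """Read a tab-separated matrix: first column gene symbol, header row sample IDs."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class SampleLabels:
    """Mapping of sample identifier to 'cancer' or 'control'."""

    labels: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {CANCER, CONTROL}
        if bad:
            raise ValueError(f"unknown sample labels: {sorted(bad)}")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        for cls_ in (CANCER, CONTROL):
            if sum(self.labels.get(s) == cls_ for s in matrix.sample_ids) < 2:
                raise ValueError(f"need at least 2 '{cls_}' samples")

    def samples_of(self, cls_: str, sample_ids: Sequence[str]) -> list[str]:
        return [s for s in sample_ids if self.labels.get(s) == cls_]

    @classmethod
    def read_tsv(cls, path) -> "SampleLabels":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
        if df["sample_id"].iloc[0] == "sample_id":  # tolerate a header row
            df = df.iloc[1:]
        return cls(pd.Series(df["label"].values, index=df["sample_id"].values))

    def write_tsv(self, path) -> None:
        self.labels.rename_axis("sample_id").rename("label").to_csv(path, sep="\t", header=False)


@dataclass
class LogRatioMatrix:
    """log2(cancer intensity / mean control intensity), genes × cancer samples."""

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cancer_sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RegulationCalls:
    """Three-level regulation calls per (gene, cancer sample).

    ``calls`` holds +1 (up), -1 (down) or 0 (neutral): up iff the log2 ratio
    is ≥ log2(fold_cutoff), down iff ≤ -log2(fold_cutoff), inclusive at the
    boundary.
    """

    calls: pd.DataFrame  # int8, genes × cancer samples
    fold_cutoff: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def cancer_sample_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class SLPairTable:
    """Candidate (gene_a, gene_b) pairs, e.g. literature-collected synthetic-lethal pairs.

    Self-pairs are rejected; unordered duplicates are collapsed keeping the
    first orientation seen.
    """

    pairs: list[tuple[str, str]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.provenance and len(self.provenance) != len(self.pairs):
            raise ValueError("provenance must align with pairs")
        seen: set[frozenset] = set()
        pairs, prov = [], []
        for i, (a, b) in enumerate(self.pairs):
            if a == b:
                raise ValueError(f"self-pair not allowed: {a}")
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((a, b))
            prov.append(self.provenance[i] if self.provenance else "")
        self.pairs = pairs
        self.provenance = prov

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @classmethod
    def read_tsv(cls, path) -> "SLPairTable":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.iloc[0, 0] in ("gene_a", "geneA"):
            df = df.iloc[1:]
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        prov = list(df.iloc[:, 2]) if df.shape[1] > 2 else []
        return cls(pairs, [("" if pd.isna(p) else p) for p in prov])

    def write_tsv(self, path) -> None:
        rows = [
            (a, b, self.provenance[i] if self.provenance else "")
            for i, (a, b) in enumerate(self.pairs)
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance"]).to_csv(
            path, sep="\t", index=False, header=False
        )


@dataclass
class PatternFractionRecord:
    """Per-pair joint-pattern fractions, with optional permutation p / q values.

    ``f_uu`` is the fraction of cancer samples in which gene_a is called up
    and gene_b up, and so on; samples where either gene is neutral count only
    in the denominator, so the four fractions sum to at most 1.
    """

    gene_a: str
    gene_b: str
    f_uu: float
    f_ud: float
    f_du: float
    f_dd: float
    n_samples: int
    p_perm: dict[str, float] = field(default_factory=dict)
    q_value: dict[str, float] = field(default_factory=dict)

    def fraction(self, pattern: Pattern) -> float:
        return getattr(self, f"f_{pattern}")


# ---------------------------------------------------------------------------
# operations


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common distribution of sorted-row means.

    Each column's values are replaced, rank for rank, by the across-column
    mean of the sorted columns; within-column order is preserved and every
    column ends up with the identical sorted multiset. Ties are resolved by
    stable sort position, which makes the operation exactly idempotent.
    """
    v = matrix.values
    arr = v.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("cannot quantile-normalize non-finite values")
    if arr.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is a no-op", stacklevel=2)
        return ExpressionMatrix(v.copy())
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.take_along_axis(arr, order, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    np.put_along_axis(out, order, ref[:, None], axis=0)
    return ExpressionMatrix(pd.DataFrame(out, index=v.index, columns=v.columns))


def log_ratio_vs_controls(matrix: ExpressionMatrix, labels: SampleLabels) -> LogRatioMatrix:
    """log2 ratio of each cancer sample against the mean of control samples.

    The control average is taken on the linear intensity scale, then logged,
    and the result is restricted to cancer columns.
    """
    labels.validate_against(matrix)
    v = matrix.values
    cancer = labels.samples_of(CANCER, matrix.sample_ids)
    control = labels.samples_of(CONTROL, matrix.sample_ids)
    if not control:
        raise ValueError("no control samples")
    ctrl_mean = v[control].mean(axis=1)
    bad = ctrl_mean[ctrl_mean <= 0]
    if len(bad):
        raise ValueError(f"non-positive control mean for gene(s): {list(bad.index[:5])}")
    ratios = np.log2(v[cancer].div(ctrl_mean, axis=0))
    return LogRatioMatrix(ratios)


def call_regulation(ratios: LogRatioMatrix, fold_cutoff: float = 1.5) -> RegulationCalls:
    """Three-level up/down/neutral call at a linear fold-change cutoff (inclusive)."""
    if fold_cutoff <= 1:
        raise ValueError(f"fold_cutoff must be > 1, got {fold_cutoff}")
    c = np.log2(fold_cutoff)
    arr = ratios.values.to_numpy(dtype=float)
    calls = np.zeros(arr.shape, dtype=np.int8)
    calls[arr >= c] = 1
    calls[arr <= -c] = -1
    return RegulationCalls(
        pd.DataFrame(calls, index=ratios.values.index, columns=ratios.values.columns),
        fold_cutoff,
    )


def pattern_fractions(calls: RegulationCalls, pair: tuple[str, str]) -> PatternFractionRecord:
    """Fractions of cancer samples showing each ordered joint regulation pattern.

    Neutral-containing samples contribute only to the denominator, so
    f_uu + f_ud + f_du + f_dd ≤ 1.
    """
    a, b = pair
    for g in (a, b):
        if g not in calls.calls.index:
            raise KeyError(f"gene not present in regulation calls: {g}")
    ca = calls.calls.loc[a].to_numpy()
    cb = calls.calls.loc[b].to_numpy()
    n = len(ca)
    f = {
        "uu": float(np.mean((ca == 1) & (cb == 1))),
        "ud": float(np.mean((ca == 1) & (cb == -1))),
        "du": float(np.mean((ca == -1) & (cb == 1))),
        "dd": float(np.mean((ca == -1) & (cb == -1))),
    }
    return PatternFractionRecord(a, b, f["uu"], f["ud"], f["du"], f["dd"], n)


def _fractions_for_control_sets(
    a: np.ndarray, b: np.ndarray, control_idx: np.ndarray, pattern: Pattern, fold_cutoff: float
) -> np.ndarray:
    """Pattern fraction for each row of ``control_idx`` (a P × k matrix of
    column indices designating which samples act as controls); the complement
    of each control set plays the role of the cancer samples."""
    n = a.size
    P, k = control_idx.shape
    c = np.log2(fold_cutoff)
    mask = np.zeros((P, n), dtype=bool)
    np.put_along_axis(mask, control_idx, True, axis=1)
    cmean_a = (a[None, :] * mask).sum(axis=1) / k
    cmean_b = (b[None, :] * mask).sum(axis=1) / k
    ra = np.log2(a[None, :] / cmean_a[:, None])
    rb = np.log2(b[None, :] / cmean_b[:, None])
    dir_a, dir_b = pattern
    hit_a = ra >= c if dir_a == "u" else ra <= -c
    hit_b = rb >= c if dir_b == "u" else rb <= -c
    hits = hit_a & hit_b & ~mask
    return hits.sum(axis=1) / (n - k)


def permutation_pvalue(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    pair: tuple[str, str],
    pattern: Pattern,
    n_perm: int = 10_000,
    seed: int | None = None,
    fold_cutoff: float = 1.5,
    method: Literal["monte-carlo", "exhaustive"] = "monte-carlo",
) -> float:
    """Upper-tail permutation p-value for one pair's pattern fraction.

    Each rearrangement re-assigns which samples form the control set (keeping
    the class sizes), recomputes the log ratios, regulation calls and pattern
    fraction over the new cancer set, and the p-value is the add-one-corrected
    upper tail: ``(1 + #{permuted ≥ observed}) / (n_perm + 1)``. With
    ``method="exhaustive"`` every possible control set is enumerated instead
    and the p-value is the exact proportion ``#{≥ observed} / #sets``.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels.validate_against(matrix)
    sample_ids = matrix.sample_ids
    control = labels.samples_of(CONTROL, sample_ids)
    n, k = len(sample_ids), len(control)
    if not 0 < k < n:
        raise ValueError(f"degenerate class sizes: {k} controls of {n} samples")

    a = matrix.values.loc[pair[0]].to_numpy(dtype=float)
    b = matrix.values.loc[pair[1]].to_numpy(dtype=float)
    obs_idx = np.array([sample_ids.index(s) for s in control])[None, :]
    observed = _fractions_for_control_sets(a, b, obs_idx, pattern, fold_cutoff)[0]

    if method == "exhaustive":
        idx = np.array(list(combinations(range(n), k)))
        frac = _fractions_for_control_sets(a, b, idx, pattern, fold_cutoff)
        return float(np.mean(frac >= observed - 1e-12))
    rng = np.random.default_rng(seed)
    # first k positions of a random permutation give a uniform control set
    keys = rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1)[:, :k]
    frac = _fractions_for_control_sets(a, b, idx, pattern, fold_cutoff)
    exceed = int(np.sum(frac >= observed - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def screen_sl_pairs(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    pairs: SLPairTable,
    fold_cutoff: float = 1.5,
    n_perm: int = 10_000,
    seed: int | None = None,
    tested_patterns: Sequence[Pattern] = ("uu", "du"),
    normalize: bool = True,
) -> list[PatternFractionRecord]:
    """Run the full expression screen over a pair list.

    Computes pattern fractions for every pair, permutation p-values for the
    tested patterns (by default the concordant-up and discordant down-up
    patterns), and Storey q-values per tested pattern across pairs. Pairs
    whose genes are absent from the matrix are silently dropped.
    """
    if normalize:
        matrix = quantile_normalize(matrix)
    ratios = log_ratio_vs_controls(matrix, labels)
    calls = call_regulation(ratios, fold_cutoff)
    present = set(matrix.gene_ids)
    records = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        if a not in present or b not in present:
            continue
        rec = pattern_fractions(calls, (a, b))
        for pat in tested_patterns:
            rec.p_perm[pat] = permutation_pvalue(
                matrix,
                labels,
                (a, b),
                pat,
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
                fold_cutoff=fold_cutoff,
            )
        records.append(rec)
    for pat in tested_patterns:
        qs = storey_qvalues(np.array([r.p_perm[pat] for r in records]))
        for r, q in zip(records, qs):
            r.q_value[pat] = float(q)
    return records


def select_initial_panel(
    records: Iterable[PatternFractionRecord],
    threshold: float = 0.15,
    kras_threshold: float = 0.25,
    include_list: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Select the initial pair panel by pattern-fraction thresholds.

    A pair qualifies when max(f_uu, f_du) ≥ ``threshold``; pairs containing
    KRAS must reach the stricter ``kras_threshold`` to qualify through their
    (down, up) fraction (their (up, up) route uses the ordinary threshold).
    ``include_list`` pairs are appended regardless, flagged "prior-knowledge".
    Returns the full table with ``selected`` and ``reason`` columns.
    """
    for name, t in (("threshold", threshold), ("kras_threshold", kras_threshold)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    include = {frozenset(p) for p in include_list}
    rows = []
    for r in records:
        is_kras = "KRAS" in (r.gene_a, r.gene_b)
        reasons = []
        if r.f_uu >= threshold:
            reasons.append("f_uu")
        du_thresh = kras_threshold if is_kras else threshold
        if r.f_du >= du_thresh:
            reasons.append("f_du")
        if frozenset((r.gene_a, r.gene_b)) in include:
            reasons.append("prior-knowledge")
        rows.append(
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "f_uu": r.f_uu,
                "f_ud": r.f_ud,
                "f_du": r.f_du,
                "f_dd": r.f_dd,
                "p_uu": r.p_perm.get("uu", np.nan),
                "p_du": r.p_perm.get("du", np.nan),
                "q_uu": r.q_value.get("uu", np.nan),
                "q_du": r.q_value.get("du", np.nan),
                "selected": bool(reasons),
                "reason": "+".join(reasons),
            }
        )
    return pd.DataFrame(rows)
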