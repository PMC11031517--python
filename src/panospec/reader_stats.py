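"""Ordinal reader-score aggregation and Wilcoxon signed-rank comparisons.

A reader study scores each simulated image modality (conventional PAN,
virtual monoenergetic images, material thickness images) per case and
criterion on a 1-5 ordinal scale.  This module validates the long-format
score table, aggregates per-reader means/SDs and across-reader averages, and
compares every spectral modality against the conventional-PAN baseline with a
paired Wilcoxon signed-rank test.

The test follows the classical convention also used by mainstream statistics
packages: zero differences are dropped (n adjusted), ties in |d| get
mid-ranks, W = min(W+, W-).  The two-sided p-value is exact for n <= 15 —
computed by enumerating all sign assignments conditionally on the observed
mid-ranks — and otherwise uses the normal approximation with tie and
continuity corrections.  No multiplicity correction is applied by default; a
Holm or Bonferroni switch is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

MODALITIES = ("PAN", "PVMI40", "PVMI60", "PETI_BONE", "PETI_COMBO")
CRITERIA = (
    "bone_quality",
    "detail_visualization",
    "artefacts",
    "overall_quality",
    "diagnostic_acceptability",
)
_COLUMNS = ("reader", "case", "modality", "criterion", "score")


@dataclass
class ReaderScoreTable:
    """Validated long-format table of ordinal 1-5 scores."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"score table is missing columns: {missing}")
        df = df.loc[:, list(_COLUMNS)].copy()
        bad_modality = ~df["modality"].isin(MODALITIES)
        if bad_modality.any():
            raise ValueError(f"unknown modality values in rows {list(df.index[bad_modality])}")
        bad_criterion = ~df["criterion"].isin(CRITERIA)
        if bad_criterion.any():
            raise ValueError(f"unknown criterion values in rows {list(df.index[bad_criterion])}")
        scores = pd.to_numeric(df["score"], errors="coerce")
        bad_score = scores.isna() | (scores != scores.round()) | (scores < 1) | (scores > 5)
        if bad_score.any():
            raise ValueError(f"scores must be integers 1..5; invalid rows {list(df.index[bad_score])}")
        df["score"] = scores.astype(int)
        dup = df.duplicated(subset=["reader", "case", "modality", "criterion"])
        if dup.any():
            raise ValueError(f"duplicate (reader, case, modality, criterion) keys in rows {list(df.index[dup])}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def load_scores(path) -> ReaderScoreTable:
    """Read and validate a reader-score CSV (reader,case,modality,criterion,score)."""
    return ReaderScoreTable(pd.read_csv(path))


@dataclass
class AggregateResult:
    """Per-reader means/SDs, across-reader averages, per-modality totals."""

    per_reader: pd.DataFrame       # index (modality, criterion, reader): mean, sd
    average: pd.DataFrame          # index (modality, criterion): average score
    total_points: pd.Series        # per modality: sum of reader means over criteria


def aggregate_scores(table: ReaderScoreTable) -> AggregateResult:
    """Aggregate a score table the way reader-study summary tables are built.

    The across-reader average is the unweighted mean of the per-reader means
    (readers score equal case counts), and a modality's total points is the
    sum of all per-reader means over the criteria — out of
    ``5 * n_criteria * n_readers`` possible points.
    """
    df = table.records
    if df.empty:
        raise ValueError("score table is empty")
    per_reader = (
        df.groupby(["modality", "criterion", "reader"], sort=False)["score"]
        .agg(mean="mean", sd="std")
        .sort_index()
    )
    average = (
        per_reader["mean"].groupby(level=["modality", "criterion"]).mean().to_frame("average")
    )
    total_points = per_reader["mean"].groupby(level="modality").sum()
    return AggregateResult(per_reader, average, total_points)


@dataclass
class TestResult:
    """Outcome of one paired signed-rank comparison against the baseline."""

    label: str
    statistic: float               # W = min(W+, W-)
    p_value: float
    n: int                         # pairs after zero removal
    direction: str                 # 'positive' | 'negative' | 'tied'
    method: str = ""
    significant: bool | None = None
    untestable: bool = False


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| for the nonzero differences d."""
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(len(d), dtype=float)
    sorted_abs = absd[order]
    i = 0
    while i < len(d):
        j = i
        while j + 1 < len(d) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks, absd


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """P(|W+ - mu| >= |w_plus - mu|) under random sign flips of the ranks.

    The null distribution of W+ is built by convolution over the (doubled,
    hence integer) mid-ranks; exact, including tied |d|.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = np.rint(2.0 * w_plus).astype(np.int64)
    mu2 = total / 2.0
    dev = abs(w2 - mu2)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu2) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(x, y, exact_max_n: int = 15) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test of x against y.

    Zero differences are removed.  For n <= ``exact_max_n`` the p-value is
    exact by sign-flip enumeration on the observed mid-ranks; for larger n the
    normal approximation with tie correction and a 0.5 continuity correction
    is used.  Raises if every pair is tied rather than returning p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero pairs: all paired differences are zero")
    ranks, _ = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if w_plus > w_minus:
        direction = "positive"
    elif w_plus < w_minus:
        direction = "negative"
    else:
        direction = "tied"

    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction over groups of tied |d|
        _, counts = np.unique(np.abs(d), return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        if var <= 0:
            raise ValueError("zero variance after tie correction")
        dev = abs(w_plus - mu)
        z = max(dev - 0.5, 0.0) / math.sqrt(var)
        p = float(2.0 * norm.sf(z))
        method = "normal-approx"
    return TestResult(
        label="x vs y",
        statistic=w,
        p_value=min(p, 1.0),
        n=n,
        direction=direction,
        method=method,
    )


def compare_modalities(
    table: ReaderScoreTable,
    baseline: str = "PAN",
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[TestResult]:
    """Signed-rank tests of every non-baseline modality against the baseline.

    Scores are paired by (reader, case) within each criterion.  Comparisons in
    which every pair is tied are returned flagged ``untestable`` instead of a
    p-value.  ``correction`` may be ``'holm'`` or ``'bonferroni'``; by default
    raw p-values are compared to ``alpha``.
    """
    df = table.records
    if baseline not in set(df["modality"]):
        raise ValueError(f"baseline modality {baseline!r} not present in table")
    if correction not in (None, "holm", "bonferroni"):
        raise ValueError("correction must be None, 'holm' or 'bonferroni'")

    results: list[TestResult] = []
    others = [m for m in MODALITIES if m != baseline and m in set(df["modality"])]
    wide = df.set_index(["modality", "criterion", "reader", "case"])["score"].sort_index()
    for modality in others:
        for criterion in CRITERIA:
            try:
                base = wide.loc[(baseline, criterion)]
                alt = wide.loc[(modality, criterion)]
            except KeyError:
                continue
            missing = base.index.symmetric_difference(alt.index)
            if len(missing):
                raise ValueError(
                    f"unpaired (reader, case) keys for {modality}/{criterion}: {list(missing)}"
                )
            alt = alt.reindex(base.index)
            label = f"{modality} vs {baseline} [{criterion}]"
            try:
                res = wilcoxon_signed_rank(alt.to_numpy(), base.to_numpy())
            except ValueError as err:
                if "no nonzero pairs" in str(err):
                    results.append(
                        TestResult(label, math.nan, math.nan, 0, "tied", "exact", None, True)
                    )
                    continue
                raise
            res.label = label
            results.append(res)

    testable = [r for r in results if not r.untestable]
    if correction is None:
        for r in testable:
            r.significant = r.p_value < alpha
    elif correction == "bonferroni":
        for r in testable:
            r.significant = r.p_value * len(testable) < alpha
    else:  # holm
        order = np.argsort([r.p_value for r in testable])
        m = len(testable)
        running = True
        for rank, idx in enumerate(order):
            r = testable[idx]
            running = running and (r.p_value * (m - rank) < alpha)
            r.significant = running
    return results


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Results as a tidy DataFrame (one row per comparison)."""
    return pd.DataFrame(
        {
            "comparison": [r.label for r in results],
            "W": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
            "untestable": [r.untestable for r in results],
        }
    )


def simulate_scores(
    n_readers: int = 3,
    n_cases: int = 17,
    baseline_probs=(0.05, 0.15, 0.35, 0.30, 0.15),
    modality_shift: dict[str, int] | None = None,
    seed: int = 0,
) -> ReaderScoreTable:
    """Simulate an ordinal score table for end-to-end statistics testing.

    Baseline (PAN) scores are drawn per (reader, case, criterion) from the
    categorical distribution ``baseline_probs`` over 1..5.  A modality listed
    in ``modality_shift`` scores the baseline value plus its ordinal shift,
    clipped to [1, 5] (shift coupling: all paired differences share the sign
    of the shift); any other modality draws independently from the same
    distribution.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(baseline_probs, dtype=float)
    if probs.shape != (5,) or probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("baseline_probs must be 5 non-negative values summing to 1")
    modality_shift = modality_shift or {}
    rows = []
    for reader in range(1, n_readers + 1):
        for case in range(1, n_cases + 1):
            for criterion in CRITERIA:
                base = int(rng.choice(5, p=probs)) + 1
                for modality in MODALITIES:
                    if modality == "PAN":
                        score = base
                    elif modality in modality_shift:
                        score = int(np.clip(base + modality_shift[modality], 1, 5))
                    else:
                        score = int(rng.choice(5, p=probs)) + 1
                    rows.append((f"R{reader}", f"C{case:02d}", modality, criterion, score))
    return ReaderScoreTable(pd.DataFrame(rows, columns=list(_COLUMNS)))
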