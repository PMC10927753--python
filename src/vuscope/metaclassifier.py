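"""Majority-vote pathogenicity classification from per-predictor verdicts.

A variant carries one verdict (benign ``B``, pathogenic ``P``, or missing
``NA``) from each of 15 established missense predictors.  The benign rate
``B/(B+P)`` over the non-missing verdicts is compared to a mode-specific
threshold: at or below the threshold the ensemble calls the variant
pathogenic, above it the call stays "uncertain significance" (VUS).  Three
operating modes trade sensitivity against false-positive rate via their
thresholds (high-coverage 0.40, intermediate 0.24, low-FPR 0.08).

The numeric predictor scores are carried as metadata only: the verdicts are
issued upstream against per-predictor optimized cutoffs that are not
reproducible from a single global score threshold, so verdicts are explicit
inputs here, never derived from scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .utils import round_half_up

#: Canonical predictor order; input tables must provide exactly these 15.
PREDICTORS: tuple[str, ...] = (
    "SIFT", "PolyPhen2", "LRT", "MutationTaster", "MutationAssessor",
    "PROVEAN", "MetaSVM", "M-CAP", "Revel", "MutPred", "MVP", "DEOGEN2",
    "ClinPred", "LIST-S2", "CADD",
)

VERDICTS = ("B", "P", "NA")

#: Operating modes, ordered from most permissive threshold to strictest.
MODES = ("high_coverage", "intermediate", "low_fpr")


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


class UndefinedRateError(ValueError):
    """Raised when every predictor verdict is missing for a variant."""


@dataclass(frozen=True)
class PredictorEntry:
    predictor_name: str
    verdict: str               # "B" | "P" | "NA"
    score: Optional[float] = None

    def __post_init__(self):
        if self.predictor_name not in PREDICTORS:
            raise FormatError(f"unknown predictor {self.predictor_name!r}")
        if self.verdict not in VERDICTS:
            raise FormatError(
                f"verdict must be B/P/NA, got {self.verdict!r} "
                f"for {self.predictor_name}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise FormatError(f"score out of [0,1]: {self.score}")


@dataclass(frozen=True)
class VariantScoreSet:
    """One variant's 15 predictor verdicts (one table row)."""

    variant_id: str            # protein-level label, e.g. "P471L"
    cdna: str                  # HGVS c. string, e.g. "c.1412C>T"
    entries: tuple[PredictorEntry, ...] = ()

    def __post_init__(self):
        names = [e.predictor_name for e in self.entries]
        if tuple(names) != tuple(PREDICTORS):
            raise FormatError(
                f"{self.variant_id}: expected the 15 canonical predictors in "
                f"order, got {len(names)}")

    def counts(self) -> tuple[int, int, int]:
        """(n_benign, n_pathogenic, n_na)."""
        v = [e.verdict for e in self.entries]
        return v.count("B"), v.count("P"), v.count("NA")


@dataclass(frozen=True)
class ModeThresholds:
    """P-to-VUS thresholds for the three operating modes.

    ``reported_fpr`` is descriptive metadata (the false-positive rates quoted
    for the stricter modes); it never enters the classification.
    """

    high_coverage: float = 0.40
    intermediate: float = 0.24
    low_fpr: float = 0.08
    reported_fpr: dict = field(
        default_factory=lambda: {"low_fpr": 11.5, "intermediate": 20.0})

    def __post_init__(self):
        if not (self.high_coverage > self.intermediate > self.low_fpr > 0):
            raise ValueError("thresholds must satisfy high > intermediate > low > 0")

    def threshold(self, mode: str) -> float:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        return getattr(self, mode)


@dataclass(frozen=True)
class ClassificationResult:
    variant_id: str
    n_benign: int
    n_pathogenic: int
    n_na: int
    rate: float                       # unrounded B/(B+P)
    verdict_per_mode: dict            # mode -> "P" | "VUS"

    @property
    def rate_2dp(self) -> float:
        return round_half_up(self.rate, 2)


def compute_rate(scores: VariantScoreSet) -> float:
    """Benign rate B/(B+P); NA verdicts drop out of both counts.

    The returned value is unrounded; use :func:`ClassificationResult.rate_2dp`
    or :func:`vuscope.utils.round_half_up` for 2-dp display.
    """
    n_b, n_p, _ = scores.counts()
    if n_b + n_p == 0:
        raise UndefinedRateError(
            f"{scores.variant_id}: all 15 verdicts are NA, rate undefined")
    return n_b / (n_b + n_p)


def classify(rate: float, thresholds: ModeThresholds, mode: str) -> str:
    """Mode verdict: ``P`` if rate <= threshold(mode), else ``VUS``.

    A rate exactly at the threshold calls P: classification uses the
    unrounded rate, and a 1/15 benign rate (0.0667) must stay pathogenic at
    the 0.08 low-FPR threshold.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate out of [0,1]: {rate}")
    return "P" if rate <= thresholds.threshold(mode) else "VUS"


def classify_all(table: Sequence[VariantScoreSet],
                 thresholds: ModeThresholds | None = None,
                 ) -> list[ClassificationResult]:
    """Classify every variant under all three modes, preserving input order."""
    if not table:
        raise ValueError("empty variant table")
    thresholds = thresholds or ModeThresholds()
    out = []
    for vs in table:
        n_b, n_p, n_na = vs.counts()
        try:
            rate = compute_rate(vs)
        except UndefinedRateError:
            raise
        verdicts = {m: classify(rate, thresholds, m) for m in MODES}
        out.append(ClassificationResult(
            variant_id=vs.variant_id, n_benign=n_b, n_pathogenic=n_p,
            n_na=n_na, rate=rate, verdict_per_mode=verdicts))
    return out


# ---------------------------------------------------------------------------
# I/O

def parse_predictor_table(path: str | Path) -> list[VariantScoreSet]:
    """Read a predictor-verdict TSV into VariantScoreSets.

    Dialect: columns ``variant_id``, ``cdna``, then ``<predictor>_verdict``
    (B|P|NA) and ``<predictor>_score`` for each of the 15 canonical
    predictors.  Scores may be blank/NA.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        return []
    required = ["variant_id", "cdna"]
    verdict_cols = [f"{p}_verdict" for p in PREDICTORS]
    missing = [c for c in required + verdict_cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    extra_verdicts = [c for c in df.columns
                      if c.endswith("_verdict") and c not in verdict_cols]
    if extra_verdicts:
        raise FormatError(f"unknown predictor columns: {extra_verdicts}")
    out = []
    for _, row in df.iterrows():
        entries = []
        for p in PREDICTORS:
            verdict = row[f"{p}_verdict"].strip()
            raw_score = row.get(f"{p}_score", "")
            raw_score = raw_score.strip() if isinstance(raw_score, str) else ""
            score = None if raw_score in ("", "NA", "nan") else float(raw_score)
            entries.append(PredictorEntry(p, verdict, score))
        out.append(VariantScoreSet(
            variant_id=row["variant_id"], cdna=row["cdna"],
            entries=tuple(entries)))
    return out


def write_report(results: Iterable[ClassificationResult],
                 tsv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> pd.DataFrame:
    """Flatten classification results to a report table (TSV/JSON optional)."""
    rows = []
    for r in results:
        rows.append({
            "variant_id": r.variant_id,
            "n_benign": r.n_benign, "n_pathogenic": r.n_pathogenic,
            "n_na": r.n_na, "rate": f"{r.rate_2dp:.2f}",
            **{f"verdict_{m}": r.verdict_per_mode[m] for m in MODES},
        })
    df = pd.DataFrame(rows)
    if tsv_path:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
    return df
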