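"""Validation metrics for PASI estimation.

Four views of model quality are reported:

* total-PASI mean absolute error (MAE);
* per-subscore classification accuracy, treating the area band as a
  7-label and erythema/induration/desquamation as 5-label problems;
* MAE stratified by the true severity band (low / medium / high);
* pairwise trend consistency — over all unordered pairs of visits, the
  fraction whose predicted PASI ordering matches the reference ordering,
  stratified by the reference score gap (0-5, 6-10, >10 points).

Trend consistency is an ordering statistic: pairs whose reference scores
tie carry no ordering information and are excluded from the denominator,
while a predicted tie on a strictly ordered reference pair counts as
incorrect by default (the conservative reading of a binary success rule;
switchable via ``tie_policy``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    N_AREA_LABELS,
    N_SEVERITY_LABELS,
    SUBSCORE_NAMES,
    read_visits_csv,
    severity_band,
)

__all__ = [
    "EvalReport",
    "TrendReport",
    "mae",
    "subscore_accuracy",
    "count_pairs",
    "trend_consistency",
    "evaluate",
]

#: Reference-gap strata (half-open, in PASI points) mirroring the
#: "0-5 / 6-10 / >10" gap table.
DEFAULT_GAP_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 5.0),
    (5.0, 10.0),
    (10.0, math.inf),
)
GAP_BAND_KEYS = ("band_0_5", "band_6_10", "band_gt10")


class EvalInputError(ValueError):
    pass


def mae(predicted: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error between two equal-length score lists."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise EvalInputError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise EvalInputError("mae of empty lists is undefined")
    return float(np.mean(np.abs(p - t)))


def subscore_accuracy(
    predicted: Sequence[int], truth: Sequence[int], n_labels: int
) -> float:
    """Fraction of exactly matching ordinal labels in {0..n_labels-1}."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape or p.ndim != 1:
        raise EvalInputError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise EvalInputError("accuracy of empty label lists is undefined")
    for name, arr in (("predicted", p), ("truth", t)):
        if arr.min() < 0 or arr.max() >= n_labels:
            raise EvalInputError(
                f"{name} labels outside 0..{n_labels - 1}: "
                f"range [{arr.min()}, {arr.max()}]"
            )
    return float(np.mean(p == t))


def count_pairs(n_visits: int) -> int:
    """Number of unordered visit pairs, C(n, 2) = n(n-1)/2."""
    if n_visits < 0:
        raise EvalInputError(f"n_visits must be >= 0, got {n_visits}")
    return n_visits * (n_visits - 1) // 2


@dataclass
class TrendReport:
    """Pairwise ordering consistency, overall and per reference-gap band."""

    overall: float | None
    per_band: dict[str, float | None]
    pairs_per_band: dict[str, int]
    n_pairs_total: int       #: all unordered pairs C(n,2)
    n_pairs_used: int        #: pairs with strictly ordered reference scores
    insufficient: bool = False

    def as_dict(self) -> dict:
        d = {"overall": self.overall, "pairs_per_band": dict(self.pairs_per_band)}
        d.update(self.per_band)
        d["n_pairs_total"] = self.n_pairs_total
        d["n_pairs_used"] = self.n_pairs_used
        if self.insufficient:
            d["insufficient_pairs"] = True
        return d


def trend_consistency(
    truth: Sequence[float],
    predicted: Sequence[float],
    gap_bands: Sequence[tuple[float, float]] = DEFAULT_GAP_BANDS,
    tie_policy: str = "incorrect",
) -> TrendReport:
    """Concordance of predicted vs reference PASI over all visit pairs.

    A pair (i, j) is consistent iff sign(predicted_i - predicted_j) equals
    sign(truth_i - truth_j).  Pairs with tied reference scores are dropped
    from the denominator.  ``tie_policy`` controls predicted ties on
    strictly ordered reference pairs: "incorrect" (default) or "half"
    (count 0.5, the Kendall tau-x convention).

    Invariant under any strictly increasing transform of the predictions.
    """
    if tie_policy not in ("incorrect", "half"):
        raise EvalInputError(f"unknown tie_policy {tie_policy!r}")
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise EvalInputError(f"length mismatch: {t.shape} vs {p.shape}")
    n = t.size
    iu, ju = np.triu_indices(n, k=1)
    dt = t[iu] - t[ju]
    dp = p[iu] - p[ju]
    usable = dt != 0
    gaps = np.abs(dt[usable])
    concord = np.sign(dp[usable]) == np.sign(dt[usable])
    score = concord.astype(float)
    if tie_policy == "half":
        score[dp[usable] == 0] = 0.5

    per_band: dict[str, float | None] = {}
    pairs_per_band: dict[str, int] = {}
    for key, (lo, hi) in zip(GAP_BAND_KEYS, gap_bands):
        in_band = (gaps > lo) & (gaps <= hi)
        pairs_per_band[key] = int(in_band.sum())
        per_band[key] = float(score[in_band].mean()) if in_band.any() else None

    n_used = int(usable.sum())
    if n_used < 2:
        return TrendReport(
            overall=None,
            per_band=per_band,
            pairs_per_band=pairs_per_band,
            n_pairs_total=count_pairs(n),
            n_pairs_used=n_used,
            insufficient=True,
        )
    return TrendReport(
        overall=float(score.mean()),
        per_band=per_band,
        pairs_per_band=pairs_per_band,
        n_pairs_total=count_pairs(n),
        n_pairs_used=n_used,
    )


@dataclass
class EvalReport:
    """Full validation report for one prediction set."""

    pasi_mae: float
    subscore_accuracy: dict[str, float]
    mae_by_severity: dict[str, float | None]
    trend: TrendReport
    n_visits: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "pasi_mae": self.pasi_mae,
            "subscore_accuracy": dict(self.subscore_accuracy),
            "mae_by_severity": dict(self.mae_by_severity),
            "trend": self.trend.as_dict(),
            "n_visits": self.n_visits,
            **self.extra,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def evaluate(
    predictions: str | Path | pd.DataFrame,
    truth: str | Path | pd.DataFrame,
) -> EvalReport:
    """Compare a predictions visit table against a reference visit table.

    Both inputs use the long visit CSV schema (one row per region with the
    four subscores plus the composed ``pasi``).  Visits are matched on
    (patient_id, visit_id); unmatched keys on either side are an error.
    """
    pred_visits = _load(predictions)
    true_visits = _load(truth)
    pkeys = {(v.patient_id, v.visit_id): v for v in pred_visits}
    tkeys = {(v.patient_id, v.visit_id): v for v in true_visits}
    if set(pkeys) != set(tkeys):
        only_p = sorted(set(pkeys) - set(tkeys))
        only_t = sorted(set(tkeys) - set(pkeys))
        raise EvalInputError(
            f"visit keys differ; only in predictions: {only_p[:5]}, "
            f"only in truth: {only_t[:5]}"
        )
    keys = sorted(pkeys)
    p_pasi = [pkeys[k].pasi for k in keys]
    t_pasi = [tkeys[k].pasi for k in keys]

    acc: dict[str, float] = {}
    for name in SUBSCORE_NAMES:
        n_labels = N_AREA_LABELS if name == "area_band" else N_SEVERITY_LABELS
        p_lab, t_lab = [], []
        for k in keys:
            for a in tkeys[k].regions:
                t_lab.append(getattr(a, name))
                p_lab.append(getattr(pkeys[k].region(a.region), name))
        key = "area" if name == "area_band" else name
        acc[key] = subscore_accuracy(p_lab, t_lab, n_labels)

    strata = {"low": [], "medium": [], "high": []}
    for pp, tp in zip(p_pasi, t_pasi):
        strata[severity_band(tp)].append(abs(pp - tp))
    mae_by_sev = {
        k: (float(np.mean(v)) if v else None) for k, v in strata.items()
    }

    return EvalReport(
        pasi_mae=mae(p_pasi, t_pasi),
        subscore_accuracy=acc,
        mae_by_severity=mae_by_sev,
        trend=trend_consistency(t_pasi, p_pasi),
        n_visits=len(keys),
    )


def _load(src: str | Path | pd.DataFrame):
    if isinstance(src, pd.DataFrame):
        import io

        buf = io.StringIO()
        src.to_csv(buf, index=False)
        buf.seek(0)
        return read_visits_csv(buf)  # type: ignore[arg-type]
    return read_visits_csv(src)
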