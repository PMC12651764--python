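"""Method-agreement statistics between predicted and reference scores.

Two scoring methods — here a network and an examiner average — are
compared with the standard agreement suite: MAE and RMSE in rubric
points, Pearson r, tie-corrected Spearman ρ, Lin's concordance
correlation ρc with its accuracy component Cb, Bland–Altman bias with 95%
limits of agreement, within-threshold accuracy (±1 / ±2 points), and
ICC(2,1) for inter-examiner reliability.

Conventions, both deliberate and configurable at the call sites: the
difference direction is predicted − reference throughout; Lin's ρc uses
population (1/n) moments, the original convention; the Bland–Altman
standard deviation uses the n−1 denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rubric import CRITERION_KEYS

__all__ = [
    "PairedScores",
    "AgreementReport",
    "DegenerateInputError",
    "mae",
    "rmse",
    "pearson_r",
    "spearman_rho",
    "lin_ccc",
    "bland_altman",
    "icc_2_1",
    "pct_within",
    "agreement_report",
    "evaluate_cases",
    "per_criterion_table",
]

_EPS = 1e-9


class DegenerateInputError(ValueError):
    """An agreement statistic is undefined for this input (zero variance)."""


@dataclass
class PairedScores:
    """Reference and predicted totals for the same cases, in rubric points."""

    reference: np.ndarray
    predicted: np.ndarray
    case_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.reference.shape != self.predicted.shape:
            raise ValueError("reference and predicted must have equal length")
        if len(self.reference) < 2:
            raise ValueError("need at least 2 paired scores")
        if not (np.all(np.isfinite(self.reference)) and np.all(np.isfinite(self.predicted))):
            raise ValueError("paired scores must be finite")
        if self.case_ids is not None and len(self.case_ids) != len(self.reference):
            raise ValueError("case_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.reference)

    @property
    def differences(self) -> np.ndarray:
        """Signed differences, predicted − reference."""
        return self.predicted - self.reference


def mae(p: PairedScores) -> float:
    return float(np.mean(np.abs(p.differences)))


def rmse(p: PairedScores) -> float:
    return float(np.sqrt(np.mean(p.differences**2)))


def _require_variance(p: PairedScores) -> None:
    if p.n < 3:
        raise DegenerateInputError("correlation needs at least 3 pairs")
    if np.var(p.reference) == 0 or np.var(p.predicted) == 0:
        raise DegenerateInputError("zero variance in one of the score vectors")


def pearson_r(p: PairedScores) -> float:
    _require_variance(p)
    return float(stats.pearsonr(p.reference, p.predicted).statistic)


def spearman_rho(p: PairedScores) -> float:
    """Spearman's ρ with mid-rank tie correction (Pearson on mid-ranks)."""
    _require_variance(p)
    return float(stats.spearmanr(p.reference, p.predicted).statistic)


def lin_ccc(p: PairedScores) -> tuple[float, float]:
    """Lin's concordance correlation ρc and its accuracy component Cb.

    ρc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (1/n) moments;
    Cb = ρc / r, so ρc = r · Cb.
    """
    _require_variance(p)
    x, y = p.reference, p.predicted
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    ccc = 2.0 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
    cb = ccc / pearson_r(p)
    return float(ccc), float(cb)


def bland_altman(p: PairedScores) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high): mean difference ± 1.96·sd (n−1)."""
    d = p.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_2_1(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix``: complete n×k array of n cases scored by k raters.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete n x k matrix with n >= 2, k >= 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("rater matrix must be complete (no missing cells)")
    n, k = m.shape
    gm = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + gm
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    if msr == 0 and mse == 0:
        raise DegenerateInputError("all-equal rater matrix; ICC undefined")
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def pct_within(
    p: PairedScores, thresholds: Sequence[float] = (1.0, 2.0)
) -> dict[float, float]:
    """Percentage of cases with |predicted − reference| ≤ t for each t."""
    d = np.abs(p.differences)
    return {
        float(t): float(100.0 * np.count_nonzero(d <= t + _EPS) / p.n)
        for t in thresholds
    }


@dataclass
class AgreementReport:
    n: int
    mae: float
    rmse: float
    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    ccc: Optional[float]
    cb: Optional[float]
    bias: float
    loa_low: float
    loa_high: float
    pct_within: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n", "mae", "rmse", "pearson_r", "spearman_rho", "ccc", "cb",
            "bias", "loa_low", "loa_high",
        )}
        d["pct_within"] = {str(k): v for k, v in self.pct_within.items()}
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


def agreement_report(
    p: PairedScores, thresholds: Sequence[float] = (1.0, 2.0)
) -> AgreementReport:
    """The full statistic set.  Correlation-type statistics are reported as
    None when the input is degenerate (e.g. perfect-stub predictions with
    zero difference variance still have a defined MAE and bias)."""
    try:
        r = pearson_r(p)
        rho = spearman_rho(p)
        ccc, cb = lin_ccc(p)
    except DegenerateInputError:
        r = rho = ccc = cb = None
    bias, lo, hi = bland_altman(p)
    return AgreementReport(
        n=p.n,
        mae=mae(p),
        rmse=rmse(p),
        pearson_r=r,
        spearman_rho=rho,
        ccc=ccc,
        cb=cb,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        pct_within=pct_within(p, thresholds),
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation of labeled cases against a fitted model


def per_criterion_table(
    case_ids: Sequence[str],
    reference_sheets: Sequence,
    predicted_sheets: Sequence,
    reference_totals: Sequence[float],
    predicted_totals: Sequence[float],
) -> pd.DataFrame:
    """Case-by-case true vs predicted table, one row pair per criterion
    (the layout used to report per-domain scoring accuracy)."""
    rows = {}
    for key in CRITERION_KEYS:
        rows[f"true_{key}"] = [s.values[key] for s in reference_sheets]
        rows[f"predicted_{key}"] = [s.values[key] for s in predicted_sheets]
    rows["true_total"] = list(reference_totals)
    rows["predicted_total"] = list(predicted_totals)
    return pd.DataFrame(rows, index=list(case_ids)).T


def evaluate_cases(
    cases: Sequence,
    estimator,
    n_points: int = 2048,
    seed: int = 0,
    thresholds: Sequence[float] = (1.0, 2.0),
) -> tuple[AgreementReport, pd.DataFrame]:
    """Preprocess, predict and compare each labeled case.

    ``cases`` may hold in-memory meshes (``.mesh``) or mesh paths
    (``.mesh_path``); each needs a reference ``.sheet``.  Totals are
    compared using the network's jointly trained total head.
    """
    from . import geometry
    from .rubric import total_score

    cfg = geometry.SamplerConfig(n_points=n_points, seed=seed)
    ids, ref_sheets, pred_sheets, ref_totals, pred_totals = [], [], [], [], []
    for case in cases:
        mesh = case.mesh if getattr(case, "mesh", None) is not None else geometry.read_obj(
            case.mesh_path
        )
        cloud = geometry.normalize(geometry.sample_point_cloud(mesh, cfg))
        sheet, total_head, _ = estimator.predict_sheets(
            cloud.points[None], case_ids=[case.case_id]
        )[0]
        ids.append(case.case_id)
        ref_sheets.append(case.sheet)
        pred_sheets.append(sheet)
        ref_totals.append(total_score(case.sheet))
        pred_totals.append(total_head)
    paired = PairedScores(ref_totals, pred_totals, case_ids=ids)
    report = agreement_report(paired, thresholds)
    table = per_criterion_table(ids, ref_sheets, pred_sheets, ref_totals, pred_totals)
    return report, table
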