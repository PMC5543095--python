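"""Fit evaluation: block curves vs. the participant reference, and variance.

The reference learning curve is the mean proportion of correct responses of
the 55 participants in each of the 12 twenty-trial blocks, together with the
across-participant standard deviations.  Model fit is summarised by the
Pearson correlation r (relative fit: are the trends captured?), its square
r², and the root-mean-square error (absolute fit).  RMSE is computed on the
proportion (0-1) scale; feeding percent-scale curves is a guarded error
because it silently inflates RMSE a hundredfold.

Levene's test (the original, mean-centred variant) compares variances, e.g.
the across-run spread of the model against an empirically plausible spread.
The reference SDs are carried for plotting and variance comparisons only;
they enter neither r nor RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulator import BatchResult


class ZeroVarianceError(ValueError):
    """The model curve is constant, so the Pearson correlation is undefined."""


@dataclass(frozen=True)
class ReferenceCurve:
    """12 block means and SDs on the percent scale."""

    block_means: tuple[float, ...]
    block_sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.block_means) != 12 or len(self.block_sds) != 12:
            raise ValueError("a reference curve has exactly 12 block means and SDs")

    def proportions(self) -> np.ndarray:
        return np.asarray(self.block_means, dtype=float) / 100.0

    def sd_proportions(self) -> np.ndarray:
        return np.asarray(self.block_sds, dtype=float) / 100.0


def load_reference_curve(path: str | Path | None = None) -> ReferenceCurve:
    """Load the packaged participant curve (or a CSV in the same layout)."""
    if path is None:
        ref = resources.files("revcat").joinpath("data/participant_curve.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df = df.sort_values("block")
    return ReferenceCurve(
        block_means=tuple(float(x) for x in df["mean_pct"]),
        block_sds=tuple(float(x) for x in df["sd_pct"]),
    )


#: Participant block means and SDs (percent), 12 blocks of 20 trials.
PARTICIPANT_CURVE = load_reference_curve()


@dataclass(frozen=True)
class FitResult:
    """Relative (r, r²) and absolute (RMSE, proportion scale) fit."""

    r: float
    r2: float
    rmse: float


def _as_proportions(curve, name: str) -> np.ndarray:
    if isinstance(curve, ReferenceCurve):
        return curve.proportions()
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(
            f"{name} must be on the proportion (0-1) scale; "
            "percent-scale values would corrupt the RMSE"
        )
    return arr


def fit_statistics(model_curve, reference) -> FitResult:
    """Pearson r, r², and RMSE between two paired block curves.

    Both curves must be on the proportion scale (a :class:`ReferenceCurve`
    is converted automatically) and of equal length.  A constant model
    curve raises :class:`ZeroVarianceError`.
    """
    model = _as_proportions(model_curve, "model_curve")
    ref = _as_proportions(reference, "reference")
    if model.shape != ref.shape:
        raise ValueError("model and reference curves must have equal length")
    if model.size < 2:
        raise ValueError("need at least two paired blocks")
    if np.ptp(model) == 0.0:
        raise ZeroVarianceError("model curve is constant; r is undefined")
    r = float(sps.pearsonr(model, ref).statistic)
    rmse = float(np.sqrt(np.mean((model - ref) ** 2)))
    return FitResult(r=r, r2=r * r, rmse=rmse)


def levene_test(*groups) -> tuple[float, float]:
    """Original (mean-centred) Levene test for equality of variances.

    W is the one-way ANOVA F statistic of the absolute deviations from the
    group means; p comes from the F(k-1, N-k) distribution.  Degenerate
    all-identical data yield W = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    zs = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("each group needs at least two observations")
        zs.append(np.abs(arr - arr.mean()))
    k = len(zs)
    n_total = sum(z.size for z in zs)
    grand = np.concatenate(zs).mean()
    between = sum(z.size * (z.mean() - grand) ** 2 for z in zs)
    within = sum(((z - z.mean()) ** 2).sum() for z in zs)
    if within == 0.0:
        if between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    w = (n_total - k) / (k - 1) * between / within
    p = float(sps.f.sf(w, k - 1, n_total - k))
    return float(w), p


def fraction_below(
    batch: BatchResult, block_index: int, criterion: float = 0.85
) -> float:
    """Share of a batch's runs whose block proportion is below ``criterion``.

    ``block_index`` is 1-based; the 85% default is the conventional
    learning criterion separating learner from non-learner runs.
    """
    if not 1 <= block_index <= 12:
        raise ValueError("block_index must be in 1..12")
    props = batch.block_matrix()[:, block_index - 1]
    return float(np.mean(props < criterion))


def report_table(batches: list[BatchResult], reference: ReferenceCurve) -> pd.DataFrame:
    """Fit table: one row per configuration plus MEAN/MIN/MAX summary rows."""
    rows = []
    for batch in batches:
        fit = fit_statistics(batch.block_means, reference)
        rows.append(
            {"config": batch.config.label, "r": fit.r, "r2": fit.r2, "rmse": fit.rmse}
        )
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "config": ["MEAN", "MIN", "MAX"],
            "r": [df["r"].mean(), df["r"].min(), df["r"].max()],
            "r2": [df["r2"].mean(), df["r2"].min(), df["r2"].max()],
            "rmse": [df["rmse"].mean(), df["rmse"].min(), df["rmse"].max()],
        }
    )
    return pd.concat([df, summary], ignore_index=True)
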