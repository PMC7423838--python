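"""Observed-vs-predicted calibration in six risk bins, plus run reporting.

Validation patients are sorted by predicted risk and split into six
contiguous bins of (near-)equal size, bin 1 holding the lowest-risk and
bin 6 the highest-risk patients.  Per bin the observed toxicity incidence
is compared with the mean predicted probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .lasso import BootstrapEnsemble, FinalModelRow, final_model_frame

DEFAULT_N_BINS = 6


def incidence_percent(events: int, n: int, decimals: int = 1) -> float:
    """Cohort incidence as a percentage, rounded for reporting."""
    if n <= 0 or events < 0 or events > n:
        raise ParameterError(f"invalid counts events={events}, n={n}")
    return float(round(100.0 * events / n, decimals))


@dataclass
class CalibrationTable:
    """Per-bin observed and mean predicted incidence."""

    table: pd.DataFrame  # columns: bin, n, events_observed, incidence_observed,
    #                               incidence_predicted_mean
    run_id: str = ""

    def __post_init__(self) -> None:
        required = {
            "bin",
            "n",
            "events_observed",
            "incidence_observed",
            "incidence_predicted_mean",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ParameterError(f"calibration table missing columns: {sorted(missing)}")

    @property
    def n_total(self) -> int:
        return int(self.table["n"].sum())

    @property
    def events_total(self) -> int:
        return int(self.table["events_observed"].sum())


def calibration_bins(
    predicted: np.ndarray,
    observed: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    patient_ids: Sequence[str] | None = None,
    run_id: str = "",
) -> CalibrationTable:
    """Bin patients by predicted risk and tabulate observed incidence.

    Sorting is stable (ties broken by patient id); bins are contiguous
    with sizes differing by at most one, remainder patients allocated to
    the highest-risk bins.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=int)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ParameterError("predicted and observed must be 1-D of equal length")
    n = predicted.size
    if n < n_bins:
        raise ParameterError(f"need at least {n_bins} patients, got {n}")
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (predicted[i], str(patient_ids[i])))

    base, rem = divmod(n, n_bins)
    sizes = [base] * (n_bins - rem) + [base + 1] * rem  # extras to top-risk bins
    rows = []
    start = 0
    for b, size in enumerate(sizes, start=1):
        idx = order[start : start + size]
        start += size
        obs = observed[idx]
        rows.append(
            {
                "bin": b,
                "n": size,
                "events_observed": int(obs.sum()),
                "incidence_observed": float(obs.mean()),
                "incidence_predicted_mean": float(predicted[idx].mean()),
            }
        )
    return CalibrationTable(pd.DataFrame(rows), run_id=run_id)


# ---------------------------------------------------------------------------
# Report


def _block(df: pd.DataFrame) -> str:
    """Fixed-width table rendered as a fenced code block."""
    with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
        body = df.to_string(index=False)
    return f"```\n{body}\n```"


def build_report(
    run_id: str,
    ensemble: BootstrapEnsemble,
    final_rows: Sequence[FinalModelRow],
    calibration: CalibrationTable,
    univariate: pd.DataFrame,
    clusters: pd.DataFrame,
    config: Mapping | None = None,
) -> str:
    """Assemble the markdown run report.

    All artifacts must come from the same run: any non-empty ``run_id``
    mismatch, or an empty ensemble, raises :class:`ConsistencyError`.
    """
    if ensemble.coef_matrix.size == 0:
        raise ConsistencyError("empty bootstrap ensemble")
    for name, rid in (("ensemble", ensemble.run_id), ("calibration", calibration.run_id)):
        if rid and rid != run_id:
            raise ConsistencyError(f"{name} run id {rid!r} does not match {run_id!r}")

    freq = ensemble.selection_counts.sort_values(ascending=False)
    pair = ensemble.pair_counts

    lines = [
        f"# Toxicity modeling run report `{run_id}`",
        "",
        "## Univariate screening (Spearman vs ordinal grade)",
        "",
        _block(univariate),
        "",
        "## Feature clusters (Pearson > threshold)",
        "",
        _block(clusters),
        "",
        f"## Selection frequencies over {ensemble.n_boot} bootstrap models",
        "",
        f"Mean validation AUC {ensemble.mean_auc:.4f} (SD {ensemble.sd_auc:.4f}); "
        f"{ensemble.n_redrawn} degenerate replicates redrawn.",
        "",
        _block(freq.to_frame().reset_index(names="feature")),
        "",
        "## Pairwise co-selection frequencies",
        "",
        _block(pair.reset_index(names="feature")),
        "",
        "## Final model (full training data)",
        "",
        _block(final_model_frame(final_rows)),
        "",
        "## Calibration (observed vs predicted, six risk bins)",
        "",
        _block(calibration.table),
        "",
        "## Reproducibility",
        "",
        f"- ensemble seed: {ensemble.seed}",
    ]
    if config:
        for key in sorted(config):
            lines.append(f"- {key}: {config[key]}")
    lines.append("")
    return "\n".join(lines)
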