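"""Evaluation of DPI-ELISA plate readouts.

The screen's statistics are deliberately simple enough for a spreadsheet:
each well's raw absorbance is divided by the plate-wide mean ("relative
normalized absorbance", plate mean 1 by construction), all wells are rank
sorted (the S-plot), and the significance border is placed two standard
deviations above the mean of the normalized values (2-sigma, the p = 0.05
convention for a normal null). Library probes strictly above the border
are called positive.

For quantitative follow-up assays (single probes, technical replicates)
absorbances are normalized to the empty-vector control wells and
expressed as percent binding relative to a reference probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plate import PlateLayout, PlateReadout, sort_wells

__all__ = [
    "ScreenResult",
    "QuantResult",
    "normalize_plate",
    "call_positives",
    "analyze_readout",
    "replicate_concordance",
    "quantify_binding",
]


def normalize_plate(readout: PlateReadout | dict[str, float]) -> dict[str, float]:
    """Relative normalized absorbance: each well over the plate mean.

    The mean runs over every well probed with the extract, controls and
    empty wells included. Raises on an all-zero plate (mean undefined as
    a divisor) and on fewer than two wells.
    """
    values = readout.values if isinstance(readout, PlateReadout) else readout
    if len(values) < 2:
        raise ValueError("need at least two wells to normalize")
    arr = np.asarray(list(values.values()), dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite absorbance values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("plate mean is zero; normalization undefined")
    return {w: v / mean for w, v in values.items()}


@dataclass
class ScreenResult:
    """Normalized values, ranking, 2-sigma threshold and positive calls."""

    normalized: dict[str, float]
    ranking: list[str]  # wells by descending normalized value
    sigma: float
    threshold: float
    positives: list[str]  # library wells strictly above threshold
    sigma_multiplier: float = 2.0
    layout: PlateLayout | None = None

    def splot_frame(self) -> pd.DataFrame:
        """Rank-sorted table behind the S-plot diagram."""
        rows = []
        for rank, w in enumerate(self.ranking, start=1):
            p = self.layout.probe_at(w) if self.layout else None
            rows.append(
                {
                    "rank": rank,
                    "well": w,
                    "probe_id": p.probe_id if p else "",
                    "class": p.probe_class if p else "",
                    "normalized": self.normalized[w],
                    "positive": w in set(self.positives),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return self.splot_frame().sort_values("well", kind="stable").reset_index(
            drop=True
        )


def call_positives(
    normalized: dict[str, float],
    layout: PlateLayout | None = None,
    sigma_multiplier: float = 2.0,
    include_controls: bool = False,
) -> ScreenResult:
    """Rank wells and call those above mean + ``sigma_multiplier`` * sd.

    The mean and standard deviation are computed over all normalized
    wells (mean is 1 by construction). Only wells holding library probes
    are eligible positives unless ``include_controls`` or no layout is
    given. Ranking ties break by well coordinate.
    """
    arr = np.asarray(list(normalized.values()), dtype=float)
    sigma = float(arr.std(ddof=0))
    threshold = float(arr.mean() + sigma_multiplier * sigma)
    if sigma == 0:
        warnings.warn("zero variance across wells; no positives callable")
    # python sort is stable: pre-sorting by well coordinate breaks ties
    ranking = sorted(sort_wells(normalized), key=lambda w: -normalized[w])
    if layout is not None and not include_controls:
        eligible = set(layout.wells_by_class("library"))
    else:
        eligible = set(normalized)
    positives = [
        w
        for w in ranking
        if w in eligible and normalized[w] > threshold and sigma > 0
    ]
    return ScreenResult(
        normalized=normalized,
        ranking=ranking,
        sigma=sigma,
        threshold=threshold,
        positives=positives,
        sigma_multiplier=sigma_multiplier,
        layout=layout,
    )


def analyze_readout(
    readout: PlateReadout,
    layout: PlateLayout | None = None,
    sigma_multiplier: float = 2.0,
    include_controls: bool = False,
) -> ScreenResult:
    """normalize_plate then call_positives, the standard per-plate path."""
    return call_positives(
        normalize_plate(readout), layout, sigma_multiplier, include_controls
    )


def replicate_concordance(
    result_a: ScreenResult, result_b: ScreenResult
) -> tuple[float, list[str]]:
    """Pearson r over shared wells plus the reproducible positive set.

    The standard reproducibility figure for plate screens: normalized
    values of two biological replicates correlated against each other;
    probes called positive in both replicates count as reproducibly
    bound.
    """
    shared = sorted(set(result_a.normalized) & set(result_b.normalized))
    if len(shared) < 3:
        raise ValueError("need at least three shared wells for a correlation")
    xs = [result_a.normalized[w] for w in shared]
    ys = [result_b.normalized[w] for w in shared]
    r = float(stats.pearsonr(xs, ys).statistic)
    reproducible = sort_wells(set(result_a.positives) & set(result_b.positives))
    return r, reproducible


@dataclass
class QuantResult:
    """Quantitative relative-binding assay summary (one row per probe)."""

    table: pd.DataFrame = field(repr=False)
    reference_probe: str = ""

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def quantify_binding(
    values: pd.DataFrame,
    empty_vector_rows: list[str],
    reference_probe: str,
) -> QuantResult:
    """Relative binding of single probes across technical replicates.

    ``values`` holds raw absorbances, one row per probe, one column per
    replicate; ``empty_vector_rows`` name the rows probed with the empty
    vector control extract. Per replicate, each absorbance is divided by
    the mean of the empty-vector rows (normalized absorbance); relative
    binding is the normalized absorbance as a percentage of the reference
    probe's mean. The error is half the range for two replicates and the
    maximum deviation from the mean otherwise. The significance flag is a
    two-sided Welch test of a probe's normalized replicate values against
    the empty-vector values at p < 0.05 — with two replicates this is
    advisory only.
    """
    if reference_probe not in values.index:
        raise ValueError(f"reference probe {reference_probe!r} not in table")
    missing = [r for r in empty_vector_rows if r not in values.index]
    if missing:
        raise ValueError(f"empty-vector rows missing from table: {missing}")
    if values.shape[1] < 2:
        raise ValueError("need at least two technical replicates")
    ev = values.loc[empty_vector_rows]
    normalized = values / ev.mean(axis=0)
    ref_mean = normalized.loc[reference_probe].mean()
    relative = normalized / ref_mean * 100.0
    ev_flat = normalized.loc[empty_vector_rows].to_numpy().ravel()
    rows = []
    for probe in values.index:
        rel = relative.loc[probe].to_numpy(dtype=float)
        mean = rel.mean()
        if rel.size == 2:
            err = float(np.ptp(rel) / 2.0)
        else:
            err = float(np.abs(rel - mean).max())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny n: Welch is advisory
            p = stats.ttest_ind(
                normalized.loc[probe], ev_flat, equal_var=False
            ).pvalue
        rows.append(
            {
                "probe": probe,
                "normalized_abs": float(normalized.loc[probe].mean()),
                "relative_binding_pct": float(mean),
                "abs_error_pct": err,
                "p_value": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return QuantResult(table=pd.DataFrame(rows), reference_probe=reference_probe)
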