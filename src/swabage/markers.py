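"""Screen CpGs for cell-type specificity between two tissue β-matrices.

A good cell-type marker separates the two tissues widely and stably, and
must not drift with donor age (otherwise the deconvolution would confound
composition with age). Three criteria, applied per candidate CpG:

i)   large absolute difference in mean β between tissue A and tissue B;
ii)  low within-tissue variance (sum of the two sample variances);
iii) negligible Pearson correlation with chronological age in an
     age-annotated reference cohort (|r| below ``age_corr_max``, default
     0.05 — an anti-correlation is equally disqualifying).

Probes passing (iii) are filtered to the lowest ``var_sum_quantile``
quantile of variance sums (default the lowest decile), then ranked by
Δmean descending; ties break toward smaller variance sum, then
lexicographic probe ID, so the ranking is fully deterministic and
invariant to sample and probe order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import BetaMatrix

__all__ = ["MarkerCandidate", "screen_markers", "characterize_markers"]


@dataclass(frozen=True)
class MarkerCandidate:
    """Per-CpG screening record."""

    probe_id: str
    mean_a: float
    mean_b: float
    abs_delta_mean: float
    var_sum: float
    age_corr: float | None
    passes_age_filter: bool
    passes_var_filter: bool
    rank: int | None = None


def _column_stats(matrix: BetaMatrix, probe: str) -> tuple[float, float, int]:
    col = matrix.values[probe].to_numpy()
    col = col[~np.isnan(col)]
    if len(col) == 0:
        return float("nan"), float("nan"), 0
    var = float(np.var(col, ddof=1)) if len(col) > 1 else 0.0
    return float(np.mean(col)), var, len(col)


def _age_correlation(matrix: BetaMatrix, probe: str) -> float | None:
    b = matrix.values[probe].to_numpy()
    a = matrix.ages.to_numpy()
    ok = ~np.isnan(b) & ~np.isnan(a)
    if ok.sum() < 3 or np.std(b[ok]) == 0 or np.std(a[ok]) == 0:
        return None
    return float(np.corrcoef(b[ok], a[ok])[0, 1])


def screen_markers(
    tissue_a: BetaMatrix,
    tissue_b: BetaMatrix,
    age_reference: BetaMatrix,
    age_corr_max: float = 0.05,
    var_sum_quantile: float = 0.10,
    top_k: int | None = None,
    max_missing_frac: float = 0.20,
    full_table: bool = False,
) -> list[MarkerCandidate]:
    """Rank shared CpGs as cell-type-marker candidates.

    Returns the ranked candidates that pass all filters (truncated to
    ``top_k`` when given). With ``full_table=True`` every screened probe is
    returned, rejected ones carrying ``rank=None`` and their pass/fail
    flags, in ranked-then-rejected order.
    """
    shared = [
        p
        for p in tissue_a.probe_ids
        if p in set(tissue_b.probe_ids) and p in set(age_reference.probe_ids)
    ]
    if not shared:
        raise ValueError("the two tissue matrices and the age reference share no probes")
    n_aged = (~np.isnan(age_reference.ages.to_numpy())).sum()
    if n_aged < 3:
        raise ValueError(f"age reference needs ≥ 3 samples with age, has {n_aged}")

    records: list[MarkerCandidate] = []
    for probe in sorted(shared):
        mean_a, var_a, n_a = _column_stats(tissue_a, probe)
        mean_b, var_b, n_b = _column_stats(tissue_b, probe)
        # probes too sparsely measured in either tissue are not screened
        if n_a < (1 - max_missing_frac) * tissue_a.n_samples:
            continue
        if n_b < (1 - max_missing_frac) * tissue_b.n_samples:
            continue
        r = _age_correlation(age_reference, probe)
        records.append(
            MarkerCandidate(
                probe_id=probe,
                mean_a=mean_a,
                mean_b=mean_b,
                abs_delta_mean=abs(mean_a - mean_b),
                var_sum=var_a + var_b,
                age_corr=r,
                passes_age_filter=r is not None and abs(r) < age_corr_max,
                passes_var_filter=False,  # set below
            )
        )

    age_ok = [c for c in records if c.passes_age_filter]
    if age_ok:
        cutoff = float(np.quantile([c.var_sum for c in age_ok], var_sum_quantile))
    else:
        cutoff = -np.inf
    records = [
        MarkerCandidate(
            **{
                **c.__dict__,
                "passes_var_filter": c.passes_age_filter and c.var_sum <= cutoff,
            }
        )
        for c in records
    ]

    selected = sorted(
        (c for c in records if c.passes_var_filter),
        key=lambda c: (-c.abs_delta_mean, c.var_sum, c.probe_id),
    )
    if not selected:
        warnings.warn("all probes vetoed by the screening criteria", stacklevel=2)
    if top_k is not None:
        selected = selected[:top_k]
    selected = [
        MarkerCandidate(**{**c.__dict__, "rank": i + 1}) for i, c in enumerate(selected)
    ]
    if not full_table:
        return selected
    chosen = {c.probe_id for c in selected}
    rejected = sorted(
        (c for c in records if c.probe_id not in chosen), key=lambda c: c.probe_id
    )
    return selected + rejected


def candidates_to_frame(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in candidates])


def characterize_markers(
    candidates: list[MarkerCandidate] | list[str],
    datasets: Mapping[str, BetaMatrix],
) -> pd.DataFrame:
    """Per-candidate, per-dataset mean and sd of β.

    Rows are candidate probes; columns a (dataset, statistic) MultiIndex.
    A probe absent from a dataset yields NaN cells, never a failure.
    """
    probes = [c.probe_id if isinstance(c, MarkerCandidate) else str(c) for c in candidates]
    cols = pd.MultiIndex.from_product([list(datasets), ["mean", "sd"]])
    out = pd.DataFrame(index=probes, columns=cols, dtype=float)
    for name, matrix in datasets.items():
        for probe in probes:
            if probe not in matrix.values.columns:
                continue
            col = matrix.values[probe].to_numpy()
            col = col[~np.isnan(col)]
            if len(col) == 0:
                continue
            out.loc[probe, (name, "mean")] = float(np.mean(col))
            out.loc[probe, (name, "sd")] = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
    return out
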