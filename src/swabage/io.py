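"""Readers/writers for β-value matrices, sample sheets and cytology tables.

Canonical β scale is the fraction in [0, 1]. Percent-scale exports (common
from pyrosequencing software) must be read with ``percent_scale=True``,
which divides by 100 before validation. Missing β-values stay missing —
nothing here imputes.

All files are plain delimited UTF-8 text with a header; the delimiter is
auto-detected among tab, comma and semicolon. Decimal commas are not
supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BetaProfile",
    "BetaMatrix",
    "CytologyRecord",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "read_cytology",
    "join",
    "PCT_EPITHELIAL_LABEL",
]

#: label key under which counted epithelial percentages are attached by join()
PCT_EPITHELIAL_LABEL = "pct_epithelial_counted"

_DELIMITERS = ("\t", ",", ";")


@dataclass
class BetaProfile:
    """One sample's β-values at named CpG probes, plus metadata.

    ``betas`` maps probe_id to a fraction in [0, 1]; a probe absent from the
    map is missing for this sample. ``age_years`` is None when unknown
    (prediction-only samples).
    """

    sample_id: str
    betas: dict[str, float] = field(default_factory=dict)
    age_years: float | None = None
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for probe, b in self.betas.items():
            _check_beta(b, f"sample {self.sample_id!r}, probe {probe!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative age {self.age_years}")

    def get(self, probe_id: str) -> float | None:
        v = self.betas.get(probe_id)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v


class BetaMatrix:
    """Samples × probes β-value table with per-sample metadata.

    Thin wrapper around a pandas DataFrame (rows = samples, columns = probe
    IDs, NaN = missing) carrying an age Series and a string-label DataFrame
    aligned on the sample index.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        ages: pd.Series | None = None,
        labels: pd.DataFrame | None = None,
    ) -> None:
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        vals = values.astype(float)
        bad = (vals < 0) | (vals > 1)
        if bad.any().any():
            r, c = next(zip(*np.nonzero(bad.to_numpy())))
            raise ValueError(
                f"β out of [0,1] at sample {vals.index[r]!r}, probe {vals.columns[c]!r}: "
                f"{vals.iat[r, c]}"
            )
        self.values = vals
        self.ages = (
            ages.reindex(vals.index).astype(float)
            if ages is not None
            else pd.Series(np.nan, index=vals.index, dtype=float)
        )
        self.labels = (
            labels.reindex(vals.index)
            if labels is not None
            else pd.DataFrame(index=vals.index)
        )
        #: free-form provenance (e.g. clip counts from the cohort generator)
        self.meta: dict = {}

    # -- container protocol -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def probe_ids(self) -> list[str]:
        return [str(p) for p in self.values.columns]

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[BetaProfile]:
        return iter(self.profiles())

    def profiles(self) -> list[BetaProfile]:
        out = []
        for sid in self.values.index:
            row = self.values.loc[sid]
            betas = {p: float(v) for p, v in row.items() if not np.isnan(v)}
            age = self.ages.loc[sid]
            lab = {}
            if not self.labels.empty:
                lab = {
                    k: str(v)
                    for k, v in self.labels.loc[sid].items()
                    if v is not None and not (isinstance(v, float) and np.isnan(v))
                }
            out.append(
                BetaProfile(
                    sample_id=str(sid),
                    betas=betas,
                    age_years=None if np.isnan(age) else float(age),
                    labels=lab,
                )
            )
        return out

    def profile(self, sample_id: str) -> BetaProfile:
        for p in self.profiles():
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    @classmethod
    def from_profiles(cls, profiles: Iterable[BetaProfile]) -> "BetaMatrix":
        profiles = list(profiles)
        probe_order: list[str] = []
        for p in profiles:
            for probe in p.betas:
                if probe not in probe_order:
                    probe_order.append(probe)
        idx = [p.sample_id for p in profiles]
        values = pd.DataFrame(
            [[p.betas.get(probe, np.nan) for probe in probe_order] for p in profiles],
            index=idx,
            columns=probe_order,
            dtype=float,
        )
        ages = pd.Series(
            [np.nan if p.age_years is None else p.age_years for p in profiles],
            index=idx,
            dtype=float,
        )
        label_keys: list[str] = []
        for p in profiles:
            for k in p.labels:
                if k not in label_keys:
                    label_keys.append(k)
        labels = pd.DataFrame(
            [[p.labels.get(k) for k in label_keys] for p in profiles],
            index=idx,
            columns=label_keys,
        )
        return cls(values, ages, labels)

    def subset_probes(self, probes: list[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, probes], self.ages, self.labels)


@dataclass(frozen=True)
class CytologyRecord:
    """Counted percentage of epithelial cells in one stained swab smear."""

    sample_id: str
    pct_epithelial: float
    n_cells_counted: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_epithelial <= 100:
            raise ValueError(
                f"sample {self.sample_id!r}: pct_epithelial {self.pct_epithelial} "
                "outside [0, 100]"
            )
        if self.n_cells_counted is not None and self.n_cells_counted <= 0:
            raise ValueError(f"sample {self.sample_id!r}: n_cells_counted must be positive")


# ---------------------------------------------------------------------------


def _check_beta(v: float, where: str) -> None:
    if np.isnan(v):
        return
    if not 0.0 <= v <= 1.0:
        hint = ""
        if 1.0 < v <= 100.0:
            hint = " (value looks percent-scale; pass percent_scale=True / --percent-scale)"
        raise ValueError(f"β-value {v} outside [0,1] at {where}{hint}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_beta_matrix(
    path,
    orientation: str = "samples_as_rows",
    percent_scale: bool = False,
) -> BetaMatrix:
    """Read a delimited β table into a :class:`BetaMatrix`.

    Parameters
    ----------
    orientation
        ``samples_as_rows`` (header row holds probe IDs) or
        ``probes_as_rows`` (GEO series-matrix style; transposed on read).
    percent_scale
        Divide all values by 100 before validation.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "probes_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0, dtype=str)
    if orientation == "probes_as_rows":
        df = df.T
    num = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                v = np.nan
            else:
                try:
                    v = float(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"{path.name}: non-numeric cell {raw!r} at sample "
                        f"{df.index[i]!r}, probe {df.columns[j]!r}"
                    ) from exc
            if percent_scale:
                v = v / 100.0
            _check_beta(v, f"{path.name}: sample {df.index[i]!r}, probe {df.columns[j]!r}")
            num.iat[i, j] = v
    return BetaMatrix(num)


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Write samples-as-rows CSV; round-trips values to ≥6 decimals."""
    matrix.values.to_csv(path, float_format="%.10g", index_label="sample_id")


def read_sample_sheet(path) -> dict[str, tuple[float | None, dict[str, str]]]:
    """Read a sample sheet into ``{sample_id: (age_years, labels)}``.

    Requires a ``sample_id`` column; ``age`` (or ``age_years``) is optional,
    all other columns become string labels. Negative ages are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError(f"{path.name}: sample sheet lacks a 'sample_id' column")
    id_col = cols["sample_id"]
    age_col = cols.get("age") or cols.get("age_years")
    out: dict[str, tuple[float | None, dict[str, str]]] = {}
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        age: float | None = None
        if age_col is not None:
            raw = row[age_col]
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                age = float(raw)
                if age < 0:
                    raise ValueError(f"{path.name}: sample {sid!r} has negative age {age}")
        labels = {
            c: str(row[c]).strip()
            for c in df.columns
            if c not in (id_col, age_col) and str(row[c]).strip() not in ("", "nan", "NA")
        }
        out[sid] = (age, labels)
    return out


def read_cytology(path) -> list[CytologyRecord]:
    """Read a cytology table (sample_id, pct_epithelial[, n_cells_counted])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    cols = {c.strip().lower(): c for c in df.columns}
    for needed in ("sample_id", "pct_epithelial"):
        if needed not in cols:
            raise ValueError(f"{path.name}: cytology table lacks a {needed!r} column")
    n_col = cols.get("n_cells_counted")
    records = []
    for _, row in df.iterrows():
        n = None
        if n_col is not None and not pd.isna(row[n_col]):
            n = int(row[n_col])
        records.append(
            CytologyRecord(
                sample_id=str(row[cols["sample_id"]]).strip(),
                pct_epithelial=float(row[cols["pct_epithelial"]]),
                n_cells_counted=n,
            )
        )
    return records


def join(
    matrix: BetaMatrix,
    sheet: Mapping[str, tuple[float | None, dict[str, str]]] | None = None,
    cytology: Iterable[CytologyRecord] | None = None,
) -> BetaMatrix:
    """Attach sample-sheet metadata and counted cell fractions by sample ID.

    Unmatched sheet or cytology entries trigger a warning, never a failure.
    Idempotent: applying the same sheet twice equals applying it once.
    """
    ages = matrix.ages.copy()
    labels = matrix.labels.copy()
    present = set(matrix.sample_ids)
    if sheet:
        unmatched = [sid for sid in sheet if sid not in present]
        if unmatched:
            warnings.warn(f"sample sheet entries not in matrix: {unmatched}", stacklevel=2)
        for sid, (age, lab) in sheet.items():
            if sid not in present:
                continue
            if age is not None:
                ages.loc[sid] = age
            for k, v in lab.items():
                if k not in labels.columns:
                    labels[k] = pd.Series(index=labels.index, dtype=object)
                labels.loc[sid, k] = v
    if cytology:
        cyto_unmatched = [r.sample_id for r in cytology if r.sample_id not in present]
        if cyto_unmatched:
            warnings.warn(f"cytology entries not in matrix: {cyto_unmatched}", stacklevel=2)
        if PCT_EPITHELIAL_LABEL not in labels.columns:
            labels[PCT_EPITHELIAL_LABEL] = pd.Series(index=labels.index, dtype=object)
        for rec in cytology:
            if rec.sample_id in present:
                labels.loc[rec.sample_id, PCT_EPITHELIAL_LABEL] = repr(rec.pct_epithelial)
    return BetaMatrix(matrix.values, ages, labels)


def counted_fractions(matrix: BetaMatrix) -> pd.Series:
    """Counted epithelial percentages previously attached by :func:`join`.

    Returns a float Series indexed by sample ID (NaN where not counted).
    """
    if PCT_EPITHELIAL_LABEL not in matrix.labels.columns:
        return pd.Series(np.nan, index=matrix.values.index, dtype=float)
    return matrix.labels[PCT_EPITHELIAL_LABEL].astype(float)
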