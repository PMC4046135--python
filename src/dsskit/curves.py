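"""Dose-response data model, plate normalization and tabular I/O.

The primary on-disk format is a long table with one row per well
(``sample_id, drug_id, concentration_nM, response[, replicate]``).  In
memory a single sample x drug dilution series is a :class:`DoseResponseCurve`
and a cohort-level result is a :class:`ScoreMatrix` (samples x drugs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseCurve",
    "PlateControls",
    "ScoreMatrix",
    "DegeneratePlateError",
    "DrtParseError",
    "normalize_viability",
    "collapse_replicates",
    "read_drt_table",
    "curves_from_frame",
    "read_plate_controls",
    "write_score_matrix",
    "read_score_matrix",
]

REQUIRED_COLUMNS = ("sample_id", "drug_id", "concentration_nM", "response")


class DegeneratePlateError(ValueError):
    """Negative and positive control readouts coincide; the plate is unusable."""


class DrtParseError(ValueError):
    """A dose-response table violates the input contract."""


@dataclass(frozen=True)
class PlateControls:
    """Per-plate control readouts in raw (e.g. luminescence) units.

    ``negative_mean`` is the DMSO (vehicle) control defining 0 % inhibition,
    ``positive_mean`` the kill control (benzethonium chloride) defining
    100 % inhibition.
    """

    negative_mean: float
    positive_mean: float

    def __post_init__(self) -> None:
        if self.negative_mean == self.positive_mean:
            raise DegeneratePlateError(
                "negative and positive control means are equal "
                f"({self.negative_mean}); plate cannot be normalized"
            )


@dataclass(frozen=True)
class DoseResponseCurve:
    """One sample x drug dilution series, sorted by ascending concentration.

    Responses are percent growth inhibition (0 = no effect, 100 = complete
    inhibition).  Concentrations are nM and strictly increasing; replicate
    collapse must happen before construction (see :func:`collapse_replicates`).
    """

    sample_id: str
    drug_id: str
    concentrations: np.ndarray  # nM, strictly increasing
    responses: np.ndarray  # percent inhibition

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.ndim != 1 or conc.shape != resp.shape or conc.size < 1:
            raise ValueError("concentrations/responses must be equal-length 1-D arrays")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (nM)")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing; collapse replicates first")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    @property
    def log10_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)

    def __len__(self) -> int:
        return self.concentrations.size


@dataclass(frozen=True)
class ScoreMatrix:
    """Samples x drugs matrix of one response metric (DSS1/2/3, dDSS, AA, IC50).

    ``values`` is a DataFrame indexed by sample_id with drug_id columns;
    missing cells are NaN.  ``settings`` records the scoring settings the
    values were computed under (free-form key -> scalar mapping).
    """

    values: pd.DataFrame
    metric: str
    settings: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("sample and drug ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_viability(raw, controls: PlateControls):
    """Convert a raw viability readout to percent growth inhibition.

    ``100 * (neg - raw) / (neg - pos)``, clipped to [0, 100]: the DMSO
    control maps to 0 %, the kill control to 100 %, and growth stimulation
    (readout above the negative control) is treated as no inhibition.
    Accepts scalars or arrays.
    """
    neg, pos = controls.negative_mean, controls.positive_mean
    inhib = 100.0 * (neg - np.asarray(raw, dtype=float)) / (neg - pos)
    out = np.clip(inhib, 0.0, 100.0)
    return float(out) if np.isscalar(raw) else out


def collapse_replicates(
    concentrations: Sequence[float], responses: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse technical replicates to the per-concentration median.

    Returns (unique ascending concentrations, median responses).  Idempotent:
    applying it to already-collapsed data is the identity.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size == 0:
        raise ValueError("no data points")
    uniq = np.unique(conc)
    med = np.array([np.median(resp[conc == c]) for c in uniq])
    return uniq, med


def curves_from_frame(df: pd.DataFrame) -> list[DoseResponseCurve]:
    """Group a validated long-format table into collapsed, sorted curves."""
    curves = []
    for (sample, drug), grp in df.groupby(["sample_id", "drug_id"], sort=True):
        conc, resp = collapse_replicates(
            grp["concentration_nM"].to_numpy(), grp["response"].to_numpy()
        )
        curves.append(DoseResponseCurve(str(sample), str(drug), conc, resp))
    return curves


def _validate_drt_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DrtParseError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise DrtParseError("dose-response table contains no data rows")
    conc = pd.to_numeric(df["concentration_nM"], errors="coerce")
    bad = df.index[~(conc > 0)]
    if len(bad):
        # +2: header line plus 1-based numbering of the first data row
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise DrtParseError(
            f"non-positive or non-numeric concentration_nM at line(s) {lines}"
        )
    out = df.copy()
    out["concentration_nM"] = conc
    out["response"] = pd.to_numeric(out["response"], errors="raise")
    return out


def read_drt_table(path) -> list[DoseResponseCurve]:
    """Read a long-format dose-response CSV into collapsed curves.

    Required columns: sample_id, drug_id, concentration_nM, response.
    Optional columns (replicate, plate_id, ...) are carried through grouping
    but otherwise ignored; replicate rows are collapsed to the median.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise DrtParseError(f"empty dose-response file: {path}") from None
    return curves_from_frame(_validate_drt_frame(df))


def read_plate_controls(path) -> dict[str, PlateControls]:
    """Read a plate-control CSV (plate_id, negative_mean, positive_mean)."""
    df = pd.read_csv(path, comment="#")
    for col in ("plate_id", "negative_mean", "positive_mean"):
        if col not in df.columns:
            raise DrtParseError(f"missing required column(s): {col}")
    return {
        str(r.plate_id): PlateControls(float(r.negative_mean), float(r.positive_mean))
        for r in df.itertuples()
    }


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    """Write a ScoreMatrix as CSV with ``#``-comment header lines.

    The metric and every settings entry go into ``# key: value`` lines so the
    file round-trips through :func:`read_score_matrix` (missing cells become
    empty fields and return as NaN).
    """
    buf = io.StringIO()
    buf.write(f"# metric: {matrix.metric}\n")
    for key, val in matrix.settings.items():
        buf.write(f"# {key}: {val}\n")
    matrix.values.to_csv(buf, index_label="sample_id")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def _parse_setting(text: str):
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def read_score_matrix(path) -> ScoreMatrix:
    """Read a score-matrix CSV written by :func:`write_score_matrix`."""
    settings: dict[str, object] = {}
    metric = "unknown"
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "metric":
                    metric = val
                else:
                    settings[key] = _parse_setting(val)
        else:
            data_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(data_lines)), index_col="sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ScoreMatrix(values=df, metric=metric, settings=settings)
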