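"""Reading, validation, normalization and aggregation of gel-band time courses.

The package consumes pre-quantified band intensities (densitometry of
fluorescent SDS-PAGE gels) as delimited text with the long-format
header ``time_min, species, replicate, intensity``.  A reference
intensity of unreacted parent substrate — a separate gel lane never
exposed to the ubiquitination assay — is carried as header metadata and
is the denominator of the relative scale C_i / C_o on which model and
data are compared.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .models import SPECIES, UB_SPECIES

REQUIRED_COLUMNS = ("time_min", "species", "replicate", "intensity")


@dataclass(frozen=True)
class BandIntensityTable:
    """Long-format band intensities plus the parent reference intensity.

    ``frame`` has columns time_min (minutes >= 0), species (one of
    parent/mono/di/tri/tetra), replicate (positive integer id) and
    intensity (arbitrary fluorescence units >= 0).  ``metadata`` holds
    free-form provenance key-values round-tripped through the file
    header.
    """

    frame: pd.DataFrame
    parent_reference: float
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"missing required columns: {missing}")
        frame = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
        try:
            frame["time_min"] = frame["time_min"].astype(float)
            frame["replicate"] = frame["replicate"].astype(int)
            frame["intensity"] = frame["intensity"].astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric value in table: {exc}") from exc
        bad_species = sorted(set(frame["species"]) - set(SPECIES))
        if bad_species:
            raise ParseError(
                f"unknown species label(s) {bad_species}; expected one of {list(SPECIES)}"
            )
        if np.any(frame["time_min"].to_numpy() < 0):
            raise ParseError("time_min values must be >= 0")
        if np.any(frame["replicate"].to_numpy() < 1):
            raise ParseError("replicate ids must be positive integers")
        intensities = frame["intensity"].to_numpy()
        if not np.all(np.isfinite(intensities)) or np.any(intensities < 0):
            raise ParseError("intensities must be finite and >= 0")
        keys = frame[["time_min", "species", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ParseError(
                f"duplicate (time, species, replicate) key: "
                f"({dup['time_min']}, {dup['species']}, {dup['replicate']})"
            )
        if not np.isfinite(self.parent_reference) or self.parent_reference <= 0:
            raise ParseError(f"parent_reference must be > 0, got {self.parent_reference!r}")
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frame["time_min"].to_numpy())

    @property
    def n_replicates(self) -> int:
        return int(self.frame["replicate"].nunique())


def _detect_sep(header_line: str, dialect: str) -> str:
    if dialect == "auto":
        return "\t" if "\t" in header_line else ","
    if dialect in (",", "\t", "comma", "tab"):
        return {"comma": ",", "tab": "\t"}.get(dialect, dialect)
    raise ParseError(f"unknown dialect {dialect!r}; expected 'auto', 'comma' or 'tab'")


def read_timecourse(path, dialect: str = "auto", parent_reference: float | None = None) -> BandIntensityTable:
    """Parse a delimited band-intensity file.

    Leading ``# key: value`` lines are metadata; ``parent_reference``
    must appear there unless supplied as an argument.
    """
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    metadata: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                metadata[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise ParseError(f"{path}: no table content found")
    sep = _detect_sep(body_lines[0], dialect)
    try:
        frame = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=sep)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse table: {exc}") from exc
    if parent_reference is None:
        if "parent_reference" not in metadata:
            raise ParseError(
                f"{path}: parent_reference absent from header metadata and not supplied"
            )
        try:
            parent_reference = float(metadata["parent_reference"])
        except ValueError as exc:
            raise ParseError(f"{path}: invalid parent_reference: {exc}") from exc
    try:
        return BandIntensityTable(frame, parent_reference, metadata)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timecourse(table: BandIntensityTable, path, dialect: str = ",") -> None:
    """Write a table with metadata header lines; inverse of read_timecourse."""
    sep = _detect_sep("", dialect) if dialect != "auto" else ","
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# parent_reference: {table.parent_reference!r}\n")
        for key, value in table.metadata.items():
            if key == "parent_reference":
                continue
            handle.write(f"# {key}: {value}\n")
        table.frame.to_csv(handle, sep=sep, index=False)


def normalize_to_parent(table: BandIntensityTable) -> pd.DataFrame:
    """Per-replicate relative values C_i / C_o.

    Divides every intensity by the unreacted-parent reference; returns
    columns time_min, species, replicate, relative in input order.
    """
    if table.parent_reference <= 0:
        raise ValidationError("parent_reference must be > 0")
    out = table.frame.copy()
    out["relative"] = out["intensity"] / table.parent_reference
    return out.drop(columns=["intensity"])


@dataclass(frozen=True)
class TimeCourseDataset:
    """Replicate-aggregated relative time courses.

    ``mean`` and ``sd`` are (time x species) tables of the replicate
    average and sample standard deviation; absent cells are NaN and are
    skipped by the fitting objective.  ``replicates`` retains the
    per-replicate relative values for replicate-level fitting.
    """

    times: np.ndarray
    mean: pd.DataFrame
    sd: pd.DataFrame
    counts: pd.DataFrame
    n: int
    replicates: pd.DataFrame | None = None
    single_replicate_warning: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("replicate count must be >= 1")
        if np.nanmin(self.mean.to_numpy(), initial=0.0) < 0:
            raise ValidationError("relative values must be >= 0")
        if np.nanmin(self.sd.to_numpy(), initial=0.0) < 0:
            raise ValidationError("standard deviations must be >= 0")

    def values(self, species: str) -> np.ndarray:
        """Mean relative values of one species over ``times`` (NaN = absent)."""
        if species in self.mean.columns:
            return self.mean[species].to_numpy()
        return np.full(self.times.size, np.nan)

    def ub_matrix(self) -> np.ndarray:
        """(time x 4) matrix of the four ubiquitinated species' means."""
        return np.column_stack([self.values(s) for s in UB_SPECIES])


def aggregate_replicates(relative: pd.DataFrame) -> TimeCourseDataset:
    """Average replicates into a TimeCourseDataset.

    Mean and sample (n-1) standard deviation per (time, species); a
    single replicate yields sd = 0 and sets the warning flag.
    """
    if relative.empty:
        raise ValidationError("cannot aggregate an empty table")
    grouped = relative.groupby(["time_min", "species"])["relative"]
    mean = grouped.mean().unstack("species")
    counts = grouped.size().unstack("species")
    sd = grouped.std(ddof=1).unstack("species")
    single = bool((counts == 1).to_numpy(na_value=False).any())
    # a lone replicate has no spread estimate -> sd 0; absent cells stay NaN
    sd = sd.fillna(0.0).where(mean.notna())
    times = mean.index.to_numpy(dtype=float)
    n = int(relative["replicate"].nunique())
    return TimeCourseDataset(
        times=times,
        mean=mean,
        sd=sd,
        counts=counts,
        n=n,
        replicates=relative.copy(),
        single_replicate_warning=single,
    )


def load_dataset(path, dialect: str = "auto", parent_reference: float | None = None) -> TimeCourseDataset:
    """read -> normalize -> aggregate convenience pipeline."""
    table = read_timecourse(path, dialect=dialect, parent_reference=parent_reference)
    return aggregate_replicates(normalize_to_parent(table))
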