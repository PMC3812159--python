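"""Ranking of degrons by the k1/k5 metric and fit-result serialization.

Rate constants are reported on the conventional x10^3 display scale
(constants of a few 1e-3 per minute print as single-digit numbers);
internally everything stays per-minute.  A degron is classified
"favorable" when its substrate is mono-ubiquitinated faster than it is
degraded (k1/k5 > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .fitting import FitResult, k1_over_k5
from .models import UB_SPECIES, ModelTopology, RateConstants

_RATE_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9")


def display_scale(value: float) -> float:
    """Per-minute rate constant -> x10^3 display value, decimally exact."""
    return float(Decimal(repr(value)) * 1000)


@dataclass(frozen=True)
class DegronRanking:
    """Per-degron summary table ordered by k1/k5 descending.

    Ties in the ratio are ordered alphabetically by degron name.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        ratios = self.frame["k1_over_k5"].to_numpy()
        if np.any(np.diff(ratios) > 0):
            raise ValidationError("ranking must be ordered by k1/k5 descending")
        if not (self.frame["favorable"] == (self.frame["k1_over_k5"] > 1)).all():
            raise ValidationError("favorable flag inconsistent with ratio")

    @property
    def favorable(self) -> tuple[str, ...]:
        """Degrons with k1/k5 > 1, in ranking order."""
        sub = self.frame[self.frame["favorable"]]
        return tuple(sub["degron"])

    def to_csv(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def rank_degrons(
    results: Mapping[str, Union[FitResult, RateConstants]],
) -> DegronRanking:
    """Build a ranking table from per-degron fits (or bare constants).

    Accepts either :class:`FitResult` objects or plain
    :class:`RateConstants` (e.g. a transcribed reference table); cSSD
    and Pearson columns are NaN for the latter.
    """
    if not results:
        raise ValidationError("need >= 1 fit result to rank")
    rows = []
    for name, res in results.items():
        if isinstance(res, FitResult):
            params, cssd_val, pearson = res.params, res.cssd, dict(res.pearson)
        elif isinstance(res, RateConstants):
            params, cssd_val, pearson = res, np.nan, {}
        else:
            raise ValidationError(f"cannot rank object of type {type(res).__name__}")
        ratio = k1_over_k5(params)
        row = {"degron": name}
        for key in _RATE_NAMES:
            row[key] = display_scale(getattr(params, key))
        row["k1_over_k5"] = ratio
        row["cssd"] = cssd_val
        for species in UB_SPECIES:
            r = pearson.get(species)
            row[f"r_{species}"] = np.nan if r is None else r
        row["favorable"] = ratio > 1
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["k1_over_k5", "degron"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return DegronRanking(frame)


# ---------------------------------------------------------------------------
# Fit-result text serialization (key-value header + chain table)


def write_fit_result(result: FitResult, path, name: str | None = None) -> None:
    """Serialize a fit as a structured text document."""
    lines = ["# degronkinetics fit result"]
    if name is not None:
        lines.append(f"name: {name}")
    lines.append(f"variant: {result.topology.variant}")
    lines.append(f"native_ub_fraction: {result.topology.native_ub_fraction!r}")
    lines.append(f"seed: {result.seed}")
    lines.append(f"cssd: {result.cssd!r}")
    lines.append(f"acceptance_rate: {result.acceptance_rate!r}")
    for key in _RATE_NAMES:
        lines.append(f"{key}: {getattr(result.params, key)!r}")
    for species in UB_SPECIES:
        r = result.pearson.get(species)
        lines.append(f"r_{species}: {'NA' if r is None else repr(r)}")
    for warning in result.warnings:
        lines.append(f"warning: {warning}")
    lines.append("[chain]")
    lines.append(",".join(_RATE_NAMES))
    for row in result.chain:
        lines.append(",".join(repr(float(v)) for v in row))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")


def read_fit_result(path) -> tuple[FitResult, str | None]:
    """Parse a serialized fit; returns (result, optional degron name)."""
    with open(path, "r", encoding="utf-8") as handle:
        lines = [line.rstrip("\n") for line in handle]
    header: dict[str, str] = {}
    chain_rows: list[list[float]] = []
    in_chain = False
    warnings: list[str] = []
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        if line.strip() == "[chain]":
            in_chain = True
            continue
        if in_chain:
            if line.startswith("k1,"):
                continue
            chain_rows.append([float(v) for v in line.split(",")])
        else:
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if not _:
                raise ParseError(f"{path}: malformed header line {line!r}")
            if key == "warning":
                warnings.append(value)
            else:
                header[key] = value
    try:
        params = RateConstants(*(float(header[k]) for k in _RATE_NAMES))
        pearson = {
            s: (None if header[f"r_{s}"] == "NA" else float(header[f"r_{s}"]))
            for s in UB_SPECIES
        }
        result = FitResult(
            params=params,
            cssd=float(header["cssd"]),
            pearson=pearson,
            acceptance_rate=float(header["acceptance_rate"]),
            chain=np.array(chain_rows) if chain_rows else np.empty((0, 9)),
            best_trace=np.empty(0),
            seed=int(header["seed"]),
            topology=ModelTopology(header["variant"], float(header["native_ub_fraction"])),
            warnings=tuple(warnings),
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: invalid fit-result document: {exc}") from exc
    return result, header.get("name")
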