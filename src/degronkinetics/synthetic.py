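"""Synthetic gel-densitometry time courses with known ground truth.

Quantified fluorescence-gel experiments of this kind yield the relative
band intensity of parent and mono- through tetra-ubiquitinated
substrate at a handful of time points over a 0-240 min incubation, in
triplicate, with spread roughly proportional to signal.  This module
emulates exactly that: a noiseless trajectory from the kinetic model,
perturbed per replicate by multiplicative noise and truncated at zero.
Generated tables are consumable by the data module and carry their
generation parameters as header metadata.

It also ships a reference table of fitted rate constants for the nine
degron-based substrates studied with this assay (Bonger, p53, iNOS,
IFNAR1, TAZ, Cyclin D1, SRC3, HIF-1a, beta-Catenin), stored on the
per-minute scale.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BandIntensityTable
from .exceptions import UnknownDegronError, ValidationError
from .models import (
    MULTI_MONO,
    SPECIES,
    ModelTopology,
    RateConstants,
    simulate,
)

#: Default sampling grid (minutes): six points spanning the 240-min assay.
DEFAULT_TIMES = (10.0, 30.0, 60.0, 120.0, 180.0, 240.0)

#: Default replicate count.
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise law for simulated band intensities.

    ``gaussian_cv`` perturbs each value v to v * (1 + cv * z) with
    standard normal z, truncated at 0; ``lognormal`` multiplies by a
    unit-mean lognormal factor with the same coefficient of variation
    (strictly positive, no truncation needed).
    """

    kind: str = "gaussian_cv"
    cv: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_cv", "lognormal"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if not np.isfinite(self.cv) or self.cv < 0:
            raise ValidationError(f"cv must be >= 0, got {self.cv!r}")

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return values.copy()
        if self.kind == "gaussian_cv":
            noisy = values * (1.0 + self.cv * rng.standard_normal(values.shape))
            return np.clip(noisy, 0.0, None)
        sigma = np.sqrt(np.log1p(self.cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
        return values * factors


# Reference rate constants per degron, transcribed on the per-minute
# scale (the usual report convention multiplies them by 10^3).
REFERENCE_RATE_CONSTANTS: dict[str, RateConstants] = {
    "Bonger": RateConstants(8.1e-3, 3.6e-3, 2.1e-3, 1.5e-3, 4.0e-3, 0.01e-3, 1.0e-3, 0.01e-3, 0.01e-3),
    "p53": RateConstants(13.1e-3, 5.5e-3, 3.2e-3, 3.2e-3, 8.7e-3, 0.01e-3, 0.01e-3, 0.01e-3, 0.33e-3),
    "iNOS": RateConstants(6.8e-3, 2.7e-3, 2.5e-3, 1.4e-3, 4.2e-3, 1.0e-3, 0.01e-3, 0.01e-3, 0.3e-3),
    "IFNAR1": RateConstants(7.2e-3, 5.2e-3, 2.1e-3, 1.2e-3, 7.5e-3, 0.01e-3, 0.01e-3, 0.01e-3, 0.1e-3),
    "TAZ": RateConstants(6.1e-3, 7.2e-3, 4.7e-3, 2.2e-3, 2.3e-3, 1.5e-3, 0.1e-3, 0.5e-3, 0.1e-3),
    "Cyclin D1": RateConstants(3.4e-3, 5.9e-3, 4.1e-3, 2.1e-3, 7.2e-3, 0.01e-3, 0.01e-3, 0.01e-3, 1.8e-3),
    "SRC3": RateConstants(2.8e-3, 1.5e-3, 1.2e-3, 1.0e-3, 8.5e-3, 0.01e-3, 0.01e-3, 0.01e-3, 0.33e-3),
    "HIF-1α": RateConstants(2.6e-3, 3.0e-3, 1.9e-3, 1.0e-3, 7.0e-3, 0.1e-3, 0.1e-3, 0.4e-3, 0.8e-3),
    "β-Catenin": RateConstants(6.2e-3, 6.4e-3, 2.6e-3, 1.4e-3, 4.0e-3, 0.1e-3, 0.1e-3, 1.0e-3, 3.0e-3),
}

DEGRON_NAMES = tuple(REFERENCE_RATE_CONSTANTS)

# ASCII conveniences for the Greek-lettered degron names.
_ALIASES = {
    "hif-1a": "HIF-1α",
    "hif1a": "HIF-1α",
    "hif-1alpha": "HIF-1α",
    "beta-catenin": "β-Catenin",
    "b-catenin": "β-Catenin",
    "betacatenin": "β-Catenin",
    "cyclind1": "Cyclin D1",
    "cyclin-d1": "Cyclin D1",
}


def _canonical_name(name: str) -> str:
    normalized = unicodedata.normalize("NFC", name).strip()
    lowered = normalized.lower()
    for candidate in DEGRON_NAMES:
        if lowered == candidate.lower():
            return candidate
    alias = _ALIASES.get(lowered.replace(" ", ""))
    if alias is not None:
        return alias
    raise UnknownDegronError(
        f"unknown degron {name!r}; available: {', '.join(DEGRON_NAMES)}"
    )


def reference_parameters(name: str) -> RateConstants:
    """Reference rate constants for one degron (per-minute scale).

    Accepts ASCII aliases for the Greek-lettered names (e.g. "HIF-1a",
    "beta-Catenin"); raises :class:`UnknownDegronError` otherwise.
    """
    return REFERENCE_RATE_CONSTANTS[_canonical_name(name)]


def generate_timecourse(
    params: RateConstants,
    topology: ModelTopology = MULTI_MONO,
    times=DEFAULT_TIMES,
    noise: NoiseModel = NoiseModel(),
    n_reps: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> BandIntensityTable:
    """Simulate a band-intensity table from known rate constants.

    The noiseless trajectory (relative scale, parent_reference = 1) is
    perturbed independently per replicate and cell by ``noise``.
    Deterministic under a fixed ``seed``.
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    traj = simulate(params, topology, times=times)
    clean = np.column_stack([traj.species(s) for s in SPECIES])  # (n_times, 5)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        noisy = noise.perturb(clean, rng)
        for i, t in enumerate(traj.times):
            for j, species in enumerate(SPECIES):
                rows.append((t, species, rep, noisy[i, j]))
    frame = pd.DataFrame(rows, columns=["time_min", "species", "replicate", "intensity"])
    metadata = {
        "generator": "degronkinetics.synthetic.generate_timecourse",
        "seed": str(seed),
        "noise_kind": noise.kind,
        "noise_cv": repr(noise.cv),
        "n_reps": str(n_reps),
        "variant": topology.variant,
        "native_ub_fraction": repr(topology.native_ub_fraction),
        **{name: repr(value) for name, value in params.as_dict().items()},
    }
    return BandIntensityTable(frame, parent_reference=1.0, metadata=metadata)
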