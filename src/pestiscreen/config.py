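"""Framework configuration: model coefficients, cutoffs, bounds, references.

The packaged defaults encode the published screening rules:

* safer chemical space ("rule of 2"): log D_o/w < 1.7 and ΔE > 6 eV;
* Briggs "Rule of 3": log D_o/w < 3 for active-ingredient efficacy;
* substituent stabilization: total E(2) > 24 kcal/mol marks good
  photodegradation propensity;
* per-category performance bounds for five functional classes and seven
  modes of action (inclusive ranges).

The tier-2 electron-transfer coefficients (orbital gap → ΔG_et⁰, barrier →
log k) are calibration constants of the upstream kinetics model and are
deliberately exposed as plain config entries so users can refit them with
:func:`pestiscreen.substructural.fit_linear` against their own reference
data. The packaged defaults are documented placeholders: the gap → ΔG model
defaults to the pure eV→kcal/mol unit conversion (slope 23.0605, intercept
0), and the barrier → log k model defaults to coefficients calibrated so
that the default synthetic population reproduces its declared mixture-mean
log k moments (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .models import BoundsEntry, BoundsTable, LinearModel

#: Seed for the packaged synthetic E_LUMO reference distribution.
_ELUMO_REFERENCE_SEED = 20220330
#: Moments of the packaged synthetic E_LUMO reference (eV).
_ELUMO_REFERENCE_MEAN = -0.5
_ELUMO_REFERENCE_SD = 1.0
_ELUMO_REFERENCE_N = 1000

#: Published per-category performance boundary ranges:
#: (category, kind, log_d_min, log_d_max, delta_e_min, delta_e_max).
DEFAULT_BOUNDS = [
    ("acaricide", "functional_class", -0.55, 8.1, 3.75, 6.76),
    ("fungicide", "functional_class", -6.1, 6.34, 2.51, 7.13),
    ("herbicide", "functional_class", -1.53, 6.61, 3.43, 7.14),
    ("insecticide", "functional_class", -7.44, 7.19, 3.97, 6.96),
    ("undefined", "functional_class", -5.69, 11.47, 2.40, 7.17),
    ("UOP", "moa", -0.37, 4.22, 3.96, 5.43),
    ("ACE", "moa", 0.32, 4.89, 4.35, 6.51),
    ("N", "moa", -3.42, 5.74, 3.71, 10.08),
    ("CNS", "moa", -0.94, 6.77, 5.39, 6.61),
    ("EP", "moa", -0.88, 5.18, 3.62, 9.41),
    ("NDP", "moa", -2.12, 2.1, 4.54, 6.43),
    ("PN", "moa", -5.44, 5.74, 3.45, 7.71),
]


def default_bounds_table() -> BoundsTable:
    """The packaged 12-row performance-bounds table."""
    return BoundsTable([BoundsEntry(*row) for row in DEFAULT_BOUNDS])


def synthetic_elumo_reference(
    mean: float = _ELUMO_REFERENCE_MEAN,
    sd: float = _ELUMO_REFERENCE_SD,
    n: int = _ELUMO_REFERENCE_N,
    seed: int = _ELUMO_REFERENCE_SEED,
) -> list[float]:
    """SYNTHETIC stand-in for the no/low-concern E_LUMO reference set.

    The true reference distribution of no- to low-concern chemicals is not
    distributed with this package; this fixed-seed normal sample keeps the
    percentile machinery runnable and is labeled SYNTHETIC in every report.
    Users with the real reference list should load it via
    ``elumo_reference`` in the config file.
    """
    rng = np.random.default_rng(seed)
    return sorted(float(x) for x in rng.normal(mean, sd, n))


@dataclass
class Cutoffs:
    """Scalar screening cutoffs. All comparisons against them are strict."""

    log_d_safe: float = 1.7
    delta_e_safe_ev: float = 6.0
    briggs_log_d: float = 3.0
    e2_good_kcal: float = 24.0
    #: lower E(2) group boundary (withdrawing vs. weak/mixed); midpoint of
    #: the published group confidence-interval edges 9.9 and 14.3 kcal/mol.
    e2_lower_kcal: float = 12.0


@dataclass
class FrameworkConfig:
    """All tunables for a screening run.

    ``logk_predictor`` selects what the log k model is chained to:
    ``"barrier"`` (the Marcus barrier ΔG‡, default) or ``"gap"`` (the raw
    SOMO–HOMO gap in eV).
    """

    tier2_dg_model: LinearModel = field(
        default_factory=lambda: LinearModel(slope=23.0605, intercept=0.0)
    )
    marcus_lambda: float = 35.0  # reorganization energy, kcal/mol
    logk_model: LinearModel = field(
        default_factory=lambda: LinearModel(slope=-0.18, intercept=12.09)
    )
    logk_predictor: str = "barrier"
    log_k_max: float = 9.7  # diffusion-limited cap on log10 k
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    bounds_table: BoundsTable = field(default_factory=default_bounds_table)
    elumo_reference: list[float] = field(default_factory=synthetic_elumo_reference)
    #: True while elumo_reference is the packaged synthetic stand-in.
    elumo_reference_synthetic: bool = True

    def __post_init__(self) -> None:
        if self.marcus_lambda <= 0:
            raise ValidationError(
                f"marcus_lambda must be > 0, got {self.marcus_lambda}"
            )
        if self.logk_predictor not in ("barrier", "gap"):
            raise ConfigurationError(
                f"logk_predictor must be 'barrier' or 'gap', "
                f"got {self.logk_predictor!r}"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def model_dict(m: LinearModel) -> dict[str, float]:
            return {"slope": m.slope, "intercept": m.intercept}

        return {
            "tier2_dg_model": model_dict(self.tier2_dg_model),
            "marcus_lambda": self.marcus_lambda,
            "logk_model": model_dict(self.logk_model),
            "logk_predictor": self.logk_predictor,
            "log_k_max": self.log_k_max,
            "cutoffs": {
                "log_d_safe": self.cutoffs.log_d_safe,
                "delta_e_safe_ev": self.cutoffs.delta_e_safe_ev,
                "briggs_log_d": self.cutoffs.briggs_log_d,
                "e2_good_kcal": self.cutoffs.e2_good_kcal,
                "e2_lower_kcal": self.cutoffs.e2_lower_kcal,
            },
            "bounds_table": [
                {
                    "category": e.category,
                    "kind": e.kind,
                    "log_d_min": e.log_d_min,
                    "log_d_max": e.log_d_max,
                    "delta_e_min": e.delta_e_min,
                    "delta_e_max": e.delta_e_max,
                }
                for e in self.bounds_table.entries
            ],
            "elumo_reference": list(self.elumo_reference),
            "elumo_reference_synthetic": self.elumo_reference_synthetic,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FrameworkConfig":
        base = cls()
        try:
            kwargs: dict[str, Any] = {}
            if "tier2_dg_model" in d:
                kwargs["tier2_dg_model"] = LinearModel(**d["tier2_dg_model"])
            if "logk_model" in d:
                kwargs["logk_model"] = LinearModel(**d["logk_model"])
            for key in ("marcus_lambda", "logk_predictor", "log_k_max"):
                if key in d:
                    kwargs[key] = d[key]
            if "cutoffs" in d:
                kwargs["cutoffs"] = Cutoffs(**d["cutoffs"])
            if "bounds_table" in d:
                kwargs["bounds_table"] = BoundsTable(
                    [BoundsEntry(**row) for row in d["bounds_table"]]
                )
            if "elumo_reference" in d:
                kwargs["elumo_reference"] = [float(x) for x in d["elumo_reference"]]
                kwargs["elumo_reference_synthetic"] = bool(
                    d.get("elumo_reference_synthetic", False)
                )
            unknown = set(d) - {
                "tier2_dg_model", "logk_model", "marcus_lambda",
                "logk_predictor", "log_k_max", "cutoffs", "bounds_table",
                "elumo_reference", "elumo_reference_synthetic",
            }
            if unknown:
                raise ConfigurationError(
                    f"unknown config keys: {sorted(unknown)}"
                )
            return cls(**{**{}, **kwargs}) if kwargs else base
        except TypeError as exc:  # bad nested keys
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "FrameworkConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        try:
            data = yaml.safe_load(p.read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config {p}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {p} is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form; embedded in reports
        so redesign comparisons can enforce comparability."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
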