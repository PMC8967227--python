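"""Domain types shared by all tiers.

Unit conventions
----------------
Frontier-orbital energies (``e_homo``, ``e_lumo``, ``e_somo``) are stored in
eV. Reaction energetics (electron-transfer free energy ΔG_et⁰, Marcus barrier
ΔG‡, stabilization energies E(2)) are in kcal/mol. The conversion constant
``EV_TO_KCAL`` is applied only inside model operations, never in storage.
log D_o/w is the dimensionless octanol–water distribution coefficient at
pH 7.4.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .errors import DescriptorError, ValidationError

#: 1 eV per molecule = 23.0605 kcal/mol
EV_TO_KCAL = 23.0605


class FunctionalClass(str, enum.Enum):
    """Pesticide functional class (agronomic use category)."""

    acaricide = "acaricide"
    fungicide = "fungicide"
    herbicide = "herbicide"
    insecticide = "insecticide"
    undefined = "undefined"


class Moa(str, enum.Enum):
    """Mode of toxic action.

    UOP: uncoupling of oxidative phosphorylation; ACE: acetylcholinesterase
    inhibition; N: narcosis; CNS: central nervous system seizure/stimulant;
    EP: electrophile/pro-electrophile; NDP: neurodepressant; PN: polar
    narcosis.
    """

    UOP = "UOP"
    ACE = "ACE"
    N = "N"
    CNS = "CNS"
    EP = "EP"
    NDP = "NDP"
    PN = "PN"


class CoreClass(str, enum.Enum):
    """PPRI-oxidizable core chemotypes recognized by the detector."""

    phenol = "phenol"
    aniline = "aniline"
    aryl_ether = "aryl_ether"
    sulfide = "sulfide"
    thiol = "thiol"


@dataclass
class Compound:
    """A pesticide (or candidate analog) with its electronic descriptors.

    ``smiles`` is optional: descriptor-only workflows are allowed, but any
    structure-based operation (core detection, deduplication by structure)
    requires it. ``e_homo``/``e_lumo`` are in eV; ``log_d`` is log D_o/w at
    pH 7.4.
    """

    id: str
    e_homo: Optional[float] = None
    e_lumo: Optional[float] = None
    log_d: Optional[float] = None
    name: Optional[str] = None
    smiles: Optional[str] = None
    functional_class: Optional[FunctionalClass] = None
    moa: Optional[Moa] = None
    core_classes: Optional[frozenset[CoreClass]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("compound id must be a non-empty string")
        if self.e_homo is not None and self.e_lumo is not None:
            if self.e_lumo < self.e_homo:
                raise ValidationError(
                    f"compound {self.id!r}: e_lumo ({self.e_lumo}) < "
                    f"e_homo ({self.e_homo})"
                )

    @property
    def delta_e(self) -> float:
        """HOMO–LUMO gap ΔE in eV (≥ 0)."""
        return delta_e(self)


def delta_e(compound: Compound) -> float:
    """HOMO–LUMO gap ΔE = e_lumo − e_homo, in eV.

    Raises :class:`DescriptorError` if either orbital energy is missing.
    The gap is shift-invariant: adding a constant to both energies leaves
    it unchanged.
    """
    if compound.e_homo is None or compound.e_lumo is None:
        raise DescriptorError(
            f"compound {compound.id!r}: orbital energies required for ΔE"
        )
    return compound.e_lumo - compound.e_homo


@dataclass
class Sensitizer:
    """One ³CDOM* surrogate molecule with its SOMO energy in eV."""

    id: str
    cdom_class: str
    e_somo: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sensitizer id must be non-empty")
        if not math.isfinite(self.e_somo):
            raise ValidationError(f"sensitizer {self.id!r}: e_somo not finite")


@dataclass
class SensitizerPanel:
    """The ³CDOM* mixture: a panel of sensitizers with unique ids."""

    sensitizers: list[Sensitizer]

    def __post_init__(self) -> None:
        if not self.sensitizers:
            raise ValidationError("sensitizer panel is empty")
        ids = [s.id for s in self.sensitizers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sensitizer ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sensitizers)

    def __iter__(self) -> Iterator[Sensitizer]:
        return iter(self.sensitizers)

    @property
    def mean_somo(self) -> float:
        return sum(s.e_somo for s in self.sensitizers) / len(self.sensitizers)


@dataclass
class LinearModel:
    """A univariate linear model y = slope·x + intercept.

    The diagnostic fields (r2, rmse, n, p_value) are populated by
    :func:`pestiscreen.substructural.fit_linear`; hand-specified models
    carry only the coefficients.
    """

    slope: float
    intercept: float
    r2: Optional[float] = None
    rmse: Optional[float] = None
    n: Optional[int] = None
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValidationError("linear model coefficients must be finite")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"r2 out of [0, 1]: {self.r2}")
        if self.n is not None and self.n < 2:
            raise ValidationError(f"fitted model needs n >= 2, got {self.n}")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass
class PairResult:
    """One pesticide–sensitizer electron-transfer prediction.

    ``gap`` = E_SOMO(sensitizer) − E_HOMO(pesticide) in eV; energetics in
    kcal/mol; ``log_k`` is log10 of the second-order rate constant.
    """

    compound_id: str
    sensitizer_id: str
    gap: float
    dg_et0: float
    dg_barrier: float
    log_k: float


@dataclass
class MixtureSummary:
    """Mixture-averaged photodegradation potential for one compound."""

    compound_id: str
    mean_dg_et0: float
    mean_log_k: float
    n_pairs: int


@dataclass
class CompositeScore:
    """Percentile-combined thermodynamic/kinetic photodegradation score.

    ``pct_dg`` is oriented so that a *lower* (more favorable) ΔG_et⁰ gets a
    *higher* percentile; ``score`` is the arithmetic mean of the two
    percentiles, 0–100.
    """

    compound_id: str
    pct_log_k: float
    pct_dg: float
    score: float

    def __post_init__(self) -> None:
        for label, v in (
            ("pct_log_k", self.pct_log_k),
            ("pct_dg", self.pct_dg),
            ("score", self.score),
        ):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{label} out of [0, 100]: {v}")


@dataclass
class HazardAssessment:
    """Rule-of-2 / Briggs / E_LUMO screening verdicts for one compound."""

    compound_id: str
    log_d_ok: bool
    reactivity_ok: bool
    in_safe_space: bool
    briggs_ok: bool
    elumo_percentile: float

    def __post_init__(self) -> None:
        if self.in_safe_space != (self.log_d_ok and self.reactivity_ok):
            raise ValidationError(
                "in_safe_space must equal log_d_ok AND reactivity_ok"
            )


@dataclass
class BoundsEntry:
    """Performance boundary ranges for one functional-class or MOA category."""

    category: str
    kind: str  # "functional_class" or "moa"
    log_d_min: float
    log_d_max: float
    delta_e_min: float
    delta_e_max: float

    def __post_init__(self) -> None:
        if self.log_d_min > self.log_d_max:
            raise ValidationError(
                f"{self.category}: log_d_min > log_d_max"
            )
        if self.delta_e_min > self.delta_e_max:
            raise ValidationError(
                f"{self.category}: delta_e_min > delta_e_max"
            )


@dataclass
class BoundsTable:
    """Category → performance-boundary lookup (inclusive ranges)."""

    entries: list[BoundsEntry]

    def __post_init__(self) -> None:
        cats = [e.category for e in self.entries]
        if len(set(cats)) != len(cats):
            raise ValidationError("duplicate categories in bounds table")
        self._by_category = {e.category: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def categories(self) -> list[str]:
        return [e.category for e in self.entries]

    def get(self, category: str) -> Optional[BoundsEntry]:
        return self._by_category.get(category)


def mean(values: Sequence[float]) -> float:
    if not values:
        raise ValidationError("mean of empty sequence")
    return float(sum(values)) / len(values)
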