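"""Tier-2 indirect photodegradation: electron-transfer energetics and rates.

The rate-determining step of indirect photodegradation is single-electron
transfer from the pesticide to excited triplet-state chromophoric dissolved
organic matter (³CDOM*). Its driving force is modeled linearly in the
frontier-orbital gap

    gap = E_SOMO(sensitizer) − E_HOMO(pesticide)   [eV]
    ΔG_et⁰ = slope · gap + intercept               [kcal/mol]

so a higher pesticide HOMO means a smaller gap and a more favorable
(lower) ΔG_et⁰. The activation barrier follows classical Marcus theory,

    ΔG‡ = (λ + ΔG⁰)² / (4λ)

with reorganization energy λ > 0, and log10 of the second-order rate
constant is a linear function of the barrier (or, optionally, of the raw
gap), capped at the diffusion limit.

Mixture behavior is emulated by averaging each compound's pairwise
predictions over the full sensitizer panel, and compounds are ranked with a
composite percentile score combining kinetic (log k) and thermodynamic
(−ΔG_et⁰) standing in the population.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .config import FrameworkConfig
from .errors import DescriptorError, ParameterError, ValidationError
from .models import (
    Compound,
    CompositeScore,
    LinearModel,
    MixtureSummary,
    PairResult,
    Sensitizer,
    SensitizerPanel,
)


def predict_dg(c: Compound, s: Sensitizer, model: LinearModel) -> float:
    """ΔG_et⁰ (kcal/mol) for one pesticide–sensitizer pair.

    ``model`` maps the SOMO−HOMO gap (eV) to kcal/mol; the packaged default
    is the pure unit conversion (slope 23.0605, intercept 0).
    """
    if c.e_homo is None:
        raise DescriptorError(f"compound {c.id!r}: e_homo required")
    if s.e_somo is None or not math.isfinite(s.e_somo):
        raise DescriptorError(f"sensitizer {s.id!r}: e_somo required")
    gap = s.e_somo - c.e_homo
    return model.predict(gap)


def marcus_barrier(dg_et0: float, lambda_reorg: float) -> float:
    """Marcus activation free energy ΔG‡ = (λ + ΔG⁰)²/(4λ), kcal/mol.

    Non-negative everywhere, zero exactly at the activationless point
    ΔG⁰ = −λ, and convex in ΔG⁰ (the inverted region ΔG⁰ < −λ slows back
    down).
    """
    if lambda_reorg <= 0:
        raise ParameterError(
            f"reorganization energy must be > 0, got {lambda_reorg}"
        )
    return (lambda_reorg + dg_et0) ** 2 / (4.0 * lambda_reorg)


def logk_from_barrier(dg_barrier: float, model: LinearModel, cap: float) -> float:
    """log10 k from the activation barrier, capped at the diffusion limit.

    With a negative slope this is monotone non-increasing in the barrier.
    """
    if not math.isfinite(cap):
        raise ParameterError(f"diffusion cap must be finite, got {cap}")
    return min(model.predict(dg_barrier), cap)


def assess_pair(
    c: Compound, s: Sensitizer, config: Optional[FrameworkConfig] = None
) -> PairResult:
    """Full tier-2 chain for one pair: gap → ΔG_et⁰ → ΔG‡ → log k."""
    config = config or FrameworkConfig()
    if c.e_homo is None:
        raise DescriptorError(f"compound {c.id!r}: e_homo required")
    gap = s.e_somo - c.e_homo
    dg = config.tier2_dg_model.predict(gap)
    barrier = marcus_barrier(dg, config.marcus_lambda)
    predictor = barrier if config.logk_predictor == "barrier" else gap
    log_k = logk_from_barrier(predictor, config.logk_model, config.log_k_max)
    return PairResult(
        compound_id=c.id,
        sensitizer_id=s.id,
        gap=gap,
        dg_et0=dg,
        dg_barrier=barrier,
        log_k=log_k,
    )


def assess_pairs(
    compounds: Sequence[Compound],
    panel: SensitizerPanel,
    config: Optional[FrameworkConfig] = None,
) -> list[PairResult]:
    """All |compounds| × |panel| pairwise predictions, in input order."""
    config = config or FrameworkConfig()
    return [assess_pair(c, s, config) for c in compounds for s in panel]


def mixture_average(pairs: Sequence[PairResult]) -> MixtureSummary:
    """Mixture-averaged ΔG_et⁰ and log k for one compound across the panel."""
    if not pairs:
        raise ValidationError("mixture_average needs at least one pair")
    ids = {p.compound_id for p in pairs}
    if len(ids) != 1:
        raise ValidationError(f"mixed compound ids in mixture_average: {sorted(ids)}")
    return MixtureSummary(
        compound_id=pairs[0].compound_id,
        mean_dg_et0=float(np.mean([p.dg_et0 for p in pairs])),
        mean_log_k=float(np.mean([p.log_k for p in pairs])),
        n_pairs=len(pairs),
    )


def summarize_mixture(
    pairs: Sequence[PairResult],
) -> list[MixtureSummary]:
    """Group pairwise results by compound (input order) and average each."""
    by_compound: dict[str, list[PairResult]] = {}
    for p in pairs:
        by_compound.setdefault(p.compound_id, []).append(p)
    return [mixture_average(group) for group in by_compound.values()]


def percentile_rank(
    values: Sequence[float], x: float, exclude_self: bool = True
) -> float:
    """Counting percentile of ``x`` against a reference population, 0–100.

    Convention: (#below + ½·#equal)/n × 100 over the reference, with the
    midrank ½ handling ties. When ``exclude_self`` is set (the default) one
    exact occurrence of ``x`` is removed from the reference first, so that a
    member of a population is ranked against the *other* members: the unique
    maximum of a list scores 100, the median of {1..5} scores 50, and two
    identical members score 50 against each other. For an external query
    value the two conventions coincide.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("percentile_rank needs a non-empty reference")
    if exclude_self:
        matches = np.flatnonzero(arr == x)
        if matches.size:
            arr = np.delete(arr, matches[0])
        if arr.size == 0:
            # a lone member is its own median
            return 50.0
    below = int(np.count_nonzero(arr < x))
    equal = int(np.count_nonzero(arr == x))
    return 100.0 * (below + 0.5 * equal) / arr.size


def composite_score(summaries: Sequence[MixtureSummary]) -> list[CompositeScore]:
    """Composite photodegradation score for each compound in a population.

    ``pct_log_k`` ranks the mixture-mean log k (higher = faster = higher
    percentile); ``pct_dg`` ranks −ΔG_et⁰ (lower free energy = more
    favorable = higher percentile); the score is their arithmetic mean.
    Being rank-based, the score is invariant under any strictly increasing
    transform of either underlying quantity.
    """
    if len(summaries) < 2:
        raise ValidationError(
            "composite_score needs a population of >= 2 compounds; "
            "supply a reference population to rank against"
        )
    log_ks = [s.mean_log_k for s in summaries]
    neg_dgs = [-s.mean_dg_et0 for s in summaries]
    out = []
    for s in summaries:
        pk = percentile_rank(log_ks, s.mean_log_k)
        pd_ = percentile_rank(neg_dgs, -s.mean_dg_et0)
        out.append(CompositeScore(
            compound_id=s.compound_id,
            pct_log_k=pk,
            pct_dg=pd_,
            score=0.5 * (pk + pd_),
        ))
    return out
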