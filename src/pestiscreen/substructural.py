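"""Tier-3 substructural models.

Two complementary views of how ring substituents control the stability of
the radical cation left behind by electron transfer:

* **E(2) stabilization** — natural-bond-orbital second-order perturbation
  energies for substituent → ring donor–acceptor interactions are summed
  per compound (E_stab = Σ E(2)); totals above 24 kcal/mol mark compounds
  with good propensity to photodegrade. Totals partition into three
  substituent-character groups: strongly electron-withdrawing, weakly
  withdrawing/donating, and strongly electron-donating.
* **Hirshfeld ring charge** — the total Hirshfeld partial charge on the
  aromatic ring (Σ_r X_C) predicts ΔG_et⁰ through a univariate linear
  model; more electron density on the core (more negative charge sum)
  means more facile photodegradation. The packaged coefficients are
  slope 146.62 kcal/mol per charge unit and intercept −38.89 kcal/mol.

Both E(2) values and Hirshfeld charges are *inputs* (from the user's own
wavefunction analysis); nothing here touches electronic structure.

The module also hosts :func:`fit_linear`, the ordinary-least-squares fitter
used across tiers to (re)calibrate any of the univariate models.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import Cutoffs
from .errors import DegenerateFitError, ValidationError
from .models import LinearModel

#: Default ring-charge → ΔG_et⁰ model (kcal/mol per elementary charge).
DEFAULT_RING_CHARGE_MODEL = LinearModel(slope=146.62, intercept=-38.89)


class E2Group(str, enum.Enum):
    """Substituent character inferred from total E(2) stabilization."""

    strongly_withdrawing = "strongly_withdrawing"
    weak_mixed = "weak_mixed"
    strongly_donating = "strongly_donating"


@dataclass
class SubstituentAnalysis:
    """Per-compound E(2) bookkeeping and group assignment."""

    compound_id: str
    e2_pairwise: list[tuple[str, float]]
    e2_total: float
    e2_group: E2Group
    good_photodeg: bool


@dataclass
class RingChargeRecord:
    """Per-compound Hirshfeld ring-charge sum and predicted ΔG_et⁰."""

    compound_id: str
    sum_ring_charge: float
    dg_pred: float


def e2_total(pairwise: Sequence[float]) -> float:
    """Total stabilization energy: the sum of pairwise E(2) values.

    Stabilization energies are non-negative by construction; a negative
    entry indicates corrupted input and raises.
    """
    for v in pairwise:
        if v < 0:
            raise ValidationError(f"negative E(2) value: {v}")
    return float(sum(pairwise))


def e2_group(
    total: float, cutoffs: Optional[Cutoffs] = None
) -> tuple[E2Group, bool]:
    """Group a total E(2) and flag good photodegradation propensity.

    The grouping partitions [0, ∞) exhaustively and disjointly:
    [0, lower) → strongly withdrawing; [lower, good] → weak/mixed;
    (good, ∞) → strongly donating. ``good_photodeg`` is the strict
    total > 24 kcal/mol criterion, so the upper group boundary coincides
    with the good-photodegradation cutoff.
    """
    cutoffs = cutoffs or Cutoffs()
    if total < 0:
        raise ValidationError(f"negative E(2) total: {total}")
    if total < cutoffs.e2_lower_kcal:
        group = E2Group.strongly_withdrawing
    elif total <= cutoffs.e2_good_kcal:
        group = E2Group.weak_mixed
    else:
        group = E2Group.strongly_donating
    return group, total > cutoffs.e2_good_kcal


def analyze_substituents(
    compound_id: str,
    pairwise: Sequence[tuple[str, float]],
    cutoffs: Optional[Cutoffs] = None,
) -> SubstituentAnalysis:
    total = e2_total([v for _, v in pairwise])
    group, good = e2_group(total, cutoffs)
    return SubstituentAnalysis(
        compound_id=compound_id,
        e2_pairwise=list(pairwise),
        e2_total=total,
        e2_group=group,
        good_photodeg=good,
    )


def hirshfeld_dg(
    sum_ring_charge: float, model: Optional[LinearModel] = None
) -> float:
    """ΔG_et⁰ (kcal/mol) predicted from the total Hirshfeld ring charge."""
    model = model or DEFAULT_RING_CHARGE_MODEL
    return model.predict(sum_ring_charge)


def ring_charge_record(
    compound_id: str,
    sum_ring_charge: float,
    model: Optional[LinearModel] = None,
) -> RingChargeRecord:
    return RingChargeRecord(
        compound_id=compound_id,
        sum_ring_charge=sum_ring_charge,
        dg_pred=hirshfeld_dg(sum_ring_charge, model),
    )


def fit_linear(
    x: Sequence[float], y: Sequence[float], rmse_divisor: str = "n"
) -> LinearModel:
    """Ordinary least squares y = slope·x + intercept with diagnostics.

    r² = 1 − SS_res/SS_tot (defined as 0 when y is constant); RMSE uses
    divisor n by default (``rmse_divisor="n-2"`` gives the residual
    standard error instead); the p-value is the two-sided test of
    slope ≠ 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    n = xa.size
    if n < 2:
        raise DegenerateFitError(f"need n >= 2 points, got {n}")
    ssx = float(np.sum((xa - xa.mean()) ** 2))
    if ssx == 0.0:
        raise DegenerateFitError("x is constant; slope undefined")
    if rmse_divisor not in ("n", "n-2"):
        raise ValidationError(f"rmse_divisor must be 'n' or 'n-2'")

    slope = float(np.sum((xa - xa.mean()) * (ya - ya.mean())) / ssx)
    intercept = float(ya.mean() - slope * xa.mean())
    resid = ya - (slope * xa + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # numerical guard: exact fits can land at 1 + eps
    r2 = min(max(r2, 0.0), 1.0)
    divisor = n if rmse_divisor == "n" else max(n - 2, 1)
    rmse = math.sqrt(ss_res / divisor)

    if n > 2 and ss_res > 0:
        se_slope = math.sqrt(ss_res / (n - 2) / ssx)
        t = slope / se_slope
        p_value = 2.0 * float(stats.t.sf(abs(t), n - 2))
    else:
        # exact interpolation (or n == 2): the test statistic degenerates
        p_value = 0.0 if slope != 0 else 1.0
    return LinearModel(
        slope=slope, intercept=intercept, r2=r2, rmse=rmse, n=n,
        p_value=p_value,
    )


@dataclass(frozen=True)
class GroupCI:
    """Mean and t-based confidence interval for one substituent group."""

    group: str
    n: int
    mean: float
    ci_low: float
    ci_high: float

    @property
    def half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


def group_confidence_intervals(
    groups: dict[str, Sequence[float]], level: float = 0.99
) -> dict[str, GroupCI]:
    """Per-group mean ± t(level, n−1)·s/√n confidence intervals.

    Groups with fewer than two members are degenerate and raise.
    """
    out: dict[str, GroupCI] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        n = arr.size
        if n < 2:
            raise DegenerateFitError(
                f"group {name!r} needs n >= 2 for a confidence interval"
            )
        m = float(arr.mean())
        s = float(arr.std(ddof=1))
        half = float(stats.t.ppf(0.5 + level / 2.0, n - 1)) * s / math.sqrt(n)
        out[name] = GroupCI(group=name, n=n, mean=m, ci_low=m - half,
                            ci_high=m + half)
    return out
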