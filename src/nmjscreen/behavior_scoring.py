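"""Screen and Rescreen statistics.

The primary screen scores every treated fish with a robust z-score against
the plate's wild-type controls after median normalization, then classifies
each drug's quadruplicate into TOXIC / NON_HIT / HIT_A / HIT_B.  The
rescreen rescales raw distances to a 0-100 "normalized percent activation"
(NPA) between the morphant and wild-type control medians and passes drugs
whose mean NPA reaches the cutoff.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .screen_data import FishObservation, Group, ScreenTable

__all__ = [
    "Category",
    "NpaVariant",
    "ControlSummary",
    "PlateControls",
    "ScreenScore",
    "NPAResult",
    "ScreenReport",
    "z_prime",
    "median_normalize",
    "robust_z",
    "classify_drug",
    "screen",
    "npa",
    "rescreen",
    "dose_response_summary",
    "dilution_concentration",
    "hit_percentage",
    "category_partition_total",
    "mad",
]


class Category(enum.Enum):
    TOXIC = "TOXIC"
    NON_HIT = "NON_HIT"
    HIT_A = "HIT_A"
    HIT_B = "HIT_B"


class NpaVariant(enum.Enum):
    #: (X - mu_n) / (mu_p - mu_n) * 100: morphant median -> 0, WT median -> 100
    STANDARD = "STANDARD"
    #: the sign-flipped printed form (mu_n - X) / (mu_p - mu_n) * 100
    AS_PRINTED = "AS_PRINTED"


def mad(values: Sequence[float], consistency: float = 1.0) -> float:
    """Median absolute deviation.

    ``consistency`` defaults to 1.0 (raw MAD); pass 1.4826 for the normal
    consistency constant.
    """
    vals = list(values)
    m = median(vals)
    return consistency * median([abs(v - m) for v in vals])


@dataclass(frozen=True)
class ControlSummary:
    """Median / MAD / count of one control group's values."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def from_values(cls, values: Sequence[float], consistency: float = 1.0) -> "ControlSummary":
        vals = list(values)
        if not vals:
            raise ValueError("cannot summarize an empty control group")
        return cls(mu=float(median(vals)), sigma=float(mad(vals, consistency)), n=len(vals))


@dataclass(frozen=True)
class PlateControls:
    plate_index: int
    wt: ControlSummary  # positive control
    mo: ControlSummary  # negative control


class SeparationError(ValueError):
    """Positive and negative control medians coincide."""


def z_prime(pos: ControlSummary, neg: ControlSummary) -> float:
    """Assay-quality factor 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|.

    The absolute separation makes the value invariant under swapping which
    control is labeled positive.  Always <= 1, and equals 1 only when both
    spreads are zero.
    """
    sep = abs(pos.mu - neg.mu)
    if sep == 0:
        raise SeparationError("control medians are equal: Z' undefined")
    return 1.0 - 3.0 * (pos.sigma + neg.sigma) / sep


class NormalizationError(ValueError):
    pass


def median_normalize(
    distances: Sequence[float], wt_controls: Sequence[float]
) -> list[float]:
    """Fold-of-control normalization: x' = x / median(wild-type controls)."""
    if not list(wt_controls):
        raise NormalizationError("no wild-type control values to normalize against")
    m = median(list(wt_controls))
    if m == 0:
        raise NormalizationError("wild-type control median is zero")
    return [x / m for x in distances]


#: divisor floor used when the control MAD collapses to zero
_MIN_SPREAD = 1e-9


def _guarded_mad(values: Sequence[float], consistency: float = 1.0) -> float:
    s = mad(values, consistency)
    if s == 0:
        m = abs(median(list(values)))
        s = _MIN_SPREAD * (m if m > 0 else 1.0)
        warnings.warn(
            "control MAD is zero; substituting a minimal spread so z-scores stay finite",
            RuntimeWarning,
            stacklevel=3,
        )
    return s


def robust_z(
    x_prime: float, wt_prime: Sequence[float], consistency: float = 1.0
) -> float:
    """z = (x' - median(c')) / mad(c') against normalized wild-type controls."""
    c = list(wt_prime)
    if not c:
        raise ValueError("wt_prime must be non-empty")
    return (x_prime - median(c)) / _guarded_mad(c, consistency)


@dataclass(frozen=True)
class ScreenScore:
    drug_id: str
    fish_z: tuple[float | None, ...]  # None marks a dead fish (z undefined)
    alive: tuple[bool, ...]
    mean_z: float | None
    n_dead: int
    category: Category


def classify_drug(
    fish: Sequence[tuple[float | None, bool]],
    mean_z_threshold: float = 0.0,
    fish_z_threshold: float = -1.0,
    toxic_dead_min: int = 3,
    min_rescued: int = 2,
    replicate_count: int = 4,
) -> Category:
    """Four-way call on one drug's quadruplicate.

    ``fish`` is a sequence of (z, alive) with z = None for dead fish.
    TOXIC when >= ``toxic_dead_min`` fish are dead; otherwise a hit when at
    least ``min_rescued`` living fish exceed ``fish_z_threshold`` — HIT_A if
    the mean z over living fish exceeds ``mean_z_threshold``, HIT_B
    otherwise; anything else is NON_HIT.  Dead fish never satisfy the
    per-fish criterion.
    """
    if len(fish) != replicate_count:
        raise ValueError(f"expected {replicate_count} fish, got {len(fish)}")
    n_dead = sum(1 for _, a in fish if not a)
    if n_dead >= toxic_dead_min:
        return Category.TOXIC
    alive_z = [z for z, a in fish if a and z is not None]
    n_rescued = sum(1 for z in alive_z if z > fish_z_threshold)
    if n_rescued >= min_rescued:
        mean_z = sum(alive_z) / len(alive_z)
        return Category.HIT_A if mean_z > mean_z_threshold else Category.HIT_B
    return Category.NON_HIT


@dataclass
class ScreenReport:
    scores: list[ScreenScore]
    plate_z_prime: dict[int, float]
    plate_controls: dict[int, PlateControls]
    category_counts: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "plate_z_prime": {str(k): v for k, v in self.plate_z_prime.items()},
            "category_counts": dict(self.category_counts),
            "n_drugs": len(self.scores),
        }


class MissingControlsError(ValueError):
    pass


def _usable(obs: Iterable[FishObservation]) -> list[FishObservation]:
    return [o for o in obs if not o.excluded]


def _alive_distances(obs: Iterable[FishObservation]) -> list[float]:
    return [o.distance_m for o in obs if o.alive]


def plate_controls(table: ScreenTable, plate_index: int) -> PlateControls:
    wt = _alive_distances(_usable(table.controls(Group.WT_CONTROL, plate_index)))
    mo = _alive_distances(_usable(table.controls(Group.MO_CONTROL, plate_index)))
    if not wt:
        raise MissingControlsError(f"plate {plate_index} has no living WT controls")
    if not mo:
        raise MissingControlsError(f"plate {plate_index} has no living MO controls")
    return PlateControls(
        plate_index=plate_index,
        wt=ControlSummary.from_values(wt),
        mo=ControlSummary.from_values(mo),
    )


def screen(
    table: ScreenTable,
    mean_z_threshold: float = 0.0,
    fish_z_threshold: float = -1.0,
    toxic_dead_min: int = 3,
) -> ScreenReport:
    """Score and classify every drug of the primary screen, plate by plate."""
    per_plate_wt_prime: dict[int, list[float]] = {}
    controls: dict[int, PlateControls] = {}
    zprimes: dict[int, float] = {}
    for plate in table.plates():
        pc = plate_controls(table, plate)
        controls[plate] = pc
        try:
            zprimes[plate] = z_prime(pc.wt, pc.mo)
        except SeparationError:
            zprimes[plate] = float("nan")
        wt_raw = _alive_distances(_usable(table.controls(Group.WT_CONTROL, plate)))
        per_plate_wt_prime[plate] = median_normalize(wt_raw, wt_raw)

    scores: list[ScreenScore] = []
    for drug, obs in sorted(table.by_drug().items()):
        obs = sorted(_usable(obs), key=lambda o: o.fish_index)
        plates_used = {o.address.plate_index for o in obs}
        if len(plates_used) != 1:
            raise ValueError(
                f"drug {drug}: replicates span plates {sorted(plates_used)}; "
                "all fish of a drug must share one reading plate"
            )
        plate = plates_used.pop()
        wt_raw = _alive_distances(_usable(table.controls(Group.WT_CONTROL, plate)))
        wt_prime = per_plate_wt_prime[plate]
        fish_z: list[float | None] = []
        alive: list[bool] = []
        for o in obs:
            alive.append(o.alive)
            if not o.alive:
                fish_z.append(None)
            else:
                xp = median_normalize([o.distance_m], wt_raw)[0]
                fish_z.append(robust_z(xp, wt_prime))
        n_dead = sum(1 for a in alive if not a)
        alive_z = [z for z, a in zip(fish_z, alive) if a and z is not None]
        mean_z = sum(alive_z) / len(alive_z) if alive_z else None
        category = classify_drug(
            list(zip(fish_z, alive)),
            mean_z_threshold=mean_z_threshold,
            fish_z_threshold=fish_z_threshold,
            toxic_dead_min=toxic_dead_min,
            replicate_count=len(obs),
        )
        scores.append(
            ScreenScore(
                drug_id=drug,
                fish_z=tuple(fish_z),
                alive=tuple(alive),
                mean_z=mean_z,
                n_dead=n_dead,
                category=category,
            )
        )

    counts = {c.value: 0 for c in Category}
    for s in scores:
        counts[s.category.value] += 1
    return ScreenReport(
        scores=scores,
        plate_z_prime=zprimes,
        plate_controls=controls,
        category_counts=counts,
    )


def npa(
    X: float, controls: PlateControls, variant: NpaVariant = NpaVariant.STANDARD
) -> float:
    """Normalized percent activation of a raw distance against plate controls.

    STANDARD maps the morphant control median to 0 and the wild-type median
    to 100; AS_PRINTED is the sign-flipped published formula, kept for
    comparability.
    """
    mu_p, mu_n = controls.wt.mu, controls.mo.mu
    if mu_p == mu_n:
        raise SeparationError("control medians are equal: NPA undefined")
    if variant is NpaVariant.AS_PRINTED:
        return (mu_n - X) / (mu_p - mu_n) * 100.0
    return (X - mu_n) / (mu_p - mu_n) * 100.0


@dataclass(frozen=True)
class NPAResult:
    drug_id: str
    fish_npa: tuple[float, ...]  # living fish only
    mean_npa: float | None
    pass50: bool


def rescreen(
    table: ScreenTable,
    cutoff: float = 50.0,
    variant: NpaVariant = NpaVariant.STANDARD,
) -> list[NPAResult]:
    """Per-drug mean NPA over living fish; pass when mean >= cutoff (inclusive)."""
    ctrl = {p: plate_controls(table, p) for p in table.plates()}
    results = []
    for drug, obs in sorted(table.by_drug().items()):
        values = [
            npa(o.distance_m, ctrl[o.address.plate_index], variant)
            for o in sorted(_usable(obs), key=lambda o: o.fish_index)
            if o.alive
        ]
        mean_npa = sum(values) / len(values) if values else None
        results.append(
            NPAResult(
                drug_id=drug,
                fish_npa=tuple(values),
                mean_npa=mean_npa,
                pass50=(mean_npa is not None and mean_npa >= cutoff),
            )
        )
    return results


def dose_response_summary(
    tables: Mapping[float, ScreenTable],
    toxic_dead_fraction: float | None = None,
) -> dict[float, dict]:
    """Per-dose mean/SEM of treated distances plus a toxicity flag.

    A dose is toxic when its dead fraction reaches ``toxic_dead_fraction``
    (default 3/replicate_count, mirroring the behavioral toxicity rule);
    toxic doses are excluded from the response curve.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 doses")
    out: dict[float, dict] = {}
    for dose in sorted(tables):
        table = tables[dose]
        treated = [o for o in _usable(table.observations) if o.group is Group.TREATED]
        n = len(treated)
        n_dead = sum(1 for o in treated if not o.alive)
        alive_d = [o.distance_m for o in treated if o.alive]
        frac = toxic_dead_fraction
        if frac is None:
            frac = min(3, table.replicate_count) / table.replicate_count
        toxic = n > 0 and (n_dead / n) >= frac
        mean = float(np.mean(alive_d)) if alive_d else None
        sem = (
            float(np.std(alive_d, ddof=1) / math.sqrt(len(alive_d)))
            if len(alive_d) > 1
            else None
        )
        out[dose] = {
            "n": n,
            "n_dead": n_dead,
            "dead_fraction": (n_dead / n) if n else 0.0,
            "mean_distance_m": mean,
            "sem_distance_m": sem,
            "toxic": toxic,
            "in_curve": not toxic,
        }
    return out


# ---------------------------------------------------------------------------
# small arithmetic helpers used by reports
# ---------------------------------------------------------------------------


def dilution_concentration(
    stock_concentration: float, stock_volume: float, added_to_volume: float
) -> float:
    """Concentration after adding ``stock_volume`` of stock to ``added_to_volume``
    of medium (same units): C * V_stock / (V_stock + V_medium)."""
    total = stock_volume + added_to_volume
    if total <= 0:
        raise ValueError("total volume must be positive")
    return stock_concentration * stock_volume / total


def hit_percentage(n_hits: int, library_size: int) -> float:
    """100 x hits / library size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return 100.0 * n_hits / library_size


def category_partition_total(counts: Mapping[str, int]) -> int:
    """Sum of category counts; the partition invariant says this equals the
    number of screened drugs."""
    expected = {c.value for c in Category}
    unknown = set(counts) - expected
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    return sum(counts.values())
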