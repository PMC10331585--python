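"""Synthetic inputs for every pipeline stage.

Three generators: behavioral screen tables (96-well layout, wild-type and
morphant controls in columns 1 and 12, treated drugs in quadruplicate),
drug->target / target-target interaction tables with designed recurrence,
and two-channel neuromuscular-junction micrographs with full ground truth.

All generators are pure functions of their parameters and a seed; every
stage draws from an independent RNG stream keyed off (seed, stage name) so
that, e.g., adding drugs does not perturb the control draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .screen_data import (
    ROWS,
    DrugRecord,
    FishObservation,
    Group,
    ScreenTable,
    WellAddress,
)

__all__ = [
    "CohortParams",
    "DrugEffect",
    "NetworkParams",
    "ImageTruth",
    "Spot",
    "rng_for",
    "simulate_screen",
    "simulate_rescreen",
    "simulate_drug_target_tables",
    "simulate_nmj_image",
    "make_image_truth",
    "write_nmj_image",
    "read_nmj_image",
]

#: treated-plate geometry: drugs occupy columns 2..11, controls columns 1 / 12
DRUG_COLUMNS = tuple(range(2, 12))
DRUGS_PER_PLATE = len(ROWS) * len(DRUG_COLUMNS)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Independent deterministic stream for (seed, stage)."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# behavioral screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugEffect:
    """Per-drug generative effect: rescue strength e in [0,1] and toxicity."""

    rescue_strength: float = 0.0
    p_tox: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rescue_strength <= 1.0:
            raise ValueError(f"rescue_strength must be in [0,1], got {self.rescue_strength}")
        if not 0.0 <= self.p_tox <= 1.0:
            raise ValueError(f"p_tox must be in [0,1], got {self.p_tox}")


@dataclass
class CohortParams:
    """Generative parameters of the behavioral cohort.

    Wild-type distances are log-normal around ``wt_distance_median_m`` with
    coefficient of variation ``wt_distance_cv``.  A morphant fish is a
    complete non-mover with probability ``mo_zero_fraction``; otherwise it
    travels a wild-type draw scaled by ``1 - mo_mover_reduction``.  A
    treated fish dies with its drug's ``p_tox``; a surviving treated fish
    interpolates between a morphant draw (e = 0) and a wild-type draw
    (e = 1).
    """

    n_drugs: int = 0
    wt_distance_median_m: float = 1.0
    wt_distance_cv: float = 0.25
    mo_zero_fraction: float = 0.792
    mo_mover_reduction: float = 0.85
    replicate_count: int = 4
    drug_effects: Mapping[str, DrugEffect] = field(default_factory=dict)
    default_effect: DrugEffect = field(default_factory=DrugEffect)
    n_control_wells: int = 2  # wells per control column actually seeded per plate
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("mo_zero_fraction", self.mo_zero_fraction),
            ("mo_mover_reduction", self.mo_mover_reduction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.wt_distance_median_m <= 0:
            raise ValueError("wt_distance_median_m must be > 0")
        if self.wt_distance_cv <= 0:
            raise ValueError("wt_distance_cv must be > 0")
        if self.n_drugs < 0 or self.replicate_count < 1:
            raise ValueError("n_drugs must be >= 0 and replicate_count >= 1")
        if not 1 <= self.n_control_wells <= len(ROWS):
            raise ValueError("n_control_wells must be in 1..8")

    def effect_of(self, drug_id: str) -> DrugEffect:
        return self.drug_effects.get(drug_id, self.default_effect)

    @property
    def sigma_log(self) -> float:
        """Log-normal shape parameter matching the requested CV."""
        return float(np.sqrt(np.log1p(self.wt_distance_cv**2)))


def _wt_draw(rng: np.random.Generator, params: CohortParams, n: int) -> np.ndarray:
    return params.wt_distance_median_m * np.exp(params.sigma_log * rng.standard_normal(n))


def _mo_draw(rng: np.random.Generator, params: CohortParams, n: int) -> np.ndarray:
    moving = rng.random(n) >= params.mo_zero_fraction
    dist = _wt_draw(rng, params, n) * (1.0 - params.mo_mover_reduction)
    return np.where(moving, dist, 0.0)


def drug_ids(params: CohortParams) -> list[str]:
    return [f"D{i + 1:04d}" for i in range(params.n_drugs)]


def _plate_layout(params: CohortParams) -> list[tuple[str, WellAddress]]:
    """Assign each drug a well, filling plates row-major over columns 2..11."""
    out = []
    for i, drug in enumerate(drug_ids(params)):
        plate = i // DRUGS_PER_PLATE + 1
        slot = i % DRUGS_PER_PLATE
        row = ROWS[slot // len(DRUG_COLUMNS)]
        col = DRUG_COLUMNS[slot % len(DRUG_COLUMNS)]
        out.append((drug, WellAddress(plate, row, col)))
    return out


def simulate_screen(params: CohortParams, stage: str = "screen") -> ScreenTable:
    """Generate a full screen table for ``params`` (deterministic per seed).

    Controls are placed in columns 1 (wild type) and 12 (morphant) of every
    plate, ``n_control_wells`` wells per column with ``replicate_count``
    fish each.
    """
    layout = _plate_layout(params)
    n_plates = max(1, (params.n_drugs + DRUGS_PER_PLATE - 1) // DRUGS_PER_PLATE)

    observations: list[FishObservation] = []
    rep = params.replicate_count

    rng_wt = rng_for(params.seed, f"{stage}/wt-controls")
    rng_mo = rng_for(params.seed, f"{stage}/mo-controls")
    for plate in range(1, n_plates + 1):
        for w in range(params.n_control_wells):
            wt_addr = WellAddress(plate, ROWS[w], 1)
            for d, fi in zip(_wt_draw(rng_wt, params, rep), range(1, rep + 1)):
                observations.append(
                    FishObservation(wt_addr, fi, Group.WT_CONTROL, None, True, float(d))
                )
            mo_addr = WellAddress(plate, ROWS[w], 12)
            for d, fi in zip(_mo_draw(rng_mo, params, rep), range(1, rep + 1)):
                observations.append(
                    FishObservation(mo_addr, fi, Group.MO_CONTROL, None, True, float(d))
                )

    for drug, addr in layout:
        rng = rng_for(params.seed, f"{stage}/drug/{drug}")
        eff = params.effect_of(drug)
        dead = rng.random(rep) < eff.p_tox
        mo = _mo_draw(rng, params, rep)
        wt = _wt_draw(rng, params, rep)
        dist = (1.0 - eff.rescue_strength) * mo + eff.rescue_strength * wt
        for fi in range(1, rep + 1):
            if dead[fi - 1]:
                observations.append(
                    FishObservation(addr, fi, Group.TREATED, drug, False, 0.0)
                )
            else:
                observations.append(
                    FishObservation(addr, fi, Group.TREATED, drug, True, float(dist[fi - 1]))
                )

    drugs = [DrugRecord(drug_id=d) for d, _ in layout]
    return ScreenTable(observations=observations, drugs=drugs, replicate_count=rep)


def simulate_rescreen(params: CohortParams, hit_ids: Sequence[str]) -> ScreenTable:
    """Regenerate only ``hit_ids`` under the same model, independent stream."""
    known = set(drug_ids(params))
    unknown = [h for h in hit_ids if h not in known]
    if unknown:
        raise ValueError(f"unknown hit id(s): {', '.join(unknown)}")
    full = simulate_screen(params, stage="rescreen")
    keep_plates = {
        o.address.plate_index for o in full.observations if o.drug_id in set(hit_ids)
    } or {1}
    obs = [
        o
        for o in full.observations
        if (o.drug_id in set(hit_ids))
        or (o.drug_id is None and o.address.plate_index in keep_plates)
    ]
    drugs = [d for d in full.drugs if d.drug_id in set(hit_ids)]
    return ScreenTable(observations=obs, drugs=drugs, replicate_count=full.replicate_count)


# ---------------------------------------------------------------------------
# drug-target tables
# ---------------------------------------------------------------------------


@dataclass
class NetworkParams:
    """Parameters for synthetic drug->target and target-target tables."""

    n_hit_drugs: int
    n_targets: int
    recurrent_target_spec: Sequence[tuple[str, int]] = ()
    unknown_fraction: float = 0.0
    edge_density: float = 0.1
    confidence_low: float = 0.0
    confidence_high: float = 1.0
    extra_targets_per_drug: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.unknown_fraction <= 1.0:
            raise ValueError("unknown_fraction must be in [0,1]")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0,1]")
        for _, m in self.recurrent_target_spec:
            if m < 1:
                raise ValueError("recurrence multiplicities must be >= 1")
            if m > self.n_hit_drugs:
                raise ValueError(
                    f"multiplicity {m} exceeds n_hit_drugs={self.n_hit_drugs}"
                )


def simulate_drug_target_tables(
    params: NetworkParams, hit_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (drug->target pairs, target-target edges) as DataFrames.

    Each ``(target, m)`` entry of ``recurrent_target_spec`` is wired to
    exactly ``m`` distinct hit drugs; a ``unknown_fraction`` share of drugs
    (chosen among those not consumed by the recurrence spec) receives zero
    targets; every remaining drug gets ``extra_targets_per_drug`` random
    non-recurrent targets.  Edges are Bernoulli(``edge_density``) over
    target pairs with uniform confidences in [confidence_low, confidence_high].
    """
    rng = rng_for(params.seed, "network")
    if hit_ids is None:
        hits = [f"D{i + 1:04d}" for i in range(params.n_hit_drugs)]
    else:
        hits = list(hit_ids)
        if len(hits) != params.n_hit_drugs:
            raise ValueError("hit_ids length must equal n_hit_drugs")

    spec_targets = [t for t, _ in params.recurrent_target_spec]
    targets = list(spec_targets)
    i = 1
    while len(targets) < params.n_targets:
        cand = f"T{i:03d}"
        if cand not in targets:
            targets.append(cand)
        i += 1
    other_targets = [t for t in targets if t not in spec_targets]

    pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    for tgt, mult in params.recurrent_target_spec:
        pool = [h for h in hits if h not in used] or hits
        if mult > len(pool):
            # allow recurrent targets to share drugs once the unused pool runs out
            chosen = list(rng.choice(hits, size=mult, replace=False))
        else:
            chosen = list(rng.choice(pool, size=mult, replace=False))
        used.update(chosen)
        pairs.extend((d, tgt) for d in chosen)

    n_unknown = int(round(params.unknown_fraction * len(hits)))
    free = [h for h in hits if h not in used]
    if n_unknown > len(free):
        raise ValueError(
            f"cannot make {n_unknown} unknown drugs: only {len(free)} drugs "
            "are free of recurrent-target assignments"
        )
    unknown = set(rng.choice(free, size=n_unknown, replace=False)) if n_unknown else set()

    for h in hits:
        if h in used or h in unknown:
            continue
        if other_targets and params.extra_targets_per_drug > 0:
            k = min(params.extra_targets_per_drug, len(other_targets))
            for tgt in rng.choice(other_targets, size=k, replace=False):
                pairs.append((h, str(tgt)))

    edges: list[tuple[str, str, float]] = []
    for a_i in range(len(targets)):
        for b_i in range(a_i + 1, len(targets)):
            if rng.random() < params.edge_density:
                conf = float(
                    rng.uniform(params.confidence_low, params.confidence_high)
                )
                edges.append((targets[a_i], targets[b_i], conf))

    pairs_df = pd.DataFrame(pairs, columns=["drug_id", "target_id"])
    edges_df = pd.DataFrame(edges, columns=["target_a", "target_b", "confidence"])
    return pairs_df, edges_df


# ---------------------------------------------------------------------------
# NMJ images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spot:
    """AChR cluster ground truth: center (row, col), radius px, peak intensity."""

    center: tuple[float, float]
    radius_px: float
    peak: float


@dataclass
class ImageTruth:
    """Ground-truth geometry of one synthetic two-channel micrograph.

    Channel 1 (axon marker) renders a horizontal spinal-cord band plus axon
    polylines descending from it; channel 2 (AChR marker) renders Gaussian
    spots.  ``body_band`` is a dim foreground region in the AChR channel so
    body detection has something to find, mimicking diffuse embryo signal.
    """

    image_shape: tuple[int, int] = (256, 512)
    pixel_size_um: float = 1.0
    # cord thickness must exceed the downstream 20-px median-filter radius,
    # otherwise smoothing erases the band
    cord_band: tuple[int, int] = (32, 32)  # (top row, thickness px)
    body_band: tuple[int, int] = (24, 204)  # (top row, thickness px)
    axons: Sequence[Sequence[tuple[float, float]]] = ()  # polylines [(r, c), ...]
    spots: Sequence[Spot] = ()
    on_axon_fraction: float | None = None  # recorded design value, if any
    axon_width_px: int = 3
    cord_level: float = 12000.0
    axon_level: float = 9000.0
    body_level: float = 1500.0
    background: tuple[float, float] = (150.0, 150.0)
    noise_sd: tuple[float, float] = (30.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for s in self.spots:
            r, c = s.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"spot center {s.center} outside image {self.image_shape}")
        for poly in self.axons:
            for r, c in poly:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(f"axon vertex ({r}, {c}) outside image")
        top, thick = self.cord_band
        if top < 0 or top + thick > h:
            raise ValueError("cord_band outside image")

    def axon_lengths_um(self) -> list[float]:
        out = []
        for poly in self.axons:
            pts = np.asarray(poly, dtype=float)
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            out.append(float(steps.sum() * self.pixel_size_um))
        return out


def polyline_length_um(poly: Sequence[tuple[float, float]], pixel_size_um: float) -> float:
    pts = np.asarray(poly, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() * pixel_size_um)


def render_axon_mask(truth: ImageTruth, include_cord: bool = True) -> np.ndarray:
    """Binary mask of the rendered axon polylines (and optionally the cord)."""
    h, w = truth.image_shape
    mask = np.zeros((h, w), dtype=bool)
    for poly in truth.axons:
        pts = np.asarray(poly, dtype=float)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[keep], cc[keep]] = True
    if truth.axon_width_px > 1:
        mask = dilation(mask, disk(truth.axon_width_px // 2))
    if include_cord:
        top, thick = truth.cord_band
        mask[top : top + thick, :] = True
    return mask


def spot_mask_from_truth(truth: ImageTruth) -> np.ndarray:
    h, w = truth.image_shape
    mask = np.zeros((h, w), dtype=bool)
    for s in truth.spots:
        rr, cc = draw_disk(s.center, s.radius_px, shape=(h, w))
        mask[rr, cc] = True
    return mask


def simulate_nmj_image(truth: ImageTruth) -> tuple[np.ndarray, ImageTruth]:
    """Render the two-channel image described by ``truth``.

    Returns ``(image, truth)`` with ``image`` of shape (2, H, W) uint16,
    channel 0 = axon marker, channel 1 = AChR marker.
    """
    h, w = truth.image_shape
    rng = rng_for(truth.seed, "image-noise")

    axon_ch = np.full((h, w), truth.background[0], dtype=float)
    top, thick = truth.cord_band
    axon_ch[top : top + thick, :] += truth.cord_level
    axon_lines = render_axon_mask(truth, include_cord=False)
    axon_ch[axon_lines] = np.maximum(axon_ch[axon_lines], truth.background[0] + truth.axon_level)

    achr_ch = np.full((h, w), truth.background[1], dtype=float)
    btop, bthick = truth.body_band
    achr_ch[btop : btop + bthick, :] += truth.body_level
    if truth.spots:
        rgrid, cgrid = np.mgrid[0:h, 0:w]
        for s in truth.spots:
            sigma = max(s.radius_px / 2.0, 0.5)
            r0, c0 = s.center
            d2 = (rgrid - r0) ** 2 + (cgrid - c0) ** 2
            # truncate at 4 sigma to keep rendering linear in spot count
            near = d2 <= (4 * sigma) ** 2
            achr_ch[near] += s.peak * np.exp(-d2[near] / (2 * sigma**2))

    if truth.noise_sd[0] > 0:
        axon_ch += rng.normal(0.0, truth.noise_sd[0], size=(h, w))
    if truth.noise_sd[1] > 0:
        achr_ch += rng.normal(0.0, truth.noise_sd[1], size=(h, w))

    img = np.stack([axon_ch, achr_ch])
    return np.clip(img, 0, 65535).astype(np.uint16), truth


def make_image_truth(
    n_spots: int = 20,
    n_axons: int = 8,
    axon_length_um: float = 120.0,
    on_axon_fraction: float = 1.0,
    image_shape: tuple[int, int] = (256, 512),
    pixel_size_um: float = 1.0,
    spot_radius_px: tuple[float, float] = (3.0, 6.0),
    spot_peak: float = 20000.0,
    axon_width_px: int = 3,
    length_jitter: float = 0.0,
    noise_sd: tuple[float, float] = (30.0, 30.0),
    seed: int = 0,
) -> ImageTruth:
    """Design a plausible embryo: cord band, descending axons, AChR spots.

    Axons descend ventrally from the cord with a small deterministic slant.
    A fraction ``on_axon_fraction`` of spots is centered on the axon
    centerlines; the rest sit on body pixels well away from any axon.
    """
    if not 0.0 <= on_axon_fraction <= 1.0:
        raise ValueError("on_axon_fraction must be in [0,1]")
    h, w = image_shape
    rng = rng_for(seed, "image-truth")
    cord_top = max(8, h // 8)
    cord_thick = max(28, h // 8)  # must survive the 20-px median smoothing
    body_top = max(0, cord_top - 8)
    body_thick = min(h - body_top - 8, int(h * 0.8))

    axons = []
    length_px_nominal = axon_length_um / pixel_size_um
    margin = 12
    for i in range(n_axons):
        c0 = margin + (i + 0.5) * (w - 2 * margin) / max(n_axons, 1)
        r0 = cord_top + cord_thick - 1
        length_px = length_px_nominal * (1.0 + length_jitter * (rng.random() - 0.5))
        slant = (-1) ** i * 0.15  # mild alternating slant, keeps axons separated
        dr = length_px / np.hypot(1.0, slant)
        r1 = min(r0 + dr, h - 4)
        c1 = np.clip(c0 + slant * (r1 - r0), 2, w - 3)
        axons.append([(float(r0), float(c0)), (float(r1), float(c1))])

    proto = ImageTruth(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        cord_band=(cord_top, cord_thick),
        body_band=(body_top, body_thick),
        axons=axons,
        axon_width_px=axon_width_px,
        seed=seed,
    )

    n_on = int(round(on_axon_fraction * n_spots))
    spots: list[Spot] = []
    min_sep = 4.0 * spot_radius_px[1]

    # on-axon candidates: points along the polylines, clear of cord and frame
    on_candidates: list[tuple[float, float]] = []
    clear_top = cord_top + cord_thick + 2 + spot_radius_px[1]
    for (r0, c0), (r1, c1) in axons:
        seg_len = float(np.hypot(r1 - r0, c1 - c0))
        n_slots = max(int(seg_len // min_sep), 1)
        for k in range(n_slots):
            t = (k + 0.5) / n_slots
            r, c = r0 + t * (r1 - r0), c0 + t * (c1 - c0)
            if r >= clear_top and 4 <= c < w - 4:
                on_candidates.append((r, c))

    # off-axon candidates: body pixels far from every axon
    axon_px = render_axon_mask(proto, include_cord=False)
    far = ~dilation(axon_px, disk(int(axon_width_px // 2 + 12)))
    rows, cols = np.mgrid[0:h, 0:w]
    in_body = (
        (rows >= clear_top)
        & (rows < body_top + body_thick - 4)
        & (cols > 8)
        & (cols < w - 8)
    )
    off_idx = np.flatnonzero(far & in_body)
    off_candidates = [(float(r), float(c)) for r, c in zip(*np.unravel_index(off_idx, (h, w)))]

    def _place(pool: list[tuple[float, float]], n: int) -> None:
        placed = 0
        order = rng.permutation(len(pool))
        for j in order:
            if placed >= n:
                break
            r, c = pool[int(j)]
            if all(np.hypot(r - s.center[0], c - s.center[1]) >= min_sep for s in spots):
                radius = float(rng.uniform(*spot_radius_px))
                spots.append(Spot((r, c), radius, spot_peak))
                placed += 1
        if placed < n:
            raise ValueError(
                f"could only place {placed}/{n} spots with separation {min_sep:.1f}px; "
                "reduce n_spots or spot radius"
            )

    _place(on_candidates, n_on)
    _place(off_candidates, n_spots - n_on)

    return ImageTruth(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        cord_band=(cord_top, cord_thick),
        body_band=(body_top, body_thick),
        axons=axons,
        spots=spots,
        on_axon_fraction=on_axon_fraction,
        axon_width_px=axon_width_px,
        noise_sd=noise_sd,
        seed=seed,
    )


def write_nmj_image(
    image: np.ndarray,
    path: str | Path,
    pixel_size_um: float = 1.0,
    embryo_id: str = "",
    group: str = "",
    drug_id: str = "",
) -> Path:
    """Write a (2, H, W) uint16 TIFF plus a sidecar JSON with metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": pixel_size_um,
                "embryo_id": embryo_id,
                "group": group,
                "drug_id": drug_id,
            },
            indent=2,
        )
    )
    return path


def read_nmj_image(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    img = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return img, meta
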