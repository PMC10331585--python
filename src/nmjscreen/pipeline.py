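"""End-to-end demo pipeline on synthetic data.

Runs the whole funnel: simulate a primary screen -> score and classify ->
rescreen the hits -> NPA cutoff -> drug-target recurrence filter -> NMJ
image simulation and quantification for the surviving drugs -> cellular
z-scoring -> final hit list.  Fully deterministic for a given master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from . import behavior_scoring as bs
from . import cellular_scoring as cs
from . import nmj_imaging as im
from . import synthetic_data as syn
from . import target_network as tn

__all__ = ["PipelineConfig", "run_demo", "write_bundle"]


@dataclass
class PipelineConfig:
    """Every knob of the demo pipeline, with module defaults."""

    # cohort
    n_drugs: int = 100
    n_true_rescuers: int = 5
    true_rescue_strength: float = 1.0
    null_rescue_strength: float = 0.0
    wt_distance_median_m: float = 1.0
    wt_distance_cv: float = 0.25
    mo_zero_fraction: float = 0.792
    mo_mover_reduction: float = 0.85
    replicate_count: int = 4
    n_control_wells: int = 4
    # behavioral scoring
    mean_z_threshold: float = 0.0
    fish_z_threshold: float = -1.0
    toxic_dead_min: int = 3
    npa_cutoff: float = 50.0
    npa_variant: str = "STANDARD"
    # network filter
    confidence_cutoff: float = 0.7
    recurrence_cutoff: int = 3
    n_targets: int = 12
    edge_density: float = 0.15
    # imaging
    image_height: int = 224
    image_width: int = 448
    embryos_per_drug: int = 4
    n_wt_embryos: int = 8
    n_mo_embryos: int = 4
    wt_n_spots: int = 20
    mo_n_spots: int = 6
    wt_axon_length_um: float = 110.0
    mo_axon_length_um: float = 40.0
    wt_on_axon_fraction: float = 0.9
    mo_on_axon_fraction: float = 0.2
    image_axon_width_px: int = 15
    image_spot_radius: tuple[float, float] = (3.0, 4.0)
    n_image_axons: int = 6
    axon_length_jitter: float = 0.1
    # cellular scoring
    cellular_z_threshold: float = -1.0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "image_spot_radius" in data:
            data = dict(data, image_spot_radius=tuple(data["image_spot_radius"]))
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_spot_radius"] = list(d["image_spot_radius"])
        return d


def _cohort_params(cfg: PipelineConfig, seed: int) -> syn.CohortParams:
    effects = {}
    for i in range(cfg.n_drugs):
        drug = f"D{i + 1:04d}"
        e = cfg.true_rescue_strength if i < cfg.n_true_rescuers else cfg.null_rescue_strength
        effects[drug] = syn.DrugEffect(rescue_strength=e, p_tox=0.0)
    return syn.CohortParams(
        n_drugs=cfg.n_drugs,
        wt_distance_median_m=cfg.wt_distance_median_m,
        wt_distance_cv=cfg.wt_distance_cv,
        mo_zero_fraction=cfg.mo_zero_fraction,
        mo_mover_reduction=cfg.mo_mover_reduction,
        replicate_count=cfg.replicate_count,
        drug_effects=effects,
        n_control_wells=cfg.n_control_wells,
        seed=seed,
    )


def _truth_for(cfg: PipelineConfig, wt_like: bool, seed: int) -> syn.ImageTruth:
    # Poisson counts give the control cohorts natural spread, so the robust
    # MAD in the cellular z-scores never collapses to zero
    rng = syn.rng_for(seed, "embryo-design")
    mean_spots = cfg.wt_n_spots if wt_like else cfg.mo_n_spots
    n_spots = max(2, int(rng.poisson(mean_spots)))
    return syn.make_image_truth(
        n_spots=n_spots,
        n_axons=cfg.n_image_axons,
        axon_length_um=cfg.wt_axon_length_um if wt_like else cfg.mo_axon_length_um,
        on_axon_fraction=cfg.wt_on_axon_fraction if wt_like else cfg.mo_on_axon_fraction,
        image_shape=(cfg.image_height, cfg.image_width),
        spot_radius_px=cfg.image_spot_radius,
        axon_width_px=cfg.image_axon_width_px,
        length_jitter=cfg.axon_length_jitter,
        seed=seed,
    )


def _quantify_truth(cfg: PipelineConfig, truth: syn.ImageTruth, embryo_id: str) -> im.CellularMetrics:
    img, _ = syn.simulate_nmj_image(truth)
    image = im.NMJImage.from_array(img, truth.pixel_size_um, embryo_id=embryo_id)
    return im.quantify_embryo(image, im.QuantifyConfig())


def _image_seed(master_seed: int, tag: str) -> int:
    import zlib

    return (master_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def run_demo(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Run the full synthetic funnel and return the report bundle (JSON-safe)."""
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed

    # 1. primary screen
    params = _cohort_params(cfg, seed)
    table = syn.simulate_screen(params)
    report = bs.screen(
        table,
        mean_z_threshold=cfg.mean_z_threshold,
        fish_z_threshold=cfg.fish_z_threshold,
        toxic_dead_min=cfg.toxic_dead_min,
    )
    screen_hits = sorted(
        s.drug_id
        for s in report.scores
        if s.category in (bs.Category.HIT_A, bs.Category.HIT_B)
    )

    # 2. rescreen + NPA cutoff
    npa_results: list[bs.NPAResult] = []
    npa_hits: list[str] = []
    if screen_hits:
        retable = syn.simulate_rescreen(params, screen_hits)
        npa_results = bs.rescreen(
            retable, cutoff=cfg.npa_cutoff, variant=bs.NpaVariant[cfg.npa_variant]
        )
        npa_hits = sorted(r.drug_id for r in npa_results if r.pass50)

    # 3. drug-target recurrence filter
    selected: list[str] = []
    net_report = None
    if npa_hits:
        n_recurrent = 3 if len(npa_hits) >= 3 else 0
        spec = [("T_REC", 3)] if n_recurrent else []
        unknown_fraction = (len(npa_hits) - n_recurrent) / len(npa_hits)
        net_params = syn.NetworkParams(
            n_hit_drugs=len(npa_hits),
            n_targets=cfg.n_targets,
            recurrent_target_spec=spec,
            unknown_fraction=unknown_fraction,
            edge_density=cfg.edge_density,
            seed=seed,
        )
        pairs, edges = syn.simulate_drug_target_tables(net_params, hit_ids=npa_hits)
        graph = tn.build_graph(pairs, edges, npa_hits, cfg.confidence_cutoff)
        net_report = tn.select_hits(graph, recurrence_cutoff=cfg.recurrence_cutoff)
        selected = sorted(net_report.favorite_hits | net_report.unknown_hits)

    # 4. imaging + cellular scoring
    wt_metrics = [
        _quantify_truth(cfg, _truth_for(cfg, True, _image_seed(seed, f"wt/{i}")), f"WT{i}")
        for i in range(cfg.n_wt_embryos)
    ]
    mo_metrics = [
        _quantify_truth(cfg, _truth_for(cfg, False, _image_seed(seed, f"mo/{i}")), f"MO{i}")
        for i in range(cfg.n_mo_embryos)
    ]
    true_rescuers = {f"D{i + 1:04d}" for i in range(cfg.n_true_rescuers)}
    cellular_scores: list[cs.CellularScore] = []
    drug_metrics_rows: list[dict] = []
    for drug in selected:
        wt_like = drug in true_rescuers
        metrics = [
            _quantify_truth(
                cfg,
                _truth_for(cfg, wt_like, _image_seed(seed, f"drug/{drug}/{k}")),
                f"{drug}-{k}",
            )
            for k in range(cfg.embryos_per_drug)
        ]
        for m in metrics:
            row = m.as_dict()
            row["drug_id"] = drug
            drug_metrics_rows.append(row)
        cellular_scores.append(
            cs.score_drug(drug, metrics, wt_metrics, cfg.cellular_z_threshold)
        )
    final_hits = sorted(s.drug_id for s in cellular_scores if s.final_hit)

    # 5. group statistics on the control cohorts
    stats_report = {}
    for p in cs.PARAMETERS:
        vals_wt = [getattr(m, p) for m in wt_metrics if getattr(m, p) is not None]
        vals_mo = [getattr(m, p) for m in mo_metrics if getattr(m, p) is not None]
        if len(vals_wt) >= 2 and len(vals_mo) >= 2:
            gc = cs.group_compare({"WT": vals_wt, "MO": vals_mo})
            stats_report[p] = gc.to_json_dict()

    hit_table = cs.hitmap(cellular_scores)
    funnel = {
        "n_drugs": cfg.n_drugs,
        "screen_hits": len(screen_hits),
        "rescreen_hits": len(npa_hits),
        "network_selected": len(selected),
        "final_hits": len(final_hits),
    }
    return {
        "config": cfg.to_dict(),
        "seed": seed,
        "funnel": funnel,
        "screen": {
            "category_counts": report.category_counts,
            "plate_z_prime": {str(k): v for k, v in report.plate_z_prime.items()},
            "hits": screen_hits,
        },
        "rescreen": {
            "results": [
                {
                    "drug_id": r.drug_id,
                    "mean_npa": r.mean_npa,
                    "pass": r.pass50,
                }
                for r in npa_results
            ],
            "hits": npa_hits,
        },
        "network": net_report.to_json_dict() if net_report else None,
        "cellular": {
            "hitmap": hit_table,
            "final_hits": final_hits,
        },
        "group_statistics": stats_report,
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "demo_bundle.json"
    path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return path
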