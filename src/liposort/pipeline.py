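"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` describes a full screening-and-sorting
experiment: population mixture, imaging, detection, (optional) tracking,
photoactivation and FACS models, selection policy, and readout.  The
canonical experiment designs ship as presets:

* ``fig2_yfp_mock``    -- expression screening of a 1:39 two-gene mock
  library by reporter-intensity thresholding, 84-uW stimulation anywhere
  in the FOV, qPCR-style genotype readout;
* ``fig3_mind_mock``   -- membrane-localization screening of 1:9 / 1:39 /
  1:39 mock mixtures with the ring classifier;
* ``fig4_dynamics``    -- 5-frame video screening for dynamic membrane
  reorganization, center-of-FOV stimulation;
* ``fig5_mts_library`` -- pooled nine-variant membrane-targeting-sequence
  library with a sequencing readout.

``run_experiment`` executes simulate -> render -> detect (-> track) ->
select -> photoactivate -> FACS -> sort -> quantify for each replicate,
writes stage artifacts to a run directory when requested, and is fully
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detect import DetectionParams, detect_frame, detections_to_csv, video_filter
from .errors import ConfigurationError, LiposortError
from .population import (
    DEFAULT_MTS_WINDOWS,
    GenotypeSpec,
    PopulationConfig,
    generate_reads,
    make_mts_library,
    population_to_csv,
    sample_population,
)
from .quantify import (
    MtsExtractor,
    count_variants,
    filter_reads,
    fractions_and_fold,
    summarize_replicates,
    variant_counts_by_name,
)
from .render import ImagingConfig, render_frame, render_video, save_stack
from .sortsim import (
    FacsModel,
    activation_log_to_csv,
    LaserModel,
    confusion_metrics,
    default_gates,
    events_to_csv,
    facs_measure,
    gate_and_sort,
    photoactivate,
    quadrant_precision,
)
from .track import TrackerParams, link_tracks, select_targets, targets_to_csv, tracks_to_csv

__all__ = ["ExperimentConfig", "RunReport", "run_experiment", "preset", "PRESETS"]

logger = logging.getLogger("liposort")


@dataclass
class ExperimentConfig:
    population: PopulationConfig
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    laser: LaserModel = field(default_factory=LaserModel)
    facs: FacsModel = field(default_factory=FacsModel)
    mode: str = "static"  # "static" or "video"
    policy: str = "anywhere"  # "center_only" or "anywhere"
    classify: bool = True  # run the ring classifier (False = intensity screening)
    positive_genotypes: tuple[str, ...] = ()
    replicates: int = 1
    seed: int = 0
    n_templates: int = 100_000
    readout: str = "counts"  # "counts" (qPCR-style) or "reads" (sequencing)
    n_reads: int = 4000
    read_error_rate: float = 0.003
    read_junk_fraction: float = 0.05
    center_radius_um: float = 20.0
    #: Volume ratios per replicate, e.g. ((1, 9), (1, 39), (1, 39)); when set,
    #: replicate k remixes the first component against the rest at this ratio.
    replicate_ratios: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("static", "video"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.policy not in ("center_only", "anywhere"):
            raise ConfigurationError(f"unknown policy {self.policy!r}")
        if self.readout not in ("counts", "reads"):
            raise ConfigurationError(f"unknown readout {self.readout!r}")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=_jsonable)), fh)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        """Build a config from one nested YAML/JSON document."""
        data = dict(data)
        pop = dict(data.pop("population"))
        comps = [
            (GenotypeSpec(**dict(g)), float(f)) for g, f in pop.pop("components")
        ]
        for key in ("diameter_lognormal", "diameter_range_um", "liposomes_per_fov"):
            if key in pop:
                pop[key] = tuple(pop[key])
        kwargs = {"population": PopulationConfig(components=comps, **pop)}
        sub = {"imaging": ImagingConfig, "detection": DetectionParams,
               "tracker": TrackerParams, "laser": LaserModel, "facs": FacsModel}
        for key, klass in sub.items():
            if key in data:
                block = dict(data.pop(key))
                if key == "imaging" and "frame_times_s" in block:
                    block["frame_times_s"] = tuple(block["frame_times_s"])
                if key == "laser" and "p_off" in block:
                    block["p_off"] = {int(k): float(v) for k, v in dict(block["p_off"]).items()}
                if key == "facs" and block.get("gates") is not None:
                    block["gates"] = tuple(block["gates"])
                kwargs[key] = klass(**block)
        for key in ("positive_genotypes",):
            if key in data:
                data[key] = tuple(data[key])
        if data.get("replicate_ratios") is not None:
            data["replicate_ratios"] = tuple(tuple(r) for r in data["replicate_ratios"])
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load a config from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)


@dataclass
class RunReport:
    config_summary: dict
    replicates: list
    aggregate: dict

    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config_summary,
            "replicates": self.replicates,
            "aggregate": self.aggregate,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _population_for_replicate(config: ExperimentConfig, rep: int) -> PopulationConfig:
    pop = config.population
    if config.replicate_ratios is None:
        return pop
    a, b = config.replicate_ratios[rep % len(config.replicate_ratios)]
    total = a + b
    first = pop.components[0][0]
    rest = [g for g, _ in pop.components[1:]]
    rest_fraction = b / total / max(len(rest), 1)
    comps = [(first, a / total)] + [(g, rest_fraction) for g in rest]
    return dataclasses.replace(pop, components=comps)


def _template_counts(pop_cfg: PopulationConfig, n_templates: int, rng) -> dict[str, int]:
    """Presort template pool: counts multinomial in volume x template share."""
    shares = np.asarray([f * g.template_share for g, f in pop_cfg.components], dtype=float)
    shares = shares / shares.sum()
    draw = rng.multinomial(n_templates, shares)
    return {g.name: int(c) for (g, _), c in zip(pop_cfg.components, draw)}


def _screen_fov(config, pop_cfg, fov_idx, rng, artifacts, id_offset=0):
    """Simulate, image and analyse one FOV; returns (population, targets, detections)."""
    fov_pop = sample_population(
        dataclasses.replace(pop_cfg, n_fov=1, seed=None), rng
    )[0]
    for i, lp in enumerate(fov_pop):
        lp.fov = fov_idx
        lp.id = id_offset + i  # ids unique across the whole replicate
    img_cfg = config.imaging
    px = img_cfg.px_um
    center = (img_cfg.fov_um / 2.0, img_cfg.fov_um / 2.0)
    det_rows = []
    if config.mode == "static":
        protein = render_frame(fov_pop, img_cfg, "protein", 0.0, rng)
        if config.classify or config.detection.detect_channel == "membrane":
            membrane = render_frame(fov_pop, img_cfg, "membrane", 0.0, rng)
        else:
            membrane = protein
        dets = detect_frame(membrane, protein, config.detection, px_um=px,
                            classify=config.classify)
        det_rows = [(fov_idx, 0, d) for d in dets]
        qualifier = None if config.classify else (lambda d: True)
        targets = select_targets(dets, config.policy, center, config.center_radius_um,
                                 qualifier=qualifier)
        stack = None
    else:
        stack = render_video(fov_pop, img_cfg, rng, channels=("membrane", "protein"),
                             fov_id=fov_idx)
        per_frame = []
        for k in range(len(img_cfg.frame_times_s)):
            dets = detect_frame(stack.channels["membrane"][k], stack.channels["protein"][k],
                                config.detection, px_um=px, classify=True)
            dets = video_filter(dets)
            per_frame.append(dets)
            det_rows.extend((fov_idx, k, d) for d in dets)
        tracks = link_tracks(per_frame, config.tracker)
        targets = select_targets(tracks, config.policy, center, config.center_radius_um)
        if artifacts is not None:
            tracks_to_csv(tracks, artifacts / f"tracks_fov{fov_idx:04d}.csv", fov=fov_idx)
        # the final population snapshot carries the drifted centers
        fov_pop = stack.truth[-1]
    if artifacts is not None and stack is not None:
        save_stack(stack, artifacts / f"fov{fov_idx:04d}.tiff")
    return fov_pop, targets, det_rows


def run_experiment(config: ExperimentConfig, outdir=None, save_images: bool = False):
    """Run the full pipeline for every replicate and aggregate the results.

    Per replicate: simulate and screen every FOV, photoactivate the
    selected targets, measure the pooled sample by FACS against gates set
    on an unstimulated control aliquot, sort the tag-high events, and
    quantify genotype fractions pre/post sorting.  A replicate that fails
    in one stage is logged and skipped; the others continue.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        fh = logging.FileHandler(out / "log.txt")
        fh.setLevel(logging.INFO)
        logger.addHandler(fh)
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.replicates)
    replicate_reports = []
    tables = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(rep_seeds[rep])
        rep_dir = out / f"replicate_{rep}" if out is not None else None
        if rep_dir is not None:
            rep_dir.mkdir(exist_ok=True)
        stage = "simulate"
        try:
            pop_cfg = _population_for_replicate(config, rep)
            counts_pre = _template_counts(pop_cfg, config.n_templates, rng)
            logger.info("replicate %d: presort template counts %s", rep, counts_pre)
            population = []
            det_rows = []
            target_rows = []
            act_log = []
            n_targets = 0
            stage = "screen"
            art = rep_dir if (rep_dir is not None and save_images) else None
            reason = "dynamic" if config.mode == "video" else (
                "class2" if config.classify else "intensity")
            for fov_idx in range(pop_cfg.n_fov):
                fov_pop, targets, rows = _screen_fov(config, pop_cfg, fov_idx, rng, art,
                                                     id_offset=len(population))
                det_rows.extend(rows)
                stage = "photoactivate"
                act_log.extend(photoactivate(fov_pop, targets, config.laser, rng,
                                             fov_um=config.imaging.fov_um))
                target_rows.extend((fov_idx, x, y, reason) for x, y in targets)
                n_targets += len(targets)
                population.extend(fov_pop)
                stage = "screen"
            stage = "facs"
            # unstimulated control aliquot: same sample, activation stripped
            control = [dataclasses.replace(lp, activated=False) for lp in population]
            control_events = facs_measure(control, config.facs, rng)
            gates = config.facs.gates or default_gates(control_events, config.facs)
            events = facs_measure(population, config.facs, rng)
            sorted_ids, quadrants = gate_and_sort(events, gates)
            stage = "quantify"
            by_id = {lp.id: lp for lp in population}
            counts_post = {g.name: 0 for g, _ in pop_cfg.components}
            for lid in sorted_ids:
                counts_post[by_id[lid].genotype.name] += 1
            rep_report = _quantify_replicate(
                config, pop_cfg, counts_pre, counts_post, population, events,
                sorted_ids, quadrants, gates, n_targets, rng, tables,
            )
            rep_report["replicate"] = rep
            replicate_reports.append(rep_report)
            if rep_dir is not None:
                detections_to_csv(det_rows, rep_dir / "detections.csv")
                targets_to_csv(target_rows, rep_dir / "targets.csv")
                activation_log_to_csv(act_log, rep_dir / "activation_log.csv")
                events_to_csv(events, rep_dir / "events.csv")
                population_to_csv([population], rep_dir / "population.csv")
        except LiposortError as exc:
            logger.error("replicate %d failed at stage %s: %s", rep, stage, exc)
            replicate_reports.append({"replicate": rep, "failed_stage": stage,
                                      "error": str(exc)})
    aggregate = _aggregate(replicate_reports, tables)
    report = RunReport(
        config_summary={"seed": config.seed, "mode": config.mode, "policy": config.policy,
                        "replicates": config.replicates,
                        "n_fov": config.population.n_fov,
                        "laser_power_uw": config.laser.power_uw,
                        "p_off": config.laser.p_off_current,
                        "recovery_prob": config.facs.recovery_prob},
        replicates=replicate_reports,
        aggregate=aggregate,
    )
    if out is not None:
        report.to_json(out / "report.json")
    return report


def _quantify_replicate(config, pop_cfg, counts_pre, counts_post, population, events,
                        sorted_ids, quadrants, gates, n_targets, rng, tables):
    positives = set(config.positive_genotypes) or {pop_cfg.components[0][0].name}
    truth_ids = [lp.id for lp in population
                 if lp.expressing and lp.genotype.name in positives]
    activated_ids = [lp.id for lp in population if lp.activated]
    precision, sensitivity = confusion_metrics(activated_ids, truth_ids,
                                               [lp.id for lp in population])
    rep_report = {
        "screened": len(population),
        "stimulated": n_targets,
        "activated": len(activated_ids),
        "events": len(events),
        "sorted": len(sorted_ids),
        "precision": precision,
        "sensitivity": sensitivity,
        "quadrants": quadrants,
        "quadrant_precision": quadrant_precision(quadrants),
        "gates": list(gates),
        "empty_sort": sum(counts_post.values()) == 0,
    }
    if config.readout == "reads":
        rep_report.update(_sequencing_readout(config, counts_pre, counts_post, rng))
    # the presort composition is known whether or not anything was sorted
    total_pre = sum(counts_pre.values())
    rep_report["frac_pre"] = sum(counts_pre.get(g, 0) for g in positives) / total_pre
    if sum(counts_post.values()) > 0:
        table = fractions_and_fold(counts_pre, counts_post)
        tables.append(table)
        pos_rows = table[table.genotype.isin(positives)]
        rep_report["frac_post"] = float(pos_rows.frac_post.sum())
        rep_report["fold_enrichment"] = (
            rep_report["frac_post"] / rep_report["frac_pre"]
            if rep_report["frac_pre"] > 0 else None
        )
        rep_report["variant_table"] = table.to_dict(orient="records")
    return rep_report


def _sequencing_readout(config, counts_pre, counts_post, rng):
    """Sequence presort and sorted pools and count variants from the reads."""
    library = make_mts_library()
    extractor = MtsExtractor(left_flank=library.left_flank,
                             right_flank=library.right_flank)
    out = {}
    for tag, counts in (("pre", counts_pre), ("post", counts_post)):
        total = sum(counts.values())
        if total == 0:
            out[f"seq_counts_{tag}"] = {}
            continue
        fractions = {k: v / total for k, v in counts.items() if v > 0}
        reads = generate_reads(fractions, config.n_reads,
                               error_rate=config.read_error_rate,
                               rng=rng, library=library,
                               junk_fraction=config.read_junk_fraction)
        kept = filter_reads(reads, extractor.length_window)
        window_counts, qc = count_variants(kept, extractor)
        out[f"seq_counts_{tag}"] = variant_counts_by_name(window_counts, library.variants)
        out[f"seq_qc_{tag}"] = qc
    return out


def _aggregate(replicate_reports, tables):
    ok = [r for r in replicate_reports if "failed_stage" not in r]
    agg = {"n_ok": len(ok), "n_failed": len(replicate_reports) - len(ok)}
    for key in ("frac_pre", "frac_post", "fold_enrichment", "precision", "sensitivity"):
        vals = [r[key] for r in ok if r.get(key) is not None]
        if vals:
            agg[f"{key}_mean"] = float(np.mean(vals))
            agg[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    if tables:
        agg["variant_summary"] = summarize_replicates(tables).to_dict(orient="records")
    return agg


# --------------------------------------------------------------------------
# Presets


def _fig2_yfp_mock() -> ExperimentConfig:
    yfp = GenotypeSpec(name="YFP", phenotype="lumen")
    ctrl = GenotypeSpec(name="btubB", phenotype="none")
    # density fixed at the off-target calibration point (100 vesicles/FOV);
    # 2000 FOVs per replicate -- the lower end of the real screens'
    # 2000-5000 FOVs -- keeps sorted-event counts statistically useful
    pop = PopulationConfig(components=[(yfp, 1 / 40), (ctrl, 39 / 40)],
                           liposomes_per_fov=(100, 100), n_fov=2000)
    return ExperimentConfig(
        population=pop,
        detection=DetectionParams(detect_channel="protein"),
        laser=LaserModel(power_uw=84),
        facs=FacsModel(recovery_prob=0.15),
        mode="static",
        policy="anywhere",
        classify=False,
        positive_genotypes=("YFP",),
        replicates=3,
    )


def _fig3_mind_mock() -> ExperimentConfig:
    mind = GenotypeSpec(name="minD", phenotype="membrane")
    # the reporter is co-encapsulated everywhere; without MinD it stays in
    # the lumen, so the control population renders as lumen-localized
    ctrl = GenotypeSpec(name="btubB", phenotype="lumen")
    pop = PopulationConfig(components=[(mind, 1 / 10), (ctrl, 9 / 10)], n_fov=60)
    return ExperimentConfig(
        population=pop,
        detection=DetectionParams(detect_channel="membrane"),
        laser=LaserModel(power_uw=34),
        mode="static",
        policy="anywhere",
        classify=True,
        positive_genotypes=("minD",),
        replicates=3,
        replicate_ratios=((1, 9), (1, 39), (1, 39)),
    )


def _fig4_dynamics() -> ExperimentConfig:
    minde = GenotypeSpec(name="minDE", phenotype="oscillatory")
    ctrl = GenotypeSpec(name="minD_btubB", phenotype="membrane")
    pop = PopulationConfig(components=[(minde, 0.5), (ctrl, 0.5)], n_fov=40)
    return ExperimentConfig(
        population=pop,
        detection=DetectionParams(detect_channel="membrane"),
        tracker=TrackerParams(),
        laser=LaserModel(power_uw=34),
        mode="video",
        policy="center_only",
        classify=True,
        positive_genotypes=("minDE",),
        replicates=3,
    )


def _fig5_mts_library() -> ExperimentConfig:
    binders = {"Var1", "Var7"}
    comps = [
        (GenotypeSpec(name=f"Var{i}",
                      phenotype="membrane" if f"Var{i}" in binders else "lumen",
                      mts_variant=DEFAULT_MTS_WINDOWS[f"Var{i}"]), 1 / 9)
        for i in range(1, 10)
    ]
    pop = PopulationConfig(components=comps, n_fov=60)
    return ExperimentConfig(
        population=pop,
        detection=DetectionParams(detect_channel="membrane"),
        laser=LaserModel(power_uw=34),
        mode="static",
        policy="anywhere",
        classify=True,
        positive_genotypes=("Var1", "Var7"),
        replicates=3,
        readout="reads",
    )


PRESETS = {
    "fig2_yfp_mock": _fig2_yfp_mock,
    "fig3_mind_mock": _fig3_mind_mock,
    "fig4_dynamics": _fig4_dynamics,
    "fig5_mts_library": _fig5_mts_library,
}


def preset(name: str) -> ExperimentConfig:
    """Return a fully-populated config for one of the canonical designs."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return factory()
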