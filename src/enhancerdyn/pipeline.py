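"""End-to-end driver: synth -> dynamics -> classify -> profiles -> linkage -> atlas.

Runs the stages in dependency order on a generated (or pre-existing)
scenario directory, writes per-stage TSV/JSON outputs, and emits a single
JSON report with the headline quantities: stable-site counts, PU.1
pre-binding, binding-order fractions, promoter-state mixes, the 100-kb
window association, per-class terminal expression folds, and the lineage
activity/occupancy tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classes as enh_classes
from . import dynamics, linkage, lineage, profiles
from .genome import (
    GenomicInterval,
    PeakSet,
    read_bed,
    read_bedgraph,
    read_genes,
    overlaps_any,
)
from .synth import (
    ScenarioConfig,
    SyntheticDataset,
    generate_scenario,
    load_dataset,
    paper_default_config,
)

log = logging.getLogger("enhancerdyn")

MARK_ORDER = ("H3K4Me1", "H3K27Ac", "P300", "H3K27Me3")


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus scenario/source paths."""

    out_dir: Path
    data_dir: Path | None = None          # existing dataset; generated if None
    scenario: ScenarioConfig | None = None
    min_overlap: int = 1
    stability_mode: str = "gapfree"
    min_tss_distance: int = 2000
    half_window: int = 1000
    promoter_half_window: int = 1000
    mark_threshold: float = 2.0
    require_p300: bool = False
    flank: int = 500
    fold_threshold: float = 2.0
    expression_floor: float = 1.0
    window_max: int = 1_000_000
    window_step: int = 10_000
    headline_window: int = 100_000
    profile_window: int = 6000
    profile_bin: int = 100
    seed: int = 1

    def parameters(self) -> dict:
        """Parameter echo for the report; paths are omitted so that reports
        from identical runs in different directories compare byte-identical
        (the log records the full paths)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("data_dir")
        d["scenario"] = asdict(self.scenario) if self.scenario else None
        if d["scenario"]:
            d["scenario"] = _jsonable(d["scenario"])
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 6)
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# Stage helpers (reused by the CLI and the acceptance script)


def load_tf_timecourse(ds: SyntheticDataset, factor: str, series: str) -> dict[int, PeakSet]:
    times = (
        list(ds.config.time_points_hpi)
        if series == "hpi"
        else list(ds.config.early_time_points_min)
    )
    return {t: read_bed(ds.tf_bed(factor, series, t)) for t in times}


def stage_dynamics(
    ds: SyntheticDataset, min_overlap: int = 1, stability_mode: str = "gapfree"
) -> dict:
    """Non-redundant C/EBPα regions, stability calls, PU.1 pre-binding."""
    cebpa = load_tf_timecourse(ds, "cebpa", "hpi")
    presence = dynamics.build_presence(cebpa, min_overlap, factor="cebpa")
    terminal = ds.config.time_points_hpi[-1]
    baseline = ds.config.time_points_hpi[0]
    labels = dynamics.classify_stability(
        presence, terminal, baseline_times=[baseline], mode=stability_mode
    )
    stable = PeakSet(
        [iv for iv, lab in zip(presence.regions, labels) if lab == "stable"],
        source_label="cebpa_stable",
    )
    pu1_t0 = read_bed(ds.tf_bed("pu1", "hpi", baseline))
    prebound = dynamics.prebound_fraction(stable, pu1_t0, min_overlap)
    return {
        "presence": presence,
        "stability": labels,
        "stable": stable,
        "prebound_pu1": prebound,
    }


def stage_binding_order(ds: SyntheticDataset, min_overlap: int = 1) -> dict:
    """Joint C/EBPα/PU.1 presence over the early minute series + order calls."""
    cebpa = load_tf_timecourse(ds, "cebpa", "min")
    pu1 = load_tf_timecourse(ds, "pu1", "min")
    pooled = PeakSet(
        [iv for ps in list(cebpa.values()) + list(pu1.values()) for iv in ps.intervals]
    )
    from .genome import merge_intervals

    universe = merge_intervals(pooled)
    pa = dynamics.build_presence(cebpa, min_overlap, regions=universe, factor="cebpa")
    pb = dynamics.build_presence(pu1, min_overlap, regions=universe, factor="pu1")
    calls = dynamics.binding_order_table(pa, pb)
    return {"universe": universe, "calls": calls, "pa": pa, "pb": pb}


def cebpa_first_fraction(
    universe: PeakSet, calls: list, target_sites: PeakSet
) -> float:
    """Fraction of universe regions overlapping ``target_sites`` called a_first."""
    hit = overlaps_any(universe, target_sites)
    subset = [c for c, h in zip(calls, hit) if h]
    if not subset:
        return float("nan")
    return sum(c.order == "a_first" for c in subset) / len(subset)


def stage_classify(
    ds: SyntheticDataset,
    stable: PeakSet,
    min_tss_distance: int = 2000,
    half_window: int = 1000,
    promoter_half_window: int = 1000,
    threshold: float = 2.0,
    require_p300: bool = False,
    seed: int = 0,
) -> list:
    genes = read_genes(ds.genes_bed)
    baseline = ds.config.time_points_hpi[0]
    mark_tracks = {
        m: read_bedgraph(ds.mark_track(m, baseline), ds.genome) for m in MARK_ORDER
    }
    k4me3 = read_bedgraph(ds.mark_track("H3K4Me3", baseline), ds.genome)
    promoter_tracks = {"H3K4Me3": k4me3, "H3K27Me3": mark_tracks["H3K27Me3"]}
    return enh_classes.build_enhancer_records(
        stable,
        genes,
        mark_tracks,
        promoter_tracks,
        min_tss_distance=min_tss_distance,
        half_window=half_window,
        promoter_half_window=promoter_half_window,
        threshold=threshold,
        require_p300=require_p300,
        background_seed=seed,
    )


def promoter_mix(records, mark_class: str) -> dict[str, float]:
    """Promoter-state distribution of one mark class, as fractions."""
    members = [r for r in records if r.mark_class == mark_class]
    if not members:
        return {s: float("nan") for s in ("active", "inactive", "bivalent")}
    return {
        s: sum(r.promoter_state == s for r in members) / len(members)
        for s in ("active", "inactive", "bivalent")
    }


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "chrom": r.region.chrom,
            "start": r.region.start,
            "end": r.region.end,
            "name": r.region.name,
            "score": r.region.score,
            "strand": r.region.strand,
            "mark_class": r.mark_class,
            "promoter_state": r.promoter_state,
            "final_class": r.final_class,
            "nearest_gene": r.nearest_gene,
            "tss_distance": r.tss_distance,
        }
        for m, st in r.mark_states.items():
            row[f"fold_{m}"] = round(st.fold_enrichment, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, threshold: float = 2.0) -> list:
    records = []
    fold_cols = [c for c in df.columns if c.startswith("fold_")]
    for _, row in df.iterrows():
        states = {
            c[len("fold_"):]: enh_classes.MarkState(
                c[len("fold_"):], float(row[c]), float(row[c]) >= threshold
            )
            for c in fold_cols
        }
        records.append(
            enh_classes.EnhancerRecord(
                region=GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"]),
                    str(row.get("name", ".")), float(row.get("score", 0.0)),
                    str(row.get("strand", ".")),
                ),
                mark_states=states,
                mark_class=row["mark_class"],
                promoter_state=row["promoter_state"],
                final_class=row["final_class"],
                nearest_gene=row["nearest_gene"],
                tss_distance=int(row["tss_distance"]),
            )
        )
    return records


def stage_linkage(
    ds: SyntheticDataset,
    records,
    stable: PeakSet,
    fold_threshold: float = 2.0,
    floor: float = 1.0,
    window_max: int = 1_000_000,
    window_step: int = 10_000,
    headline_window: int = 100_000,
) -> dict:
    expr = linkage.read_expression(ds.expression_timecourse)
    annotation = read_genes(ds.genes_bed)
    times = [str(t) for t in ds.config.time_points_hpi]
    baseline, terminal = times[0], times[-1]
    calls = linkage.call_regulated(expr, baseline, terminal, fold_threshold, floor)
    up_genes = [c.gene_id for c in calls if c.label == "up"]
    windows = list(range(0, window_max + window_step, window_step))
    curve = linkage.window_fraction_curve(up_genes, annotation, stable, windows)
    curve_map = dict(curve)
    kinetics = linkage.class_expression_kinetics(
        records, expr, baseline, times, "up", fold_threshold, floor
    )
    # rank-sum contrast of terminal folds between the two final classes
    folds = {}
    for cls in ("pre_existing", "de_novo"):
        genes = sorted(
            {
                r.nearest_gene
                for r in records
                if r.final_class == cls and r.nearest_gene in set(up_genes)
            }
        )
        folds[cls] = (
            (expr.loc[genes, terminal] + floor) / (expr.loc[genes, baseline] + floor)
        ).to_numpy()
    if folds["pre_existing"].size and folds["de_novo"].size:
        _, p = linkage.compare_groups(
            folds["de_novo"], folds["pre_existing"], "wilcoxon_two_tailed"
        )
    else:
        p = float("nan")
    return {
        "calls": calls,
        "n_up": len(up_genes),
        "curve": curve,
        "upregulated_within_headline_window": curve_map[headline_window],
        "kinetics": kinetics,
        "terminal_fold_median": {cls: k[terminal] for cls, k in kinetics.items()},
        "class_contrast_p": p,
    }


def stage_atlas(ds: SyntheticDataset, records, flank: int = 500) -> dict:
    tree = lineage.LineageTree(dict(lineage.HEMATOPOIESIS_TREE))
    act_peaks = {
        ct: read_bed(ds.celltype_bed("k27ac", ct)) for ct in ds.config.lineage_activity
    }
    occ_peaks = {
        ct: read_bed(ds.celltype_bed("cebpa", ct)) for ct in ds.config.occupancy
    }
    activity = lineage.activity_fractions(records, act_peaks, flank)
    occupancy = lineage.occupancy_fractions(records, occ_peaks, flank)
    n = {
        cls: sum(r.final_class == cls for r in records)
        for cls in ("pre_existing", "de_novo")
    }
    pooled = {}
    for ct in occupancy.index:
        num = sum(occupancy.loc[ct, cls] * n[cls] for cls in n)
        denom = sum(n.values())
        pooled[ct] = num / denom if denom else float("nan")
    trajectory = lineage.trajectory_report(tree, activity)
    return {
        "tree": tree,
        "activity": activity,
        "occupancy": occupancy,
        "occupancy_pooled": pooled,
        "trajectory": trajectory,
    }


def stage_profiles(ds: SyntheticDataset, records, window: int = 6000, bin: int = 100) -> dict:
    """K27Ac kinetic summaries and MNase nucleosome profiles per class."""
    centers = {
        cls: [
            (r.region.chrom, r.region.midpoint)
            for r in records
            if r.final_class == cls
        ]
        for cls in ("pre_existing", "de_novo")
    }
    baseline = ds.config.time_points_hpi[0]
    terminal = ds.config.time_points_hpi[-1]
    summaries: dict[str, dict] = {}
    for t in (baseline, terminal):
        track = read_bedgraph(ds.mark_track("H3K27Ac", t), ds.genome)
        for cls, cts in centers.items():
            if not cts:
                continue
            m = profiles.binned_matrix(track, cts, window, bin, label="H3K27Ac", time=str(t))
            prof = profiles.average_profile(m)
            summaries.setdefault(cls, {})[str(t)] = {
                "peak_bin": profiles.peak_bin_summary(prof),
                "center": profiles.center_summary(prof),
            }
    mnase = {}
    for cond in ("preB", "iMPhi"):
        frags = read_bed(ds.mnase_bed(cond))
        for cls, cts in centers.items():
            if not cts:
                continue
            mnase[f"{cond}_{cls}"] = profiles.mnase_profile(
                frags, cts, window, condition=f"{cond}_{cls}"
            )
    return {"k27ac_summaries": summaries, "mnase": mnase}


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; write per-stage outputs and report.json under out_dir."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"parameters": _jsonable(cfg.parameters())}
    t_start = time.time()
    try:
        log.info("out_dir=%s data_dir=%s", out_dir, cfg.data_dir)
        log.info("parameters: %s", json.dumps(report["parameters"], sort_keys=True))

        def timed(name):
            # timings go to the log only, keeping report.json reproducible
            log.info("stage %s done at %.2fs", name, time.time() - t_start)

        if cfg.data_dir is not None:
            ds = load_dataset(cfg.data_dir)
        else:
            scenario = cfg.scenario or paper_default_config(cfg.seed)
            ds, _ = generate_scenario(scenario, out_dir / "data")
        timed("synth")

        dyn = stage_dynamics(ds, cfg.min_overlap, cfg.stability_mode)
        labels = dyn["stability"]
        stable = dyn["stable"]
        pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in dyn["presence"].regions],
                "start": [iv.start for iv in dyn["presence"].regions],
                "end": [iv.end for iv in dyn["presence"].regions],
                "stability": labels,
            }
        ).to_csv(out_dir / "stability.tsv", sep="\t", index=False)
        report["n_regions"] = len(dyn["presence"].regions)
        report["n_stable"] = sum(l == "stable" for l in labels)
        report["n_transient"] = sum(l == "transient" for l in labels)
        report["prebound_pu1_pct"] = 100.0 * dyn["prebound_pu1"]
        timed("dynamics")

        order = stage_binding_order(ds, cfg.min_overlap)
        timed("binding_order")

        records = stage_classify(
            ds,
            stable,
            cfg.min_tss_distance,
            cfg.half_window,
            cfg.promoter_half_window,
            cfg.mark_threshold,
            cfg.require_p300,
            cfg.seed,
        )
        records_to_frame(records).to_csv(out_dir / "enhancers.tsv", sep="\t", index=False)
        mark_dn = PeakSet([r.region for r in records if r.mark_class == "de_novo"])
        report["binding_order"] = {
            "de_novo_cebpa_first_pct": 100.0
            * cebpa_first_fraction(order["universe"], order["calls"], mark_dn)
        }
        report["classes"] = {
            "mark": {
                c: sum(r.mark_class == c for r in records)
                for c in ("pre_existing", "de_novo", "ambiguous")
            },
            "final": {
                c: sum(r.final_class == c for r in records)
                for c in ("pre_existing", "de_novo", "excluded")
            },
            "promoter_mix_pre_existing_pct": {
                k: 100.0 * v for k, v in promoter_mix(records, "pre_existing").items()
            },
            "promoter_mix_de_novo_pct": {
                k: 100.0 * v for k, v in promoter_mix(records, "de_novo").items()
            },
        }
        timed("classify")

        prof = stage_profiles(ds, records, cfg.profile_window, cfg.profile_bin)
        report["profiles"] = {"k27ac_summaries": prof["k27ac_summaries"]}
        for key, np_prof in prof["mnase"].items():
            pd.DataFrame({"offset": np_prof.offsets, "value": np_prof.values}).to_csv(
                out_dir / f"mnase_profile_{key}.tsv", sep="\t", index=False
            )
        timed("profiles")

        link = stage_linkage(
            ds,
            records,
            stable,
            cfg.fold_threshold,
            cfg.expression_floor,
            cfg.window_max,
            cfg.window_step,
            cfg.headline_window,
        )
        pd.DataFrame(link["curve"], columns=["window", "fraction"]).to_csv(
            out_dir / "window_fraction_curve.tsv", sep="\t", index=False
        )
        report["linkage"] = {
            "n_up": link["n_up"],
            "upregulated_within_100kb_pct": 100.0
            * link["upregulated_within_headline_window"],
            "terminal_fold_median": link["terminal_fold_median"],
            "class_contrast_p": link["class_contrast_p"],
        }
        timed("linkage")

        atlas = stage_atlas(ds, records, cfg.flank)
        atlas["activity"].to_csv(out_dir / "activity.tsv", sep="\t")
        atlas["occupancy"].to_csv(out_dir / "occupancy.tsv", sep="\t")
        (out_dir / "trajectory.json").write_text(
            json.dumps(_jsonable(atlas["trajectory"]), indent=1, sort_keys=True)
        )
        report["atlas"] = {
            "activity_pct": _jsonable((100.0 * atlas["activity"]).to_dict()),
            "occupancy_pct": _jsonable((100.0 * atlas["occupancy"]).to_dict()),
            "occupancy_pooled_pct": {
                k: 100.0 * v for k, v in atlas["occupancy_pooled"].items()
            },
        }
        timed("atlas")
    except Exception as exc:
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=1, sort_keys=True)
        )
        log.removeHandler(handler)
        handler.close()
        raise
    report = _jsonable(report)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.removeHandler(handler)
    handler.close()
    return report
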