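"""End-to-end synthetic-study runner.

Chains simulate -> detect -> gate -> cnv / expr -> surv into one
reproducible run: renders a slide and enumerates its rare cells, checks
copy-number ratio clonality under whole-genome doubling, derives the
cross-line survivor gene set and scores it per cell, and tests the
survival association of IGC presence.  Every stage writes its artifacts
under the output directory, and a JSON manifest records the seed, the
config hash and package versions so a rerun with the same config
reproduces all deterministic artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cnv, expr, gating, imaging, surv, synth

logger = logging.getLogger("rarecell")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a full synthetic-study run.

    Stage specs default to the package's standard study conditions; any
    field can be overridden via the YAML config the CLI accepts.  The
    master ``seed`` derives per-stage seeds deterministically.
    """

    seed: int = 0
    out_dir: str = "rarecell_run"
    slide: synth.SlideSpec = field(default_factory=synth.SlideSpec)
    segmentation: imaging.SegmentationConfig = field(
        default_factory=imaging.SegmentationConfig
    )
    gates: gating.GateConfig = field(default_factory=gating.GateConfig)
    expr_sim: synth.ExprSimSpec | None = None
    cohort: synth.CohortSpec = field(default_factory=synth.CohortSpec)
    n_cnv_cells_per_clone: int = 5
    cnv_bins: int = 1000

    def config_hash(self) -> str:
        payload = _serializable(self)
        payload.pop("out_dir", None)  # hash identifies the analysis, not the location
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _serializable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serializable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("list")
    return obj


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _stage_slide(cfg: RunConfig, out: Path) -> dict:
    spec = cfg.slide
    spec.seed = _stage_seed(cfg.seed, "slide")
    slide, truth = synth.generate_slide(spec)
    imaging.write_slide_tiff(slide, out / "slide.tiff")
    pd.DataFrame([asdict(t) for t in truth]).to_csv(out / "truth.csv", index=False)

    cell_mask = imaging.build_cell_mask(slide, cfg.segmentation)
    dapi_mask = imaging.segment_channel(slide["DAPI"], cfg.segmentation)
    records = imaging.extract_cells(slide, cell_mask, dapi_mask, cfg.segmentation)
    background = imaging.estimate_background(slide, cell_mask)
    imaging.records_to_frame(records).to_csv(out / "features.csv", index=False)

    labels = gating.immunophenotype(records, cfg.gates, background)
    ctc_d = [
        r.nucleus_equivalent_diameter_um
        for r, lab in zip(records, labels)
        if lab == "CTC_candidate"
    ]
    flags, ref = gating.classify_igc(np.asarray(ctc_d), cfg.gates)
    markers = gating.marker_positive(records, cfg.gates, background)
    enum = gating.enumerate_sample(labels, flags, markers, sample_id="synthetic")
    summary = gating.summarize_cohort([enum])
    summary.to_csv(out / "sample_summary.csv", index=False)
    return {
        "n_cells_detected": len(records),
        "n_cells_truth": len(truth),
        "enumeration": {
            "WBC": enum.n_wbc,
            "CTC": enum.n_ctc,
            "CTC_IGC": enum.n_ctc_igc,
            "other": enum.n_other,
        },
        "igc_reference_diameter_um": None if np.isnan(ref) else round(ref, 2),
        "igc_positive": bool(enum.igc_positive),
    }


def _stage_cnv(cfg: RunConfig, out: Path) -> dict:
    bins = synth.default_genome_bins(n_bins=cfg.cnv_bins, seed=_stage_seed(cfg.seed, "bins"))
    n_bins = len(bins)
    rng = np.random.default_rng(_stage_seed(cfg.seed, "clones"))
    cn_a = synth.random_clone_cn(bins, seed=_stage_seed(cfg.seed, "cloneA"))
    cn_b = synth.random_clone_cn(bins, seed=_stage_seed(cfg.seed, "cloneB"))
    profiles, meta = [], []
    for name, cn, wgds in (("A", cn_a, (1, 2)), ("B", cn_b, (1,))):
        for wgd in wgds:
            spec = synth.ClonalCNSpec(
                bins=bins,
                copy_number=cn,
                wgd_multiplier=wgd,
                gc_coeffs=(0.3, 3.0, -3.0),
                seed=int(rng.integers(2**31 - 1)),
            )
            bc = synth.generate_bin_counts(spec, n_cells=cfg.n_cnv_cells_per_clone)
            corr = cnv.gc_correct(bc)
            for i in range(bc.n_cells):
                rp = cnv.to_ratio(corr[i], bins, cell_id=f"{name}_wgd{wgd}_{i}")
                profiles.append(cnv.segment_profile(rp))
                meta.append({"clone": name, "wgd": wgd})
    r_wgd = cnv.compare_profiles(profiles[0], profiles[cfg.n_cnv_cells_per_clone])["r"]
    link, labels = cnv.cluster_profiles(profiles, n_clusters=2)
    clone_of = np.array([m["clone"] for m in meta])
    # clustering recovers clones iff labels are constant within each clone
    pure = all(len(np.unique(labels[clone_of == c])) == 1 for c in np.unique(clone_of))
    seg_table = pd.concat(
        [p.segments_frame().assign(cell_id=p.cell_id) for p in profiles],
        ignore_index=True,
    )
    seg_table.to_csv(out / "segments.tsv", sep="\t", index=False)
    return {
        "wgd_ratio_correlation": round(float(r_wgd), 4),
        "clones_separated": bool(pure and len(np.unique(labels)) == 2),
        "n_profiles": len(profiles),
    }


def _stage_expr(cfg: RunConfig, out: Path) -> dict:
    spec = cfg.expr_sim
    if spec is None:
        rng = np.random.default_rng(_stage_seed(cfg.seed, "expr"))
        sig_idx = rng.choice(2000, size=309, replace=False)
        spec = synth.ExprSimSpec(
            n_genes=2000,
            survivor_signature={int(i): 2.0 for i in sig_idx},
            seed=_stage_seed(cfg.seed, "expr_counts"),
        )
    cm = synth.generate_expression(spec)
    results = []
    for line in spec.lines:
        for cond in spec.conditions:
            if cond == spec.control_condition:
                continue
            results.append(
                expr.differential_expression(cm, cond, spec.control_condition, line=line)
            )
    survivor = expr.shared_upregulated(results, name="survivor_set")
    (out / "survivor_set.txt").write_text("\n".join(survivor.genes) + "\n")
    for r in results:
        r.table.to_csv(out / f"de_{r.contrast.replace(':', '_')}.csv", index=False)
    conc = expr.lfc_concordance(results[0], results[2], survivor) if len(survivor) >= 3 else None

    norm = expr.normalize_log(cm)
    scores = expr.jasmine_score(norm, cm.gene_ids, survivor)
    treated = (cm.meta["condition"] != spec.control_condition).to_numpy()
    sep = float(scores["score"][treated].mean() - scores["score"][~treated].mean())

    truth = set(f"gene{i}" for i in spec.survivor_signature)
    found = set(survivor.genes)
    sens = len(found & truth) / len(truth) if truth else float("nan")
    prec = len(found & truth) / len(found) if found else float("nan")
    return {
        "n_survivor_genes": len(survivor),
        "survivor_sensitivity": round(sens, 4),
        "survivor_precision": round(prec, 4),
        "lfc_concordance_r": None if conc is None else round(conc, 4),
        "jasmine_treated_minus_control": round(sep, 4),
    }


def _stage_surv(cfg: RunConfig, out: Path) -> dict:
    spec = cfg.cohort
    spec.seed = _stage_seed(cfg.seed, "cohort")
    ct = synth.generate_cohort(spec)
    ct.to_csv(out / "cohort.csv", index=False)
    chi2, p = surv.logrank_test(ct)
    medians = {}
    for g in ("positive", "negative"):
        km = surv.km_estimate(ct, group=g)
        medians[g] = None if np.isnan(km.median) else round(km.median, 2)
    return {"logrank_chi2": round(chi2, 4), "logrank_p": float(p), "km_median_months": medians}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return the report dict (also written to disk).

    A stage failure halts the run with the failing stage named; artifacts
    from completed stages are retained.
    """
    out = Path(cfg.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("ok")
        probe.unlink()
    except OSError as e:
        raise RuntimeError(f"output directory {out} is not writable: {e}") from None

    report: dict = {}
    stages = [
        ("slide", _stage_slide),
        ("cnv", _stage_cnv),
        ("expr", _stage_expr),
        ("surv", _stage_surv),
    ]
    for name, fn in stages:
        logger.info("running stage %s", name)
        try:
            report[name] = fn(cfg, out)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": _serializable(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
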