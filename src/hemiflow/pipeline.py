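"""End-to-end analysis pipeline on simulated (or ingested) group data.

Stage order mirrors the analysis it re-implements: simulate the two
cohorts -> voxelwise GLM and group activation maps -> FDR + cluster
thresholding -> minimum-statistic conjunction -> ROI definition ->
per-subject lateralization index -> percent signal change ->
HRF-deconvolved conditional GC per subject -> bootstrap-thresholded
networks -> In-Out degrees, hemispheric counts -> group comparisons.

Every run writes a manifest with the config hash, the seeds used and a
SHA-256 checksum of every output file; the manifest content is fully
determined by the configuration, so identical config + seed reproduce
it bytewise.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activation as act
from . import cgc as cgcmod
from . import io as hio
from . import laterality as lat
from . import network as netmod
from .config import PipelineConfig
from .paradigm import CONTROL, TASK, build_paradigm
from .synthetic import (
    GroupSpec,
    build_parcellation,
    demo_network,
    simulate_group,
)

log = logging.getLogger("hemiflow")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def record(self, path: Path):
        self.checksums[path.name] = hio.sha256_of(path)


def _stage(manifest: RunManifest, name: str, **params):
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))
    manifest.stages.append({"stage": name, **params})


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunManifest:
    """Run the full pipeline; returns the manifest (also written as JSON)."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seed=config.seed)

    pc = config.paradigm
    paradigm = build_paradigm(
        pc.n_blocks_per_condition, pc.block_duration_s, pc.tr_s, pc.n_dummy
    )
    sim = config.simulation
    network = demo_network(
        coupling=sim.coupling,
        self_coupling=sim.self_coupling,
        noise_sd=sim.neural_noise_sd,
    )
    parcellation = build_parcellation(network.region_names)
    gains = np.array(
        [
            float(sim.input_gains.get(r, sim.input_gains.get("default", 1.0)))
            for r in network.region_names
        ]
    )
    hio.write_json(config.to_dict(), out / "config.json")
    manifest.record(out / "config.json")

    # --- stage 1: simulate -------------------------------------------------
    groups = {}
    for gi, gcfg in enumerate(sim.groups):
        spec = GroupSpec(
            n_subjects=gcfg.n_subjects,
            asymmetry_ratio=gcfg.asymmetry_ratio,
            edge_deltas=[tuple(e) for e in gcfg.edge_deltas],
            between_subject_sd=gcfg.between_subject_sd,
            label=gcfg.label,
        )
        groups[gcfg.label] = simulate_group(
            network, paradigm, spec,
            seed=config.seed + 1000 * (gi + 1),
            make_voxels=True,
            parcellation=parcellation,
            input_gain=gains,
            bold_noise_sd=sim.bold_noise_sd,
            voxel_noise_sd=sim.voxel_noise_sd,
            effect_scale=sim.effect_scale,
            p_active=sim.p_active,
        )
        _stage(manifest, "simulate", group=gcfg.label,
               n_subjects=gcfg.n_subjects)
    hio.write_volume(parcellation.labels, parcellation.affine,
                     out / "parcellation.nii")
    manifest.record(out / "parcellation.nii")
    hio.write_json(
        {
            "region_names": network.region_names,
            "adjacency": network.adjacency,
            "hrf_time_to_peak_s": [h.time_to_peak_s for h in network.hrf_specs],
            "seed": config.seed,
        },
        out / "ground_truth.json",
    )
    manifest.record(out / "ground_truth.json")

    # --- stage 2: activation maps per group --------------------------------
    ac = config.activation
    design = act.build_design(paradigm, drift_order=ac.drift_order)
    contrast = design.contrast_vector({TASK: 1.0, CONTROL: -1.0})
    subject_t = {}  # label -> list of subject t volumes
    group_maps = {}
    for label, subjects in groups.items():
        cmaps, tvols = [], []
        for s in subjects:
            res = act.fit_glm(s.voxel_data, design, contrast)
            cmaps.append(res.contrast_estimate.reshape(parcellation.shape))
            tvols.append(res.t_volume())
        subject_t[label] = tvols
        t, p = act.group_tmap(np.stack(cmaps))
        group_maps[label] = (t, p)
        hio.write_volume(t, parcellation.affine, out / f"tmap_{label}.nii")
        manifest.record(out / f"tmap_{label}.nii")
        _stage(manifest, "activation", group=label, q=ac.q,
               min_cluster=ac.min_cluster)

    rule = act.default_threshold_rule(ac.q, ac.min_cluster, ac.connectivity)
    conjoint = act.conjunction(
        [t for t, _ in group_maps.values()],
        [p for _, p in group_maps.values()],
        threshold_rule=rule,
    )
    hio.write_volume(
        conjoint.mask.astype(np.int16), parcellation.affine,
        out / "conjunction_mask.nii",
    )
    manifest.record(out / "conjunction_mask.nii")
    hio.write_json(conjoint.threshold_meta, out / "threshold_meta.json")
    manifest.record(out / "threshold_meta.json")
    _stage(manifest, "conjunction", n_voxels=conjoint.n_voxels)

    rois = act.define_rois(conjoint, parcellation)
    _stage(manifest, "rois", n_rois=len(rois))

    # --- stage 3: laterality and signal change ------------------------------
    hemi_mask = parcellation.hemisphere_mask()
    li_rows, psc_rows = [], []
    territories = dict(config.laterality.territories or {"cerebral": None})
    for label, tvols in subject_t.items():
        for si, tvol in enumerate(tvols):
            for terr_name, prefixes in territories.items():
                terr = None
                if prefixes:
                    terr = np.isin(
                        parcellation.labels,
                        [parcellation.region_names.index(r) + 1
                         for r in parcellation.region_names
                         if any(r.startswith(p) for p in prefixes)],
                    )
                res, fit, _ = lat.li_for_tmap(
                    tvol, hemi_mask, territory=terr, territory_name=terr_name,
                    n_steps=config.laterality.n_steps,
                )
                li_rows.append(
                    {
                        "group": label, "subject": si,
                        "territory": terr_name, "li": res.li,
                        "category": res.category,
                        "c_left": fit.c_left, "c_right": fit.c_right,
                        "model_form": fit.model_form,
                    }
                )
        for si, s in enumerate(groups[label]):
            for roi in rois:
                series = act.extract_roi_series(s.voxel_data, roi)
                psc_rows.append(
                    {
                        "group": label, "subject": si, "roi": roi.name,
                        "hemisphere": roi.hemisphere,
                        "signal_change_pct": act.percent_signal_change(
                            series, design, contrast
                        ),
                    }
                )
    li_df = pd.DataFrame(li_rows)
    li_df.to_csv(out / "laterality.tsv", sep="\t", index=False)
    manifest.record(out / "laterality.tsv")
    psc_df = pd.DataFrame(psc_rows)
    psc_df.to_csv(out / "signal_change.tsv", sep="\t", index=False)
    manifest.record(out / "signal_change.tsv")
    _stage(manifest, "laterality", n_subjects=len(li_rows))

    # --- stage 4: connectivity ----------------------------------------------
    cc = config.connectivity
    if len(rois) < 3:
        raise RuntimeError(
            "[connectivity] fewer than 3 conjoint ROIs; conditional GC "
            "needs at least 3 — check activation thresholds/effect size"
        )
    cgc_by_group, null_by_group, counts_by_group = {}, {}, {}
    for label, subjects in groups.items():
        cgcs, nulls, counts = [], [], []
        for si, s in enumerate(subjects):
            cgc = cgcmod.cgc_pipeline(
                s, rois=rois, basis=cc.basis, deconvolve_bold=cc.deconvolve,
                reg=cc.regularization, max_order=cc.max_order,
                criterion=cc.criterion,
            )
            series = cgc.analyzed_series
            var_fit = cgcmod.fit_var(series, cgc.order)
            null = netmod.bootstrap_threshold(
                series, var_fit, n_reps=cc.n_reps, alpha=cc.alpha,
                seed=s.seed + 17,
            )
            net = netmod.build_network(
                cgc, null, hemispheres=[r.hemisphere for r in rois]
            )
            cgcs.append(cgc)
            nulls.append(null)
            counts.append(netmod.hemispheric_counts(net))
        cgc_by_group[label] = cgcs
        null_by_group[label] = nulls
        counts_by_group[label] = counts
        _stage(manifest, "connectivity", group=label,
               order=cgcs[0].order, n_reps=cc.n_reps)

    # --- stage 5: group networks, degrees, comparisons ----------------------
    comp = config.comparison
    for label in groups:
        gnet = netmod.group_network(
            cgc_by_group[label], null_by_group[label],
            alpha_group=comp.alpha_group,
            hemispheres=[r.hemisphere for r in rois],
        )
        # diagonal stays NaN; off-diagonal entries are never NaN
        mean_f = np.mean(
            np.stack([c.f_values for c in cgc_by_group[label]]), axis=0
        )
        hio.write_matrix_tsv(mean_f, [r.name for r in rois],
                             out / f"cgc_mean_{label}.tsv")
        manifest.record(out / f"cgc_mean_{label}.tsv")
        edges = pd.DataFrame(
            [
                {"source": s_, "target": t_,
                 "f_mean": mean_f[[r.name for r in rois].index(s_),
                                  [r.name for r in rois].index(t_)],
                 "significant": True}
                for s_, t_ in gnet.edges()
            ]
        )
        edges.to_csv(out / f"edges_{label}.tsv", sep="\t", index=False)
        manifest.record(out / f"edges_{label}.tsv")
        deg = netmod.in_out_degrees(gnet)
        deg.to_csv(out / f"degrees_{label}.tsv", sep="\t", index=False)
        manifest.record(out / f"degrees_{label}.tsv")
        try:
            import networkx as nx

            nx.write_graphml(gnet.to_networkx(), out / f"network_{label}.graphml")
            manifest.record(out / f"network_{label}.graphml")
        except ImportError:  # pragma: no cover
            pass
        _stage(manifest, "network", group=label, n_edges=gnet.n_edges)

    labels = list(groups)
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        edge_cmp = netmod.compare_edge_groups(
            cgc_by_group[a], cgc_by_group[b],
            direction=comp.direction, alpha_fwe=comp.alpha_fwe,
        )
        edge_cmp.to_csv(out / "edge_comparison.tsv", sep="\t", index=False)
        manifest.record(out / "edge_comparison.tsv")
        count_cmp = netmod.compare_count_groups(
            counts_by_group[a], counts_by_group[b], alpha=comp.count_alpha
        )
        count_cmp.to_csv(out / "count_comparison.tsv", sep="\t", index=False)
        manifest.record(out / "count_comparison.tsv")
        _stage(manifest, "compare", groups=f"{a}-vs-{b}")

    hio.write_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest
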