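"""End-to-end orchestration: synthetic inputs -> contrasts, graphs, signatures.

``run_pipeline`` strings the stages together exactly once, writing plain-text
outputs under a target directory.  It exists so the whole analysis can be
reproduced from one seed, and so the command-line entry point stays thin.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import cyto_clean, graphnet, pls, preproc, synth

__all__ = ["run_pipeline", "DEFAULT_PIPELINE_CONFIG", "preprocess_scan"]

#: a scaled-down study used by the examples and the shell entry point: full
#: structure (2 genotypes x 4 ages, blocks, planted cytokines) at a size that
#: runs end to end in a couple of minutes.
DEFAULT_PIPELINE_CONFIG = synth.SynthConfig(
    n_subjects_per_group=6,
    n_rois=16,
    n_systems=4,
    affected_systems=(1, 2),
    n_timepoints_per_scan=200,
    scans_per_subject=2,
)


def preprocess_scan(scan: preproc.ScanTimeSeries,
                    trace: preproc.MotionTrace,
                    threshold: float = preproc.SCRUB_THRESHOLD_MM,
                    band: tuple[float, float] = (0.01, 0.1)):
    """Scrub -> nuisance GLM -> bandpass -> correlate for one scan.

    The nuisance design holds the six rigid motion parameters plus a WM-CSF
    style global regressor (here the mean ROI signal, standing in for the
    white-matter/CSF mask signal an imaging pipeline would extract).
    Returns ``(matrix, scrub_result)``; ``matrix`` is None when the scan
    fails the 90% retention rule.
    """
    scrub = preproc.scrub_volumes(trace, threshold=threshold)
    if not scrub.scan_kept:
        return None, scrub
    scan = preproc.apply_scrub(scan, scrub)
    keep = scan.censor_mask
    motion_regs = np.column_stack([trace.translations, trace.rotations])[keep]
    wmcsf = scan.data[:, keep].mean(axis=0)
    scan = preproc.nuisance_regress(scan, np.column_stack([wmcsf, motion_regs]))
    scan = preproc.bandpass(scan, *band)
    return preproc.roi_correlation(scan), scrub


def run_pipeline(config: synth.SynthConfig | None = None,
                 outdir: str | Path = "cytoconn_out",
                 seed: int | None = None,
                 contrast_age: float | None = None,
                 cv_repeats: int = 50,
                 n_perm: int = 200) -> dict:
    """Run the full synthetic study once and write all outputs.

    Stages: generate scans and motion traces; scrub/regress/filter/correlate;
    per-genotype group means, disease difference matrix, system aggregation
    and the edgewise mixed-model genotype contrast at ``contrast_age``
    (default: last age) with BH-FDR; graph metrics and hub scores on group
    means; cytokine panel generation, censoring, retention, and per-genotype
    age-PLSR with CV component selection, orthogonalization, VIP signature
    and permutation significance.  Returns a JSON-serialisable summary (also
    written to ``summary.json``).
    """
    config = DEFAULT_PIPELINE_CONFIG if config is None else config
    if seed is not None:
        config = replace(config, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- synthesis
    scans = synth.gen_scan_set(config)
    systems = synth.make_system_definition(config)
    synth.write_systems_json(systems, outdir / "systems.json")

    # --- preprocessing
    matrices = []
    retained_fractions = []
    for i, scan in enumerate(scans):
        trace = synth.gen_motion_trace(config, n_volumes=scan.n_volumes, salt=i)
        matrix, scrub = preprocess_scan(scan, trace)
        retained_fractions.append(scrub.retained_fraction)
        if matrix is not None:
            matrices.append(matrix)
    mat_dir = outdir / "connectivity"
    mat_dir.mkdir(exist_ok=True)
    for m in matrices:
        sid = m.metadata["scan_id"]
        m.to_frame().to_csv(mat_dir / f"{sid}.tsv", sep="\t",
                            float_format="%.10g")
        (mat_dir / f"{sid}.json").write_text(json.dumps(
            {k: v for k, v in m.metadata.items()}, default=str))

    age = config.ages[-1] if contrast_age is None else contrast_age
    at_age = [m for m in matrices if m.metadata["age_months"] == age]
    groups = {g: [m for m in at_age if m.metadata["genotype"] == g]
              for g in synth.GENOTYPES}

    # --- group means, difference, systems, edgewise contrast
    means = {g: conn.group_mean_matrix(ms, group=g) for g, ms in groups.items()}
    diff = conn.difference_matrix(means["5xFAD"], means["WT"])
    diff.to_csv(outdir / f"difference_m{age:g}.tsv", sep="\t",
                float_format="%.10g")
    for g, m in means.items():
        conn.aggregate_system(m, systems).to_csv(
            outdir / f"systems_{g}_m{age:g}.tsv", sep="\t",
            float_format="%.10g")
    edge_table = conn.matrices_to_edge_table(at_age)
    stats = conn.fit_edgewise_lme(edge_table)
    stats.table.to_csv(outdir / f"edge_stats_m{age:g}.csv", index=False,
                       float_format="%.10g")
    roi_order = means["5xFAD"].roi_names
    pd.DataFrame(stats.mask(roi_order).astype(int), index=roi_order,
                 columns=roi_order).to_csv(outdir / f"sig_mask_m{age:g}.tsv",
                                           sep="\t")

    # --- graph metrics on group means
    graph_summary = {}
    for g, m in means.items():
        gm = graphnet.graph_metrics(m)
        gm.node_table.to_csv(outdir / f"graph_nodes_{g}_m{age:g}.csv",
                             index=False, float_format="%.10g")
        graph_summary[g] = gm.to_global_dict()
    (outdir / "graph_global.json").write_text(
        json.dumps(graph_summary, indent=2, default=float))

    # --- cytokines
    panel = synth.gen_cytokine_panel(config)
    panel = cyto_clean.censor(panel)
    panel, audit = cyto_clean.retain_analytes(panel)
    audit.to_csv(outdir / "cytokine_audit.csv", index=False,
                 float_format="%.10g")
    pls_summary = {}
    for g in synth.GENOTYPES:
        X, meta = cyto_clean.panel_to_wide(panel, genotype=g)
        y = meta["age_months"].to_numpy(float)
        cv = pls.cross_validate(X.to_numpy(), y, repeats=cv_repeats,
                                seed=config.seed + 11)
        model = pls.fit_pls(X.to_numpy(), y, cv.chosen_A,
                            names=list(X.columns))
        omodel = pls.orthogonalize(model)
        sig = pls.signature_report(omodel)
        sig.to_csv(outdir / f"signature_{g}.csv", index=False,
                   float_format="%.10g")
        perm = pls.permutation_test(X.to_numpy(), y, cv.chosen_A,
                                    n_perm=n_perm, cv_repeats=5,
                                    seed=config.seed + 13)
        pls_summary[g] = {
            "chosen_A": cv.chosen_A, "k_folds": cv.k,
            "rmsecv": cv.chosen_statistic(),
            "permutation_z": perm.z, "permutation_p": perm.p,
            "n_vip": int(len(sig)),
            "vip_analytes": sig["analyte"].tolist(),
        }

    summary = {
        "config": asdict(config),
        "n_scans": len(scans),
        "n_scans_kept": len(matrices),
        "mean_retained_fraction": float(np.mean(retained_fractions)),
        "contrast_age_months": age,
        "n_significant_edges": int(stats.table["sig"].sum()),
        "n_edges": int(len(stats.table)),
        "graph": graph_summary,
        "pls": pls_summary,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    default=float))
    return summary
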