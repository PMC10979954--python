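"""Synthetic study-structured inputs: scans, motion, cytokine panels, fixtures.

The generator emulates the design of a longitudinal mouse imaging/cytokine
study: two genotypes (5xFAD vs WT littermates) by four ages (1.5, 2, 4, 6
months), several EPI scans per imaging session, ROI time courses with
block-community correlation structure organised into anatomical systems, a
disease effect expressed as a Fisher-z shift on designated system blocks at
designated ages, subject-level random intercepts, log-normal 23-analyte
cytokine panels with planted age-covarying analytes and detection-limit
censoring, and motion traces with spike artefacts.

All effects on correlations are applied in z-space and back-transformed, so
generated matrices are always valid correlation matrices (after a nearest
positive-definite repair of the block target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, SystemDefinition, SEVEN_SYSTEMS
from .cyto_clean import CytokinePanel
from .preproc import MotionTrace, ScanTimeSeries, SCRUB_THRESHOLD_MM

__all__ = [
    "SynthConfig",
    "gen_scan_set",
    "gen_motion_trace",
    "gen_cytokine_panel",
    "gen_toy_graph",
    "make_system_definition",
    "planted_block_mask",
    "write_scan_set",
    "write_cytokine_panel",
    "write_systems_json",
    "read_scan_set",
]

GENOTYPES = ("5xFAD", "WT")

CYTOKINE_NAMES_23 = (
    "IL-1a", "IL-1b", "IL-2", "IL-3", "IL-4", "IL-5", "IL-6", "IL-9",
    "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-17A", "Eotaxin", "G-CSF",
    "GM-CSF", "IFN-g", "KC", "MCP-1", "MIP-1a", "MIP-1b", "RANTES", "TNF-a",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 10 subjects per genotype, four ages
    in months, 28 ROIs grouped into 7 anatomical systems, 4 scans of 300
    volumes at TR 1.5 s per subject and age, within/between-system target
    correlations 0.6 / 0.2, a -0.3 z-unit disease effect on the hippocampal
    and thalamic blocks at 4 and 6 months, subject random-intercept SD 0.1 z,
    23 cytokines with three planted analytes whose log-concentration climbs
    0.5 SD per month of age in the 5xFAD group, detection limits 1-10000
    pg/mL, and a 2% per-volume motion-spike probability (each spike censors
    itself plus two neighbours, so ~6% of volumes are discarded and the large
    majority of scans clear the 90% retention rule, as in a habituated awake
    imaging session).
    """

    n_subjects_per_group: int = 10
    ages: tuple[float, ...] = (1.5, 2.0, 4.0, 6.0)
    n_rois: int = 28
    n_systems: int = 7
    n_timepoints_per_scan: int = 300
    scans_per_subject: int = 4
    tr_seconds: float = 1.5
    within_system_r: float = 0.6
    between_system_r: float = 0.2
    genotype_effect: float = -0.3
    affected_systems: tuple[int, ...] = (3, 5)   # Hippocampus, Thalamus blocks
    affected_ages: tuple[float, ...] = (4.0, 6.0)
    subject_sd: float = 0.1
    n_cytokines: int = 23
    planted_analytes: tuple[int, ...] = (19, 20, 17)   # MIP-1a, MIP-1b, KC
    planted_age_slopes: tuple[float, ...] = (0.5, 0.5, 0.5)
    planted_genotype: str | None = "5xFAD"
    cytokine_log_sd: float = 1.0
    detection_floor: float = 1.0
    detection_ceiling: float = 10000.0
    spike_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "n_rois", "n_systems",
                     "n_timepoints_per_scan", "scans_per_subject",
                     "n_cytokines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("within_system_r", "between_system_r"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.detection_floor >= self.detection_ceiling:
            raise ValueError("detection_floor must be below detection_ceiling")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike_rate must lie in [0, 1]")
        if self.n_systems > self.n_rois:
            raise ValueError("cannot have more systems than ROIs")
        if len(self.planted_age_slopes) != len(self.planted_analytes):
            raise ValueError("planted_age_slopes must match planted_analytes")
        if any(a >= self.n_systems for a in self.affected_systems):
            raise ValueError("affected_systems index out of range")
        if any(a >= self.n_cytokines for a in self.planted_analytes):
            raise ValueError("planted_analytes index out of range")

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *salt])


def _system_labels(config: SynthConfig) -> list[str]:
    if config.n_systems == 7:
        return list(SEVEN_SYSTEMS)
    return [f"System{i + 1}" for i in range(config.n_systems)]


def _roi_assignment(config: SynthConfig) -> np.ndarray:
    """Contiguous block assignment of ROI index -> system index."""
    return np.concatenate([
        np.full(len(chunk), s, dtype=int)
        for s, chunk in enumerate(np.array_split(np.arange(config.n_rois),
                                                 config.n_systems))
    ])


def roi_names(config: SynthConfig) -> list[str]:
    return [f"ROI{i + 1:02d}" for i in range(config.n_rois)]


def make_system_definition(config: SynthConfig) -> SystemDefinition:
    labels = _system_labels(config)
    assign = _roi_assignment(config)
    names = roi_names(config)
    return SystemDefinition({
        lab: [names[i] for i in np.flatnonzero(assign == s)]
        for s, lab in enumerate(labels)
    })


def _nearest_pd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-definite correlation matrix."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-3:
        raise ValueError(
            f"block correlation target is structurally indefinite "
            f"(min eigenvalue {vals.min():.4g}); reduce |within/between r|")
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _target_correlation(config: SynthConfig, genotype: str, age: float,
                        subject_shift: float) -> np.ndarray:
    assign = _roi_assignment(config)
    same = assign[:, None] == assign[None, :]
    z = np.where(same, np.arctanh(config.within_system_r),
                 np.arctanh(config.between_system_r))
    if (genotype == "5xFAD" and age in config.affected_ages
            and config.genotype_effect != 0):
        for s in config.affected_systems:
            block = assign == s
            mask = np.outer(block, block)
            z = np.where(mask, z + config.genotype_effect, z)
    z = z + subject_shift
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return _nearest_pd(r)


def planted_block_mask(config: SynthConfig) -> np.ndarray:
    """Boolean edge mask (upper triangle meaningful) of the perturbed blocks."""
    assign = _roi_assignment(config)
    mask = np.zeros((config.n_rois, config.n_rois), dtype=bool)
    for s in config.affected_systems:
        block = assign == s
        mask |= np.outer(block, block)
    np.fill_diagonal(mask, False)
    return mask


def gen_scan_set(config: SynthConfig, ages: tuple[float, ...] | None = None
                 ) -> list[ScanTimeSeries]:
    """Draw every subject x age x scan ROI time series.

    Each scan samples a multivariate normal whose correlation matrix is the
    block target shifted, in z-space, by the disease effect (on affected
    blocks, affected ages, 5xFAD only) and by the subject's random intercept.
    """
    ages = config.ages if ages is None else ages
    names = roi_names(config)
    scans: list[ScanTimeSeries] = []
    for g_idx, genotype in enumerate(GENOTYPES):
        for s_idx in range(config.n_subjects_per_group):
            subject = f"{genotype}-{s_idx + 1:02d}"
            subj_rng = config.rng(1, g_idx, s_idx)
            shift = float(subj_rng.normal(0.0, config.subject_sd)) \
                if config.subject_sd > 0 else 0.0
            for age in ages:
                corr = _target_correlation(config, genotype, age, shift)
                L = np.linalg.cholesky(corr)
                for scan_idx in range(config.scans_per_subject):
                    draw_rng = config.rng(2, g_idx, s_idx,
                                          int(age * 10), scan_idx)
                    noise = draw_rng.standard_normal(
                        (config.n_rois, config.n_timepoints_per_scan))
                    data = L @ noise
                    scans.append(ScanTimeSeries(
                        data=data, roi_names=list(names),
                        tr=config.tr_seconds, subject_id=subject,
                        genotype=genotype, age_months=age,
                        scan_id=f"{subject}_m{age:g}_s{scan_idx + 1}"))
    return scans


def gen_motion_trace(config: SynthConfig,
                     n_volumes: int | None = None,
                     salt: int = 0) -> MotionTrace:
    """Baseline sub-threshold jitter with Bernoulli motion spikes.

    Baseline translations are uniform in +-0.01 mm and rotations in +-0.001
    rad, keeping displacement well below the 0.125 mm censor threshold; at
    spike volumes a large translation pushes displacement above threshold.
    Ground-truth spike indices are recorded on the trace.
    """
    n = config.n_timepoints_per_scan if n_volumes is None else n_volumes
    rng = config.rng(3, salt)
    translations = rng.uniform(-0.01, 0.01, size=(n, 3))
    rotations = rng.uniform(-0.001, 0.001, size=(n, 3))
    spikes = np.flatnonzero(rng.random(n) < config.spike_rate)
    for i in spikes:
        translations[i, 0] = rng.uniform(0.15, 0.5) * rng.choice([-1, 1])
    trace = MotionTrace(translations, rotations, spike_indices=spikes)
    assert config.spike_rate == 0 or len(spikes) == 0 or \
        trace.displacement[spikes].min() > SCRUB_THRESHOLD_MM
    return trace


def gen_cytokine_panel(config: SynthConfig,
                       n_subjects_per_genotype: int | None = None,
                       genotypes: tuple[str, ...] = GENOTYPES,
                       region: str = "parietal") -> CytokinePanel:
    """Log-normal cytokine concentrations with planted age-covarying analytes.

    Subjects are cross-sectional (one dissection age each), assigned to ages
    round-robin.  Log concentrations are analyte baseline + planted slope x
    age (for planted analytes in the planted genotype; both genotypes when
    ``planted_genotype`` is None) + N(0, cytokine_log_sd) noise.  Values
    outside the detection limits are flagged (not yet censored — that is the
    cleaning module's job).
    """
    rng = config.rng(4)
    n_per = (config.n_subjects_per_group * len(config.ages)
             if n_subjects_per_genotype is None else n_subjects_per_genotype)
    analytes = list(CYTOKINE_NAMES_23[:config.n_cytokines])
    if config.n_cytokines > len(CYTOKINE_NAMES_23):
        analytes += [f"Analyte{i + 1}" for i in
                     range(len(CYTOKINE_NAMES_23), config.n_cytokines)]
    baselines = rng.normal(np.log(50.0), 0.5, size=config.n_cytokines)
    slopes = np.zeros(config.n_cytokines)
    for idx, slope in zip(config.planted_analytes, config.planted_age_slopes):
        slopes[idx] = slope * config.cytokine_log_sd
    rows = []
    for genotype in genotypes:
        for s_idx in range(n_per):
            subject = f"{genotype}-C{s_idx + 1:02d}"
            age = config.ages[s_idx % len(config.ages)]
            planted_on = (config.planted_genotype is None
                          or genotype == config.planted_genotype)
            logc = (baselines
                    + (slopes * age if planted_on else 0.0)
                    + rng.normal(0.0, config.cytokine_log_sd,
                                 size=config.n_cytokines))
            conc = np.exp(logc)
            for a_idx, analyte in enumerate(analytes):
                rows.append({
                    "subject": subject, "genotype": genotype,
                    "age_months": age, "region": region, "analyte": analyte,
                    "concentration_pg_per_ml": float(conc[a_idx]),
                    "below_limit": bool(conc[a_idx] < config.detection_floor),
                    "above_limit": bool(conc[a_idx] > config.detection_ceiling),
                })
    limits = pd.DataFrame(
        {"lower_pg_ml": config.detection_floor,
         "upper_pg_ml": config.detection_ceiling},
        index=pd.Index(analytes, name="analyte"))
    planted = [analytes[i] for i in config.planted_analytes]
    return CytokinePanel(pd.DataFrame(rows), limits, planted)


def gen_toy_graph(name: str) -> ConnectivityMatrix:
    """Small fixed connectivity fixtures with known exact metric values.

    * ``triangle_unit`` — 3 nodes, all off-diagonal r = 1
    * ``star5``         — hub node 0 tied to 4 leaves at r = 0.5
    * ``path4``         — 4-node chain with unit weights
    * ``random5_seeded``— 5 nodes, symmetric weights in (0, 1), fixed seed
    """
    if name == "triangle_unit":
        r = np.ones((3, 3))
    elif name == "star5":
        r = np.eye(5)
        r[0, 1:] = r[1:, 0] = 0.5
    elif name == "path4":
        r = np.eye(4)
        for i in range(3):
            r[i, i + 1] = r[i + 1, i] = 1.0
    elif name == "random5_seeded":
        rng = np.random.default_rng(20230517)
        u = rng.uniform(0.05, 0.95, size=(5, 5))
        r = np.triu(u, 1)
        r = r + r.T
        np.fill_diagonal(r, 1.0)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    n = r.shape[0]
    return ConnectivityMatrix(r, [f"N{i}" for i in range(n)],
                              metadata={"fixture": name})


# ---------------------------------------------------------------------------
# file round-trip (plain-text formats)

def write_scan_set(scans: list[ScanTimeSeries], outdir: str | Path) -> Path:
    """One TSV (ROIs x time, ROI-name header column) per scan + manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for scan in scans:
        fname = f"{scan.scan_id}.tsv"
        df = pd.DataFrame(scan.data, index=scan.roi_names)
        df.to_csv(outdir / fname, sep="\t", header=False, float_format="%.10g")
        manifest.append({"subject": scan.subject_id, "genotype": scan.genotype,
                         "age_months": scan.age_months, "scan_id": scan.scan_id,
                         "tr": scan.tr, "file": fname})
    mpath = outdir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(mpath, index=False)
    return mpath


def read_scan_set(manifest_path: str | Path) -> list[ScanTimeSeries]:
    mpath = Path(manifest_path)
    manifest = pd.read_csv(mpath)
    scans = []
    for row in manifest.itertuples():
        df = pd.read_csv(mpath.parent / row.file, sep="\t", header=None,
                         index_col=0)
        scans.append(ScanTimeSeries(
            data=df.to_numpy(), roi_names=[str(i) for i in df.index],
            tr=float(row.tr), subject_id=str(row.subject),
            genotype=str(row.genotype), age_months=float(row.age_months),
            scan_id=str(row.scan_id)))
    return scans


def write_cytokine_panel(panel: CytokinePanel, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "cytokines.csv"
    panel.data.to_csv(path, index=False, float_format="%.10g")
    panel.limits.to_csv(outdir / "curve_limits.csv", float_format="%.10g")
    return path


def write_systems_json(systems: SystemDefinition, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(systems.systems, indent=2))
    return path
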