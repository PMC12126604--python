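"""Synthetic single-myofibre study generator with known ground truth.

Emulates both measurement channels of the dual single-fibre assay so every
pipeline stage can be exercised end-to-end without any download:

* MANT-ATP chase traces on the two-phase acquisition grid, generated from the
  double-exponential model with per-fibre (P1, T1, P2, T2) and Gaussian frame
  noise; in the generator the amplitudes are constrained to P1 + P2 = 1 so
  that DRX% = 100 - SRX% exactly.
* A fibre-level protein-group matrix: per-protein log2 baselines, additive
  participant random effects, MYH-isoform-driven subtypes, subtype-specific
  effect sizes on a planted effect set, and abundance-dependent logistic
  dropout (left-censoring-like, as in label-free DIA data).
* SRX percentages optionally coupled to standardised protein abundances with
  subtype-specific coefficients, enabling divergent (opposite-sign-by-
  subtype) couplings.
* "Disease" cohorts in which every subtype effect is attenuated by a factor
  lambda and the SRX distribution is homogenised (shifted and variance-
  scaled), with optional per-protein sign flips.

Default parameters follow the study conditions the pipeline is meant for:
8 control participants of ~11 fibres, a 1500-protein universe with dropout
tuned to roughly 780 detected proteins per fibre, control SRX spread
54.5 +- 32 %, and disease SRX regimes 38.4 +- 8.6 % / 33.0 +- 14.8 % with 3
participants per condition.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .decay import DecayTrace, build_timegrid, double_exponential
from .exceptions import InvalidParameterError
from .qc import ProteinMatrix

__all__ = [
    "UniverseConfig",
    "CohortConfig",
    "StudyConfig",
    "Universe",
    "SyntheticStudy",
    "draw_universe",
    "simulate_cohort",
    "simulate_srx_coupling",
    "simulate_traces",
    "simulate_disease_config",
    "simulate_study",
    "control_study_config",
    "disease_study_config",
    "write_study",
    "load_config",
    "save_config",
]

MYH_PROTEINS = {"MYH7": "P_MYH7", "MYH2": "P_MYH2", "MYH1": "P_MYH1"}

#: Mean MYH isoform mixture fractions (MYH7, MYH2, MYH1) per subtype.
SUBTYPE_MYH_FRACTIONS = {
    "I": (0.92, 0.06, 0.02),
    "I/IIa": (0.55, 0.43, 0.02),
    "IIa": (0.03, 0.93, 0.04),
    "IIx": (0.02, 0.08, 0.90),
}

#: Exposure of a fibre to the type-I-vs-IIa effect axis.
SUBTYPE_EFFECT_WEIGHT = {"I": 1.0, "I/IIa": 0.5, "IIa": 0.0, "IIx": 0.0}


@dataclass
class UniverseConfig:
    """Protein universe shared by every cohort of a study."""

    n_proteins: int = 1500
    baseline_mean: float = 14.0  # log2 LFQ
    baseline_sd: float = 2.0
    tau_min: float = 0.2  # per-protein fibre-to-fibre SD (log2)
    tau_max: float = 0.6
    n_effect_proteins: int = 100
    effect_size: float = 1.5  # |delta| log2, type I vs type IIa
    n_core_proteins: int = 200  # abundant proteins detected in every fibre
    myh_base_log2: float = 17.0
    myh_noise_sd: float = 0.3  # fibre-to-fibre SD of total MYH intensity (log2)
    myh_iso_noise_sd: float = 0.15  # per-isoform measurement SD (log2)
    myh_dirichlet_conc: float = 300.0


@dataclass
class CohortConfig:
    """One condition's fibre cohort."""

    condition: str = "control"
    participant_prefix: str = "C"
    n_participants: int = 8
    fibres_per_participant: int = 11
    subtype_probs: dict = field(
        default_factory=lambda: {"I": 0.45, "I/IIa": 0.10, "IIa": 0.45}
    )
    participant_sd: float = 0.3
    dropout: bool = True
    dropout_midpoint: float = 14.5  # log2 intensity of 50% detection
    dropout_slope: float = 1.5
    srx_base: float = 54.5
    srx_noise_sd: float = 32.0
    effect_attenuation: float = 1.0  # lambda in [0, 1]
    sign_flip_proteins: list = field(default_factory=list)
    t1_mean: float = 2.0
    t1_sd: float = 0.4
    t2_mean: float = 150.0
    t2_sd: float = 25.0
    trace_sigma: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_attenuation <= 1.0):
            raise InvalidParameterError("effect_attenuation must lie in [0, 1]")
        if self.trace_sigma < 0:
            raise ValueError("trace_sigma must be non-negative")
        total = sum(self.subtype_probs.values())
        if not np.isclose(total, 1.0):
            raise InvalidParameterError("subtype_probs must sum to 1")


@dataclass
class StudyConfig:
    """Universe + cohorts + phenotype couplings + acquisition grid."""

    universe: UniverseConfig = field(default_factory=UniverseConfig)
    cohorts: list = field(default_factory=lambda: [CohortConfig()])
    #: protein id -> {subtype or "all": beta}; beta in SRX percentage points
    #: per SD of the protein's log2 abundance.
    couplings: dict = field(default_factory=dict)
    grid_step_early: float = 5.0
    grid_early_end: float = 90.0
    grid_step_late: float = 10.0
    grid_total_end: float = 390.0

    def timegrid(self) -> np.ndarray:
        return build_timegrid(
            self.grid_step_early,
            self.grid_early_end,
            self.grid_step_late,
            self.grid_total_end,
        )


@dataclass
class Universe:
    """Drawn protein-level ground truth (shared across cohorts)."""

    proteins: pd.Index
    genes: pd.Series
    mu: pd.Series  # baseline log2
    tau: pd.Series  # per-protein SD
    effects: pd.Series  # delta per effect protein (log2, type I minus IIa)
    core: pd.Index  # dropout-exempt (always-detected) proteins


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes plus the generating truth."""

    matrix: ProteinMatrix  # raw-scale, with dropout
    complete_log2: pd.DataFrame  # pre-dropout log2 values (truth)
    traces: list
    fibre_truth: pd.DataFrame  # per fibre: participant, condition, subtype, srx...
    universe: Universe
    config: StudyConfig


def draw_universe(config: StudyConfig, rng: np.random.Generator) -> Universe:
    uc = config.universe
    ids = [f"P{i + 1:05d}" for i in range(uc.n_proteins)]
    gene_names = [f"GENE{i + 1:04d}" for i in range(uc.n_proteins)]
    proteins = pd.Index(ids + list(MYH_PROTEINS.values()), name="protein")
    genes = pd.Series(gene_names + list(MYH_PROTEINS), index=proteins, name="gene")
    mu = pd.Series(
        np.concatenate(
            [
                rng.normal(uc.baseline_mean, uc.baseline_sd, uc.n_proteins),
                np.full(3, uc.myh_base_log2),
            ]
        ),
        index=proteins,
        name="mu",
    )
    tau = pd.Series(
        np.concatenate(
            [
                rng.uniform(uc.tau_min, uc.tau_max, uc.n_proteins),
                np.full(3, uc.myh_noise_sd),
            ]
        ),
        index=proteins,
        name="tau",
    )
    chosen = rng.choice(uc.n_proteins, size=uc.n_effect_proteins, replace=False)
    signs = np.where(np.arange(uc.n_effect_proteins) % 2 == 0, 1.0, -1.0)
    effects = pd.Series(
        uc.effect_size * signs,
        index=pd.Index([ids[i] for i in np.sort(chosen)], name="protein"),
        name="delta",
    )
    core_idx = rng.choice(uc.n_proteins, size=uc.n_core_proteins, replace=False)
    core = pd.Index([ids[i] for i in np.sort(core_idx)], name="protein")
    return Universe(
        proteins=proteins, genes=genes, mu=mu, tau=tau, effects=effects, core=core
    )


def _simulate_one_cohort(
    cohort: CohortConfig,
    universe: Universe,
    uc: UniverseConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete (pre-dropout) log2 matrix and per-fibre annotation truth."""
    labels = list(cohort.subtype_probs)
    probs = np.array([cohort.subtype_probs[k] for k in labels])
    fibre_rows = []
    cols = {}
    n_p = len(universe.proteins)
    delta = universe.effects.reindex(universe.proteins).fillna(0.0).to_numpy()
    flip = np.isin(universe.proteins, list(cohort.sign_flip_proteins))
    delta_eff = cohort.effect_attenuation * delta * np.where(flip, -1.0, 1.0)
    myh_pos = [universe.proteins.get_loc(p) for p in MYH_PROTEINS.values()]
    for i in range(cohort.n_participants):
        participant = f"{cohort.participant_prefix}{i + 1}"
        b_part = rng.normal(0.0, cohort.participant_sd)
        for j in range(cohort.fibres_per_participant):
            fibre_id = f"{participant}_f{j + 1:02d}"
            subtype = labels[rng.choice(len(labels), p=probs)]
            w = SUBTYPE_EFFECT_WEIGHT[subtype]
            values = (
                universe.mu.to_numpy()
                + b_part
                + w * delta_eff
                + rng.normal(0.0, universe.tau.to_numpy(), n_p)
            )
            # MYH rows follow the subtype's isoform mixture on the raw scale
            base_fr = np.array(SUBTYPE_MYH_FRACTIONS[subtype])
            conc = uc.myh_dirichlet_conc * np.clip(base_fr, 1e-3, None)
            fractions = rng.dirichlet(conc)
            myh_total = 2.0 ** (
                universe.mu.iloc[myh_pos[0]]
                + b_part
                + rng.normal(0.0, universe.tau.iloc[myh_pos[0]])
            )
            iso_noise = rng.normal(0.0, uc.myh_iso_noise_sd, 3)
            for pos, fr, eps in zip(myh_pos, fractions, iso_noise):
                values[pos] = (
                    np.log2(fr * myh_total) + eps if fr > 1e-12 else -np.inf
                )
            cols[fibre_id] = values
            fibre_rows.append(
                {
                    "fibre_id": fibre_id,
                    "participant": participant,
                    "condition": cohort.condition,
                    "subtype": subtype,
                    "rel7_true": fractions[0],
                    "rel2_true": fractions[1],
                    "rel1_true": fractions[2],
                }
            )
    log2 = pd.DataFrame(cols, index=universe.proteins)
    log2 = log2.replace(-np.inf, np.nan)
    truth = pd.DataFrame(fibre_rows).set_index("fibre_id")
    return log2, truth


def _apply_dropout(
    log2: pd.DataFrame,
    cohort: CohortConfig,
    rng: np.random.Generator,
    core: pd.Index | None = None,
    extra_exempt: tuple = (),
) -> pd.DataFrame:
    """Abundance-dependent missingness: P(observed) = logistic((v - m)/s).

    Proteins in ``core`` model the very abundant sarcomeric/housekeeping set
    seen in every run and are exempt from dropout, as are the MYH isoform
    rows and any SRX-coupled proteins (a phenotype can only be coupled to a
    protein the assay actually measures).
    """
    if not cohort.dropout:
        return log2.copy()
    v = log2.to_numpy()
    if cohort.dropout_slope == 0:
        prob = (v > cohort.dropout_midpoint).astype(float)
    else:
        from scipy.special import expit

        prob = expit((v - cohort.dropout_midpoint) / cohort.dropout_slope)
    keep = rng.random(v.shape) < prob
    exempt = list(core) if core is not None else []
    exempt += [p for p in MYH_PROTEINS.values() if p in log2.index]
    exempt += [p for p in extra_exempt if p in log2.index]
    if exempt:
        keep[log2.index.get_indexer(pd.Index(exempt).unique())] = True
    return log2.where(keep)


def simulate_srx_coupling(
    complete_log2: pd.DataFrame,
    subtypes: pd.Series,
    couplings: Mapping[str, Mapping[str, float]],
    base_mean: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.Series:
    """SRX% per fibre, optionally coupled to standardised protein abundance.

    srx = clip(base_mean + sum_p beta[p][scope(fibre)] * z_p(fibre)
               + Normal(0, noise_sd), 0, 100)

    where z_p is the protein's log2 value standardised across the cohort and
    the scope key is the fibre's subtype, falling back to "all".
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    fibres = complete_log2.columns
    srx = np.full(len(fibres), float(base_mean))
    for protein, betas in couplings.items():
        vals = complete_log2.loc[protein]
        z = (vals - vals.mean()) / vals.std(ddof=0)
        for i, f in enumerate(fibres):
            beta = betas.get(subtypes[f], betas.get("all", 0.0))
            srx[i] += beta * z[f]
    srx = srx + rng.normal(0.0, noise_sd, len(fibres)) if noise_sd > 0 else srx
    return pd.Series(np.clip(srx, 0.0, 100.0), index=fibres, name="srx_true")


def simulate_traces(
    params: pd.DataFrame,
    grid: np.ndarray,
    rng: np.random.Generator,
    sigma: float | None = None,
    roi_amplitude: float = 1000.0,
    roi_background: float = 50.0,
) -> list:
    """Noisy double-exponential traces from a per-fibre parameter table.

    ``params`` is indexed by fibre id with columns P1, T1, P2, T2 and
    (unless ``sigma`` overrides it) ``sigma``.  The noisy series is
    re-anchored so the t=0 frame equals 1, and raw ROI/background columns are
    synthesised so that re-normalising them reproduces the series exactly.
    """
    traces = []
    for fibre_id, row in params.iterrows():
        s = float(row["sigma"]) if sigma is None else float(sigma)
        if s < 0:
            raise ValueError("sigma must be non-negative")
        y = double_exponential(grid, row["P1"], row["T1"], row["P2"], row["T2"])
        if s > 0:
            y = y + rng.normal(0.0, s, y.size)
        y = y / y[0]
        roi = np.column_stack(
            [
                roi_background + roi_amplitude * y * 1.05,
                roi_background + roi_amplitude * y * 0.95,
                roi_background + roi_amplitude * y,
            ]
        )
        traces.append(
            DecayTrace(
                fibre_id=str(fibre_id),
                times=grid,
                normalised=y,
                roi_means=roi,
                background=np.full(y.size, roi_background),
            )
        )
    return traces


def simulate_cohort(
    cohort: CohortConfig,
    universe: Universe,
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """One cohort: pre-dropout log2 matrix, fibre truth, SRX truth."""
    if cohort.n_participants < 1 or cohort.fibres_per_participant < 1:
        raise ValueError("cohort must have participants and fibres")
    log2, truth = _simulate_one_cohort(cohort, universe, config.universe, rng)
    srx = simulate_srx_coupling(
        log2,
        truth["subtype"],
        config.couplings,
        cohort.srx_base,
        cohort.srx_noise_sd,
        rng,
    )
    truth = truth.assign(srx_true=srx)
    truth["drx_true"] = 100.0 - truth["srx_true"]
    truth["P2"] = truth["srx_true"] / 100.0
    truth["P1"] = 1.0 - truth["P2"]
    truth["T1"] = np.clip(
        rng.normal(cohort.t1_mean, cohort.t1_sd, len(truth)), 0.5, None
    )
    truth["T2"] = np.clip(
        rng.normal(cohort.t2_mean, cohort.t2_sd, len(truth)), 20.0, None
    )
    truth["sigma"] = cohort.trace_sigma
    return log2, truth, srx


def simulate_study(config: StudyConfig, seed: int) -> SyntheticStudy:
    """Generate all cohorts of a study under one master seed."""
    master = np.random.SeedSequence(seed)
    universe_rng = np.random.default_rng(master.spawn(1)[0])
    universe = draw_universe(config, universe_rng)
    log2_blocks, truth_blocks, dropped_blocks, traces = [], [], [], []
    for cohort, child in zip(
        config.cohorts, master.spawn(len(config.cohorts) + 1)[1:]
    ):
        c1, c2, c3 = child.spawn(3)
        rng = np.random.default_rng(c1)
        log2, truth, _srx = simulate_cohort(cohort, universe, config, rng)
        dropped = _apply_dropout(
            log2,
            cohort,
            np.random.default_rng(c2),
            core=universe.core,
            extra_exempt=tuple(config.couplings),
        )
        traces.extend(
            simulate_traces(
                truth[["P1", "T1", "P2", "T2", "sigma"]],
                config.timegrid(),
                np.random.default_rng(c3),
            )
        )
        log2_blocks.append(log2)
        truth_blocks.append(truth)
        dropped_blocks.append(dropped)
    complete = pd.concat(log2_blocks, axis=1)
    dropped = pd.concat(dropped_blocks, axis=1)
    fibre_truth = pd.concat(truth_blocks, axis=0)
    annotations = fibre_truth[["participant", "condition"]].copy()
    matrix = ProteinMatrix(
        values=2.0**dropped,
        annotations=annotations,
        genes=universe.genes,
        scale="raw",
    )
    return SyntheticStudy(
        matrix=matrix,
        complete_log2=complete,
        traces=traces,
        fibre_truth=fibre_truth,
        universe=universe,
        config=config,
    )


def simulate_disease_config(
    control: CohortConfig,
    condition: str,
    participant_prefix: str,
    effect_attenuation: float,
    srx_shift: float = 0.0,
    srx_scale: float = 1.0,
    subtype_probs: dict | None = None,
    sign_flip_proteins: Sequence[str] = (),
    n_participants: int = 3,
    fibres_per_participant: int = 10,
) -> CohortConfig:
    """Disease cohort derived from a control cohort.

    Every planted subtype effect is multiplied by ``effect_attenuation``
    (lambda), the SRX distribution is shifted by ``srx_shift`` percentage
    points and its spread scaled by ``srx_scale``, and the subtype
    composition can be skewed (type-I-enriched for an ACTA1-like cohort,
    type-IIa-enriched for a TNNT1-like one).
    """
    if not (0.0 <= effect_attenuation <= 1.0):
        raise InvalidParameterError("effect_attenuation must lie in [0, 1]")
    return replace(
        control,
        condition=condition,
        participant_prefix=participant_prefix,
        n_participants=n_participants,
        fibres_per_participant=fibres_per_participant,
        subtype_probs=dict(subtype_probs or control.subtype_probs),
        srx_base=control.srx_base + srx_shift,
        srx_noise_sd=control.srx_noise_sd * srx_scale,
        effect_attenuation=effect_attenuation,
        sign_flip_proteins=list(sign_flip_proteins),
    )


def control_study_config(**overrides) -> StudyConfig:
    """Healthy-control study at the default conditions."""
    cfg = StudyConfig()
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def disease_study_config(
    effect_attenuation: float = 0.3,
    sign_flip_proteins: Sequence[str] = (),
) -> StudyConfig:
    """Control + two nemaline-myopathy-like cohorts.

    The ACTA1-like cohort is type-I-enriched with SRX 38.4 +- 8.6 %; the
    TNNT1-like cohort is type-IIa-enriched with SRX 33.0 +- 14.8 %.
    """
    control = CohortConfig()
    acta1 = simulate_disease_config(
        control,
        condition="ACTA1",
        participant_prefix="A",
        effect_attenuation=effect_attenuation,
        srx_shift=38.4 - control.srx_base,
        srx_scale=8.6 / control.srx_noise_sd,
        subtype_probs={"I": 0.80, "I/IIa": 0.10, "IIa": 0.10},
        sign_flip_proteins=sign_flip_proteins,
    )
    tnnt1 = simulate_disease_config(
        control,
        condition="TNNT1",
        participant_prefix="T",
        effect_attenuation=effect_attenuation,
        srx_shift=33.0 - control.srx_base,
        srx_scale=14.8 / control.srx_noise_sd,
        subtype_probs={"I": 0.10, "I/IIa": 0.10, "IIa": 0.80},
        sign_flip_proteins=sign_flip_proteins,
    )
    return StudyConfig(cohorts=[control, acta1, tnnt1])


# ---------------------------------------------------------------------------
# configuration and file round-trips


def save_config(config: StudyConfig, path) -> None:
    payload = {
        "universe": asdict(config.universe),
        "cohorts": [asdict(c) for c in config.cohorts],
        "couplings": config.couplings,
        "grid_step_early": config.grid_step_early,
        "grid_early_end": config.grid_early_end,
        "grid_step_late": config.grid_step_late,
        "grid_total_end": config.grid_total_end,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return StudyConfig(
        universe=UniverseConfig(**payload.get("universe", {})),
        cohorts=[CohortConfig(**c) for c in payload.get("cohorts", [{}])],
        couplings=payload.get("couplings", {}),
        grid_step_early=payload.get("grid_step_early", 5.0),
        grid_early_end=payload.get("grid_early_end", 90.0),
        grid_step_late=payload.get("grid_step_late", 10.0),
        grid_total_end=payload.get("grid_total_end", 390.0),
    )


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write traces CSV, PG-matrix TSV, annotation CSV and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": outdir / "traces.csv",
        "pg_matrix": outdir / "pg_matrix.tsv",
        "annotations": outdir / "annotations.csv",
        "fibre_truth": outdir / "truth_fibres.tsv",
        "effect_truth": outdir / "truth_effects.tsv",
        "config": outdir / "config.yaml",
    }
    frames = []
    for tr in study.traces:
        frames.append(
            pd.DataFrame(
                {
                    "fibre_id": tr.fibre_id,
                    "time_s": tr.times,
                    "roi1": tr.roi_means[:, 0],
                    "roi2": tr.roi_means[:, 1],
                    "roi3": tr.roi_means[:, 2],
                    "background": tr.background,
                }
            )
        )
    pd.concat(frames).to_csv(paths["traces"], index=False)
    pg = study.matrix.values.copy()
    pg.insert(0, "Genes", study.matrix.genes)
    pg.insert(0, "Protein.Group", pg.index)
    pg.to_csv(paths["pg_matrix"], sep="\t", index=False)
    study.matrix.annotations.reset_index(names="fibre_id").to_csv(
        paths["annotations"], index=False
    )
    study.fibre_truth.reset_index().to_csv(
        paths["fibre_truth"], sep="\t", index=False
    )
    study.universe.effects.reset_index().to_csv(
        paths["effect_truth"], sep="\t", index=False
    )
    save_config(study.config, paths["config"])
    return paths
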