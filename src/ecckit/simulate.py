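"""Synthetic cohort generator.

Emulates the study design the downstream analyses assume: a toy genome with
gene models, enhancer/DHS/CpG tracks and a seven-class repeat table; per
sample, a Circle-Map-style eccDNA candidate table; a tumor/normal cohort
(defaults 81 / 33); and disease-free-survival outcomes for the tumor arm
drawn from an exponential proportional-hazards model with planted
per-feature log-hazard ratios.

Tumor eccDNA lengths follow a two-component log-normal mixture with modes
near 180 and 360 bp; normals a single shorter mode. Tumor placement weights
carry multiplicative uplifts on regulatory and repeat categories, planting
the group-wise proportion differences the comparisons are meant to detect.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation, features, filters
from .io_formats import (
    CANDIDATE_COLUMNS,
    GenomeLayout,
    write_candidate_table,
    write_clinical_table,
    write_genome_layout,
)

__all__ = [
    "LengthMixture",
    "SurvivalConfig",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genome_and_tracks",
    "simulate_sample",
    "simulate_survival",
    "simulate_cohort",
    "cohort_feature_matrix",
    "write_cohort",
]

MIN_CHROM_LENGTH = 50_000

#: Placement categories the candidate sampler draws from. "background"
#: means uniform placement anywhere on the genome.
PLACEMENT_CATEGORIES = (
    "background", "gene", "exon", "enhancer", "dhs", "cpg_island",
    "sine", "line", "ltr", "dna_repeat", "simple_repeat",
    "low_complexity", "satellite",
)

DEFAULT_CATEGORY_WEIGHTS = {
    "background": 0.30, "gene": 0.25, "exon": 0.04, "enhancer": 0.03,
    "dhs": 0.04, "cpg_island": 0.03, "sine": 0.10, "line": 0.08,
    "ltr": 0.04, "dna_repeat": 0.03, "simple_repeat": 0.03,
    "low_complexity": 0.02, "satellite": 0.01,
}

#: Tumor-vs-normal multiplicative uplifts on placement weights, in the
#: direction of the observed group differences (regulatory elements and
#: most repeat classes up in tumors; satellite flat).
DEFAULT_TUMOR_MULTIPLIERS = {
    "background": 1.0, "gene": 1.1, "exon": 1.5, "enhancer": 1.8,
    "dhs": 1.7, "cpg_island": 1.6, "sine": 1.3, "line": 1.4,
    "ltr": 1.5, "dna_repeat": 1.4, "simple_repeat": 1.4,
    "low_complexity": 1.4, "satellite": 1.0,
}


@dataclass(frozen=True)
class LengthMixture:
    """Log-normal mixture over eccDNA lengths, parameterized by modes."""

    weights: tuple[float, ...]
    modes_bp: tuple[float, ...]
    sigmas: tuple[float, ...]

    def __post_init__(self):
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if len({len(self.weights), len(self.modes_bp), len(self.sigmas)}) != 1:
            raise ValueError("mixture component lists must have equal length")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=list(self.weights))
        mode = np.asarray(self.modes_bp)[comp]
        sigma = np.asarray(self.sigmas)[comp]
        # lognormal mode = exp(mu - sigma^2)  =>  mu = ln(mode) + sigma^2
        mu = np.log(mode) + sigma**2
        return np.exp(rng.normal(mu, sigma))


TUMOR_LENGTHS = LengthMixture((0.55, 0.45), (180.0, 360.0), (0.12, 0.12))
NORMAL_LENGTHS = LengthMixture((1.0,), (150.0,), (0.35,))


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential proportional-hazards outcome model for the tumor arm."""

    baseline_hazard: float = 0.0022        # events / month at eta = 0
    log_hr: Mapping[str, float] = field(
        default_factory=lambda: {"intron_proportion": 0.7, "repeat_all_proportion": 0.7}
    )
    horizon_months: float = 60.0           # administrative censoring
    random_censoring_rate: float = 0.001   # extra feature-independent censoring
    lost_to_followup: float = 0.12         # fraction with missing DFS fields


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 3
    chrom_length_bp: int = 1_000_000
    n_tumor: int = 81
    n_normal: int = 33
    ecc_per_sample: float = 300.0
    min_length_bp: int = 50
    tumor_lengths: LengthMixture = TUMOR_LENGTHS
    normal_lengths: LengthMixture = NORMAL_LENGTHS
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    tumor_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_MULTIPLIERS)
    )
    pass_fraction: float = 0.9
    mapped_reads_range: tuple[int, int] = (2_000_000, 20_000_000)
    survival: SurvivalConfig = SurvivalConfig()

    def __post_init__(self):
        if self.chrom_length_bp < MIN_CHROM_LENGTH:
            raise ValueError(
                f"chromosome too short to place requested tracks "
                f"(need >= {MIN_CHROM_LENGTH} bp)"
            )
        if not np.isclose(sum(self.category_weights.values()), 1.0):
            raise ValueError("category_weights must sum to 1")
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction outside [0, 1]")

    @staticmethod
    def null(**overrides) -> "SimulationConfig":
        """Effect-free configuration: identical group parameters, no planted
        hazards — for calibration and type-I-error checks."""
        base = dict(
            tumor_lengths=NORMAL_LENGTHS,
            tumor_multipliers={c: 1.0 for c in PLACEMENT_CATEGORIES},
            survival=SurvivalConfig(log_hr={}),
        )
        base.update(overrides)
        return SimulationConfig(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category_weights"] = dict(self.category_weights)
        d["tumor_multipliers"] = dict(self.tumor_multipliers)
        d["survival"]["log_hr"] = dict(self.survival.log_hr)
        return d


@dataclass
class SyntheticCohort:
    layout: GenomeLayout
    tracks: dict[str, pd.DataFrame]
    samples: dict[str, pd.DataFrame]   # candidate tables incl. simulated_pass
    clinical: pd.DataFrame
    truth: dict
    config: SimulationConfig

    def build_catalog(self) -> dict[str, annotation.IntervalSet]:
        t = self.tracks
        return annotation.build_catalog(
            t["gene_model"], t["enhancer"], t["dhs"], t["cpg_island"],
            t["repeats"], self.layout,
        )


# ---------------------------------------------------------------------------
# Genome and tracks


def _place_uniform(rng, L: int, n: int, min_len: int, max_len: int):
    lengths = rng.integers(min_len, max_len + 1, size=n)
    starts = rng.integers(0, np.maximum(1, L - lengths), size=n)
    return starts, starts + lengths


def _make_gene_rows(rng, chrom: str, L: int) -> list[tuple]:
    rows = []
    pos, gi = 0, 0
    while True:
        pos += int(rng.exponential(12_000)) + 500
        g_len = int(rng.integers(2_000, 15_001))
        if pos + g_len >= L:
            break
        gi += 1
        s, e = pos, pos + g_len
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"{chrom}_g{gi}"
        rows.append((chrom, s, e, name, strand, "gene"))
        # alternate exon/intron segments spanning the gene body
        n_ex = int(rng.integers(2, 7))
        w = rng.gamma(2.0, 1.0, size=2 * n_ex - 1)
        bounds = np.concatenate([[0], np.cumsum(w / w.sum() * g_len)]).astype(int) + s
        bounds[-1] = e
        for k in range(2 * n_ex - 1):
            seg_s, seg_e = int(bounds[k]), int(bounds[k + 1])
            if seg_e <= seg_s:
                continue
            feat = "exon" if k % 2 == 0 else "intron"
            rows.append((chrom, seg_s, seg_e, name, strand, feat))
        utr5_len, utr3_len = int(rng.integers(100, 301)), int(rng.integers(150, 401))
        if strand == "+":
            rows.append((chrom, s, min(s + utr5_len, e), name, strand, "utr5"))
            rows.append((chrom, max(s, e - utr3_len), e, name, strand, "utr3"))
        else:
            rows.append((chrom, max(s, e - utr5_len), e, name, strand, "utr5"))
            rows.append((chrom, s, min(s + utr3_len, e), name, strand, "utr3"))
        pos = e
    return rows


_REPEAT_CLASS_PROBS = {
    "SINE": 0.45, "LINE": 0.20, "LTR": 0.12, "DNA": 0.10,
    "Simple_repeat": 0.06, "Low_complexity": 0.04, "Satellite": 0.03,
}
_REPEAT_LEN_RANGES = {
    "SINE": (120, 330), "LINE": (500, 6000), "LTR": (300, 5000),
    "DNA": (200, 2000), "Simple_repeat": (50, 500),
    "Low_complexity": (50, 300), "Satellite": (500, 5000),
}


def simulate_genome_and_tracks(config: SimulationConfig):
    """Build the toy genome layout and all annotation input tracks."""
    ss = np.random.SeedSequence([config.seed, 0x7AC5])
    rng = np.random.default_rng(ss)
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    layout = GenomeLayout(names, {n: config.chrom_length_bp for n in names})

    gene_rows: list[tuple] = []
    bed_rows = {"enhancer": [], "dhs": [], "cpg_island": []}
    repeat_rows: list[tuple] = []
    per_mb_counts = {"enhancer": 60, "dhs": 80, "cpg_island": 50}
    bed_lens = {"enhancer": (200, 2000), "dhs": (150, 1000), "cpg_island": (200, 1500)}

    for chrom in names:
        L = layout.length(chrom)
        mb = L / 1e6
        gene_rows.extend(_make_gene_rows(rng, chrom, L))
        for track, per_mb in per_mb_counts.items():
            n = max(1, int(round(per_mb * mb)))
            lo, hi = bed_lens[track]
            s, e = _place_uniform(rng, L, n, lo, hi)
            bed_rows[track].extend(
                (chrom, int(a), int(b), f"{track}_{chrom}_{i}") for i, (a, b) in enumerate(zip(s, e))
            )
        n_rep = max(7, int(round(300 * mb)))
        classes = rng.choice(
            list(_REPEAT_CLASS_PROBS), size=n_rep, p=list(_REPEAT_CLASS_PROBS.values())
        )
        for i, cls in enumerate(classes):
            lo, hi = _REPEAT_LEN_RANGES[cls]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, L - length)))
            if cls == "SINE":
                u = rng.random()
                fam = "Alu" if u < 0.70 else ("MIR" if u < 0.95 else "tRNA")
            else:
                fam = cls
            repeat_rows.append((chrom, start, start + length, f"{fam}_{chrom}_{i}", cls, fam))

    # guarantee every repeat class appears at least once
    present = {r[4] for r in repeat_rows}
    for cls in _REPEAT_CLASS_PROBS:
        if cls not in present:
            lo, hi = _REPEAT_LEN_RANGES[cls]
            start = int(rng.integers(0, config.chrom_length_bp - hi))
            fam = "Alu" if cls == "SINE" else cls
            repeat_rows.append((names[0], start, start + lo, f"{fam}_fill", cls, fam))

    tracks = {
        "gene_model": pd.DataFrame(
            gene_rows, columns=["chrom", "start", "end", "name", "strand", "feature"]
        ),
        "repeats": pd.DataFrame(
            repeat_rows,
            columns=["chrom", "start", "end", "repName", "repClass", "repFamily"],
        ),
    }
    for track, rows in bed_rows.items():
        tracks[track] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return layout, tracks


# ---------------------------------------------------------------------------
# Per-sample candidate tables


def _placement_index(tracks: dict[str, pd.DataFrame], layout: GenomeLayout):
    """Per placement category: arrays of (chrom, start, end) to drop circles on."""
    sources = {
        "gene": tracks["gene_model"].query("feature == 'gene'"),
        "exon": tracks["gene_model"].query("feature == 'exon'"),
        "enhancer": tracks["enhancer"],
        "dhs": tracks["dhs"],
        "cpg_island": tracks["cpg_island"],
    }
    for cls, cat in annotation.REPEAT_CLASS_MAP.items():
        sources[cat] = tracks["repeats"].query(f"repClass == '{cls}'")
    index = {}
    for cat, frame in sources.items():
        if len(frame) == 0:
            continue
        index[cat] = (
            frame["chrom"].to_numpy(dtype=object),
            frame["start"].to_numpy(dtype=np.int64),
            frame["end"].to_numpy(dtype=np.int64),
        )
    return index


def _group_weights(config: SimulationConfig, group: str) -> np.ndarray:
    w = np.array([config.category_weights.get(c, 0.0) for c in PLACEMENT_CATEGORIES])
    if group == "tumor":
        m = np.array([config.tumor_multipliers.get(c, 1.0) for c in PLACEMENT_CATEGORIES])
        w = w * m
    return w / w.sum()


def simulate_sample(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    layout: GenomeLayout,
    placement: dict,
):
    """Draw one sample's candidate table and its mapped-read count.

    Returns a candidate frame carrying an extra boolean ``simulated_pass``
    truth column: candidates generated to fail were given support/coverage
    fields violating exactly one acceptance criterion.
    """
    if group not in ("tumor", "normal"):
        raise ValueError(f"group must be 'tumor' or 'normal', got {group!r}")
    n = max(1, int(rng.poisson(config.ecc_per_sample)))
    mixture = config.tumor_lengths if group == "tumor" else config.normal_lengths
    lengths = np.clip(
        np.round(mixture.sample(n, rng)).astype(np.int64),
        config.min_length_bp,
        config.chrom_length_bp // 2,
    )

    probs = _group_weights(config, group)
    cat_ids = rng.choice(len(PLACEMENT_CATEGORIES), size=n, p=probs)

    chrom_arr = np.empty(n, dtype=object)
    start_arr = np.zeros(n, dtype=np.int64)
    chrom_names = np.asarray(layout.names, dtype=object)
    chrom_lens = np.asarray([layout.length(c) for c in layout.names], dtype=np.int64)
    chrom_probs = chrom_lens / chrom_lens.sum()

    for ci, cat in enumerate(PLACEMENT_CATEGORIES):
        sel = np.flatnonzero(cat_ids == ci)
        if sel.size == 0:
            continue
        if cat == "background" or cat not in placement:
            ch_idx = rng.choice(len(chrom_names), size=sel.size, p=chrom_probs)
            chrom_arr[sel] = chrom_names[ch_idx]
            span = np.maximum(1, chrom_lens[ch_idx] - lengths[sel])
            start_arr[sel] = (rng.random(sel.size) * span).astype(np.int64)
            continue
        ivc, ivs, ive = placement[cat]
        j = rng.integers(0, len(ivs), size=sel.size)
        chrom_arr[sel] = ivc[j]
        L = np.asarray([layout.length(c) for c in ivc[j]], dtype=np.int64)
        # start range guaranteeing >= 1 bp overlap with the chosen interval
        lo = np.maximum(0, ivs[j] - lengths[sel] + 1)
        hi = np.minimum(ive[j] - 1, L - lengths[sel])
        bad = hi < lo
        start = lo + (rng.random(sel.size) * (hi - lo + 1)).astype(np.int64)
        start[bad] = np.clip(ivs[j][bad], 0, np.maximum(0, L[bad] - lengths[sel][bad]))
        start_arr[sel] = start

    # read support and coverage statistics
    pass_mask = rng.random(n) < config.pass_fraction
    split = 2 + rng.poisson(2.0, n)
    disc = 1 + rng.poisson(1.5, n)
    score = 50.0 + rng.gamma(2.0, 25.0, n)
    mean_cov = rng.gamma(3.0, 5.0, n) + 1.0
    sd_cov = mean_cov * 0.3
    sdr = rng.uniform(0.40, 0.95, n)
    edr = rng.uniform(0.40, 0.95, n)
    unc = rng.uniform(0.0, 0.08, n)

    fail_idx = np.flatnonzero(~pass_mask)
    violated = rng.integers(0, 5, size=fail_idx.size)
    for k, i in enumerate(fail_idx):
        v = violated[k]
        if v == 0:
            split[i] = rng.integers(0, 2)
        elif v == 1:
            split[i], disc[i] = 2, 0
        elif v == 2:
            score[i] = rng.uniform(0.0, 49.9)
        elif v == 3:
            sdr[i] = rng.uniform(0.0, 0.33)
        else:
            unc[i] = rng.uniform(0.10, 0.50)

    frame = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": start_arr,
            "end": start_arr + lengths,
            "discordant_reads": disc.astype(np.int64),
            "split_reads": split.astype(np.int64),
            "score": score,
            "mean_coverage": mean_cov,
            "sd_coverage": sd_cov,
            "start_depth_ratio": sdr,
            "end_depth_ratio": edr,
            "uncovered_fraction": unc,
            "simulated_pass": pass_mask,
        }
    )
    frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    lo, hi = config.mapped_reads_range
    mapped_reads = int(rng.integers(lo, hi))
    return frame, mapped_reads


# ---------------------------------------------------------------------------
# Survival outcomes


def simulate_survival(
    feature_matrix: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    standardize: bool = True,
) -> pd.DataFrame:
    """Draw DFS outcomes for tumor samples from an exponential PH model.

    Hazard for sample i: ``baseline_hazard * exp(sum_j beta_j * z_ij)`` with
    z the (optionally standardized) planted features. Censoring combines an
    administrative horizon, an independent random-censoring clock, and a
    lost-to-follow-up fraction whose DFS fields are set missing.
    """
    sc = config.survival
    n = len(feature_matrix)
    eta = np.zeros(n)
    for feat, beta in sc.log_hr.items():
        if feat not in feature_matrix.columns:
            raise ValueError(f"planted feature {feat!r} absent from matrix")
        x = feature_matrix[feat].to_numpy(dtype=float)
        if standardize:
            sd = x.std()
            x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta += beta * x

    lam = sc.baseline_hazard * np.exp(eta)
    if sc.horizon_months <= 0:
        time = np.zeros(n)
        event = np.zeros(n, dtype=int)
    else:
        with np.errstate(divide="ignore"):
            t_event = rng.exponential(1.0 / np.maximum(lam, 1e-300))
        t_cens = (
            rng.exponential(1.0 / sc.random_censoring_rate, size=n)
            if sc.random_censoring_rate > 0
            else np.full(n, np.inf)
        )
        t_cens = np.minimum(t_cens, sc.horizon_months)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

    out = pd.DataFrame(
        {"dfs_time": time, "dfs_event": event.astype(float)},
        index=feature_matrix.index,
    )
    lost = rng.random(n) < sc.lost_to_followup
    out.loc[lost, ["dfs_time", "dfs_event"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# Whole-cohort assembly


def cohort_feature_matrix(
    cohort: "SyntheticCohort",
    thresholds: filters.FilterThresholds | None = None,
    roster=None,
):
    """Run filter -> annotate -> quantify over the cohort; returns the
    feature matrix (samples x 58) and the aligned tissue labels."""
    catalog = cohort.build_catalog()
    overlaps, mapped = {}, {}
    clin = cohort.clinical.set_index("sample_id")
    for sid, table in cohort.samples.items():
        kept, _ = filters.apply_filters(
            table.loc[:, list(CANDIDATE_COLUMNS)], thresholds
        )
        overlaps[sid] = annotation.annotate(kept, catalog)
        mapped[sid] = int(clin.loc[sid, "mapped_reads"])
    matrix = features.quantify_cohort(overlaps, mapped, roster)
    labels = clin.loc[matrix.index, "tissue_label"]
    return matrix, labels


def simulate_cohort(
    config: SimulationConfig | None = None, include_survival: bool = True
) -> SyntheticCohort:
    """Generate the full synthetic cohort, survival outcomes included."""
    config = config or SimulationConfig()
    layout, tracks = simulate_genome_and_tracks(config)
    placement = _placement_index(tracks, layout)

    ss = np.random.SeedSequence([config.seed, 0x5A11])
    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    groups = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    child_seeds = ss.spawn(len(sample_ids) + 1)

    samples: dict[str, pd.DataFrame] = {}
    clin_rows = []
    truth_samples = {}
    for sid, group, child in zip(sample_ids, groups, child_seeds[:-1]):
        rng = np.random.default_rng(child)
        table, mapped_reads = simulate_sample(config, group, rng, layout, placement)
        samples[sid] = table
        clin_rows.append((sid, group, np.nan, np.nan, mapped_reads))
        truth_samples[sid] = {
            "group": group,
            "n_candidates": int(len(table)),
            "n_pass": int(table["simulated_pass"].sum()),
        }

    clinical = pd.DataFrame(
        clin_rows,
        columns=["sample_id", "tissue_label", "dfs_time", "dfs_event", "mapped_reads"],
    )
    cohort = SyntheticCohort(
        layout=layout,
        tracks=tracks,
        samples=samples,
        clinical=clinical,
        truth={
            "config": config.to_dict(),
            "samples": truth_samples,
            "planted_log_hr": dict(config.survival.log_hr),
        },
        config=config,
    )

    if include_survival and config.n_tumor > 0:
        matrix, labels = cohort_feature_matrix(cohort)
        tumor_matrix = matrix.loc[labels == "tumor"]
        surv_rng = np.random.default_rng(child_seeds[-1])
        surv = simulate_survival(tumor_matrix, config, surv_rng)
        clinical = clinical.set_index("sample_id")
        clinical.loc[surv.index, ["dfs_time", "dfs_event"]] = surv
        cohort.clinical = clinical.reset_index()
        cohort.truth["n_events"] = int(np.nansum(surv["dfs_event"].to_numpy()))
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Serialize a cohort: tracks/, samples/*.tsv, clinical.tsv, truth.json."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(exist_ok=True)
    write_genome_layout(cohort.layout, outdir / "tracks" / "genome.chrom.sizes")
    cohort.tracks["gene_model"].to_csv(
        outdir / "tracks" / "gene_model.tsv", sep="\t", index=False
    )
    cohort.tracks["repeats"].to_csv(
        outdir / "tracks" / "repeats.tsv", sep="\t", index=False
    )
    for track in ("enhancer", "dhs", "cpg_island"):
        cohort.tracks[track].to_csv(
            outdir / "tracks" / f"{track}.bed", sep="\t", index=False, header=False
        )
    for sid, table in cohort.samples.items():
        write_candidate_table(table, outdir / "samples" / f"{sid}.tsv")
    write_clinical_table(cohort.clinical, outdir / "clinical.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True, default=str)
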