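"""Synthetic data with known ground truth.

Three generators emulate the experimental designs the analysis modules
consume:

* :func:`simulate_expression_panel` — a cell-line panel built around four
  isogenic MES/ADRN pairs plus extra unpaired lines, with planted
  lineage-signature genes on the linear intensity scale of detection-called
  microarrays.
* :func:`simulate_timecourse` — a doxycycline-inducible NOTCH3-IC
  time-course (days 0/1/7/14/21 by default) including transient-induction,
  washout and gamma-secretase-inhibitor scenarios, a commitment rule for the
  endogenous feed-forward cascade, and a transgene that lacks the 3'UTR so
  it is visible only to CDS probesets.
* :func:`simulate_chip_landscape` — paired H3K27ac coverage tracks on a toy
  chromosome with planted ADRN-specific and MES-specific super-enhancers,
  typical enhancers, Poisson read noise, and an RBPJ-consensus motif planted
  at an elevated rate inside MES super-enhancers.

Every generator returns a :class:`ScenarioTruth` describing exactly what was
planted.  Truth is for tests and benchmarking only; no analysis operation in
this package reads it.

Noise model
-----------
Intensities are linear-scale and right-skewed, so noise is a multiplicative
lognormal factor with unit mean and coefficient of variation ``noise_cv``.
With ``noise_cv = 0`` every value equals its configured mean exactly, which
makes closed-form checks possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stage_rng
from .containers import ABSENT, PRESENT, ExpressionMatrix
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "TrajectoryConfig",
    "Scenario",
    "Gene",
    "EnhancerTruth",
    "GenomeModel",
    "ScenarioTruth",
    "default_genome",
    "simulate_expression_panel",
    "simulate_timecourse",
    "simulate_chip_landscape",
    "cascade_clock",
    "commitment_time",
    "cumulative_induction",
    "RBPJ_CONSENSUS",
]

#: Consensus planted for the RBPJ-style motif (forward strand insertions).
RBPJ_CONSENSUS = "CGTGGGAA"

CASCADE_GENES = ("JAG1", "NOTCH1", "NOTCH2", "NOTCH3", "MAML2", "HES1")
#: Endogenous baseline intensity of each cascade gene (linear units).
CASCADE_BASELINES = {
    "JAG1": 250.0,
    "NOTCH1": 280.0,
    "NOTCH2": 320.0,
    "NOTCH3": 300.0,
    "MAML2": 260.0,
    "HES1": 350.0,
}
#: Genes with both a CDS and a 3'UTR probeset; only NOTCH3 carries a transgene.
UTR_PROBESET_GENES = ("NOTCH1", "NOTCH2", "NOTCH3")
TRANSGENE_GENE = "NOTCH3"


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Shared parameters of the expression generators.

    Intensities are linear-scale (MAS5-like).  ``effect_linear`` is the
    planted MES-minus-ADRN difference of every signature gene before noise;
    the panel generator plants it exactly, so the zero-noise panel separates
    states by precisely this amount.
    """

    n_genes: int = 5000
    n_mes_signature: int = 300
    n_adrn_signature: int = 250
    n_pairs: int = 4
    extra_lines: int = 8
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 0.5
    effect_linear: float = 500.0
    noise_cv: float = 0.2
    detection_threshold: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_mes_signature": self.n_mes_signature,
            "n_adrn_signature": self.n_adrn_signature,
            "n_pairs": self.n_pairs,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.extra_lines < 0:
            raise ConfigurationError("extra_lines must be >= 0")
        if self.n_mes_signature + self.n_adrn_signature >= self.n_genes:
            raise ConfigurationError("planted signature genes must be fewer than n_genes")
        if self.effect_linear <= 0:
            raise ConfigurationError("effect_linear must be positive")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be non-negative")


@dataclass(frozen=True)
class Scenario:
    """One induction regimen of the time course.

    ``induction_windows`` are (start_day, end_day) intervals during which
    doxycycline keeps the transgene on; harvest at ``t`` counts as induced if
    ``start <= t <= end`` for some window.  ``gsi_active`` models continuous
    gamma-secretase inhibition (RO4929097), which blocks cleavage of the
    endogenous receptors and hence the feed-forward cascade, but not the
    already-cleaved transgene.
    """

    name: str
    induction_windows: tuple[tuple[float, float], ...] = ()
    gsi_active: bool = False


def _default_scenarios() -> tuple[Scenario, ...]:
    return (
        Scenario("control"),
        Scenario("persistent", ((0.0, 21.0),)),
        Scenario("gsi", ((0.0, 21.0),), gsi_active=True),
        Scenario("transient7", ((0.0, 7.0),)),
        Scenario("transient3", ((0.0, 3.0),)),
    )


@dataclass(frozen=True)
class TrajectoryConfig:
    """Kinetics of the induction time course.

    Per-gene trajectories interpolate logistically between the ADRN and MES
    endpoint means; ADRN-down genes are centered at ``adrn_switch_day`` and
    MES-up genes at the later ``mes_switch_day``, reproducing the observed
    onset ordering (ADRN repression within a day, MES induction around a
    week).  ``commitment_days`` is the minimum cumulative induction after
    which the endogenous cascade self-sustains through washout.
    """

    timepoints: tuple[float, ...] = (0.0, 1.0, 7.0, 14.0, 21.0)
    adrn_switch_day: float = 0.5
    mes_switch_day: float = 6.0
    cascade_switch_day: float = 0.5
    switch_steepness: float = 4.0
    transgene_level: float = 2000.0
    commitment_days: float = 5.0
    direct_adrn_fraction: float = 0.15
    n_adrn_tfs: int = 18
    n_mes_tfs: int = 20
    n_mes_tfs_responsive: int = 8
    scenarios: tuple[Scenario, ...] = field(default_factory=_default_scenarios)

    def __post_init__(self) -> None:
        tp = self.timepoints
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        if not self.adrn_switch_day < self.mes_switch_day:
            raise ConfigurationError("adrn_switch_day must precede mes_switch_day")
        if self.commitment_days <= 0:
            raise ConfigurationError("commitment_days must be positive")
        if self.switch_steepness <= 0:
            raise ConfigurationError("switch_steepness must be positive")
        if not 0 <= self.direct_adrn_fraction <= 1:
            raise ConfigurationError("direct_adrn_fraction must be in [0, 1]")
        if not 0 <= self.n_mes_tfs_responsive <= self.n_mes_tfs:
            raise ConfigurationError("responsive MES TFs cannot exceed the CRC size")
        span = (tp[0], tp[-1])
        for sc in self.scenarios:
            for s, e in sc.induction_windows:
                if e < s:
                    raise ConfigurationError(f"scenario {sc.name!r}: window ({s}, {e}) reversed")
                if s < span[0] or e > span[1]:
                    raise ConfigurationError(
                        f"scenario {sc.name!r}: window ({s}, {e}) outside time span {span}"
                    )


# --------------------------------------------------------------------------
# genome model


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(f"gene {self.gene_id}: degenerate interval")


@dataclass(frozen=True)
class EnhancerTruth:
    start: int
    end: int
    state_a_level: float
    state_b_level: float
    cls: str  # "ADRN-SE" | "MES-SE" | "typical" | "background"


@dataclass(frozen=True)
class GenomeModel:
    """A toy chromosome: genes, planted enhancer landscape and (optionally) sequence."""

    chrom_name: str
    chrom_length: int
    bin_width: int
    genes: tuple[Gene, ...]
    enhancer_truth: tuple[EnhancerTruth, ...]
    sequence: str | None = None
    background_level: float = 1.0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.bin_width <= 0:
            raise ConfigurationError("chromosome length and bin width must be positive")
        if self.chrom_length % self.bin_width:
            raise ConfigurationError("bin_width must divide chrom_length")
        for e in self.enhancer_truth:
            if not (0 <= e.start < e.end <= self.chrom_length):
                raise ConfigurationError(f"enhancer interval ({e.start}, {e.end}) out of bounds")
            if e.start % self.bin_width or e.end % self.bin_width:
                raise ConfigurationError("enhancer intervals must align to the bin grid")
        if self.sequence is not None and len(self.sequence) != self.chrom_length:
            raise ConfigurationError("sequence length must equal chrom_length")

    def intervals(self, cls: str) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.enhancer_truth if e.cls == cls]


def default_genome(
    n_mes_se: int = 8,
    n_adrn_se: int = 8,
    n_typical: int = 200,
    bin_width: int = 50,
    se_width: int = 3000,
    typical_width: int = 1000,
    pitch: int = 16000,
    margin: int = 20000,
    typical_level: float = 8.0,
    se_level_low: float = 3.0,
    se_level_base: float = 25.0,
    se_level_step: float = 4.0,
    background_level: float = 1.0,
) -> GenomeModel:
    """Deterministic default enhancer layout.

    Regions sit on a fixed pitch comfortably wider than the default 12.5 kb
    stitching distance, so distinct planted regions never merge.  Planted SEs
    carry graded levels (base + i*step) so their ranked signals are well
    separated on the hockey-stick curve.  Each planted SE overlaps one gene;
    a handful of intergenic genes exercise nearest-TSS assignment.
    """

    n_regions = n_mes_se + n_adrn_se + n_typical
    # spread SE slots evenly through the region order, alternating MES/ADRN
    n_se = n_mes_se + n_adrn_se
    se_slots = (
        set(np.linspace(4, n_regions - 5, n_se).round().astype(int).tolist()) if n_se else set()
    )
    truth: list[EnhancerTruth] = []
    genes: list[Gene] = []
    mes_i = adrn_i = 0
    for idx in range(n_regions):
        start = margin + idx * pitch
        if idx in se_slots:
            take_mes = (mes_i + adrn_i) % 2 == 0 and mes_i < n_mes_se or adrn_i >= n_adrn_se
            end = start + se_width
            if take_mes:
                level = se_level_base + se_level_step * mes_i
                truth.append(EnhancerTruth(start, end, se_level_low, level, "MES-SE"))
                gid = f"MESG{mes_i:02d}"
                mes_i += 1
            else:
                level = se_level_base + se_level_step * adrn_i
                truth.append(EnhancerTruth(start, end, level, se_level_low, "ADRN-SE"))
                gid = f"ADRG{adrn_i:02d}"
                adrn_i += 1
            genes.append(Gene(gid, start - 500, end + 500, "+", start - 500))
        else:
            end = start + typical_width
            truth.append(EnhancerTruth(start, end, typical_level, typical_level, "typical"))
    # intergenic genes for nearest-TSS assignment, placed in region gaps
    for j in range(6):
        pos = margin + (j + 1) * (n_regions * pitch // 8) + pitch // 2
        genes.append(Gene(f"BGRG{j:02d}", pos, pos + 400, "-", pos + 400 - 1))
    chrom_length = margin * 2 + n_regions * pitch
    chrom_length += (-chrom_length) % bin_width
    return GenomeModel(
        chrom_name="chrS",
        chrom_length=chrom_length,
        bin_width=bin_width,
        genes=tuple(sorted(genes, key=lambda g: g.start)),
        enhancer_truth=tuple(truth),
        background_level=background_level,
    )


# --------------------------------------------------------------------------
# ground truth


@dataclass
class ScenarioTruth:
    """Generator-side ground truth; consumed by tests only, never by analysis."""

    planted_mes_genes: frozenset[str] = frozenset()
    planted_adrn_genes: frozenset[str] = frozenset()
    per_gene_switch_day: dict[str, float] = field(default_factory=dict)
    committed: dict[str, bool] = field(default_factory=dict)
    planted_se: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    planted_motif_sites: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    direct_adrn_genes: frozenset[str] = frozenset()
    cascade_genes: tuple[str, ...] = ()
    adrn_tfs: tuple[str, ...] = ()
    mes_tfs: tuple[str, ...] = ()
    responsive_mes_tfs: frozenset[str] = frozenset()
    probe_annotation: pd.DataFrame | None = None
    transgene_level: float = 0.0

    def __post_init__(self) -> None:
        if self.planted_mes_genes & self.planted_adrn_genes:
            raise ConfigurationError("planted MES and ADRN gene sets must be disjoint")


# --------------------------------------------------------------------------
# helpers


def _noise(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def _detection(values: pd.DataFrame, threshold: float) -> pd.DataFrame:
    return pd.DataFrame(
        np.where(values.to_numpy() >= threshold, PRESENT, ABSENT),
        index=values.index,
        columns=values.columns,
    )


def _position(tau: float, switch_day: float, steepness: float) -> float:
    """Normalized logistic position in [0, 1): exactly 0 at tau = 0."""
    lo = expit(-steepness * switch_day)
    return float((expit(steepness * (tau - switch_day)) - lo) / (1.0 - lo))


def dox_on(windows: Sequence[tuple[float, float]], t: float) -> bool:
    """Transgene status at harvest time t (windows inclusive of both edges)."""
    return any(s <= t <= e for s, e in windows)


def cumulative_induction(windows: Sequence[tuple[float, float]], t: float) -> float:
    """Total induced time in [0, t]."""
    return sum(max(0.0, min(e, t) - s) for s, e in windows if s <= t)


def commitment_time(
    windows: Sequence[tuple[float, float]], commitment_days: float
) -> float | None:
    """Earliest time at which cumulative induction reaches the commitment threshold."""
    acc = 0.0
    for s, e in sorted(windows):
        span = e - s
        if acc + span >= commitment_days:
            return s + (commitment_days - acc)
        acc += span
    return None


def cascade_clock(
    t: float,
    windows: Sequence[tuple[float, float]],
    commitment_days: float,
    gsi_active: bool,
) -> float:
    """Effective cascade time at harvest t.

    The clock advances 1:1 while the cascade is driven (transgene on without
    inhibitor, or any time after commitment) and decays 1:1 toward zero
    otherwise, modelling relaxation of the transcriptional state after an
    uncommitted washout.  Under gamma-secretase inhibition the cascade never
    advances.
    """

    if gsi_active:
        return 0.0
    commit_t = commitment_time(windows, commitment_days)
    edges = {0.0, t}
    for s, e in windows:
        if s < t:
            edges.add(s)
        if e < t:
            edges.add(e)
    if commit_t is not None and commit_t < t:
        edges.add(commit_t)
    grid = sorted(edges)
    clock = 0.0
    for a, b in zip(grid, grid[1:]):
        mid = 0.5 * (a + b)
        active = dox_on(windows, mid) or (commit_t is not None and mid >= commit_t)
        if active:
            clock += b - a
        else:
            clock = max(0.0, clock - (b - a))
    return clock


def transgene_clock(t: float, windows: Sequence[tuple[float, float]]) -> float:
    """Like the cascade clock but driven directly (and only) by the transgene."""
    edges = {0.0, t}
    for s, e in windows:
        if s < t:
            edges.add(s)
        if e < t:
            edges.add(e)
    grid = sorted(edges)
    clock = 0.0
    for a, b in zip(grid, grid[1:]):
        mid = 0.5 * (a + b)
        clock = clock + (b - a) if dox_on(windows, mid) else max(0.0, clock - (b - a))
    return clock


# --------------------------------------------------------------------------
# expression panel


def _panel_structure(
    config: SimulationConfig,
) -> tuple[pd.Index, np.ndarray, np.ndarray, np.ndarray]:
    """Shared probeset universe of the panel and the time course.

    Both generators model the same array platform, so probeset ids,
    per-gene baselines and the planted signature membership are drawn from
    one substream seeded only by ``config.seed``.  A signature derived from
    the panel therefore applies directly to time-course samples.
    """

    rng = stage_rng(config.seed, "panel")
    ids = pd.Index([f"ps{i:05d}_at" for i in range(config.n_genes)], name="probeset")
    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    )
    planted = rng.permutation(config.n_genes)[
        : config.n_mes_signature + config.n_adrn_signature
    ]
    mes_idx = np.sort(planted[: config.n_mes_signature])
    adrn_idx = np.sort(planted[config.n_mes_signature :])
    return ids, baselines, mes_idx, adrn_idx


def simulate_expression_panel(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ScenarioTruth]:
    """Isogenic MES/ADRN pairs plus an unpaired cell-line panel.

    One sample per pair member and per extra line.  Every planted MES
    signature gene exceeds its ADRN value by exactly ``effect_linear`` before
    noise, in the same direction in all pairs; planted ADRN genes mirror
    this.  Non-signature genes share means across states.  Detection calls
    threshold the noisy intensity at ``detection_threshold``.
    """

    rng = stage_rng(config.seed, "panel-noise")
    ids, baselines, mes_idx, adrn_idx = _panel_structure(config)

    mes_mean = baselines.copy()
    adrn_mean = baselines.copy()
    mes_mean[mes_idx] += config.effect_linear
    adrn_mean[adrn_idx] += config.effect_linear

    sample_ids: list[str] = []
    meta: list[dict] = []
    columns: list[np.ndarray] = []
    for p in range(1, config.n_pairs + 1):
        for lineage, mean in (("MES", mes_mean), ("ADRN", adrn_mean)):
            sample_ids.append(f"pair{p}_{lineage}")
            meta.append({"lineage": lineage, "pair_id": f"pair{p}"})
            columns.append(mean)
    n_extra_mes = config.extra_lines // 2
    for j in range(config.extra_lines):
        lineage = "MES" if j < n_extra_mes else "ADRN"
        sample_ids.append(f"line{j:02d}_{lineage}")
        meta.append({"lineage": lineage, "pair_id": None})
        columns.append(mes_mean if lineage == "MES" else adrn_mean)

    means = np.column_stack(columns)
    values = means * _noise(rng, config.noise_cv, means.shape)
    values_df = pd.DataFrame(values, index=ids, columns=sample_ids)
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample"))
    em = ExpressionMatrix(values_df, _detection(values_df, config.detection_threshold), samples)
    truth = ScenarioTruth(
        planted_mes_genes=frozenset(ids[mes_idx]),
        planted_adrn_genes=frozenset(ids[adrn_idx]),
    )
    return em, truth


# --------------------------------------------------------------------------
# induction time course


def simulate_timecourse(
    config: SimulationConfig, traj: TrajectoryConfig
) -> tuple[ExpressionMatrix, ScenarioTruth]:
    """NOTCH3-IC induction time course across the configured scenarios.

    Probesets comprise the planted signature genes, two CRC transcription
    factor sets (all ADRN TFs cascade-responsive; a subset of MES TFs
    responsive), the six endogenous cascade genes (JAG1, NOTCH1-3, MAML2,
    HES1) and background genes.  NOTCH1/2/3 are measured by both a CDS and a
    3'UTR probeset; the NOTCH3-IC transgene lacks the 3'UTR and contributes
    ``transgene_level`` to the NOTCH3 CDS probeset only, while doxycycline
    is on.
    """

    rng = stage_rng(config.seed, "timecourse")
    ids, baselines, mes_idx, adrn_idx = _panel_structure(config)
    mes_genes = ids[mes_idx].to_list()
    adrn_genes = ids[adrn_idx].to_list()
    adrn_tfs = [f"ADRN_TF_{i:02d}" for i in range(traj.n_adrn_tfs)]
    mes_tfs = [f"MES_TF_{i:02d}" for i in range(traj.n_mes_tfs)]
    responsive_mes = frozenset(mes_tfs[: traj.n_mes_tfs_responsive])

    n_direct = int(round(traj.direct_adrn_fraction * len(adrn_genes)))
    direct_adrn = frozenset(
        np.array(adrn_genes)[rng.permutation(len(adrn_genes))[:n_direct]].tolist()
    )

    # probeset layout: plain genes get one probeset named after the gene;
    # NOTCH1/2/3 get <gene>_cds and <gene>_3utr.
    annot_rows: list[dict] = []
    plain = (
        ids.to_list()
        + adrn_tfs
        + mes_tfs
        + [g for g in CASCADE_GENES if g not in UTR_PROBESET_GENES]
    )
    for g in plain:
        annot_rows.append({"probeset": g, "gene": g, "region": "CDS"})
    for g in UTR_PROBESET_GENES:
        annot_rows.append({"probeset": f"{g}_cds", "gene": g, "region": "CDS"})
        annot_rows.append({"probeset": f"{g}_3utr", "gene": g, "region": "3UTR"})
    annot = pd.DataFrame(annot_rows).set_index("probeset")

    extra_genes = adrn_tfs + mes_tfs + list(CASCADE_GENES)
    base = dict(zip(ids, baselines))
    for g in extra_genes:
        base[g] = CASCADE_BASELINES.get(
            g, float(np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd)))
        )

    # trajectory class per probeset: 0 flat background, 1 MES-up, 2 ADRN-down
    # (cascade-gated), 3 ADRN-down with a direct transgene response,
    # 4 cascade gene.  Evaluated vectorially per sample from scalar clocks.
    probesets = annot.index.to_list()
    gene_of = annot["gene"].to_numpy()
    region_of = annot["region"].to_numpy()
    mes_like = frozenset(mes_genes) | responsive_mes
    adrn_like = frozenset(adrn_genes) | frozenset(adrn_tfs)
    cls = np.zeros(len(probesets), dtype=int)
    for i, g in enumerate(gene_of):
        if g in CASCADE_GENES:
            cls[i] = 4
        elif g in mes_like:
            cls[i] = 1
        elif g in direct_adrn:
            cls[i] = 3
        elif g in adrn_like:
            cls[i] = 2
    base_arr = np.array([base[g] for g in gene_of])
    transgene_mask = (gene_of == TRANSGENE_GENE) & (region_of == "CDS")

    k = traj.switch_steepness
    e = config.effect_linear
    sample_ids: list[str] = []
    meta: list[dict] = []
    cols: list[np.ndarray] = []
    for scen in traj.scenarios:
        for t in traj.timepoints:
            c = cascade_clock(t, scen.induction_windows, traj.commitment_days, scen.gsi_active)
            d = transgene_clock(t, scen.induction_windows)
            on = dox_on(scen.induction_windows, t)
            pos = {
                1: _position(c, traj.mes_switch_day, k),
                2: _position(c, traj.adrn_switch_day, k),
                3: _position(max(c, d), traj.adrn_switch_day, k),
                4: _position(c, traj.cascade_switch_day, k),
            }
            col = base_arr.copy()
            col[cls == 1] += pos[1] * e
            col[cls == 2] += (1.0 - pos[2]) * e
            col[cls == 3] += (1.0 - pos[3]) * e
            col[cls == 4] += pos[4] * e
            if on:
                col[transgene_mask] += traj.transgene_level
            sample_ids.append(f"{scen.name}_d{t:g}")
            meta.append(
                {
                    "lineage": "unknown",
                    "pair_id": None,
                    "scenario": scen.name,
                    "day": t,
                    "dox": on,
                    "gsi": scen.gsi_active,
                }
            )
            cols.append(col)

    means = np.column_stack(cols)
    values = means * _noise(rng, config.noise_cv, means.shape)
    values_df = pd.DataFrame(
        values, index=pd.Index(probesets, name="probeset"), columns=sample_ids
    )
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample"))
    em = ExpressionMatrix(values_df, _detection(values_df, config.detection_threshold), samples)

    switch_day: dict[str, float] = {}
    for g, c_i in zip(gene_of, cls):
        switch_day[g] = {
            0: math.nan,
            1: traj.mes_switch_day,
            2: traj.adrn_switch_day,
            3: traj.adrn_switch_day,
            4: traj.cascade_switch_day,
        }[int(c_i)]
    committed = {
        sc.name: (not sc.gsi_active)
        and cumulative_induction(sc.induction_windows, traj.timepoints[-1])
        >= traj.commitment_days
        for sc in traj.scenarios
    }
    truth = ScenarioTruth(
        planted_mes_genes=frozenset(mes_genes) | responsive_mes,
        planted_adrn_genes=frozenset(adrn_genes) | frozenset(adrn_tfs),
        per_gene_switch_day=switch_day,
        committed=committed,
        direct_adrn_genes=direct_adrn,
        cascade_genes=CASCADE_GENES,
        adrn_tfs=tuple(adrn_tfs),
        mes_tfs=tuple(mes_tfs),
        responsive_mes_tfs=responsive_mes,
        probe_annotation=annot,
        transgene_level=traj.transgene_level,
    )
    return em, truth


# --------------------------------------------------------------------------
# ChIP landscape

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_consensus(seq: np.ndarray, consensus: bytes) -> None:
    """Mutate chance forward-strand occurrences of the consensus away, in place."""
    pat = np.frombuffer(consensus, dtype=np.uint8)
    L = len(pat)
    for _ in range(10):
        hit = np.ones(len(seq) - L + 1, dtype=bool)
        for j in range(L):
            hit &= seq[j : j + len(hit)] == pat[j]
        pos = np.flatnonzero(hit)
        if pos.size == 0:
            return
        mid = L // 2
        for p in pos:
            seq[p + mid] = _BASES[(int(np.where(_BASES == seq[p + mid])[0][0]) + 1) % 4]
    raise RuntimeError("failed to scrub consensus occurrences")  # pragma: no cover


def simulate_chip_landscape(
    config: SimulationConfig,
    genome: GenomeModel,
    lib_factor_a: float = 1.0,
    lib_factor_b: float = 1.0,
    poisson_noise: bool = True,
    motif_rate: float = 3.3e-4,
    mes_rate_multiplier: float = 5.0,
    consensus: str = RBPJ_CONSENSUS,
) -> tuple["CoverageTrack", "CoverageTrack", GenomeModel, ScenarioTruth]:
    """Paired H3K27ac coverage (state A = ADRN, state B = induced MES).

    Per-bin counts are Poisson with mean = class level x library factor
    (``poisson_noise=False`` keeps the exact expected counts, for
    closed-form checks).  The chromosome sequence carries forward-strand
    insertions of the RBPJ-style consensus: background rate ``motif_rate``
    per bp genome-wide, elevated by ``mes_rate_multiplier`` inside MES
    super-enhancers.  Chance occurrences of the consensus are scrubbed
    before planting, so the truth list enumerates forward occurrences
    exhaustively.
    """

    from .containers import CoverageTrack  # local import avoids cycle at type time

    if lib_factor_a <= 0 or lib_factor_b <= 0:
        raise ConfigurationError("library-size factors must be positive")
    rng = stage_rng(config.seed, "chip")
    n_bins = genome.chrom_length // genome.bin_width
    level_a = np.full(n_bins, genome.background_level, dtype=float)
    level_b = level_a.copy()
    for e in genome.enhancer_truth:
        sl = slice(e.start // genome.bin_width, e.end // genome.bin_width)
        level_a[sl] = e.state_a_level
        level_b[sl] = e.state_b_level

    if poisson_noise:
        counts_a = rng.poisson(level_a * lib_factor_a).astype(float)
        counts_b = rng.poisson(level_b * lib_factor_b).astype(float)
    else:
        counts_a = level_a * lib_factor_a
        counts_b = level_b * lib_factor_b
    track_a = CoverageTrack(
        genome.chrom_name, genome.bin_width, 0, counts_a, max(counts_a.sum(), 1.0)
    )
    track_b = CoverageTrack(
        genome.chrom_name, genome.bin_width, 0, counts_b, max(counts_b.sum(), 1.0)
    )

    seq = _random_sequence(rng, genome.chrom_length)
    cons = consensus.encode()
    _scrub_consensus(seq, cons)
    L = len(cons)

    mes_se = genome.intervals("MES-SE")
    positions: list[int] = []
    n_bg_sites = rng.poisson(motif_rate * genome.chrom_length)
    if n_bg_sites:
        positions.extend(
            rng.integers(0, genome.chrom_length - L, size=n_bg_sites).tolist()
        )
    for s, e in mes_se:
        extra = rng.poisson((mes_rate_multiplier - 1.0) * motif_rate * (e - s))
        if extra:
            positions.extend(rng.integers(s, e - L, size=extra).tolist())
    kept: list[int] = []
    for p in sorted(set(positions)):
        if not kept or p - kept[-1] >= L:
            kept.append(p)
    pat = np.frombuffer(cons, dtype=np.uint8)
    for p in kept:
        seq[p : p + L] = pat

    genome_with_seq = replace(genome, sequence=seq.tobytes().decode("ascii"))
    truth = ScenarioTruth(
        planted_se={
            cls: genome.intervals(cls) for cls in ("MES-SE", "ADRN-SE", "typical")
        },
        planted_motif_sites=[((p, p + L), "RBPJ_SYN") for p in kept],
    )
    return track_a, track_b, genome_with_seq, truth
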