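"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_bioid_counts` — run-level spectral-count tables with
  planted true interactors (bait-dependent Poisson rates, absent from
  controls), background contaminants (equal rates in bait and control
  runs), bait self-counts per condition, condition-specific planted
  log2 fold changes (including restored / attenuated / non-responsive
  triplets), and a shared lognormal random effect per biological replicate
  that induces realistic replicate correlation.

* :func:`simulate_field_image` — fields of disk-shaped cells whose
  interiors fill the "total" channel and whose membrane annuli fill the
  "surface" channel at a known surface:total intensity ratio, over a
  uniform background with optional Poisson shot noise.

* :func:`simulate_flipr_trace` — piecewise membrane-potential traces: flat
  baseline, first-order rise after the agonist to a known dF/F0 amplitude,
  and exponential decay after the inhibitor towards a known residual level.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CONTROL_CONDITION, COLUMNS, SpectralCountTable
from .errors import ValidationError
from .flipr import FLIPRTrace
from .imaging import FieldImage

# ---------------------------------------------------------------------------
# spectral counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A prey's log2 fold change vs the reference condition."""

    prey: str
    condition: str
    log2fc: float


@dataclass
class CountSimConfig:
    """Study conditions for the spectral-count generator.

    The replicate structure defaults to two technical replicates from each
    of two biological replicates per condition (four runs), with two
    control runs of the free-tag line.  The default scenario has 60 true
    preys over 600 background contaminants, and the mutant bait is half as
    abundant as the wild-type one (the drug-treated mutant matches the
    untreated mutant) so bait normalization is exercised.
    """

    n_bio_reps: int = 2
    n_tech_reps: int = 2
    n_control_runs: int = 2
    n_true_preys: int = 60
    n_background_preys: int = 600
    bait_self_count: dict[str, float] = field(
        default_factory=lambda: {"WT": 100.0, "dF508": 50.0, "dF508+Orkambi": 50.0}
    )
    reference_condition: str = "WT"
    bait_gene: str = "CFTR"
    control_bait: str = "BIRA"
    true_prey_rate_range: tuple[float, float] = (10.0, 80.0)
    contaminant_rate: float = 2.0
    true_prey_control_rate: float = 0.0
    bio_effect_sd: float = 0.2
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_bio_reps < 1 or self.n_tech_reps < 1 or self.n_control_runs < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.reference_condition not in self.bait_self_count:
            raise ValidationError("reference condition needs a bait self count")
        if any(v <= 0 for v in self.bait_self_count.values()):
            raise ValidationError("bait self counts must be positive")
        lo, hi = self.true_prey_rate_range
        if not (0 < lo <= hi):
            raise ValidationError("true prey rate range must be positive")
        if self.contaminant_rate < 0 or self.true_prey_control_rate < 0:
            raise ValidationError("rates must be non-negative")
        for eff in self.planted_effects:
            if eff.condition not in self.bait_self_count:
                raise ValidationError(
                    f"planted effect for unknown condition {eff.condition!r}"
                )


@dataclass(frozen=True)
class TruthTable:
    """Ground truth accompanying a simulated count table."""

    preys: pd.DataFrame  # index prey; columns: kind, base_rate
    planted: pd.DataFrame  # columns: prey, condition, log2fc
    trio_labels: pd.DataFrame  # columns: prey, label (may be empty)

    def true_preys(self) -> set[str]:
        return set(self.preys.index[self.preys["kind"] == "true"])

    def contaminants(self) -> set[str]:
        return set(self.preys.index[self.preys["kind"] == "contaminant"])

    def planted_log2fc(self, prey: str, condition: str) -> float:
        sel = self.planted[
            (self.planted["prey"] == prey) & (self.planted["condition"] == condition)
        ]
        return float(sel["log2fc"].iloc[0]) if len(sel) else 0.0

    def pairwise_truth(self, condition: str, fc_threshold: float = 1.0) -> pd.Series:
        """True gained/lost/unchanged label per true prey for reference-vs-
        *condition*, derived from the planted fold changes."""
        labels = {}
        for prey in sorted(self.true_preys()):
            fc = self.planted_log2fc(prey, condition)
            if fc >= fc_threshold:
                labels[prey] = "gained"
            elif fc <= -fc_threshold:
                labels[prey] = "lost"
            else:
                labels[prey] = "unchanged"
        return pd.Series(labels, name="label")


def default_count_scenario(seed: int = 0) -> CountSimConfig:
    """The default planted scenario: 60 true preys (10 stable, 10 gained,
    10 lost, and 10 each of restored / attenuated / non-responsive
    triplets, all at |log2FC| = 3) over 600 background contaminants."""
    mut, drug = "dF508", "dF508+Orkambi"
    effects: list[PlantedEffect] = []
    trio_rows = []
    names = [f"TRUE{i:03d}" for i in range(1, 61)]
    groups = {
        "stable": names[0:10],
        "gained": names[10:20],
        "lost": names[20:30],
        "restored": names[30:40],
        "attenuated": names[40:50],
        "non_responsive": names[50:60],
    }
    plan = {
        "stable": (0.0, 0.0),
        "gained": (3.0, 3.0),
        "lost": (-3.0, -3.0),
        "restored": (-3.0, 0.0),
        "attenuated": (3.0, 0.0),
        "non_responsive": (3.0, 3.0),
    }
    for group, preys in groups.items():
        fc_mut, fc_drug = plan[group]
        for prey in preys:
            if fc_mut:
                effects.append(PlantedEffect(prey, mut, fc_mut))
            if fc_drug:
                effects.append(PlantedEffect(prey, drug, fc_drug))
            if group in ("restored", "attenuated", "non_responsive"):
                trio_rows.append((prey, group))
    cfg = CountSimConfig(planted_effects=effects, seed=seed)
    cfg._trio_rows = trio_rows  # consumed by simulate_bioid_counts
    return cfg


def simulate_bioid_counts(cfg: CountSimConfig) -> tuple[SpectralCountTable, TruthTable]:
    """Draw a spectral-count table and its ground truth from *cfg*.

    True preys receive Poisson counts in bait runs at rate
    ``base_rate * self(c)/self(ref) * 2^planted_log2fc * g`` where ``g`` is
    a lognormal effect shared by the runs of one biological replicate, and
    (by default) zero counts in control runs.  Background preys are Poisson
    at the contaminant rate in every run, controls included.  The bait gene
    itself appears as a prey at the per-condition self-count rate so that
    bait abundances can be recovered from the table.
    """
    rng = np.random.default_rng(cfg.seed)
    conditions = list(cfg.bait_self_count)
    ref_self = cfg.bait_self_count[cfg.reference_condition]

    true_names = [f"TRUE{i:03d}" for i in range(1, cfg.n_true_preys + 1)]
    bg_names = [f"BG{i:04d}" for i in range(1, cfg.n_background_preys + 1)]
    lo, hi = cfg.true_prey_rate_range
    base_rates = rng.uniform(lo, hi, size=cfg.n_true_preys)

    planted: dict[tuple[str, str], float] = {
        (e.prey, e.condition): e.log2fc for e in cfg.planted_effects
    }

    rows: list[tuple] = []
    for cond in conditions:
        self_rate = cfg.bait_self_count[cond]
        scale = self_rate / ref_self
        rep = 0
        for b in range(cfg.n_bio_reps):
            g = rng.lognormal(mean=0.0, sigma=cfg.bio_effect_sd)
            for t in range(cfg.n_tech_reps):
                rep += 1
                run_id = f"{cond}_b{b + 1}t{t + 1}"
                rates = base_rates * scale * g
                fc = np.array(
                    [2.0 ** planted.get((p, cond), 0.0) for p in true_names]
                )
                counts = rng.poisson(rates * fc)
                for prey, c in zip(true_names, counts):
                    if c > 0:
                        rows.append((run_id, cfg.bait_gene, cond, rep, prey, int(c)))
                bg_counts = rng.poisson(cfg.contaminant_rate * g, size=len(bg_names))
                for prey, c in zip(bg_names, bg_counts):
                    if c > 0:
                        rows.append((run_id, cfg.bait_gene, cond, rep, prey, int(c)))
                self_count = rng.poisson(self_rate * g)
                if self_count > 0:
                    rows.append(
                        (run_id, cfg.bait_gene, cond, rep, cfg.bait_gene, int(self_count))
                    )
    for k in range(cfg.n_control_runs):
        run_id = f"control_{k + 1}"
        bg_counts = rng.poisson(cfg.contaminant_rate, size=len(bg_names))
        for prey, c in zip(bg_names, bg_counts):
            if c > 0:
                rows.append((run_id, cfg.control_bait, CONTROL_CONDITION, k + 1, prey, int(c)))
        if cfg.true_prey_control_rate > 0:
            tp_counts = rng.poisson(cfg.true_prey_control_rate, size=len(true_names))
            for prey, c in zip(true_names, tp_counts):
                if c > 0:
                    rows.append(
                        (run_id, cfg.control_bait, CONTROL_CONDITION, k + 1, prey, int(c))
                    )

    table = SpectralCountTable.from_frame(pd.DataFrame(rows, columns=list(COLUMNS)))

    preys = pd.DataFrame(
        {
            "kind": ["true"] * len(true_names) + ["contaminant"] * len(bg_names),
            "base_rate": list(base_rates) + [cfg.contaminant_rate] * len(bg_names),
        },
        index=pd.Index(true_names + bg_names, name="prey"),
    )
    planted_frame = pd.DataFrame(
        [(e.prey, e.condition, e.log2fc) for e in cfg.planted_effects],
        columns=["prey", "condition", "log2fc"],
    )
    trio_rows = getattr(cfg, "_trio_rows", [])
    trio = pd.DataFrame(trio_rows, columns=["prey", "label"])
    return table, TruthTable(preys=preys, planted=planted_frame, trio_labels=trio)


# ---------------------------------------------------------------------------
# field images
# ---------------------------------------------------------------------------


@dataclass
class ImageSimConfig:
    """Geometry and intensities for synthetic reporter fields.

    Cells are non-overlapping disks; the disk interior carries the total-
    channel intensity and the membrane annulus carries the surface-channel
    intensity, set to ``true_surface_total_ratio * total_intensity`` so the
    constructed per-field surface:total ratio is known exactly.
    """

    field_shape: tuple[int, int] = (192, 192)
    n_cells: int = 30
    cell_radius: float = 8.0
    ring_width: float = 2.5
    true_surface_total_ratio: float = 0.5
    total_intensity: float = 8000.0
    background_level: float = 100.0
    shot_noise: str = "poisson"  # poisson | none
    n_fields: int = 25
    seed: int = 0
    max_place_tries: int = 5000

    def __post_init__(self):
        h, w = self.field_shape
        if self.cell_radius * 2 + 4 > min(h, w):
            raise ValidationError("cell radius too large for the field")
        if self.ring_width <= 0 or self.ring_width > self.cell_radius:
            raise ValidationError("ring must lie inside the cell")
        peak = self.total_intensity + self.background_level
        if peak > 65535:
            raise ValidationError("intensities exceed the 16-bit range")
        if self.shot_noise not in ("poisson", "none"):
            raise ValidationError("shot_noise must be 'poisson' or 'none'")


def _place_cells(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.field_shape
    margin = cfg.cell_radius + 2
    min_sep = 2 * cfg.cell_radius + 2
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < cfg.n_cells:
        if tries >= cfg.max_place_tries:
            raise ValidationError(
                f"could not place {cfg.n_cells} non-overlapping cells "
                f"in {cfg.field_shape} after {cfg.max_place_tries} tries"
            )
        tries += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
            centers.append((y, x))
    return np.array(centers) if centers else np.empty((0, 2))


def simulate_field_image(
    cfg: ImageSimConfig, rng: np.random.Generator | None = None
) -> tuple[FieldImage, float]:
    """One synthetic field and its true surface:total ratio."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    h, w = cfg.field_shape
    total = np.zeros((h, w), dtype=float)
    surface = np.zeros((h, w), dtype=float)
    cellfree = np.ones((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = _place_cells(cfg, rng) if cfg.n_cells > 0 else np.empty((0, 2))
    s_intensity = cfg.true_surface_total_ratio * cfg.total_intensity
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = d2 <= cfg.cell_radius**2
        ring = disk & (d2 >= (cfg.cell_radius - cfg.ring_width) ** 2)
        total[disk] = cfg.total_intensity
        surface[ring] = s_intensity
        cellfree &= d2 > (cfg.cell_radius + 3) ** 2
    total += cfg.background_level
    surface += cfg.background_level
    if cfg.shot_noise == "poisson":
        total = rng.poisson(total).astype(float)
        surface = rng.poisson(surface).astype(float)
    total = np.clip(total, 0, 65535)
    surface = np.clip(surface, 0, 65535)
    field = FieldImage(surface=surface, total=total, background_mask=cellfree)
    return field, cfg.true_surface_total_ratio


def simulate_field_set(cfg: ImageSimConfig) -> tuple[list[FieldImage], float]:
    """cfg.n_fields independent fields sharing one truth ratio."""
    rng = np.random.default_rng(cfg.seed)
    fields = [simulate_field_image(cfg, rng)[0] for _ in range(cfg.n_fields)]
    return fields, cfg.true_surface_total_ratio


# ---------------------------------------------------------------------------
# FLIPR traces
# ---------------------------------------------------------------------------


@dataclass
class TraceSimConfig:
    """Piecewise trace: baseline, first-order agonist rise, inhibitor decay.

    Noise is additive Gaussian in dF/F0 units (sd ``noise_sd`` times the
    baseline level).  Times are seconds; the defaults read every 10 s with
    a 3-minute baseline before the agonist and 5 minutes between agonist
    and inhibitor.
    """

    sampling_interval: float = 10.0
    duration: float = 720.0
    baseline_level: float = 1000.0
    response_amplitude: float = 0.5
    inhibitor_residual_fraction: float = 0.2
    noise_sd: float = 0.01
    fsk_time: float = 180.0
    inh_time: float = 480.0
    rise_tau: float = 20.0
    decay_tau: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fsk_time < self.inh_time < self.duration):
            raise ValidationError("event times must satisfy 0 < fsk < inh < duration")
        if self.response_amplitude < 0:
            raise ValidationError("response amplitude must be >= 0")
        if self.baseline_level <= 0:
            raise ValidationError("baseline level must be positive")


@dataclass(frozen=True)
class TraceTruth:
    peak_dff0: float
    inhibitor_sensitive_fraction: float


def simulate_flipr_trace(
    cfg: TraceSimConfig, rng: np.random.Generator | None = None
) -> tuple[FLIPRTrace, TraceTruth]:
    """One synthetic trace and the noise-free truth of its readouts."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration + 1e-9, cfg.sampling_interval)
    base = cfg.baseline_level
    amp = cfg.response_amplitude
    f = np.full_like(t, base)
    rise = (t > cfg.fsk_time) & (t <= cfg.inh_time)
    f[rise] = base * (1 + amp * (1 - np.exp(-(t[rise] - cfg.fsk_time) / cfg.rise_tau)))
    peak_at_inh = amp * (1 - np.exp(-(cfg.inh_time - cfg.fsk_time) / cfg.rise_tau))
    resid = amp * cfg.inhibitor_residual_fraction
    post = t > cfg.inh_time
    f[post] = base * (
        1 + resid + (peak_at_inh - resid) * np.exp(-(t[post] - cfg.inh_time) / cfg.decay_tau)
    )
    f = f + rng.normal(0.0, cfg.noise_sd * base, size=t.shape)
    f = np.clip(f, 0.0, None)
    trace = FLIPRTrace(time=t, fluorescence=f, fsk_time=cfg.fsk_time, inh_time=cfg.inh_time)
    truth_peak = peak_at_inh
    truth_fraction = (
        (truth_peak - resid) / truth_peak if truth_peak > 0 else float("nan")
    )
    return trace, TraceTruth(peak_dff0=truth_peak, inhibitor_sensitive_fraction=truth_fraction)
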