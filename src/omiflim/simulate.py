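"""Synthetic TCSPC scene and cohort generator.

Everything the analysis consumes can be produced here with known ground
truth: 256-bin photon-count decay cubes for the NAD(P)H and FAD channels
(Poisson photon statistics, IRF-convolved two-component decays), mCherry
and GFP reporter intensity images, and cohorts of cells nested in larvae
nested in experiment days with injected treatment, day-block, and
larva-level effects.

Cells are non-overlapping disks. Each cell draws its true decay parameters
(tau1, tau2, alpha1 per channel) and photon budgets from group-specific
distributions; TNF-alpha-positive cells shift those distributions in the
directions observed for proinflammatory macrophages (lower redox ratio,
lower NAD(P)H lifetimes, higher free-NAD(P)H fraction). All randomness is
driven by explicit seeds, one child stream per field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .axes import IRFKernel, TimeAxis, make_irf
from .fitting import DEFAULT_BOUNDS, FitBounds
from .io import DecayCube
from .model import DecayModelParams, mean_lifetime, model_decay

__all__ = [
    "ChannelDistribution",
    "CellPopulation",
    "SceneSpec",
    "CellTruth",
    "GroundTruthScene",
    "CohortDesign",
    "CohortSim",
    "make_irf",
    "make_scene",
    "render_decay_cube",
    "render_reporter_images",
    "simulate_cohort",
    "default_population",
    "TNFA_POSITIVE_EFFECTS",
]

CHANNELS = ("nadph", "fad")

# Default shifts applied to TNF-alpha-positive cells, following the observed
# direction of change in proinflammatory macrophages: lower NAD(P)H
# lifetimes, higher free fraction, lower NAD(P)H intensity (hence lower
# redox ratio). FAD endpoints are left unchanged (no consistent shift was
# observed for them).
TNFA_POSITIVE_EFFECTS: dict[str, float] = {
    "nadph_tau1": 0.85,
    "nadph_tau2": 0.85,
    "nadph_alpha1": 1.15,
    "nadph_budget": 0.65,
}


@dataclass(frozen=True)
class ChannelDistribution:
    """Per-channel distribution of true decay parameters across cells.

    Means are geometric centers; each cell multiplies them by lognormal
    deviates (a shared whole-cell factor on the lifetimes plus independent
    per-parameter jitter with coefficient of variation ``component_cv``).
    ``budget`` is the expected decay photons per pixel.
    """

    tau1: float
    tau2: float
    alpha1: float
    budget: float
    component_cv: float = 0.03

    def __post_init__(self) -> None:
        b: FitBounds = DEFAULT_BOUNDS
        if not b.tau1[0] <= self.tau1 <= b.tau1[1]:
            raise ValueError(f"tau1 mean {self.tau1} outside fitter bounds {b.tau1}")
        if not b.tau2[0] <= self.tau2 <= b.tau2[1]:
            raise ValueError(f"tau2 mean {self.tau2} outside fitter bounds {b.tau2}")
        if not 0.0 < self.alpha1 < 1.0:
            raise ValueError(f"alpha1 mean must be in (0,1), got {self.alpha1}")
        if self.budget <= 0:
            raise ValueError("photon budget must be positive")

    def scaled(self, mult: dict[str, float]) -> "ChannelDistribution":
        """New distribution with means multiplied (keys: tau1, tau2, alpha1,
        budget); alpha1 is capped into (0, 0.99]."""
        for k, v in mult.items():
            if v <= 0:
                raise ValueError(f"multiplier for {k} must be positive, got {v}")
        return replace(
            self,
            tau1=float(np.clip(self.tau1 * mult.get("tau1", 1.0), *DEFAULT_BOUNDS.tau1)),
            tau2=float(np.clip(self.tau2 * mult.get("tau2", 1.0), *DEFAULT_BOUNDS.tau2)),
            alpha1=float(min(self.alpha1 * mult.get("alpha1", 1.0), 0.99)),
            budget=self.budget * mult.get("budget", 1.0),
        )


@dataclass(frozen=True)
class CellPopulation:
    """Joint NAD(P)H / FAD distribution for one activation group.

    ``cell_sd`` is the SD (log scale) of a whole-cell lognormal factor
    shared by both channels' lifetimes and budgets — it models cell-to-cell
    metabolic variation and induces correlated endpoints within a cell.
    """

    nadph: ChannelDistribution
    fad: ChannelDistribution
    cell_sd: float = 0.05

    def scaled(self, effects: dict[str, float]) -> "CellPopulation":
        """Apply flat multipliers keyed '<channel>_<param>' (e.g.
        'nadph_tau2': 0.85) to the distribution means."""
        per_channel: dict[str, dict[str, float]] = {c: {} for c in CHANNELS}
        for key, v in effects.items():
            ch, _, param = key.partition("_")
            if ch not in per_channel or param not in ("tau1", "tau2", "alpha1", "budget"):
                raise ValueError(f"unknown effect key {key!r}")
            per_channel[ch][param] = v
        return replace(
            self,
            nadph=self.nadph.scaled(per_channel["nadph"]),
            fad=self.fad.scaled(per_channel["fad"]),
        )


def default_population(tnfa_positive: bool = False) -> CellPopulation:
    """Baseline macrophage population (TNF-alpha-negative), with
    literature-typical free/bound lifetimes and a redox ratio of ~0.67."""
    pop = CellPopulation(
        nadph=ChannelDistribution(tau1=0.4, tau2=2.5, alpha1=0.7, budget=5000.0),
        fad=ChannelDistribution(tau1=0.4, tau2=2.0, alpha1=0.6, budget=2500.0),
    )
    if tnfa_positive:
        pop = pop.scaled(TNFA_POSITIVE_EFFECTS)
    return pop


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one field of view."""

    shape: tuple[int, int] = (64, 64)
    n_cells: int = 10
    radius_range: tuple[float, float] = (3.0, 5.0)
    non_overlap: bool = True
    tnfa_fraction: float = 0.0
    tnfa_labels: tuple[bool, ...] | None = None  # overrides tnfa_fraction
    negative: CellPopulation = field(default_factory=default_population)
    positive: CellPopulation = field(
        default_factory=lambda: default_population(tnfa_positive=True)
    )
    background_offset: float = 0.1  # counts per bin per pixel
    larva_id: str = "larva-0"
    day_id: str = "day-0"
    treatment: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.tnfa_labels is not None and len(self.tnfa_labels) != self.n_cells:
            raise ValueError("tnfa_labels length must equal n_cells")
        if self.background_offset < 0:
            raise ValueError("background_offset must be nonnegative")
        if not (0.0 <= self.tnfa_fraction <= 1.0):
            raise ValueError("tnfa_fraction must be in [0,1]")


@dataclass
class CellTruth:
    """Ground-truth parameters of one simulated cell."""

    cell_id: int
    center: tuple[float, float]
    radius: float
    tnfa_positive: bool
    # channel -> dict(tau1, tau2, alpha1, budget)
    params: dict[str, dict[str, float]]

    def endpoint_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for ch in CHANNELS:
            p = self.params[ch]
            row[f"{ch}_t1"] = p["tau1"]
            row[f"{ch}_t2"] = p["tau2"]
            row[f"{ch}_a1"] = p["alpha1"]
            row[f"{ch}_tm"] = float(mean_lifetime(p["tau1"], p["tau2"], p["alpha1"]))
            row[f"{ch}_budget"] = p["budget"]
        bn, bf = row["nadph_budget"], row["fad_budget"]
        row["orr"] = bn / (bn + bf)
        return row


@dataclass
class GroundTruthScene:
    """One simulated field of view with full ground truth."""

    spec: SceneSpec
    labels: np.ndarray  # int, 0 = background, one owning cell per pixel
    cells: list[CellTruth]
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id

    def intensity_map(self, channel: str) -> np.ndarray:
        """Per-pixel true decay-photon budget for a channel."""
        out = np.zeros(self.shape, dtype=float)
        for cell in self.cells:
            out[self.labels == cell.cell_id] = cell.params[channel]["budget"]
        return out

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            row = {
                "cell_id": cell.cell_id,
                "larva_id": self.spec.larva_id,
                "day_id": self.spec.day_id,
                "treatment": self.spec.treatment,
                "tnfa_status": "positive" if cell.tnfa_positive else "negative",
                **cell.endpoint_row(),
            }
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_channel(
    dist: ChannelDistribution, shared: float, rng: np.random.Generator
) -> dict[str, float]:
    cv = dist.component_cv
    jit = rng.normal(0.0, cv, size=4) if cv > 0 else np.zeros(4)
    b = DEFAULT_BOUNDS
    tau1 = float(np.clip(dist.tau1 * shared * np.exp(jit[0]), *b.tau1))
    tau2 = float(np.clip(dist.tau2 * shared * np.exp(jit[1]), *b.tau2))
    alpha1 = float(np.clip(dist.alpha1 * np.exp(jit[2]), 0.01, 0.99))
    budget = float(dist.budget * shared * np.exp(jit[3]))
    return {"tau1": tau1, "tau2": max(tau2, tau1), "alpha1": alpha1, "budget": budget}


def draw_cell(
    pop: CellPopulation, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Draw one cell's true parameters for both channels (truncated to the
    fitter's default bounds)."""
    shared = float(np.exp(rng.normal(0.0, pop.cell_sd))) if pop.cell_sd > 0 else 1.0
    return {ch: _draw_channel(getattr(pop, ch), shared, rng) for ch in CHANNELS}


def _place_disks(
    spec: SceneSpec, rng: np.random.Generator, max_tries: int = 5000
) -> list[tuple[float, float, float]]:
    rows, cols = spec.shape
    placed: list[tuple[float, float, float]] = []
    for i in range(spec.n_cells):
        r_lo, r_hi = spec.radius_range
        for _ in range(max_tries):
            rad = float(rng.uniform(r_lo, r_hi))
            cy = float(rng.uniform(rad, rows - rad))
            cx = float(rng.uniform(rad, cols - rad))
            if spec.non_overlap and any(
                (cy - y) ** 2 + (cx - x) ** 2 < (rad + r + 1.0) ** 2
                for y, x, r in placed
            ):
                continue
            placed.append((cy, cx, rad))
            break
        else:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping cells of radius "
                f"{spec.radius_range} in a {rows}x{cols} field (placed {i})"
            )
    return placed


def make_scene(spec: SceneSpec) -> GroundTruthScene:
    """Build a ground-truth scene: place cells and draw their true decay
    parameters from the group distributions. Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    disks = _place_disks(spec, rng)
    rows, cols = spec.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    labels = np.zeros(spec.shape, dtype=np.int32)

    if spec.tnfa_labels is not None:
        statuses = list(spec.tnfa_labels)
    else:
        statuses = list(rng.random(spec.n_cells) < spec.tnfa_fraction)

    cells: list[CellTruth] = []
    for i, ((cy, cx, rad), positive) in enumerate(zip(disks, statuses), start=1):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        labels[mask] = i
        pop = spec.positive if positive else spec.negative
        cells.append(
            CellTruth(
                cell_id=i,
                center=(cy, cx),
                radius=rad,
                tnfa_positive=bool(positive),
                params=draw_cell(pop, rng),
            )
        )
    meta = {
        "seed": spec.seed,
        "larva_id": spec.larva_id,
        "day_id": spec.day_id,
        "treatment": spec.treatment,
    }
    return GroundTruthScene(spec=spec, labels=labels, cells=cells, meta=meta)


def render_decay_cube(
    scene: GroundTruthScene,
    channel: str,
    irf: IRFKernel,
    time_axis: TimeAxis,
    seed: int = 0,
    noise: bool = True,
    wrap: bool = False,
) -> DecayCube:
    """Render a photon-count decay cube for one channel.

    Expected per-bin counts are the IRF-convolved two-component decay scaled
    to each pixel's photon budget plus the constant background offset;
    observed counts are independent Poisson draws (``noise=True``) or the
    expectations themselves (``noise=False``).
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    rows, cols = scene.shape
    n = time_axis.n_bins
    expected = np.full((rows, cols, n), float(scene.spec.background_offset))
    for cell in scene.cells:
        if channel not in cell.params:
            raise ValueError(f"cell {cell.cell_id} has no parameters for {channel!r}")
        p = cell.params[channel]
        curve = model_decay(
            DecayModelParams(
                amplitude=p["budget"], alpha1=p["alpha1"], tau1=p["tau1"],
                tau2=p["tau2"], offset=0.0,
            ),
            time_axis,
            irf,
            wrap=wrap,
        )
        expected[scene.labels == cell.cell_id] = curve + scene.spec.background_offset
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.int64)
    else:
        counts = expected
    meta = {**scene.meta, "render_seed": seed, "noise": noise, "irf_fwhm_ps": irf.fwhm_ps}
    return DecayCube(counts=counts, time_axis=time_axis, channel=channel, meta=meta)


def render_reporter_images(
    scene: GroundTruthScene,
    signal: float = 1000.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (mCherry, GFP) intensity images.

    mCherry is bright inside every cell; GFP is bright only inside
    TNF-alpha-positive cells. With ``noise_sd=0`` the images are noiseless
    masks (mCherry support equals the union of cell masks exactly); with
    ``noise_sd>0`` Gaussian noise around ``background`` is added everywhere.
    """
    mask_all = scene.labels > 0
    pos_mask = np.zeros(scene.shape, dtype=bool)
    for cell in scene.cells:
        if cell.tnfa_positive:
            pos_mask |= scene.labels == cell.cell_id
    mcherry = signal * mask_all.astype(float)
    gfp = signal * pos_mask.astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mcherry = np.clip(mcherry + rng.normal(background, noise_sd, scene.shape), 0, None)
        gfp = np.clip(gfp + rng.normal(background, noise_sd, scene.shape), 0, None)
    return mcherry, gfp


@dataclass(frozen=True)
class CohortDesign:
    """Design of a simulated cohort: cells nested in larvae nested in days.

    Fixed treatment effects are multiplicative on endpoint-distribution
    means; day blocks and larva random effects act as lognormal factors
    (additive on the log scale), inducing within-larva correlation with
    intraclass correlation larva_sd^2 / (larva_sd^2 + cell_sd^2) on log
    endpoints (exact when ``component_cv`` is 0).
    """

    treatments: tuple[str, ...] = ("control", "treated")
    treatment_effects: dict = field(default_factory=dict)  # name -> effect dict
    tnfa_fraction: dict | float = 0.3
    n_days: int = 3
    larvae_per_day: int = 5  # per treatment
    cells_per_larva: int = 20
    larva_sd: float = 0.05
    day_sd: float = 0.03
    cell_sd: float = 0.05
    component_cv: float = 0.03
    field_shape: tuple[int, int] = (128, 128)
    radius_range: tuple[float, float] = (3.0, 5.0)
    background_offset: float = 0.1
    baseline: CellPopulation | None = None
    tnfa_effects: dict = field(default_factory=lambda: dict(TNFA_POSITIVE_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, eff in self.treatment_effects.items():
            for k, v in eff.items():
                if v <= 0:
                    raise ValueError(
                        f"treatment {name!r}: multiplier {k}={v} must be positive"
                    )
        for sd in (self.larva_sd, self.day_sd, self.cell_sd, self.component_cv):
            if sd < 0:
                raise ValueError("SDs must be nonnegative")

    def fraction_for(self, treatment: str) -> float:
        if isinstance(self.tnfa_fraction, dict):
            return float(self.tnfa_fraction.get(treatment, 0.0))
        return float(self.tnfa_fraction)


@dataclass
class CohortSim:
    """Result of :func:`simulate_cohort`."""

    design: CohortDesign
    scenes: list[GroundTruthScene]
    truth: pd.DataFrame
    day_log_shifts: np.ndarray


def _population_for(
    design: CohortDesign, treatment: str, log_factor: float
) -> tuple[CellPopulation, CellPopulation]:
    base = design.baseline or default_population()
    base = replace(
        base,
        cell_sd=design.cell_sd,
        nadph=replace(base.nadph, component_cv=design.component_cv),
        fad=replace(base.fad, component_cv=design.component_cv),
    )
    eff = design.treatment_effects.get(treatment, {})
    neg = base.scaled(eff) if eff else base
    # larva/day lognormal factor applied to lifetimes and budgets
    f = float(np.exp(log_factor))
    shift = {
        f"{ch}_{p}": f for ch in CHANNELS for p in ("tau1", "tau2", "budget")
    }
    neg = neg.scaled(shift)
    pos = neg.scaled(design.tnfa_effects)
    return neg, pos


def simulate_cohort(design: CohortDesign, geometry: bool = True) -> CohortSim:
    """Simulate a full cohort.

    Returns per-larva fields (one scene per larva) plus a ground-truth table
    with one row per cell recording every injected value. With
    ``geometry=False`` cell placement and label images are skipped (empty
    scenes) — useful for statistics-only simulations at scale.
    """
    rng = np.random.default_rng(design.seed)
    day_shifts = rng.normal(0.0, design.day_sd, design.n_days)
    scenes: list[GroundTruthScene] = []
    tables: list[pd.DataFrame] = []
    for treatment in design.treatments:
        for d in range(design.n_days):
            for l in range(design.larvae_per_day):
                larva_shift = float(rng.normal(0.0, design.larva_sd))
                neg, pos = _population_for(
                    design, treatment, day_shifts[d] + larva_shift
                )
                field_seed = int(rng.integers(0, 2**31))
                larva_id = f"{treatment}-d{d}-l{l}"
                spec = SceneSpec(
                    shape=design.field_shape,
                    n_cells=design.cells_per_larva,
                    radius_range=design.radius_range,
                    tnfa_fraction=design.fraction_for(treatment),
                    negative=neg,
                    positive=pos,
                    background_offset=design.background_offset,
                    larva_id=larva_id,
                    day_id=f"day-{d}",
                    treatment=treatment,
                    seed=field_seed,
                )
                if geometry:
                    scene = make_scene(spec)
                else:
                    scene = _paramless_scene(spec)
                scenes.append(scene)
                tables.append(scene.truth_table())
    truth = pd.concat(tables, ignore_index=True)
    return CohortSim(design=design, scenes=scenes, truth=truth, day_log_shifts=day_shifts)


def _paramless_scene(spec: SceneSpec) -> GroundTruthScene:
    """Scene with cell parameters drawn but no geometry (labels all zero)."""
    rng = np.random.default_rng(spec.seed)
    statuses = rng.random(spec.n_cells) < spec.tnfa_fraction
    cells = [
        CellTruth(
            cell_id=i,
            center=(np.nan, np.nan),
            radius=np.nan,
            tnfa_positive=bool(s),
            params=draw_cell(spec.positive if s else spec.negative, rng),
        )
        for i, s in enumerate(statuses, start=1)
    ]
    labels = np.zeros(spec.shape, dtype=np.int32)
    meta = {
        "seed": spec.seed,
        "larva_id": spec.larva_id,
        "day_id": spec.day_id,
        "treatment": spec.treatment,
    }
    return GroundTruthScene(spec=spec, labels=labels, cells=cells, meta=meta)
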