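"""Synthetic single-cell 4i data with a planted senescence-subpopulation structure.

The generator emulates a 31-day etoposide induction time course read out by
iterative indirect immunofluorescence (4i): an untreated control day plus 12
post-induction time points, 16 protein markers, and a mixture of six
biological roles — healthy cells, two transitional populations, and three
terminal populations (large-nuclear senescent, high-concentration senescent,
and a non-senescent terminal state) that emerge on a staged schedule.

Two couplings are built in because the downstream analysis depends on them:

* **Dilution coupling** — per-cell nuclear *mean* intensity is always derived
  as total / area; it is never sampled independently.  Roles whose nuclear
  area outgrows their total protein therefore show declining concentration.
* **Staged emergence** — mixture weights over roles shift with day: the
  senescent transitional population appears immediately (17% of cells at
  day 2), the large-nuclear terminal population arises at day 11, and the
  high-concentration population not before day 17 (7.8% of cells by day 31).

The module also renders phantom image scenes (nuclear mask + per-round
channel images with known inter-round shifts) so the quantification stage can
be tested against exact pixel-level ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "HEALTHY",
    "SENESCENT_TRANSITIONAL",
    "NONSENESCENT_TRANSITIONAL",
    "LARGE_NUCLEAR",
    "HIGH_CONCENTRATION",
    "NONSENESCENT_TERMINAL",
    "DEFAULT_TIME_POINTS",
    "DEFAULT_MARKERS",
    "SENESCENCE_MARKERS",
    "SASP_MARKERS",
    "SubpopProfile",
    "SyntheticScenario",
    "default_scenario",
    "emergence_schedule",
    "sample_cells",
    "render_scene",
    "Scene",
    "feature_columns",
]

HEALTHY = "healthy"
SENESCENT_TRANSITIONAL = "senescent_transitional"
NONSENESCENT_TRANSITIONAL = "nonsenescent_transitional"
LARGE_NUCLEAR = "large_nuclear"
HIGH_CONCENTRATION = "high_concentration"
NONSENESCENT_TERMINAL = "nonsenescent_terminal"

#: The six biological roles, in canonical order.
ROLES: Tuple[str, ...] = (
    HEALTHY,
    SENESCENT_TRANSITIONAL,
    NONSENESCENT_TRANSITIONAL,
    LARGE_NUCLEAR,
    HIGH_CONCENTRATION,
    NONSENESCENT_TERMINAL,
)

#: Untreated control (day 0) plus 12 post-induction time points over 31 days.
DEFAULT_TIME_POINTS: Tuple[int, ...] = (0, 2, 4, 7, 9, 11, 14, 17, 21, 24, 26, 28, 31)

#: Nine named senescence / SASP / signaling markers plus seven generic fillers.
DEFAULT_MARKERS: Tuple[str, ...] = (
    "p53", "p21", "p16", "p-p65", "GATA4", "PARP1", "JAK2", "pSTAT3", "IL-6",
    "MK10", "MK11", "MK12", "MK13", "MK14", "MK15", "MK16",
)

#: Core senescence markers used for role mapping downstream.
SENESCENCE_MARKERS: Tuple[str, ...] = ("p53", "p21", "p16", "p-p65", "GATA4", "PARP1")

#: IL-6 pathway markers with cytoplasmic (SASP) signal in the
#: high-concentration role only.
SASP_MARKERS: Tuple[str, ...] = ("IL-6", "JAK2", "pSTAT3")

BASE_AREA_PX = 250.0

# Baseline nuclear mean intensity per marker (arbitrary units).
_BASE_MEAN = {
    "p53": 120.0, "p21": 80.0, "p16": 60.0, "p-p65": 100.0, "GATA4": 70.0,
    "PARP1": 90.0, "JAK2": 110.0, "pSTAT3": 85.0, "IL-6": 75.0,
    "MK10": 65.0, "MK11": 95.0, "MK12": 70.0, "MK13": 80.0, "MK14": 60.0,
    "MK15": 90.0, "MK16": 100.0,
}

# Terminal nuclear-area multiplier per role (reached at the day-11 plateau).
_AREA_FACTOR = {
    HEALTHY: 1.0,
    SENESCENT_TRANSITIONAL: 1.55,
    NONSENESCENT_TRANSITIONAL: 1.25,
    LARGE_NUCLEAR: 2.8,
    HIGH_CONCENTRATION: 1.45,
    NONSENESCENT_TERMINAL: 1.35,
}

# Total nuclear protein multiplier per (role, marker); unspecified -> 1.0.
# p21 in the transitional/large-nuclear roles is handled by a day curve below.
_TOTAL_FACTOR: Dict[str, Dict[str, float]] = {
    HEALTHY: {},
    SENESCENT_TRANSITIONAL: {
        "p53": 1.5, "p16": 2.2, "p-p65": 2.2, "GATA4": 1.8, "PARP1": 1.8,
        "JAK2": 1.7, "pSTAT3": 1.7,
    },
    NONSENESCENT_TRANSITIONAL: {"MK10": 2.4, "MK11": 2.4, "MK13": 1.7,
                                "MK14": 1.4},
    LARGE_NUCLEAR: {
        "p53": 2.3, "p16": 2.2, "p-p65": 2.3, "GATA4": 2.8, "PARP1": 2.8,
        "JAK2": 1.5, "pSTAT3": 1.5, "IL-6": 1.3,
        "MK10": 1.8, "MK11": 1.8, "MK12": 1.8, "MK13": 1.8, "MK14": 1.8,
        "MK15": 1.8, "MK16": 1.8,
    },
    HIGH_CONCENTRATION: {
        "p53": 2.6, "p21": 2.6, "p16": 2.6, "p-p65": 2.6, "GATA4": 2.6,
        "PARP1": 2.6, "JAK2": 2.2, "pSTAT3": 2.2, "IL-6": 2.0,
        "MK10": 1.2, "MK11": 1.2, "MK12": 1.2,
    },
    NONSENESCENT_TERMINAL: {"MK10": 3.5, "MK11": 3.5, "MK12": 2.5,
                            "MK13": 2.0, "MK14": 1.8},
}

# Cytoplasmic-ring mean multiplier per (role, marker); baseline cyto mean is
# 0.4 x the nuclear baseline.  Only the high-concentration role secretes.
_CYTO_FACTOR: Dict[str, Dict[str, float]] = {
    HIGH_CONCENTRATION: {"IL-6": 5.0, "JAK2": 4.0, "pSTAT3": 4.0},
}

# Transition structure: each role's cells approach their full state along a
# path from a parent state (terminals arrive via their transitional parent),
# so the population carries the density continuum that trajectory inference
# assumes.  A per-cell progress latent u in (0, 1] interpolates log-states.
_PARENT = {
    HEALTHY: HEALTHY,
    SENESCENT_TRANSITIONAL: HEALTHY,
    NONSENESCENT_TRANSITIONAL: HEALTHY,
    LARGE_NUCLEAR: SENESCENT_TRANSITIONAL,
    HIGH_CONCENTRATION: SENESCENT_TRANSITIONAL,
    NONSENESCENT_TERMINAL: NONSENESCENT_TRANSITIONAL,
}


def _draw_progress(role: str, k: int, rng: np.random.Generator) -> np.ndarray:
    """Per-cell transition progress: mass near 1 (arrived) with a decaying
    tail back along the approach path, bounded at the path midpoint so role
    identity is never ambiguous."""
    if role == HEALTHY:
        return np.ones(k)
    return 1.0 - 0.5 * rng.beta(1.0, 1.5, k)


# Staged emergence schedule: per-day mixture weight of each role.  Rows over
# roles sum to 1 at every day.  Anchors: day 0 pure control; senescent
# transitional = 0.17 at day 2; large-nuclear first nonzero at day 11;
# high-concentration first nonzero at day 17, reaching 0.078 at day 31.
_DEFAULT_SCHEDULE: Dict[str, Dict[int, float]] = {
    HEALTHY: dict(zip(DEFAULT_TIME_POINTS,
                      (1.0, .60, .50, .40, .32, .25, .20, .15, .12, .10, .09, .08, .07))),
    SENESCENT_TRANSITIONAL: dict(zip(DEFAULT_TIME_POINTS,
                      (0.0, .17, .20, .23, .25, .22, .20, .18, .16, .14, .13, .12, .11))),
    NONSENESCENT_TRANSITIONAL: dict(zip(DEFAULT_TIME_POINTS,
                      (0.0, .20, .22, .23, .22, .20, .18, .16, .14, .13, .12, .11, .10))),
    LARGE_NUCLEAR: dict(zip(DEFAULT_TIME_POINTS,
                      (0.0, 0.0, 0.0, 0.0, 0.0, .08, .15, .20, .25, .28, .30, .31, .32))),
    HIGH_CONCENTRATION: dict(zip(DEFAULT_TIME_POINTS,
                      (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, .02, .035, .05, .06, .07, .078))),
    NONSENESCENT_TERMINAL: dict(zip(DEFAULT_TIME_POINTS,
                      (0.0, .03, .08, .14, .21, .25, .27, .29, .295, .30, .30, .31, .322))),
}


def _area_ramp(day: float) -> float:
    """Growth ramp saturating at the day-11 plateau."""
    return min(day, 11.0) / 11.0


def _p21_curve(role: str, day: float) -> float:
    """p21 total-protein factor: early spike, decline, late re-rise only in
    the large-nuclear role."""
    if role == SENESCENT_TRANSITIONAL:
        # spike at day 2, declining to below baseline by day 11
        if day <= 2:
            return 2.2
        if day >= 11:
            return 0.6
        return 2.2 + (0.6 - 2.2) * (day - 2) / 9.0
    if role == LARGE_NUCLEAR:
        return 2.5
    return _TOTAL_FACTOR.get(role, {}).get("p21", 1.0)


@dataclass
class SubpopProfile:
    """Generative profile of one biological role.

    ``marker_kinetics`` maps marker -> (total_curve, cyto_curve), both
    functions of day.  Mean nuclear intensity is *derived* per cell as
    total / area and is deliberately absent from the profile.
    """

    area_curve: Callable[[float], float]
    marker_kinetics: Dict[str, Tuple[Callable[[float], float], Callable[[float], float]]]
    emergence_weight: Callable[[float], float]


@dataclass
class SyntheticScenario:
    """Full generative description of a synthetic 4i time course."""

    time_points_days: Tuple[int, ...] = DEFAULT_TIME_POINTS
    cells_per_time_point: int = 1200
    marker_names: Tuple[str, ...] = DEFAULT_MARKERS
    subpopulation_profiles: Dict[str, SubpopProfile] = field(default_factory=dict)
    rng_seed: int = 0
    sigma_log_area: float = 0.10        # biological dispersion of log nuclear area
    sigma_biological: float = 0.10      # per-cell lognormal dispersion of totals
    sigma_measurement: float = 0.05     # multiplicative lognormal measurement noise

    def __post_init__(self) -> None:
        if self.cells_per_time_point <= 0:
            raise ValueError("cells_per_time_point must be positive")
        if self.subpopulation_profiles:
            roles = set(self.subpopulation_profiles)
            if roles != set(ROLES):
                raise ValueError(
                    f"exactly the six roles {ROLES} must be defined, got {sorted(roles)}"
                )

    def validate(self) -> None:
        """Check mixture-weight and control-condition invariants."""
        for day in self.time_points_days:
            w = emergence_schedule(self, day)
            if (w < 0).any():
                raise ValueError(f"negative emergence weight at day {day}")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"emergence weights at day {day} sum to {w.sum()}")
        w0 = emergence_schedule(self, self.time_points_days[0])
        if abs(w0[HEALTHY] - 1.0) > 1e-12:
            raise ValueError("time point 0 must contain only the healthy role")


def default_scenario(
    cells_per_time_point: int = 1200,
    rng_seed: int = 0,
    sigma_measurement: float = 0.05,
    sigma_biological: float = 0.10,
    sigma_log_area: float = 0.10,
) -> SyntheticScenario:
    """Build the default 13-day, 16-marker, six-role scenario.

    Passing ``sigma_measurement=0`` (with the other sigmas untouched) keeps
    biological dispersion but removes measurement noise, so the recorded
    mean x area == total identity is exact.
    """
    profiles: Dict[str, SubpopProfile] = {}
    for role in ROLES:
        af = _AREA_FACTOR[role]
        kinetics = {}
        for m in DEFAULT_MARKERS:
            base_total = _BASE_MEAN[m] * BASE_AREA_PX

            def total_curve(day: float, role=role, m=m, base_total=base_total) -> float:
                # marker state is a property of the role, not the day; only
                # p21 carries an explicit day curve (spike/decline/re-rise)
                if m == "p21":
                    f = _p21_curve(role, day)
                else:
                    f = _TOTAL_FACTOR.get(role, {}).get(m, 1.0)
                return base_total * f

            base_cyto = 0.4 * _BASE_MEAN[m]

            def cyto_curve(day: float, role=role, m=m, base_cyto=base_cyto) -> float:
                return base_cyto * _CYTO_FACTOR.get(role, {}).get(m, 1.0)

            kinetics[m] = (total_curve, cyto_curve)

        def area_curve(day: float, af=af, role=role) -> float:
            if role == HEALTHY:
                return BASE_AREA_PX
            return BASE_AREA_PX * (1.0 + (af - 1.0) * _area_ramp(day))

        def weight(day: float, role=role) -> float:
            return _DEFAULT_SCHEDULE[role].get(int(day), 0.0)

        profiles[role] = SubpopProfile(area_curve, kinetics, weight)

    return SyntheticScenario(
        cells_per_time_point=cells_per_time_point,
        subpopulation_profiles=profiles,
        rng_seed=rng_seed,
        sigma_log_area=sigma_log_area,
        sigma_biological=sigma_biological,
        sigma_measurement=sigma_measurement,
    )


def emergence_schedule(scenario: SyntheticScenario, day: int) -> pd.Series:
    """Role mixture weights at ``day``.

    Raises ``ValueError`` if ``day`` is not one of the scenario's time points.
    """
    if day not in scenario.time_points_days:
        raise ValueError(
            f"day {day} is not a scenario time point {tuple(scenario.time_points_days)}"
        )
    profiles = scenario.subpopulation_profiles or default_scenario().subpopulation_profiles
    w = pd.Series({role: float(profiles[role].emergence_weight(day)) for role in ROLES})
    return w


def feature_columns(marker_names: Sequence[str] = DEFAULT_MARKERS) -> List[str]:
    """Measurement columns of the per-cell feature table, in canonical order."""
    cols = ["nuclear_area_px"]
    for m in marker_names:
        cols += [f"{m}_nuc_mean", f"{m}_nuc_total", f"{m}_cyto_mean"]
    return cols


def sample_cells(
    scenario: SyntheticScenario,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sample the per-cell feature table and its ground-truth twin.

    Returns ``(features, truth)``; rows are aligned one-to-one.  ``truth``
    carries the role label and the noise-free values.  Measurement noise is a
    single multiplicative lognormal factor applied to each (cell, marker)
    intensity field, so the recorded total remains exactly area x mean.
    """
    scenario.validate()
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    profiles = scenario.subpopulation_profiles
    markers = list(scenario.marker_names)
    n = scenario.cells_per_time_point

    feat_rows, truth_rows = [], []
    cell_id = 0
    for day in scenario.time_points_days:
        w = emergence_schedule(scenario, day)
        counts = rng.multinomial(n, w.to_numpy())
        for role, k in zip(ROLES, counts):
            if k == 0:
                continue
            prof = profiles[role]
            parent = profiles[_PARENT.get(role, role)]
            u = _draw_progress(role, k, rng)
            # log-interpolate between the parent state and the full role
            # state, then additive Gaussian on log-area (biological dispersion)
            log_area = u * np.log(prof.area_curve(day)) \
                + (1 - u) * np.log(parent.area_curve(day))
            area = np.exp(log_area + rng.normal(0.0, scenario.sigma_log_area, k))
            area = np.maximum(np.round(area), 1.0)

            feats = {"day": np.full(k, day), "nuclear_area_px": area}
            truths = {"day": np.full(k, day), "role": np.full(k, role, dtype=object),
                      "nuclear_area_px": area, "progress": u}
            for m in markers:
                total_curve, cyto_curve = prof.marker_kinetics[m]
                p_total_curve, p_cyto_curve = parent.marker_kinetics[m]
                log_total = u * np.log(total_curve(day)) \
                    + (1 - u) * np.log(p_total_curve(day))
                total = np.exp(log_total
                               + rng.normal(0.0, scenario.sigma_biological, k))
                mean = total / area
                log_cyto = u * np.log(cyto_curve(day)) \
                    + (1 - u) * np.log(p_cyto_curve(day))
                cyto = np.exp(log_cyto
                              + rng.normal(0.0, scenario.sigma_biological, k))
                truths[f"{m}_nuc_total"] = total
                truths[f"{m}_nuc_mean"] = mean
                truths[f"{m}_cyto_mean"] = cyto
                # measurement noise: one factor on the nuclear intensity
                # field (total derives from the noisy mean), one on the ring
                eps = np.exp(rng.normal(0.0, scenario.sigma_measurement, k))
                eps_c = np.exp(rng.normal(0.0, scenario.sigma_measurement, k))
                mean_obs = mean * eps
                feats[f"{m}_nuc_mean"] = mean_obs
                feats[f"{m}_nuc_total"] = mean_obs * area
                feats[f"{m}_cyto_mean"] = cyto * eps_c
            feat_rows.append(pd.DataFrame(feats))
            truth_rows.append(pd.DataFrame(truths))
        cell_id += n

    features = pd.concat(feat_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    features.insert(0, "cell_id", np.arange(1, len(features) + 1))
    truth.insert(0, "cell_id", features["cell_id"].to_numpy())
    # canonical column order
    features = features[["cell_id", "day"] + feature_columns(markers)]
    return features, truth


# ---------------------------------------------------------------------------
# phantom image rendering
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A rendered phantom field: labeled mask, per-round channel images with
    known inter-round shifts, and the pixel-exact ground truth table."""

    mask: np.ndarray                          # uint16 labels, 0 = background
    rounds: List[Dict[str, np.ndarray]]       # each round: marker -> image (incl. "DNA")
    offsets: List[Tuple[int, int]]            # (dy, dx) applied to each round
    truth: pd.DataFrame                       # per-label true area/mean/total/cyto
    ring_width: int = 5


def _shift_int(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def render_scene(
    scenario: SyntheticScenario,
    day: int,
    field_size: Tuple[int, int] = (512, 512),
    n_cells: int = 12,
    round_layout: Optional[List[List[str]]] = None,
    offsets: Optional[List[Tuple[int, int]]] = None,
    image_noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Scene:
    """Render a phantom imaging field for ``day``.

    Nuclei are non-overlapping ellipses with uniform intensity equal to the
    cell's true nuclear mean; a surrounding cytoplasm band (Chebyshev width 5,
    matching the quantification ring) carries the true cytoplasmic mean.
    Nuclei are placed with >= 2*ring_width+1 px Chebyshev clearance so rings
    never collide, and fully inside the field.  Per-round global integer
    translations make registration testable.

    Raises ``RuntimeError`` naming the number actually placed when the field
    cannot fit ``n_cells``.
    """
    from scipy import ndimage as ndi

    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed + 10_000 + day)
    if day not in scenario.time_points_days:
        raise ValueError(f"day {day} is not a scenario time point")
    markers = list(scenario.marker_names)
    if round_layout is None:
        # three channels per round alongside the DNA reference channel
        round_layout = [markers[i:i + 3] for i in range(0, len(markers), 3)]
    if offsets is None:
        offsets = [(0, 0)] * len(round_layout)
    if len(offsets) != len(round_layout):
        raise ValueError("one (dy, dx) offset required per round")

    h, w = field_size
    ring = 5
    mask = np.zeros((h, w), dtype=np.uint16)
    occupied = np.zeros((h, w), dtype=bool)   # nuclei dilated by clearance

    weights = emergence_schedule(scenario, day).to_numpy()
    roles_drawn = rng.choice(len(ROLES), size=n_cells, p=weights)
    profiles = scenario.subpopulation_profiles

    placed, rows = 0, []
    clearance = 2 * ring + 1
    for i in range(n_cells):
        role = ROLES[roles_drawn[i]]
        prof = profiles[role]
        target_area = prof.area_curve(day) * np.exp(
            rng.normal(0.0, scenario.sigma_log_area))
        q = rng.uniform(0.7, 1.0)             # axis ratio
        a = np.sqrt(target_area / (np.pi * q))
        b = q * a
        ok = False
        for _ in range(200):                  # rejection placement
            margin = int(np.ceil(max(a, b))) + ring + 1
            if 2 * margin >= min(h, w):
                break
            cy = rng.integers(margin, h - margin)
            cx = rng.integers(margin, w - margin)
            rr, cc = _ellipse_pixels(cy, cx, a, b, (h, w))
            if rr.size == 0:
                continue
            box = np.zeros((h, w), dtype=bool)
            box[rr, cc] = True
            grown = ndi.binary_dilation(box, structure=np.ones((clearance, clearance)))
            if not (grown & occupied).any():
                label = placed + 1
                mask[rr, cc] = label
                occupied |= grown
                rows.append({"cell_id": label, "day": day, "role": role,
                             "nuclear_area_px": float(rr.size)})
                placed += 1
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n_cells} nuclei in field {field_size}; "
                f"placed {placed}")

    truth = pd.DataFrame(rows)
    # true per-cell intensities; the drawn pixel count is the true area
    for m in markers:
        means, cytos, totals = [], [], []
        for r in rows:
            prof = profiles[r["role"]]
            total_curve, cyto_curve = prof.marker_kinetics[m]
            mean = (total_curve(day) / prof.area_curve(day)) * np.exp(
                rng.normal(0.0, scenario.sigma_biological))
            cyto = cyto_curve(day) * np.exp(rng.normal(0.0, scenario.sigma_biological))
            means.append(mean)
            cytos.append(cyto)
            totals.append(mean * r["nuclear_area_px"])
        truth[f"{m}_nuc_mean"] = means
        truth[f"{m}_nuc_total"] = totals
        truth[f"{m}_cyto_mean"] = cytos

    # cytoplasm band: Chebyshev dilation of each nucleus minus all nuclei;
    # clearance placement guarantees bands are disjoint
    nuclei = mask > 0
    struct = np.ones((2 * ring + 1, 2 * ring + 1), dtype=bool)
    band_of = {}
    for label in truth["cell_id"]:
        cell = mask == label
        band = ndi.binary_dilation(cell, structure=struct) & ~nuclei
        band_of[label] = band

    rounds_out: List[Dict[str, np.ndarray]] = []
    for rnd, chans in enumerate(round_layout):
        dy, dx = offsets[rnd]
        imgs: Dict[str, np.ndarray] = {}
        dna = np.zeros((h, w), dtype=float)
        dna[nuclei] = 1000.0
        imgs["DNA"] = dna
        for m in chans:
            img = np.zeros((h, w), dtype=float)
            for _, r in truth.iterrows():
                label = int(r["cell_id"])
                img[mask == label] = r[f"{m}_nuc_mean"]
                img[band_of[label]] = r[f"{m}_cyto_mean"]
            imgs[m] = img
        for key in list(imgs):
            shifted = _shift_int(imgs[key], dy, dx)
            if image_noise_sigma > 0:
                shifted = shifted + rng.normal(0.0, image_noise_sigma, shifted.shape)
            imgs[key] = shifted
        rounds_out.append(imgs)

    return Scene(mask=mask, rounds=rounds_out, offsets=list(offsets), truth=truth)


def _ellipse_pixels(cy: float, cx: float, a: float, b: float,
                    shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    from skimage.draw import ellipse

    return ellipse(cy, cx, a, b, shape=shape)


def write_scenario(scenario: SyntheticScenario, path: str) -> None:
    """Serialize the scenario's scalar configuration (not its curves) to YAML."""
    import yaml

    cfg = {
        "time_points_days": list(scenario.time_points_days),
        "cells_per_time_point": scenario.cells_per_time_point,
        "marker_names": list(scenario.marker_names),
        "rng_seed": scenario.rng_seed,
        "sigma_log_area": scenario.sigma_log_area,
        "sigma_biological": scenario.sigma_biological,
        "sigma_measurement": scenario.sigma_measurement,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
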