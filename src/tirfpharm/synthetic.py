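"""Ground-truthed synthetic data for every analysis stage.

This module emulates the four kinds of raw data the downstream analyses
consume, each with the statistical structure those analyses assume:

* TIRF-like fields: a dark background with a smooth low-frequency
  non-uniformity, one or more cell-shaped foreground plateaus, bright
  sub-resolution puncta (isotropic Gaussians) on the cell area, Poisson
  shot noise plus Gaussian read noise, quantized to 16 bits.
* Four-parameter-logistic (4PL) dose-response plates with multiplicative
  noise and saturating positive-control wells.
* One-site saturation radioligand binding with a linear nonspecific
  component, grouped by condition and day (lognormal day effect on Bmax),
  with optional competitive or noncompetitive inhibitors.
* One-compartment oral-absorption pharmacokinetic profiles.

Every generator is deterministic given its spec's ``seed``: identical
specs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "RawField",
    "NoiseModel",
    "AssaySpec",
    "Inhibitor",
    "BindingSpec",
    "PKSpec",
    "PlacementError",
    "generate_field",
    "generate_dose_response",
    "generate_binding",
    "generate_pk_profile",
    "four_pl",
]

U16_MAX = 65535


class PlacementError(RuntimeError):
    """Requested non-overlapping geometry could not be placed."""


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise on expected counts, then additive
    Gaussian read noise (sd in 16-bit units)."""

    shot: bool = True
    read_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.read_sd < 0:
            raise ValueError("read_sd must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(shot=False, read_sd=0.0)


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic TIRF field.

    Intensities are in 16-bit camera counts.  ``cell_radius_px`` is the
    mean semi-axis of the elliptical cell footprints; each axis is
    jittered by +/- ``cell_radius_jitter_px``.  Puncta are isotropic
    Gaussians of width ``puncta_sigma_px`` truncated at 4 sigma, with
    peak amplitudes drawn uniformly from ``puncta_amplitude``.
    """

    image_height_px: int = 192
    image_width_px: int = 192
    n_cells: int = 1
    cell_radius_px: float = 45.0
    cell_radius_jitter_px: float = 8.0
    n_puncta_per_cell: int = 10
    puncta_sigma_px: float = 1.5
    puncta_amplitude: tuple[float, float] = (15000.0, 45000.0)
    background_level: float = 500.0
    background_gradient_amplitude: float = 0.0
    background_gradient_sigma_px: float = 80.0
    cell_plateau: float = 12000.0
    cell_edge_sigma_px: float = 3.0
    min_separation_px: float = 0.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.cell_radius_px <= 0 or self.puncta_sigma_px <= 0:
            raise ValueError("radii and sigma must be positive")
        if self.n_puncta_per_cell < 0:
            raise ValueError("n_puncta_per_cell must be nonnegative")
        lo, hi = self.puncta_amplitude
        if not (0 <= lo <= hi <= U16_MAX):
            raise ValueError("puncta_amplitude must satisfy 0 <= lo <= hi <= 65535")
        if not (0 <= self.background_level <= U16_MAX):
            raise ValueError("background_level must lie in [0, 65535]")
        if self.background_gradient_amplitude < 0:
            raise ValueError("background_gradient_amplitude must be >= 0")


@dataclass
class GroundTruth:
    """Everything injected into a synthetic field, for oracle use."""

    puncta_centers: list[tuple[float, float]]
    puncta_amplitudes: list[float]
    cell_masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.puncta_centers) != len(self.puncta_amplitudes):
            raise ValueError("centers and amplitudes must have equal length")

    @property
    def cell_union(self) -> np.ndarray:
        out = np.zeros_like(self.cell_masks[0], dtype=bool)
        for m in self.cell_masks:
            out |= m
        return out


@dataclass
class RawField:
    """A 16-bit single-channel field plus identifying metadata."""

    pixels: np.ndarray
    field_id: str = ""
    treatment_label: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if px.min() < 0 or px.max() > U16_MAX:
            raise ValueError("pixel values must lie in [0, 65535]")
        self.pixels = px.astype(np.uint16)


def _place_ellipses(spec: FieldSpec, rng: np.random.Generator,
                    max_retries: int = 500) -> list[tuple[float, float, float, float]]:
    """Place non-overlapping (cy, cx, ry, rx) ellipses; raises PlacementError."""
    placed: list[tuple[float, float, float, float]] = []
    h, w = spec.image_height_px, spec.image_width_px
    for _ in range(spec.n_cells):
        for _attempt in range(max_retries):
            ry = spec.cell_radius_px + rng.uniform(-1, 1) * spec.cell_radius_jitter_px
            rx = spec.cell_radius_px + rng.uniform(-1, 1) * spec.cell_radius_jitter_px
            ry, rx = max(ry, 3.0), max(rx, 3.0)
            cy = rng.uniform(ry, h - ry) if h > 2 * ry else h / 2
            cx = rng.uniform(rx, w - rx) if w > 2 * rx else w / 2
            # conservative circle test on the larger semi-axes
            ok = all(
                np.hypot(cy - py, cx - px) > max(ry, rx) + max(pry, prx)
                for (py, px, pry, prx) in placed
            )
            if ok:
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"after {max_retries} retries"
            )
    return placed


def _place_puncta(mask: np.ndarray, n: int, min_sep: float,
                  rng: np.random.Generator, max_retries: int = 2000
                  ) -> list[tuple[float, float]]:
    rows, cols = np.nonzero(mask)
    if rows.size == 0 and n > 0:
        raise PlacementError("empty cell footprint cannot hold puncta")
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(max_retries):
            i = rng.integers(0, rows.size)
            r, c = float(rows[i]), float(cols[i])
            if all(np.hypot(r - pr, c - pc) >= min_sep for pr, pc in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place {n} puncta with min separation {min_sep}"
            )
    return centers


def generate_field(spec: FieldSpec) -> tuple[RawField, GroundTruth]:
    """Render one synthetic TIRF field and its ground truth.

    The expected image is ``background + gradient + cell plateaus +
    sum of truncated Gaussian puncta``; shot noise (Poisson on the
    expected counts), read noise (Gaussian) and 16-bit quantization are
    then applied in that order.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    yy, xx = np.mgrid[0:h, 0:w]

    expected = np.full((h, w), float(spec.background_level))
    if spec.background_gradient_amplitude > 0:
        by = rng.uniform(0, h)
        bx = rng.uniform(0, w)
        s2 = 2.0 * spec.background_gradient_sigma_px ** 2
        expected += spec.background_gradient_amplitude * np.exp(
            -((yy - by) ** 2 + (xx - bx) ** 2) / s2
        )

    ellipses = _place_ellipses(spec, rng)
    cell_masks: list[np.ndarray] = []
    plateau = np.zeros((h, w))
    for (cy, cx, ry, rx) in ellipses:
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=(h, w))
        mask[rr, cc] = True
        cell_masks.append(mask)
        plateau[mask] += spec.cell_plateau
    if spec.cell_edge_sigma_px > 0:
        # diffraction-limited optics: the footprint edge falls off smoothly
        plateau = gaussian_filter(plateau, spec.cell_edge_sigma_px)
    expected += plateau

    centers: list[tuple[float, float]] = []
    amplitudes: list[float] = []
    lo, hi = spec.puncta_amplitude
    trunc = 4.0 * spec.puncta_sigma_px
    for mask in cell_masks:
        for (r, c) in _place_puncta(mask, spec.n_puncta_per_cell,
                                    spec.min_separation_px, rng):
            amp = rng.uniform(lo, hi)
            r0, r1 = int(max(0, np.floor(r - trunc))), int(min(h, np.ceil(r + trunc) + 1))
            c0, c1 = int(max(0, np.floor(c - trunc))), int(min(w, np.ceil(c + trunc) + 1))
            ys, xs = np.mgrid[r0:r1, c0:c1]
            d2 = (ys - r) ** 2 + (xs - c) ** 2
            g = amp * np.exp(-d2 / (2.0 * spec.puncta_sigma_px ** 2))
            g[d2 > trunc ** 2] = 0.0
            expected[r0:r1, c0:c1] += g
            centers.append((r, c))
            amplitudes.append(amp)

    img = expected
    if spec.noise_model.shot:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_model.read_sd > 0:
        img = img + rng.normal(0.0, spec.noise_model.read_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)

    raw = RawField(pixels=pixels, field_id=f"synthetic-{spec.seed}")
    return raw, GroundTruth(centers, amplitudes, cell_masks)


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

def four_pl(conc: np.ndarray | float, bottom: float, top: float,
            ec50: float, hill: float) -> np.ndarray | float:
    """Four-parameter logistic: bottom + (top-bottom)/(1 + (EC50/c)^hill)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)


@dataclass(frozen=True)
class AssaySpec:
    """An 11-point half-log dose-response plate design.

    Concentrations are centred on the true EC50:
    ``log10(c_i) = true_log10_ec50 + spacing * (i - (n_points-1)/2)``.
    Noise is multiplicative: ``response * (1 + eps)``, eps ~ N(0, cv).
    A saturating positive-control concentration is included on every
    replicate (the plate's full-agonist reference wells).
    """

    true_bottom: float = 0.0
    true_top: float = 100.0
    true_log10_ec50: float = -8.0
    true_hill: float = 1.0
    n_points: int = 11
    spacing: float = 0.5
    n_replicates: int = 3
    cv_noise: float = 0.05
    control_conc_molar: float = 5e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if self.true_hill == 0:
            raise ValueError("true_hill must be nonzero")

    @property
    def concentrations(self) -> np.ndarray:
        offsets = np.arange(self.n_points) - (self.n_points - 1) / 2.0
        return 10.0 ** (self.true_log10_ec50 + self.spacing * offsets)


def generate_dose_response(spec: AssaySpec) -> pd.DataFrame:
    """Simulate a plate: columns conc_molar, response, replicate, role."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_replicates):
        for c in spec.concentrations:
            mu = four_pl(c, spec.true_bottom, spec.true_top,
                         10.0 ** spec.true_log10_ec50, spec.true_hill)
            eps = rng.normal(0.0, spec.cv_noise) if spec.cv_noise > 0 else 0.0
            rows.append((c, float(mu) * (1.0 + eps), rep, "test"))
        mu = four_pl(spec.control_conc_molar, spec.true_bottom, spec.true_top,
                     10.0 ** spec.true_log10_ec50, spec.true_hill)
        eps = rng.normal(0.0, spec.cv_noise) if spec.cv_noise > 0 else 0.0
        rows.append((spec.control_conc_molar, float(mu) * (1.0 + eps),
                     rep, "positive_control"))
    return pd.DataFrame(rows, columns=["conc_molar", "response",
                                       "replicate", "role"])


# ---------------------------------------------------------------------------
# saturation binding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Inhibitor:
    """Inhibitor acting on one binding group.

    mode "competitive": apparent Kd is multiplied by (1 + conc/Ki)
    (the classic Cheng-Prusoff shift); mode "noncompetitive": Bmax is
    multiplied by (1 - fraction_blocked).
    """

    mode: str
    ki_nM: float = 1.0
    conc_nM: float = 0.0
    fraction_blocked: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("competitive", "noncompetitive"):
            raise ValueError("mode must be 'competitive' or 'noncompetitive'")
        if self.mode == "competitive" and (self.ki_nM <= 0 or self.conc_nM < 0):
            raise ValueError("competitive mode needs ki_nM > 0, conc_nM >= 0")
        if not (0.0 <= self.fraction_blocked <= 1.0):
            raise ValueError("fraction_blocked must lie in [0, 1]")


# spec: 8 points, 0.2-15 nM, as used in the saturation-with-inhibitor design
DEFAULT_LIGAND_CONCS = tuple(np.geomspace(0.2, 15.0, 8).round(4))


@dataclass(frozen=True)
class BindingSpec:
    """Grouped one-site saturation binding with nonspecific background."""

    kd_true: float = 1.3
    bmax_true: float = 1000.0
    ns_slope: float = 10.0
    ligand_concs: tuple[float, ...] = DEFAULT_LIGAND_CONCS
    groups: tuple[tuple[str, Inhibitor | None], ...] = (("total", None),)
    days_per_group: int = 3
    day_effect_sd: float = 0.1
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_true <= 0 or self.bmax_true <= 0:
            raise ValueError("kd_true and bmax_true must be positive")
        if any(c <= 0 for c in self.ligand_concs):
            raise ValueError("all ligand concentrations must be positive")
        if self.days_per_group < 1:
            raise ValueError("days_per_group must be >= 1")
        if self.day_effect_sd < 0 or self.noise_cv < 0:
            raise ValueError("day_effect_sd and noise_cv must be >= 0")


def generate_binding(spec: BindingSpec) -> pd.DataFrame:
    """Simulate counts: columns group, day, ligand_conc_nM, condition, counts.

    condition is "total" (specific + nonspecific) or "nsb" (nonspecific
    only, i.e. the saturating-blocker wells).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, inhibitor in spec.groups:
        kd_app = spec.kd_true
        bmax_grp = spec.bmax_true
        if inhibitor is not None:
            if inhibitor.mode == "competitive":
                kd_app = spec.kd_true * (1.0 + inhibitor.conc_nM / inhibitor.ki_nM)
            else:
                bmax_grp = spec.bmax_true * (1.0 - inhibitor.fraction_blocked)
        for day in range(spec.days_per_group):
            day_mult = (np.exp(rng.normal(0.0, spec.day_effect_sd))
                        if spec.day_effect_sd > 0 else 1.0)
            bmax_day = bmax_grp * day_mult
            for L in spec.ligand_concs:
                specific = bmax_day * L / (L + kd_app)
                ns = spec.ns_slope * L
                for condition, mu in (("total", specific + ns), ("nsb", ns)):
                    eps = (rng.normal(0.0, spec.noise_cv)
                           if spec.noise_cv > 0 else 0.0)
                    rows.append((label, day, float(L), condition,
                                 mu * (1.0 + eps)))
    return pd.DataFrame(rows, columns=["group", "day", "ligand_conc_nM",
                                       "condition", "counts"])


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------

class DegenerateKineticsError(ValueError):
    """ka == ke makes the standard oral-absorption closed form singular."""


@dataclass(frozen=True)
class PKSpec:
    """One-compartment oral-absorption PK with repeated dosing.

    Doses are mg/kg; concentrations are reported as total brain nM via
    the brain-to-plasma ratio and molar mass.  The unbound brain
    fraction ``fu_b`` is carried as metadata for occupancy projection
    and is not applied here.
    """

    dose_times_h: tuple[float, ...] = (0.0,)
    doses_mg_per_kg: tuple[float, ...] = (1.0,)
    ka_per_h: float = 1.5
    ke_per_h: float = 0.3
    vd_l_per_kg: float = 5.0
    brain_to_plasma_ratio: float = 1.0
    fu_b: float = 0.02
    mol_weight_g_per_mol: float = 350.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dose_times_h) != len(self.doses_mg_per_kg):
            raise ValueError("dose_times_h and doses_mg_per_kg lengths differ")
        if min(self.ka_per_h, self.ke_per_h, self.vd_l_per_kg) <= 0:
            raise ValueError("ka, ke, vd must be positive")
        if not (0 < self.fu_b <= 1):
            raise ValueError("fu_b must lie in (0, 1]")
        if self.ka_per_h == self.ke_per_h:
            raise DegenerateKineticsError("ka == ke is not supported")


def generate_pk_profile(spec: PKSpec,
                        t_grid_h: Sequence[float] | None = None) -> pd.DataFrame:
    """Deterministic superposition of single-dose Bateman curves.

    Returns columns time_h, c_total_brain_nM.
    """
    if t_grid_h is None:
        t_end = max(spec.dose_times_h) + 24.0
        t_grid_h = np.linspace(0.0, t_end, 241)
    t = np.asarray(t_grid_h, dtype=float)
    ka, ke, vd = spec.ka_per_h, spec.ke_per_h, spec.vd_l_per_kg
    c_plasma = np.zeros_like(t)
    for t0, dose in zip(spec.dose_times_h, spec.doses_mg_per_kg):
        dt = t - t0
        active = dt > 0
        term = np.zeros_like(t)
        term[active] = (dose / vd) * ka / (ka - ke) * (
            np.exp(-ke * dt[active]) - np.exp(-ka * dt[active])
        )
        c_plasma += term  # mg/L
    c_brain_nM = (c_plasma / spec.mol_weight_g_per_mol) * 1e6 \
        * spec.brain_to_plasma_ratio
    return pd.DataFrame({"time_h": t, "c_total_brain_nM": c_brain_nM})


def spec_to_dict(spec) -> dict:
    """Serializable view of any generator spec (for manifests/configs)."""
    d = dataclasses.asdict(spec)
    return d
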