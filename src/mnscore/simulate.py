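"""Synthetic peripheral-blood-smear simulator with per-cell ground truth.

Renders tiled smear fields in two stain modalities:

* ``fluorescence`` — a two-channel field (cell body + DNA) emulating a
  Hoechst-stained smear in which enucleated red cells carry no nuclear DNA
  and micronuclei appear as small, bright DNA foci inside the cell body.
* ``brightfield_mgg`` — an RGB field emulating a May-Grünwald-Giemsa
  (Romanowsky) stained smear: mature normochromic erythrocytes (NCEs) stain
  salmon-pink with central pallor, reticulocytes (RETs) stain a bluish-grey
  hue and run slightly larger, micronuclei and leukocyte nuclei stain purple.

Every rendered cell is recorded in a ground-truth table (class, micronucleus
count, position, size, shape), so segmentation and classification can be
scored against a known answer.  Rendering uses smooth radial intensity
profiles plus additive Gaussian noise; it is deliberately simple — enough to
exercise threshold-based segmentation, chromatic classification and the
object-separation chain, not to look photorealistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError

MODALITY_FLUORESCENCE = "fluorescence"
MODALITY_MGG = "brightfield_mgg"
MODALITIES = (MODALITY_FLUORESCENCE, MODALITY_MGG)

# truth "class" labels (modality-independent base populations)
CLASS_RBC = "RBC"
CLASS_WBC = "WBC"
CLASS_PLATELET = "PLATELET"

MORPH_NORMAL = "normal"
MORPH_ECHINOCYTE = "echinocyte"
MORPH_ELONGATED = "elongated"

TRUTH_COLUMNS = [
    "field_id", "cell_id", "class", "mn_count",
    "x_px", "y_px", "diameter_um", "aspect_ratio", "morphology", "is_ret",
]


@dataclass
class DegradationRates:
    """Fractions of (non-reticulocyte) RBCs showing storage-degradation shapes."""

    echinocyte_fraction: float = 0.0
    elongated_fraction: float = 0.0


@dataclass
class NoiseModel:
    """Additive Gaussian noise on top of a flat background."""

    background_level: float = 0.05
    sd: float = 0.02


@dataclass
class SimulationConfig:
    """Population and rendering parameters for one simulated smear field.

    The population defaults are the baseline conditions of a healthy mouse
    peripheral smear: a spontaneous micronucleated-RBC fraction of 0.139%
    and a reticulocyte fraction of 1.46% of circulating RBCs.
    """

    modality: str = MODALITY_FLUORESCENCE
    field_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.25          # typical 40x scanner resolution
    n_cells_target: int = 600
    p_mn: float = 0.00139                # P(RBC carries >=1 micronucleus)
    p_multi_given_mn: float = 0.0        # P(>=2 foci | MN-positive)
    ret_fraction: float = 0.0146         # reticulocytes among RBCs
    wbc_fraction: float = 0.002
    platelet_fraction: float = 0.02
    rbc_diameter_um: tuple[float, float] = (5.5, 0.5)   # (mean, sd)
    ret_diameter_scale: float = 1.25     # RETs are slightly larger than NCEs
    mn_diameter_um: tuple[float, float] = (1.0, 0.2)
    mn_pos_diameter_scale: float = 1.15  # MN+ cells run larger than MN-
    overlap_fraction: float = 0.0        # fraction of cells placed touching
    degradation: DegradationRates = dc_field(default_factory=DegradationRates)
    noise: NoiseModel = dc_field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigError(f"unknown modality {self.modality!r}")
        rows, cols = self.field_size_px
        if rows < 32 or cols < 32:
            raise ConfigError("field_size_px too small to place a cell")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.n_cells_target < 0:
            raise ConfigError("n_cells_target must be >= 0")
        for name in ("p_mn", "p_multi_given_mn", "ret_fraction",
                     "wbc_fraction", "platelet_fraction", "overlap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.wbc_fraction + self.platelet_fraction > 1.0:
            raise ConfigError("wbc_fraction + platelet_fraction exceed 1")
        d = self.degradation
        if not (0.0 <= d.echinocyte_fraction <= 1.0 and
                0.0 <= d.elongated_fraction <= 1.0):
            raise ConfigError("degradation fractions outside [0, 1]")
        if d.echinocyte_fraction + d.elongated_fraction > 1.0:
            raise ConfigError("degradation fractions exceed 1 combined")
        if self.ret_diameter_scale <= 1.0:
            raise ConfigError("ret_diameter_scale must be > 1")
        if self.rbc_diameter_um[0] <= 0 or self.mn_diameter_um[0] <= 0:
            raise ConfigError("diameters must be positive")

    @property
    def n_channels(self) -> int:
        return 2 if self.modality == MODALITY_FLUORESCENCE else 3

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.modality == MODALITY_FLUORESCENCE:
            return ("cell_body", "dna")
        return ("R", "G", "B")


@dataclass
class SmearField:
    """One raster field: ``raster`` is (rows, cols, channels) float32 in [0, 1]."""

    raster: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    provenance: str = "simulated"
    field_id: str = "field000"

    def __post_init__(self) -> None:
        if self.raster.ndim != 3 or self.raster.shape[2] != len(self.channels):
            raise ConfigError("raster channel count must match channel names")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            from .errors import ChannelError
            raise ChannelError(
                f"field {self.field_id} has channels {self.channels}, not {name!r}")
        return self.raster[:, :, idx]


@dataclass
class SimulationTruth:
    """Ground-truth table plus the injected parameters."""

    records: pd.DataFrame
    config: SimulationConfig
    totals: dict[str, int]

    @classmethod
    def from_records(cls, records: pd.DataFrame,
                     config: SimulationConfig) -> "SimulationTruth":
        totals = records["class"].value_counts().to_dict()
        return cls(records=records, config=config,
                   totals={str(k): int(v) for k, v in totals.items()})

    @property
    def n_cells(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def sample_population(config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-cell attributes (class, morphology, MN status, size).

    This is the statistical half of the simulator; rendering consumes its
    output.  Exposed separately so population calibration can be checked
    cheaply at large n without rasterising.
    """
    n = config.n_cells_target
    u = rng.random(n)
    is_wbc = u < config.wbc_fraction
    is_plt = (~is_wbc) & (u < config.wbc_fraction + config.platelet_fraction)
    is_rbc = ~(is_wbc | is_plt)

    is_ret = is_rbc & (rng.random(n) < config.ret_fraction)

    # storage-degradation morphologies affect mature (non-RET) RBCs
    m = rng.random(n)
    deg = config.degradation
    is_ech = is_rbc & ~is_ret & (m < deg.echinocyte_fraction)
    is_elo = (is_rbc & ~is_ret & ~is_ech
              & (m < deg.echinocyte_fraction + deg.elongated_fraction))

    has_mn = is_rbc & (rng.random(n) < config.p_mn)
    multi = has_mn & (rng.random(n) < config.p_multi_given_mn)
    mn_count = np.where(multi, 2, np.where(has_mn, 1, 0))

    mu, sd = config.rbc_diameter_um
    diam = np.clip(rng.normal(mu, sd, n), 4.0, 7.0)
    diam = np.where(is_ret, np.minimum(diam * config.ret_diameter_scale, 7.8), diam)
    diam = np.where(has_mn, np.minimum(diam * config.mn_pos_diameter_scale, 7.8), diam)
    diam = np.where(is_wbc, np.clip(rng.normal(10.0, 1.0, n), 8.0, 13.0), diam)
    diam = np.where(is_plt, np.clip(rng.normal(2.2, 0.3, n), 1.5, 3.0), diam)

    aspect = np.ones(n)
    aspect[is_elo] = rng.uniform(2.6, 4.0, int(is_elo.sum()))

    cls = np.where(is_wbc, CLASS_WBC, np.where(is_plt, CLASS_PLATELET, CLASS_RBC))
    morph = np.where(is_ech, MORPH_ECHINOCYTE,
                     np.where(is_elo, MORPH_ELONGATED, MORPH_NORMAL))

    return pd.DataFrame({
        "class": cls,
        "is_ret": is_ret,
        "morphology": morph,
        "mn_count": mn_count.astype(int),
        "diameter_um": diam,
        "aspect_ratio": aspect,
    })


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

_EDGE_MARGIN_PX = 4      # keep cells clear of the field border
_CONTACT_GAP_PX = 5.0    # minimum surface gap between non-touching cells


def _place_cells(radii_px: np.ndarray, shape: tuple[int, int],
                 overlap_fraction: float, rng: np.random.Generator,
                 max_attempts_per_cell: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample cell centres; a configured fraction touch a neighbour."""
    rows, cols = shape
    n = len(radii_px)
    ys = np.empty(n)
    xs = np.empty(n)
    touch = rng.random(n) < overlap_fraction
    for i in range(n):
        r = radii_px[i]
        lo_y, hi_y = r + _EDGE_MARGIN_PX, rows - r - _EDGE_MARGIN_PX - 1
        lo_x, hi_x = r + _EDGE_MARGIN_PX, cols - r - _EDGE_MARGIN_PX - 1
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PlacementError(
                f"field {shape} too small for a cell of radius {r:.1f}px")
        placed = False
        for _ in range(max_attempts_per_cell):
            if touch[i] and i > 0:
                j = int(rng.integers(0, i))
                ang = rng.uniform(0, 2 * np.pi)
                d = 0.85 * (r + radii_px[j])
                y = ys[j] + d * np.sin(ang)
                x = xs[j] + d * np.cos(ang)
                if not (lo_y <= y <= hi_y and lo_x <= x <= hi_x):
                    continue
                dy = ys[:i] - y
                dx = xs[:i] - x
                dist = np.hypot(dy, dx)
                limit = radii_px[:i] + r + _CONTACT_GAP_PX
                mask = np.ones(i, bool)
                mask[j] = False
                if np.all(dist[mask] >= limit[mask]):
                    placed = True
                    break
            else:
                y = rng.uniform(lo_y, hi_y)
                x = rng.uniform(lo_x, hi_x)
                if i == 0:
                    placed = True
                    break
                dist = np.hypot(ys[:i] - y, xs[:i] - x)
                if np.all(dist >= radii_px[:i] + r + _CONTACT_GAP_PX):
                    placed = True
                    break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} in a {shape} field; "
                "reduce n_cells_target or enlarge field_size_px")
        ys[i], xs[i] = y, x
    return ys, xs


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _crop(shape, cy, cx, rad):
    r0 = max(int(np.floor(cy - rad)), 0)
    r1 = min(int(np.ceil(cy + rad)) + 1, shape[0])
    c0 = max(int(np.floor(cx - rad)), 0)
    c1 = min(int(np.ceil(cx + rad)) + 1, shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), yy - cy, xx - cx


def _cell_shape_field(cell, cy, cx, shape):
    """Return (crop slices, edge, rho_norm) for the cell's outline.

    ``edge`` ramps 0→1 over ~1 px at the boundary; ``rho_norm`` is the
    normalised radial coordinate (0 centre, 1 boundary) used for pallor.
    """
    r = cell["radius_px"]
    aspect = cell["aspect_ratio"]
    if cell["morphology"] == MORPH_ELONGATED and aspect > 1.0:
        a = r * np.sqrt(aspect)     # area-preserving ellipse semi-axes
        b = r / np.sqrt(aspect)
        sl, dy, dx = _crop(shape, cy, cx, a + 2)
        phi = cell["angle"]
        xr = dx * np.cos(phi) + dy * np.sin(phi)
        yr = -dx * np.sin(phi) + dy * np.cos(phi)
        q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        edge = np.clip((1.0 - q) * b, 0.0, 1.0)
        return sl, edge, q
    if cell["morphology"] == MORPH_ECHINOCYTE:
        amp, k = 0.22, cell["n_spicules"]
        sl, dy, dx = _crop(shape, cy, cx, r * (1 + amp) + 2)
        rho = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        rb = r * (1.0 + amp * np.cos(k * (theta - cell["angle"])))
        edge = np.clip(rb - rho, 0.0, 1.0)
        return sl, edge, rho / r
    sl, dy, dx = _crop(shape, cy, cx, r + 2)
    rho = np.hypot(dy, dx)
    edge = np.clip(r - rho, 0.0, 1.0)
    return sl, edge, rho / max(r, 1e-6)


def _mn_offsets(cell, rng):
    """Focus centres (dy, dx) strictly inside the host body."""
    r_host = cell["radius_px"]
    if cell["morphology"] == MORPH_ELONGATED:
        r_host = cell["radius_px"] / np.sqrt(cell["aspect_ratio"])
    elif cell["morphology"] == MORPH_ECHINOCYTE:
        r_host = cell["radius_px"] * (1 - 0.22)
    r_mn = cell["mn_radius_px"]
    max_off = max(r_host - r_mn - 2.5, 0.0)
    k = cell["mn_count"]
    if k <= 1:
        d = rng.uniform(0, max_off)
        ang = rng.uniform(0, 2 * np.pi)
        return [(d * np.sin(ang), d * np.cos(ang))]
    off = np.clip(0.55 * max_off, min(r_mn + 2.0, max_off), max_off)
    ang = rng.uniform(0, 2 * np.pi)
    return [(off * np.sin(ang), off * np.cos(ang)),
            (-off * np.sin(ang), -off * np.cos(ang))]


# stain colours as optical densities subtracted from the bright background
_MGG_OD = {
    "nce": np.array([0.12, 0.30, 0.30]),
    "ret": np.array([0.33, 0.30, 0.18]),
    "wbc_body": np.array([0.10, 0.15, 0.10]),
    "wbc_nucleus": np.array([0.40, 0.65, 0.25]),
    "mn": np.array([0.30, 0.55, 0.20]),
    "platelet": np.array([0.20, 0.35, 0.15]),
}
_MGG_BACKGROUND = 0.92


def _render_fluorescence(raster, cells, rng):
    body = raster[:, :, 0]
    dna = raster[:, :, 1]
    shape = body.shape
    for cell in cells:
        cy, cx = cell["y_px"], cell["x_px"]
        if cell["class"] == CLASS_WBC:
            sl, edge, _rho = _cell_shape_field(cell, cy, cx, shape)
            body[sl] += 0.70 * edge
            rn = 0.62 * cell["radius_px"]
            sln, dyn, dxn = _crop(shape, cy, cx, rn + 2)
            dna[sln] += 0.85 * np.clip(rn - np.hypot(dyn, dxn), 0.0, 1.0)
            continue
        if cell["class"] == CLASS_PLATELET:
            sl, edge, _rho = _cell_shape_field(cell, cy, cx, shape)
            body[sl] += 0.30 * edge
            continue
        sl, edge, rho = _cell_shape_field(cell, cy, cx, shape)
        pallor = 0.90 - 0.35 * np.exp(-(rho / 0.45) ** 2)  # central pallor dip
        body[sl] += 0.75 * pallor * edge
        for dy, dx in ([] if cell["mn_count"] == 0 else _mn_offsets(cell, rng)):
            rm = cell["mn_radius_px"]
            slm, dym, dxm = _crop(shape, cy + dy, cx + dx, rm + 2)
            # half-pixel halo keeps even the smallest foci above threshold
            dna[slm] += 0.85 * np.clip(rm + 0.5 - np.hypot(dym, dxm), 0.0, 1.0)


def _render_mgg(raster, cells, rng):
    shape = raster.shape[:2]
    for cell in cells:
        cy, cx = cell["y_px"], cell["x_px"]
        if cell["class"] == CLASS_WBC:
            sl, edge, _rho = _cell_shape_field(cell, cy, cx, shape)
            raster[sl[0], sl[1], :] -= edge[..., None] * _MGG_OD["wbc_body"]
            rn = 0.62 * cell["radius_px"]
            sln, dyn, dxn = _crop(shape, cy, cx, rn + 2)
            e = np.clip(rn - np.hypot(dyn, dxn), 0.0, 1.0)
            raster[sln[0], sln[1], :] -= e[..., None] * _MGG_OD["wbc_nucleus"]
            continue
        if cell["class"] == CLASS_PLATELET:
            sl, edge, _rho = _cell_shape_field(cell, cy, cx, shape)
            raster[sl[0], sl[1], :] -= edge[..., None] * _MGG_OD["platelet"]
            continue
        sl, edge, rho = _cell_shape_field(cell, cy, cx, shape)
        if cell["is_ret"]:
            od = _MGG_OD["ret"]
            prof = edge * (1.0 - 0.15 * np.exp(-(rho / 0.45) ** 2))
        else:
            od = _MGG_OD["nce"]
            prof = edge * (1.0 - 0.35 * np.exp(-(rho / 0.45) ** 2))
        raster[sl[0], sl[1], :] -= prof[..., None] * od
        for dy, dx in ([] if cell["mn_count"] == 0 else _mn_offsets(cell, rng)):
            rm = cell["mn_radius_px"]
            slm, dym, dxm = _crop(shape, cy + dy, cx + dx, rm + 2)
            e = np.clip(rm + 0.5 - np.hypot(dym, dxm), 0.0, 1.0)
            raster[slm[0], slm[1], :] -= e[..., None] * _MGG_OD["mn"]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_field(config: SimulationConfig,
                   field_id: str = "field000") -> tuple[SmearField, SimulationTruth]:
    """Render one smear field and its ground-truth table.

    Deterministic for a fixed ``config`` (including ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop = sample_population(config, rng)
    n = len(pop)
    px = config.pixel_size_um

    radii_px = pop["diameter_um"].to_numpy() / 2.0 / px
    # elongated cells occupy their semi-major axis
    elong = pop["morphology"].to_numpy() == MORPH_ELONGATED
    eff = radii_px * np.where(elong, np.sqrt(pop["aspect_ratio"].to_numpy()), 1.0)
    ys, xs = _place_cells(eff, config.field_size_px, config.overlap_fraction, rng)

    mn_mu, mn_sd = config.mn_diameter_um
    cells = []
    for i in range(n):
        cells.append({
            "class": pop["class"].iat[i],
            "is_ret": bool(pop["is_ret"].iat[i]),
            "morphology": pop["morphology"].iat[i],
            "mn_count": int(pop["mn_count"].iat[i]),
            "aspect_ratio": float(pop["aspect_ratio"].iat[i]),
            "radius_px": float(radii_px[i]),
            "mn_radius_px": float(
                np.clip(rng.normal(mn_mu, mn_sd), 0.7, 1.8) / 2.0 / px),
            "y_px": float(ys[i]),
            "x_px": float(xs[i]),
            "angle": float(rng.uniform(0, np.pi)),
            "n_spicules": int(rng.integers(6, 11)),
        })

    rows, cols = config.field_size_px
    nz = config.noise
    if config.modality == MODALITY_FLUORESCENCE:
        raster = np.empty((rows, cols, 2), dtype=np.float64)
        raster[:, :, 0] = nz.background_level
        raster[:, :, 1] = 0.6 * nz.background_level
        _render_fluorescence(raster, cells, rng)
    else:
        raster = np.full((rows, cols, 3), _MGG_BACKGROUND, dtype=np.float64)
        _render_mgg(raster, cells, rng)
    raster += rng.normal(0.0, nz.sd, raster.shape)
    raster = np.clip(raster, 0.0, 1.0).astype(np.float32)

    records = pd.DataFrame({
        "field_id": field_id,
        "cell_id": np.arange(n),
        "class": pop["class"].to_numpy(),
        "mn_count": pop["mn_count"].to_numpy(),
        "x_px": xs,
        "y_px": ys,
        "diameter_um": pop["diameter_um"].to_numpy(),
        "aspect_ratio": pop["aspect_ratio"].to_numpy(),
        "morphology": pop["morphology"].to_numpy(),
        "is_ret": pop["is_ret"].to_numpy(),
    })[TRUTH_COLUMNS]

    field = SmearField(raster=raster, channels=config.channel_names,
                       pixel_size_um=px, provenance="simulated",
                       field_id=field_id)
    return field, SimulationTruth.from_records(records, config)


def field_seeds(master_seed: int, n_fields: int) -> list[int]:
    """Deterministic per-field seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n_fields, np.uint64)]


def simulate_sample(config: SimulationConfig,
                    n_fields: int) -> tuple[list[SmearField], SimulationTruth]:
    """Simulate one blood film as ``n_fields`` independent fields.

    Per-field seeds derive deterministically from ``config.seed``; the
    aggregated truth concatenates the per-field tables.
    """
    if n_fields < 1:
        raise ConfigError("n_fields must be >= 1")
    fields = []
    tables = []
    for i, seed in enumerate(field_seeds(config.seed, n_fields)):
        sub = dataclasses.replace(config, seed=seed)
        f, t = simulate_field(sub, field_id=f"field{i:04d}")
        fields.append(f)
        tables.append(t.records)
    records = pd.concat(tables, ignore_index=True)
    return fields, SimulationTruth.from_records(records, config)


def degrade_sample(config: SimulationConfig, storage_hours: float,
                   temperature_class: str) -> SimulationConfig:
    """Map pre-analytical storage to degradation-morphology rates.

    Echinocyte and elongated-RBC fractions rise monotonically with storage
    time, much faster at room temperature (``"RT"``) than refrigerated
    (``"cold"``); the reticulocyte fraction is left untouched.  The mapping
    is a saturating-exponential increment — a phenomenological stand-in
    calibrated only to the qualitative ordering (RT >> cold, identity at 0 h).
    """
    if storage_hours < 0:
        raise ConfigError("storage_hours must be >= 0")
    if temperature_class not in ("RT", "cold"):
        raise ConfigError("temperature_class must be 'RT' or 'cold'")
    if temperature_class == "RT":
        a_ech, a_elo, tau = 0.12, 0.06, 8.0
    else:
        a_ech, a_elo, tau = 0.02, 0.01, 24.0
    gain = 1.0 - np.exp(-storage_hours / tau)
    base = config.degradation
    new = DegradationRates(
        echinocyte_fraction=min(base.echinocyte_fraction + a_ech * gain, 0.6),
        elongated_fraction=min(base.elongated_fraction + a_elo * gain, 0.6),
    )
    return dataclasses.replace(config, degradation=new)
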