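"""Per-cell classification and micronucleus-focus counting.

Two stain-specific taxonomies plus a degradation-morphology pass:

* fluorescence (Hoechst): MN+-RBC, MN--RBC, WBC, platelet, debris;
* brightfield MGG: MN+/- normochromic erythrocytes (NCEs), MN+/-
  reticulocytes (RETs), WBC;
* degradation (MGG QC pass): NCE, WBC, RET, echinocyte, elongated RBC.

Only the elongation gate (aspect ratio > 2.5) comes from the assay
definition; the remaining numeric gates are this package's own operating
points, exposed in :class:`ClassifierParams` and calibrated on the bundled
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .errors import ChannelError, ConfigError
from .segment import CellMask
from .simulate import SmearField

# -- label vocabularies -----------------------------------------------------
SCHEME_FLUOR = "fluorescence"
SCHEME_MGG = "mgg"
SCHEME_DEGRADATION = "degradation"

FLUOR_LABELS = ("MN_POS_RBC", "MN_NEG_RBC", "WBC", "PLATELET", "DEBRIS")
MGG_LABELS = ("MN_NEG_NCE", "MN_POS_NCE", "WBC", "MN_NEG_RET", "MN_POS_RET")
DEGRADATION_LABELS = ("NCE", "WBC", "RET", "ECHINOCYTE", "ELONGATED_RBC")

SCHEMES: dict[str, tuple[str, ...]] = {
    SCHEME_FLUOR: FLUOR_LABELS,
    SCHEME_MGG: MGG_LABELS,
    SCHEME_DEGRADATION: DEGRADATION_LABELS,
}

#: labels for which a micronucleus count is not a meaningful quantity
MN_UNDEFINED_LABELS = frozenset({"WBC", "PLATELET", "DEBRIS"})


@dataclass(frozen=True)
class ClassLabel:
    scheme: str
    label: str

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.label not in SCHEMES[self.scheme]:
            raise ConfigError(
                f"label {self.label!r} not in scheme {self.scheme!r}")


@dataclass
class DnaFocus:
    """One DNA-positive (or purple-staining) focus inside a host cell."""

    host_cell_id: int
    area_um2: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]
    mean_signal: float


@dataclass
class ClassifierParams:
    """Numeric gates of the rule-based classifier."""

    # focus detection
    mn_focus_area_range_um2: tuple[float, float] = (0.2, 6.0)
    dna_signal_min: float = 0.35          # fluorescence DNA channel threshold
    purple_score_min: float = 0.22        # MGG purple-chromaticity threshold
    focus_inside_fraction_min: float = 0.5
    # WBC gates
    wbc_dna_area_min_um2: float = 6.0
    wbc_dna_to_cell_ratio_min: float = 0.25
    # platelet / debris gates (fluorescence surrogates)
    platelet_area_max_um2: float = 7.0
    debris_solidity_max: float = 0.70
    # reticulocyte chromatic gate (MGG): mean(B) - mean(R) over the mask
    ret_blue_dominance_min: float = 0.0
    # degradation gates (calibrated on simulated smears: post-separation
    # masks are slightly blunted, which raises echinocyte solidity)
    echinocyte_spicule_min: int = 3
    echinocyte_solidity_max: float = 0.94
    elongated_aspect_ratio_min: float = 2.5

    def __post_init__(self):
        lo, hi = self.mn_focus_area_range_um2
        if not (0 < lo < hi):
            raise ConfigError("mn_focus_area_range_um2 must be ordered and > 0")
        if self.elongated_aspect_ratio_min <= 1:
            raise ConfigError("elongated_aspect_ratio_min must be > 1")
        if not (0 < self.focus_inside_fraction_min <= 1):
            raise ConfigError("focus_inside_fraction_min must be in (0, 1]")


@dataclass
class CellRecord:
    """A classified cell: mask geometry + label + MN count + features."""

    cell_id: int
    label: ClassLabel
    mn_count: int
    area_um2: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]
    solidity: float
    aspect_ratio: float
    dna_area_ratio: float = 0.0
    blue_dominance: float = float("nan")
    morphology: str | None = None
    mn_count_defined: bool = True
    field_id: str = ""
    mask: CellMask | None = dc_field(default=None, repr=False)

    def __post_init__(self):
        if self.label.label.startswith("MN_POS") and self.mn_count < 1:
            raise ConfigError("MN_POS label requires mn_count >= 1")
        if (self.mn_count_defined and self.mn_count >= 1
                and not self.label.label.startswith("MN_POS")):
            raise ConfigError("mn_count >= 1 requires an MN_POS label")


# ---------------------------------------------------------------------------
# feature images
# ---------------------------------------------------------------------------

def dna_signal_image(field: SmearField) -> np.ndarray:
    """Image in which nuclear DNA is bright.

    Fluorescence: the DNA channel directly.  Brightfield MGG: a purple
    chromaticity score, ``(R + B)/2 - G`` — purple Romanowsky-stained
    chromatin is dark in green relative to red and blue, while pink/blue
    cytoplasm and the white background score near zero.
    """
    if "dna" in field.channels:
        return field.channel("dna")
    if all(c in field.channels for c in "RGB"):
        r, g, b = (field.channel(c) for c in "RGB")
        return (r + b) / 2.0 - g
    raise ChannelError(f"no DNA-bearing channel in {field.channels}")


def blue_dominance(field: SmearField, cell: CellMask) -> float:
    """Mean blue-minus-red intensity over the cell mask (MGG only).

    Bluish-grey reticulocytes score positive; salmon-pink NCEs negative.
    """
    b = field.channel("B")
    r = field.channel("R")
    pix = cell.pixels
    return float(b[pix[:, 0], pix[:, 1]].mean() - r[pix[:, 0], pix[:, 1]].mean())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def detect_dna_foci(field: SmearField, cell: CellMask,
                    params: ClassifierParams,
                    ) -> tuple[list[DnaFocus], list[DnaFocus]]:
    """Find DNA-positive foci belonging to one cell.

    Returns ``(foci, large_components)``: components whose area falls in
    ``mn_focus_area_range_um2`` are micronucleus candidates; larger ones
    (candidate leukocyte nuclei) are reported separately.  A component
    straddling the cell boundary counts if at least half its pixels lie
    inside the mask.
    """
    signal = dna_signal_image(field)
    thr = (params.dna_signal_min if "dna" in field.channels
           else params.purple_score_min)
    pad = 3
    m, (r0, c0) = cell.crop_mask(pad=pad)
    crop = signal[r0:r0 + m.shape[0], c0:c0 + m.shape[1]]
    lab, n = ndi.label(crop > thr)
    if n == 0:
        return [], []
    px2 = cell.pixel_size_um ** 2
    lo, hi = params.mn_focus_area_range_um2
    foci: list[DnaFocus] = []
    large: list[DnaFocus] = []
    for sl_idx, sl in enumerate(ndi.find_objects(lab), start=1):
        if sl is None:
            continue
        comp = lab[sl] == sl_idx
        inside = comp & m[sl]
        n_comp = int(comp.sum())
        if inside.sum() / n_comp < params.focus_inside_fraction_min:
            continue
        area = n_comp * px2
        if area < lo:
            continue
        rr, cc = np.nonzero(comp)
        cy = float(rr.mean()) + sl[0].start + r0
        cx = float(cc.mean()) + sl[1].start + c0
        focus = DnaFocus(
            host_cell_id=cell.cell_id,
            area_um2=area,
            equivalent_diameter_um=2.0 * np.sqrt(area / np.pi),
            centroid=(cy, cx),
            mean_signal=float(crop[sl][comp].mean()),
        )
        (foci if area <= hi else large).append(focus)
    return foci, large


def _dna_area_ratio(cell: CellMask, foci, large) -> float:
    total = sum(f.area_um2 for f in foci) + sum(f.area_um2 for f in large)
    return total / cell.area_um2


def classify_cell_fluorescence(cell: CellMask, foci: list[DnaFocus],
                               large_dna_components: list[DnaFocus],
                               params: ClassifierParams,
                               field_id: str = "") -> CellRecord:
    """Assign one of the five Hoechst-modality labels to a retained cell."""
    ratio = _dna_area_ratio(cell, foci, large_dna_components)
    has_dna = bool(foci or large_dna_components)
    if (any(f.area_um2 >= params.wbc_dna_area_min_um2
            for f in large_dna_components + foci)
            or ratio >= params.wbc_dna_to_cell_ratio_min):
        label, mn, defined = "WBC", 0, False
    elif not has_dna and cell.area_um2 < params.platelet_area_max_um2:
        label, mn, defined = "PLATELET", 0, False
    elif not has_dna and cell.solidity < params.debris_solidity_max:
        label, mn, defined = "DEBRIS", 0, False
    elif foci:
        label, mn, defined = "MN_POS_RBC", len(foci), True
    else:
        label, mn, defined = "MN_NEG_RBC", 0, True
    return CellRecord(
        cell_id=cell.cell_id, label=ClassLabel(SCHEME_FLUOR, label),
        mn_count=mn, mn_count_defined=defined,
        area_um2=cell.area_um2,
        equivalent_diameter_um=cell.equivalent_diameter_um,
        centroid=cell.centroid, solidity=cell.solidity,
        aspect_ratio=cell.aspect_ratio, dna_area_ratio=ratio,
        field_id=field_id, mask=cell)


def classify_cell_mgg(cell: CellMask, foci: list[DnaFocus],
                      large_dna_components: list[DnaFocus],
                      blue_dominance_index: float,
                      params: ClassifierParams,
                      field_id: str = "") -> CellRecord:
    """Assign one of the five MGG-modality labels to a retained cell."""
    ratio = _dna_area_ratio(cell, foci, large_dna_components)
    if (any(f.area_um2 >= params.wbc_dna_area_min_um2
            for f in large_dna_components + foci)
            or ratio >= params.wbc_dna_to_cell_ratio_min):
        label, mn, defined = "WBC", 0, False
    else:
        is_ret = blue_dominance_index >= params.ret_blue_dominance_min
        pos = len(foci) >= 1
        if is_ret:
            label = "MN_POS_RET" if pos else "MN_NEG_RET"
        else:
            label = "MN_POS_NCE" if pos else "MN_NEG_NCE"
        mn, defined = (len(foci) if pos else 0), True
    return CellRecord(
        cell_id=cell.cell_id, label=ClassLabel(SCHEME_MGG, label),
        mn_count=mn, mn_count_defined=defined,
        area_um2=cell.area_um2,
        equivalent_diameter_um=cell.equivalent_diameter_um,
        centroid=cell.centroid, solidity=cell.solidity,
        aspect_ratio=cell.aspect_ratio, dna_area_ratio=ratio,
        blue_dominance=blue_dominance_index,
        field_id=field_id, mask=cell)


def count_spicules(cell: CellMask, n_bins: int = 180,
                   smooth_bins: int = 7) -> int:
    """Count membrane spicules from the angular boundary-radius profile.

    The boundary contour is binned by polar angle around the centroid; the
    per-bin maximum radius gives a circular profile that is smoothed (to
    suppress single-pixel boundary jitter) and whose prominent peaks are
    counted as spicule tips.
    """
    contour = cell.contour
    cy, cx = cell.centroid
    dy = contour[:, 0] - cy
    dx = contour[:, 1] - cx
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    prof = np.full(n_bins, -np.inf)
    np.maximum.at(prof, bins, rad)
    # fill empty bins by nearest-neighbour interpolation on the circle
    empty = ~np.isfinite(prof)
    if empty.all():
        return 0
    if empty.any():
        idx = np.arange(n_bins)
        prof[empty] = np.interp(idx[empty], idx[~empty], prof[~empty],
                                period=n_bins)
    if smooth_bins > 1:
        prof = ndi.uniform_filter1d(prof, smooth_bins, mode="wrap")
    mean_r = prof.mean()
    if mean_r <= 0:
        return 0
    # pad both ends with the opposite quarter so seam peaks are found once
    q = n_bins // 4
    wrapped = np.concatenate([prof[-q:], prof, prof[:q]])
    peaks, _ = find_peaks(wrapped, prominence=0.10 * mean_r)
    peaks = peaks[(peaks >= q) & (peaks < q + n_bins)]
    return int(len(peaks))


def classify_morphology(cell: CellMask, params: ClassifierParams) -> str | None:
    """Degradation-morphology label, or ``None`` if the shape is unremarkable.

    Elongation (aspect ratio above the 2.5 gate) takes precedence over
    crenation; an echinocyte call requires both enough boundary spicules and
    solidity below the smooth-disc ceiling.
    """
    if cell.aspect_ratio > params.elongated_aspect_ratio_min:
        return "ELONGATED_RBC"
    if (cell.solidity <= params.echinocyte_solidity_max
            and count_spicules(cell) >= params.echinocyte_spicule_min):
        return "ECHINOCYTE"
    return None


def degradation_label(record: CellRecord, params: ClassifierParams) -> str:
    """Map an MGG cell record into the five-class degradation scheme."""
    if record.label.label == "WBC":
        return "WBC"
    morph = record.morphology
    if morph in ("ELONGATED_RBC", "ECHINOCYTE"):
        return morph
    if record.label.label.endswith("RET"):
        return "RET"
    return "NCE"
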