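"""End-to-end orchestration: fields in, frequencies and QC out.

Stage order is fixed: segment → exclude WBC/platelet masks → separate
juxtaposed cells → size filter → classify → quantify.  Every object that
leaves the pipeline is tallied with a reason, so the accounting identity

    cells_detected = cells_retained + Σ excluded_by_reason

holds per field and per sample, and can be audited from the report alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field

from . import __version__
from .classify import (ClassifierParams, classify_cell_fluorescence,
                       classify_cell_mgg, classify_morphology,
                       blue_dominance, detect_dna_foci)
from .errors import ConfigError
from .io import config_hash, read_field
from .quantify import (FrequencyResult, SampleCounts, frequency,
                       multi_mn_frequency, qc_evaluable, QC_PASS,
                       MIN_EVALUABLE_RBC, NON_RBC_LABELS)
from .segment import (CellMask, SegmentationParams, apply_exclusion_masks,
                      filter_by_size, segment_cell_bodies,
                      separate_juxtaposed)
from .simulate import (MODALITY_FLUORESCENCE, SimulationConfig, SmearField,
                       simulate_sample)

log = logging.getLogger("mnscore.pipeline")

EXCLUSION_REASONS = ("wbc_mask", "platelet_mask", "eroded_empty",
                     "size_below", "size_above", "border")


@dataclass
class PipelineConfig:
    """Everything one scoring run needs.

    Exactly one of ``simulation`` (generate fields in memory) or
    ``input_paths`` (read TIFF fields from disk) must be set.
    """

    modality: str = MODALITY_FLUORESCENCE
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    classifier: ClassifierParams = dc_field(default_factory=ClassifierParams)
    min_rbc: int = MIN_EVALUABLE_RBC
    simulation: SimulationConfig | None = None
    n_fields: int = 1
    input_paths: list[str] | None = None
    degradation_pass: bool = False
    sample_id: str = "sample"
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.input_paths is None):
            raise ConfigError(
                "exactly one of simulation / input_paths must be set")
        if self.simulation is not None and self.n_fields < 1:
            raise ConfigError("n_fields must be >= 1")
        if self.min_rbc < 0:
            raise ConfigError("min_rbc must be >= 0")


@dataclass
class FieldResult:
    field_id: str
    records: list
    detected: int
    retained: int
    excluded: dict[str, int]


@dataclass
class SampleReport:
    """Per-sample scoring summary; frequencies withheld when QC fails."""

    sample_id: str
    modality: str
    counts: SampleCounts
    frequencies: dict[str, FrequencyResult]
    qc_status: str
    evaluable_rbc: int
    detected: int
    retained: int
    excluded: dict[str, int]
    config_hash: str
    seed: int
    version: str = __version__
    records: list = dc_field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        freqs = {
            name: {"numerator": f.numerator, "denominator": f.denominator,
                   "value_percent": f.value_percent}
            for name, f in self.frequencies.items()
        }
        return {
            "sample_id": self.sample_id,
            "modality": self.modality,
            "counts": {k: int(v) for k, v in sorted(self.counts.counts.items())},
            "frequencies": freqs,
            "qc_status": self.qc_status,
            "evaluable_rbc": self.evaluable_rbc,
            "cells_detected": self.detected,
            "cells_retained": self.retained,
            "excluded_by_reason": {k: int(self.excluded.get(k, 0))
                                   for k in EXCLUSION_REASONS},
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
        }


def _prepass_exclusions(field: SmearField, cells: list[CellMask],
                        clf: ClassifierParams, seg: SegmentationParams,
                        ) -> tuple[list[CellMask], list[CellMask]]:
    """Identify WBC and platelet masks among raw components.

    WBC: carries a nuclear-scale DNA (or purple) component, or is DNA-dense.
    Platelet: below the cell-size floor with no DNA signal at all.
    """
    wbc, platelet = [], []
    for cell in cells:
        foci, large = detect_dna_foci(field, cell, clf)
        dna_area = sum(f.area_um2 for f in foci) + sum(f.area_um2 for f in large)
        if (any(f.area_um2 >= clf.wbc_dna_area_min_um2 for f in large + foci)
                or dna_area / cell.area_um2 >= clf.wbc_dna_to_cell_ratio_min):
            wbc.append(cell)
        elif not foci and not large and cell.area_um2 < clf.platelet_area_max_um2:
            platelet.append(cell)
    return wbc, platelet


def process_field(field: SmearField, modality: str,
                  seg: SegmentationParams, clf: ClassifierParams,
                  degradation_pass: bool = False) -> FieldResult:
    """Run the full per-field chain and classify every retained cell."""
    raw = segment_cell_bodies(field, seg)
    wbc_masks, platelet_masks = _prepass_exclusions(field, raw, clf, seg)
    after_excl, _removed = apply_exclusion_masks(
        raw, wbc_masks + platelet_masks)
    n_wbc_excluded = sum(1 for c in _removed
                         if any(c is w for w in wbc_masks))
    n_plt_excluded = len(_removed) - n_wbc_excluded

    separated, n_eroded = separate_juxtaposed(after_excl, seg,
                                              field.pixel_size_um)
    retained, size_tally = filter_by_size(separated, seg)

    detected = len(separated) + n_eroded + len(_removed)
    excluded = {
        "wbc_mask": n_wbc_excluded,
        "platelet_mask": n_plt_excluded,
        "eroded_empty": n_eroded,
        "size_below": size_tally["below"],
        "size_above": size_tally["above"],
        "border": size_tally["border"],
    }

    records = []
    for cell in retained:
        foci, large = detect_dna_foci(field, cell, clf)
        if modality == MODALITY_FLUORESCENCE:
            rec = classify_cell_fluorescence(cell, foci, large, clf,
                                             field_id=field.field_id)
        else:
            bd = blue_dominance(field, cell)
            rec = classify_cell_mgg(cell, foci, large, bd, clf,
                                    field_id=field.field_id)
        if degradation_pass and rec.label.label != "WBC":
            rec.morphology = classify_morphology(cell, clf)
        records.append(rec)

    log.info("%s: detected=%d retained=%d excluded=%s",
             field.field_id, detected, len(retained), excluded)
    return FieldResult(field_id=field.field_id, records=records,
                       detected=detected, retained=len(retained),
                       excluded=excluded)


def _sample_frequencies(modality: str, records, counts: SampleCounts,
                        degradation_pass: bool) -> dict[str, FrequencyResult]:
    freqs: dict[str, FrequencyResult] = {}
    if modality == MODALITY_FLUORESCENCE:
        freqs["MN_POS_RBC"] = frequency(
            counts.get("MN_POS_RBC"), counts.get("MN_NEG_RBC"), "MN⁺-RBC")
    else:
        nce_pos, nce_neg = counts.get("MN_POS_NCE"), counts.get("MN_NEG_NCE")
        ret_pos, ret_neg = counts.get("MN_POS_RET"), counts.get("MN_NEG_RET")
        freqs["MN_POS_NCE"] = frequency(nce_pos, nce_neg, "MN⁺-NCE")
        if ret_pos + ret_neg > 0:
            freqs["MN_POS_RET"] = frequency(ret_pos, ret_neg, "MN⁺-RET")
        freqs["RET"] = frequency(ret_pos + ret_neg, nce_pos + nce_neg, "RET")
    freqs["MULTI_MN"] = multi_mn_frequency(records)
    if degradation_pass:
        rbc = [r for r in records if r.label.label not in NON_RBC_LABELS]
        ech = sum(1 for r in rbc if r.morphology == "ECHINOCYTE")
        elo = sum(1 for r in rbc if r.morphology == "ELONGATED_RBC")
        freqs["ECHINOCYTE"] = frequency(ech, len(rbc) - ech, "echinocyte")
        freqs["ELONGATED"] = frequency(elo, len(rbc) - elo, "elongated")
    return freqs


def run_pipeline(config: PipelineConfig) -> SampleReport:
    """Score one sample end to end; deterministic for a fixed config."""
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed,
                                  modality=config.modality)
        fields, _truth = simulate_sample(sim, config.n_fields)
    else:
        fields = [read_field(p) for p in config.input_paths]
        if not fields:
            raise ConfigError("input_paths is empty")

    all_records = []
    detected = retained = 0
    excluded = {k: 0 for k in EXCLUSION_REASONS}
    for field in fields:
        fr = process_field(field, config.modality, config.segmentation,
                           config.classifier, config.degradation_pass)
        all_records.extend(fr.records)
        detected += fr.detected
        retained += fr.retained
        for k, v in fr.excluded.items():
            excluded[k] += v

    counts = SampleCounts.from_records(all_records)
    qc = qc_evaluable(counts, config.min_rbc)
    freqs = (_sample_frequencies(config.modality, all_records, counts,
                                 config.degradation_pass)
             if qc == QC_PASS else {})

    return SampleReport(
        sample_id=config.sample_id, modality=config.modality,
        counts=counts, frequencies=freqs, qc_status=qc,
        evaluable_rbc=counts.evaluable_rbc,
        detected=detected, retained=retained, excluded=excluded,
        config_hash=config_hash(config), seed=config.seed,
        records=all_records)
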