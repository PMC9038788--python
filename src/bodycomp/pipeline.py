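"""End-to-end orchestration: volume in -> QC-gated slice extraction ->
QC-gated tissue segmentation -> body-composition report out.

The bundle couples the two cross-validated ensembles with the QC models that
were fitted on their own cross-validation predictions, so that a deployed
pipeline carries its calibrated uncertainty models with it. Exclusion is
advisory metadata: every input case yields exactly one report, flagged cases
are never dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .imaging import SAT, SM, VAT, CTVolume, CompartmentMask, extract_slice
from .metrics import (BodyCompositionReport, FMFSpec, UndefinedFMF,
                      agreement, aggregate_agreement, compartment_area,
                      fatty_muscle_fraction)
from .quality_control import (DiceModel, PresenceModel, QCDecision, QCPolicy,
                              crop_excluding_disk, fit_dice_model,
                              fit_presence, mean_entropy, predict_dice,
                              qc_decide, restrictive_exclusion)
from .slice_extraction import (ExtractorConfig, ExtractorEnsemble,
                               LabelMapSpec, delta_z, predict_disk,
                               train_extractor)
from .tissue_segmentation import (CDFNetConfig, SegmenterEnsemble, dice,
                                  segment_slice, train_segmenter)
from . import nets, slice_extraction as _sx

__all__ = [
    "PipelineBundle",
    "build_bundle",
    "run_case",
    "evaluate_cohort",
    "config_hash",
    "load_yaml_config",
]


def config_hash(*objs) -> str:
    """Stable hash of the dataclass configs a bundle was built from."""
    blob = json.dumps([dataclasses.asdict(o) if dataclasses.is_dataclass(o)
                       else o for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_yaml_config(path: str) -> dict:
    """Read the single YAML file covering all module configurations."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    out = {}
    ec = dict(raw.get("extractor", {}))
    for k in ("target_spacing", "patch_size", "clip_hu"):
        if k in ec:
            ec[k] = tuple(ec[k])
    out["extractor"] = ExtractorConfig(**ec)
    out["label_map"] = LabelMapSpec(**raw.get("label_map", {}))
    sc = dict(raw.get("segmenter", {}))
    for k in ("input_size", "clip_hu"):
        if k in sc:
            sc[k] = tuple(sc[k])
    out["segmenter"] = CDFNetConfig(**sc)
    fm = dict(raw.get("fmf", {}))
    if "fat_hu_range" in fm:
        fm["fat_hu_range"] = tuple(fm["fat_hu_range"])
    out["fmf"] = FMFSpec(**fm)
    out["qc_policy"] = QCPolicy(**raw.get("qc_policy", {}))
    return out


@dataclass
class PipelineBundle:
    """Everything a deployment needs: both ensembles, both QC models, specs."""

    extractor: ExtractorEnsemble
    segmenter: SegmenterEnsemble
    presence: PresenceModel
    dice_model: DiceModel
    fmf_spec: FMFSpec = field(default_factory=FMFSpec)
    policy: QCPolicy = field(default_factory=QCPolicy)
    config_hash: str = ""

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.extractor.save(os.path.join(outdir, "extractor"))
        self.segmenter.save(os.path.join(outdir, "segmenter"))
        meta = {
            "presence": dataclasses.asdict(self.presence),
            "dice_model": dataclasses.asdict(self.dice_model),
            "fmf_spec": dataclasses.asdict(self.fmf_spec),
            "policy": dataclasses.asdict(self.policy),
            "config_hash": self.config_hash,
        }
        with open(os.path.join(outdir, "bundle.json"), "w") as f:
            json.dump(meta, f, indent=1)

    @classmethod
    def load(cls, outdir: str) -> "PipelineBundle":
        with open(os.path.join(outdir, "bundle.json")) as f:
            meta = json.load(f)
        dm = meta["dice_model"]
        dm["ci_intercept"] = tuple(dm["ci_intercept"])
        dm["ci_slope"] = tuple(dm["ci_slope"])
        fm = meta["fmf_spec"]
        fm["fat_hu_range"] = tuple(fm["fat_hu_range"])
        return cls(
            extractor=ExtractorEnsemble.load(os.path.join(outdir, "extractor")),
            segmenter=SegmenterEnsemble.load(os.path.join(outdir, "segmenter")),
            presence=PresenceModel(**meta["presence"]),
            dice_model=DiceModel(**dm),
            fmf_spec=FMFSpec(**fm),
            policy=QCPolicy(**meta["policy"]),
            config_hash=meta["config_hash"],
        )


def build_bundle(cases, extractor_config: ExtractorConfig | None = None,
                 label_spec: LabelMapSpec | None = None,
                 segmenter_config: CDFNetConfig | None = None,
                 fmf_spec: FMFSpec | None = None,
                 policy: QCPolicy | None = None,
                 crop_margin_mm: float = 10.0) -> PipelineBundle:
    """Train both ensembles on phantom-style cases and fit both QC models.

    ``cases`` is a list of objects exposing ``volume``, ``annotation``,
    ``target_z`` and ``mask_at(z)`` (e.g. :class:`~bodycomp.phantom.PhantomCase`).
    The presence model is fitted on cross-validation blob volumes of the full
    volumes (positives) and their disk-excluding crops (negatives); the Dice
    regressor on cross-validation (entropy, muscle Dice) pairs.
    """
    extractor_config = extractor_config or ExtractorConfig()
    label_spec = label_spec or LabelMapSpec()
    segmenter_config = segmenter_config or CDFNetConfig()
    fmf_spec = fmf_spec or FMFSpec()
    policy = policy or QCPolicy()

    vol_ann = [(c.volume, c.annotation) for c in cases]
    extractor = train_extractor(vol_ann, extractor_config, label_spec)

    # presence QC: positives = CV blob volumes; negatives = blob volumes of
    # the disk-excluding crops, each predicted by the case's held-out model
    volumes_ml, labels = [], []
    for rec in extractor.val_records:
        volumes_ml.append(rec["blob_volume_ml"])
        labels.append(1)
    for i, c in enumerate(cases):
        crop = crop_excluding_disk(c.volume, c.annotation, crop_margin_mm,
                                   rng_seed=extractor_config.seed + i)
        net = extractor.models[extractor.fold_of_case[i]]
        norm, spc, _ = _sx._prep_case(crop, extractor_config)
        probs = nets.sliding_window_probs(net, norm, tuple(extractor_config.patch_size))
        blob = _sx.largest_component(probs[1] >= 0.5)
        volumes_ml.append(float(blob.sum() * np.prod(spc) / 1000.0))
        labels.append(0)
    presence = fit_presence(volumes_ml, labels)

    samples = [(extract_slice(c.volume, c.target_z), c.mask_at(c.target_z))
               for c in cases]
    segmenter = train_segmenter(samples, segmenter_config)
    pairs = [(mean_entropy(rec["prob"], class_code=SM), rec["dice_sm"])
             for rec in segmenter.val_records]
    dice_model = fit_dice_model(pairs)

    return PipelineBundle(
        extractor=extractor, segmenter=segmenter, presence=presence,
        dice_model=dice_model, fmf_spec=fmf_spec, policy=policy,
        config_hash=config_hash(extractor_config, label_spec, segmenter_config,
                                fmf_spec, policy),
    )


def run_case(bundle: PipelineBundle, volume: CTVolume) -> BodyCompositionReport:
    """Run the full pipeline on one volume.

    An absent-level QC verdict short-circuits segmentation; a report is
    always produced with the exclusion flag and reason populated. Under the
    cohort QC policy, ``excluded`` for low predicted Dice is decided later at
    cohort level (see :func:`evaluate_cohort`); the per-case report then
    carries the predicted Dice with ``reason='none'``.
    """
    stages = ["slice_extraction"]
    res = predict_disk(bundle.extractor, volume)
    presence_prob = float(bundle.presence.predict_proba(res.blob_volume_ml))
    stages.append("presence_qc")
    prov = {"config_hash": bundle.config_hash,
            "blob_volume_ml": res.blob_volume_ml}

    if presence_prob < bundle.policy.presence_threshold or not res.detected:
        qc = QCDecision(presence_prob=presence_prob, presence_flag=True,
                        predicted_dice_sm=None, excluded=True,
                        reason="absent_level")
        prov["stages"] = stages
        return BodyCompositionReport(
            patient_id=volume.patient_id, z_index=None, z_mm=None,
            area_sm_cm2=None, area_vat_cm2=None, area_sat_cm2=None,
            fmf=None, qc=qc, provenance=prov)

    sl = extract_slice(volume, res.z_index)
    stages.append("tissue_segmentation")
    seg = segment_slice(bundle.segmenter, sl)
    stages.append("segmentation_qc")
    ent = mean_entropy(seg.prob, class_code=SM)
    pdice = predict_dice(bundle.dice_model, ent)
    qc = qc_decide(presence_prob, pdice, bundle.policy,
                   in_excluded_decile=False)

    area_sm = compartment_area(seg.mask, SM)
    area_vat = compartment_area(seg.mask, VAT)
    area_sat = compartment_area(seg.mask, SAT)
    try:
        fmf = fatty_muscle_fraction(sl, seg.mask, bundle.fmf_spec)
    except UndefinedFMF:
        fmf = None
    prov["stages"] = stages
    prov["mean_entropy_sm"] = ent
    return BodyCompositionReport(
        patient_id=volume.patient_id, z_index=res.z_index, z_mm=res.z_mm,
        area_sm_cm2=area_sm, area_vat_cm2=area_vat, area_sat_cm2=area_sat,
        fmf=fmf, qc=qc, provenance=prov)


@dataclass
class CohortReport:
    """Per-case reports plus cohort-level summaries, stratified by QC."""

    reports: list
    per_case_agreement: dict
    summary: dict

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.reports:
            d = r.to_dict()
            d.pop("provenance", None)
            rows.append(d)
        return pd.DataFrame(rows, columns=[
            "patient_id", "z_index", "z_mm", "area_sm_cm2", "area_vat_cm2",
            "area_sat_cm2", "fmf", "presence_prob", "predicted_dice_sm",
            "excluded", "reason"])


def evaluate_cohort(bundle: PipelineBundle, cases) -> CohortReport:
    """Run the pipeline on a cohort and evaluate against its ground truth.

    ``cases`` expose ``volume``, ``annotation``, ``metadata`` (reference
    areas/FMF) and ``mask_at(z)``. Applies the restrictive cohort exclusion
    to the predicted muscle Dice, then reports z-deviation tolerance
    accuracies, per-class Dice at the predicted slice, and agreement with the
    reference values stratified by QC status.
    """
    if not cases:
        raise ValueError("empty cohort")
    reports = [run_case(bundle, c.volume) for c in cases]

    if bundle.policy.mode == "cohort_decile":
        pool = {r.patient_id: r.qc.predicted_dice_sm for r in reports
                if r.qc.predicted_dice_sm is not None}
        excluded_ids = restrictive_exclusion(pool, bundle.policy.fraction) if pool else set()
        for r in reports:
            if r.patient_id in excluded_ids:
                r.qc = QCDecision(presence_prob=r.qc.presence_prob,
                                  presence_flag=r.qc.presence_flag,
                                  predicted_dice_sm=r.qc.predicted_dice_sm,
                                  excluded=True, reason="low_predicted_dice")

    per_case_agreement = {}
    dz_list, hits = [], {"0mm": [], "5mm": [], "10mm": []}
    dice_rows = []
    for case, rep in zip(cases, reports):
        ref = {
            "area_sm_cm2": case.metadata.get("true_area_sm_cm2"),
            "area_vat_cm2": case.metadata.get("true_area_vat_cm2"),
            "area_sat_cm2": case.metadata.get("true_area_sat_cm2"),
            "fmf": case.metadata.get("true_fmf"),
        }
        per_case_agreement[rep.patient_id] = agreement(rep, ref)
        pseudo = None
        if rep.z_index is not None:
            pseudo = _PredStub(rep.z_index, rep.z_mm)
        dzr = delta_z(pseudo, case.annotation, case.volume)
        if dzr.delta_mm is not None:
            dz_list.append(dzr.delta_mm)
        hits["0mm"].append(dzr.hit_0mm)
        hits["5mm"].append(dzr.hit_5mm)
        hits["10mm"].append(dzr.hit_10mm)
        if rep.z_index is not None:
            gt_mask = case.mask_at(rep.z_index)
            sl = extract_slice(case.volume, rep.z_index)
            seg = segment_slice(bundle.segmenter, sl)
            dice_rows.append({
                "patient_id": rep.patient_id,
                "dice_sm": dice(seg.mask, gt_mask, SM),
                "dice_vat": dice(seg.mask, gt_mask, VAT),
                "dice_sat": dice(seg.mask, gt_mask, SAT),
                "excluded": rep.qc.excluded,
            })

    def _ms(vals):
        vals = list(vals)
        if not vals:
            return {"mean": None, "sd": None, "n": 0}
        return {"mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals)}

    passed = [per_case_agreement[r.patient_id] for r in reports if not r.qc.excluded]
    excl = [per_case_agreement[r.patient_id] for r in reports if r.qc.excluded]
    summary = {
        "n": len(cases),
        "n_passed": sum(not r.qc.excluded for r in reports),
        "n_excluded": sum(r.qc.excluded for r in reports),
        "delta_z_mm": _ms(dz_list),
        "accuracy_0mm": float(np.mean(hits["0mm"])),
        "accuracy_5mm": float(np.mean(hits["5mm"])),
        "accuracy_10mm": float(np.mean(hits["10mm"])),
        "dice_sm": _ms([d["dice_sm"] for d in dice_rows]),
        "dice_vat": _ms([d["dice_vat"] for d in dice_rows]),
        "dice_sat": _ms([d["dice_sat"] for d in dice_rows]),
        "dice_sm_passed": _ms([d["dice_sm"] for d in dice_rows if not d["excluded"]]),
        "dice_sm_excluded": _ms([d["dice_sm"] for d in dice_rows if d["excluded"]]),
        "agreement_passed": aggregate_agreement(passed) if passed else None,
        "agreement_excluded": aggregate_agreement(excl) if excl else None,
    }
    return CohortReport(reports=reports, per_case_agreement=per_case_agreement,
                        summary=summary)


class _PredStub:
    """Minimal prediction view for delta_z from a finished report."""

    def __init__(self, z_index, z_mm):
        self.z_index = z_index
        self.z_mm = z_mm
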